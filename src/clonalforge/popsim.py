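"""Stochastic serial-transfer batch-culture simulator.

Models an adaptive-laboratory-evolution (ALE) protocol for *E. coli*:
repeated batch growth from OD600 ~0.004 to ~0.5 (~7 doublings in 5 mL,
i.e. ~1.6e6 -> ~2e8 cells) followed by a 1:125 dilution bottleneck.
Within a growth phase the population is advanced in discrete baseline
generations; each generation applies, in order,

1. mutation supply (Poisson draws of new single-allele mutants, with an
   inducible mutator multiplier),
2. conjugative recombination ("genderless" mating: every cell is both
   donor and recipient; a contiguous chromosomal segment starting at an
   oriT anchor is transferred, with co-transfer probability of a locus
   at distance d decaying as exp(-d/L)),
3. genotype-specific exponential doubling, optionally attenuated by a
   Hill-type drug dose-response.

The four classic regimes (+/- mutator x +/- recombination) are realized
by toggling the mutation-rate multiplier and the conjugation step.

All randomness flows through a single ``numpy.random.Generator`` so runs
are bit-reproducible from their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "DOUBLINGS_PER_HOUR_BASELINE",
    "CELLS_PER_OD_PER_ML",
    "DEFAULT_CHROMOSOME_BP",
    "WILD_TYPE",
    "PopulationExtinct",
    "MutationAllele",
    "TransferProtocol",
    "ConjugationParams",
    "HillDrugResponse",
    "PopulationState",
    "StrainModel",
    "grow_population",
    "apply_mutation",
    "apply_conjugation",
    "serial_transfer",
    "run_evolution",
    "ScenarioConfig",
    "EvolutionTrajectory",
    "TransferRecord",
]

#: Growth-rate threshold of the ramping protocol: 7 generations in 12 h.
DOUBLINGS_PER_HOUR_BASELINE = 7.0 / 12.0

#: Calibration constant: OD600 0.004 in 5 mL corresponds to ~1.6e6 cells,
#: and the OD ~0.5 growth stop to ~2e8 cells.
CELLS_PER_OD_PER_ML = 8.0e7

#: E. coli BW25113 chromosome length (circular).
DEFAULT_CHROMOSOME_BP = 4_631_469

GenotypeKey = frozenset
WILD_TYPE: GenotypeKey = frozenset()


class PopulationExtinct(RuntimeError):
    """Raised when a population can no longer grow or is fully diluted away."""


@dataclass(frozen=True)
class MutationAllele:
    """A single tracked mutation.

    Parameters
    ----------
    id:
        Short label, e.g. ``"glpK288"``.
    gene:
        Gene the mutation falls in.
    position_bp:
        0-based coordinate on the circular chromosome.
    fitness_delta:
        Additive improvement to relative growth rate (0.35 = +35%).
    tolerance_factor:
        Multiplicative increase of the drug-tolerance parameter (1 = none).
    """

    id: str
    gene: str
    position_bp: int
    fitness_delta: float
    tolerance_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError(f"allele {self.id}: position_bp must be >= 0")
        if self.fitness_delta <= -1:
            raise ValueError(f"allele {self.id}: fitness_delta must be > -1")
        if self.tolerance_factor <= 0:
            raise ValueError(f"allele {self.id}: tolerance_factor must be > 0")


@dataclass(frozen=True)
class TransferProtocol:
    """Serial-transfer protocol: dilution target and growth stop.

    Defaults correspond to the OD 0.004 inoculum / OD ~0.5 stop in 5 mL:
    1.6e6 cells diluted 1:125 from a 2e8-cell culture, ~7 generations
    per transfer. ``max_generations`` bounds a growth phase (12 h at the
    baseline rate); populations that cannot reach the stop density in
    that window are transferred anyway, as in the bench protocol.
    """

    inoculum_fraction: float = 0.008
    stop_cells: float = 2.0e8
    max_generations: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.inoculum_fraction < 1:
            raise ValueError("inoculum_fraction must be in (0, 1)")
        if self.stop_cells <= 0:
            raise ValueError("stop_cells must be > 0")

    @property
    def start_cells(self) -> float:
        return self.inoculum_fraction * self.stop_cells

    @property
    def generations_per_transfer(self) -> float:
        return math.log2(1.0 / self.inoculum_fraction)


@dataclass(frozen=True)
class ConjugationParams:
    """Mass-action conjugation parameters.

    ``gamma`` has units mL / (cell * h) and acts on the donor x recipient
    density product. ``cotransfer_length_bp`` is the mean of the
    exponential transferred-segment length, so an allele at distance d
    downstream of an oriT anchor co-transfers with probability
    exp(-d / cotransfer_length_bp).
    """

    gamma: float
    cotransfer_length_bp: float = 1.0e5
    enabled: bool = True
    oriT_positions: tuple = (0,)

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.cotransfer_length_bp <= 0:
            raise ValueError("cotransfer_length_bp must be > 0")
        if len(self.oriT_positions) == 0:
            raise ValueError("at least one oriT position is required")


class HillDrugResponse:
    """Hill-type growth attenuation: rate factor 1 / (1 + (C/tol)^h).

    Half-maximal at C = tolerance; h defaults to 4 (steep, but finite).
    """

    def __init__(self, hill_coefficient: float = 4.0):
        if hill_coefficient <= 0:
            raise ValueError("hill_coefficient must be > 0")
        self.hill_coefficient = hill_coefficient

    def factor(self, conc: float, tolerance: float) -> float:
        if conc < 0:
            raise ValueError("drug concentration must be >= 0")
        if conc == 0:
            return 1.0
        return 1.0 / (1.0 + (conc / tolerance) ** self.hill_coefficient)


@dataclass
class PopulationState:
    """Genotype census of one batch culture plus its environment.

    ``counts`` maps genotype (frozenset of allele ids) to cell count.
    Counts are kept integral after every stochastic step; deterministic
    growth may hold fractional expectations in between.
    """

    counts: dict
    drug_conc: float = 0.0
    mutator_on: bool = False
    mutation_rate_multiplier: float = 20.0
    generations_elapsed: float = 0.0

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def frequencies(self) -> dict:
        n = self.total()
        if n <= 0:
            raise PopulationExtinct("population empty")
        return {g: c / n for g, c in self.counts.items()}

    def allele_frequencies(self) -> dict:
        n = self.total()
        freqs: dict = {}
        for g, c in self.counts.items():
            for a in g:
                freqs[a] = freqs.get(a, 0.0) + c
        return {a: c / n for a, c in freqs.items()}


class StrainModel:
    """Maps allele sets to growth phenotype (rate, drug tolerance).

    Growth rate defaults to ``base * (1 + sum fitness_delta)`` (additive);
    a ``fitness_overrides`` mapping (allele-id set -> improvement over
    wild type) injects measured combination fitnesses, e.g. from a
    reconstructed-mutant fitness table, including epistasis.
    """

    def __init__(
        self,
        alleles: Iterable[MutationAllele],
        base_growth_rate: float = DOUBLINGS_PER_HOUR_BASELINE,
        base_tolerance: float = 1.0,
        chromosome_bp: int = DEFAULT_CHROMOSOME_BP,
        fitness_overrides: Mapping | None = None,
    ):
        self.alleles = {}
        for a in alleles:
            if a.id in self.alleles:
                raise ValueError(f"duplicate allele id {a.id!r}")
            if a.position_bp >= chromosome_bp:
                raise ValueError(f"allele {a.id} position beyond chromosome")
            self.alleles[a.id] = a
        if base_growth_rate <= 0:
            raise ValueError("base_growth_rate must be > 0")
        self.base_growth_rate = base_growth_rate
        self.base_tolerance = base_tolerance
        self.chromosome_bp = chromosome_bp
        self.fitness_overrides = (
            {frozenset(k): float(v) for k, v in fitness_overrides.items()}
            if fitness_overrides
            else {}
        )
        self._rate_cache: dict = {}
        self._tol_cache: dict = {}
        self._mating_cache: dict = {}

    def allele(self, allele_id: str) -> MutationAllele:
        return self.alleles[allele_id]

    def relative_fitness(self, genotype: GenotypeKey) -> float:
        """Growth rate relative to wild type (wild type = 1)."""
        if genotype in self.fitness_overrides:
            return 1.0 + self.fitness_overrides[genotype]
        return 1.0 + sum(self.alleles[a].fitness_delta for a in genotype)

    def growth_rate(self, genotype: GenotypeKey) -> float:
        """Doublings per hour of a genotype in drug-free medium."""
        r = self._rate_cache.get(genotype)
        if r is None:
            r = self.base_growth_rate * self.relative_fitness(genotype)
            if r <= 0:
                raise ValueError(f"non-positive growth rate for {set(genotype)}")
            self._rate_cache[genotype] = r
        return r

    def tolerance(self, genotype: GenotypeKey) -> float:
        t = self._tol_cache.get(genotype)
        if t is None:
            t = self.base_tolerance
            for a in genotype:
                t *= self.alleles[a].tolerance_factor
            self._tol_cache[genotype] = t
        return t

    def circular_distance(self, position_bp: int, anchor_bp: int) -> int:
        """Transfer distance from anchor, measured in transfer direction."""
        return (position_bp - anchor_bp) % self.chromosome_bp


def _effective_rates(state: PopulationState, model: StrainModel, drug: HillDrugResponse) -> dict:
    return {
        g: model.growth_rate(g) * drug.factor(state.drug_conc, model.tolerance(g))
        for g in state.counts
    }


def _double_once(state: PopulationState, model: StrainModel, drug: HillDrugResponse) -> PopulationState:
    """Advance one baseline generation of deterministic exponential growth.

    Each genotype multiplies by 2^(r_eff / r_baseline).
    """
    rates = _effective_rates(state, model, drug)
    counts = {
        g: c * 2.0 ** (rates[g] / model.base_growth_rate)
        for g, c in state.counts.items()
    }
    return replace(state, counts=counts, generations_elapsed=state.generations_elapsed + 1)


def grow_population(
    state: PopulationState,
    protocol: TransferProtocol,
    model: StrainModel,
    drug: HillDrugResponse | None = None,
) -> PopulationState:
    """Grow a batch culture in discrete generation steps until the stop
    density is reached or the 12-h window (``max_generations``) elapses.

    Pure growth: no mutation or mating sub-steps (see :func:`run_evolution`
    for the interleaved protocol).
    """
    drug = drug if drug is not None else HillDrugResponse()
    if state.total() < 1:
        raise PopulationExtinct("no viable cells at start of growth")
    rates = _effective_rates(state, model, drug)
    if all(r <= 0 for r in rates.values()):
        raise PopulationExtinct("all effective growth rates <= 0")
    out = state
    gens = 0
    while out.total() < protocol.stop_cells and gens < protocol.max_generations:
        out = _double_once(out, model, drug)
        gens += 1
    return out


def apply_mutation(
    state: PopulationState,
    supply: Sequence[MutationAllele],
    base_rate: float,
    rng: np.random.Generator,
) -> PopulationState:
    """One generation of mutation supply.

    Each genotype emits new single-allele mutants for every supply allele
    it does not already carry, with Poisson expectation
    ``count * base_rate * multiplier`` per allele (``base_rate`` is the
    per-cell, per-generation probability of acquiring one specific
    allele). Re-mutation to an allele already present is a no-op.
    """
    if base_rate < 0:
        raise ValueError("base_rate must be >= 0")
    if base_rate > 1:
        raise ValueError("base_rate is a probability, must be <= 1")
    if base_rate == 0 or not supply:
        return state

    mult = state.mutation_rate_multiplier if state.mutator_on else 1.0
    genos = list(state.counts)
    counts = np.array([state.counts[g] for g in genos], dtype=float)
    n_a = len(supply)
    lam = np.tile(counts[:, None], (1, n_a)) * base_rate * mult
    # mask alleles already carried
    for i, g in enumerate(genos):
        for j, a in enumerate(supply):
            if a.id in g:
                lam[i, j] = 0.0
    draws = rng.poisson(lam)

    new_counts = dict(state.counts)
    for i, g in enumerate(genos):
        emitted = draws[i].sum()
        if emitted == 0:
            continue
        avail = math.floor(new_counts[g])
        if emitted > avail:  # cannot emit more mutants than cells present
            # thin draws proportionally (rare; only at tiny counts)
            keep = rng.multivariate_hypergeometric(draws[i], avail)
            draws[i] = keep
            emitted = avail
        new_counts[g] = new_counts[g] - emitted
        for j, a in enumerate(supply):
            k = int(draws[i, j])
            if k == 0:
                continue
            child = g | {a.id}
            new_counts[child] = new_counts.get(child, 0) + k
    new_counts = {g: c for g, c in new_counts.items() if c > 0}
    return replace(state, counts=new_counts)


def _mating_outcomes(
    model: StrainModel, params: ConjugationParams, donor: GenotypeKey, recipient: GenotypeKey
):
    """Distribution of recombinant genotypes for one donor->recipient mating.

    The transferred segment starts at an oriT anchor (uniform over the
    configured sites) and extends an Exp(cotransfer_length) distance in
    the transfer direction. Alleles of either parent inside the segment
    take the donor's state; the recipient keeps everything outside.
    Returns (outcomes, probabilities); cached per (donor, recipient).
    """
    key = (donor, recipient, params.cotransfer_length_bp, params.oriT_positions)
    cached = model._mating_cache.get(key)
    if cached is not None:
        return cached
    L = params.cotransfer_length_bp
    weight = 1.0 / len(params.oriT_positions)
    agg: dict = {}
    for anchor in params.oriT_positions:
        dist = {
            a: model.circular_distance(model.alleles[a].position_bp, anchor)
            for a in donor | recipient
        }
        cuts = sorted(set(dist.values()))
        edges = cuts + [math.inf]
        lower = [0.0] + cuts  # segment-length intervals [lower, edge)
        for lo, hi in zip(lower, edges):
            prob = math.exp(-lo / L) - (0.0 if math.isinf(hi) else math.exp(-hi / L))
            if prob <= 0:
                continue
            # a segment of length l in [lo, hi) covers alleles with d < hi
            # equivalently d <= lo given cuts; use d < hi boundary
            covered = {a for a, d in dist.items() if d < hi and d <= lo}
            out = frozenset((recipient - covered) | (covered & donor))
            agg[out] = agg.get(out, 0.0) + weight * prob
    outcomes = list(agg)
    probs = np.array([agg[o] for o in outcomes])
    probs = probs / probs.sum()
    model._mating_cache[key] = (outcomes, probs)
    return outcomes, probs


def apply_conjugation(
    state: PopulationState,
    params: ConjugationParams,
    duration: float,
    volume: float,
    model: StrainModel,
    rng: np.random.Generator,
    growth_rates: Mapping | None = None,
) -> PopulationState:
    """One conjugation sub-step of ``duration`` hours in ``volume`` mL.

    Mating events between an (ordered) donor/recipient genotype pair are
    Poisson with expectation gamma * N_d * N_r * duration / volume
    (every genotype is both donor and recipient — "genderless"). When
    per-genotype effective growth rates are supplied the pair density
    product is integrated exactly over the within-step exponential
    growth instead of being evaluated at the step start.
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    if params.gamma < 0:
        raise ValueError("gamma must be >= 0")
    if not params.enabled or params.gamma == 0:
        return state

    genos = list(state.counts)
    counts = np.array([state.counts[g] for g in genos], dtype=float)
    lam = params.gamma * np.outer(counts, counts) * duration / volume
    if growth_rates is not None:
        # Integrate the pair density product over the within-step exponential
        # growth (the step spans one baseline generation): each genotype
        # multiplies by 2^rel over the step, so the product grows as e^(k u)
        # with k = ln2 * (rel_d + rel_r) and the left-endpoint rate picks up
        # the factor (e^k - 1) / k.
        rel = np.array(
            [growth_rates[g] / model.base_growth_rate for g in genos], dtype=float
        )
        k = math.log(2.0) * np.add.outer(rel, rel)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(np.abs(k) > 1e-12, np.expm1(k) / k, 1.0)
        lam = lam * corr
    np.fill_diagonal(lam, 0.0)  # identical-genotype matings change nothing

    events = rng.poisson(lam)
    if not events.any():
        return state
    new_counts = dict(state.counts)
    for i, j in zip(*np.nonzero(events)):
        donor, recipient = genos[i], genos[j]
        n = int(events[i, j])
        # a recipient cell must exist for each conversion
        avail = math.floor(max(new_counts.get(recipient, 0), 0))
        n = min(n, avail)
        if n == 0:
            continue
        outcomes, probs = _mating_outcomes(model, params, donor, recipient)
        if len(outcomes) == 1 and outcomes[0] == recipient:
            continue
        draws = rng.multinomial(n, probs)
        for out, kdraw in zip(outcomes, draws):
            if kdraw == 0 or out == recipient:
                continue
            new_counts[recipient] = new_counts[recipient] - kdraw
            new_counts[out] = new_counts.get(out, 0) + kdraw
    new_counts = {g: c for g, c in new_counts.items() if c > 0}
    return replace(state, counts=new_counts)


def serial_transfer(
    state: PopulationState, protocol: TransferProtocol, rng: np.random.Generator
) -> PopulationState:
    """Dilution bottleneck: each cell independently survives with
    probability ``inoculum_fraction`` (binomial per genotype, i.e. a
    multinomial subsample in expectation). Genotypes hitting zero are
    dropped; an empty post-transfer population signals extinction.
    """
    if state.total() < 1.0 / protocol.inoculum_fraction:
        raise PopulationExtinct("population too small to survive dilution")
    new_counts = {}
    for g, c in state.counts.items():
        k = int(rng.binomial(int(round(c)), protocol.inoculum_fraction))
        if k > 0:
            new_counts[g] = k
    if not new_counts:
        raise PopulationExtinct("population lost at transfer bottleneck")
    return replace(state, counts=new_counts)


# ---------------------------------------------------------------------------
# Scenario configuration and full evolution runs
# ---------------------------------------------------------------------------


class AlleleSpec(BaseModel):
    id: str
    gene: str
    position_bp: int = Field(ge=0)
    fitness_delta: float = Field(gt=-1)
    tolerance_factor: float = Field(default=1.0, gt=0)

    def to_allele(self) -> MutationAllele:
        return MutationAllele(
            id=self.id,
            gene=self.gene,
            position_bp=self.position_bp,
            fitness_delta=self.fitness_delta,
            tolerance_factor=self.tolerance_factor,
        )


class ConjugationSpec(BaseModel):
    enabled: bool = False
    gamma: float = Field(default=0.0, ge=0)
    cotransfer_length_bp: float = Field(default=1.0e5, gt=0)
    oriT_positions: tuple = (0,)


class RampSpec(BaseModel):
    enabled: bool = False
    start_conc: float = Field(default=1.33, gt=0)
    threshold_dbl_per_h: float = Field(default=DOUBLINGS_PER_HOUR_BASELINE, gt=0)


class ScenarioConfig(BaseModel):
    """Validated description of one full evolution scenario."""

    alleles: list = Field(default_factory=list)
    inoculum_fraction: float = Field(default=0.008, gt=0, lt=1)
    stop_cells: float = Field(default=2.0e8, gt=0)
    max_generations: int = Field(default=7, ge=1)
    base_rate: float = Field(default=0.0, ge=0, le=1)
    mutator_on: bool = False
    mutation_rate_multiplier: float = Field(default=20.0, gt=0)
    conjugation: ConjugationSpec = Field(default_factory=ConjugationSpec)
    ramp: RampSpec = Field(default_factory=RampSpec)
    n_transfers: int = Field(ge=1)
    seed: int
    volume_ml: float = Field(default=5.0, gt=0)
    chromosome_bp: int = Field(default=DEFAULT_CHROMOSOME_BP, gt=0)
    base_growth_rate: float = Field(default=DOUBLINGS_PER_HOUR_BASELINE, gt=0)
    base_tolerance: float = Field(default=1.0, gt=0)
    drug_hill_coefficient: float = Field(default=4.0, gt=0)
    #: optional starting composition, genotype -> fraction; genotypes are
    #: "+"-joined allele ids or "WT". Default: pure wild type. Used e.g.
    #: to seed reconstructed single mutants for a selection experiment.
    initial_composition: dict | None = None

    @field_validator("alleles")
    @classmethod
    def _unique_ids(cls, v):
        specs = [a if isinstance(a, AlleleSpec) else AlleleSpec(**a) for a in v]
        ids = [a.id for a in specs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate allele ids in scenario")
        return specs

    @model_validator(mode="after")
    def _check_conjugation(self):
        if self.conjugation.enabled and self.conjugation.gamma <= 0:
            raise ValueError("conjugation enabled but gamma <= 0")
        if self.initial_composition is not None:
            known = {a.id for a in self.alleles}
            total = 0.0
            for key, frac in self.initial_composition.items():
                if frac < 0:
                    raise ValueError("initial_composition fractions must be >= 0")
                total += frac
                for aid in self._parse_genotype(key):
                    if aid not in known:
                        raise ValueError(f"unknown allele {aid!r} in initial_composition")
            if abs(total - 1.0) > 1e-9:
                raise ValueError("initial_composition fractions must sum to 1")
        return self

    @staticmethod
    def _parse_genotype(key: str) -> GenotypeKey:
        if key in ("WT", ""):
            return WILD_TYPE
        return frozenset(key.split("+"))

    def initial_counts(self) -> dict:
        start = round(self.protocol().start_cells)
        if self.initial_composition is None:
            return {WILD_TYPE: float(start)}
        counts = {
            self._parse_genotype(k): round(f * start)
            for k, f in self.initial_composition.items()
            if f > 0
        }
        return {g: float(c) for g, c in counts.items() if c > 0}

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def protocol(self) -> TransferProtocol:
        return TransferProtocol(
            inoculum_fraction=self.inoculum_fraction,
            stop_cells=self.stop_cells,
            max_generations=self.max_generations,
        )

    def strain_model(self) -> StrainModel:
        return StrainModel(
            [a.to_allele() for a in self.alleles],
            base_growth_rate=self.base_growth_rate,
            base_tolerance=self.base_tolerance,
            chromosome_bp=self.chromosome_bp,
        )

    def conjugation_params(self) -> ConjugationParams:
        return ConjugationParams(
            gamma=self.conjugation.gamma,
            cotransfer_length_bp=self.conjugation.cotransfer_length_bp,
            enabled=self.conjugation.enabled,
            oriT_positions=tuple(self.conjugation.oriT_positions),
        )


@dataclass(frozen=True)
class TransferRecord:
    """Snapshot taken at the end of one growth phase, before dilution."""

    transfer: int
    cumulative_generations: float
    drug_conc: float
    realized_growth_rate: float  # doublings per hour over the phase
    total_cells: float
    mean_fitness: float  # population-mean relative growth rate
    allele_frequencies: dict
    genotype_census: dict


@dataclass
class EvolutionTrajectory:
    config: ScenarioConfig
    records: list
    final_state: PopulationState
    extinct: bool = False

    def allele_frequency_frame(self):
        """Tidy table: (transfer, generation, allele, frequency)."""
        import pandas as pd

        rows = []
        allele_ids = [a.id for a in self.config.alleles]
        for rec in self.records:
            for a in allele_ids:
                rows.append(
                    {
                        "transfer": rec.transfer,
                        "generation": rec.cumulative_generations,
                        "allele": a,
                        "frequency": rec.allele_frequencies.get(a, 0.0),
                    }
                )
        return pd.DataFrame(rows, columns=["transfer", "generation", "allele", "frequency"])

    def census_frame(self):
        import pandas as pd

        rows = []
        for rec in self.records:
            for g, c in sorted(rec.genotype_census.items(), key=lambda kv: -kv[1]):
                rows.append(
                    {
                        "transfer": rec.transfer,
                        "genotype": "+".join(sorted(g)) if g else "WT",
                        "count": c,
                    }
                )
        return pd.DataFrame(rows, columns=["transfer", "genotype", "count"])

    def mean_fitness_series(self):
        return [(r.transfer, r.mean_fitness) for r in self.records]


def run_evolution(config: ScenarioConfig) -> EvolutionTrajectory:
    """Run a full serial-transfer evolution scenario.

    Alternates growth phases (mutation -> conjugation -> doubling per
    baseline generation) with dilution bottlenecks; if the antibiotic
    ramp is enabled, the concentration is updated from the realized
    growth rate of each phase. Fully reproducible from ``config.seed``.
    """
    from . import ramp as ramp_mod

    rng = np.random.default_rng(config.seed)
    protocol = config.protocol()
    model = config.strain_model()
    drug = HillDrugResponse(config.drug_hill_coefficient)
    conj = config.conjugation_params()
    supply = [model.alleles[a.id] for a in config.alleles]
    gen_duration = 1.0 / model.base_growth_rate  # hours per baseline generation

    state = PopulationState(
        counts=config.initial_counts(),
        drug_conc=config.ramp.start_conc if config.ramp.enabled else 0.0,
        mutator_on=config.mutator_on,
        mutation_rate_multiplier=config.mutation_rate_multiplier,
    )
    ramp_state = (
        ramp_mod.RampState(current_conc=config.ramp.start_conc)
        if config.ramp.enabled
        else None
    )

    records: list = []
    extinct = False
    for t in range(1, config.n_transfers + 1):
        start_total = state.total()
        if start_total < 1:
            extinct = True
            break
        gens = 0
        while state.total() < protocol.stop_cells and gens < protocol.max_generations:
            if config.base_rate > 0 and supply:
                state = apply_mutation(state, supply, config.base_rate, rng)
            if conj.enabled:
                rates = _effective_rates(state, model, drug)
                state = apply_conjugation(
                    state, conj, gen_duration, config.volume_ml, model, rng, growth_rates=rates
                )
            state = _double_once(state, model, drug)
            gens += 1
        hours = gens * gen_duration
        end_total = state.total()
        realized = math.log2(end_total / start_total) / hours if hours > 0 else 0.0
        freqs = state.frequencies()
        mean_fit = sum(c * model.relative_fitness(g) for g, c in state.counts.items()) / end_total
        records.append(
            TransferRecord(
                transfer=t,
                cumulative_generations=state.generations_elapsed,
                drug_conc=state.drug_conc,
                realized_growth_rate=realized,
                total_cells=end_total,
                mean_fitness=mean_fit,
                allele_frequencies=state.allele_frequencies(),
                genotype_census={g: c for g, c in state.counts.items()},
            )
        )
        if ramp_state is not None:
            ramp_state = ramp_mod.ramp_step(ramp_state, realized)
            state = replace(state, drug_conc=ramp_state.current_conc)
        try:
            state = serial_transfer(state, protocol, rng)
        except PopulationExtinct:
            extinct = True
            break
    return EvolutionTrajectory(config=config, records=records, final_state=state, extinct=extinct)
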