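"""Canonical simulation scenarios.

Two ready-made scenario builders on the glycerol fitness landscape:

- :func:`glycerol_regime_config` — a de-novo evolution from wild type
  with the three recurrent beneficial targets (glpK, rpoC, cyaA), used
  to race the four regimes (+/- mutator x +/- sexual recombination);
- :func:`seeded_selection_config` — a short selection experiment seeded
  with reconstructed single mutants, used to demonstrate recombinant
  formation and its census signature.

Gene coordinates are approximate BW25113 positions; the oriT anchor is
placed ~76 kb upstream of glpK so that the glpK-cyaA co-transfer
geometry (~100 kb apart, within reach of a typical transferred segment)
is respected. The simulator's ``gamma`` is the raw mating-pair rate
constant (the segment-transfer kernel is applied on top of it);
``GAMMA_RAW`` is a literature-typical value for an efficient
conjugative system.
"""

from __future__ import annotations

from .popsim import ScenarioConfig

__all__ = [
    "GAMMA_RAW",
    "GLYCEROL_ALLELES",
    "ORIT_POSITION",
    "glycerol_regime_config",
    "seeded_selection_config",
]

#: Raw mating-pair rate constant, mL/(cell h), before the co-transfer
#: kernel; an efficient engineered conjugative system.
GAMMA_RAW = 1.0e-9

ORIT_POSITION = 3_850_000

#: The three recurrent beneficial targets on glycerol, one chosen allele
#: per gene; improvements follow the measured ordering glpK > rpoC > cyaA.
GLYCEROL_ALLELES = (
    dict(id="glpK288", gene="glpK", position_bp=3_926_000, fitness_delta=0.35),
    dict(id="rpoC1022", gene="rpoC", position_bp=4_185_000, fitness_delta=0.20),
    dict(id="cyaA797", gene="cyaA", position_bp=3_990_000, fitness_delta=0.10),
)


def glycerol_regime_config(
    sexual: bool,
    mutator: bool,
    seed: int,
    n_transfers: int = 100,
    base_rate: float = 1.0e-10,
    gamma: float = GAMMA_RAW,
) -> ScenarioConfig:
    """Wild-type start on the glycerol landscape, one of four regimes.

    ``base_rate`` 1e-10 per allele per cell per generation keeps the
    uninduced populations mutation-limited (~0.04 mutational events per
    allele per growth phase); the mutator multiplies it 20-fold.
    """
    return ScenarioConfig(
        alleles=list(GLYCEROL_ALLELES),
        base_rate=base_rate,
        mutator_on=mutator,
        conjugation=dict(
            enabled=sexual,
            gamma=gamma if sexual else 0.0,
            cotransfer_length_bp=1.0e5,
            oriT_positions=(ORIT_POSITION,),
        ),
        n_transfers=n_transfers,
        seed=seed,
    )


def seeded_selection_config(
    sexual: bool,
    seed: int,
    n_transfers: int = 3,
    gamma: float = GAMMA_RAW,
) -> ScenarioConfig:
    """Selection experiment seeded with reconstructed single mutants.

    45% glpK695 + 45% cyaA797 + 10% wild type; spontaneous mutation is
    negligible (1e-12 per allele), so a double mutant can only arise by
    mating — the asexual control is the no-recombination baseline.
    """
    alleles = [
        dict(id="glpK695", gene="glpK", position_bp=3_926_000, fitness_delta=0.34),
        dict(id="cyaA797", gene="cyaA", position_bp=3_990_000, fitness_delta=0.10),
    ]
    return ScenarioConfig(
        alleles=alleles,
        base_rate=1.0e-12,
        mutator_on=False,
        conjugation=dict(
            enabled=sexual,
            gamma=gamma if sexual else 0.0,
            cotransfer_length_bp=1.0e5,
            oriT_positions=(ORIT_POSITION,),
        ),
        n_transfers=n_transfers,
        seed=seed,
        initial_composition={"glpK695": 0.45, "cyaA797": 0.45, "WT": 0.10},
    )
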