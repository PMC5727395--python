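"""Synthetic-data generators with known ground truth.

Every input the analysis modules consume can be generated here:
combinatorial fitness tables with injected epistasis, qPCR-style allele
frequency series, random-isolate genotype tables, and noisy tolerance
ramp trajectories. Each generator is a pure function of its parameters
and seed, and returns the ground truth alongside the data so estimator
recovery can be asserted exactly.

Noise models are deliberately the simplest consistent with the assays
being emulated: additive Gaussian technical error for qPCR frequencies
(clamped to [0, 1.05] like real runs that slightly overshoot 100%),
Gaussian replicate noise for plate-reader fitness improvements, and
multiplicative log-normal error for drug concentrations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .epistasis import FitnessEntry, FitnessTable

__all__ = [
    "make_fitness_table",
    "make_allele_series",
    "make_isolate_table",
    "make_ramp_trajectory",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class FitnessTableTruth:
    additive_effects: dict
    epistasis: dict  # mask -> injected e
    sem: float
    seed: int


def make_fitness_table(
    additive_effects: Mapping,
    epistasis_spec: Mapping | None = None,
    sem: float = 0.0,
    n_replicates: int = 18,
    seed: int = 0,
):
    """Full 2^n combinatorial fitness table (n <= 6 genes).

    ``additive_effects`` maps gene -> single-mutant improvement;
    ``epistasis_spec`` maps a multi-mutation mask to its net epistasis e,
    so the mask's noiseless improvement is (1 + e) * sum of singles.
    Gaussian replicate noise with s.d. ``sem`` is added to every
    non-wild-type entry. Returns (FitnessTable, FitnessTableTruth).
    """
    genes = sorted(additive_effects)
    if len(genes) > 6:
        raise ValueError("at most 6 genes supported")
    eps = {frozenset(k): float(v) for k, v in (epistasis_spec or {}).items()}
    rng = _rng(seed)
    entries = {frozenset(): FitnessEntry(0.0, 0.0, n_replicates)}
    for r in range(1, len(genes) + 1):
        for combo in itertools.combinations(genes, r):
            mask = frozenset(combo)
            s = sum(additive_effects[g] for g in combo)
            a = s * (1.0 + eps.get(mask, 0.0)) if r >= 2 else s
            noise = rng.normal(0.0, sem) if sem > 0 else 0.0
            entries[mask] = FitnessEntry(a + noise, sem, n_replicates)
    truth = FitnessTableTruth(
        additive_effects=dict(additive_effects),
        epistasis=eps,
        sem=sem,
        seed=seed if isinstance(seed, int) else -1,
    )
    return FitnessTable(entries), truth


def make_allele_series(
    trajectory, qpcr_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """qPCR-style allele-frequency series from a simulated trajectory.

    Adds Gaussian technical noise (s.d. ``qpcr_sd``) to the true
    per-allele frequencies and clamps to [0, 1.05], mimicking allele
    specific qPCR with three technical replicates. ``trajectory`` is an
    EvolutionTrajectory or a tidy frame with columns (transfer,
    generation, allele, frequency). Returns a long-format frame with an
    added ``sd`` column; the input frequencies are the ground truth.
    """
    df = (
        trajectory.allele_frequency_frame()
        if hasattr(trajectory, "allele_frequency_frame")
        else trajectory.copy()
    )
    rng = _rng(seed)
    noisy = df["frequency"].to_numpy(dtype=float)
    if qpcr_sd > 0:
        noisy = noisy + rng.normal(0.0, qpcr_sd, size=len(noisy))
    out = df.copy()
    out["frequency"] = np.clip(noisy, 0.0, 1.05)
    out["sd"] = qpcr_sd
    return out


def make_isolate_table(
    genotype_distribution: Mapping, n_isolates: int, seed: int = 0
) -> pd.DataFrame:
    """Random-isolate genotype table (isolates x mutations, 0/1).

    Draws ``n_isolates`` isolates multinomially from a genotype
    distribution (allele-set -> frequency, summing to 1), the in-silico
    analogue of picking random colonies and typing each tracked
    mutation by allele-specific PCR.
    """
    genos = list(genotype_distribution)
    probs = np.array([genotype_distribution[g] for g in genos], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("genotype distribution must be >= 0 and sum to 1")
    mutations = sorted({m for g in genos for m in g})
    rng = _rng(seed)
    if n_isolates == 0:
        return pd.DataFrame(columns=mutations, dtype=int)
    draws = rng.multinomial(n_isolates, probs)
    rows = []
    for g, k in zip(genos, draws):
        present = set(g)
        rows.extend([{m: int(m in present) for m in mutations}] * int(k))
    rng.shuffle(rows)
    return pd.DataFrame(rows, columns=mutations, dtype=int)


def make_ramp_trajectory(
    a: float,
    b: float,
    C_abo: float,
    noise_sd: float = 0.0,
    n: int = 30,
    generations_per_transfer: float = 7.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy tolerance-ramp series from C(t) = C_0 exp(a (t + b)).

    One point per transfer at t = g, 2g, ... generations with
    multiplicative log-normal noise of log-s.d. ``noise_sd``. Columns
    (transfer, generations, concentration) feed the ramp fitter
    directly; the inputs are the ground truth.
    """
    if a <= 0 or C_abo <= 0:
        raise ValueError("a and C_abo must be > 0")
    if n < 4:
        raise ValueError("need at least 4 points")
    rng = _rng(seed)
    t = generations_per_transfer * np.arange(1, n + 1)
    c = C_abo * np.exp(a * (t + b))
    if noise_sd > 0:
        c = c * np.exp(rng.normal(0.0, noise_sd, size=n))
    return pd.DataFrame(
        {"transfer": np.arange(1, n + 1), "generations": t, "concentration": c}
    )
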