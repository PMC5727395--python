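"""Additive-model epistasis over combinatorial mutant fitness tables.

Fitness values are *improvements* relative to wild type (WT = 0), as
measured for reconstructed single/double/triple mutants. For a genotype
carrying mutations with single-mutant improvements a_i the net epistasis
is

    e = (a_combined - sum_i a_i) / sum_i a_i,

a per-genotype quantity (one value per multi-mutation mask). Pairs of
mutations are additionally classified as showing no / magnitude / sign /
reciprocal-sign epistasis from the sign of each mutation's effect in the
other's background, with an equality tolerance tau.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FitnessEntry",
    "FitnessTable",
    "EpistasisValue",
    "additive_epistasis",
    "epistasis_landscape",
    "detect_sign_epistasis",
    "PairClassification",
    "MissingMaskError",
]

Mask = frozenset


class MissingMaskError(KeyError):
    """A required genotype mask is absent from the fitness table."""


@dataclass(frozen=True)
class FitnessEntry:
    improvement: float  # relative fitness improvement over WT (WT = 0)
    sem: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


class FitnessTable:
    """Genotype mask -> measured fitness improvement (+- s.e.m.).

    Masks are sets of mutation labels (one chosen allele per gene). The
    wild-type (empty) mask must be present with improvement 0.
    """

    def __init__(self, entries: Mapping):
        self.entries = {}
        for mask, entry in entries.items():
            key = frozenset(mask)
            if key in self.entries:
                raise ValueError(f"duplicate mask {sorted(key)}")
            if not isinstance(entry, FitnessEntry):
                entry = FitnessEntry(*entry) if isinstance(entry, tuple) else FitnessEntry(float(entry))
            self.entries[key] = entry
        wt = self.entries.get(frozenset())
        if wt is None:
            raise ValueError("wild-type (empty) mask missing from table")
        if wt.improvement != 0:
            raise ValueError("wild-type improvement must be 0")

    @property
    def genes(self) -> tuple:
        out: set = set()
        for mask in self.entries:
            out |= mask
        return tuple(sorted(out))

    def improvement(self, mask: Iterable) -> float:
        return self._entry(mask).improvement

    def _entry(self, mask: Iterable) -> FitnessEntry:
        key = frozenset(mask)
        try:
            return self.entries[key]
        except KeyError:
            raise MissingMaskError(f"mask {sorted(key)} not in table") from None

    def __contains__(self, mask) -> bool:
        return frozenset(mask) in self.entries

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str = "fitness_improvement",
                   sem_col: str = "sem", n_col: str = "n") -> "FitnessTable":
        """Build from a table whose gene columns hold 1/0 (or "+"/"-")
        presence marks — the genotype-grid layout of combinatorial
        reconstruction experiments.
        """
        meta = {value_col, sem_col, n_col}
        gene_cols = [c for c in df.columns if c not in meta]
        entries = {}
        for _, row in df.iterrows():
            mask = frozenset(g for g in gene_cols if int(row[g]) == 1)
            entries[mask] = FitnessEntry(
                improvement=float(row[value_col]),
                sem=float(row[sem_col]) if sem_col in df.columns else 0.0,
                n_replicates=int(row[n_col]) if n_col in df.columns else 1,
            )
        return cls(entries)

    def to_frame(self) -> pd.DataFrame:
        genes = self.genes
        rows = []
        for mask in sorted(self.entries, key=lambda m: (len(m), tuple(sorted(m)))):
            e = self.entries[mask]
            row = {g: int(g in mask) for g in genes}
            row.update(fitness_improvement=e.improvement, sem=e.sem, n=e.n_replicates)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EpistasisValue:
    mask: Mask
    e: float
    se: float
    defined: bool = True


def additive_epistasis(table: FitnessTable, mask: Iterable) -> EpistasisValue:
    """Net epistasis of one genotype mask against the additive expectation.

    e = (a_combined - sum of component single improvements) / (that sum).
    Single-mutation masks return e = 0 by convention. A zero additive
    expectation is flagged undefined (e = nan). Uncertainty is first-order
    propagation of the entry s.e.m.s.
    """
    key = frozenset(mask)
    if len(key) <= 1:
        entry = table._entry(key)  # still require presence
        return EpistasisValue(mask=key, e=0.0, se=0.0)
    combined = table._entry(key)
    singles = [table._entry(frozenset({g})) for g in sorted(key)]
    s = sum(x.improvement for x in singles)
    if s == 0:
        return EpistasisValue(mask=key, e=math.nan, se=math.nan, defined=False)
    e = (combined.improvement - s) / s
    # de/da_comb = 1/s ; de/da_i = -a_comb / s^2
    var = (combined.sem / s) ** 2 + sum(
        (combined.improvement * x.sem / s ** 2) ** 2 for x in singles
    )
    return EpistasisValue(mask=key, e=e, se=math.sqrt(var))


def epistasis_landscape(table: FitnessTable) -> dict:
    """Epistasis for every multi-mutation mask in the table, sorted by
    (size, labels). Masks whose component singles are missing or whose
    additive expectation is zero are reported undefined rather than
    aborting the rest of the landscape.
    """
    out: dict = {}
    masks = sorted(
        (m for m in table.entries if len(m) >= 2),
        key=lambda m: (len(m), tuple(sorted(m))),
    )
    for mask in masks:
        try:
            out[mask] = additive_epistasis(table, mask)
        except MissingMaskError as err:
            warnings.warn(f"skipping {sorted(mask)}: {err}")
            out[mask] = EpistasisValue(mask=mask, e=math.nan, se=math.nan, defined=False)
    return out


@dataclass(frozen=True)
class PairClassification:
    pair: Mask
    classification: str  # none | magnitude | sign | reciprocal_sign | boundary
    effect_a_alone: float
    effect_a_in_b: float
    effect_b_alone: float
    effect_b_in_a: float
    tau: float


def _sign(x: float, tau: float) -> int:
    if x > tau:
        return 1
    if x < -tau:
        return -1
    return 0


def detect_sign_epistasis(table: FitnessTable, tau: float | None = None) -> dict:
    """Classify every gene pair with all four masks present.

    For pair (A, B) the four effects are A alone, A in B's background,
    B alone, B in A's background. With equality tolerance tau (default
    2 x pooled s.e.m. when provided, else 1e-9):

    - both mutations keep their sign in both backgrounds -> "none" if the
      double is additive within tau, else "magnitude";
    - exactly one mutation flips sign -> "sign";
    - both flip -> "reciprocal_sign";
    - any effect indistinguishable from zero -> "boundary".

    Pairs with missing masks are skipped with a warning.
    """
    genes = table.genes
    out: dict = {}
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            masks = [frozenset(), {ga}, {gb}, {ga, gb}]
            if not all(m in table for m in masks):
                warnings.warn(f"pair ({ga}, {gb}): missing masks, skipped")
                continue
            a = table.improvement({ga})
            b = table.improvement({gb})
            ab = table.improvement({ga, gb})
            if tau is None:
                sems = [table._entry(m).sem for m in masks]
                pooled = float(np.sqrt(np.mean(np.square(sems))))
                tau_pair = 2.0 * pooled if pooled > 0 else 1e-9
            else:
                tau_pair = tau
            eff = {
                "a_alone": a,
                "a_in_b": ab - b,
                "b_alone": b,
                "b_in_a": ab - a,
            }
            signs = {k: _sign(v, tau_pair) for k, v in eff.items()}
            if 0 in signs.values():
                label = "boundary"
            else:
                flip_a = signs["a_alone"] != signs["a_in_b"]
                flip_b = signs["b_alone"] != signs["b_in_a"]
                if flip_a and flip_b:
                    label = "reciprocal_sign"
                elif flip_a or flip_b:
                    label = "sign"
                elif abs(ab - (a + b)) <= tau_pair:
                    label = "none"
                else:
                    label = "magnitude"
            out[frozenset({ga, gb})] = PairClassification(
                pair=frozenset({ga, gb}),
                classification=label,
                effect_a_alone=eff["a_alone"],
                effect_a_in_b=eff["a_in_b"],
                effect_b_alone=eff["b_alone"],
                effect_b_in_a=eff["b_in_a"],
                tau=tau_pair,
            )
    return out


def landscape_frame(table: FitnessTable, tau: float | None = None) -> pd.DataFrame:
    """Tidy export: one row per multi-mutation mask with e, se and (for
    pairs) the sign-epistasis classification."""
    land = epistasis_landscape(table)
    pairs = detect_sign_epistasis(table, tau=tau)
    rows = []
    for mask, val in land.items():
        rows.append(
            {
                "mask": "+".join(sorted(mask)),
                "n_mutations": len(mask),
                "e": val.e,
                "se_e": val.se,
                "defined": val.defined,
                "classification": pairs[mask].classification if mask in pairs else "",
            }
        )
    return pd.DataFrame(rows, columns=["mask", "n_mutations", "e", "se_e", "defined", "classification"])
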