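"""Inference from allele-frequency series and isolate genotype tables.

qPCR-style per-mutation population frequencies and allele-specific-PCR
genotyping of random isolates are the two windows this module reads:

- the sum of per-locus frequencies is the mean number of tracked
  mutations per cell (linearity of expectation), the quantity that
  first hints at co-occurrence when it exceeds 1;
- max(0, sum - 1) is the pigeonhole lower bound on the fraction of
  cells carrying at least two of the tracked mutations;
- a census of isolate genotypes exposes the molecular signature of a
  mating event: single-mutant genotypes {X} and {Y} coexisting with the
  double {X, Y}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FREQ_CLAMP_LIMIT",
    "mean_mutations_per_cell",
    "min_cooccurrence_bound",
    "genotype_census",
    "census_marginal_consistency",
    "recombination_evidence_report",
    "RecombinationEvidence",
]

#: Frequencies in (1, 1.05] are treated as qPCR technical error and
#: clamped to 1 with a warning; anything above is a hard error.
FREQ_CLAMP_LIMIT = 1.05


def _clean_frequency(name: str, f: float) -> float:
    if not math.isfinite(f) or f < 0:
        raise ValueError(f"frequency of {name!r} out of [0, 1]: {f}")
    if f > FREQ_CLAMP_LIMIT:
        raise ValueError(
            f"frequency of {name!r} = {f} exceeds the {FREQ_CLAMP_LIMIT} clamp limit"
        )
    if f > 1.0:
        warnings.warn(f"frequency of {name!r} = {f} clamped to 1 (technical noise)")
        return 1.0
    return f


def mean_mutations_per_cell(freqs: Mapping) -> float:
    """Expected number of tracked mutations per cell: the sum of the
    per-locus population frequencies (loci must be distinct).
    """
    return float(sum(_clean_frequency(k, float(v)) for k, v in freqs.items()))


def min_cooccurrence_bound(
    freqs: Mapping, same_gene_exclusive: bool = False, gene_of: Mapping | None = None
) -> float:
    """Lower bound on the fraction of cells carrying >= 2 of the listed
    mutations: max(0, sum of frequencies - 1).

    The bound is the pigeonhole minimum consistent with the marginals
    (exact when no cell carries more than two). With
    ``same_gene_exclusive`` the mutations are grouped by gene
    (``gene_of`` maps mutation -> gene; default: everything before the
    last digit-run is the gene) and alleles of one gene are treated as
    mutually exclusive per cell, which requires each gene's summed
    frequency to stay <= 1; the bound itself is unchanged.
    """
    clean = {k: _clean_frequency(k, float(v)) for k, v in freqs.items()}
    if same_gene_exclusive and clean:
        if gene_of is None:
            gene_of = {k: k.rstrip("0123456789") for k in clean}
        per_gene: dict = {}
        for k, f in clean.items():
            per_gene[gene_of[k]] = per_gene.get(gene_of[k], 0.0) + f
        for gene, tot in per_gene.items():
            if tot > 1.0 + 1e-9:
                raise ValueError(
                    f"gene {gene!r}: summed allele frequency {tot:.3f} > 1 "
                    "contradicts per-cell exclusivity"
                )
    return max(0.0, sum(clean.values()) - 1.0)


def _as_bool_frame(table: pd.DataFrame) -> pd.DataFrame:
    if table.columns.duplicated().any():
        raise ValueError("mutation ids must be unique")
    return table.astype(bool)


def genotype_census(table: pd.DataFrame) -> dict:
    """Group identical isolate rows; returns genotype (frozenset of
    mutation ids) -> isolate count, in descending-count order.
    """
    df = _as_bool_frame(table)
    counts: dict = {}
    muts = list(df.columns)
    for row in df.itertuples(index=False):
        g = frozenset(m for m, present in zip(muts, row) if present)
        counts[g] = counts.get(g, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0])))))


def census_marginals(census: Mapping, n_isolates: int | None = None) -> dict:
    """Per-mutation frequency implied by a genotype census."""
    n = n_isolates if n_isolates is not None else sum(census.values())
    if n <= 0:
        return {}
    out: dict = {}
    for g, c in census.items():
        for m in g:
            out[m] = out.get(m, 0) + c
    return {m: c / n for m, c in out.items()}


def census_marginal_consistency(
    census: Mapping, freqs: Mapping, n_isolates: int
) -> dict:
    """z-scores comparing census marginal frequencies with qPCR-style
    population frequencies: z = (f_census - f_pop) / sqrt(f_pop (1 -
    f_pop) / n). A population frequency of exactly 0 or 1 that the
    census contradicts yields an infinite (flagged) z.
    """
    if n_isolates <= 0:
        raise ValueError("n_isolates must be > 0")
    marg = census_marginals(census, n_isolates)
    out: dict = {}
    for m, f_pop in freqs.items():
        f_pop = _clean_frequency(m, float(f_pop))
        f_cen = marg.get(m, 0.0)
        if f_pop in (0.0, 1.0):
            out[m] = 0.0 if f_cen == f_pop else math.copysign(math.inf, f_cen - f_pop)
            continue
        out[m] = (f_cen - f_pop) / math.sqrt(f_pop * (1 - f_pop) / n_isolates)
    return out


@dataclass(frozen=True)
class RecombinationEvidence:
    mutation_x: str
    mutation_y: str
    count_x_only: int
    count_y_only: int
    count_xy: int


def recombination_evidence_report(census: Mapping) -> list:
    """Mutation pairs whose single-mutant genotypes {X} and {Y} coexist
    with the double {X, Y} in the census — the molecular signature of a
    mating event combining two independently arisen mutations (a pair
    lacking either singleton is not flagged).
    """
    singles = {next(iter(g)): c for g, c in census.items() if len(g) == 1}
    report = []
    for g, c_xy in census.items():
        if len(g) != 2:
            continue
        x, y = sorted(g)
        if x in singles and y in singles:
            report.append(
                RecombinationEvidence(
                    mutation_x=x,
                    mutation_y=y,
                    count_x_only=singles[x],
                    count_y_only=singles[y],
                    count_xy=c_xy,
                )
            )
    report.sort(key=lambda r: (r.mutation_x, r.mutation_y))
    return report
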