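"""Luria-Delbruck fluctuation-test simulation and mutation-rate estimation.

Parallel cultures grown from a small inoculum accumulate mutants whose
count distribution is jackpot-skewed: a mutation arising early founds an
exponentially larger clone. The number of mutations per culture m is
estimated by maximum likelihood under the Lea-Coulson distribution,
whose probabilities follow the Ma-Sandri-Sarkar (MSS) recursion

    p_0 = exp(-m),    p_k = (m / k) * sum_{i=0}^{k-1} p_i / (k - i + 1),

and the mutation rate is m / N_t (mutations per cell per generation,
with N_t the final cells per culture). Confidence intervals come from
the profile likelihood at the chi-square(1) 95% cutoff, falling back to
a normal approximation on ln m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "FluctuationExperiment",
    "RateEstimate",
    "simulate_ld_cultures",
    "mss_probabilities",
    "estimate_rate_mss",
    "estimate_rate_p0",
    "fold_change",
    "FoldChange",
]

#: Observed counts above this are right-censored into the top likelihood
#: bin; keeps the O(k^2) MSS recursion tractable under extreme jackpots.
DEFAULT_JACKPOT_CAP = 1024

_CHI2_95 = 3.841458820694124  # chi-square(1) 95% quantile


@dataclass(frozen=True)
class FluctuationExperiment:
    """Mutant colony counts of parallel cultures, all grown to N_t cells."""

    counts: tuple
    N_t: float

    def __post_init__(self) -> None:
        if self.N_t <= 0:
            raise ValueError("N_t must be > 0")
        if any((c < 0 or int(c) != c) for c in self.counts):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_cultures(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class RateEstimate:
    m: float  # expected mutations per culture
    rate: float  # per cell per generation, m / N_t
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rate <= self.ci_high):
            raise ValueError("CI must bracket the rate estimate")


def simulate_ld_cultures(
    N0: float,
    N_t: float,
    rate: float,
    n_cultures: int,
    rng: np.random.Generator | int,
) -> FluctuationExperiment:
    """Simulate parallel cultures grown by doubling from N0 to ~N_t.

    Over each of the G = round(log2(N_t / N0)) generations, new mutant
    lineages arise with Poisson expectation rate * N_{g-1} (one per
    mutated division); each lineage is born at a division drawn
    uniformly within the generation (divisions are asynchronous in a
    batch culture) and its neutral descendants grow deterministically,
    reaching N_final / N_birth cells at the end of growth. This is the
    classic jackpot construction, so simulated counts follow the
    Lea-Coulson distribution with m = rate * (N_final - N0). The
    reported ``N_t`` is the realized final count N0 * 2^G.
    """
    if not N_t > N0 >= 1:
        raise ValueError("require N_t > N0 >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    G = max(int(round(math.log2(N_t / N0))), 1)
    pops = N0 * 2.0 ** np.arange(G)  # N_{g-1} for g = 1..G
    n_final = N0 * 2.0 ** G
    counts = []
    for _ in range(n_cultures):
        events = rng.poisson(rate * pops)
        total = 0.0
        for g_idx, k in enumerate(events):
            if k == 0:
                continue
            # birth uniform over the generation's divisions: N_birth in
            # [N_{g-1}, N_g); clone size N_final / N_birth
            u = rng.random(k)
            total += np.floor(n_final / (pops[g_idx] * (1.0 + u))).sum()
        counts.append(int(total))
    return FluctuationExperiment(counts=tuple(counts), N_t=n_final)


def mss_probabilities(m: float, k_max: int) -> np.ndarray:
    """Lea-Coulson probabilities p_0 .. p_{k_max} by the MSS recursion."""
    if m < 0:
        raise ValueError("m must be >= 0")
    p = np.zeros(k_max + 1)
    p[0] = math.exp(-m)
    if m == 0:
        return p
    for k in range(1, k_max + 1):
        # weights 1/(k - i + 1) for i = 0..k-1
        p[k] = (m / k) * np.dot(p[:k], 1.0 / np.arange(k + 1, 1, -1))
    return p


def _log_likelihood(m: float, hist: np.ndarray, k_top: int) -> float:
    """Log-likelihood of a count histogram with counts >= k_top censored
    into the top bin (tail mass folded in, keeping the likelihood proper).
    """
    if m <= 0:
        return -math.inf
    p = mss_probabilities(m, k_top)
    tail = max(1.0 - p[:k_top].sum(), 1e-300)
    probs = np.concatenate([np.maximum(p[:k_top], 1e-300), [tail]])
    return float(np.dot(hist, np.log(probs)))


def estimate_rate_mss(
    exp: FluctuationExperiment, jackpot_cap: int = DEFAULT_JACKPOT_CAP
) -> RateEstimate:
    """Maximum-likelihood m under the Lea-Coulson distribution.

    Counts are truncated at k_max = max(count) + 1 (tail mass in the top
    bin), additionally capped at ``jackpot_cap``. The 95% CI is the
    profile likelihood crossing of the chi-square(1) cutoff, with a
    normal-on-ln(m) fallback when a crossing cannot be bracketed.
    """
    if exp.n_cultures < 5:
        raise ValueError("need at least 5 parallel cultures")
    counts = np.asarray(exp.counts, dtype=int)
    if counts.max(initial=0) == 0:
        # P0 likelihood e^(-n m) is maximized at m = 0; the one-sided
        # bound solves e^(-n m) = 0.05.
        upper_m = -math.log(0.05) / exp.n_cultures
        return RateEstimate(m=0.0, rate=0.0, ci_low=0.0, ci_high=upper_m / exp.N_t)
    k_top = int(min(counts.max() + 1, jackpot_cap))
    if counts.min() >= k_top:
        raise ValueError("jackpot-saturated: every count is at the censoring cap")
    clipped = np.minimum(counts, k_top)
    hist = np.bincount(clipped, minlength=k_top + 1).astype(float)

    def nll(log_m: float) -> float:
        return -_log_likelihood(math.exp(log_m), hist, k_top)

    res = minimize_scalar(nll, bounds=(-7.0, 8.0), method="bounded",
                          options={"xatol": 1e-8})
    m_hat = math.exp(res.x)
    ll_max = -res.fun
    target = ll_max - _CHI2_95 / 2.0

    def diff(log_m: float) -> float:
        return _log_likelihood(math.exp(log_m), hist, k_top) - target

    lo = hi = None
    try:
        if diff(res.x - 6.0) < 0:
            lo = math.exp(brentq(diff, res.x - 6.0, res.x, xtol=1e-8))
        if diff(min(res.x + 6.0, 8.5)) < 0:
            hi = math.exp(brentq(diff, res.x, min(res.x + 6.0, 8.5), xtol=1e-8))
    except ValueError:
        pass
    if lo is None or hi is None:
        # normal approximation on ln m from the numerical curvature
        h = 1e-4
        curv = (nll(res.x + h) + nll(res.x - h) - 2 * res.fun) / h ** 2
        se = 1.0 / math.sqrt(max(curv, 1e-12))
        lo = lo if lo is not None else m_hat * math.exp(-1.959963985 * se)
        hi = hi if hi is not None else m_hat * math.exp(1.959963985 * se)
    return RateEstimate(
        m=m_hat, rate=m_hat / exp.N_t, ci_low=lo / exp.N_t, ci_high=hi / exp.N_t
    )


def estimate_rate_p0(exp: FluctuationExperiment) -> RateEstimate:
    """The P0 method: m = -ln(fraction of mutant-free cultures)."""
    counts = np.asarray(exp.counts)
    n0 = int((counts == 0).sum())
    if n0 == 0:
        raise ValueError("P0 method needs at least one mutant-free culture")
    p0_hat = n0 / exp.n_cultures
    m = -math.log(p0_hat)
    se_m = math.sqrt((1 - p0_hat) / (exp.n_cultures * p0_hat))  # delta method
    lo = max(m - 1.959963985 * se_m, 0.0)
    hi = m + 1.959963985 * se_m
    return RateEstimate(m=m, rate=m / exp.N_t, ci_low=lo / exp.N_t, ci_high=hi / exp.N_t)


@dataclass(frozen=True)
class FoldChange:
    fold: float
    ci_low: float
    ci_high: float
    finite: bool = True


def fold_change(induced: RateEstimate, uninduced: RateEstimate) -> FoldChange:
    """Mutation-rate fold change (induced / uninduced) with a CI that
    combines the two log-scale uncertainties in quadrature. A zero
    uninduced rate yields an infinite, flagged fold.
    """
    if uninduced.rate == 0:
        return FoldChange(fold=math.inf, ci_low=math.inf, ci_high=math.inf, finite=False)
    fold = induced.rate / uninduced.rate
    z = 1.959963985

    def log_se(est: RateEstimate) -> float:
        if est.ci_low <= 0 or est.ci_high <= 0:
            return math.nan
        return (math.log(est.ci_high) - math.log(est.ci_low)) / (2 * z)

    se = math.hypot(log_se(induced), log_se(uninduced))
    if math.isnan(se):
        return FoldChange(fold=fold, ci_low=0.0, ci_high=math.inf, finite=True)
    return FoldChange(
        fold=fold,
        ci_low=fold * math.exp(-z * se),
        ci_high=fold * math.exp(z * se),
    )
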