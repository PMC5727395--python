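"""Antibiotic escalation controller and tolerance-trajectory fitting.

The ramping protocol raises the drug challenge whenever the culture kept
a growth rate above 0.583 doublings/h (7 generations in 12 h): +25% per
improving transfer, switching to +50% after three consecutive improving
transfers until the first non-improving one. Tolerance-vs-generation
trajectories are summarized with the two-term exponential

    C(t) = C_0 * exp(a * (t + b))

with ramp rate ``a`` (per generation) and lag ``b`` (generations).
Because C_0 and b are confounded when both are free (only C_0 * e^(a b)
is identifiable), C_0 is fixed to the first observed concentration —
the known starting challenge of the evolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GROWTH_THRESHOLD_DBL_PER_H",
    "RampState",
    "RampFit",
    "ramp_step",
    "fit_tolerance_ramp",
    "target_crossing_generation",
    "NeverReachesTarget",
]

#: 7 generations in 12 h.
GROWTH_THRESHOLD_DBL_PER_H = 7.0 / 12.0

#: Consecutive improving transfers required to engage 50% ramping.
AGGRESSIVE_STREAK = 3


class NeverReachesTarget(ValueError):
    """The fitted ramp has a <= 0 and never crosses the target tolerance."""


@dataclass(frozen=True)
class RampState:
    """Controller state: current challenge and the improvement streak."""

    current_conc: float
    consecutive_improvements: int = 0
    aggressive_mode: bool = False

    def __post_init__(self) -> None:
        if self.current_conc <= 0:
            raise ValueError("current_conc must be > 0")
        if self.consecutive_improvements < 0:
            raise ValueError("consecutive_improvements must be >= 0")


def ramp_step(
    state: RampState,
    growth_rate: float,
    threshold: float = GROWTH_THRESHOLD_DBL_PER_H,
) -> RampState:
    """Advance the controller by one transfer.

    An improving transfer (growth rate above threshold at the current
    concentration) multiplies the challenge by 1.25 — or 1.50 once three
    consecutive improvements have engaged aggressive mode. A
    non-improving transfer leaves the concentration unchanged and resets
    both the streak and aggressive mode.
    """
    if growth_rate < 0:
        raise ValueError("growth_rate must be >= 0")
    if growth_rate > threshold:
        factor = 1.50 if state.aggressive_mode else 1.25
        streak = state.consecutive_improvements + 1
        return RampState(
            current_conc=state.current_conc * factor,
            consecutive_improvements=streak,
            aggressive_mode=state.aggressive_mode or streak >= AGGRESSIVE_STREAK,
        )
    return RampState(
        current_conc=state.current_conc,
        consecutive_improvements=0,
        aggressive_mode=False,
    )


@dataclass(frozen=True)
class RampFit:
    """Fitted two-term exponential tolerance model."""

    a: float  # exponential improvement rate per generation
    b: float  # lag, generations
    C_abo: float  # baseline concentration (fixed to first observation)
    residual_norm: float  # RMS residual of log-concentration
    degenerate: bool = False

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.C_abo * np.exp(self.a * (t + self.b))


def fit_tolerance_ramp(t, C, C_abo: float | None = None) -> RampFit:
    """Least-squares fit of C(t) = C_0 exp(a (t + b)) on log-concentration.

    Only C_0 * e^(a b) is identifiable when C_0 is free, so C_0 is fixed:
    by default to the first observed concentration (the evolution's known
    starting challenge), or to an explicit ``C_abo`` when the true
    baseline is known (e.g. synthetic ground truth). The fit is then an
    ordinary linear regression of ln C on t (exact under multiplicative
    log-normal noise, and exactly invariant to reordering of the data
    points). A constant-concentration series returns a = 0, b = 0 with
    the ``degenerate`` flag set.
    """
    t = np.asarray(t, dtype=float)
    C = np.asarray(C, dtype=float)
    if t.shape != C.shape or t.ndim != 1:
        raise ValueError("t and C must be 1-D arrays of equal length")
    if len(t) < 4:
        raise ValueError("at least 4 points are required")
    if np.any(C <= 0):
        raise ValueError("concentrations must be > 0")
    if np.ptp(t) == 0:
        raise ValueError("constant t: fit is singular")

    if C_abo is not None:
        if C_abo <= 0:
            raise ValueError("C_abo must be > 0")
        c0 = float(C_abo)
    else:
        order = np.argsort(t, kind="stable")
        c0 = float(C[order][0])  # concentration at the earliest time point
    logc = np.log(C)

    if np.ptp(logc) == 0:
        resid = float(np.sqrt(np.mean((logc - logc.mean()) ** 2)))
        return RampFit(a=0.0, b=0.0, C_abo=c0, residual_norm=resid, degenerate=True)

    slope, intercept = np.polyfit(t, logc, 1)
    a = float(slope)
    if a == 0.0:
        b = 0.0
        degenerate = True
    else:
        b = float((intercept - math.log(c0)) / a)
        degenerate = False
    resid = float(np.sqrt(np.mean((logc - (intercept + slope * t)) ** 2)))
    return RampFit(a=a, b=b, C_abo=c0, residual_norm=resid, degenerate=degenerate)


def target_crossing_generation(fit: RampFit, target: float) -> float:
    """Generation t* at which the fitted ramp crosses ``target``:
    t* = ln(target / C_0) / a - b.
    """
    if target <= 0:
        raise ValueError("target must be > 0")
    if fit.a <= 0:
        raise NeverReachesTarget("fitted ramp rate a <= 0: target never reached")
    return math.log(target / fit.C_abo) / fit.a - fit.b
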