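"""Regenerate the calibrated conjugation rate constant.

Bisection on log10(gamma) so that the deterministic mating model yields
2e5 AB recombinant cells per transfer at the canonical composition
(5% A, 5% B, 90% C, P_i = 1.6e6 -> P_f = 2e8 in 5 mL). The result is
frozen as ``clonalforge.estimates.CALIBRATED_GAMMA``; rerun this script
and update the constant if the mating model changes.

Usage: python scripts/calibrate_gamma.py
"""

from clonalforge import estimates


def main() -> None:
    params = estimates.EstimateParams()
    gamma = estimates.calibrate_gamma(params, target_cells=2.0e5)
    frac, cells = estimates.expected_recombinants(params, gamma=gamma)
    print(f"calibrated gamma          : {gamma!r} mL/(cell h)")
    print(f"recombinant cells/transfer: {cells:.6g}")
    print(f"recombinant fraction      : {frac:.6g}")
    print(f"current frozen constant   : {estimates.CALIBRATED_GAMMA!r}")
    drift = abs(gamma - estimates.CALIBRATED_GAMMA) / gamma
    print(f"relative drift            : {drift:.3g}")


if __name__ == "__main__":
    main()
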