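"""Small published reference datasets used as worked-example inputs.

``SELECTION_EXPERIMENT_FRACTIONS`` holds the allele-specific qPCR
fractions of the six seeded mutations in each of six replicate
genderless populations after 55 generations of selection on glycerol
(mean over three technical replicates; standard deviations in
``SELECTION_EXPERIMENT_SD``). Summing a replicate's fractions gives the
mean number of tracked mutations per cell — ~2 in every replicate, the
population-level fingerprint of recombinant genotypes.
"""

from __future__ import annotations

SELECTION_MUTATIONS = (
    "rpoC1022",
    "cyaA797",
    "cyaA2227",
    "glpK695",
    "glpK288",
    "glpK694",
)

#: replicate (1-6) -> mutation -> population fraction
SELECTION_EXPERIMENT_FRACTIONS = {
    1: {
        "rpoC1022": 0.911,
        "cyaA797": 0.003,
        "cyaA2227": 0.498,
        "glpK695": 0.007,
        "glpK288": 0.399,
        "glpK694": 0.426,
    },
    2: {
        "rpoC1022": 0.839,
        "cyaA797": 0.002,
        "cyaA2227": 0.181,
        "glpK695": 0.019,
        "glpK288": 0.672,
        "glpK694": 0.260,
    },
    3: {
        "rpoC1022": 0.868,
        "cyaA797": 0.001,
        "cyaA2227": 0.252,
        "glpK695": 0.015,
        "glpK288": 0.832,
        "glpK694": 0.109,
    },
    4: {
        "rpoC1022": 0.936,
        "cyaA797": 0.001,
        "cyaA2227": 0.326,
        "glpK695": 0.010,
        "glpK288": 0.592,
        "glpK694": 0.495,
    },
    5: {
        "rpoC1022": 0.821,
        "cyaA797": 0.007,
        "cyaA2227": 0.455,
        "glpK695": 0.155,
        "glpK288": 0.367,
        "glpK694": 0.504,
    },
    6: {
        "rpoC1022": 0.805,
        "cyaA797": 0.003,
        "cyaA2227": 0.088,
        "glpK695": 0.018,
        "glpK288": 0.840,
        "glpK694": 0.151,
    },
}

SELECTION_EXPERIMENT_SD = {
    1: {
        "rpoC1022": 0.039,
        "cyaA797": 0.001,
        "cyaA2227": 0.056,
        "glpK695": 0.001,
        "glpK288": 0.106,
        "glpK694": 0.055,
    },
    2: {
        "rpoC1022": 0.055,
        "cyaA797": 0.001,
        "cyaA2227": 0.018,
        "glpK695": 0.006,
        "glpK288": 0.022,
        "glpK694": 0.073,
    },
    3: {
        "rpoC1022": 0.025,
        "cyaA797": 0.001,
        "cyaA2227": 0.028,
        "glpK695": 0.004,
        "glpK288": 0.012,
        "glpK694": 0.034,
    },
    4: {
        "rpoC1022": 0.019,
        "cyaA797": 0.001,
        "cyaA2227": 0.056,
        "glpK695": 0.005,
        "glpK288": 0.063,
        "glpK694": 0.097,
    },
    5: {
        "rpoC1022": 0.011,
        "cyaA797": 0.002,
        "cyaA2227": 0.031,
        "glpK695": 0.056,
        "glpK288": 0.019,
        "glpK694": 0.060,
    },
    6: {
        "rpoC1022": 0.019,
        "cyaA797": 0.001,
        "cyaA2227": 0.008,
        "glpK695": 0.006,
        "glpK288": 0.008,
        "glpK694": 0.025,
    },
}
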