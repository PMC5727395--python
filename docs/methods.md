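# Methods

This note documents the models behind `clonalforge`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
benchmarks do and do not demonstrate.

## Serial-transfer population model (`popsim`)

A batch culture is represented as a census mapping genotypes (sets of
tracked mutation alleles) to cell counts, in a fixed volume (default
5 mL). Growth is advanced in **discrete baseline generations** rather
than a continuous ODE: the experimental protocol is itself stepwise
(transfer at OD ~0.5, ~7 doublings), and discrete steps make the
interleaving of mutation and mating sub-steps well defined. Within one
generation the order is: mutation, conjugation, doubling.

- **Calibration of cell numbers.** OD600 to cells is fixed at 8×10⁷
  cells/OD/mL, so the OD 0.004 inoculum in 5 mL is 1.6×10⁶ cells and
  the OD ~0.5 stop is 2×10⁸ — the anchors of the worked estimates. A
  growth phase is capped at 7 baseline generations (12 h at the 0.583
  doublings/h baseline); populations that cannot reach the stop density
  in the window are transferred anyway, as on the bench.
- **Growth.** Genotype rates are additive by default:
  r = r₀·(1 + Σ fitness_delta); a `fitness_overrides` table injects
  measured combination fitnesses (epistasis) where available. Per
  baseline generation each genotype multiplies by 2^(r_eff/r₀).
- **Drug response.** r_eff = r / (1 + (C/tolerance)^h), Hill coefficient
  h = 4 by default. The half-maximal anchor at C = tolerance is the only
  constraint the protocol imposes; h = 4 is a minimal steep-but-smooth
  choice, and both h and the per-allele tolerance factors are exposed.
- **Mutation supply.** A finite configured list of beneficial alleles
  (the adaptive regimes of interest are supply-limited); deleterious
  genome-wide load is out of scope. Each genotype emits single-allele
  mutants with Poisson expectation N·μ·(mutator multiplier), μ being the
  per-cell per-generation probability of one specific allele.
  Re-mutation to an allele already carried is a no-op. The mutator
  multiplier defaults to 20×, matching the order of the measured
  induction fold-change of a dam-overexpression mutator (~20×).
- **Conjugation.** Mating events between an ordered donor/recipient
  genotype pair are Poisson with mass-action expectation
  γ·N_d·N_r·Δt/V; every genotype is simultaneously donor and recipient
  ("genderless"). Within a generation step the density product is
  integrated over the exponential growth of both parents (factor
  (e^k − 1)/k, k = ln2·(rel_d + rel_r)), so in the small-γ limit the
  expected number of events over a phase equals the continuous integral
  ∫γ·D(t)·R(t)/V·dt exactly (verified against quadrature in the tests).
  Each event transfers a contiguous segment starting at an oriT anchor
  (uniform over configured sites; one site by default) whose length is
  exponential with mean `cotransfer_length_bp` (default 100 kb), on a
  circular chromosome (default 4,631,469 bp, 0-based coordinates). The
  recipient's allele state across the transferred interval is replaced
  by the donor's — so a wild-type donor can also *remove* a recipient's
  mutation, and a segment reaching one locus but not the next is what
  creates new allele combinations. Outcome distributions per genotype
  pair are enumerated exactly from the breakpoint distances and cached.
- **Bottleneck.** Each cell survives transfer independently with
  probability `inoculum_fraction` (binomial per genotype). This makes
  the process a Wright–Fisher-like drift chain; the tests confirm a
  neutral allele at frequency f fixes with probability f.
- **Randomness.** One `numpy.random.Generator` per run, seeded from the
  scenario config; identical seed + config reproduce trajectories
  bit-identically. Counts are integers after every stochastic step;
  deterministic growth holds fractional expectations in between.

## Antibiotic ramp and tolerance fit (`ramp`)

The controller raises the challenge 25% after any transfer whose
realized growth rate exceeded 0.583 doublings/h, switches to 50% steps
after three consecutive improving transfers, and drops back on the
first stall. Tolerance trajectories are summarized by
C(t) = C₀·e^(a(t+b)). Because C₀ and the lag b enter only through
C₀·e^(ab), they are not jointly identifiable; C₀ is therefore fixed —
to the first observed concentration by default (the evolution's known
starting challenge), or to an explicit value when the true baseline is
known (synthetic data). With C₀ fixed the fit is an ordinary linear
regression of ln C on t, which is exact maximum likelihood under
multiplicative log-normal noise, needs no starting values or bounds,
and is exactly invariant to the ordering of data points. A constant
series returns a = 0 with a degenerate flag. The target-crossing time
is the closed form t* = ln(target/C₀)/a − b.

## Mating vs spontaneous mutation (`estimates`)

Both sides of the comparison are deterministic expectations for one
growth phase (1.6×10⁶ → 2×10⁸ cells).

**Mutation side (stepwise model).** The population doubles for
G = ceil(log₂(P_f/P_i)) = 7 generations. At generation g the expected
new specific-site mutants are N_g·μ/(4·genome), N_g = P_i·2^g,
μ = 1/100 per cell per generation. "Propagated at twice wild-type
fitness" admits several accounting conventions, all implemented:

| convention  | cohort growth per remaining generation | result (defaults) |
|-------------|----------------------------------------|-------------------|
| `multiplier` (default) | × w (the fitness value, 2)  | **0.774**         |
| `doubling`  | × 2^w (w times the doubling rate)      | 14.0              |
| `events`    | none (count mutational events)         | 0.219             |

plus an `include_generation_zero` flag for an inoculum cohort. The
default is the convention whose result matches the canonical worked
value (~0.78) from these parameters; the alternatives are retained
because the phrase is genuinely ambiguous. (With a 4.6 Mb round-number
genome the default convention gives 0.779; the packaged default genome
is the BW25113 4,631,469 bp, giving 0.774.)

**Mating side (mass-action model).** Four subpopulations — A and B
(5% each, relative fitness 1.55), background C (90%, 1.2) and the
recombinant AB (1.8) — grow from P_i until the total reaches P_f, with
AB formed at rate γ·A·B/V (within-generation growth integrated exactly;
formed cohorts then take the remaining doubling steps, mirroring the
simulator's sub-step order). γ here is an *effective* AB-forming rate
constant: it folds in co-transfer geometry and is calibrated once by
bisection so the default composition yields 2×10⁵ recombinant cells per
transfer (`CALIBRATED_GAMMA` = 9.566×10⁻¹¹ mL·cell⁻¹·h⁻¹;
`scripts/calibrate_gamma.py` regenerates it). The headline comparison,
log₁₀(recombinant cells) − log₁₀(expected mutants), is ~5.4 orders of
magnitude at the defaults. The stochastic simulator reproduces the
deterministic expectation at small populations and small γ (the
regime where second-order fluxes — e.g. wild-type donors stripping a
recipient's allele — are negligible); the agreement test runs at
P_i = 10⁴ with γ = 2×10⁻⁸.

## Epistasis (`epistasis`)

Fitness values are improvements over wild type (WT ≡ 0). For a
multi-mutation mask, e = (a_combined − Σ singles)/(Σ singles) — one
value per genotype, undefined (flagged) when the additive expectation
is zero. e is invariant to rescaling all fitnesses and to gene
relabeling. Uncertainty is first-order propagation of the entry
s.e.m.s. Pair classification (none/magnitude/sign/reciprocal-sign) uses
the sign of each mutation's effect in the other's background with an
equality tolerance τ (default 2× the pooled s.e.m. when s.e.m.s are
available, else 10⁻⁹); an effect indistinguishable from zero — e.g. a
double exactly matching its stronger single — is reported as
"boundary" rather than forced into a sign class.

## Allele-frequency inference (`allele_dynamics`)

The mean number of tracked mutations per cell is Σfᵢ by linearity of
expectation (loci distinct). The minimum co-occurrence fraction
max(0, Σfᵢ − 1) is the pigeonhole lower bound on cells carrying ≥2 of
the tracked mutations; it is exact when no cell carries more than two,
which is the regime the assays address (the tests enumerate that domain
exhaustively). qPCR frequencies slightly above 1 (≤1.05) are clamped
with a warning — technical error of allele-specific qPCR — and larger
values are rejected. An optional flag treats alleles of the same gene
as mutually exclusive per cell, which adds the consistency requirement
that each gene's summed allele frequency stay ≤1. The mating signature
requires the census to contain the two single-mutant genotypes *and*
their double simultaneously; a missing singleton leaves the pair
unflagged, since the double could then be the singleton's descendant.

## Fluctuation analysis (`fluctuation`)

Cultures are simulated by the classic jackpot construction: mutations
arise per generation with Poisson mean rate·N_{g−1} (one per mutated
division), each at a division drawn uniformly within the generation,
and the clone grows deterministically to N_final/N_birth cells. This
makes simulated counts follow the Lea–Coulson distribution with
m = rate·(N_final − N₀) — the distribution the estimator assumes, so
estimator calibration can be tested cleanly. m̂ maximizes the
likelihood built from the Ma–Sandri–Sarkar recursion, with counts
truncated at max(count)+1 (tail mass folded into the top bin) and
additionally right-censored at a jackpot cap (default 1024) to keep
the O(k²) recursion tractable; censoring keeps the likelihood proper.
The 95% CI is the profile-likelihood crossing of the χ²(1) cutoff with
a normal-on-ln(m) fallback. Note the Lea–Coulson tail is heavy (mass
beyond k_max decays like m/k_max), so truncated probability vectors sum
to 1 only up to that tail. Mutator fold-changes divide two rate
estimates and combine their log-scale CI half-widths in quadrature.

## Synthetic data (`synthetic_data`) and what the benchmarks show

Every generator is a pure function of its parameters and seed and
returns ground truth beside the data. Noise models are deliberately
minimal: Gaussian replicate noise for plate-reader fitness
improvements, additive Gaussian technical error for qPCR frequencies
(clamped to [0, 1.05]), multiplicative log-normal noise for drug
concentrations. Real data depart from these in ways the benchmarks do
not probe: qPCR error grows near 0 and 1 and across primer pairs,
plate-reader fitness has day effects, tolerance trajectories are step
functions of the controller rather than smooth exponentials, and real
populations carry untracked passenger mutations. Passing the synthetic
benchmarks therefore demonstrates correctness of the estimators under
their stated models — recovery of known rates, coverage of stated CIs,
exact landscape algebra — not robustness to every artefact of bench
data.

## Benchmark scenarios and problem sizes

The packaged study conditions use the experimental scale directly
(1.6×10⁶ → 2×10⁸ cells per phase) — the simulator tracks genotype
counts, not cells, so full scale is cheap. The regime race uses the
three recurrent glycerol targets (glpK +0.35, rpoC +0.20, cyaA +0.10,
additive), base rate 10⁻¹⁰ per allele per cell per generation (×20 when
induced), a raw mating constant of 10⁻⁹ mL·cell⁻¹·h⁻¹ with a 100 kb
segment kernel and the oriT anchor ~76 kb upstream of glpK, 100
transfers, 50 seeds per regime, and a target mean relative fitness of
1.5 (reachable only with a multi-mutation genotype). The neutral-drift
check shrinks the bottleneck to 100 cells so fixation happens within
hundreds of transfers. The census benchmark seeds glpK695 and cyaA797
mutants at 45% each with mutation effectively off (10⁻¹²), runs three
transfers, and types 96 isolates, mirroring the allele-specific-PCR
survey design.

## Known limitations

- Conjugation transfers a single contiguous segment per event from one
  anchor; multi-segment transfer and recipient recombination-tract
  heterogeneity are not modeled.
- The mating-side γ is an effective constant calibrated to a printed
  model output, not a measured pair-formation rate; only its order of
  magnitude is meaningful.
- No deleterious mutation load, no plasmid dynamics, no surface
  exclusion, no lag/stationary-phase physiology: fitness is purely the
  exponential growth rate between transfers.
- The stepwise mutant accounting is a bookkeeping convention; its
  alternatives differ by up to ~18× (see the table above) and are all
  exposed.
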