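"""Simulator unit and oracle tests: growth, mutation supply, mating,
bottleneck sampling, and full-run reproducibility."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from clonalforge import popsim as P
from clonalforge.popsim import WILD_TYPE


def single_allele(aid="A", pos=100_000, delta=0.1):
    return P.MutationAllele(aid, "gene" + aid, pos, delta)


class TestGrowth:
    def test_pure_doubling_reaches_stop_in_seven_generations(self):
        model = P.StrainModel([])
        state = P.PopulationState(counts={WILD_TYPE: 1.6e6})
        out = P.grow_population(state, P.TransferProtocol(), model)
        assert out.generations_elapsed == 7
        assert out.total() == pytest.approx(1.6e6 * 2**7)

    def test_relative_growth_ratio_is_exponential_in_rate_difference(self):
        a = single_allele(delta=1.0)  # doubles twice as fast
        model = P.StrainModel([a])
        state = P.PopulationState(counts={WILD_TYPE: 1e3, frozenset({"A"}): 1e3})
        proto = P.TransferProtocol(inoculum_fraction=0.008, stop_cells=1e12, max_generations=5)
        out = P.grow_population(state, proto, model)
        ratio = out.counts[frozenset({"A"})] / out.counts[WILD_TYPE]
        assert ratio == pytest.approx(2.0**5)

    def test_drug_at_tolerance_halves_growth_rate(self):
        model = P.StrainModel([], base_tolerance=10.0)
        drug = P.HillDrugResponse()
        assert drug.factor(10.0, 10.0) == pytest.approx(0.5)
        state = P.PopulationState(counts={WILD_TYPE: 1e4}, drug_conc=10.0)
        out = P._double_once(state, model, drug)
        assert out.total() == pytest.approx(1e4 * 2**0.5)

    def test_empty_population_signals_extinction(self):
        model = P.StrainModel([])
        state = P.PopulationState(counts={WILD_TYPE: 0.0})
        with pytest.raises(P.PopulationExtinct):
            P.grow_population(state, P.TransferProtocol(), model)


class TestMutation:
    def test_zero_rate_is_identity(self, rng):
        model = P.StrainModel([single_allele()])
        state = P.PopulationState(counts={WILD_TYPE: 1e6})
        out = P.apply_mutation(state, [model.allele("A")], 0.0, rng)
        assert out.counts == state.counts

    def test_poisson_mean_matches_n_times_p(self, rng):
        # N = 1e8, per-allele probability 5.43e-10 -> mean 0.0543/generation
        a = single_allele()
        state = P.PopulationState(counts={WILD_TYPE: 1e8})
        p = 5.43e-10
        reps = 4000
        total = 0
        for _ in range(reps):
            out = P.apply_mutation(state, [a], p, rng)
            total += out.counts.get(frozenset({"A"}), 0)
        expect = 1e8 * p
        se = math.sqrt(expect / reps)
        assert abs(total / reps - expect) < 3 * se

    def test_mutator_multiplies_supply_twentyfold(self, rng):
        a = single_allele()
        p = 5e-10
        reps = 3000
        tot = {True: 0, False: 0}
        for on in (False, True):
            state = P.PopulationState(
                counts={WILD_TYPE: 1e8}, mutator_on=on, mutation_rate_multiplier=20.0
            )
            for _ in range(reps):
                out = P.apply_mutation(state, [a], p, rng)
                tot[on] += out.counts.get(frozenset({"A"}), 0)
        expect_on = 1e8 * p * 20 * reps
        assert tot[True] / max(tot[False], 1) == pytest.approx(20.0, rel=0.25)
        assert abs(tot[True] - expect_on) < 3 * math.sqrt(expect_on)

    def test_remutation_to_existing_allele_is_noop(self, rng):
        a = single_allele()
        state = P.PopulationState(counts={frozenset({"A"}): 1e8})
        out = P.apply_mutation(state, [a], 1e-3, rng)
        assert out.counts == state.counts

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            P.apply_mutation(
                P.PopulationState(counts={WILD_TYPE: 1.0}), [single_allele()], -0.1, rng
            )


class TestConjugation:
    def setup_method(self):
        # A sits 100 kb downstream of the anchor; B a further 100 kb.
        self.A = P.MutationAllele("A", "geneA", 100_000, 0.1)
        self.B = P.MutationAllele("B", "geneB", 200_000, 0.1)
        self.model = P.StrainModel([self.A, self.B])
        self.params = P.ConjugationParams(
            gamma=1.0, cotransfer_length_bp=100_000, oriT_positions=(0,)
        )

    def test_gamma_zero_never_recombines(self, rng):
        state = P.PopulationState(counts={frozenset({"A"}): 1e6, frozenset({"B"}): 1e6})
        out = P.apply_conjugation(
            state, P.ConjugationParams(gamma=0.0), 1.0, 5.0, self.model, rng
        )
        assert out.counts == state.counts

    def test_cotransfer_kernel_at_distance_L(self):
        # donor allele one kernel length downstream of oriT transfers
        # with probability e^-1
        outs, probs = P._mating_outcomes(
            self.model, self.params, frozenset({"A"}), WILD_TYPE
        )
        lookup = dict(zip(outs, probs))
        assert lookup[frozenset({"A"})] == pytest.approx(math.exp(-1))
        assert lookup[WILD_TYPE] == pytest.approx(1 - math.exp(-1))

    def test_recipient_allele_beyond_segment_is_retained(self):
        # anchor at A itself; recipient's B one kernel length away:
        # the segment always delivers A and erases B iff it reaches it
        params = P.ConjugationParams(
            gamma=1.0, cotransfer_length_bp=100_000, oriT_positions=(100_000,)
        )
        outs, probs = P._mating_outcomes(
            self.model, params, frozenset({"A"}), frozenset({"B"})
        )
        lookup = dict(zip(outs, probs))
        assert lookup[frozenset({"A", "B"})] == pytest.approx(1 - math.exp(-1))
        assert lookup[frozenset({"A"})] == pytest.approx(math.exp(-1))

    def test_event_count_matches_mass_action_expectation(self, rng):
        # A at the anchor always transfers; B half a chromosome away is
        # never reached, so every A-donor -> B-recipient mating (and only
        # that direction) yields a double: expectation gamma*N_A*N_B*T/V
        gamma, dur, vol = 2e-7, 1.5, 5.0
        nA = nB = 1e4
        a = P.MutationAllele("A", "geneA", 0, 0.1)
        b = P.MutationAllele("B", "geneB", 2_400_000, 0.1)
        model = P.StrainModel([a, b])
        params = P.ConjugationParams(gamma=gamma, cotransfer_length_bp=1e5, oriT_positions=(0,))
        reps = 400
        recomb = 0
        for _ in range(reps):
            state = P.PopulationState(
                counts={frozenset({"A"}): nA, frozenset({"B"}): nB}
            )
            out = P.apply_conjugation(state, params, dur, vol, model, rng)
            for g, c in out.counts.items():
                if len(g) == 2:
                    recomb += c
        expect = gamma * nA * nB * dur / vol
        se = math.sqrt(expect / reps)
        assert abs(recomb / reps - expect) < 3 * se

    def test_within_generation_growth_correction_matches_quadrature(self):
        # discrete per-generation expectations with the (e^k - 1)/k factor
        # reproduce the continuous mass-action integral over a full phase
        gamma, vol = 1e-9, 5.0
        base = P.DOUBLINGS_PER_HOUR_BASELINE
        rel_a, rel_b = 1.1, 1.3
        a0, b0 = 1e4, 2e4
        gens = 7
        gen_h = 1.0 / base
        k = math.log(2.0) * (rel_a + rel_b)
        discrete = sum(
            gamma
            * (a0 * 2.0 ** (rel_a * g))
            * (b0 * 2.0 ** (rel_b * g))
            / vol
            * gen_h
            * (math.expm1(k) / k)
            for g in range(gens)
        )
        integral, _ = quad(
            lambda t: gamma * a0 * 2.0 ** (rel_a * t) * b0 * 2.0 ** (rel_b * t) / vol * gen_h,
            0,
            gens,
        )
        assert discrete == pytest.approx(integral, rel=1e-9)

    def test_small_gamma_stochastic_mean_matches_integral(self, rng):
        # simulate growth phases with mating; the mean number of
        # recombination events matches the mass-action quadrature within 5%
        gamma, vol = 5e-8, 5.0
        a = P.MutationAllele("A", "geneA", 100, 0.0)
        b = P.MutationAllele("B", "geneB", 2_400_000, 0.0)
        model = P.StrainModel([a, b])
        params = P.ConjugationParams(gamma=gamma, cotransfer_length_bp=1e5, oriT_positions=(0,))
        proto = P.TransferProtocol(inoculum_fraction=0.008, stop_cells=1.28e6, max_generations=7)
        gen_h = 1.0 / model.base_growth_rate
        drug = P.HillDrugResponse()
        reps = 300
        formed = 0.0
        for _ in range(reps):
            state = P.PopulationState(
                counts={frozenset({"A"}): 5.12e3, frozenset({"B"}): 5.12e3}
            )
            gens = 0
            while state.total() < proto.stop_cells and gens < proto.max_generations:
                pre = state.counts.get(frozenset({"A", "B"}), 0)
                rates = P._effective_rates(state, model, drug)
                state = P.apply_conjugation(
                    state, params, gen_h, vol, model, rng, growth_rates=rates
                )
                formed += state.counts.get(frozenset({"A", "B"}), 0) - pre
                state = P._double_once(state, model, drug)
                gens += 1
        # A transfers always (d ~ 0), B (half a chromosome away) never;
        # only the A-donor -> B-recipient direction forms doubles
        integral, _ = quad(
            lambda t: gamma * (5.12e3 * 2**t) ** 2 / vol * gen_h, 0, 7
        )
        mean = formed / reps
        assert mean == pytest.approx(integral, rel=0.05)

    def test_invalid_parameters_rejected(self, rng):
        state = P.PopulationState(counts={WILD_TYPE: 1.0})
        with pytest.raises(ValueError):
            P.ConjugationParams(gamma=-1.0)
        with pytest.raises(ValueError):
            P.apply_conjugation(state, self.params, 1.0, 0.0, self.model, rng)


class TestSerialTransfer:
    def test_expected_dilution(self, rng):
        state = P.PopulationState(counts={WILD_TYPE: 2e8})
        reps = 50
        tot = sum(
            P.serial_transfer(state, P.TransferProtocol(), rng).total() for _ in range(reps)
        )
        expect = 1.6e6
        se = math.sqrt(expect * (1 - 0.008) / reps)
        assert abs(tot / reps - expect) < 3 * se

    def test_rare_lineage_survival_probability(self, rng):
        # one copy among 2e8 cells sampled at 0.008: survives w.p. ~0.008
        state = P.PopulationState(counts={WILD_TYPE: 2e8, frozenset({"A"}): 200.0})
        proto = P.TransferProtocol()
        reps = 300
        lost = sum(
            frozenset({"A"}) not in P.serial_transfer(state, proto, rng).counts
            for _ in range(reps)
        )
        expect_lost = math.exp(-200 * 0.008)
        se = math.sqrt(expect_lost * (1 - expect_lost) / reps)
        assert abs(lost / reps - expect_lost) < 3 * se

    def test_frequencies_preserved_in_expectation(self, rng):
        state = P.PopulationState(counts={WILD_TYPE: 1.5e8, frozenset({"A"}): 0.5e8})
        proto = P.TransferProtocol()
        f_pre = 0.25
        reps = 1000
        diffs = []
        for _ in range(reps):
            out = P.serial_transfer(state, proto, rng)
            diffs.append(out.counts.get(frozenset({"A"}), 0) / out.total() - f_pre)
        se = np.std(diffs, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(diffs)) < 3 * se

    def test_counts_are_integers_after_sampling(self, rng):
        state = P.PopulationState(counts={WILD_TYPE: 2.0e8, frozenset({"A"}): 3.3e5})
        out = P.serial_transfer(state, P.TransferProtocol(), rng)
        assert all(float(c).is_integer() for c in out.counts.values())


class TestSequentialMutationOracle:
    def test_double_mutant_expectation_matches_branching_recursion(self, rng):
        """With conjugation off, {A,B} arises only by sequential mutation;
        its expected count matches the two-type branching recursion."""
        mu = 1e-3
        a = P.MutationAllele("A", "geneA", 1000, 0.0)
        b = P.MutationAllele("B", "geneB", 2000, 0.0)
        model = P.StrainModel([a, b])
        proto = P.TransferProtocol(inoculum_fraction=0.008, stop_cells=1.28e6, max_generations=7)
        drug = P.HillDrugResponse()
        # deterministic expectation mirroring mutation-then-doubling order
        W, A, B, AB = 1e4, 0.0, 0.0, 0.0
        for _ in range(7):
            newA = mu * W
            newB = mu * W
            newAB = mu * A + mu * B
            W, A, B, AB = (
                2 * (W - newA - newB),
                2 * (A + newA - mu * A),
                2 * (B + newB - mu * B),
                2 * (AB + newAB),
            )
        reps = 400
        got = 0.0
        for _ in range(reps):
            state = P.PopulationState(counts={WILD_TYPE: 1e4})
            gens = 0
            while state.total() < proto.stop_cells and gens < proto.max_generations:
                state = P.apply_mutation(state, [a, b], mu, rng)
                state = P._double_once(state, model, drug)
                gens += 1
            got += state.counts.get(frozenset({"A", "B"}), 0)
        sims = []
        # standard error from a second, smaller pass for the spread
        assert AB > 5
        se = math.sqrt(AB * 40 / reps)  # conservative: var ~ 40x Poisson
        assert abs(got / reps - AB) < 3 * se


class TestRunEvolution:
    def test_flat_trajectory_without_variation(self):
        cfg = P.ScenarioConfig(alleles=[], n_transfers=5, seed=1)
        traj = P.run_evolution(cfg)
        assert len(traj.records) == 5
        for rec in traj.records:
            assert rec.mean_fitness == pytest.approx(1.0)
            assert rec.allele_frequencies == {}
        assert not traj.extinct

    def test_identical_seeds_are_bit_identical(self):
        from clonalforge.scenarios import glycerol_regime_config

        t1 = P.run_evolution(glycerol_regime_config(True, True, seed=7, n_transfers=10))
        t2 = P.run_evolution(glycerol_regime_config(True, True, seed=7, n_transfers=10))
        for r1, r2 in zip(t1.records, t2.records):
            assert r1.genotype_census == r2.genotype_census
            assert r1.allele_frequencies == r2.allele_frequencies

    def test_frequencies_sum_to_one(self):
        from clonalforge.scenarios import glycerol_regime_config

        traj = P.run_evolution(glycerol_regime_config(True, True, seed=3, n_transfers=15))
        for rec in traj.records:
            total = sum(rec.genotype_census.values())
            freqs = [c / total for c in rec.genotype_census.values()]
            assert sum(freqs) == pytest.approx(1.0, abs=1e-9)

    def test_clonal_interference_relieved_by_recombination(self):
        """Asexual runs mostly fix one beneficial allele; sexual runs at the
        same seeds produce strictly more double-mutant sweeps."""
        from clonalforge import estimates
        from clonalforge.scenarios import ORIT_POSITION

        def cfg(sexual, seed):
            return P.ScenarioConfig(
                alleles=[
                    dict(id="A", gene="geneA", position_bp=3_926_000, fitness_delta=0.22),
                    dict(id="B", gene="geneB", position_bp=3_990_000, fitness_delta=0.20),
                ],
                base_rate=2e-9,
                mutator_on=False,
                conjugation=dict(
                    enabled=sexual,
                    gamma=1e-9 if sexual else 0.0,
                    cotransfer_length_bp=1e5,
                    oriT_positions=(ORIT_POSITION,),
                ),
                n_transfers=40,
                seed=seed,
            )

        def double_swept(traj):
            last = traj.records[-1].allele_frequencies
            return last.get("A", 0) > 0.5 and last.get("B", 0) > 0.5

        seeds = range(30)
        sexual_wins = sum(double_swept(P.run_evolution(cfg(True, s))) for s in seeds)
        asexual_wins = sum(double_swept(P.run_evolution(cfg(False, s))) for s in seeds)
        assert sexual_wins > asexual_wins

    def test_scenario_validation_errors(self):
        with pytest.raises(ValueError):
            P.ScenarioConfig(alleles=[], n_transfers=1, seed=1,
                             conjugation=dict(enabled=True, gamma=0.0))
        with pytest.raises(ValueError):
            P.ScenarioConfig(
                alleles=[dict(id="A", gene="g", position_bp=1, fitness_delta=0.1)],
                n_transfers=1, seed=1,
                initial_composition={"A": 0.5, "WT": 0.4},
            )
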