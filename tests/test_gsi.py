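"""Genotype simulation, assignment likelihoods, EM, accuracy and fits."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest

from poolgsi import gsi, popgen, synthetic
from poolgsi.gsi import (
    BaselineSet,
    GenotypeMatrix,
    assign,
    accuracy_curve,
    em_mixture,
    evaluate_accuracy,
    fit_required_markers,
    genotype_log_likelihood,
    independent_alleles,
    simulate_genotypes,
)
from poolgsi.tables import AlleleFrequencyTable


def _table(freq_matrix, pops=None, n=50.0):
    freq_matrix = np.asarray(freq_matrix, dtype=float)
    pops = pops or [f"p{j}" for j in range(1, freq_matrix.shape[1] + 1)]
    df = pd.DataFrame(
        freq_matrix,
        index=[f"L{i}" for i in range(1, freq_matrix.shape[0] + 1)],
        columns=pops,
    )
    return AlleleFrequencyTable(df, pd.Series(float(n), index=pops))


def _baseline_from_counts(pops, loci, b_counts, copies):
    return BaselineSet(
        pops,
        pd.DataFrame(np.asarray(b_counts, dtype=float), index=loci, columns=pops),
        pd.Series(np.asarray(copies, dtype=float), index=pops),
    )


def polya_genotype_prob(x_a, x_b, dosage):
    """Brute-force Polya-urn probability of drawing two gene copies.

    Enumerates the two ordered draws under a Dirichlet(1/2, 1/2) posterior
    given baseline counts (x_a, x_b); independent of the closed form used
    by the implementation.
    """
    total = 0.0
    for draw in product("AB", repeat=2):
        p = 1.0
        xa, xb = x_a + 0.5, x_b + 0.5
        for allele in draw:
            denom = xa + xb
            if allele == "A":
                p *= xa / denom
                xa += 1
            else:
                p *= xb / denom
                xb += 1
        if draw.count("B") == dosage:
            total += p
    return total


class TestSimulateGenotypes:
    def test_fixed_locus_gives_dosage_two(self):
        table = _table([[1.0, 1.0]])
        gm = simulate_genotypes(table, 20, seed=1)
        assert (gm.genotypes.to_numpy() == 2).all()

    def test_hwe_proportions_at_half(self):
        table = _table([[0.5]], pops=["p1"])
        gm = simulate_genotypes(table, 10000, seed=2)
        counts = np.bincount(gm.genotypes.to_numpy().ravel(), minlength=3) / 10000
        np.testing.assert_allclose(counts, [0.25, 0.5, 0.25], atol=0.02)

    def test_deterministic(self, small_system):
        a = simulate_genotypes(small_system["freqs"], 10, seed=3).genotypes
        b = simulate_genotypes(small_system["freqs"], 10, seed=3).genotypes
        pd.testing.assert_frame_equal(a, b)


class TestRannalaMountain:
    def test_empty_baseline_closed_form(self):
        base = _baseline_from_counts(["p1"], ["L1"], [[0]], [0])
        ll = genotype_log_likelihood(pd.DataFrame({"L1": [0, 1, 2]}), base)
        probs = np.exp(ll.to_numpy().ravel())
        np.testing.assert_allclose(probs, [0.375, 0.25, 0.375], atol=1e-12)

    def test_all_A_baseline_penalizes_BB(self):
        base = _baseline_from_counts(["p1"], ["L1"], [[0]], [200])
        ll = genotype_log_likelihood(pd.DataFrame({"L1": [2]}), base)
        expected = (0.5 * 1.5) / (201 * 202)
        assert math.exp(ll.iloc[0, 0]) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("x_b,copies", [(0, 0), (3, 10), (10, 10), (57, 140)])
    def test_genotype_probabilities_sum_to_one(self, x_b, copies):
        base = _baseline_from_counts(["p1"], ["L1"], [[x_b]], [copies])
        ll = genotype_log_likelihood(pd.DataFrame({"L1": [0, 1, 2]}), base)
        assert np.exp(ll.to_numpy()).sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_polya_urn_enumeration(self):
        # 2-locus, 2-population toy baseline vs brute-force Polya urn
        base = _baseline_from_counts(
            ["p1", "p2"], ["L1", "L2"], [[3, 17], [9, 2]], [20, 24]
        )
        for g1, g2 in product(range(3), repeat=2):
            ll = genotype_log_likelihood(
                pd.DataFrame({"L1": [g1], "L2": [g2]}), base
            )
            for s, pop in enumerate(["p1", "p2"]):
                copies = base.gene_copies[pop]
                expected = 1.0
                for locus, g in (("L1", g1), ("L2", g2)):
                    xb = base.b_counts.loc[locus, pop]
                    expected *= polya_genotype_prob(copies - xb, xb, g)
                assert math.exp(ll.iloc[0, s]) == pytest.approx(expected, rel=1e-12)


class TestEmMixture:
    def test_single_source_mixture_recovered(self):
        rng = np.random.default_rng(31)
        freq = np.column_stack([rng.uniform(0.05, 0.3, 60),
                                rng.uniform(0.7, 0.95, 60)])
        table = _table(freq, pops=["near", "far"])
        base = BaselineSet.from_genotypes(
            simulate_genotypes(table, 100, role="baseline", seed=32)
        )
        mix = simulate_genotypes(table, 200, seed=33,
                                 n_by_pop={"near": 200, "far": 0})
        theta, trace = em_mixture(mix, base)
        assert theta["near"] >= 0.99

    def test_loglik_monotone_nondecreasing(self, small_system):
        freqs = small_system["freqs"]
        base = BaselineSet.from_genotypes(
            simulate_genotypes(freqs, 50, role="baseline", seed=34)
        )
        mix = simulate_genotypes(freqs, 50, seed=35)
        _, trace = em_mixture(mix, base)
        diffs = np.diff(trace)
        assert (diffs >= -1e-8).all()

    def test_identical_populations_recover_combined_share(self):
        rng = np.random.default_rng(36)
        p = rng.uniform(0.2, 0.8, 80)
        distinct = rng.uniform(0.2, 0.8, 80)
        table = _table(np.column_stack([p, p, distinct]),
                       pops=["twin1", "twin2", "other"])
        base = BaselineSet.from_genotypes(
            simulate_genotypes(table, 200, role="baseline", seed=37)
        )
        mix = simulate_genotypes(
            table, 0, seed=38, n_by_pop={"twin1": 300, "twin2": 100, "other": 200}
        )
        theta, _ = em_mixture(mix, base)
        assert theta["twin1"] + theta["twin2"] == pytest.approx(400 / 600, abs=0.05)

    def test_three_stock_composition_recovery(self):
        truth = synthetic.make_truth(100, 3, pop_fst=0.1,
                                     outlier_fraction=0.0, seed=39)
        freqs, _ = synthetic.generate_population_frequencies(truth)
        pops = freqs.populations
        base = BaselineSet.from_genotypes(
            simulate_genotypes(freqs, 100, role="baseline", seed=40)
        )
        mix = simulate_genotypes(
            freqs, 0, seed=41,
            n_by_pop={pops[0]: 250, pops[1]: 150, pops[2]: 100},
        )
        theta, _ = em_mixture(mix, base)
        expected = np.array([0.5, 0.3, 0.2])
        assert np.abs(theta.to_numpy() - expected).max() <= 0.05


class TestAssign:
    def test_private_alleles_give_decisive_posterior(self):
        freq = np.vstack([np.tile([0.0, 1.0], (30, 1))])
        table = _table(freq, pops=["a", "b"])
        base = BaselineSet.from_genotypes(
            simulate_genotypes(table, 100, role="baseline", seed=51)
        )
        mix = simulate_genotypes(table, 0, seed=52, n_by_pop={"a": 0, "b": 50})
        result = assign(mix, base, prior="uniform")
        assert (result.posterior["b"] > 0.999).all()

    def test_identical_populations_split_evenly(self):
        freq = np.tile([0.4, 0.4], (20, 1))
        table = _table(freq, pops=["a", "b"])
        base = _baseline_from_counts(
            ["a", "b"], [f"L{i}" for i in range(1, 21)],
            np.full((20, 2), 40.0), [100, 100],
        )
        mix = simulate_genotypes(table, 30, seed=53)
        mix = GenotypeMatrix(
            mix.genotypes[[f"L{i}" for i in range(1, 21)]], mix.origin, "mixture"
        )
        with pytest.warns(UserWarning, match="tied"):
            result = assign(mix, base, prior="uniform")
        np.testing.assert_allclose(result.posterior.to_numpy(), 0.5, atol=1e-9)

    def test_posteriors_sum_to_one(self, small_system):
        freqs = small_system["freqs"]
        base = BaselineSet.from_genotypes(
            simulate_genotypes(freqs, 60, role="baseline", seed=54)
        )
        mix = simulate_genotypes(freqs, 40, seed=55)
        result = assign(mix, base)
        np.testing.assert_allclose(
            result.posterior.sum(axis=1).to_numpy(), 1.0, atol=1e-9
        )


class TestEvaluateAccuracy:
    def test_all_correct_is_hundred(self):
        result = gsi.AssignmentResult(
            posterior=pd.DataFrame({"a": [1.0, 1.0]}),
            assigned=pd.Series(["a", "a"]),
            origin=pd.Series(["a", "a"]),
        )
        overall, per_pop = evaluate_accuracy(result)
        assert overall == 100.0

    def test_random_assignment_matches_chance(self):
        rng = np.random.default_rng(61)
        pops = [f"p{i}" for i in range(23)]
        origin = pd.Series(np.repeat(pops, 500))
        assigned = pd.Series(rng.choice(pops, size=len(origin)))
        result = gsi.AssignmentResult(
            posterior=pd.DataFrame(), assigned=assigned, origin=origin
        )
        overall, _ = evaluate_accuracy(result)
        assert overall == pytest.approx(100 / 23, abs=2.0)

    def test_per_population_average_recovers_overall(self):
        origin = pd.Series(["a"] * 10 + ["b"] * 30)
        assigned = pd.Series(["a"] * 5 + ["b"] * 5 + ["b"] * 30)
        result = gsi.AssignmentResult(
            posterior=pd.DataFrame(), assigned=assigned, origin=origin
        )
        overall, per_pop = evaluate_accuracy(result)
        weights = origin.value_counts()
        weighted = (per_pop * weights / weights.sum()).sum()
        assert weighted == pytest.approx(overall)


class TestIndependentAlleles:
    def test_snp_panel(self):
        assert independent_alleles([2] * 100) == 100

    def test_str_panel(self):
        ks = [13] * 15 + [14] * 3
        assert independent_alleles(ks) == 219

    def test_empty_panel(self):
        assert independent_alleles([]) == 0


class TestAccuracyCurve:
    def test_rejects_degenerate_size(self, small_system):
        with pytest.raises(ValueError):
            accuracy_curve(small_system["freqs"], small_system["freqs"].loci,
                           [0], seed=1)

    def test_accuracy_improves_with_panel_size(self, small_system):
        freqs = small_system["freqs"]
        ranking = gsi.pd.Series(popgen.delta(freqs)).sort_values(ascending=False)
        curve = accuracy_curve(
            freqs, list(ranking.index), [10, 25, 50, 100],
            n_baseline=60, n_mixture=60, seed=6,
        )
        assert curve["overall_pct"].is_monotonic_increasing


class TestExponentialFit:
    def test_exact_recovery_on_noiseless_data(self):
        x = np.array([25, 50, 100, 200, 400], dtype=float)
        a_true, b_true = math.log(100), -50.0
        y = np.exp(a_true + b_true / x)
        curve = pd.DataFrame({"independent_alleles": x, "overall_pct": y})
        fit = fit_required_markers(curve)
        assert fit.a == pytest.approx(a_true, abs=1e-9)
        assert fit.b == pytest.approx(b_true, abs=1e-9)
        assert fit.required_x[95.0] == math.ceil(-50 / (math.log(95) - a_true)) == 975

    def test_required_x_matches_direct_inversion(self):
        x = np.array([10, 20, 50, 150], dtype=float)
        a_true, b_true = math.log(99), -30.0
        y = np.exp(a_true + b_true / x)
        fit = fit_required_markers(
            pd.DataFrame({"independent_alleles": x, "overall_pct": y})
        )
        for t in (80.0, 90.0, 95.0):
            direct = math.ceil(b_true / (math.log(t) - a_true))
            assert fit.required_x[t] == direct

    def test_saturated_curve_reports_smallest_observed_x(self):
        curve = pd.DataFrame(
            {"independent_alleles": [25.0, 50.0, 100.0],
             "overall_pct": [100.0, 100.0, 100.0]}
        )
        with pytest.warns(UserWarning):
            fit = fit_required_markers(curve)
        assert abs(fit.b) < 1e-9
        assert fit.required_x[95.0] == 25

    def test_target_above_asymptote_unattainable(self):
        x = np.array([10, 50, 100], dtype=float)
        y = np.exp(math.log(90) - 20.0 / x)
        fit = fit_required_markers(
            pd.DataFrame({"independent_alleles": x, "overall_pct": y})
        )
        assert fit.required_x[95.0] is None
        assert fit.required_x[80.0] is not None
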