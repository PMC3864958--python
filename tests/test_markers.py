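"""Ranking, quartile classification, linkage pruning, subsets, outlier scan."""

import numpy as np
import pandas as pd
import pytest

from poolgsi import markers, popgen, synthetic
from poolgsi.markers import (
    McmcSettings,
    classify_upper_quartile,
    counts_from_frequencies,
    log10_posterior_odds,
    make_subsets,
    prune_linked,
    rank_loci,
    scan_outliers,
    top_overlap,
)


class TestRankLoci:
    def test_descending_by_score(self):
        scores = pd.Series({"l1": 0.5, "l2": 0.2})
        r = rank_loci("delta", scores)
        assert r.loci == ["l1", "l2"]

    def test_ties_break_lexicographically(self):
        scores = pd.Series({"b": 0.5, "a": 0.5, "c": 0.1})
        r = rank_loci("delta", scores)
        assert r.loci == ["a", "b", "c"]

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.random(50), index=[f"x{i:02d}" for i in range(50)])
        r = rank_loci("pairwise_fst", scores)
        oracle = sorted(scores.index, key=lambda l: (-scores[l], l))
        assert r.loci == oracle

    def test_nan_scores_sink_to_bottom(self):
        scores = pd.Series({"a": np.nan, "b": 0.1, "c": 0.9})
        r = rank_loci("global_fst", scores)
        assert r.loci == ["c", "b", "a"]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            rank_loci("bogus", pd.Series({"a": 1.0}))

    def test_random_is_seeded_permutation(self):
        scores = pd.Series(0.0, index=[f"x{i}" for i in range(30)])
        r1 = rank_loci("random", scores, seed=5)
        r2 = rank_loci("random", scores, seed=5)
        assert r1.loci == r2.loci
        assert sorted(r1.loci) == sorted(scores.index)


class TestUpperQuartile:
    def test_integer_scores_1_to_100(self):
        scores = pd.Series(
            np.arange(1, 101, dtype=float), index=[f"l{i:03d}" for i in range(100)]
        )
        flags = classify_upper_quartile(scores)
        # linear-interpolation 75th percentile of 1..100 is 75.25
        assert flags.sum() == 25
        assert flags[scores >= 75.25].all()

    def test_degenerate_equal_scores_all_flagged(self):
        scores = pd.Series(1.0, index=list("abcd"))
        assert classify_upper_quartile(scores).all()

    def test_single_high_score(self):
        scores = pd.Series([0.0, 0.0, 0.0, 1.0], index=list("abcd"))
        flags = classify_upper_quartile(scores)
        assert flags.tolist() == [False, False, False, True]


class TestPruneLinked:
    def _map(self, rows):
        return pd.DataFrame(rows, columns=["locus_id", "chromosome", "position_cM"])

    def test_colocated_keeps_better_ranked(self):
        ranking = rank_loci("delta", pd.Series({"good": 0.9, "bad": 0.1}))
        pmap = self._map([("good", "c1", 10.0), ("bad", "c1", 10.5)])
        pruned = prune_linked(ranking, pmap, min_cM=1.0)
        assert pruned.loci == ["good"]

    def test_different_chromosomes_all_kept(self):
        ranking = rank_loci("delta", pd.Series({"a": 0.9, "b": 0.1}))
        pmap = self._map([("a", "c1", 10.0), ("b", "c2", 10.0)])
        assert prune_linked(ranking, pmap).loci == ["a", "b"]

    def test_unmapped_loci_kept(self):
        ranking = rank_loci("delta", pd.Series({"a": 0.9, "zz": 0.5, "b": 0.1}))
        pmap = self._map([("a", "c1", 10.0), ("b", "c1", 10.2)])
        assert prune_linked(ranking, pmap).loci == ["a", "zz"]

    def test_kept_set_satisfies_pairwise_constraint(self):
        rng = np.random.default_rng(11)
        loci = [f"m{i:03d}" for i in range(100)]
        pmap = self._map(
            [(l, f"c{rng.integers(1, 4)}", float(rng.uniform(0, 30)))
             for l in loci]
        )
        scores = pd.Series(rng.random(100), index=loci)
        pruned = prune_linked(rank_loci("delta", scores), pmap, min_cM=1.0)
        pos = pmap.set_index("locus_id")
        kept = pruned.loci
        for i, x in enumerate(kept):
            for y in kept[i + 1:]:
                if pos.at[x, "chromosome"] == pos.at[y, "chromosome"]:
                    assert abs(pos.at[x, "position_cM"]
                               - pos.at[y, "position_cM"]) > 1.0
        # greedily feasible: every dropped locus conflicts with a kept one
        for locus in set(loci) - set(kept):
            conflicts = [
                k for k in kept
                if pos.at[k, "chromosome"] == pos.at[locus, "chromosome"]
                and abs(pos.at[k, "position_cM"] - pos.at[locus, "position_cM"]) <= 1.0
            ]
            assert conflicts


class TestSubsets:
    def test_nested_prefixes(self):
        scores = pd.Series(np.arange(300, 0, -1, dtype=float),
                           index=[f"l{i:03d}" for i in range(300)])
        ranking = rank_loci("delta", scores)
        subs = make_subsets(ranking, [25, 50])
        assert set(subs[0].loci) <= set(subs[1].loci)

    def test_random_subsets_reproducible_and_distinct(self):
        scores = pd.Series(0.0, index=[f"l{i:04d}" for i in range(2880)])
        ranking = rank_loci("random", scores, seed=1)
        s1 = make_subsets(ranking, [100], random=True, seed=2)[0]
        s2 = make_subsets(ranking, [100], random=True, seed=2)[0]
        assert s1.loci == s2.loci
        assert len(set(s1.loci)) == 100

    def test_oversized_subset_rejected(self):
        ranking = rank_loci("delta", pd.Series({"a": 1.0}))
        with pytest.raises(ValueError):
            make_subsets(ranking, [2])


class TestOverlap:
    def test_overlap_identity_symmetry_bound(self):
        rng = np.random.default_rng(4)
        idx = [f"l{i:03d}" for i in range(200)]
        ra = rank_loci("delta", pd.Series(rng.random(200), index=idx))
        rb = rank_loci("delta", pd.Series(rng.random(200), index=idx))
        assert top_overlap(ra, ra, 100) == 100
        assert top_overlap(ra, rb, 100) == top_overlap(rb, ra, 100)
        assert 0 <= top_overlap(ra, rb, 100) <= 100

    def test_pairwise_and_delta_rankings_agree_on_structured_data(self):
        truth = synthetic.make_truth(600, 8, pop_fst=0.05, outlier_fraction=0.05,
                                     outlier_multiplier=8.0, seed=55)
        freqs, _ = synthetic.generate_population_frequencies(truth)
        r_pw = rank_loci("pairwise_fst", popgen.fst_pairwise(freqs).per_locus_mean)
        r_d = rank_loci("delta", popgen.delta(freqs))
        assert top_overlap(r_pw, r_d, 100) >= 50


class TestOutlierScan:
    def test_log10_po_closed_form(self):
        # inclusion probability 0.99 -> log10(0.99/0.01) ~ 1.996 ("decisive")
        lpo = log10_posterior_odds(np.array([0.99]), n_samples=1000)
        assert lpo[0] == pytest.approx(np.log10(99), abs=1e-12)

    def test_counts_within_gene_copies(self, small_system):
        counts, ncop = counts_from_frequencies(small_system["freqs"])
        assert counts.min() >= 0
        assert (counts <= ncop).all()
        assert (ncop == 100).all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            scan_outliers(np.array([[0.5]]), np.array([[10]]))
        with pytest.raises(ValueError):
            scan_outliers(np.array([[12]]), np.array([[10]]))

    def test_recovers_planted_outliers_small(self):
        truth = synthetic.make_truth(300, 12, pop_fst=0.05, outlier_fraction=0.05,
                                     outlier_multiplier=8.0, seed=71)
        freqs, flags = synthetic.generate_population_frequencies(truth)
        counts, ncop = counts_from_frequencies(freqs)
        res = scan_outliers(
            counts, ncop, loci=freqs.loci,
            mcmc=McmcSettings(burn_in=600, iterations=400, thinning=2),
            seed=3,
        )
        sel = res.table["selected"]
        truth_arr = flags.to_numpy()
        tp = int((sel.to_numpy() & truth_arr).sum())
        fp = int((sel.to_numpy() & ~truth_arr).sum())
        assert tp / truth_arr.sum() >= 0.7
        assert fp <= max(2, 0.2 * (tp + fp))

    def test_q_values_monotone_in_posterior_odds(self, small_system):
        counts, ncop = counts_from_frequencies(small_system["freqs"])
        res = scan_outliers(
            counts, ncop, loci=small_system["freqs"].loci,
            mcmc=McmcSettings(burn_in=200, iterations=150, thinning=1),
            seed=5,
        )
        tab = res.table.sort_values("log10_PO", ascending=False)
        assert tab["q_value"].is_monotonic_increasing

    def test_deterministic_given_seed(self, small_system):
        counts, ncop = counts_from_frequencies(small_system["freqs"])
        settings = McmcSettings(burn_in=100, iterations=50, thinning=1)
        a = scan_outliers(counts, ncop, mcmc=settings, seed=8).table
        b = scan_outliers(counts, ncop, mcmc=settings, seed=8).table
        pd.testing.assert_frame_equal(a, b)
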