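import numpy as np
import pandas as pd
import pytest

from methylseed.dmr_calling import Dmr
from methylseed.dmr_compare import (
    EndoDmr,
    _count_both,
    classify_endo_dmrs,
    cluster_endo_dmrs,
    feature_overlap_fractions,
    merge_and_classify,
    overlap_permutation_test,
    replicate_consistent_hyper,
)
from methylseed.io_formats import GenomicInterval


def iv(start, end, chrom="Chr1"):
    return GenomicInterval(chrom, start, end)


class TestMergeAndClassify:
    def test_single_overlap(self):
        res = merge_and_classify([iv(0, 100)], [iv(50, 150)])
        assert (res.only_a, res.both, res.only_b) == (0, 1, 0)
        assert res.merged == [iv(0, 150)]

    def test_disjoint(self):
        res = merge_and_classify([iv(0, 100)], [iv(200, 300)])
        assert (res.only_a, res.both, res.only_b) == (1, 0, 1)

    def test_within_set_merge_first(self):
        res = merge_and_classify([iv(0, 100), iv(90, 200)], [])
        assert (res.only_a, res.both, res.only_b) == (1, 0, 0)
        assert res.merged == [iv(0, 200)]

    def test_adjacent_intervals_do_not_merge(self):
        res = merge_and_classify([iv(0, 100)], [iv(100, 200)])
        assert (res.only_a, res.both, res.only_b) == (1, 0, 1)

    def test_count_conservation(self):
        rng = np.random.default_rng(2)
        A = [iv(int(s), int(s) + 50) for s in rng.integers(0, 10_000, 30)]
        B = [iv(int(s), int(s) + 80) for s in rng.integers(0, 10_000, 30)]
        res = merge_and_classify(A, B)
        assert res.only_a + res.both + res.only_b == len(res.merged)

    def test_symmetry_up_to_label_swap(self):
        rng = np.random.default_rng(3)
        A = [iv(int(s), int(s) + 120) for s in rng.integers(0, 50_000, 40)]
        B = [iv(int(s), int(s) + 60) for s in rng.integers(0, 50_000, 25)]
        ab = merge_and_classify(A, B)
        ba = merge_and_classify(B, A)
        assert (ab.only_a, ab.both, ab.only_b) == (ba.only_b, ba.both, ba.only_a)

    def test_fast_both_counter_matches_reference(self):
        """_count_both (used inside shuffles) agrees with merge_and_classify."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            nA, nB = rng.integers(1, 40, 2)
            A = [iv(int(s), int(s + rng.integers(10, 400))) for s in rng.integers(0, 20_000, nA)]
            B = [iv(int(s), int(s + rng.integers(10, 400))) for s in rng.integers(0, 20_000, nB)]
            ref = merge_and_classify(A, B).both
            start = np.array([x.start for x in A + B])
            end = np.array([x.end for x in A + B])
            codes = np.zeros(len(start), dtype=np.int64)
            src = np.array([0] * len(A) + [1] * len(B))
            assert _count_both(codes, start, end, src, 1) == ref


class TestOverlapPermutationTest:
    def test_identical_dense_sets_give_p_zero(self):
        rng = np.random.default_rng(5)
        A = [iv(int(s) * 2000, int(s) * 2000 + 1000) for s in range(250)]
        res = overlap_permutation_test(A, list(A), {"Chr1": 500_000}, n_trials=100, rng_seed=1)
        assert res.both == len(merge_and_classify(A, A).merged)
        assert res.perm_p == 0.0

    def test_empty_set_degenerate(self):
        res = overlap_permutation_test([iv(0, 100)], [], {"Chr1": 10_000}, n_trials=50, rng_seed=1)
        assert res.perm_p == 0.0
        assert res.degenerate

    def test_interval_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            overlap_permutation_test([iv(0, 20_000)], [iv(0, 10)], {"Chr1": 10_000})

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        A = [iv(int(s), int(s) + 500) for s in rng.integers(0, 90_000, 20)]
        B = [iv(int(s), int(s) + 500) for s in rng.integers(0, 90_000, 20)]
        r1 = overlap_permutation_test(A, B, {"Chr1": 100_000}, n_trials=200, rng_seed=9)
        r2 = overlap_permutation_test(A, B, {"Chr1": 100_000}, n_trials=200, rng_seed=9)
        assert r1.perm_p == r2.perm_p

    def test_pseudo_count_bounds_p_away_from_zero(self):
        A = [iv(0, 100)]
        res = overlap_permutation_test(A, [], {"Chr1": 10_000}, n_trials=50,
                                       rng_seed=1, pseudo_count=True)
        assert res.perm_p == pytest.approx(1 / 51)

    def test_unrelated_sets_give_moderate_p(self):
        """Independent random sets should not look significantly overlapping."""
        rng = np.random.default_rng(7)
        glen = 10_000_000
        A = [iv(int(s), int(s) + 5000) for s in rng.integers(0, glen - 5000, 150)]
        B = [iv(int(s), int(s) + 5000) for s in rng.integers(0, glen - 5000, 150)]
        res = overlap_permutation_test(A, B, {"Chr1": glen}, n_trials=500, rng_seed=3)
        assert res.perm_p > 0.01


class TestEndoDmrClassification:
    def _dmr(self, endosperm, embryo, dry):
        return Dmr("Chr1", 0, 100, "CHH", (10,), 1,
                   {"endosperm": endosperm, "embryo": embryo, "dry_seed": dry})

    @pytest.mark.parametrize("endo,emb,dry,expected", [
        (0.45, 0.05, 0.08, True),    # hypermethylated only in endosperm
        (0.30, 0.25, 0.05, False),   # difference 0.05 <= 0.1
        (0.45, 0.05, 0.20, False),   # methylated in wild-type dry seed
        (0.45, 0.12, 0.05, False),   # embryo not unmethylated
        (0.21, 0.05, 0.05, True),    # difference 0.16 > 0.1
    ])
    def test_truth_table(self, endo, emb, dry, expected):
        got = classify_endo_dmrs([self._dmr(endo, emb, dry)])
        assert (len(got) == 1) is expected

    def test_order_invariance(self):
        dmrs = [self._dmr(0.45, 0.05, 0.08), self._dmr(0.3, 0.25, 0.05),
                self._dmr(0.21, 0.05, 0.05)]
        fwd = [e.interval for e in classify_endo_dmrs(dmrs)]
        rev = [e.interval for e in classify_endo_dmrs(dmrs[::-1])]
        assert sorted(fwd, key=lambda x: x.start) == sorted(rev, key=lambda x: x.start)

    def test_undefined_level_skipped(self):
        d = Dmr("Chr1", 0, 100, "CHH", (10,), 1,
                {"endosperm": 0.5, "embryo": float("nan"), "dry_seed": 0.0})
        assert classify_endo_dmrs([d]) == []


class TestClusterEndoDmrs:
    def _endo(self, levels):
        return EndoDmr(interval=iv(0, 100), levels=levels)

    def test_two_separated_blocks(self):
        low = [self._endo({"s1": 0.0 + e, "s2": 0.1}) for e in (0.0, 0.01, 0.02)]
        high = [self._endo({"s1": 0.9 - e, "s2": 0.8}) for e in (0.0, 0.01, 0.02)]
        labels = cluster_endo_dmrs(low + high, k=2)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_duplicates_share_cluster(self):
        endo = [self._endo({"s1": 0.5, "s2": 0.5})] * 3 + [self._endo({"s1": 0.0, "s2": 0.0})]
        labels = cluster_endo_dmrs(endo, k=2)
        assert len(set(labels[:3])) == 1

    def test_k_equals_n_gives_singletons(self):
        endo = [self._endo({"s1": v, "s2": v}) for v in (0.1, 0.4, 0.7, 0.95)]
        labels = cluster_endo_dmrs(endo, k=4)
        assert len(set(labels)) == 4

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            cluster_endo_dmrs([self._endo({"s1": 0.1})], k=11)


class TestFeatureOverlap:
    def _features(self):
        return pd.DataFrame({
            "chrom": ["Chr1", "Chr1"],
            "start": [1000, 5000], "end": [2000, 6000],
            "id": ["g1", "te1"], "strand": ["+", "+"],
            "feature_class": ["gene", "TE"],
        })

    def test_fully_inside_te(self):
        d = Dmr("Chr1", 5100, 5200, "CHH", (5100,), 1, {})
        assert feature_overlap_fractions([d], self._features())["TE"] == 1.0

    def test_no_overlap_is_other(self):
        d = Dmr("Chr1", 9000, 9100, "CHH", (9000,), 1, {})
        assert feature_overlap_fractions([d], self._features())["other"] == 1.0

    def test_larger_overlap_wins(self):
        feats = pd.DataFrame({
            "chrom": ["Chr1", "Chr1"], "start": [0, 60], "end": [60, 200],
            "id": ["g1", "te1"], "strand": ["+", "+"],
            "feature_class": ["gene", "TE"],
        })
        d = Dmr("Chr1", 0, 100, "CHH", (10,), 1, {})  # 60 bp gene, 40 bp TE
        assert feature_overlap_fractions([d], feats)["gene"] == 1.0

    def test_fractions_sum_to_one(self):
        dmrs = [Dmr("Chr1", s, s + 100, "CHH", (s,), 1, {}) for s in (500, 1500, 5500, 9000)]
        fr = feature_overlap_fractions(dmrs, self._features())
        assert sum(fr.values()) == pytest.approx(1.0)


class TestReplicateConsistency:
    def test_counting_rule(self):
        dmrs = [None, None, None]  # only indices matter
        mut = {"r1": {0: 0.5, 1: 0.5, 2: 0.5}, "r2": {0: 0.45, 1: 0.3, 2: 0.5}}
        wt = {"r1": {0: 0.2, 1: 0.2, 2: 0.2}, "r2": {0: 0.2, 1: 0.2, 2: float("nan")}}
        count, denom, frac = replicate_consistent_hyper(dmrs, mut, wt, threshold=0.2)
        # DMR0: diffs (0.3, 0.25) -> counted; DMR1: (0.3, 0.1) -> not; DMR2: undefined -> excluded
        assert (count, denom) == (1, 2)
        assert frac == 0.5

    def test_printed_fraction_example(self):
        assert round(100 * 97 / 130) == 75

    def test_mismatched_replicates_rejected(self):
        with pytest.raises(ValueError):
            replicate_consistent_hyper([None], {"r1": {0: 1.0}}, {"r2": {0: 0.0}})
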