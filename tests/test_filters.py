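"""Filter families: definitions, composition with the basic filter,
threshold-grid nesting, blindness to sample order, and the Jaccard
threshold search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adafilter import (CountMatrix, FilterSpec, basic_filter, mean_filter,
                       max_filter, cpm_filter, zero_filter, jaccard_pair_index,
                       jaccard_threshold, jaccard_filter, apply_filter,
                       simulate_nb_fixed)
from conftest import random_count_matrix


class TestBasic:
    def test_definition(self, toy_counts):
        res = basic_filter(toy_counts)
        np.testing.assert_array_equal(res.keep, [True, False, True])
        assert res.proportion_filtered == pytest.approx(1 / 3)

    def test_single_nonzero_kept(self):
        res = basic_filter(np.array([[0, 0, 1, 0]]))
        assert res.keep[0]

    def test_equals_zero_filter_limit(self, rng):
        """The basic filter is the zero-based filter in the limit u = n-1
        (remove iff more than n-1 zeros, i.e. all n counts zero)."""
        cm = random_count_matrix(rng, m=30, n=8, max_count=3)
        np.testing.assert_array_equal(basic_filter(cm).keep,
                                      zero_filter(cm, u=cm.n - 1).keep)


class TestPercentileFilters:
    def test_mean_cutoff_linear_interpolation(self):
        """Five genes with means (1..5): the 20th percentile cutoff is 1.8,
        removing only the gene with mean 1 (strict inequality)."""
        counts = np.outer([1, 2, 3, 4, 5], [1, 1, 1, 1])
        res = mean_filter(counts, percentile=20)
        assert res.realized_threshold == pytest.approx(1.8)
        np.testing.assert_array_equal(res.keep, [False, True, True, True, True])
        assert res.proportion_filtered == pytest.approx(0.2)

    def test_small_percentile_keeps_all(self):
        counts = np.outer([1, 2, 3, 4, 5], [1, 1, 1, 1])
        res = mean_filter(counts, percentile=1e-9)
        assert res.keep.all()

    def test_ties_keep_everything(self):
        """All genes tied on the statistic: strict removal removes none, so
        the realized proportion (0) differs from the nominal percentage."""
        counts = np.full((10, 4), 7)
        res = max_filter(counts, percentile=50)
        assert res.keep.all()
        assert res.proportion_filtered == 0.0

    def test_max_uses_maximum_statistic(self):
        counts = np.array([[0, 0, 100, 0], [30, 30, 30, 30]])
        res = max_filter(counts, percentile=40)
        # maxima are (100, 30); 40th percentile cutoff is 58 -> remove gene 2
        np.testing.assert_array_equal(res.keep, [True, False])

    def test_cutoff_computed_on_basic_survivors(self):
        counts = np.vstack([np.zeros((5, 4), dtype=int),
                            np.outer([1, 2, 3, 4, 5], [1, 1, 1, 1])])
        res = mean_filter(counts, percentile=20)
        assert res.realized_threshold == pytest.approx(1.8)
        assert res.proportion_filtered == pytest.approx(0.2)


class TestCpmFilter:
    def test_hand_count(self):
        """n1=n2=2, c=1: CPM row (0.5, 0.5, 0.5, 2) has 3 samples below 1,
        which exceeds min(n1,n2)=2, so the gene is removed."""
        cpm_matrix = np.array([[0.5, 0.5, 0.5, 2.0], [5, 5, 5, 5]])
        counts = np.array([[1, 1, 1, 4], [10, 10, 10, 10]])
        res = cpm_filter(counts, 1.0, n1=2, n2=2, cpm_matrix=cpm_matrix)
        np.testing.assert_array_equal(res.keep, [False, True])

    def test_all_above_kept(self):
        cpm_matrix = np.full((3, 4), 10.0)
        counts = np.ones((3, 4), dtype=int)
        res = cpm_filter(counts, 5.0, n1=2, n2=2, cpm_matrix=cpm_matrix)
        assert res.keep.all()

    def test_grid_is_nested(self, rng):
        cm = random_count_matrix(rng, m=20, n=6, max_count=400)
        prev = None
        for c in [1, 2, 5, 25, 50, 100]:
            keep = cpm_filter(cm, c, n1=3, n2=3).keep
            if prev is not None:
                assert np.all(keep <= prev)  # removal sets nested in c
            prev = keep


class TestZeroFilter:
    def test_strict_threshold(self):
        gene = np.array([[0, 0, 0, 5, 5]])
        assert not zero_filter(gene, u=2).keep[0]  # 3 zeros > 2 -> removed
        assert zero_filter(gene, u=3).keep[0]      # 3 zeros <= 3 -> kept

    def test_grid_is_nested(self, rng):
        cm = random_count_matrix(rng, m=50, n=20, max_count=2)
        prev = None
        for u in range(16, 0, -1):
            keep = zero_filter(cm, u).keep
            if prev is not None:
                assert np.all(keep <= prev)  # removal grows as u decreases
            prev = keep


class TestJaccard:
    def test_identical_replicates(self):
        assert jaccard_pair_index([5, 0, 3], [5, 0, 3], v=1) == 1.0

    def test_hand_count(self):
        assert jaccard_pair_index([5, 0, 3], [4, 2, 0], v=1) == pytest.approx(1 / 3)

    def test_disjoint_supports(self):
        assert jaccard_pair_index([5, 0], [0, 9], v=1) == 0.0

    def test_empty_union_is_zero(self):
        assert jaccard_pair_index([0, 0], [0, 0], v=1) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            jaccard_pair_index([1, 2], [1], v=0)

    def test_duplicated_replicates_pick_smallest_cutoff(self):
        """With identical replicates in both conditions the global index is 1
        for every cutoff with a non-empty union; ties break to the smallest."""
        col = np.array([9, 4, 0, 2, 6, 1])
        counts = np.tile(col[:, None], (1, 4))
        cm = CountMatrix(counts, [f"g{i}" for i in range(6)], list("abcd"),
                         [1, 1, 2, 2])
        grid = np.array([0.0, 1.0, 2.0, 3.0])
        assert jaccard_threshold(cm, candidate_grid=grid) == 0.0

    def test_determinism(self):
        cm, _ = simulate_nb_fixed(m=100, n1=4, n2=4, pi0=1.0, mu0=3,
                                  dispersion=0.4, seed=31)
        assert jaccard_threshold(cm) == jaccard_threshold(cm)

    def test_smoothed_maximiser_matches_raw_on_unimodal_curves(self):
        """On NB data the loess-smoothed maximiser stays near the raw-grid
        maximiser; with clear unimodality they coincide."""
        low, _ = simulate_nb_fixed(m=300, n1=5, n2=5, pi0=1.0, mu0=0.5,
                                   dispersion=0.3, seed=32)
        high, _ = simulate_nb_fixed(m=200, n1=5, n2=5, pi0=1.0, mu0=80,
                                    dispersion=0.05, seed=33)
        counts = np.vstack([low.counts, high.counts])
        cm = CountMatrix(counts, [f"g{i}" for i in range(500)],
                         low.sample_ids, low.groups)
        v_star = jaccard_threshold(cm)
        # the smoothed maximiser must land on the plateau of near-maximal
        # raw similarity scores
        grid = np.unique(counts[counts <= np.percentile(counts[counts > 0], 95)])
        groups = np.asarray(cm.groups)
        raw = {}
        for v in [v_star] + list(grid.astype(float)):
            scores = []
            for g in (1, 2):
                idx = np.flatnonzero(groups == g)
                for a in range(len(idx)):
                    for b in range(a + 1, len(idx)):
                        scores.append(jaccard_pair_index(
                            counts[:, idx[a]], counts[:, idx[b]], v))
            raw[v] = np.mean(scores)
        assert raw[v_star] >= 0.95 * max(raw.values())

    def test_single_replicate_condition_rejected(self):
        cm = CountMatrix(np.ones((5, 3), dtype=int), [f"g{i}" for i in range(5)],
                         list("abc"), [1, 1, 2])
        with pytest.raises(ValueError):
            jaccard_threshold(cm)


class TestCompositionAndBlindness:
    @pytest.mark.parametrize("spec", [
        FilterSpec("basic"), FilterSpec("mean", 30), FilterSpec("max", 30),
        FilterSpec("cpm", 5), FilterSpec("zero", 3), FilterSpec("jaccard"),
    ])
    def test_keep_subset_of_basic(self, rng, spec):
        cm = random_count_matrix(rng, m=40, n=6, max_count=4)
        res = apply_filter(spec, cm, groups=cm.groups, n1=cm.n1, n2=cm.n2)
        base = basic_filter(cm).keep
        assert np.all(res.keep <= base)

    @pytest.mark.parametrize("family,threshold", [
        ("mean", 40), ("max", 40), ("cpm", 5), ("zero", 2),
    ])
    def test_blind_to_column_permutation(self, rng, family, threshold):
        cm = random_count_matrix(rng, m=30, n=8, max_count=20)
        perm = rng.permutation(cm.n)
        cm_perm = CountMatrix(cm.counts[:, perm], cm.gene_ids,
                              cm.sample_ids[perm], cm.groups[perm])
        spec = FilterSpec(family, threshold)
        keep1 = apply_filter(spec, cm, n1=cm.n1, n2=cm.n2, groups=cm.groups).keep
        keep2 = apply_filter(spec, cm_perm, n1=cm_perm.n1, n2=cm_perm.n2,
                             groups=cm_perm.groups).keep
        np.testing.assert_array_equal(keep1, keep2)

    def test_jaccard_invariant_within_conditions(self, rng):
        cm = random_count_matrix(rng, m=60, n=8, max_count=15)
        order = np.r_[rng.permutation(4), 4 + rng.permutation(4)]
        cm_perm = CountMatrix(cm.counts[:, order], cm.gene_ids,
                              cm.sample_ids[order], cm.groups[order])
        np.testing.assert_array_equal(jaccard_filter(cm).keep,
                                      jaccard_filter(cm_perm).keep)

    def test_proportion_accounting(self, rng):
        cm = random_count_matrix(rng, m=50, n=6, max_count=3)
        base = basic_filter(cm)
        res = mean_filter(cm, 50)
        n_base = base.keep.sum()
        assert res.proportion_filtered == pytest.approx(
            1 - res.keep.sum() / n_base)
        assert base.proportion_filtered == pytest.approx(
            1 - base.keep.sum() / cm.m)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.sampled_from(["mean", "max"]))
def test_percentile_nesting_property(seed, family):
    """Along the percentile grid, removal sets are nested (monotone)."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 30, size=(25, 6))
    if not (counts > 0).any(axis=1).any():
        return
    fn = mean_filter if family == "mean" else max_filter
    prev = None
    for p in [5, 20, 50, 80]:
        keep = fn(counts, p).keep
        if prev is not None:
            assert np.all(keep <= prev)
        prev = keep
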