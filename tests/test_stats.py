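"""Unit tests for permutation tests, Fisher-z edge comparison, FDR, and t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfnet import (
    bh_fdr,
    edge_z_comparison,
    normalize_regional_cbf,
    pearson_network,
    permutation_test_global,
    permutation_test_nodal,
    regional_ttests,
    sample_regional_cbf,
)
from perfnet.network import SparsityGrid
from conftest import matrix_from_values

# Fisher Z for r_A=0.5 (n=53) vs r_B=0.1 (n=30), evaluated independently at
# 40 decimal digits: (atanh(0.5)-atanh(0.1))/sqrt(1/50+1/27).
Z_ORACLE = 1.8799210672609303


def _step_up_reference(p, alpha):
    """Literal BH step-up, independent of statsmodels."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    kmax = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank * alpha / m:
            kmax = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= kmax:
            reject[i] = True
    # adjusted p with monotone enforcement
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj, reject


class TestBhFdr:
    def test_hand_worked_example(self):
        p = np.array([0.001, 0.01, 0.02, 0.9])
        adj, flags = bh_fdr(p, alpha=0.05)
        ref_adj, ref_flags = _step_up_reference(list(p), 0.05)
        assert np.allclose(adj, ref_adj)
        assert list(flags) == ref_flags == [True, True, True, False]

    def test_all_ones_nothing_rejected(self):
        _, flags = bh_fdr(np.ones(10), alpha=0.05)
        assert not flags.any()

    def test_all_zeros_everything_rejected(self):
        _, flags = bh_fdr(np.zeros(10), alpha=0.05)
        assert flags.all()

    def test_adjusted_never_below_raw(self):
        p = np.random.default_rng(0).uniform(0, 1, 200)
        adj, _ = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    @given(st.integers(0, 2**31 - 1), st.integers(1, 1000))
    @settings(max_examples=20, deadline=None)
    def test_agrees_with_step_up_reference_on_random_vectors(self, seed, m):
        p = np.random.default_rng(seed).uniform(0, 1, m)
        adj, flags = bh_fdr(p, alpha=0.05)
        ref_adj, ref_flags = _step_up_reference(list(p), 0.05)
        assert np.allclose(adj, ref_adj, atol=1e-12)
        assert list(flags) == ref_flags


def _net_from_r(r01, n, region_count=2, group="G"):
    from perfnet import CorrelationNetwork

    r = np.eye(region_count)
    r[0, 1] = r[1, 0] = r01
    return CorrelationNetwork(r=r, n_subjects=n, group=group, region_ids=list(range(1, region_count + 1)))


class TestEdgeZ:
    def test_matches_high_precision_oracle(self):
        netA = _net_from_r(0.5, 53)
        netB = _net_from_r(0.1, 30)
        res = edge_z_comparison(netA, netB, family="all")
        assert np.isclose(res.z_stat[0], Z_ORACLE, rtol=1e-12)

    def test_identical_correlations_give_zero(self):
        res = edge_z_comparison(_net_from_r(0.42, 20), _net_from_r(0.42, 15), family="all")
        assert res.z_stat[0] == 0.0
        assert res.p_raw[0] == 1.0

    def test_swapping_groups_negates_z_keeps_p(self):
        a, b = _net_from_r(0.6, 25), _net_from_r(0.2, 18)
        r1 = edge_z_comparison(a, b, family="all")
        r2 = edge_z_comparison(b, a, family="all")
        assert np.allclose(r1.z_stat, -r2.z_stat)
        assert np.allclose(r1.p_adjusted, r2.p_adjusted)

    def test_perfect_correlation_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            res = edge_z_comparison(_net_from_r(1.0, 20), _net_from_r(0.0, 20), family="all")
        assert np.isfinite(res.z_stat).all()

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="4 subjects"):
            edge_z_comparison(_net_from_r(0.5, 3), _net_from_r(0.1, 30))

    def test_union_family_subset_of_all_pairs(self, small_truth):
        cn = sample_regional_cbf(small_truth.models["CN"], seed=1)
        ad = sample_regional_cbf(small_truth.models["AD"], seed=2)
        netA = pearson_network(normalize_regional_cbf(cn))
        netB = pearson_network(normalize_regional_cbf(ad))
        union = edge_z_comparison(netA, netB, sparsity=0.83)
        full = edge_z_comparison(netA, netB, sparsity=0.83, family="all")
        assert set(union.edges) < set(full.edges)
        assert set(union.surviving) <= set(union.edges)


class TestRegionalTtests:
    def test_identical_groups_give_p_one(self):
        vals = np.random.default_rng(1).uniform(40, 80, (6, 5))
        res = regional_ttests(matrix_from_values(vals, "A"), matrix_from_values(vals, "B"))
        assert np.allclose(res.t_stat, 0.0)
        assert np.allclose(res.p_raw, 1.0)
        assert not res.significant.any()

    def test_matches_hand_welch_formula(self):
        a = np.array([[10.0], [12.0], [14.0]])
        b = np.array([[20.0], [21.0], [25.0]])
        res = regional_ttests(matrix_from_values(a, "A"), matrix_from_values(b, "B"))
        ma, mb = a.mean(), b.mean()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t_hand = (ma - mb) / np.sqrt(va / 3 + vb / 3)
        assert np.isclose(res.t_stat[0], t_hand, rtol=1e-12)

    def test_zero_variance_region_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, (5, 3))
        b = rng.uniform(0, 1, (5, 3))
        a[:, 1] = b[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero variance"):
            res = regional_ttests(matrix_from_values(a, "A"), matrix_from_values(b, "B"))
        assert res.excluded_regions == [2]
        assert np.isnan(res.p_adjusted[1])

    def test_planted_mean_shift_power(self):
        """1.5-pooled-SD reduction in 10 of 60 regions, n=53 vs 30: >= 8 recovered."""
        rng = np.random.default_rng(3)
        R, shift_regions = 60, list(range(10))
        base = rng.uniform(40, 80, R)
        sd = 6.0
        a = base + rng.normal(0, sd, (53, R))
        b = base + rng.normal(0, sd, (30, R))
        b[:, shift_regions] -= 1.5 * sd
        res = regional_ttests(matrix_from_values(a, "A"), matrix_from_values(b, "B"), alpha=0.05)
        hits = [rid - 1 for rid, f in zip(res.region_ids, res.significant) if f]
        assert len(set(hits) & set(shift_regions)) >= 8


class TestPermutationGlobal:
    def test_identical_groups_give_p_one(self, small_truth):
        mat = sample_regional_cbf(small_truth.models["CN"], seed=4)
        res = permutation_test_global(mat, mat, "global_efficiency", grid=SparsityGrid([0.83]),
                                      n_perm=100, seed=0)
        assert res[0].observed_difference == 0.0
        assert res[0].p_value == 1.0

    def test_bit_reproducible_per_seed(self, small_truth):
        a = sample_regional_cbf(small_truth.models["CN"], seed=5)
        b = sample_regional_cbf(small_truth.models["MCI"], seed=6)
        r1 = permutation_test_global(a, b, "clustering_coefficient", grid=SparsityGrid([0.79]), n_perm=100, seed=3)
        r2 = permutation_test_global(a, b, "clustering_coefficient", grid=SparsityGrid([0.79]), n_perm=100, seed=3)
        r3 = permutation_test_global(a, b, "clustering_coefficient", grid=SparsityGrid([0.79]), n_perm=100, seed=4)
        assert np.array_equal(r1[0].null_distribution, r2[0].null_distribution)
        assert r1[0].p_value == r2[0].p_value
        assert not np.array_equal(r1[0].null_distribution, r3[0].null_distribution)

    def test_p_never_zero(self, small_truth):
        a = sample_regional_cbf(small_truth.models["CN"], seed=7)
        b = sample_regional_cbf(small_truth.models["AD"], seed=8)
        res = permutation_test_global(a, b, "global_efficiency", grid=SparsityGrid([0.83]), n_perm=100, seed=0)
        assert res[0].p_value >= 1 / 101

    def test_unknown_metric_rejected(self, small_truth):
        mat = sample_regional_cbf(small_truth.models["CN"], seed=9)
        with pytest.raises(ValueError, match="metric"):
            permutation_test_global(mat, mat, "degree_entropy", n_perm=100)

    def test_incompatible_regions_rejected(self):
        a = matrix_from_values(np.random.default_rng(0).uniform(1, 2, (6, 5)), "A")
        b = matrix_from_values(np.random.default_rng(1).uniform(1, 2, (6, 4)), "B")
        with pytest.raises(ValueError, match="region"):
            permutation_test_global(a, b, "global_efficiency", n_perm=100)


class TestPermutationNodal:
    def test_region_order_preserved(self, small_truth):
        a = sample_regional_cbf(small_truth.models["CN"], seed=10)
        b = sample_regional_cbf(small_truth.models["MCI"], seed=11)
        res = permutation_test_nodal(a, b, sparsity=0.83, n_perm=100, seed=0)
        assert res.region_ids == a.region_ids
        assert res.p_values.shape == (a.n_regions,)
        assert np.all(res.p_values > 0)

    def test_ablated_bridge_region_ranks_among_smallest_p(self):
        """Severing the sole bridge between two modules in group B shows up in its BC p."""
        rng = np.random.default_rng(12)
        n, target = 60, 20
        f1 = rng.standard_normal((n, 1))
        f2 = rng.standard_normal((n, 1))
        a = np.empty((n, 21))
        a[:, :10] = 0.85 * f1 + 0.53 * rng.standard_normal((n, 10))
        a[:, 10:20] = 0.85 * f2 + 0.53 * rng.standard_normal((n, 10))
        a[:, target] = 0.6 * f1[:, 0] + 0.6 * f2[:, 0] + 0.53 * rng.standard_normal(n)
        a = 60 + 8 * a
        b = a.copy()
        # in B the bridge region folds into module X: its cross-module coupling is ablated
        b[:, target] = 60 + 8 * (0.85 * f1[:, 0] + 0.53 * rng.standard_normal(n))
        res = permutation_test_nodal(
            matrix_from_values(a, "A"), matrix_from_values(b, "B"),
            sparsity=0.48, n_perm=200, seed=1,
        )
        assert res.p_values[target] <= np.sort(res.p_values)[2]
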