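"""Cluster-permutation machinery against hand computations and enumeration."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from comaspectra.clusterstat import (
    AdjacencyGraph,
    Cluster,
    ClusterResult,
    build_adjacency,
    cluster_permutation_test,
    extract_band,
    pointwise_t,
)
from comaspectra.errors import InputError
from comaspectra.spectral import SpectrumGrid


class TestBuildAdjacency:
    def test_triangle_delaunay_all_pairs_linked(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
        g = build_adjacency(pos, ["a", "b", "c"], method="delaunay")
        assert all(len(g.neighbours(c)) == 2 for c in "abc")

    def test_tiny_distance_threshold_isolates_electrodes(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
        with pytest.raises(InputError):
            build_adjacency(pos, ["a", "b", "c"], method="distance", param=1e-6)

    def test_distance_method_matches_bruteforce_thresholding(self, rng):
        pos = rng.random((12, 2))
        param = 0.9
        g = build_adjacency(pos, method="distance", param=param)
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        thresh = param * np.median(d[~np.eye(12, dtype=bool)])
        for i in range(12):
            expect = {f"E{j}" for j in range(12) if j != i and d[i, j] < thresh}
            assert g.neighbours(f"E{i}") == expect

    def test_duplicate_positions_rejected(self):
        pos = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(InputError):
            build_adjacency(pos)

    def test_symmetry_and_irreflexivity_enforced(self):
        with pytest.raises(InputError):
            AdjacencyGraph(["a", "b"], {"a": {"b"}, "b": set()})


class TestPointwiseT:
    def test_hand_computed_pooled_t(self):
        a = np.array([1.0, 2.0]).reshape(2, 1, 1)
        b = np.array([3.0, 4.0]).reshape(2, 1, 1)
        t = pointwise_t(a, b)
        assert t[0, 0] == pytest.approx(-2 * np.sqrt(2), rel=1e-12)

    def test_identical_groups_give_zero(self, rng):
        x = rng.normal(size=(4, 2, 5))
        np.testing.assert_allclose(pointwise_t(x, x.copy()), 0.0, atol=1e-12)

    def test_swapping_groups_flips_sign(self, rng):
        a, b = rng.normal(size=(3, 2, 5)), rng.normal(size=(4, 2, 5))
        np.testing.assert_allclose(pointwise_t(a, b), -pointwise_t(b, a), atol=1e-12)

    def test_zero_variance_bin_reported_as_zero(self):
        a = np.ones((3, 1, 2))
        b = np.ones((3, 1, 2))
        b[:, 0, 1] = [0.0, 0.5, 1.0]
        t = pointwise_t(a, b)
        assert t[0, 0] == 0.0
        assert np.isfinite(t).all()

    def test_single_patient_group_rejected(self, rng):
        with pytest.raises(InputError):
            pointwise_t(rng.normal(size=(1, 2, 3)), rng.normal(size=(4, 2, 3)))


def _pair_graph():
    return AdjacencyGraph(["e0", "e1"], {"e0": {"e1"}, "e1": {"e0"}})


def _oracle_clusters(t_map, t_crit, sign):
    """Independent flood-fill clustering on a 2 x F grid (both electrodes
    mutually adjacent, frequency bins adjacent when consecutive)."""
    supra = {(e, f) for e in range(t_map.shape[0]) for f in range(t_map.shape[1])
             if sign * t_map[e, f] > t_crit}
    masses = []
    seen = set()
    for start in supra:
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            e, f = stack.pop()
            if (e, f) in comp:
                continue
            comp.add((e, f))
            for nb in ((e, f - 1), (e, f + 1), (1 - e, f)):
                if nb in supra and nb not in comp:
                    stack.append(nb)
        seen |= comp
        masses.append(sum(t_map[e, f] for e, f in comp))
    return masses


class TestClusterPermutation:
    def test_identical_groups_yield_no_clusters(self, rng):
        x = rng.normal(size=(4, 2, 5))
        res = cluster_permutation_test(x, x.copy(), _pair_graph(), n_perm=100, seed=0)
        assert res.clusters == []

    def test_p_values_respect_add_one_convention(self, rng):
        a = rng.normal(size=(5, 2, 5)) + 3.0  # huge effect
        b = rng.normal(size=(5, 2, 5))
        res = cluster_permutation_test(a, b, _pair_graph(), n_perm=200, seed=1)
        assert res.significant_clusters
        for c in res.clusters:
            assert 1 / (200 + 1) <= c.p <= 1.0

    def test_patient_order_within_groups_is_irrelevant(self, rng):
        a = rng.normal(size=(5, 2, 5)) + 1.0
        b = rng.normal(size=(6, 2, 5))
        res1 = cluster_permutation_test(a, b, _pair_graph(), n_perm=150, seed=7)
        perm_a = a[rng.permutation(5)]
        perm_b = b[rng.permutation(6)]
        res2 = cluster_permutation_test(perm_a, perm_b, _pair_graph(), n_perm=150, seed=7)
        np.testing.assert_allclose(res1.t_map, res2.t_map, atol=1e-12)
        assert sorted(round(c.mass, 9) for c in res1.clusters) == sorted(
            round(c.mass, 9) for c in res2.clusters
        )

    def test_monte_carlo_p_matches_exact_enumeration(self, rng):
        na = nb = 4
        a = rng.normal(size=(na, 2, 5))
        a[:, :, 1:3] += 1.6  # moderate localized effect
        b = rng.normal(size=(nb, 2, 5))
        res = cluster_permutation_test(
            a, b, _pair_graph(), n_perm=4000, seed=3, cluster_alpha=0.05
        )
        assert res.clusters, "toy effect should form at least one cluster"
        t_crit = sps.t.ppf(1 - 0.025, df=na + nb - 2)
        pooled = np.concatenate([a, b])
        # exact null: every C(8,4) = 70 assignment of patients to group A
        null_max = []
        for combo in itertools.combinations(range(na + nb), na):
            ga = pooled[list(combo)]
            gb = pooled[[i for i in range(na + nb) if i not in combo]]
            masses = _oracle_clusters(pointwise_t(ga, gb), t_crit, +1)
            null_max.append(max(masses) if masses else 0.0)
        null_max = np.array(null_max)
        for c in res.clusters:
            if c.sign != +1:
                continue
            p_exact = np.mean(null_max >= c.mass - 1e-12)
            se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / res.n_permutations)
            assert abs(c.p - p_exact) <= 3 * se + 1 / res.n_permutations

    def test_observed_clusters_match_oracle_flood_fill(self, rng):
        a = rng.normal(size=(5, 2, 5)) + rng.normal(size=(1, 2, 5))
        b = rng.normal(size=(5, 2, 5))
        res = cluster_permutation_test(a, b, _pair_graph(), n_perm=100, seed=2)
        t_crit = sps.t.ppf(1 - 0.025, df=8)
        expected = sorted(
            _oracle_clusters(res.t_map, t_crit, +1)
            + _oracle_clusters(res.t_map, t_crit, -1)
        )
        assert sorted(c.mass for c in res.clusters) == pytest.approx(expected)

    def test_small_groups_rejected(self, rng):
        with pytest.raises(InputError):
            cluster_permutation_test(
                rng.normal(size=(1, 2, 5)), rng.normal(size=(4, 2, 5)),
                _pair_graph(), n_perm=100,
            )


def _fake_result(sig_bins_by_cluster, grid, signs=None):
    clusters = []
    for i, bins in enumerate(sig_bins_by_cluster):
        c = Cluster(bins=set(bins), mass=10.0, sign=(signs or [+1] * 99)[i], p=0.001)
        c._significant = True
        clusters.append(c)
    return ClusterResult(
        clusters=clusters, t_map=np.zeros((2, grid.n_bins)), n_permutations=1000,
        seed=0, alpha=0.05, cluster_alpha=0.05, grid=grid,
    )


class TestExtractBand:
    def test_contiguous_cluster_maps_to_its_band(self, grid):
        f = grid.frequencies
        lo, hi = int(np.argmin(np.abs(f - 4.6))), int(np.argmin(np.abs(f - 15.2)))
        res = _fake_result([{(0, fb) for fb in range(lo, hi + 1)}], grid)
        band = extract_band(res)
        assert (band.fmin, band.fmax) == (4.6, 15.2)

    def test_no_significant_cluster_returns_none(self, grid):
        res = _fake_result([], grid)
        assert extract_band(res) is None

    def test_longest_run_wins(self, grid):
        f = grid.frequencies
        def bins(a, b):
            return {(0, fb) for fb in range(int(np.argmin(np.abs(f - a))),
                                            int(np.argmin(np.abs(f - b))) + 1)}
        res = _fake_result([bins(5.0, 6.0) | bins(10.0, 14.0)], grid)
        band = extract_band(res)
        assert (band.fmin, band.fmax) == (10.0, 14.0)

    def test_negative_clusters_ignored_by_default(self, grid):
        res = _fake_result([{(0, 30), (0, 31)}], grid, signs=[-1])
        assert extract_band(res) is None
        assert extract_band(res, signs=(+1, -1)) is not None
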