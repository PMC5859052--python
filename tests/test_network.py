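import itertools

import numpy as np
import pytest

from restcompare import (
    Montage,
    PLIMatrix,
    characteristic_path_length,
    fcd,
    small_world_sweep,
    sw_area,
    weighted_clustering,
)
from restcompare.network import SWCurve


def pli_of(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(f"c{i}" for i in range(values.shape[0]))
    return PLIMatrix(values, tuple(labels), band=None, n_samples=1000)


# -- brute-force oracles -----------------------------------------------------


def brute_clustering(w, threshold):
    w = np.where(w > threshold, w, 0.0)
    n = w.shape[0]
    ci = np.zeros(n)
    for i in range(n):
        num = den = 0.0
        for j in range(n):
            for k in range(n):
                if j == i or k == i or k == j:
                    continue
                num += w[i, j] * w[i, k] * w[j, k]
                den += w[i, j] * w[i, k]
        ci[i] = num / den if den > 0 else 0.0
    return ci, ci.mean()


def brute_path_length(w, threshold):
    w = np.where(w > threshold, w, 0.0)
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[w > 0] = 1.0 / w[w > 0]
    for mid in range(n):  # Floyd-Warshall
        dist = np.minimum(dist, dist[:, mid, None] + dist[None, mid, :])
    inv = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                inv += 1.0 / dist[i, j]
    eff = inv / (n * (n - 1))
    return (np.inf, True) if eff == 0 else (1.0 / eff, False)


def random_pli(rng, n, density=0.7):
    w = rng.uniform(0, 1, size=(n, n))
    w = (w + w.T) / 2
    mask = rng.uniform(size=(n, n)) < density
    mask &= mask.T
    w = np.where(mask, w, 0.0)
    np.fill_diagonal(w, 0.0)
    return w


# -- FCD ---------------------------------------------------------------------


class TestFCD:
    example = [[0, 0.6, 0.3], [0.6, 0, 0.7], [0.3, 0.7, 0]]

    def test_global_counts_direct(self):
        res = fcd(pli_of(self.example), tc=0.5, kind="global")
        assert list(res.counts) == [1, 2, 1]

    def test_local_counts_respect_radius(self):
        # ch0-ch1 are 2 cm apart; ch2 is 20 cm from both (beyond 5 cm radius)
        montage = Montage(
            ("c0", "c1", "c2"),
            np.array([[0.0, 0, 0], [0.02, 0, 0], [0.2, 0, 0]]),
        )
        res = fcd(pli_of(self.example), tc=0.5, kind="local", montage=montage)
        assert list(res.counts) == [1, 1, 0]

    def test_local_never_exceeds_global(self, rng, montage64):
        w = random_pli(rng, 64)
        mat = pli_of(w, labels=montage64.labels)
        for tc in (0.2, 0.5, 0.8):
            g = fcd(mat, tc, "global").counts
            l = fcd(mat, tc, "local", montage64).counts
            assert np.all(l <= g)

    def test_threshold_above_max_gives_empty_graph(self):
        res = fcd(pli_of(self.example), tc=0.9, kind="global")
        assert list(res.counts) == [0, 0, 0]

    def test_local_without_montage_errors(self):
        with pytest.raises(ValueError, match="montage"):
            fcd(pli_of(self.example), tc=0.5, kind="local")

    def test_invalid_threshold_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            fcd(pli_of(self.example), tc=1.5, kind="global")


# -- clustering / path length ------------------------------------------------


class TestClustering:
    def test_complete_triangle_equal_weights(self):
        w = np.full((3, 3), 0.5)
        np.fill_diagonal(w, 0.0)
        ci, c = weighted_clustering(w, 0.2)
        assert np.allclose(ci, 0.5)
        assert c == pytest.approx(0.5)

    def test_star_graph_has_no_triangles(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 0.8
        _, c = weighted_clustering(w, 0.2)
        assert c == 0.0

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_complete_graph_equal_weights_gives_weight(self, n):
        for w_val in (0.3, 0.6, 0.9):
            w = np.full((n, n), w_val)
            np.fill_diagonal(w, 0.0)
            _, c = weighted_clustering(w, 0.1)
            assert c == pytest.approx(w_val, abs=1e-12)

    def test_clustering_bounded_by_unit_interval(self, rng):
        for _ in range(50):
            w = random_pli(rng, 6)
            ci, c = weighted_clustering(w, rng.uniform(0.05, 0.9))
            assert np.all(ci >= 0) and np.all(ci <= 1)
            assert 0 <= c <= 1


class TestPathLength:
    def test_complete_triangle_direct_edges(self):
        w = np.full((3, 3), 0.5)
        np.fill_diagonal(w, 0.0)
        # edge length 2 beats any 2-hop path of length 4
        L, disconnected = characteristic_path_length(w, 0.2)
        assert L == pytest.approx(2.0)
        assert not disconnected

    def test_isolated_vertices_flagged_disconnected(self):
        L, disconnected = characteristic_path_length(np.zeros((2, 2)), 0.5)
        assert disconnected
        assert L == np.inf

    def test_adding_edge_never_decreases_efficiency(self, rng):
        for _ in range(30):
            w = random_pli(rng, 6, density=0.4)
            zeros = np.argwhere((w == 0) & ~np.eye(6, dtype=bool))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = rng.uniform(0.5, 1.0)
            l1, d1 = characteristic_path_length(w, 0.1)
            l2, d2 = characteristic_path_length(w2, 0.1)
            e1 = 0.0 if d1 else 1.0 / l1
            e2 = 0.0 if d2 else 1.0 / l2
            assert e2 >= e1 - 1e-12

    def test_single_vertex_errors(self):
        with pytest.raises(ValueError):
            characteristic_path_length(np.zeros((1, 1)), 0.5)


class TestOracleEquivalence:
    def test_matches_brute_force_on_small_graphs(self, rng):
        # exhaustive cross-check of C, L, SW on random weighted graphs
        for _ in range(120):
            n = int(rng.integers(2, 7))
            w = random_pli(rng, n)
            thr = float(rng.uniform(0.05, 0.95))
            ci, c = weighted_clustering(w, thr)
            bci, bc = brute_clustering(w, thr)
            assert np.allclose(ci, bci, atol=1e-12)
            L, disc = characteristic_path_length(w, thr)
            bL, bdisc = brute_path_length(w, thr)
            assert disc == bdisc
            if not disc:
                assert L == pytest.approx(bL, rel=1e-9)


# -- sweep and area ----------------------------------------------------------


class TestSweep:
    def test_default_grid_has_99_points(self):
        w = random_pli(np.random.default_rng(0), 5)
        curve = small_world_sweep(pli_of(w))
        assert len(curve.thresholds) == 99
        assert curve.thresholds[0] == pytest.approx(0.01)
        assert curve.thresholds[-1] == pytest.approx(0.99)

    def test_threshold_above_max_pli_zeroes_curve(self):
        w = np.full((4, 4), 0.3)
        np.fill_diagonal(w, 0.0)
        curve = small_world_sweep(pli_of(w), start=0.5, step=0.1, stop=0.9)
        assert np.all(curve.c_values == 0)
        assert np.all(curve.sw_values == 0)

    def test_sw_equals_c_over_l_where_connected(self):
        w = random_pli(np.random.default_rng(3), 6)
        curve = small_world_sweep(pli_of(w))
        finite = np.isfinite(curve.l_values)
        assert np.allclose(
            curve.sw_values[finite], curve.c_values[finite] / curve.l_values[finite]
        )
        assert np.all(curve.sw_values[~finite] == 0)

    def test_lattice_with_shortcuts_beats_degree_matched_random(self):
        # ring lattice (k=4 neighbours, w=0.8) plus 3 strong shortcuts vs a
        # random graph with the same number of edges and weights
        n, k = 12, 2
        sw_lattice, sw_random = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w = np.zeros((n, n))
            for i in range(n):
                for d in range(1, k + 1):
                    j = (i + d) % n
                    w[i, j] = w[j, i] = 0.8
            for _ in range(3):
                i, j = rng.integers(n), rng.integers(n)
                if i != j:
                    w[i, j] = w[j, i] = 0.8
            n_edges = int(np.sum(w > 0) // 2)
            wr = np.zeros((n, n))
            pairs = list(itertools.combinations(range(n), 2))
            chosen = rng.choice(len(pairs), size=n_edges, replace=False)
            for c in chosen:
                i, j = pairs[c]
                wr[i, j] = wr[j, i] = 0.8
            for mat, acc in ((w, sw_lattice), (wr, sw_random)):
                ci, c = weighted_clustering(mat, 0.3)
                L, disc = characteristic_path_length(mat, 0.3)
                acc.append(0.0 if disc else c / L)
        assert np.mean(sw_lattice) > np.mean(sw_random)


class TestSWArea:
    def unit_curve(self, sw_value=1.0):
        thresholds = 0.01 + 0.01 * np.arange(99)
        sw = np.full(99, sw_value)
        return SWCurve(thresholds, sw.copy(), np.ones(99), sw)

    def test_constant_curve_counts_grid_points(self):
        assert sw_area(self.unit_curve(1.0)) == pytest.approx(31.0)

    def test_zero_curve_gives_zero(self):
        assert sw_area(self.unit_curve(0.0)) == 0.0

    def test_monotone_under_pointwise_increase(self, rng):
        base = self.unit_curve(1.0)
        bigger = self.unit_curve(1.0)
        bigger.sw_values = base.sw_values + rng.uniform(0, 1, 99)
        assert sw_area(bigger) >= sw_area(base)

    def test_empty_intersection_errors(self):
        curve = self.unit_curve(1.0)
        with pytest.raises(ValueError, match="inside"):
            sw_area(curve, 2.0, 3.0)
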