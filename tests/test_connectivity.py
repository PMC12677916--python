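import numpy as np
import pytest
from scipy import stats

from bcifes.connectivity import (
    BandGraph,
    PPCMatrix,
    extract_phase,
    graph_metrics,
    ppc,
    ppc_from_phase_differences,
    ppc_matrix,
    threshold_graph,
)


# --------------------------------------------------------------- brute oracles

def brute_ppc(deltas):
    """Direct double-sum evaluation of the unbiased estimator."""
    n = len(deltas)
    total = sum(np.cos(deltas[j] - deltas[k])
                for j in range(n) for k in range(j + 1, n))
    return 2.0 * total / (n * (n - 1))


def brute_onnela_clustering(adj):
    n = adj.shape[0]
    wmax = adj.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    what = np.cbrt(adj / wmax)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            for k in range(n):
                if i != j and i != k and j != k:
                    acc += what[i, j] * what[i, k] * what[j, k]
        deg = int((adj[i] > 0).sum())
        out[i] = acc / (deg * (deg - 1)) if deg > 1 else 0.0
    return out


def brute_floyd_warshall(adj):
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j] > 0:
                d[i, j] = 1.0 / adj[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_metrics(adj):
    n = adj.shape[0]
    d = brute_floyd_warshall(adj)
    strength = adj.sum(axis=1)
    clustering = brute_onnela_clustering(adj)
    geff = sum(1.0 / d[i, j] for i in range(n) for j in range(n)
               if i != j and np.isfinite(d[i, j]) and d[i, j] > 0) / (n * (n - 1))
    finite = [d[i, j] for i in range(n) for j in range(n)
              if i != j and np.isfinite(d[i, j])]
    cpl = float(np.mean(finite)) if finite else np.nan
    local = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        ds = brute_floyd_warshall(sub)
        m = nbrs.size
        local[i] = sum(1.0 / ds[a, b] for a in range(m) for b in range(m)
                       if a != b and np.isfinite(ds[a, b]) and ds[a, b] > 0
                       ) / (m * (m - 1))
    return strength, clustering, local, geff, cpl


def as_graph(adj, labels=None):
    labels = labels or tuple(f"n{i}" for i in range(adj.shape[0]))
    return BandGraph(adjacency=adj, channel_labels=labels, band_name="test",
                     density=1.0)


# -------------------------------------------------------------------- phases

class TestExtractPhase:
    def test_tone_phase_slope_matches_frequency(self):
        fs = 250.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        phase = extract_phase(x[None], fs, (8.0, 13.0))[0]
        slope = np.polyfit(np.arange(phase.size) / fs, np.unwrap(phase), 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_identical_channels_zero_phase_difference(self, rng):
        x = rng.standard_normal(7500)
        ph = extract_phase(np.vstack([x, x]), 250.0, (8.0, 13.0))
        np.testing.assert_allclose(ph[0], ph[1], atol=1e-12)

    def test_noise_phase_is_circularly_uniform(self, rng):
        x = rng.standard_normal(60 * 250)
        phase = extract_phase(x[None], 250.0, (8.0, 13.0))[0]
        u = (phase + np.pi) / (2 * np.pi)  # map to [0, 1)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_invalid_band_raises(self):
        with pytest.raises(ValueError):
            extract_phase(np.zeros((1, 1000)), 250.0, (120.0, 130.0))


class TestPPC:
    def test_constant_lag_gives_one(self):
        deltas = np.full(50, 0.7)
        assert ppc_from_phase_differences(deltas) == pytest.approx(1.0)

    def test_two_opposite_samples_give_minus_one(self):
        assert ppc_from_phase_differences([0.0, np.pi]) == pytest.approx(-1.0)

    def test_closed_form_matches_double_sum(self, rng):
        for _ in range(20):
            deltas = rng.uniform(-np.pi, np.pi, size=rng.integers(2, 30))
            assert ppc_from_phase_differences(deltas) == pytest.approx(
                brute_ppc(deltas), abs=1e-10)

    def test_independent_phases_unbiased_null(self, rng):
        vals = [ppc_from_phase_differences(rng.uniform(-np.pi, np.pi, 200))
                for _ in range(100)]
        assert abs(np.mean(vals)) < 0.02

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            ppc_from_phase_differences([0.1])

    def test_phase_series_interface_perfect_lock(self):
        fs = 250.0
        t = np.arange(int(30 * fs)) / fs
        a = 2 * np.pi * 10.0 * t
        b = a - 1.0  # constant lag
        wrapped = lambda p: np.angle(np.exp(1j * p))
        assert ppc(wrapped(a), wrapped(b), fs) == pytest.approx(1.0, abs=1e-9)


# -------------------------------------------------------------- thresholding

class TestThreshold:
    @staticmethod
    def _mat(values):
        n = values.shape[0]
        labels = tuple(f"n{i}" for i in range(n))
        vals = values.astype(float).copy()
        np.fill_diagonal(vals, np.nan)
        return PPCMatrix(values=vals, channel_labels=labels,
                         band_name="alpha", n_segments=10)

    def test_full_density_keeps_all_positive_edges(self, rng):
        w = np.abs(rng.normal(size=(6, 6)))
        w = (w + w.T) / 2
        g = threshold_graph(self._mat(w), param=1.0)
        assert g.n_edges == 15

    def test_default_density_on_22_nodes_keeps_69_edges(self, rng):
        w = rng.uniform(0.01, 1.0, size=(22, 22))
        w = (w + w.T) / 2
        g = threshold_graph(self._mat(w), param=0.3)
        assert g.n_edges == round(0.3 * 231)  # 69

    def test_all_equal_weights_lexical_tie_break(self):
        w = np.ones((4, 4))
        g = threshold_graph(self._mat(w), param=0.5)
        assert g.n_edges == 3  # round(0.5 * 6)
        kept = {(i, j) for i in range(4) for j in range(i + 1, 4)
                if g.adjacency[i, j] > 0}
        assert kept == {(0, 1), (0, 2), (0, 3)}  # first in (i, j) order

    def test_negative_values_never_retained(self):
        w = np.full((4, 4), -0.1)
        g = threshold_graph(self._mat(w), param=1.0)
        assert g.n_edges == 0

    def test_absolute_mode_and_bad_density(self, rng):
        w = np.array([[0, 0.9, 0.1], [0.9, 0, 0.4], [0.1, 0.4, 0]])
        g = threshold_graph(self._mat(w), method="absolute", param=0.5)
        assert g.n_edges == 1
        with pytest.raises(ValueError):
            threshold_graph(self._mat(w), param=0.0)


# -------------------------------------------------------------- graph metrics

class TestGraphMetrics:
    def test_complete_graph_closed_forms(self):
        adj = np.ones((5, 5)) - np.eye(5)
        m = graph_metrics(as_graph(adj), n_random=0)
        assert m.mean_clustering == pytest.approx(1.0)
        assert m.characteristic_path_length == pytest.approx(1.0)
        assert m.global_efficiency == pytest.approx(1.0)
        assert m.mean_local_efficiency == pytest.approx(1.0)
        np.testing.assert_allclose(m.node_strength, 4.0)

    def test_path_graph_characteristic_length(self):
        adj = np.zeros((4, 4))
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = 1.0
        m = graph_metrics(as_graph(adj), n_random=0)
        assert m.characteristic_path_length == pytest.approx(10.0 / 6.0)
        assert m.mean_clustering == 0.0

    def test_oracle_agreement_on_random_weighted_graphs(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 9))
            w = rng.uniform(0.0, 1.0, size=(n, n))
            w = (w + w.T) / 2
            w[w < 0.3] = 0.0  # sparsify; may disconnect
            np.fill_diagonal(w, 0.0)
            m = graph_metrics(as_graph(w), n_random=0)
            s, c, le, ge, cpl = brute_metrics(w)
            np.testing.assert_allclose(m.node_strength, s, atol=1e-9)
            np.testing.assert_allclose(m.clustering, c, atol=1e-9)
            np.testing.assert_allclose(m.local_efficiency, le, atol=1e-9)
            assert m.global_efficiency == pytest.approx(ge, abs=1e-9)
            if np.isfinite(cpl):
                assert m.characteristic_path_length == pytest.approx(cpl, abs=1e-9)

    def test_permutation_equivariance(self, rng):
        n = 7
        w = rng.uniform(0.1, 1.0, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        perm = rng.permutation(n)
        wp = w[np.ix_(perm, perm)]
        m = graph_metrics(as_graph(w), n_random=0)
        mp = graph_metrics(as_graph(wp), n_random=0)
        np.testing.assert_allclose(mp.node_strength.to_numpy(),
                                   m.node_strength.to_numpy()[perm], atol=1e-12)
        np.testing.assert_allclose(mp.clustering.to_numpy(),
                                   m.clustering.to_numpy()[perm], atol=1e-12)
        assert mp.global_efficiency == pytest.approx(m.global_efficiency)
        assert mp.characteristic_path_length == pytest.approx(
            m.characteristic_path_length)

    def test_small_world_lattice_with_shortcuts_sigma_above_one(self):
        # ring lattice, each node linked to 2 neighbours each side, plus
        # a few deterministic shortcuts: the canonical small-world shape
        n = 20
        adj = np.zeros((n, n))
        for i in range(n):
            for k in (1, 2):
                j = (i + k) % n
                adj[i, j] = adj[j, i] = 1.0
        for i, j in ((0, 10), (3, 14), (7, 17)):
            adj[i, j] = adj[j, i] = 1.0
        m = graph_metrics(as_graph(adj), n_random=30, seed=1)
        assert m.small_world_index > 1.0

    def test_small_world_seed_determinism(self, rng):
        w = rng.uniform(0.1, 1.0, size=(10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        a = graph_metrics(as_graph(w), n_random=10, seed=5).small_world_index
        b = graph_metrics(as_graph(w), n_random=10, seed=5).small_world_index
        assert a == b

    def test_disconnected_pairs_excluded_and_counted(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[2, 3] = adj[3, 2] = 1.0
        m = graph_metrics(as_graph(adj), n_random=0)
        assert m.n_disconnected_pairs == 4
        assert m.characteristic_path_length == pytest.approx(1.0)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            graph_metrics(as_graph(np.zeros((2, 2))), n_random=0)


def test_ppc_matrix_coupled_channels_reach_unity(rng):
    """Identical narrowband signals on two channels give PPC = 1 in-band."""
    fs = 250.0
    from scipy.signal import butter, sosfiltfilt
    sos = butter(4, [9.0, 11.0], btype="bandpass", fs=fs, output="sos")
    shared = sosfiltfilt(sos, rng.standard_normal(int(120 * fs)))
    other = sosfiltfilt(sos, rng.standard_normal(int(120 * fs)))
    data = np.vstack([shared, shared, other])
    mat = ppc_matrix(data, fs, (8.0, 13.0), channel_labels=("a", "b", "c"))
    assert mat.values[0, 1] == pytest.approx(1.0, abs=1e-6)
    assert abs(mat.values[0, 2]) < 0.5
    assert np.allclose(mat.values, mat.values.T, equal_nan=True)
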