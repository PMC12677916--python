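"""Band-limited functional connectivity and graph-theoretic network metrics.

Connectivity is estimated with pairwise phase consistency (PPC): band-pass
filtered analytic phases are pooled into non-overlapping segments (one
circular-mean phase-difference sample per segment) and fed to the unbiased
estimator

    PPC = 2 / (N (N-1)) * sum_{j<k} cos(dtheta_j - dtheta_k)
        = (|sum_j exp(i dtheta_j)|^2 - N) / (N (N-1)),

whose expectation is 0 for independent phases at any N.  Matrices are
thresholded (proportional density by default) into weighted graphs, and
node strength, weighted clustering (Onnela geometric-mean triangle form),
local/global efficiency (lengths = 1/weight), characteristic path length
over connected pairs, and the small-world index sigma = (C/C_rand)/(L/L_rand)
against degree-preserving rewired surrogates are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.sparse.csgraph import shortest_path


# ---------------------------------------------------------------- phase / PPC

def extract_phase(
    data: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float],
    edge_seconds: float = 1.0,
    order: int = 4,
) -> np.ndarray:
    """Instantaneous phase per channel within ``band``.

    Zero-phase Butterworth band-pass, analytic-signal (Hilbert) phase in
    (-pi, pi]; ``edge_seconds`` of filter/Hilbert transients are discarded
    at each end.
    """
    low, high = band
    nyq = sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist)")
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sampling_rate,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, data, axis=1)
    phase = np.angle(sps.hilbert(filtered, axis=1))
    trim = int(round(edge_seconds * sampling_rate))
    if 2 * trim >= phase.shape[1]:
        raise ValueError("epoch too short after edge trimming")
    return phase[:, trim: phase.shape[1] - trim]


def ppc_from_phase_differences(deltas: np.ndarray) -> float:
    """Unbiased PPC from an ensemble of phase-difference samples."""
    deltas = np.asarray(deltas, dtype=np.float64).ravel()
    n = deltas.size
    if n < 2:
        raise ValueError("PPC needs at least 2 phase-difference samples")
    resultant = np.abs(np.exp(1j * deltas).sum()) ** 2
    return float((resultant - n) / (n * (n - 1)))


def segment_phase_differences(
    phase_a: np.ndarray,
    phase_b: np.ndarray,
    sampling_rate: float,
    segment_seconds: float = 2.0,
) -> np.ndarray:
    """One circular-mean phase difference per non-overlapping segment."""
    phase_a = np.asarray(phase_a).ravel()
    phase_b = np.asarray(phase_b).ravel()
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase series must have equal length")
    seg = int(round(segment_seconds * sampling_rate))
    n_seg = phase_a.size // seg
    if n_seg < 2:
        raise ValueError("fewer than 2 segments available")
    d = (phase_a - phase_b)[: n_seg * seg].reshape(n_seg, seg)
    return np.angle(np.exp(1j * d).mean(axis=1))


def ppc(
    phase_a: np.ndarray,
    phase_b: np.ndarray,
    sampling_rate: float,
    segment_seconds: float = 2.0,
) -> float:
    """PPC between two phase series with default 2-s segment pooling."""
    deltas = segment_phase_differences(phase_a, phase_b, sampling_rate,
                                       segment_seconds)
    return ppc_from_phase_differences(deltas)


@dataclass
class PPCMatrix:
    """Symmetric channels x channels PPC for one band; diagonal is NaN.

    ``values`` keeps raw estimates (slightly negative values are possible
    for the unbiased estimator); :meth:`floored` clips at 0 for graph
    construction.
    """

    values: np.ndarray
    channel_labels: tuple[str, ...]
    band_name: str
    n_segments: int

    def floored(self) -> np.ndarray:
        return np.clip(self.values, 0.0, None)


def ppc_matrix(
    data: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float],
    channel_labels: tuple[str, ...] | None = None,
    band_name: str = "",
    segment_seconds: float = 2.0,
) -> PPCMatrix:
    """All-pairs PPC for one epoch and band."""
    phases = extract_phase(data, sampling_rate, band)
    n_ch = phases.shape[0]
    seg = int(round(segment_seconds * sampling_rate))
    n_seg = phases.shape[1] // seg
    if n_seg < 2:
        raise ValueError("epoch supplies fewer than 2 PPC segments")
    # circular segment means of e^{i phase}, then pairwise differences
    z = np.exp(1j * phases[:, : n_seg * seg]).reshape(n_ch, n_seg, seg).mean(axis=2)
    seg_phase = np.angle(z)
    values = np.full((n_ch, n_ch), np.nan)
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            d = np.angle(np.exp(1j * (seg_phase[i] - seg_phase[j])))
            values[i, j] = values[j, i] = ppc_from_phase_differences(d)
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(n_ch))
    return PPCMatrix(values=values, channel_labels=tuple(channel_labels),
                     band_name=band_name, n_segments=n_seg)


# ----------------------------------------------------------------- thresholding

@dataclass
class BandGraph:
    """Thresholded weighted connectivity graph for one band."""

    adjacency: np.ndarray
    channel_labels: tuple[str, ...]
    band_name: str
    density: float
    metrics: "GraphMetricSet | None" = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))


def threshold_graph(
    ppc: PPCMatrix,
    method: str = "proportional",
    param: float = 0.3,
) -> BandGraph:
    """Threshold a PPC matrix into a weighted graph.

    ``proportional`` retains the top ``param`` fraction of the n(n-1)/2
    possible edges by weight (ties broken by stable (i, j) lexical order);
    ``absolute`` retains weights >= ``param``.  Negative or floored-to-zero
    values are never retained.
    """
    w = ppc.floored()
    n = w.shape[0]
    adj = np.zeros_like(w)
    if method == "proportional":
        if not 0.0 < param <= 1.0:
            raise ValueError("density must lie in (0, 1]")
        edges = [(w[i, j], i, j) for i in range(n) for j in range(i + 1, n)
                 if w[i, j] > 0]
        # descending weight, ascending (i, j) on ties — deterministic
        edges.sort(key=lambda e: (-e[0], e[1], e[2]))
        k = int(round(param * n * (n - 1) / 2))
        for wt, i, j in edges[:k]:
            adj[i, j] = adj[j, i] = wt
    elif method == "absolute":
        keep = np.triu(w, 1) >= param
        keep &= np.triu(w, 1) > 0
        adj[keep] = w[keep]
        adj = adj + adj.T
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    n_kept = int(np.count_nonzero(np.triu(adj, 1)))
    density = n_kept / (n * (n - 1) / 2)
    return BandGraph(adjacency=adj, channel_labels=ppc.channel_labels,
                     band_name=ppc.band_name, density=density)


# ----------------------------------------------------------------- graph metrics

@dataclass
class GraphMetricSet:
    node_strength: pd.Series
    clustering: pd.Series
    mean_clustering: float
    local_efficiency: pd.Series
    mean_local_efficiency: float
    global_efficiency: float
    characteristic_path_length: float
    n_disconnected_pairs: int
    small_world_index: float = float("nan")


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with length = 1/weight."""
    with np.errstate(divide="ignore"):
        lengths = np.where(adj > 0, 1.0 / np.where(adj > 0, adj, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return shortest_path(lengths, method="D", directed=False)


def _onnela_clustering(adj: np.ndarray) -> np.ndarray:
    """Weighted clustering: geometric mean of triangle weights, normalized
    by the maximum weight in the graph."""
    wmax = adj.max()
    if wmax <= 0:
        return np.zeros(adj.shape[0])
    what = np.cbrt(adj / wmax)
    triangles = np.diag(what @ what @ what)  # 2 * sum of cube-root triangle products
    degree = (adj > 0).sum(axis=1)
    denom = degree * (degree - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def _efficiency_from_distances(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def _local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        eff[i] = _efficiency_from_distances(_distances(sub))
    return eff


def _rewired_surrogate(adj: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving rewiring; the weight multiset is randomly
    reassigned to the rewired edge set."""
    g = nx.from_numpy_array(adj)
    n_edges = g.number_of_edges()
    if n_edges < 2:
        return adj.copy()
    weights = [d["weight"] for _, _, d in g.edges(data=True)]
    nswap = max(10 * n_edges, 100)
    try:
        nx.double_edge_swap(g, nswap=nswap, max_tries=nswap * 100,
                            seed=int(rng.integers(0, 2**31 - 1)))
    except nx.NetworkXException:  # graph too constrained to swap
        pass
    rng.shuffle(weights)
    out = np.zeros_like(adj)
    for (u, v), w in zip(g.edges(), weights):
        out[u, v] = out[v, u] = w
    return out


def _core_metrics(adj: np.ndarray) -> tuple[float, float]:
    """(mean clustering, characteristic path length) for surrogates."""
    dist = _distances(adj)
    off = ~np.eye(adj.shape[0], dtype=bool)
    finite = np.isfinite(dist) & off
    cpl = float(dist[finite].mean()) if finite.any() else np.nan
    return float(_onnela_clustering(adj).mean()), cpl


def graph_metrics(
    graph: BandGraph,
    n_random: int = 100,
    seed: int | None = None,
) -> GraphMetricSet:
    """Compute the full metric set for a thresholded graph.

    The small-world index compares clustering and path length against
    ``n_random`` degree-preserving rewired surrogates (seeded); pass
    ``n_random=0`` to skip it.  Disconnected node pairs are excluded from
    the characteristic path length and counted.
    """
    adj = np.asarray(graph.adjacency, dtype=np.float64)
    n = adj.shape[0]
    if n < 3:
        raise ValueError("graph metrics need >= 3 nodes")
    if not np.allclose(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(adj < 0):
        raise ValueError("adjacency weights must be non-negative")
    labels = list(graph.channel_labels)

    strength = pd.Series(adj.sum(axis=1), index=labels)
    clustering = pd.Series(_onnela_clustering(adj), index=labels)
    local_eff = pd.Series(_local_efficiency(adj), index=labels)
    dist = _distances(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    n_disconnected = int((off & ~np.isfinite(dist)).sum() // 2)
    cpl = float(dist[finite].mean()) if finite.any() else np.nan
    geff = _efficiency_from_distances(dist)

    sigma = float("nan")
    if n_random > 0 and graph.n_edges > 0:
        rng = np.random.default_rng(seed)
        c_rand, l_rand = [], []
        for _ in range(n_random):
            cs, ls = _core_metrics(_rewired_surrogate(adj, rng))
            c_rand.append(cs)
            l_rand.append(ls)
        c_rand_m = float(np.nanmean(c_rand))
        l_rand_m = float(np.nanmean(l_rand))
        if c_rand_m > 0 and l_rand_m > 0 and np.isfinite(cpl) and cpl > 0:
            sigma = (clustering.mean() / c_rand_m) / (cpl / l_rand_m)

    metrics = GraphMetricSet(
        node_strength=strength,
        clustering=clustering,
        mean_clustering=float(clustering.mean()),
        local_efficiency=local_eff,
        mean_local_efficiency=float(local_eff.mean()),
        global_efficiency=geff,
        characteristic_path_length=cpl,
        n_disconnected_pairs=n_disconnected,
        small_world_index=sigma,
    )
    graph.metrics = metrics
    return metrics


def metrics_table(graphs: list[BandGraph]) -> pd.DataFrame:
    """Tidy (band, node, metric, value) table over analyzed band graphs."""
    rows = []
    for g in graphs:
        m = g.metrics
        if m is None:
            continue
        for ch in g.channel_labels:
            rows.append((g.band_name, ch, "node_strength", m.node_strength[ch]))
            rows.append((g.band_name, ch, "clustering", m.clustering[ch]))
            rows.append((g.band_name, ch, "local_efficiency", m.local_efficiency[ch]))
        for name, val in (
            ("mean_clustering", m.mean_clustering),
            ("mean_local_efficiency", m.mean_local_efficiency),
            ("global_efficiency", m.global_efficiency),
            ("characteristic_path_length", m.characteristic_path_length),
            ("small_world_index", m.small_world_index),
        ):
            rows.append((g.band_name, "GLOBAL", name, val))
    return pd.DataFrame(rows, columns=["band", "node", "metric", "value"])
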