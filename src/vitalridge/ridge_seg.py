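"""Graph-based ridge segmentation of vital-sign spectrograms.

The spectrogram is treated as an image whose bright, layer-like ridge
traces the dominant oscillation frequency.  Pixels become graph nodes;
adjacent nodes are joined by edges weighted

    w_ij = 2 - (g_i + g_j) + w_min

where g is the normalized vertical gradient (or the normalized intensity in
ridge mode), so edges along the bright layer are cheap.  A virtual source
feeds every row of the first column and a virtual sink drains the last, both
at weight w_min, letting the path begin and end at any frequency.  The
minimum-weight source-to-sink path, found with Dijkstra's algorithm and
median-smoothed, is the extracted heart- or breathing-rate trace.  The
conventional per-column spectral-magnitude argmax is provided as the
baseline estimator.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from vitalridge.config import GraphWeightConfig, RadarConfig, SpectrogramConfig, band_for
from vitalridge.radar_frontend import radar_waveform
from vitalridge.series import (
    DataError,
    PhaseSeries,
    RGBTrace,
    Spectrogram,
    VitalEstimate,
)
from vitalridge.timefreq import bandpass, build_spectrogram
from vitalridge.video_frontend import rppg_waveform


def vertical_gradients(spec: Spectrogram | np.ndarray, polarity: str = "dark-to-bright") -> np.ndarray:
    """Gradient image in [0, 1] from which edge weights are computed.

    ``dark-to-bright`` / ``bright-to-dark`` take the signed first difference
    along the frequency axis (forward difference, last row replicated) with
    the corresponding sign, then min-max rescale the image to [0, 1];
    ``intensity-ridge`` rescales the magnitudes themselves, so the weight
    minimum sits on the band centre rather than its edge.  A flat image maps
    to all zeros (no rescale division).
    """
    mags = spec.magnitudes if isinstance(spec, Spectrogram) else np.asarray(spec, dtype=float)
    if mags.shape[0] < 2:
        raise DataError("gradient image needs at least two frequency rows")
    if polarity == "intensity-ridge":
        raw = mags.astype(float)
    else:
        raw = np.empty_like(mags, dtype=float)
        raw[:-1] = np.diff(mags, axis=0)
        raw[-1] = raw[-2]
        if polarity == "bright-to-dark":
            raw = -raw
        elif polarity != "dark-to-bright":
            raise ValueError(f"unknown polarity {polarity!r}")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


@dataclass
class WeightedGraph:
    """Layered pixel graph with virtual source and sink.

    Nodes are pixels (row, col) numbered col * n_rows + row, plus a source
    (id n_rows * n_cols) wired into every row of the first column and a sink
    (id + 1) out of every row of the last, both at weight ``w_min``.  Edges
    are directed and column-advancing (8-connectivity: row step -1/0/+1 to
    the next column; 4-connectivity additionally allows vertical steps
    within a column and restricts the advance to the same row), so every
    source-to-sink path crosses each column.
    """

    n_rows: int
    n_cols: int
    edges_u: np.ndarray
    edges_v: np.ndarray
    weights: np.ndarray
    node_g: np.ndarray | None = None  # gradient value per node id
    w_min: float = 1e-5

    @property
    def source(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def sink(self) -> int:
        return self.n_rows * self.n_cols + 1

    def node_id(self, row: int, col: int) -> int:
        return col * self.n_rows + row

    def row_col(self, node: int) -> tuple[int, int]:
        return node % self.n_rows, node // self.n_rows


def _pair_weight(g_u: np.ndarray, g_v: np.ndarray, dist2: float, cfg: GraphWeightConfig) -> np.ndarray:
    if cfg.mode == "gradient":
        return 2.0 - (g_u + g_v) + cfg.w_min
    # exponential intensity/distance similarity weight with cutoff radius
    return np.exp(-((g_u - g_v) ** 2) / cfg.sigma_i) * np.exp(-dist2 / cfg.sigma_p) + cfg.w_min


def assign_weights(g: np.ndarray, cfg: GraphWeightConfig | None = None) -> WeightedGraph:
    """Build the weighted layered graph from a gradient image in [0, 1]."""
    cfg = cfg or GraphWeightConfig()
    g = np.asarray(g, dtype=float)
    rows, cols = g.shape
    ids = np.arange(rows * cols).reshape(cols, rows).T  # ids[r, c] = c * rows + r

    us, vs, ws = [], [], []

    def add(u_ids: np.ndarray, v_ids: np.ndarray, dist2: float) -> None:
        if cfg.mode == "exponential" and dist2 >= cfg.radius**2:
            return
        u = u_ids.ravel()
        v = v_ids.ravel()
        w = _pair_weight(g.T.ravel()[u], g.T.ravel()[v], dist2, cfg)
        us.append(u)
        vs.append(v)
        ws.append(w)

    if cols > 1:
        if cfg.connectivity == 8:
            add(ids[:, :-1], ids[:, 1:], 1.0)                  # horizontal
            add(ids[:-1, :-1], ids[1:, 1:], 2.0)               # diagonal down
            add(ids[1:, :-1], ids[:-1, 1:], 2.0)               # diagonal up
        else:  # 4-connectivity: same-row advance only
            add(ids[:, :-1], ids[:, 1:], 1.0)
    if cfg.connectivity == 4 and rows > 1:
        add(ids[:-1, :], ids[1:, :], 1.0)                      # vertical down
        add(ids[1:, :], ids[:-1, :], 1.0)                      # vertical up

    graph = WeightedGraph(rows, cols,
                          np.concatenate(us) if us else np.empty(0, dtype=int),
                          np.concatenate(vs) if vs else np.empty(0, dtype=int),
                          np.concatenate(ws) if ws else np.empty(0, dtype=float),
                          node_g=g.T.ravel().copy(), w_min=cfg.w_min)
    # virtual terminals
    first = ids[:, 0]
    last = ids[:, -1]
    graph.edges_u = np.concatenate([graph.edges_u, np.full(rows, graph.source), last])
    graph.edges_v = np.concatenate([graph.edges_v, first, np.full(rows, graph.sink)])
    graph.weights = np.concatenate([graph.weights, np.full(2 * rows, cfg.w_min)])
    if np.any(graph.weights <= 0):
        raise DataError("graph invariant violated: nonpositive edge weight")
    return graph


def shortest_path(graph: WeightedGraph) -> np.ndarray:
    """Minimum-weight source-to-sink path, one row index per column.

    Dijkstra's algorithm with a deterministic tie-break: among equal
    tentative distances the lower row (then earlier heap insertion) is
    settled first, so equal-cost alternatives resolve toward the lowest
    frequency.  Returns the row visited in each column (the last one, when
    4-connectivity permits several per column).
    """
    if graph.n_cols == 1:
        # only terminal edges exist, so every row ties at 2 * w_min; resolve
        # by minimal node cost 2 - 2 g + w_min (ties toward the lowest row)
        if graph.node_g is not None:
            return np.array([int(np.argmin(2.0 - 2.0 * graph.node_g[: graph.n_rows] + graph.w_min))])
        return np.array([0])
    n_nodes = graph.n_rows * graph.n_cols + 2
    order = np.argsort(graph.edges_u, kind="stable")
    eu, ev, ew = graph.edges_u[order], graph.edges_v[order], graph.weights[order]
    indptr = np.searchsorted(eu, np.arange(n_nodes + 1))

    dist = np.full(n_nodes, np.inf)
    pred = np.full(n_nodes, -1, dtype=int)
    done = np.zeros(n_nodes, dtype=bool)
    dist[graph.source] = 0.0
    counter = 0
    # heap entries: (distance, row-of-node, insertion order, node)
    heap: list[tuple[float, int, int, int]] = [(0.0, graph.n_rows, 0, graph.source)]
    while heap:
        d, _, _, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        if u == graph.sink:
            break
        for k in range(indptr[u], indptr[u + 1]):
            v = ev[k]
            nd = d + ew[k]
            if nd < dist[v]:
                dist[v] = nd
                pred[v] = u
                counter += 1
                row_key = v % graph.n_rows if v < graph.n_rows * graph.n_cols else graph.n_rows
                heapq.heappush(heap, (nd, row_key, counter, v))
    if not done[graph.sink]:
        raise DataError("graph is disconnected: no source-to-sink path")

    path_rows = np.full(graph.n_cols, -1, dtype=int)
    node = pred[graph.sink]
    while node != graph.source and node != -1:
        r, c = graph.row_col(node)
        if path_rows[c] == -1:  # walking backwards: keep the LAST visit per column
            path_rows[c] = r
        node = pred[node]
    if np.any(path_rows < 0):
        raise DataError("path does not cover every column")
    return path_rows


def smooth_path(p: np.ndarray, k: int = 5) -> np.ndarray:
    """Centered running median of the path, length-preserving.

    Near the boundaries the window shrinks symmetrically (k, k-2, ..., 1),
    which keeps every window odd and centred; a monotone path is therefore
    left unchanged.
    """
    if k <= 0 or k % 2 == 0:
        raise ValueError("median window k must be a positive odd integer")
    p = np.asarray(p)
    h = k // 2
    out = np.empty_like(p)
    for i in range(p.size):
        m = min(h, i, p.size - 1 - i)
        out[i] = np.median(p[i - m : i + m + 1])
    return out


def path_to_estimate(p: np.ndarray, spec: Spectrogram, method: str = "segmentation") -> VitalEstimate:
    """Map a per-column row path to BPM via the spectrogram frequency axis."""
    p = np.asarray(p, dtype=int)
    if p.size != spec.n_time:
        raise DataError("path length does not match the number of spectrogram columns")
    return VitalEstimate(spec.time_axis_s.copy(), spec.freq_axis_bpm[p], band=spec.band,
                         method=method, source=spec.source)


def segmentation_estimate(
    spec: Spectrogram,
    cfg: GraphWeightConfig | None = None,
    median_k: int = 5,
) -> VitalEstimate:
    """Full ridge-segmentation estimator on a spectrogram."""
    cfg = cfg or GraphWeightConfig()
    g = vertical_gradients(spec, cfg.polarity)
    path = shortest_path(assign_weights(g, cfg))
    return path_to_estimate(smooth_path(path, k=median_k), spec)


def spectral_magnitude_estimate(spec: Spectrogram) -> VitalEstimate:
    """Baseline: the BPM of the largest spectral magnitude in each column.

    Ties resolve to the lowest BPM; a column that is identically zero has no
    meaningful maximum and is reported as NaN.
    """
    if spec.n_time == 0:
        raise DataError("empty spectrogram")
    idx = np.argmax(spec.magnitudes, axis=0)  # first occurrence = lowest BPM
    bpm = spec.freq_axis_bpm[idx].astype(float)
    bpm[~np.any(spec.magnitudes > 0, axis=0)] = np.nan
    return VitalEstimate(spec.time_axis_s.copy(), bpm, band=spec.band,
                         method="spectral-magnitude", source=spec.source)


def estimate_vitals(
    series: PhaseSeries | RGBTrace,
    band: str = "HR",
    method: str = "segmentation",
    radar: RadarConfig | None = None,
    graph: GraphWeightConfig | None = None,
    spectro: SpectrogramConfig | None = None,
    zero_phase: bool = False,
    k_mad: float = 6.0,
    use_phase_difference: bool = True,
    lambda_d: float = 300.0,
    smooth_k: int = 5,
    median_k: int = 5,
) -> tuple[VitalEstimate, Spectrogram]:
    """End-to-end pipeline: front end -> band-pass -> spectrogram -> estimate.

    The source branch is chosen by the input type (radar phase series or
    camera RGB trace); ``method`` selects the ridge-segmentation estimator
    or the spectral-magnitude baseline, which share the identical
    spectrogram.  Returns the estimate together with that spectrogram.
    """
    band_cfg = band_for(band)
    if isinstance(series, PhaseSeries):
        radar = radar or RadarConfig()
        disp = radar_waveform(series, radar, k_mad=k_mad,
                              use_phase_difference=use_phase_difference)
        values, fs, source = disp.values, disp.fs, "radar"
    elif isinstance(series, RGBTrace):
        values = rppg_waveform(series, lambda_d=lambda_d, smooth_k=smooth_k)
        fs, source = series.fs, "video"
    else:
        raise DataError(f"unsupported input type {type(series).__name__}")
    wave = bandpass(values, fs, band_cfg, zero_phase=zero_phase)
    spectro = spectro or SpectrogramConfig.for_band(band_cfg, fs)
    spec = build_spectrogram(wave, spectro, source=source)
    if method == "segmentation":
        est = segmentation_estimate(spec, cfg=graph, median_k=median_k)
    elif method == "spectral-magnitude":
        est = spectral_magnitude_estimate(spec)
    else:
        raise ValueError(f"unknown method {method!r}")
    return est, spec
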