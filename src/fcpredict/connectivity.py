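"""Functional connectivity inference from baseline spike trains.

Two undirected, weighted measures — Pearson correlation of 20-ms binned
counts (PCC) and the spike-time tiling coefficient (STTC, dt = 10 ms) —
both surrogate-corrected by subtracting the maximum value over 100
ISI-shuffled surrogate train pairs, keeping only positive residuals.

One directed, binary measure: cross-correlogram (CCH) peaks/troughs in the
25-ms postsynaptic window label ordered pairs excitatory/inhibitory; pairs
are filtered by an axonal-propagation-velocity bound (400 mm/s), peer
thresholds μ + γσ per label class, Dale's law, and largest-component
pruning.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np

from .types import (
    RELATIONS,
    DirectedRelationalGraph,
    NormalizedCCH,
    SpikeTrain,
    WeightedGraph,
)

log = logging.getLogger(__name__)

__all__ = [
    "bin_trains",
    "pearson_pair",
    "surrogate_train",
    "sttc_pair",
    "surrogate_corrected_fc",
    "cch",
    "velocity_filter",
    "peer_threshold",
    "apply_dales_law",
    "largest_component",
    "infer_directed_fc",
]


# ---------------------------------------------------------------------------
# binning and undirected measures
# ---------------------------------------------------------------------------

def bin_trains(trains: list, bin_ms: float = 20.0) -> np.ndarray:
    """Bin spike trains into a neurons × bins count matrix.

    Bins tile ``[0, duration)`` left-aligned with half-open ``[k·b, (k+1)·b)``
    bins; a trailing partial bin is dropped.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    duration = trains[0].duration
    if any(tr.duration != duration for tr in trains):
        raise ValueError("all trains must share one duration")
    n_bins = int(np.floor(duration * 1e3 / bin_ms))
    counts = np.zeros((len(trains), n_bins), dtype=np.int64)
    edge = n_bins * bin_ms / 1e3
    for i, tr in enumerate(trains):
        t = tr.spike_times[tr.spike_times < edge]
        idx = np.minimum((t * 1e3 / bin_ms + 1e-9).astype(np.int64), n_bins - 1)
        np.add.at(counts[i], idx, 1)
    return counts


def pearson_pair(b_i: np.ndarray, b_j: np.ndarray) -> float:
    """Pearson correlation of two binned trains (centered cosine)."""
    b_i = np.asarray(b_i, dtype=float)
    b_j = np.asarray(b_j, dtype=float)
    ci, cj = b_i - b_i.mean(), b_j - b_j.mean()
    denom = np.sqrt(np.dot(ci, ci) * np.dot(cj, cj))
    if denom == 0:
        raise ValueError("zero-variance binned train: correlation undefined")
    return float(np.dot(ci, cj) / denom)


def surrogate_train(train: SpikeTrain, rng: np.random.Generator) -> SpikeTrain:
    """ISI-shuffled surrogate: permute inter-spike intervals, keep the first
    spike time, spike count and ISI multiset."""
    t = train.spike_times
    if t.size < 3:
        warnings.warn("fewer than 3 spikes: surrogate is the original train",
                      stacklevel=2)
        return SpikeTrain(train.unit_id, t.copy(), train.duration,
                          train.chip_id, train.network_id)
    isis = np.diff(t)
    shuffled = rng.permutation(isis)
    new_t = np.concatenate([[t[0]], t[0] + np.cumsum(shuffled)])
    return SpikeTrain(train.unit_id, new_t, train.duration,
                      train.chip_id, train.network_id)


def _tiled_fraction(t: np.ndarray, dt: float, duration: float) -> float:
    """T term of the STTC: fraction of the recording covered by the union of
    ±dt windows around the spikes (overlaps merged, clipped to [0, T])."""
    if t.size == 0:
        return 0.0
    starts = np.clip(t - dt, 0.0, duration)
    ends = np.clip(t + dt, 0.0, duration)
    total = 0.0
    cur_s, cur_e = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return total / duration


def _prop_within(t_a: np.ndarray, t_b: np.ndarray, dt: float) -> float:
    """P term: fraction of spikes in a that lie within ±dt of any spike in b."""
    if t_a.size == 0:
        return 0.0
    idx = np.searchsorted(t_b, t_a)
    near = np.zeros(t_a.size, dtype=bool)
    left = idx > 0
    near[left] = (t_a[left] - t_b[idx[left] - 1]) <= dt
    right = idx < t_b.size
    near[right] |= (t_b[idx[right]] - t_a[right.nonzero()[0]]) <= dt
    return float(np.count_nonzero(near) / t_a.size)


def sttc_pair(
    train_i: SpikeTrain,
    train_j: SpikeTrain,
    dt_ms: float = 10.0,
    duration: float | None = None,
) -> float:
    """Spike-time tiling coefficient of a pair.

    ``STTC = ((P_ij − T_j)/(1 − P_ij·T_j) + (P_ji − T_i)/(1 − P_ji·T_i)) / 2``
    where P_ij is the fraction of i's spikes within ±dt of a j spike and T_i
    the fraction of the recording tiled by i's ±dt windows.  A degenerate
    denominator contributes 0.
    """
    duration = duration if duration is not None else train_i.duration
    if duration <= 0:
        raise ValueError("duration must be positive")
    ti, tj = train_i.spike_times, train_j.spike_times
    if ti.size == 0 or tj.size == 0:
        warnings.warn("empty train in STTC: value 0", stacklevel=2)
        return 0.0
    dt = dt_ms / 1e3
    t_i = _tiled_fraction(ti, dt, duration)
    t_j = _tiled_fraction(tj, dt, duration)
    p_ij = _prop_within(ti, tj, dt)
    p_ji = _prop_within(tj, ti, dt)
    total = 0.0
    for p, t in ((p_ij, t_j), (p_ji, t_i)):
        denom = 1.0 - p * t
        if denom != 0.0:
            total += (p - t) / denom
    return 0.5 * total


def surrogate_corrected_fc(
    trains: list,
    measure: str = "PCC",
    n_surrogates: int = 100,
    bin_ms: float = 20.0,
    dt_ms: float = 10.0,
    seed: int = 0,
    drop_isolated: bool = True,
) -> WeightedGraph:
    """Surrogate-corrected undirected FC graph (PCC or STTC).

    Per pair: negative or zero raw values become 0; otherwise the maximum
    value over ``n_surrogates`` surrogate pairs is subtracted and the result
    floored at 0.  Each unit gets ``n_surrogates`` ISI-shuffled surrogate
    versions (seeded once per network); surrogate pairs are matched by
    surrogate index.  Isolated nodes are removed.
    """
    if len(trains) < 2:
        raise ValueError("need at least 2 trains")
    if measure not in ("PCC", "STTC"):
        raise ValueError(f"unknown measure {measure!r}")
    rng = np.random.default_rng(seed)
    n = len(trains)
    surr = [[surrogate_train(tr, rng) for _ in range(n_surrogates)] for tr in trains]

    if measure == "PCC":
        counts = bin_trains(trains, bin_ms).astype(float)
        raw = _corr_matrix(counts)
        surr_vals = np.empty((n_surrogates, n, n))
        for s in range(n_surrogates):
            sc = bin_trains([surr[i][s] for i in range(n)], bin_ms).astype(float)
            surr_vals[s] = _corr_matrix(sc)
        surr_max = surr_vals.max(axis=0)
    else:
        duration = trains[0].duration
        raw = np.zeros((n, n))
        surr_max = np.full((n, n), -np.inf)
        for i in range(n):
            for j in range(i + 1, n):
                raw[i, j] = raw[j, i] = sttc_pair(trains[i], trains[j], dt_ms, duration)
        for s in range(n_surrogates):
            for i in range(n):
                for j in range(i + 1, n):
                    v = sttc_pair(surr[i][s], surr[j][s], dt_ms, duration)
                    if v > surr_max[i, j]:
                        surr_max[i, j] = surr_max[j, i] = v

    corrected = np.where(raw > 0, raw - surr_max, 0.0)
    corrected = np.maximum(corrected, 0.0)
    np.fill_diagonal(corrected, 0.0)
    node_ids = np.array([tr.unit_id for tr in trains])
    if drop_isolated:
        keep = corrected.sum(axis=0) > 0
        corrected = corrected[np.ix_(keep, keep)]
        node_ids = node_ids[keep]
    return WeightedGraph(node_ids=node_ids, weights=corrected, measure=measure)


def _corr_matrix(counts: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations; zero-variance rows yield 0 (logged)."""
    sd = counts.std(axis=1)
    bad = sd == 0
    if np.any(bad):
        log.warning("%d zero-variance binned trains: correlations set to 0",
                    int(bad.sum()))
    safe = counts.copy()
    safe[bad] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(safe)
    c = np.nan_to_num(c, nan=0.0)
    c[bad, :] = 0.0
    c[:, bad] = 0.0
    np.fill_diagonal(c, 0.0)
    return c


# ---------------------------------------------------------------------------
# directed (CCH) inference
# ---------------------------------------------------------------------------

def cch(
    train_i: SpikeTrain,
    train_j: SpikeTrain,
    bin_ms: float = 1.0,
    half_window_ms: float = 25.0,
) -> NormalizedCCH:
    """Cross-correlogram of the ordered pair i -> j.

    Raw counts histogram the lags ``t_j − t_i`` over ±25 ms (1-ms bins).
    The B = 25 positive-lag ("postsynaptic": target spikes following source
    spikes) bins are normalized by subtracting their mean; the bin with the
    largest |normalized| value sets the peak lag and the tentative label —
    excitatory if the extremum is a peak, inhibitory if a trough; an exact
    tie goes to excitatory.
    """
    n_side = int(round(half_window_ms / bin_ms))
    edges = np.arange(-n_side, n_side + 1) * bin_ms
    raw = np.zeros(2 * n_side, dtype=np.int64)
    ti, tj = train_i.spike_times * 1e3, train_j.spike_times * 1e3
    if ti.size == 0 or tj.size == 0:
        return NormalizedCCH(edges[:-1], raw, np.zeros(n_side), 0.0, 0.0, "none")
    lo = np.searchsorted(tj, ti - half_window_ms, side="left")
    hi = np.searchsorted(tj, ti + half_window_ms, side="right")
    for k in range(ti.size):
        if hi[k] <= lo[k]:
            continue
        lags = tj[lo[k] : hi[k]] - ti[k]
        idx = np.clip(np.floor(lags / bin_ms).astype(np.int64) + n_side,
                      0, 2 * n_side - 1)
        np.add.at(raw, idx, 1)
    post = raw[n_side:].astype(float)  # positive lags: 0..25 ms
    normalized = post - post.mean()
    if np.allclose(normalized, 0.0):
        return NormalizedCCH(edges[:-1], raw, normalized, 0.0, 0.0, "none")
    peak_bin = int(np.argmax(np.abs(normalized)))
    # tie between equal-magnitude peak and trough -> excitatory (prefer a peak)
    pos_max = normalized.max()
    if pos_max > 0 and np.isclose(pos_max, np.abs(normalized).max()):
        peak_bin = int(np.argmax(normalized))
    peak_value = float(normalized[peak_bin])
    label = "excitatory" if peak_value > 0 else "inhibitory"
    peak_lag = (peak_bin + 0.5) * bin_ms
    return NormalizedCCH(edges[:-1], raw, normalized, peak_lag, peak_value, label)


def velocity_filter(
    distance_um: float, peak_lag_ms: float, velocity_um_per_ms: float = 400.0
) -> bool:
    """Return True to *keep* the pair: the peak lag is long enough for an
    action potential at 400 mm/s (= 400 µm/ms) to cover the distance."""
    if peak_lag_ms <= 0:
        warnings.warn("non-positive peak lag: pair dropped", stacklevel=2)
        return False
    return distance_um <= velocity_um_per_ms * peak_lag_ms


def peer_threshold(labeled_pairs: list, gamma: float) -> list:
    """Hard peer thresholds μ + γσ per label class.

    ``labeled_pairs`` is a list of ``(i, j, label, peak_value)``; within each
    label class, μ and σ are computed over |peak_value| and a pair survives
    iff |peak_value| > μ + γσ (strict).  A single-member class gets σ = 0.
    """
    kept = []
    for rel in RELATIONS:
        members = [p for p in labeled_pairs if p[2] == rel]
        if not members:
            continue
        mags = np.array([abs(p[3]) for p in members])
        if mags.size < 2:
            warnings.warn(f"only one {rel} pair: σ set to 0", stacklevel=2)
        mu, sigma = mags.mean(), mags.std() if mags.size >= 2 else 0.0
        thr = mu + gamma * sigma
        kept.extend(p for p, m in zip(members, mags) if m > thr)
    return kept


def apply_dales_law(graph: DirectedRelationalGraph) -> DirectedRelationalGraph:
    """Delete the minority relation among each node's out-edges.

    Ties keep the excitatory edges.  The result is Dale-consistent: every
    node's surviving out-edges share one relation.
    """
    exc = graph.adjacency["excitatory"].copy()
    inh = graph.adjacency["inhibitory"].copy()
    n_exc, n_inh = exc.sum(axis=1), inh.sum(axis=1)
    exc[n_exc < n_inh, :] = 0
    inh[n_inh <= n_exc, :] = 0  # tie -> keep excitatory
    return DirectedRelationalGraph(
        node_ids=graph.node_ids.copy(),
        adjacency={"excitatory": exc, "inhibitory": inh},
        gamma=graph.gamma,
    )


def largest_component(graph: DirectedRelationalGraph) -> DirectedRelationalGraph:
    """Keep the largest weakly connected component of the relation union.

    Ties go to the component containing the lowest node id.  Isolated nodes
    count as singleton components.
    """
    n = graph.n_nodes
    if n == 0:
        return graph
    union = graph.union()
    g = nx.from_numpy_array(union, create_using=nx.DiGraph)
    comps = sorted(
        nx.weakly_connected_components(g),
        key=lambda c: (-len(c), min(graph.node_ids[list(c)])),
    )
    keep = np.array(sorted(comps[0]), dtype=int)
    return DirectedRelationalGraph(
        node_ids=graph.node_ids[keep],
        adjacency={r: graph.adjacency[r][np.ix_(keep, keep)] for r in RELATIONS},
        gamma=graph.gamma,
    )


def label_pairs(
    trains: list,
    positions: np.ndarray,
    bin_ms: float = 1.0,
    half_window_ms: float = 25.0,
    velocity_um_per_ms: float = 400.0,
) -> list:
    """CCH-label all ordered pairs and apply the velocity filter.

    Returns ``(i, j, label, peak_value)`` tuples with matrix indices i, j.
    """
    n = len(trains)
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] != n:
        raise ValueError("positions must be keyed like trains")
    labeled = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            h = cch(trains[i], trains[j], bin_ms, half_window_ms)
            if h.label == "none":
                continue
            dist = float(np.linalg.norm(positions[i] - positions[j]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if velocity_filter(dist, h.peak_lag, velocity_um_per_ms):
                    labeled.append((i, j, h.label, h.peak_value))
    return labeled


def infer_directed_fc(
    trains: list,
    positions: np.ndarray,
    gamma: float = 1.0,
    bin_ms: float = 1.0,
    half_window_ms: float = 25.0,
) -> DirectedRelationalGraph:
    """Full directed-FC procedure.

    CCH labeling → velocity filter → peer thresholds (μ + γσ) → Dale's law
    → largest weakly connected component.
    """
    n = len(trains)
    labeled = label_pairs(trains, positions, bin_ms, half_window_ms)
    kept = peer_threshold(labeled, gamma)
    adj = {r: np.zeros((n, n), dtype=int) for r in RELATIONS}
    for i, j, rel, _ in kept:
        adj[rel][i, j] = 1
    graph = DirectedRelationalGraph(
        node_ids=np.array([tr.unit_id for tr in trains]),
        adjacency=adj,
        gamma=gamma,
    )
    graph = apply_dales_law(graph)
    return largest_component(graph)
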