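"""Network-level characterization: participation ratio, degree strength,
shortest paths, and the minimum-size selection rule."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import bin_trains
from .types import DirectedRelationalGraph, WeightedGraph

log = logging.getLogger(__name__)

__all__ = [
    "ParticipationResult",
    "participation_ratio",
    "degree_strength",
    "avg_shortest_path",
    "select_networks",
]


@dataclass
class ParticipationResult:
    eigenvalues: np.ndarray
    pr: float
    pr_normalized: float
    n: int


def participation_ratio(trains: list, bin_ms: float = 20.0) -> ParticipationResult:
    """Participation ratio of population activity.

    Spike trains are binned (20 ms), z-transformed, and the eigenvalues
    λ_i of their correlation matrix give ``PR = (Σλ)² / Σλ²`` — the
    effective number of principal components of the population activity.
    ``PR_normalized = PR / N`` lies in [1/N, 1]; values below ~0.5 indicate
    strongly correlated (synchronized) network activity.

    Constant binned trains carry no correlation information and are dropped
    with a warning; an all-constant input raises.
    """
    if len(trains) < 2:
        raise ValueError("participation ratio needs at least 2 neurons")
    counts = bin_trains(trains, bin_ms).astype(float)
    sd = counts.std(axis=1)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("all binned trains constant: PR undefined")
    if not np.all(keep):
        log.warning("dropping %d constant binned trains for PR",
                    int((~keep).sum()))
    z = (counts[keep] - counts[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    corr = (z @ z.T) / z.shape[1]
    eig = np.linalg.eigvalsh(corr)
    eig = np.clip(eig, 0.0, None)
    pr = float(eig.sum() ** 2 / np.sum(eig**2))
    n = int(keep.sum())
    return ParticipationResult(eigenvalues=eig, pr=pr, pr_normalized=pr / n, n=n)


def degree_strength(g: WeightedGraph) -> np.ndarray:
    """Column sums of the weight matrix (per-node degree strength)."""
    return g.weights.sum(axis=0)


def avg_shortest_path(g) -> tuple[float, int]:
    """Average shortest-path length of an FC graph.

    Weighted undirected graphs use Dijkstra over 1/weight distances
    (zero-weight entries are non-edges) averaged over unordered reachable
    pairs; directed binary graphs use hop counts over ordered reachable
    pairs.  Returns ``(mean, n_excluded_pairs)`` where excluded pairs are
    unreachable ones.
    """
    if isinstance(g, WeightedGraph):
        n = g.n_nodes
        with np.errstate(divide="ignore"):
            dist = np.where(g.weights > 0, 1.0 / g.weights, np.inf)
        G = nx.Graph()
        G.add_nodes_from(range(n))
        ii, jj = np.nonzero(np.triu(g.weights, 1))
        G.add_weighted_edges_from(
            (int(i), int(j), float(dist[i, j])) for i, j in zip(ii, jj)
        )
        lengths = dict(nx.all_pairs_dijkstra_path_length(G))
        vals, excluded = [], 0
        for i in range(n):
            for j in range(i + 1, n):
                if j in lengths[i]:
                    vals.append(lengths[i][j])
                else:
                    excluded += 1
    elif isinstance(g, DirectedRelationalGraph):
        n = g.n_nodes
        G = nx.from_numpy_array(g.union(), create_using=nx.DiGraph)
        lengths = dict(nx.all_pairs_shortest_path_length(G))
        vals, excluded = [], 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if j in lengths.get(i, {}):
                    vals.append(lengths[i][j])
                else:
                    excluded += 1
    else:
        raise TypeError(f"unsupported graph type {type(g).__name__}")
    if excluded:
        log.warning("%d unreachable pairs excluded from avg shortest path", excluded)
    mean = float(np.mean(vals)) if vals else float("nan")
    return mean, excluded


def select_networks(graphs: list, min_nodes: int = 30) -> list:
    """Keep graphs with at least ``min_nodes`` nodes (post-FC-pruning)."""
    return [g for g in graphs if g.n_nodes >= min_nodes]
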