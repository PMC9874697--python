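"""Chip-aware leave-one-network-out evaluation and the ablation suite.

Every network is held out once; networks sharing the held-out network's
chip are excluded from training (an inductive, out-of-distribution
protocol).  Features and targets are standard-scaled on the training split
only.  Stochastic models (random forest, GNNs) are run 30 times with
different seeds and their per-network MSEs averaged; per-neuron squared
errors (run-averaged) feed a two-sided paired t-test against the baseline
model at α = 0.01.

Ablations replace either the FC graph (uniform-random, shuffled,
degree-preserved shuffle, spanning-tree backbone) or the node features
(training-target average, uniform-random, per-feature shuffle) to test that
the model's advantage comes from the experimental structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .gnn import GNNConfig, GNNModel
from .models import baseline_predict, forest_fit_predict, linear_fit_predict, standard_scale
from .types import CVSplit, DirectedRelationalGraph, WeightedGraph

log = logging.getLogger(__name__)

__all__ = [
    "NetworkData",
    "make_splits",
    "run_protocol",
    "paired_test",
    "ablate_fc",
    "ablate_features",
    "report",
    "CVResult",
]


@dataclass
class NetworkData:
    """Everything one network contributes to the prediction task."""

    network_id: str
    chip_id: str
    graph: object  # WeightedGraph | DirectedRelationalGraph | adjacency
    features: np.ndarray  # (n, 7)
    targets: np.ndarray  # (n,) Δfch'

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.targets = np.asarray(self.targets, dtype=float)
        if self.features.shape[0] != self.targets.size:
            raise ValueError("features and targets must align")


def make_splits(networks: list) -> list:
    """Leave-one-network-out splits with same-chip exclusion."""
    chips = {nd.chip_id for nd in networks}
    if len(chips) < 2:
        raise ValueError("chip-exclusion CV needs networks from >= 2 chips")
    splits = []
    for nd in networks:
        train, excluded = [], []
        for other in networks:
            if other.network_id == nd.network_id:
                continue
            if other.chip_id == nd.chip_id:
                excluded.append(other.network_id)
            else:
                train.append(other.network_id)
        if not train:
            raise ValueError(f"no training networks left for {nd.network_id}")
        splits.append(
            CVSplit(
                test_network_id=nd.network_id,
                train_network_ids=train,
                excluded_same_chip_ids=excluded,
            )
        )
    return splits


@dataclass
class CVResult:
    """Per-(model, network, run) MSEs plus paired-test statistics."""

    per_network_mse: dict = field(default_factory=dict)  # model -> {net -> [mse/run]}
    per_neuron_sqerr: dict = field(default_factory=dict)  # model -> run-avg vector
    paired_tests: dict = field(default_factory=dict)  # model -> (t, p, significant)
    n_runs: dict = field(default_factory=dict)

    def average_mse(self, model: str) -> float:
        """Average over networks of run-mean network MSEs."""
        per_net = self.per_network_mse[model]
        return float(np.mean([np.mean(v) for v in per_net.values()]))

    def mse_sd_over_runs(self, model: str) -> float:
        runs = np.array(
            [
                [per_run[r] for per_run in self.per_network_mse[model].values()]
                for r in range(self.n_runs[model])
            ]
        )
        return float(runs.mean(axis=1).std())


DETERMINISTIC_KINDS = {"baseline", "linear"}


def _fit_predict(kind, config, train_x, train_y, train_graphs, test_x, test_graph, seed):
    if kind == "baseline":
        return baseline_predict(train_y, test_x.shape[0])
    if kind == "linear":
        return linear_fit_predict(train_x, train_y, test_x)
    if kind == "forest":
        return forest_fit_predict(train_x, train_y, test_x, grid=config, seed=seed)
    if kind == "gnn":
        cfg_kwargs = dict(config or {})
        cfg = GNNConfig(seed=seed, **cfg_kwargs)
        model = GNNModel(train_graphs[0][1].shape[1], cfg)
        model.fit(train_graphs)
        return model.predict(test_graph, test_x)
    raise ValueError(f"unknown model kind {kind!r}")


def run_protocol(
    networks: list,
    models: dict,
    n_runs: int = 30,
    seed: int = 0,
    alpha: float = 0.01,
) -> CVResult:
    """Run the full evaluation protocol.

    ``networks`` is a list of :class:`NetworkData`; ``models`` maps a model
    name to ``{"kind": "baseline"|"linear"|"forest"|"gnn", "config": ...}``
    (for GNNs the config holds :class:`~fcpredict.gnn.GNNConfig` kwargs, for
    forests a parameter grid).  GNN specs may add ``fc_ablation`` /
    ``feature_ablation`` modes (see :func:`ablate_fc`,
    :func:`ablate_features`); graph ablations are drawn per network per run,
    feature ablations are applied to the scaled features (the
    training-target mean for ``target_average`` is the unscaled train mean).
    Deterministic models run once; stochastic models run ``n_runs`` times
    with derived seeds.  Per-neuron squared errors are averaged over runs
    before the paired t-test vs the baseline.
    """
    splits = make_splits(networks)
    by_id = {nd.network_id: nd for nd in networks}
    net_index = {nd.network_id: k for k, nd in enumerate(networks)}
    result = CVResult()
    rng = np.random.default_rng(seed)
    model_seeds = {
        name: rng.integers(2**31, size=n_runs) for name in models
    }

    for name, spec in models.items():
        kind = spec["kind"]
        config = spec.get("config")
        fc_mode = spec.get("fc_ablation")
        feat_mode = spec.get("feature_ablation")
        runs = 1 if kind in DETERMINISTIC_KINDS else n_runs
        result.n_runs[name] = runs
        per_net: dict = {}
        sq_err_runs = []  # one concatenated per-neuron vector per run
        for r in range(runs):
            run_seed = int(model_seeds[name][r])
            graphs = {nd.network_id: nd.graph for nd in networks}
            if fc_mode is not None:
                graphs = {
                    nd.network_id: ablate_fc(
                        nd.graph, fc_mode,
                        seed=(run_seed + net_index[nd.network_id]) % 2**31,
                    )
                    for nd in networks
                }
            sq_parts = []
            for split in splits:
                test_nd = by_id[split.test_network_id]
                assert test_nd.chip_id not in {
                    by_id[t].chip_id for t in split.train_network_ids
                }, "chip-exclusion violated"
                train_nds = [by_id[t] for t in split.train_network_ids]
                tr_x = np.vstack([nd.features for nd in train_nds])
                tr_y = np.concatenate([nd.targets for nd in train_nds])
                sx_tr, sx_te, _ = standard_scale(tr_x, test_nd.features)
                sy_tr, sy_te, _ = standard_scale(tr_y[:, None], test_nd.targets[:, None])
                sy_tr, sy_te = sy_tr.ravel(), sy_te.ravel()
                if feat_mode is not None:
                    tmean = float(tr_y.mean())
                    sx_tr = np.vstack([
                        ablate_features(
                            blk, feat_mode, targets_train_mean=tmean,
                            seed=(run_seed + 7 * k) % 2**31,
                        )
                        for k, blk in enumerate(_blocks(sx_tr, train_nds))
                    ])
                    sx_te = ablate_features(
                        sx_te, feat_mode, targets_train_mean=tmean,
                        seed=(run_seed + 7 * len(train_nds)) % 2**31,
                    )
                train_graphs = None
                if kind == "gnn":
                    # split the pooled scaled features back into per-network blocks
                    train_graphs = []
                    off = 0
                    for nd in train_nds:
                        n_i = nd.targets.size
                        train_graphs.append(
                            (graphs[nd.network_id], sx_tr[off : off + n_i],
                             sy_tr[off : off + n_i])
                        )
                        off += n_i
                pred = _fit_predict(
                    kind, config, sx_tr, sy_tr, train_graphs, sx_te,
                    graphs[test_nd.network_id], run_seed,
                )
                err2 = (np.asarray(pred).ravel() - sy_te) ** 2
                per_net.setdefault(split.test_network_id, [np.nan] * runs)[r] = float(
                    err2.mean()
                )
                sq_parts.append(err2)
            sq_err_runs.append(np.concatenate(sq_parts))
        result.per_network_mse[name] = per_net
        result.per_neuron_sqerr[name] = np.mean(sq_err_runs, axis=0)

    base_name = next((n for n, s in models.items() if s["kind"] == "baseline"), None)
    if base_name is not None:
        base_err = result.per_neuron_sqerr[base_name]
        for name in models:
            if name == base_name:
                continue
            result.paired_tests[name] = paired_test(
                result.per_neuron_sqerr[name], base_err, alpha=alpha
            )
    return result


def _blocks(pooled: np.ndarray, nds: list):
    off = 0
    for nd in nds:
        n_i = nd.targets.size
        yield pooled[off : off + n_i]
        off += n_i


def paired_test(
    model_errors: np.ndarray, baseline_errors: np.ndarray, alpha: float = 0.01
) -> tuple:
    """Two-sided paired t-test on per-neuron squared errors.

    Returns ``(t, p, significant)``.  Zero-variance differences make the
    test undefined; it is then reported as not significant with NaN stats.
    """
    a = np.asarray(model_errors, dtype=float)
    b = np.asarray(baseline_errors, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    if np.allclose(d.std(), 0.0):
        log.warning("zero-variance paired differences: test undefined")
        return float("nan"), float("nan"), False
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), bool(p < alpha)


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------

def ablate_fc(
    graph: WeightedGraph, mode: str, seed: int = 0,
    mst_on: str = "inverted_weights",
) -> WeightedGraph:
    """Replace the FC graph with a structural control.

    ``random_uniform``: fully connected, i.i.d. U[0, 1] weights.
    ``shuffle``: same edge count, endpoints redrawn uniformly; weights
    travel with edges.  ``shuffle_degree_preserved``: >= 10·|E| double-edge
    swaps preserving the degree sequence, weights travel.
    ``min_spanning_tree``: spanning tree of the graph computed on inverted
    weights (the maximum-weight backbone, matching the motivation of testing
    a strongly-connected edge backbone; ``mst_on="raw_weights"`` switches to
    a literal minimum-weight tree); a disconnected graph yields a
    per-component forest with a warning.
    """
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    if mode == "random_uniform":
        w = rng.uniform(0, 1, size=(n, n))
        w = np.triu(w, 1)
        w = w + w.T
        return WeightedGraph(graph.node_ids.copy(), w, graph.measure)
    ii, jj = np.nonzero(np.triu(graph.weights, 1))
    weights = graph.weights[ii, jj]
    m = weights.size
    if mode == "shuffle":
        all_pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
        chosen = rng.choice(len(all_pairs), size=m, replace=False)
        perm = rng.permutation(m)
        w = np.zeros((n, n))
        for k, c in enumerate(chosen):
            a, b = all_pairs[c]
            w[a, b] = w[b, a] = weights[perm[k]]
        return WeightedGraph(graph.node_ids.copy(), w, graph.measure)
    if mode == "shuffle_degree_preserved":
        edges = {(int(a), int(b)): float(wt) for a, b, wt in zip(ii, jj, weights)}
        n_swaps = 0
        attempts = 0
        target = 10 * m
        keys = list(edges)
        while n_swaps < target and attempts < 100 * target and m >= 2:
            attempts += 1
            k1, k2 = rng.integers(len(keys)), rng.integers(len(keys))
            if k1 == k2:
                continue
            (u, v), (x, y) = keys[k1], keys[k2]
            if len({u, v, x, y}) < 4:
                continue
            # swap to (u, x), (v, y)
            e1 = (min(u, x), max(u, x))
            e2 = (min(v, y), max(v, y))
            if e1 in edges or e2 in edges:
                continue
            w1, w2 = edges.pop((u, v)), edges.pop((x, y))
            edges[e1], edges[e2] = w1, w2
            keys = list(edges)
            n_swaps += 1
        w = np.zeros((n, n))
        for (a, b), wt in edges.items():
            w[a, b] = w[b, a] = wt
        return WeightedGraph(graph.node_ids.copy(), w, graph.measure)
    if mode == "min_spanning_tree":
        G = nx.Graph()
        G.add_nodes_from(range(n))
        for a, b, wt in zip(ii, jj, weights):
            G.add_edge(int(a), int(b), weight=wt, inv=1.0 / wt if wt > 0 else np.inf)
        if not nx.is_connected(G):
            warnings.warn("disconnected graph: spanning forest returned", stacklevel=2)
        key = "inv" if mst_on == "inverted_weights" else "weight"
        tree = nx.minimum_spanning_tree(G, weight=key, algorithm="kruskal")
        w = np.zeros((n, n))
        for a, b, data in tree.edges(data=True):
            w[a, b] = w[b, a] = data["weight"]
        return WeightedGraph(graph.node_ids.copy(), w, graph.measure)
    raise ValueError(f"unknown ablation mode {mode!r}")


def ablate_features(
    features: np.ndarray,
    mode: str,
    targets_train_mean: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Replace node features with a control.

    ``target_average``: every node's feature vector becomes the training
    targets' mean (replicated); ``random_uniform``: i.i.d. U[0, 1];
    ``shuffle_per_feature``: each column independently permuted across
    nodes.
    """
    rng = np.random.default_rng(seed)
    f = np.atleast_2d(np.asarray(features, dtype=float))
    if mode == "target_average":
        if targets_train_mean is None:
            raise ValueError("target_average needs the training-target mean")
        return np.full_like(f, float(targets_train_mean))
    if mode == "random_uniform":
        return rng.uniform(0, 1, size=f.shape)
    if mode == "shuffle_per_feature":
        out = f.copy()
        for c in range(f.shape[1]):
            out[:, c] = out[rng.permutation(f.shape[0]), c]
        return out
    raise ValueError(f"unknown ablation mode {mode!r}")


def report(result: CVResult) -> pd.DataFrame:
    """Summary table: per-model average MSE ± SD over runs and p-values."""
    rows = []
    for name in result.per_network_mse:
        t, p, sig = result.paired_tests.get(name, (np.nan, np.nan, False))
        rows.append(
            {
                "model": name,
                "avg_mse": result.average_mse(name),
                "sd_over_runs": result.mse_sd_over_runs(name)
                if result.n_runs[name] > 1
                else 0.0,
                "n_runs": result.n_runs[name],
                "t": t,
                "p": p,
                "significant": sig,
            }
        )
    df = pd.DataFrame(rows)
    best = df["avg_mse"].idxmin()
    df["best"] = False
    df.loc[best, "best"] = True
    return df
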