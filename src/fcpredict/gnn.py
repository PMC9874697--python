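"""Graph neural networks for node regression, in plain numpy.

Three layer families operate on functional-connectivity graphs:

* GCN — symmetric-normalized convolution ``X' = D̂^{-1/2} Â D̂^{-1/2} X Θ``
  with self-loops (Â = A + I, d̂_i = 1 + Σ_j e_ji) over the weighted
  undirected FC graph.
* GraphSAGE — ``x'_i = Θ_bias x_i + Θ · AGG_{j∈N(i)}(e_ji x_j)`` with mean
  or elementwise-max pooling of edge-weighted neighbor features.
* RGCN — ``x'_i = Θ_bias x_i + Σ_r (1/|N_r(i)|) Σ_{j∈N_r(i)} Θ_r x_j`` over
  the two directed relations (excitatory, inhibitory); N_r(i) are the
  in-neighbors of i under relation r.

Each convolution is followed by dropout and ReLU; the outputs of all layers
are concatenated and passed through a linear head producing one scalar per
node.  Training minimizes node-wise MSE with Adam, full-batch over all
training graphs (inductive: test graphs are never seen).  Gradients are
hand-derived; a finite-difference check lives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import RELATIONS, DirectedRelationalGraph, WeightedGraph

__all__ = [
    "GNNConfig",
    "GNNModel",
    "gcn_propagator",
    "sage_structures",
    "rgcn_propagators",
    "gcn_layer",
    "sage_layer",
    "rgcn_layer",
    "build_and_train_gnn",
]

FAMILIES = ("gcn", "sage-mean", "sage-max", "rgcn")


@dataclass
class GNNConfig:
    family: str = "sage-max"
    n_layers: int = 1
    hidden_dim: int = 16
    dropout: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 300
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not 1 <= self.n_layers <= 3:
            raise ValueError("n_layers must be in {1, 2, 3}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


# ---------------------------------------------------------------------------
# propagation structures (fixed per graph)
# ---------------------------------------------------------------------------

def gcn_propagator(adj: np.ndarray) -> np.ndarray:
    """Symmetric-normalized propagation matrix ``D̂^{-1/2} (A + I) D̂^{-1/2}``."""
    adj = np.asarray(adj, dtype=float)
    if adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T) or np.any(adj < 0):
        raise ValueError("GCN expects a symmetric, non-negative adjacency")
    a_hat = adj + np.eye(adj.shape[0])
    d = a_hat.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def sage_structures(adj: np.ndarray) -> dict:
    """Neighbor mask, edge weights, and row-mean matrix for SAGE pooling."""
    adj = np.asarray(adj, dtype=float)
    mask = adj > 0
    deg = mask.sum(axis=1)
    mean_mat = np.where(mask, adj, 0.0) / np.maximum(deg, 1)[:, None]
    mean_mat[deg == 0] = 0.0  # empty neighborhood -> zero aggregate
    return {"adj": adj, "mask": mask, "mean": mean_mat, "deg": deg}


def rgcn_propagators(graph: DirectedRelationalGraph) -> dict:
    """Per-relation in-neighbor mean matrices P_r with P_r[i, j] = 1/|N_r(i)|
    for each edge j -> i."""
    out = {}
    for r in RELATIONS:
        a_in = graph.adjacency[r].T.astype(float)  # row i lists in-neighbors
        deg = a_in.sum(axis=1)
        p = a_in / np.maximum(deg, 1)[:, None]
        p[deg == 0] = 0.0
        out[r] = p
    return out


# ---------------------------------------------------------------------------
# single layers (forward only; used directly and inside the model)
# ---------------------------------------------------------------------------

def gcn_layer(x: np.ndarray, adj: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """One GCN convolution over a weighted symmetric adjacency."""
    return gcn_propagator(adj) @ x @ theta


def sage_layer(
    x: np.ndarray,
    adj: np.ndarray,
    theta: np.ndarray,
    theta_bias: np.ndarray,
    pooling: str = "max",
) -> np.ndarray:
    """One GraphSAGE convolution (mean or elementwise max pooling)."""
    if pooling not in ("mean", "max"):
        raise ValueError(f"unknown pooling {pooling!r}")
    st = sage_structures(adj)
    if pooling == "mean":
        m = st["mean"] @ x
    else:
        m, _ = _max_aggregate(st["adj"], st["mask"], x)
    return x @ theta_bias + m @ theta


def rgcn_layer(
    x: np.ndarray,
    graph: DirectedRelationalGraph,
    theta_bias: np.ndarray,
    theta_r: dict,
) -> np.ndarray:
    """One RGCN convolution over the two binary relations."""
    props = rgcn_propagators(graph)
    out = x @ theta_bias
    for r in RELATIONS:
        out = out + props[r] @ x @ theta_r[r]
    return out


def _max_aggregate(adj: np.ndarray, mask: np.ndarray, x: np.ndarray):
    """Elementwise max over neighbors of e_ji * x_j; empty -> 0.

    Returns the aggregate and the argmax neighbor index per (node, feature)
    (−1 where the neighborhood is empty), used to route gradients.
    """
    n, f = x.shape[0], x.shape[1]
    scored = adj[:, :, None] * x[None, :, :]  # (target i, neighbor j, feat)
    scored = np.where(mask[:, :, None], scored, -np.inf)
    arg = np.argmax(scored, axis=1)  # (n, f)
    agg = np.take_along_axis(scored, arg[:, None, :], axis=1)[:, 0, :]
    empty = ~mask.any(axis=1)
    agg[empty] = 0.0
    arg[empty] = -1
    return agg, arg


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

@dataclass
class _GraphData:
    """Preprocessed per-graph structures the model consumes."""

    x: np.ndarray  # (n, in_dim) scaled node features
    y: np.ndarray | None  # (n,) scaled targets (None at pure predict time)
    structures: dict


def _prepare_graph(graph, x: np.ndarray, y: np.ndarray | None, family: str) -> _GraphData:
    if family == "rgcn":
        if not isinstance(graph, DirectedRelationalGraph):
            raise TypeError("rgcn needs a DirectedRelationalGraph")
        st = {"props": rgcn_propagators(graph)}
    else:
        if isinstance(graph, WeightedGraph):
            adj = graph.weights
        else:
            adj = np.asarray(graph, dtype=float)
        if family == "gcn":
            st = {"prop": gcn_propagator(adj)}
        else:
            st = sage_structures(adj)
    n = x.shape[0]
    if graph is not None and hasattr(graph, "n_nodes") and graph.n_nodes != n:
        raise ValueError("graph nodes must align with feature rows")
    return _GraphData(x=np.asarray(x, float), y=None if y is None else np.asarray(y, float), structures=st)


class GNNModel:
    """A stack of graph convolutions with dropout/ReLU, concatenated
    embeddings, and a linear head; trained with Adam on node-wise MSE."""

    def __init__(self, in_dim: int, config: GNNConfig):
        self.config = config
        self.in_dim = in_dim
        rng = np.random.default_rng(config.seed)
        h = config.hidden_dim
        self.layers = []
        d = in_dim
        for _ in range(config.n_layers):
            layer = {"theta": _glorot(rng, d, h)}
            if config.family in ("sage-mean", "sage-max"):
                layer["theta_bias"] = _glorot(rng, d, h)
            elif config.family == "rgcn":
                layer["theta_bias"] = _glorot(rng, d, h)
                for r in RELATIONS:
                    layer[f"theta_{r}"] = _glorot(rng, d, h)
            self.layers.append(layer)
            d = h
        self.head_w = _glorot(rng, config.n_layers * h, 1)
        self.head_b = np.zeros(1)
        self._rng = rng
        self._adam = None

    # -- forward ---------------------------------------------------------
    def _conv(self, layer: dict, x: np.ndarray, st: dict):
        fam = self.config.family
        cache = {"x": x}
        if fam == "gcn":
            sx = st["prop"] @ x
            z = sx @ layer["theta"]
            cache["sx"] = sx
        elif fam == "sage-mean":
            m = st["mean"] @ x
            z = x @ layer["theta_bias"] + m @ layer["theta"]
            cache["m"] = m
        elif fam == "sage-max":
            m, arg = _max_aggregate(st["adj"], st["mask"], x)
            z = x @ layer["theta_bias"] + m @ layer["theta"]
            cache["m"], cache["arg"] = m, arg
        else:  # rgcn
            z = x @ layer["theta_bias"]
            for r in RELATIONS:
                px = st["props"][r] @ x
                z = z + px @ layer[f"theta_{r}"]
                cache[f"px_{r}"] = px
        return z, cache

    def _conv_backward(self, layer: dict, st: dict, cache: dict, dz: np.ndarray, grads: dict):
        fam = self.config.family
        x = cache["x"]
        if fam == "gcn":
            grads["theta"] += cache["sx"].T @ dz
            dx = st["prop"].T @ (dz @ layer["theta"].T)
        elif fam == "sage-mean":
            grads["theta"] += cache["m"].T @ dz
            grads["theta_bias"] += x.T @ dz
            dx = dz @ layer["theta_bias"].T + st["mean"].T @ (dz @ layer["theta"].T)
        elif fam == "sage-max":
            grads["theta"] += cache["m"].T @ dz
            grads["theta_bias"] += x.T @ dz
            dx = dz @ layer["theta_bias"].T
            dm = dz @ layer["theta"].T  # (n, in_dim of m)
            arg = cache["arg"]
            adj = st["adj"]
            n, f = dm.shape
            # route each (i, k) gradient to neighbor j = arg[i, k], scaled by e_ji
            valid = arg >= 0
            ii, kk = np.nonzero(valid)
            jj = arg[ii, kk]
            np.add.at(dx, (jj, kk), adj[ii, jj] * dm[ii, kk])
        else:  # rgcn
            grads["theta_bias"] += x.T @ dz
            dx = dz @ layer["theta_bias"].T
            for r in RELATIONS:
                grads[f"theta_{r}"] += cache[f"px_{r}"].T @ dz
                dx = dx + st["props"][r].T @ (dz @ layer[f"theta_{r}"].T)
        return dx

    def _forward(self, g: _GraphData, train_mode: bool):
        """Returns per-node predictions and the caches needed for backprop."""
        x = g.x
        embeds, caches = [], []
        p = self.config.dropout
        for layer in self.layers:
            z, cache = self._conv(layer, x, g.structures)
            if train_mode and p > 0:
                mask = (self._rng.random(z.shape) >= p) / (1.0 - p)
            else:
                mask = np.ones_like(z)
            zd = z * mask
            a = np.maximum(zd, 0.0)
            cache.update({"z": z, "mask": mask, "zd": zd})
            caches.append(cache)
            embeds.append(a)
            x = a
        concat = np.concatenate(embeds, axis=1)
        pred = (concat @ self.head_w + self.head_b).ravel()
        return pred, {"concat": concat, "caches": caches, "embeds": embeds}

    def predict(self, graph, x: np.ndarray) -> np.ndarray:
        g = _prepare_graph(graph, x, None, self.config.family)
        pred, _ = self._forward(g, train_mode=False)
        return pred

    # -- training --------------------------------------------------------
    def _param_items(self):
        for li, layer in enumerate(self.layers):
            for name, val in layer.items():
                yield f"l{li}.{name}", layer, name, val
        yield "head_w", self.__dict__, "head_w", self.head_w
        yield "head_b", self.__dict__, "head_b", self.head_b

    def loss_and_grads(self, graphs: list[_GraphData], train_mode: bool = True):
        """Full-batch MSE over all nodes of all graphs, with gradients."""
        grads = {key: np.zeros_like(val) for key, _, _, val in self._param_items()}
        total_loss, total_n = 0.0, 0
        per_graph = []
        for g in graphs:
            pred, fwd = self._forward(g, train_mode)
            per_graph.append((pred, fwd, g))
            total_n += pred.size
        for pred, fwd, g in per_graph:
            err = pred - g.y
            total_loss += float(np.sum(err**2))
            dpred = (2.0 / total_n) * err
            # head
            grads["head_w"] += fwd["concat"].T @ dpred[:, None]
            grads["head_b"] += dpred.sum(keepdims=True)
            dconcat = dpred[:, None] @ self.head_w.T
            h = self.config.hidden_dim
            # split concat gradient per layer; add the path through deeper layers
            dembeds = [
                dconcat[:, i * h : (i + 1) * h] for i in range(self.config.n_layers)
            ]
            dnext = np.zeros_like(dembeds[-1])
            for li in range(self.config.n_layers - 1, -1, -1):
                cache = fwd["caches"][li]
                da = dembeds[li] + dnext
                dzd = da * (cache["zd"] > 0)
                dz = dzd * cache["mask"]
                layer_grads = {}
                for name in self.layers[li]:
                    layer_grads[name] = grads[f"l{li}.{name}"]
                dx = self._conv_backward(self.layers[li], g.structures, cache, dz, layer_grads)
                dnext = dx if li > 0 else None
        loss = total_loss / total_n
        if self.config.weight_decay > 0:
            for key, _, _, val in self._param_items():
                loss += self.config.weight_decay * float(np.sum(val**2))
                grads[key] += 2 * self.config.weight_decay * val
        return loss, grads

    def fit(self, graphs_xy: list) -> list:
        """Train on a list of ``(graph, X, y)`` triples; returns the loss curve."""
        cfg = self.config
        graphs = [_prepare_graph(g, x, y, cfg.family) for g, x, y in graphs_xy]
        m = {k: np.zeros_like(v) for k, _, _, v in self._param_items()}
        v = {k: np.zeros_like(val) for k, _, _, val in self._param_items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        curve = []
        for t in range(1, cfg.epochs + 1):
            loss, grads = self.loss_and_grads(graphs, train_mode=True)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (NaN loss) with {cfg}")
            curve.append(loss)
            for key, holder, name, val in self._param_items():
                g = grads[key]
                m[key] = b1 * m[key] + (1 - b1) * g
                v[key] = b2 * v[key] + (1 - b2) * g**2
                mh = m[key] / (1 - b1**t)
                vh = v[key] / (1 - b2**t)
                holder[name] = val - cfg.learning_rate * mh / (np.sqrt(vh) + eps)
        return curve


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def build_and_train_gnn(
    graphs_xy: list, config: GNNConfig
) -> tuple[GNNModel, list]:
    """Build a model sized to the features and train it full-batch.

    ``graphs_xy`` is a list of ``(graph, X, y)`` training triples (graphs may
    be ``WeightedGraph``, ``DirectedRelationalGraph`` or raw adjacency
    matrices, matching the configured family).
    """
    in_dim = graphs_xy[0][1].shape[1]
    model = GNNModel(in_dim, config)
    curve = model.fit(graphs_xy)
    return model, curve


def save_model(model: GNNModel, path) -> None:
    """Checkpoint a trained model as JSON (config + parameter arrays)."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    state = {
        "config": asdict(model.config),
        "in_dim": model.in_dim,
        "layers": [{k: v.tolist() for k, v in layer.items()}
                   for layer in model.layers],
        "head_w": model.head_w.tolist(),
        "head_b": model.head_b.tolist(),
    }
    Path(path).write_text(json.dumps(state))


def load_model(path) -> GNNModel:
    """Restore a checkpoint written by :func:`save_model`."""
    import json
    from pathlib import Path

    state = json.loads(Path(path).read_text())
    model = GNNModel(state["in_dim"], GNNConfig(**state["config"]))
    model.layers = [{k: np.asarray(v) for k, v in layer.items()}
                    for layer in state["layers"]]
    model.head_w = np.asarray(state["head_w"])
    model.head_b = np.asarray(state["head_b"])
    return model
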