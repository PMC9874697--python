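"""On-disk formats: study directories, graphs, feature tables, configs.

A study directory holds one sub-directory per network with spike times and
cluster labels (NPY), footprint stacks (NPY), electrode coordinates (CSV),
ground truth (JSON) and a YAML manifest tying everything together.  Graphs
are written as GraphML plus a plain edge-list CSV.  Every writer records the
seed and a config hash in the manifest for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .types import (
    RELATIONS,
    DirectedRelationalGraph,
    GroundTruthNetwork,
    SpikeTrain,
    StudyDataset,
    StudyNetwork,
    UnitFootprint,
    WeightedGraph,
)

__all__ = [
    "PipelineConfig",
    "write_study",
    "read_study",
    "write_graph",
    "read_graph_csv",
    "write_feature_table",
]


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults, YAML round-trippable."""

    seed: int = 0
    pcc_bin_ms: float = 20.0
    sttc_dt_ms: float = 10.0
    cch_bin_ms: float = 1.0
    cch_half_window_ms: float = 25.0
    n_surrogates: int = 100
    gamma_list: tuple = (0.0, 0.5, 1.0, 1.5, 2.0)
    rate_bounds: tuple = (0.05, 30.0)
    max_violation: float = 0.3
    min_r_square: float = 0.8
    min_nodes: int = 30
    task: str = "maximum"
    immediate_statistic: str = "max"
    n_runs: int = 30
    gnn: dict = field(
        default_factory=lambda: {
            "family": "sage-max",
            "n_layers": 1,
            "hidden_dim": 16,
            "dropout": 0.2,
            "learning_rate": 1e-3,
            "epochs": 300,
        }
    )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self._plain()))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("gamma_list", "rate_bounds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def _plain(self) -> dict:
        d = asdict(self)
        d["gamma_list"] = list(self.gamma_list)
        d["rate_bounds"] = list(self.rate_bounds)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self._plain(), sort_keys=True).encode()
        ).hexdigest()[:12]


def write_study(study: StudyDataset, path) -> None:
    """Write a study directory (NPY arrays, CSV tables, JSON truth, YAML
    manifest)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": study.seed,
        "n_baseline": study.n_baseline,
        "n_perturbation": study.n_perturbation,
        "networks": [],
    }
    for nw in study.networks:
        nid = nw.truth.network_id
        d = root / nid
        d.mkdir(exist_ok=True)
        rows = []
        for t_idx, rec in enumerate(nw.recordings):
            for tr in rec:
                rows.append((t_idx, tr.unit_id, tr.spike_times, tr.duration))
        times = np.concatenate([r[2] for r in rows]) if rows else np.empty(0)
        labels = np.concatenate(
            [np.full(r[2].size, r[1], dtype=np.int64) for r in rows]
        ) if rows else np.empty(0, dtype=np.int64)
        tps = np.concatenate(
            [np.full(r[2].size, r[0], dtype=np.int64) for r in rows]
        ) if rows else np.empty(0, dtype=np.int64)
        np.save(d / "spike_times.npy", times)
        np.save(d / "cluster_labels.npy", labels)
        np.save(d / "timepoints.npy", tps)
        durations = {str(t_idx): rec[0].duration for t_idx, rec in enumerate(nw.recordings)}
        truth = {
            "n_neurons": nw.truth.n_neurons,
            "neuron_sign": nw.truth.neuron_sign.tolist(),
            "adjacency": nw.truth.adjacency.tolist(),
            "delay": nw.truth.delay.tolist(),
            "chip_id": nw.truth.chip_id,
            "network_id": nid,
            "durations": durations,
        }
        if nw.true_response is not None:
            truth["true_response"] = np.asarray(nw.true_response).tolist()
        (d / "ground_truth.json").write_text(json.dumps(truth))
        pd.DataFrame(nw.truth.positions, columns=["x_um", "y_um"]).to_csv(
            d / "neuron_positions.csv", index=False
        )
        if nw.footprints is not None:
            np.save(d / "footprints.npy",
                    np.stack([fp.waveforms for fp in nw.footprints]))
            np.save(d / "footprint_electrodes.npy",
                    np.stack([fp.electrode_positions for fp in nw.footprints]))
            (d / "footprint_meta.json").write_text(json.dumps({
                "sampling_rate": nw.footprints[0].sampling_rate,
                "n_averaged": nw.footprints[0].n_averaged,
            }))
        manifest["networks"].append({"network_id": nid, "chip_id": nw.truth.chip_id})
    (root / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def read_study(path) -> StudyDataset:
    """Load a study directory written by :func:`write_study`."""
    root = Path(path)
    mf = root / "manifest.yaml"
    if not mf.exists():
        raise FileNotFoundError(f"study manifest not found: {mf}")
    manifest = yaml.safe_load(mf.read_text())
    networks = []
    for entry in manifest["networks"]:
        d = root / entry["network_id"]
        for fname in ("spike_times.npy", "cluster_labels.npy", "timepoints.npy",
                      "ground_truth.json", "neuron_positions.csv"):
            if not (d / fname).exists():
                raise FileNotFoundError(f"missing study file: {d / fname}")
        times = np.load(d / "spike_times.npy")
        labels = np.load(d / "cluster_labels.npy")
        tps = np.load(d / "timepoints.npy")
        truth_d = json.loads((d / "ground_truth.json").read_text())
        positions = pd.read_csv(d / "neuron_positions.csv")[["x_um", "y_um"]].to_numpy()
        truth = GroundTruthNetwork(
            n_neurons=truth_d["n_neurons"],
            neuron_sign=np.array(truth_d["neuron_sign"]),
            adjacency=np.array(truth_d["adjacency"]),
            delay=np.array(truth_d["delay"]),
            positions=positions,
            chip_id=truth_d["chip_id"],
            network_id=truth_d["network_id"],
        )
        n_tp = int(tps.max()) + 1 if tps.size else 0
        recordings = []
        for t_idx in range(n_tp):
            sel = tps == t_idx
            duration = truth_d["durations"][str(t_idx)]
            rec = []
            for u in range(truth.n_neurons):
                t = np.sort(times[sel & (labels == u)])
                rec.append(SpikeTrain(u, t, duration, truth.chip_id, truth.network_id))
            recordings.append(rec)
        footprints = None
        if (d / "footprints.npy").exists():
            waves = np.load(d / "footprints.npy")
            elec = np.load(d / "footprint_electrodes.npy")
            meta = json.loads((d / "footprint_meta.json").read_text())
            footprints = [
                UnitFootprint(u, waves[u], elec[u], meta["sampling_rate"],
                              meta["n_averaged"])
                for u in range(waves.shape[0])
            ]
        resp = truth_d.get("true_response")
        networks.append(
            StudyNetwork(
                truth=truth,
                recordings=recordings,
                footprints=footprints,
                true_response=None if resp is None else np.array(resp),
            )
        )
    return StudyDataset(
        networks=networks,
        n_baseline=manifest["n_baseline"],
        n_perturbation=manifest["n_perturbation"],
        seed=manifest["seed"],
    )


def write_graph(graph, path_prefix) -> None:
    """Write a graph as GraphML plus an edge-list CSV (source, target,
    weight, relation)."""
    prefix = Path(path_prefix)
    rows = []
    if isinstance(graph, WeightedGraph):
        G = nx.Graph()
        G.add_nodes_from(int(u) for u in graph.node_ids)
        ii, jj = np.nonzero(np.triu(graph.weights, 1))
        for a, b in zip(ii, jj):
            u, v = int(graph.node_ids[a]), int(graph.node_ids[b])
            w = float(graph.weights[a, b])
            G.add_edge(u, v, weight=w)
            rows.append((u, v, w, "undirected"))
    elif isinstance(graph, DirectedRelationalGraph):
        G = nx.DiGraph()
        G.add_nodes_from(int(u) for u in graph.node_ids)
        for r in RELATIONS:
            ii, jj = np.nonzero(graph.adjacency[r])
            for a, b in zip(ii, jj):
                u, v = int(graph.node_ids[a]), int(graph.node_ids[b])
                G.add_edge(u, v, relation=r)
                rows.append((u, v, 1.0, r))
    else:
        raise TypeError(f"unsupported graph type {type(graph).__name__}")
    nx.write_graphml(G, prefix.with_suffix(".graphml"))
    pd.DataFrame(rows, columns=["source", "target", "weight", "relation"]).to_csv(
        prefix.with_suffix(".csv"), index=False
    )


def read_graph_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_feature_table(features: list, path) -> None:
    """Feature vectors as CSV: unit_id plus the seven named columns."""
    rows = [{"unit_id": fv.unit_id, **fv.as_dict()} for fv in features]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_qc_report(report, path) -> None:
    """QC drop counts as JSON (one rule per key)."""
    Path(path).write_text(json.dumps(report.as_dict(), indent=2))


def write_metrics_table(rows: list, path) -> None:
    """Network metrics as CSV keyed by network_id.

    ``rows`` is a list of dicts, each containing at least ``network_id``.
    """
    pd.DataFrame(rows).to_csv(path, index=False)


def write_targets_table(targets_list: list, path) -> None:
    """Fold-change targets as CSV (unit_id, network_id, task, delta_fch_prime)."""
    rows = []
    for t in targets_list:
        for u, v in zip(t.unit_ids, t.delta_fch_prime):
            rows.append({"unit_id": int(u), "network_id": t.network_id,
                         "task": t.task, "delta_fch_prime": float(v)})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_results_table(result, path, fc_type: str = "", task: str = "") -> None:
    """Long-format CV results as CSV (model, fc_type, task, network_id, run, mse)."""
    rows = []
    for model, per_net in result.per_network_mse.items():
        for network_id, per_run in per_net.items():
            for run, mse in enumerate(per_run):
                rows.append({"model": model, "fc_type": fc_type, "task": task,
                             "network_id": network_id, "run": run,
                             "mse": float(mse)})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_provenance(path_prefix, config: PipelineConfig, seed: int) -> None:
    """Sidecar JSON recording the config hash and seed next to an output."""
    Path(str(path_prefix) + ".provenance.json").write_text(
        json.dumps({"config_digest": config.digest(), "seed": int(seed)})
    )
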