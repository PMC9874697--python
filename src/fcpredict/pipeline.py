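"""High-level glue: from a study to prediction-ready network data.

These helpers chain the stage modules the way the full analysis does:
targets from the recordings, node features either from the generator's
ground truth or from the QC/feature-extraction pipeline, and a graph either
from the planted coupling structure or inferred from the baseline trains.
"""

from __future__ import annotations

import numpy as np

from . import connectivity, features as feat, targets as tg
from .evaluate import NetworkData
from .synth import true_coupling_graph, true_feature_matrix
from .types import StudyDataset

__all__ = ["prepare_networks", "edge_recovery_scores", "edge_recovery_auc"]


def prepare_networks(
    study: StudyDataset,
    task: str = "maximum",
    feature_source: str = "true",
    graph_source: str = "true",
    pcc_seed: int = 0,
    n_surrogates: int = 100,
) -> list:
    """Build :class:`~fcpredict.evaluate.NetworkData` per study network.

    ``feature_source``: "true" uses the generator's ground-truth feature
    matrix; "measured" runs QC + feature extraction on the baseline trains
    and footprints (slower; units failing QC are dropped from the task).
    ``graph_source``: "true" uses the planted coupling graph; "pcc" infers
    a surrogate-corrected PCC graph from the combined baseline trains.
    """
    out = []
    for k, nw in enumerate(study.networks):
        series = tg.rate_series(nw, n_baseline=study.n_baseline)
        unit_ids, dfp = tg.neuron_fold_change(series, task)
        id_to_target = dict(zip(unit_ids.tolist(), dfp))

        if feature_source == "true":
            fmat = true_feature_matrix(
                nw.template_params, nw.template_params["burst_participation"]
            )
            ids = np.array([tr.unit_id for tr in nw.recordings[0]])
        elif feature_source == "measured":
            units = list(zip(nw.recordings[0], nw.footprints))
            fvs, _ = feat.qc_and_featurize(units)
            ids = np.array([fv.unit_id for fv in fvs])
            fmat = np.vstack([fv.values for fv in fvs]) if fvs else np.empty((0, 7))
        else:
            raise ValueError(f"unknown feature_source {feature_source!r}")

        if graph_source == "true":
            graph = true_coupling_graph(nw.truth)
        elif graph_source == "pcc":
            graph = connectivity.surrogate_corrected_fc(
                nw.recordings[0], measure="PCC", n_surrogates=n_surrogates,
                seed=pcc_seed + k, drop_isolated=False,
            )
        else:
            raise ValueError(f"unknown graph_source {graph_source!r}")

        # align everything on units that have a target and a feature row
        keep = [i for i, u in enumerate(ids) if int(u) in id_to_target]
        ids_kept = ids[keep]
        fmat = fmat[keep]
        gpos = {int(u): i for i, u in enumerate(graph.node_ids)}
        gsel = [gpos[int(u)] for u in ids_kept if int(u) in gpos]
        gmask = [int(u) in gpos for u in ids_kept]
        ids_kept = ids_kept[gmask]
        fmat = fmat[gmask]
        sub = graph.weights[np.ix_(gsel, gsel)]
        graph = type(graph)(node_ids=ids_kept, weights=sub, measure=graph.measure)
        y = np.array([id_to_target[int(u)] for u in ids_kept])
        out.append(
            NetworkData(
                network_id=nw.truth.network_id,
                chip_id=nw.truth.chip_id,
                graph=graph,
                features=fmat,
                targets=y,
            )
        )
    return out


def edge_recovery_scores(trains: list, positions: np.ndarray) -> np.ndarray:
    """|normalized CCH peak| score per ordered pair (velocity-filtered;
    unlabeled or filtered pairs score 0).  Used to quantify how well the
    directed inference separates planted edges from non-edges."""
    n = len(trains)
    scores = np.zeros((n, n))
    for i, j, _, peak in connectivity.label_pairs(trains, positions):
        scores[i, j] = abs(peak)
    return scores


def edge_recovery_auc(trains: list, truth_adjacency: np.ndarray,
                      positions: np.ndarray) -> float:
    """ROC AUC of CCH pair scores against the planted directed edges."""
    from sklearn.metrics import roc_auc_score

    n = len(trains)
    scores = edge_recovery_scores(trains, positions)
    mask = ~np.eye(n, dtype=bool)
    y_true = (np.asarray(truth_adjacency) != 0)[mask].astype(int)
    if y_true.sum() == 0 or y_true.sum() == y_true.size:
        raise ValueError("AUC undefined: need both edges and non-edges")
    return float(roc_auc_score(y_true, scores[mask]))
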