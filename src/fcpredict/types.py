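"""Core data containers shared across the pipeline.

The pipeline moves from spike-sorted units (``SpikeTrain`` + ``UnitFootprint``)
through per-unit feature vectors, inferred functional-connectivity graphs
(``WeightedGraph`` for PCC/STTC, ``DirectedRelationalGraph`` for the
CCH-derived excitatory/inhibitory relations), perturbation fold-change
targets, and finally cross-validated prediction results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SpikeTrain",
    "UnitFootprint",
    "WaveformFeatures",
    "ACGFit",
    "FiringPatternFeatures",
    "NeuronFeatureVector",
    "GroundTruthNetwork",
    "StudyNetwork",
    "StudyDataset",
    "PlantedResponseModel",
    "WeightedGraph",
    "DirectedRelationalGraph",
    "NormalizedCCH",
    "FoldChangeTargets",
    "CVSplit",
]


@dataclass
class SpikeTrain:
    """Spike times of one sorted unit within one recording.

    Times are in seconds, sorted ascending, all within ``[0, duration)``.
    """

    unit_id: int
    spike_times: np.ndarray
    duration: float
    chip_id: str = ""
    network_id: str = ""

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) < 0):
                raise ValueError(f"unit {self.unit_id}: spike times must be sorted")
            if self.spike_times[0] < 0 or self.spike_times[-1] >= self.duration:
                raise ValueError(
                    f"unit {self.unit_id}: spike times outside [0, duration)"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def rate(self) -> float:
        return self.n_spikes / self.duration


@dataclass
class UnitFootprint:
    """Averaged extracellular waveforms of one unit across electrodes.

    ``waveforms`` has one row per electrode (µV); ``electrode_positions``
    are (x, y) in µm.
    """

    unit_id: int
    waveforms: np.ndarray
    electrode_positions: np.ndarray
    sampling_rate: float
    n_averaged: int = 0

    def __post_init__(self) -> None:
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
        self.electrode_positions = np.atleast_2d(
            np.asarray(self.electrode_positions, dtype=float)
        )
        if self.waveforms.shape[0] != self.electrode_positions.shape[0]:
            raise ValueError("one position per electrode row required")


@dataclass
class WaveformFeatures:
    peak_to_trough: float  # ms
    trough_to_peak: float  # ms
    ab_ratio: float  # (B - A) / (B + A), in [-1, 1]
    half_width: float  # ms
    peak_electrode_id: int = -1


@dataclass
class ACGFit:
    c: float
    d: float
    h: float
    tau_decay: float  # ms
    tau_rise: float  # ms
    tau_burst: float  # ms
    rate_asymptote: float
    t_refrac: float  # ms
    r_square: float


@dataclass
class FiringPatternFeatures:
    burstiness: float  # fraction of ISIs < 6 ms
    tau_rise: float  # ms
    tau_decay: float  # ms


FEATURE_NAMES = (
    "peak_to_trough",
    "trough_to_peak",
    "ab_ratio",
    "half_width",
    "burstiness",
    "tau_decay",
    "tau_rise",
)


@dataclass
class NeuronFeatureVector:
    """The 7-entry single-neuron feature vector used as GNN node features."""

    unit_id: int
    values: np.ndarray  # aligned with FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (7,):
            raise ValueError("feature vector must have exactly 7 entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector has non-finite entries")

    def as_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, self.values.tolist()))


@dataclass
class GroundTruthNetwork:
    """Planted connectivity of one synthetic network.

    ``adjacency[i, j]`` is the signed coupling gain of the directed edge
    i -> j (positive for excitatory sources, negative for inhibitory ones;
    Dale-consistent by construction).  ``delay[i, j]`` is the synaptic
    delay in ms, drawn in [2, 10] for true edges.
    """

    n_neurons: int
    neuron_sign: np.ndarray  # +1 excitatory / -1 inhibitory
    adjacency: np.ndarray
    delay: np.ndarray
    positions: np.ndarray  # (n, 2) µm
    chip_id: str = ""
    network_id: str = ""

    def __post_init__(self) -> None:
        n = self.n_neurons
        self.neuron_sign = np.asarray(self.neuron_sign, dtype=int)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.delay = np.asarray(self.delay, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.adjacency.shape != (n, n) or self.delay.shape != (n, n):
            raise ValueError("adjacency/delay must be n x n")
        if self.positions.shape != (n, 2):
            raise ValueError("positions must be (n, 2)")

    @property
    def edge_mask(self) -> np.ndarray:
        return self.adjacency != 0


@dataclass
class PlantedResponseModel:
    """How planted per-neuron perturbation responses are built from features.

    The planted response of neuron i is
    ``phi_i + neighbor_weight * max_j(w_ij * phi_j) + noise`` over the
    coupling graph (a strongest-neighbor drive).  The own-feature term
    ``phi_i`` is LINEAR in the standardized true features (score
    ``feature_weights . z_i``, shifted and scaled so that roughly
    ``decrease_fraction`` of neurons respond negatively and the mean
    response is ``mean_response``); the heavy positive tail comes from the
    heavy-tailed burst-participation feature the default weights emphasize.
    Keeping phi linear matters: it makes the own-feature part of the signal
    fully learnable by a linear model, so any advantage of a graph model
    must come from the neighborhood term.
    """

    feature_weights: np.ndarray = field(
        default_factory=lambda: np.array([0.15, 0.1, 0.05, 0.1, 1.0, 0.0, 0.0])
    )
    neighbor_weight: float = 0.0
    noise_sd: float = 0.0
    decrease_fraction: float = 0.09
    mean_response: float = 5.9

    def __post_init__(self) -> None:
        self.feature_weights = np.asarray(self.feature_weights, dtype=float)
        if not 0.0 <= self.decrease_fraction < 0.5:
            raise ValueError("decrease_fraction must be in [0, 0.5)")


@dataclass
class StudyNetwork:
    """One synthetic network with its recordings and ground truth."""

    truth: GroundTruthNetwork
    recordings: list  # list over timepoints; each a list[SpikeTrain]
    footprints: Optional[list] = None  # list[UnitFootprint]
    true_response: Optional[np.ndarray] = None  # planted per-neuron Δfch'
    template_params: Optional[dict] = None


@dataclass
class StudyDataset:
    networks: list  # list[StudyNetwork]
    n_baseline: int = 2
    n_perturbation: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        chips = {nw.truth.chip_id for nw in self.networks}
        if self.networks and len(chips) < 2:
            raise ValueError("a study needs networks from at least 2 chips")

    @property
    def timepoint_labels(self) -> list:
        return [f"baseline_{i}" for i in range(self.n_baseline)] + [
            f"perturbation_{i}" for i in range(self.n_perturbation)
        ]


@dataclass
class WeightedGraph:
    """Undirected, surrogate-corrected FC graph (PCC or STTC).

    ``weights`` is symmetric, non-negative, zero-diagonal; node i of the
    matrix corresponds to ``node_ids[i]``.
    """

    node_ids: np.ndarray
    weights: np.ndarray
    measure: str = "PCC"

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.node_ids.size
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square over node_ids")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("no self-edges allowed")

    @property
    def n_nodes(self) -> int:
        return int(self.node_ids.size)

    def degree_strength(self) -> np.ndarray:
        return self.weights.sum(axis=0)


RELATIONS = ("excitatory", "inhibitory")


@dataclass
class DirectedRelationalGraph:
    """Directed binary graph with excitatory and inhibitory relations.

    ``adjacency[r][i, j] = 1`` means a directed edge i -> j of relation r.
    After Dale's-law enforcement every node's out-edges share one relation,
    and no ordered pair carries both relations.
    """

    node_ids: np.ndarray
    adjacency: dict  # relation name -> (n, n) {0,1} array
    gamma: float = 1.0

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids)
        n = self.node_ids.size
        for r in RELATIONS:
            if r not in self.adjacency:
                self.adjacency[r] = np.zeros((n, n), dtype=int)
            a = np.asarray(self.adjacency[r], dtype=int)
            if a.shape != (n, n):
                raise ValueError(f"{r} adjacency must be square over node_ids")
            self.adjacency[r] = a
        both = self.adjacency["excitatory"] & self.adjacency["inhibitory"]
        if np.any(both):
            raise ValueError("an ordered pair cannot carry both relations")

    @property
    def n_nodes(self) -> int:
        return int(self.node_ids.size)

    def union(self) -> np.ndarray:
        return (self.adjacency["excitatory"] | self.adjacency["inhibitory"]).astype(int)

    def n_edges(self) -> int:
        return int(self.union().sum())


@dataclass
class NormalizedCCH:
    """Cross-correlogram of an ordered pair with postsynaptic normalization."""

    lags_ms: np.ndarray  # bin left edges, ms
    raw: np.ndarray  # counts per bin over the full ±window
    normalized: np.ndarray  # mean-subtracted positive-lag (postsynaptic) bins
    peak_lag: float  # ms (centre of the peak bin)
    peak_value: float  # signed normalized value at the |max| bin
    label: str  # "excitatory" | "inhibitory" | "none"


@dataclass
class FoldChangeTargets:
    """Network (Δfch) and per-neuron (Δfch') fold-change targets."""

    network_id: str
    task: str  # "immediate" | "maximum"
    delta_fch: float
    unit_ids: np.ndarray
    delta_fch_prime: np.ndarray

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids)
        self.delta_fch_prime = np.asarray(self.delta_fch_prime, dtype=float)
        if self.delta_fch < 0:
            raise ValueError("Δfch is a ratio of non-negative rates")
        if np.any(self.delta_fch_prime < -1):
            raise ValueError("Δfch' cannot be below -1")


@dataclass
class CVSplit:
    """One leave-one-network-out split with same-chip exclusion."""

    test_network_id: str
    train_network_ids: list
    excluded_same_chip_ids: list
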