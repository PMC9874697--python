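"""Perturbation-induced firing-rate fold changes.

The network-level fold change is ``Δfch = max perturbation population rate /
baseline population rate``.  The per-neuron differential fold change is
``Δfch' = (max FR − baseline FR) / baseline FR``, where the max is taken
either over the first two perturbation timepoints ("immediate" task) or over
the whole perturbation window ("maximum" task).  The differential form keeps
neurons that *decrease* their rates visible (Δfch' < 0, bounded below by −1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import FoldChangeTargets, StudyNetwork

__all__ = [
    "PerturbationSeries",
    "rate_series",
    "network_fold_change",
    "neuron_fold_change",
    "fold_change_targets",
]


@dataclass
class PerturbationSeries:
    """Per-unit firing rates at one combined baseline + K perturbation
    timepoints, plus the per-timepoint population (summed) rate."""

    unit_ids: np.ndarray
    baseline_rate: np.ndarray  # (n_units,), Hz, over the combined baseline
    perturbation_rates: np.ndarray  # (n_units, K), Hz
    network_id: str = ""

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids)
        self.baseline_rate = np.asarray(self.baseline_rate, dtype=float)
        self.perturbation_rates = np.atleast_2d(
            np.asarray(self.perturbation_rates, dtype=float)
        )
        if np.any(self.baseline_rate < 0) or np.any(self.perturbation_rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def population_baseline(self) -> float:
        return float(self.baseline_rate.sum())

    @property
    def population_perturbation(self) -> np.ndarray:
        return self.perturbation_rates.sum(axis=0)


def rate_series(network: StudyNetwork, n_baseline: int = 2) -> PerturbationSeries:
    """Build a rate series from a study network's recordings.

    The first ``n_baseline`` recordings are pooled into one combined
    baseline window; each later recording is one perturbation timepoint.
    """
    recs = network.recordings
    if len(recs) <= n_baseline:
        raise ValueError("no perturbation recordings present")
    unit_ids = np.array([tr.unit_id for tr in recs[0]])
    base_t = sum(recs[k][0].duration for k in range(n_baseline))
    base_counts = np.zeros(unit_ids.size)
    for k in range(n_baseline):
        base_counts += np.array([tr.n_spikes for tr in recs[k]], dtype=float)
    pert = np.column_stack(
        [
            np.array([tr.n_spikes / tr.duration for tr in recs[k]], dtype=float)
            for k in range(n_baseline, len(recs))
        ]
    )
    return PerturbationSeries(
        unit_ids=unit_ids,
        baseline_rate=base_counts / base_t,
        perturbation_rates=pert,
        network_id=network.truth.network_id,
    )


def network_fold_change(series: PerturbationSeries) -> float:
    """Δfch: max perturbation population rate over baseline population rate."""
    base = series.population_baseline
    if base <= 0:
        raise ValueError("zero baseline population rate: Δfch undefined")
    return float(series.population_perturbation.max() / base)


def neuron_fold_change(
    series: PerturbationSeries,
    task: str = "maximum",
    immediate_statistic: str = "max",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron Δfch' for one task window.

    task="immediate" summarises the first two perturbation timepoints
    (statistic "max" by default, "mean" optional); task="maximum" takes the
    max over all perturbation timepoints.  Neurons with zero baseline rate
    are dropped with a warning.  Returns ``(unit_ids, delta_fch_prime)``.
    """
    if task == "immediate":
        window = series.perturbation_rates[:, :2]
    elif task == "maximum":
        window = series.perturbation_rates
    else:
        raise ValueError(f"unknown task {task!r}")
    if task == "immediate" and immediate_statistic == "mean":
        peak = window.mean(axis=1)
    else:
        peak = window.max(axis=1)
    base = series.baseline_rate
    ok = base > 0
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} neurons with zero baseline rate dropped",
            stacklevel=2,
        )
    dfp = (peak[ok] - base[ok]) / base[ok]
    return series.unit_ids[ok], dfp


def fold_change_targets(
    series: PerturbationSeries, task: str = "maximum", **kwargs
) -> FoldChangeTargets:
    unit_ids, dfp = neuron_fold_change(series, task, **kwargs)
    return FoldChangeTargets(
        network_id=series.network_id,
        task=task,
        delta_fch=network_fold_change(series),
        unit_ids=unit_ids,
        delta_fch_prime=dfp,
    )
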