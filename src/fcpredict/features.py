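"""Quality control and single-neuron feature extraction.

Each sorted unit is reduced to seven features: four from the average
extracellular waveform at its peak electrode (peak-to-trough duration,
trough-to-peak duration, AB ratio, action-potential half width) and three
from its firing pattern (burstiness, and the rise/decay time constants of a
triple-exponential fit to the spike-train autocorrelogram).

QC removes units with firing rates outside [0.05, 30] Hz, refractory-period
violation ratios above 0.3, overly wide or asymmetric waveforms, and poor
ACG fits (r² < 0.8).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, optimize, signal

from .types import (
    ACGFit,
    NeuronFeatureVector,
    SpikeTrain,
    UnitFootprint,
    WaveformFeatures,
)

log = logging.getLogger(__name__)


class FeatureError(ValueError):
    """A feature is undefined for this unit (unit is excluded)."""


# ---------------------------------------------------------------------------
# firing rate and spike-train histograms
# ---------------------------------------------------------------------------

def firing_rate(train: SpikeTrain, window: tuple | None = None) -> float:
    """Mean firing rate in Hz, over the whole train or a ``[t0, t1]`` window."""
    if window is None:
        t0, t1 = 0.0, train.duration
    else:
        t0, t1 = window
        if not (0.0 <= t0 < t1 <= train.duration):
            raise ValueError(f"invalid window [{t0}, {t1}]")
    t = train.spike_times
    n = int(np.count_nonzero((t >= t0) & (t < t1)))
    return n / (t1 - t0)


def autocorrelogram(
    train: SpikeTrain, bin_ms: float = 1.0, half_window_ms: float = 50.0
) -> tuple[np.ndarray, np.ndarray]:
    """Spike-train autocorrelogram over ±half_window_ms.

    Returns ``(lags_ms, counts)`` where ``lags_ms`` are bin left edges and
    bin b covers ``[b, b + bin_ms)`` ms.  Counts are over ordered spike
    pairs; zero-lag self-pairs are excluded, so the histogram is symmetric.
    The outer edge is inclusive (|lag| <= half_window_ms falls in the last
    bin on each side).
    """
    n_side = int(round(half_window_ms / bin_ms))
    if abs(n_side * bin_ms - half_window_ms) > 1e-9:
        raise ValueError("bin_ms must divide half_window_ms")
    edges = np.arange(-n_side, n_side + 1) * bin_ms
    counts = np.zeros(2 * n_side, dtype=np.int64)
    t = train.spike_times * 1e3  # ms
    if t.size < 2:
        return edges[:-1], counts
    pos = _positive_lag_hist(t, bin_ms, n_side)
    counts[n_side:] = pos
    counts[:n_side] = pos[::-1]
    return edges[:-1], counts


def _positive_lag_hist(t_ms: np.ndarray, bin_ms: float, n_side: int) -> np.ndarray:
    """Histogram of positive lags t_j - t_i (j > i) up to n_side bins."""
    w = n_side * bin_ms
    pos = np.zeros(n_side, dtype=np.int64)
    n = t_ms.size
    # windowed double loop via searchsorted: for each spike, spikes within (0, w]
    hi = np.searchsorted(t_ms, t_ms + w, side="right")
    start = np.arange(n) + 1
    for i in range(n):
        if hi[i] <= start[i]:
            continue
        lags = t_ms[start[i] : hi[i]] - t_ms[i]
        lags = lags[lags > 0]  # identical spike times carry zero lag: excluded
        # 1e-9 ms slack so lags that are exact bin edges up to float error
        # land in the intended half-open bin
        idx = np.minimum((lags / bin_ms + 1e-9).astype(np.int64), n_side - 1)
        # inclusive outer edge: lag == w maps into the last bin by the min above
        np.add.at(pos, idx, 1)
    return pos


def refractory_violation_ratio(train: SpikeTrain) -> float:
    """ACG mass within ±2 ms over ACG mass within ±50 ms (0 if no pairs)."""
    lags, counts = autocorrelogram(train, bin_ms=1.0, half_window_ms=50.0)
    total = counts.sum()
    if total == 0:
        return 0.0
    centre = counts[(lags >= -2.0) & (lags < 2.0)].sum()
    return float(centre / total)


def isi_histogram(
    train: SpikeTrain, bin_ms: float = 1.0, n_bins: int = 100
) -> np.ndarray:
    """Histogram of consecutive inter-spike intervals; ISIs >= 100 ms ignored."""
    t = train.spike_times
    counts = np.zeros(n_bins, dtype=np.int64)
    if t.size < 2:
        return counts
    isis = np.diff(t) * 1e3
    isis = isis[isis < n_bins * bin_ms]
    idx = np.minimum((isis / bin_ms + 1e-9).astype(np.int64), n_bins - 1)
    np.add.at(counts, idx, 1)
    return counts


def burstiness(
    isi_hist: np.ndarray,
    bin_ms: float = 1.0,
    burst_ms: float = 6.0,
    count_spikes: bool = False,
) -> float:
    """Fraction of ISI-histogram mass within [0, 6) ms.

    By default counts ISI entries (the number of intervals).
    ``count_spikes=True`` switches to a spike-count reading (n intervals
    involve n + 1 spikes, so the denominator gains one).  Returns 0 with a
    warning on an empty histogram.
    """
    total = int(isi_hist.sum())
    if total == 0:
        warnings.warn("empty ISI histogram; burstiness set to 0", stacklevel=2)
        return 0.0
    n_burst_bins = int(round(burst_ms / bin_ms))
    denom = total + 1 if count_spikes else total
    return float(isi_hist[:n_burst_bins].sum() / denom)


# ---------------------------------------------------------------------------
# waveform features
# ---------------------------------------------------------------------------

def select_peak_electrode(fp: UnitFootprint) -> tuple[int, np.ndarray]:
    """Pick the peak electrode of a footprint.

    Each electrode's averaged waveform is high-pass filtered (3rd-order
    Butterworth, 500 Hz); the electrode whose *filtered* trace has the
    largest peak-to-peak amplitude wins (ties -> lowest electrode index).
    Returns ``(electrode_index, unfiltered waveform)``.
    """
    if fp.sampling_rate <= 1000:
        raise ValueError("sampling rate must exceed 1 kHz")
    w = fp.waveforms
    if np.allclose(w, w[:, :1]):
        raise FeatureError("degenerate (flat) footprint")
    sos = signal.butter(3, 500.0, btype="highpass", fs=fp.sampling_rate, output="sos")
    filt = signal.sosfiltfilt(sos, w, axis=1)
    ptp = filt.max(axis=1) - filt.min(axis=1)
    idx = int(np.argmax(ptp))  # argmax takes the first maximum: the tie rule
    return idx, w[idx].copy()


def preprocess_waveform(w: np.ndarray, factor: int = 2) -> np.ndarray:
    """Upsample by cubic-spline interpolation, then z-transform.

    ``factor`` 2 maps n samples onto 2n samples spanning the same time
    support (81 -> 162); the output has mean 0 and SD 1.
    """
    if factor not in (2, 4):
        raise ValueError("factor must be 2 or 4")
    w = np.asarray(w, dtype=float)
    if w.size < 4:
        raise ValueError("need at least 4 samples for a cubic spline")
    if np.ptp(w) == 0:
        raise FeatureError("constant waveform: z-transform undefined")
    x = np.arange(w.size)
    xi = np.linspace(0, w.size - 1, w.size * factor)
    spl = interpolate.CubicSpline(x, w)
    up = spl(xi)
    return (up - up.mean()) / up.std()


def waveform_features(
    w: np.ndarray, sampling_rate_effective: float, peak_electrode_id: int = -1
) -> WaveformFeatures:
    """Landmark features of a preprocessed (z-scored, upsampled) waveform.

    Landmarks: trough = global minimum; A = maximum before the trough;
    B = maximum after the trough.  Durations are peak->trough and
    trough->peak in ms; AB ratio = (B - A)/(B + A); half width is the
    interpolated width of the trough at half its depth (depth measured from
    the z-scored zero line).
    """
    w = np.asarray(w, dtype=float)
    trough = int(np.argmin(w))
    if trough == 0 or trough == w.size - 1:
        raise FeatureError("trough at waveform boundary")
    dt_ms = 1e3 / sampling_rate_effective
    a_idx = int(np.argmax(w[:trough]))
    b_idx = trough + 1 + int(np.argmax(w[trough + 1 :]))
    a, b = float(w[a_idx]), float(w[b_idx])
    denom = a + b
    ab = (b - a) / denom if denom != 0 else 0.0
    half_level = w[trough] / 2.0  # half of trough depth below the zero line
    left = _cross_time(w, trough, half_level, direction=-1)
    right = _cross_time(w, trough, half_level, direction=+1)
    return WaveformFeatures(
        peak_to_trough=(trough - a_idx) * dt_ms,
        trough_to_peak=(b_idx - trough) * dt_ms,
        ab_ratio=float(ab),
        half_width=(right - left) * dt_ms,
        peak_electrode_id=peak_electrode_id,
    )


def _cross_time(w: np.ndarray, trough: int, level: float, direction: int) -> float:
    """Fractional sample index where w crosses `level` walking from the trough."""
    i = trough
    while 0 < i < w.size - 1:
        j = i + direction
        if w[j] >= level:
            # linear interpolation between samples i and j
            frac = (level - w[i]) / (w[j] - w[i])
            return i + direction * frac
        i = j
    return float(i)


def waveform_exclusion(
    f: WaveformFeatures,
    max_width_ms: float = 1.5,
    ab_low: float = -0.3,
    ab_high: float = 0.6,
    require_both: bool = False,
) -> bool:
    """Return True if the unit should be *dropped*.

    Default (disjunctive) rule: drop when the total trough width
    (peak-to-trough + trough-to-peak) exceeds 1.5 ms OR the AB ratio falls
    outside [-0.3, 0.6].  ``require_both=True`` switches to the conjunctive
    reading.
    """
    wide = (f.peak_to_trough + f.trough_to_peak) > max_width_ms
    asym = f.ab_ratio < ab_low or f.ab_ratio > ab_high
    return (wide and asym) if require_both else (wide or asym)


# ---------------------------------------------------------------------------
# ACG fitting
# ---------------------------------------------------------------------------

def estimate_refractory_period(acg_pos: np.ndarray, bin_ms: float = 1.0) -> float:
    """Refractory period from the positive-lag ACG.

    First differences are taken from bin 0 to the peak bin; the refractory
    period is the first bin whose difference exceeds +1 SD of those
    differences.  If none does (e.g. a strictly linear rise, where every
    difference equals the mean), fall back to 1 ms.
    """
    acg_pos = np.asarray(acg_pos, dtype=float)
    peak = int(np.argmax(acg_pos))
    if peak < 1:
        log.warning("ACG peak at bin 0; refractory fallback 1 ms")
        return 1.0 * bin_ms
    diffs = np.diff(acg_pos[: peak + 1])
    sd = diffs.std()
    if sd == 0:
        log.warning("flat ACG derivative; refractory fallback 1 ms")
        return 1.0 * bin_ms
    above = np.nonzero(diffs > sd)[0]
    if above.size == 0:
        log.warning("no ACG derivative exceeds 1 SD; refractory fallback 1 ms")
        return 1.0 * bin_ms
    return float((above[0] + 1) * bin_ms)


def acg_model(
    x: np.ndarray,
    c: float,
    d: float,
    h: float,
    tau_decay: float,
    tau_rise: float,
    tau_burst: float,
    asymptote: float,
    t_refrac: float,
) -> np.ndarray:
    """Clamped triple-exponential ACG model.

    ``max(c·exp(-(x-t_r)/τ_decay) - d·exp(-(x-t_r)/τ_rise)
        + h·exp(-(x-t_r)/τ_burst) + asymptote, 0)``
    """
    dx = x - t_refrac
    val = (
        c * np.exp(-dx / tau_decay)
        - d * np.exp(-dx / tau_rise)
        + h * np.exp(-dx / tau_burst)
        + asymptote
    )
    return np.maximum(val, 0.0)


_TAU_BOUNDS = {"tau_rise": (0.1, 50.0), "tau_burst": (0.1, 100.0), "tau_decay": (1.0, 500.0)}


def fit_acg(
    acg_pos: np.ndarray,
    t_refrac: float | None = None,
    bin_ms: float = 1.0,
    smooth_ms: float = 5.0,
    seed: int = 0,
) -> ACGFit:
    """Fit the clamped triple exponential to a positive-lag ACG.

    The ACG is smoothed with a centred moving average spanning ``smooth_ms``,
    bins below the refractory period are zeroed, and a bounded trust-region
    least-squares fit is run from several deterministic multi-starts (one
    data-driven: asymptote from the tail mean, amplitude from the peak); the
    best solution by residual norm wins.  Residuals are weighted by the
    inverse bin count (count data carry multiplicative noise; relative
    weighting also keeps the slow tail — which identifies τ_decay —
    from being drowned out by the peak).  Bins below the refractory period
    carry no information and are excluded from the fit.  ``r_square``
    compares the (unweighted) fit with the smoothed data over the fitted
    lag range — the quality gate used by QC.
    """
    y = np.asarray(acg_pos, dtype=float)
    if t_refrac is None:
        t_refrac = estimate_refractory_period(y, bin_ms)
    k = int(round(smooth_ms / bin_ms))
    kernel = np.ones(k) / k
    ys = np.convolve(y, kernel, mode="same")
    x = (np.arange(y.size) + 0.5) * bin_ms  # bin centres
    ys = ys.copy()
    ys[x < t_refrac] = 0.0
    # refractory bins carry no information about the firing pattern: the
    # residuals cover lags at/after the refractory period only
    fit_mask = x >= t_refrac

    scale = max(ys.max(), 1.0)
    lb = np.array([0.0, 0.0, 0.0, 1.0, 0.1, 0.1, 0.0])
    ub = np.array([np.inf, np.inf, np.inf, 500.0, 50.0, 100.0, np.inf])
    weights = 1.0 / np.maximum(ys, 0.1)

    def resid(p):
        model = acg_model(x, p[0], p[1], p[2], p[3], p[4], p[5], p[6], t_refrac)
        return ((model - ys) * weights)[fit_mask]

    # variable projection: for fixed time constants the model is linear in
    # (c, -d, h, asymptote); profile those out by non-negative least squares
    # over a deterministic grid of tau triples, then polish the best
    # candidates with a bounded trust-region fit of all 7 parameters
    dx = (x - t_refrac)[fit_mask]
    yw = (ys * weights)[fit_mask]
    wv = weights[fit_mask]
    candidates = []
    for td in (10.0, 12.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0, 70.0, 100.0, 200.0):
        for tr_ in (0.5, 1.0, 2.0, 3.0, 4.0, 8.0):
            for tb in (3.0, 5.0, 8.0, 12.0, 20.0, 40.0):
                a_mat = np.column_stack([
                    np.exp(-dx / td), -np.exp(-dx / tr_),
                    np.exp(-dx / tb), np.ones_like(dx),
                ]) * wv[:, None]
                try:
                    beta, rnorm = optimize.nnls(a_mat, yw)
                except Exception:  # pragma: no cover
                    continue
                candidates.append((rnorm, beta, (td, tr_, tb)))
    candidates.sort(key=lambda c: c[0])
    starts = []
    for rnorm, beta, (td, tr_, tb) in candidates[:6]:
        starts.append(np.array([beta[0], beta[1], beta[2], td, tr_, tb, beta[3]]))
    if not starts:  # pragma: no cover - NNLS failed everywhere
        scale0 = max(ys.max(), 1.0)
        starts = [np.array([scale0, scale0 * 0.8, scale0 * 0.3, 30.0, 2.0, 10.0,
                            float(ys[-10:].mean())])]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lb, ub)
        try:
            res = optimize.least_squares(resid, p0, bounds=(lb, ub), method="trf", max_nfev=1000)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FeatureError("ACG fit failed on all starts")
    p = best.x.copy()
    # the c/tau_decay and h/tau_burst terms enter symmetrically, so the
    # optimizer may swap their roles; canonicalize to tau_decay >= tau_burst
    # (an exact symmetry: the fitted curve is unchanged)
    if p[5] > p[3]:
        p[0], p[2] = p[2], p[0]
        p[3], p[5] = p[5], p[3]
    fit_vals = acg_model(x, *p, t_refrac)[fit_mask]
    data = ys[fit_mask]
    ss_res = float(np.sum((data - fit_vals) ** 2))
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return ACGFit(
        c=float(p[0]), d=float(p[1]), h=float(p[2]),
        tau_decay=float(p[3]), tau_rise=float(p[4]), tau_burst=float(p[5]),
        rate_asymptote=float(p[6]), t_refrac=float(t_refrac), r_square=float(r2),
    )


# ---------------------------------------------------------------------------
# QC + featurization pipeline
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input: int = 0
    dropped_rate: int = 0
    dropped_violation: int = 0
    dropped_waveform: int = 0
    dropped_acg_fit: int = 0
    survivors: int = 0
    details: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "dropped_rate": self.dropped_rate,
            "dropped_violation": self.dropped_violation,
            "dropped_waveform": self.dropped_waveform,
            "dropped_acg_fit": self.dropped_acg_fit,
            "survivors": self.survivors,
        }


def qc_and_featurize(
    units: list,
    rate_bounds: tuple = (0.05, 30.0),
    max_violation: float = 0.3,
    min_r_square: float = 0.8,
    upsample_factor: int = 2,
    require_both: bool = False,
) -> tuple[list, QCReport]:
    """Run QC rules in order and build 7-feature vectors for survivors.

    ``units`` is a list of ``(SpikeTrain, UnitFootprint)`` pairs keyed by the
    same unit.  Rules, in order: firing rate in [0.05, 30] Hz; refractory
    violation ratio <= 0.3; waveform width/asymmetry exclusion; ACG fit
    r² >= 0.8.  Returns feature vectors plus a per-rule drop count report.
    """
    report = QCReport(n_input=len(units))
    out: list[NeuronFeatureVector] = []
    for train, fp in units:
        if train.unit_id != fp.unit_id:
            raise ValueError(
                f"train/footprint key mismatch: {train.unit_id} vs {fp.unit_id}"
            )
        fr = firing_rate(train)
        if not (rate_bounds[0] <= fr <= rate_bounds[1]):
            report.dropped_rate += 1
            continue
        if refractory_violation_ratio(train) > max_violation:
            report.dropped_violation += 1
            continue
        try:
            eidx, raw_w = select_peak_electrode(fp)
            w = preprocess_waveform(raw_w, factor=upsample_factor)
            wf = waveform_features(
                w, fp.sampling_rate * upsample_factor, peak_electrode_id=eidx
            )
        except FeatureError:
            report.dropped_waveform += 1
            continue
        if waveform_exclusion(wf, require_both=require_both):
            report.dropped_waveform += 1
            continue
        _, acg = autocorrelogram(train, bin_ms=1.0, half_window_ms=50.0)
        acg_pos = acg[acg.size // 2 :]
        try:
            fit = fit_acg(acg_pos)
        except FeatureError:
            report.dropped_acg_fit += 1
            continue
        if fit.r_square < min_r_square:
            report.dropped_acg_fit += 1
            continue
        bst = burstiness(isi_histogram(train))
        out.append(
            NeuronFeatureVector(
                unit_id=train.unit_id,
                values=np.array([
                    wf.peak_to_trough, wf.trough_to_peak, wf.ab_ratio,
                    wf.half_width, bst, fit.tau_decay, fit.tau_rise,
                ]),
            )
        )
    report.survivors = len(out)
    return out, report
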