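"""Synthetic studies with the statistical structure the analysis assumes.

Real recordings come from cultured hippocampal neurons on high-density
microelectrode arrays: strongly synchronized population bursting (normalized
participation ratio well below 0.5), sparse excitatory/inhibitory coupling
with monosynaptic delays of 2–10 ms, per-unit extracellular footprints, and
heavy-tailed firing-rate fold changes under a disinhibiting perturbation in
which a minority (~9%) of neurons *decrease* their rates.  This module
generates studies with those properties while retaining full ground truth
(connectivity, template geometry, planted responses) so every downstream
stage can be tested against it.

Spiking is produced by a Poisson-cluster (branching) construction —
equivalent to a discrete-time conditional-intensity process: background and
common-burst spikes form a first generation; each excitatory edge spawns
offspring spikes at the edge delay (plus sub-millisecond jitter); inhibitory
edges delete target spikes around the delay.  This yields Hz-scale rates,
burst-driven correlations, and lagged cross-correlogram peaks at the planted
delays, at a fraction of the cost of stepping a 1-ms intensity grid.
"""

from __future__ import annotations

import numpy as np

from .types import (
    GroundTruthNetwork,
    PlantedResponseModel,
    SpikeTrain,
    StudyDataset,
    StudyNetwork,
    UnitFootprint,
    WeightedGraph,
)

__all__ = [
    "SimulationParameterError",
    "generate_topology",
    "simulate_spike_trains",
    "synthesize_footprints",
    "plant_perturbation",
    "true_feature_matrix",
    "generate_study",
    "DELAY_RANGE_MS",
]

DELAY_RANGE_MS = (2.0, 10.0)  # fast monosynaptic transmission delays
ELECTRODE_PITCH_UM = 17.5


class SimulationParameterError(RuntimeError):
    """Simulation parameters produce runaway or capped-out firing rates."""


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def generate_topology(
    n_neurons: int,
    frac_inhibitory: float = 0.2,
    p_connect: float = 0.05,
    grid_extent: tuple = (600.0, 600.0),
    seed: int = 0,
    chip_id: str = "chip0",
    network_id: str = "net0",
) -> GroundTruthNetwork:
    """Random Dale-consistent directed network on an electrode grid.

    Each ordered pair (i, j), i != j, is connected with probability
    ``p_connect``; edge gains are ~U(0.5, 1.5) signed by the source neuron
    (excitatory +, inhibitory −), delays ~U(2, 10) ms, positions uniform on
    the grid extent (µm).  Deterministic under ``seed``.
    """
    if n_neurons < 2:
        raise ValueError("n_neurons must be at least 2")
    if not 0.0 <= frac_inhibitory <= 1.0:
        raise ValueError("frac_inhibitory must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_neurons
    n_inh = int(round(frac_inhibitory * n))
    sign = np.ones(n, dtype=int)
    inh_idx = rng.choice(n, size=n_inh, replace=False)
    sign[inh_idx] = -1
    mask = rng.random((n, n)) < p_connect
    np.fill_diagonal(mask, False)
    gains = rng.uniform(0.5, 1.5, size=(n, n))
    adjacency = np.where(mask, gains * sign[:, None], 0.0)
    delay = np.where(mask, rng.uniform(*DELAY_RANGE_MS, size=(n, n)), 0.0)
    positions = rng.uniform([0.0, 0.0], list(grid_extent), size=(n, 2))
    return GroundTruthNetwork(
        n_neurons=n,
        neuron_sign=sign,
        adjacency=adjacency,
        delay=delay,
        positions=positions,
        chip_id=chip_id,
        network_id=network_id,
    )


# ---------------------------------------------------------------------------
# spiking
# ---------------------------------------------------------------------------

def simulate_spike_trains(
    net: GroundTruthNetwork,
    duration: float = 1200.0,
    base_rate=0.5,
    burst_rate: float = 20.0,
    coupling_scale: float = 0.15,
    burst_spikes: float = 3.0,
    burst_sd: float = 0.025,
    burst_participation=1.0,
    jitter_ms: float = 0.5,
    refractory_ms: float = 1.5,
    rate_cap: float = 30.0,
    max_generations: int = 5,
    seed: int = 0,
) -> list:
    """Simulate one recording of all neurons in a network.

    ``base_rate`` (Hz, scalar or per-neuron array) sets independent
    background firing; population bursts occur at ``burst_rate`` events/min,
    each adding ~``burst_spikes * burst_participation_i`` spikes per neuron
    spread over ±2·``burst_sd`` seconds — the common drive that makes the
    population low-dimensional.  Excitatory edges spawn offspring spikes at
    the edge delay with probability ``coupling_scale · |gain|``; inhibitory
    edges delete target spikes within ±2 ms of the delayed source spike with
    the same probability.  A 1.5-ms absolute refractory period is enforced.

    Raises ``SimulationParameterError`` if the excitatory branching ratio
    approaches 1 (runaway) or any neuron exceeds ``rate_cap`` Hz.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = net.n_neurons
    base = np.broadcast_to(np.asarray(base_rate, dtype=float), (n,)).copy()
    part = np.broadcast_to(np.asarray(burst_participation, dtype=float), (n,)).copy()
    if np.any(base < 0) or burst_rate < 0:
        raise ValueError("rates must be non-negative")

    probs = np.clip(coupling_scale * np.abs(net.adjacency), 0.0, 0.9)
    exc_rows = net.neuron_sign > 0
    # branching-process criticality: spectral radius of the excitatory
    # offspring-probability matrix must stay below 1
    radius = float(np.max(np.abs(np.linalg.eigvals(probs * exc_rows[:, None]))))
    if radius >= 0.95:
        raise SimulationParameterError(
            f"excitatory branching spectral radius {radius:.2f} >= 0.95: runaway"
        )

    spikes = [[] for _ in range(n)]
    # background
    for i in range(n):
        k = rng.poisson(base[i] * duration)
        spikes[i].append(np.sort(rng.uniform(0, duration, size=k)))
    # common bursts
    n_bursts = rng.poisson(burst_rate * duration / 60.0)
    centers = rng.uniform(0, duration, size=n_bursts)
    if n_bursts:
        counts = rng.poisson(np.outer(np.ones(n_bursts), burst_spikes * part))
        for i in range(n):
            total = counts[:, i].sum()
            if total == 0:
                continue
            t = np.repeat(centers, counts[:, i]) + rng.normal(0, burst_sd, size=total)
            spikes[i].append(t)
    gen = [np.concatenate(s) if s else np.empty(0) for s in spikes]
    gen = [t[(t >= 0) & (t < duration)] for t in gen]
    all_spikes = [t.copy() for t in gen]

    # excitatory branching cascade
    out_edges = [np.nonzero(net.adjacency[i] != 0)[0] for i in range(n)]
    for _ in range(max_generations):
        new = [[] for _ in range(n)]
        any_new = False
        for i in range(n):
            if net.neuron_sign[i] <= 0 or gen[i].size == 0:
                continue
            for j in out_edges[i]:
                p = probs[i, j]
                keep = rng.random(gen[i].size) < p
                k = int(keep.sum())
                if k == 0:
                    continue
                t = (
                    gen[i][keep]
                    + net.delay[i, j] / 1e3
                    + rng.normal(0, jitter_ms / 1e3, size=k)
                )
                t = t[(t >= 0) & (t < duration)]
                if t.size:
                    new[j].append(t)
                    any_new = True
        if not any_new:
            break
        gen = [np.concatenate(s) if s else np.empty(0) for s in new]
        for i in range(n):
            if gen[i].size:
                all_spikes[i] = np.concatenate([all_spikes[i], gen[i]])

    # inhibitory thinning
    for i in range(n):
        if net.neuron_sign[i] >= 0 or all_spikes[i].size == 0:
            continue
        src = np.sort(all_spikes[i])
        for j in out_edges[i]:
            tgt = all_spikes[j]
            if tgt.size == 0:
                continue
            centers_ij = src + net.delay[i, j] / 1e3
            idx = np.searchsorted(centers_ij, tgt)
            near = np.zeros(tgt.size, dtype=bool)
            w = 2e-3
            left = idx > 0
            near[left] = (tgt[left] - centers_ij[idx[left] - 1]) <= w
            right = idx < centers_ij.size
            near[right] |= (centers_ij[idx[right]] - tgt[right]) <= w
            drop = near & (rng.random(tgt.size) < probs[i, j])
            all_spikes[j] = tgt[~drop]

    trains = []
    for i in range(n):
        t = np.sort(all_spikes[i])
        t = _enforce_refractory(t, refractory_ms / 1e3)
        rate = t.size / duration
        if rate > rate_cap:
            raise SimulationParameterError(
                f"neuron {i} rate {rate:.1f} Hz exceeds cap {rate_cap} Hz"
            )
        trains.append(
            SpikeTrain(
                unit_id=i,
                spike_times=t,
                duration=duration,
                chip_id=net.chip_id,
                network_id=net.network_id,
            )
        )
    return trains


def _enforce_refractory(t: np.ndarray, refractory_s: float) -> np.ndarray:
    """Greedy removal of spikes closer than the refractory period."""
    if t.size < 2:
        return t
    keep = np.ones(t.size, dtype=bool)
    last = t[0]
    for k in range(1, t.size):
        if t[k] - last < refractory_s:
            keep[k] = False
        else:
            last = t[k]
    return t[keep]


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def synthesize_footprints(
    net: GroundTruthNetwork,
    sampling_rate: float = 20000.0,
    snippet_ms: float = 4.0,
    n_electrodes: int = 9,
    noise_sd: float = 1.0,
    decay_um: float = 25.0,
    seed: int = 0,
) -> tuple:
    """Parametric biphasic footprints on the electrode lattice.

    Each neuron gets a template: a Gaussian trough (depth ~U(50, 150) µV,
    half-width at half depth ~U(0.2, 0.45) ms) flanked by a pre-peak A at
    ``ptr`` ms before and a post-peak B at ``ttp`` ms after the trough.
    Amplitude decays as exp(−distance/decay_um) over the ``n_electrodes``
    lattice electrodes nearest the neuron, so the peak electrode is the
    nearest one.  Gaussian noise of ``noise_sd`` µV is added per sample.

    Returns ``(footprints, params)`` where ``params`` holds the per-neuron
    ground-truth template geometry for feature-recovery tests:
    ``ptr``/``ttp`` (ms), ``ab_ratio``, ``half_width`` (ms), ``depth`` (µV).
    """
    snippet_s = snippet_ms / 1e3
    n_samples = int(round(snippet_ms * sampling_rate / 1e3)) + 1
    rng = np.random.default_rng(seed)
    n = net.n_neurons
    params = {
        "ptr": rng.uniform(0.35, 0.70, n),
        "ttp": rng.uniform(0.45, 0.80, n),
        "half_width": rng.uniform(0.20, 0.45, n),
        "a_rel": rng.uniform(0.15, 0.35, n),
        "b_rel": rng.uniform(0.20, 0.50, n),
        "depth": rng.uniform(50.0, 150.0, n),
        "peak_sigma": rng.uniform(0.15, 0.30, n),
    }
    if params["half_width"].min() <= 0 or snippet_ms < 4.0:
        raise ValueError("snippet must cover at least 4 ms")
    params["ab_ratio"] = (params["b_rel"] - params["a_rel"]) / (
        params["b_rel"] + params["a_rel"]
    )
    # electrode lattice covering the positions
    extent = net.positions.max(axis=0) + ELECTRODE_PITCH_UM
    nx_e = int(np.ceil(extent[0] / ELECTRODE_PITCH_UM)) + 1
    ny_e = int(np.ceil(extent[1] / ELECTRODE_PITCH_UM)) + 1
    gx, gy = np.meshgrid(
        np.arange(nx_e) * ELECTRODE_PITCH_UM, np.arange(ny_e) * ELECTRODE_PITCH_UM
    )
    lattice = np.column_stack([gx.ravel(), gy.ravel()])

    t_ms = np.arange(n_samples) / sampling_rate * 1e3  # 0 .. snippet_ms
    t_c = snippet_ms / 2.0
    footprints = []
    for i in range(n):
        tmpl = template_waveform(
            t_ms,
            t_c,
            params["depth"][i],
            params["half_width"][i],
            params["ptr"][i],
            params["ttp"][i],
            params["a_rel"][i],
            params["b_rel"][i],
            params["peak_sigma"][i],
        )
        d = np.linalg.norm(lattice - net.positions[i], axis=1)
        order = np.argsort(d)[:n_electrodes]
        amp = np.exp(-d[order] / decay_um)
        waves = amp[:, None] * tmpl[None, :]
        waves = waves + rng.normal(0, noise_sd, size=waves.shape)
        footprints.append(
            UnitFootprint(
                unit_id=i,
                waveforms=waves,
                electrode_positions=lattice[order],
                sampling_rate=sampling_rate,
                n_averaged=300,
            )
        )
    return footprints, params


def template_waveform(
    t_ms: np.ndarray,
    t_c: float,
    depth: float,
    half_width: float,
    ptr: float,
    ttp: float,
    a_rel: float,
    b_rel: float,
    peak_sigma: float,
) -> np.ndarray:
    """Continuous biphasic template: Gaussian trough at ``t_c`` with peaks
    ``ptr`` ms before and ``ttp`` ms after; half_width is the trough width
    at half depth (ms)."""
    sigma_tr = half_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    w = -depth * np.exp(-((t_ms - t_c) ** 2) / (2 * sigma_tr**2))
    w = w + a_rel * depth * np.exp(-((t_ms - (t_c - ptr)) ** 2) / (2 * peak_sigma**2))
    w = w + b_rel * depth * np.exp(-((t_ms - (t_c + ttp)) ** 2) / (2 * peak_sigma**2))
    return w


# ---------------------------------------------------------------------------
# planted perturbation responses
# ---------------------------------------------------------------------------

def planted_responses_study(
    features_per_net: list,
    fc_weights_per_net: list,
    model: PlantedResponseModel,
    rng: np.random.Generator,
) -> list:
    """Planted responses for all networks of a study at once.

    Feature columns and the projection score are standardized over the
    POOLED neurons of the study, so the planted response is a function of a
    neuron's absolute features — without this, a network-relative score
    would encode network context that only graph models could exploit.
    The own-feature term is linear in the score: shifted so that its
    ``decrease_fraction`` quantile is zero and scaled to the requested mean
    response.  The decrease-fraction re-anchoring after the neighbor term
    is likewise global.  Returns one response vector per network.
    """
    sizes = [np.atleast_2d(f).shape[0] for f in features_per_net]
    f_all = np.vstack([np.atleast_2d(f) for f in features_per_net])
    sd = f_all.std(axis=0)
    z_cols = np.where(
        sd > 0, (f_all - f_all.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0
    )
    score = z_cols @ model.feature_weights
    if model.decrease_fraction > 0:
        phi_all = score - np.quantile(score, model.decrease_fraction)
    else:
        phi_all = score - score.min() + 0.1
    m = phi_all.mean()
    if m > 0:
        phi_all = phi_all * (model.mean_response / m)
    resp_list, off = [], 0
    for n_i, w in zip(sizes, fc_weights_per_net):
        phi = phi_all[off : off + n_i]
        off += n_i
        w = np.asarray(w, dtype=float)
        has_nb = (w > 0).any(axis=1)
        agg = np.where(has_nb, np.max(w * phi[None, :], axis=1), 0.0)
        resp_list.append(phi + model.neighbor_weight * agg)
    resp_all = np.concatenate(resp_list)
    if model.decrease_fraction > 0 and model.neighbor_weight != 0:
        resp_all = resp_all - np.quantile(resp_all, model.decrease_fraction)
    if model.noise_sd > 0:
        resp_all = resp_all + rng.normal(0, model.noise_sd, size=resp_all.size)
    resp_all = np.clip(resp_all, -0.95, None)
    out, off = [], 0
    for n_i in sizes:
        out.append(resp_all[off : off + n_i])
        off += n_i
    return out


def planted_responses(
    features: np.ndarray,
    fc_weights: np.ndarray,
    model: PlantedResponseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-neuron planted Δfch' from true features and a coupling graph.

    The feature score ``z_i`` is the standardized projection of the feature
    matrix onto ``model.feature_weights``; the own-feature term is the
    heavy-tailed ``phi_i = exp(mu + sigma·z_i) − 1`` with mu, sigma set so
    that P(phi < 0) = decrease_fraction and the positive tail is lognormal
    (sigma fixed at 1.04, putting the mean near 6 at the default 9%
    decrease fraction, matching the scale seen in disinhibition
    experiments).  The neighborhood term is a strongest-neighbor drive:
    ``neighbor_weight · max_j(w_ij · phi_j)`` over the coupling graph — the
    most strongly coupled, most responsive neighbor dominates the indirect
    effect of the perturbation on neuron i.  Gaussian noise is added and the
    result clipped at −0.95.
    """
    return planted_responses_study([features], [fc_weights], model, rng)[0]


def plant_perturbation(
    net: GroundTruthNetwork,
    baseline_trains: list,
    features: np.ndarray,
    fc_graph: WeightedGraph,
    model: PlantedResponseModel,
    n_timepoints: int = 7,
    seed: int = 0,
    planted_override: np.ndarray | None = None,
) -> tuple:
    """Generate perturbation recordings consistent with planted responses.

    The planted per-neuron Δfch' is computed from the true features and the
    coupling graph (see :func:`planted_responses`), or taken from
    ``planted_override``.  Each perturbation recording is regenerated as a
    Poisson train at ``(1 + response_i)`` times the neuron's measured
    combined-baseline rate — a constant scale across timepoints, which keeps
    the planted value equal to the measured Δfch' in expectation for
    increases and decreases alike.

    ``baseline_trains`` is a list of baseline recordings (each a list of
    ``SpikeTrain``).  Returns ``(perturbation_recordings, true_response)``.
    """
    if model.decrease_fraction >= 0.5:
        raise ValueError("decrease_fraction must be below 0.5")
    ids = np.array([tr.unit_id for tr in baseline_trains[0]])
    if not np.all(np.isin(fc_graph.node_ids, ids)):
        raise ValueError("fc_graph node set is not a subset of the network's units")
    rng = np.random.default_rng(seed)
    n = net.n_neurons
    if planted_override is not None:
        resp = np.asarray(planted_override, dtype=float)
        if resp.shape != (n,):
            raise ValueError("planted_override must have one entry per neuron")
    else:
        # expand the fc graph onto the full neuron set (missing nodes isolated)
        w_full = np.zeros((n, n))
        pos = {int(u): k for k, u in enumerate(ids)}
        sel = np.array([pos[int(u)] for u in fc_graph.node_ids])
        w_full[np.ix_(sel, sel)] = fc_graph.weights
        resp = planted_responses(features, w_full, model, rng)

    duration = baseline_trains[0][0].duration
    total_t = sum(b[0].duration for b in baseline_trains)
    base_counts = np.zeros(n)
    for b in baseline_trains:
        base_counts += np.array([tr.n_spikes for tr in b], dtype=float)
    base_rate = base_counts / total_t

    recordings = []
    for _ in range(n_timepoints):
        rec = []
        for i in range(n):
            lam = base_rate[i] * (1.0 + resp[i]) * duration
            k = rng.poisson(max(lam, 0.0))
            t = np.sort(rng.uniform(0, duration, size=k))
            rec.append(
                SpikeTrain(
                    unit_id=int(ids[i]),
                    spike_times=t,
                    duration=duration,
                    chip_id=net.chip_id,
                    network_id=net.network_id,
                )
            )
        recordings.append(rec)
    return recordings, resp


# ---------------------------------------------------------------------------
# full studies
# ---------------------------------------------------------------------------

def true_feature_matrix(params: dict, burst_participation: np.ndarray) -> np.ndarray:
    """Ground-truth analogue of the 7-feature vector used for planting.

    Columns mirror (peak_to_trough, trough_to_peak, ab_ratio, half_width,
    burstiness, tau_decay, tau_rise); the burstiness column is the per-neuron
    burst participation (its generative driver), and the two ACG time
    constants — which the generator does not control per neuron — are zero
    columns (they drop out of the standardized planting score).
    """
    n = burst_participation.size
    return np.column_stack(
        [
            params["ptr"],
            params["ttp"],
            params["ab_ratio"],
            params["half_width"],
            burst_participation,
            np.zeros(n),
            np.zeros(n),
        ]
    )


def true_coupling_graph(net: GroundTruthNetwork) -> WeightedGraph:
    """Symmetrized |gain| graph of the planted connectivity (zero diagonal)."""
    a = np.abs(net.adjacency)
    w = np.maximum(a, a.T)
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(node_ids=np.arange(net.n_neurons), weights=w, measure="PCC")


def generate_study(
    n_chips: int = 4,
    networks_per_chip: int = 3,
    n_neurons: tuple = (45, 75),
    duration: float = 1200.0,
    n_baseline: int = 2,
    n_perturbation: int = 7,
    frac_inhibitory: float = 0.2,
    p_connect: float = 0.15,
    coupling_scale: float = 0.08,
    burst_rate: float = 20.0,
    response_model: PlantedResponseModel | None = None,
    seed: int = 0,
) -> StudyDataset:
    """Generate a full synthetic study.

    Defaults emulate the recording design of the experiments this pipeline
    analyses: 4 chips × 3 sub-networks of ~45–75 neurons, two 20-min
    baseline recordings plus seven perturbation recordings, burst-dominated
    correlated activity over a fairly dense coupling graph (the inferred FC
    graphs of such cultures are close to fully connected), and planted
    heavy-tailed perturbation responses whose feature score is standardized
    over the pooled study.  All sizes shrink cleanly for fast tests.
    Deterministic under ``seed``.
    """
    if n_chips < 2:
        raise ValueError("a study needs at least 2 chips for chip-exclusion CV")
    model = response_model if response_model is not None else PlantedResponseModel()
    master = np.random.default_rng(seed)
    built = []
    for c in range(n_chips):
        for k in range(networks_per_chip):
            sub = np.random.default_rng(master.integers(2**31))
            n = int(sub.integers(n_neurons[0], n_neurons[1] + 1))
            net = generate_topology(
                n,
                frac_inhibitory=frac_inhibitory,
                p_connect=p_connect,
                seed=int(sub.integers(2**31)),
                chip_id=f"chip{c}",
                network_id=f"chip{c}_net{k}",
            )
            base_rates = np.clip(
                sub.lognormal(mean=np.log(0.5), sigma=0.5, size=n), 0.1, 4.0
            )
            # heavy-tailed burst participation: the generative driver of
            # burstiness and of the heavy-tailed perturbation response
            part = np.clip(sub.lognormal(0.0, 1.0, size=n), 0.2, 10.0)
            baselines = [
                simulate_spike_trains(
                    net,
                    duration=duration,
                    base_rate=base_rates,
                    burst_rate=burst_rate,
                    coupling_scale=coupling_scale,
                    burst_participation=part,
                    seed=int(sub.integers(2**31)),
                )
                for _ in range(n_baseline)
            ]
            footprints, params = synthesize_footprints(
                net, seed=int(sub.integers(2**31))
            )
            features = true_feature_matrix(params, part)
            fc = true_coupling_graph(net)
            plant_seed = int(sub.integers(2**31))
            built.append(dict(net=net, baselines=baselines, footprints=footprints,
                              params=params, part=part, base_rates=base_rates,
                              features=features, fc=fc, plant_seed=plant_seed))
    # plant all responses at once: the feature score is standardized over
    # the pooled study, not per network
    resp_rng = np.random.default_rng(master.integers(2**31))
    responses = planted_responses_study(
        [b["features"] for b in built], [b["fc"].weights for b in built],
        model, resp_rng,
    )
    networks = []
    for b, resp in zip(built, responses):
        pert, resp_out = plant_perturbation(
            b["net"], b["baselines"], b["features"], b["fc"], model,
            n_timepoints=n_perturbation, seed=b["plant_seed"],
            planted_override=resp,
        )
        networks.append(
            StudyNetwork(
                truth=b["net"],
                recordings=b["baselines"] + pert,
                footprints=b["footprints"],
                true_response=resp_out,
                template_params={**b["params"],
                                 "burst_participation": b["part"],
                                 "base_rates": b["base_rates"]},
            )
        )
    return StudyDataset(
        networks=networks,
        n_baseline=n_baseline,
        n_perturbation=n_perturbation,
        seed=seed,
    )
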