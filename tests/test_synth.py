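"""Synthetic-study generator: topology, spiking, footprints, planting."""

import numpy as np
import pytest
from scipy import stats

from fcpredict import connectivity as cn
from fcpredict import synth
from fcpredict.netmetrics import participation_ratio
from fcpredict.targets import neuron_fold_change, rate_series
from fcpredict.types import PlantedResponseModel


class TestTopology:
    def test_complete_digraph_all_excitatory(self):
        net = synth.generate_topology(10, frac_inhibitory=0.0, p_connect=1.0,
                                      seed=0)
        assert (net.adjacency > 0).sum() == 90
        assert (net.adjacency < 0).sum() == 0
        assert np.all(np.diag(net.adjacency) == 0)

    def test_deterministic_under_seed(self):
        a = synth.generate_topology(50, 0.2, 0.1, seed=7)
        b = synth.generate_topology(50, 0.2, 0.1, seed=7)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert np.array_equal(a.delay, b.delay)
        assert np.array_equal(a.positions, b.positions)

    def test_edge_count_within_binomial_interval(self):
        net = synth.generate_topology(100, 0.2, 0.05, seed=1)
        k = int((net.adjacency != 0).sum())
        n_pairs = 100 * 99
        lo, hi = stats.binom.ppf([0.005, 0.995], n_pairs, 0.05)
        assert lo <= k <= hi

    def test_delays_and_dale(self):
        net = synth.generate_topology(40, 0.25, 0.1, seed=2)
        d = net.delay[net.edge_mask]
        assert np.all((d >= 2.0) & (d <= 10.0))
        # every neuron's outgoing edges share one sign
        for i in range(40):
            row = net.adjacency[i][net.adjacency[i] != 0]
            if row.size:
                assert np.all(np.sign(row) == net.neuron_sign[i])

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            synth.generate_topology(1)


class TestSimulation:
    def test_deterministic_under_seed(self):
        net = synth.generate_topology(20, 0.2, 0.05, seed=3)
        a = synth.simulate_spike_trains(net, duration=60.0, seed=4)
        b = synth.simulate_spike_trains(net, duration=60.0, seed=4)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.spike_times, tb.spike_times)

    def test_rates_in_plausible_range(self):
        net = synth.generate_topology(30, 0.2, 0.05, seed=5)
        trains = synth.simulate_spike_trains(net, duration=300.0, seed=6)
        rates = np.array([t.rate for t in trains])
        assert np.all(rates >= 0.05) and np.all(rates <= 30.0)

    def test_bursting_gives_low_normalized_pr(self):
        net = synth.generate_topology(40, 0.2, 0.05, seed=7)
        trains = synth.simulate_spike_trains(net, duration=300.0, seed=8)
        res = participation_ratio(trains)
        assert res.pr_normalized < 0.5

    def test_uncoupled_unbursty_trains_uncorrelated(self):
        net = synth.generate_topology(10, 0.2, 0.1, seed=9)
        trains = synth.simulate_spike_trains(
            net, duration=240.0, base_rate=2.0, burst_rate=0.0,
            coupling_scale=0.0, seed=10,
        )
        g = cn.surrogate_corrected_fc(trains, "PCC", n_surrogates=100, seed=1,
                                      drop_isolated=False)
        frac = np.count_nonzero(np.triu(g.weights, 1)) / (10 * 9 / 2)
        assert frac < 0.05

    def test_strong_edge_visible_in_cch(self):
        net = synth.generate_topology(2, 0.0, 0.0, seed=0)
        net.adjacency[0, 1], net.delay[0, 1] = 1.5, 5.0
        trains = synth.simulate_spike_trains(
            net, duration=300.0, base_rate=2.0, burst_rate=5.0,
            coupling_scale=0.4, seed=3,
        )
        h = cn.cch(trains[0], trains[1])
        assert h.label == "excitatory"
        assert 3.0 <= h.peak_lag <= 7.0

    def test_runaway_coupling_raises(self):
        net = synth.generate_topology(30, 0.0, 0.5, seed=11)
        with pytest.raises(synth.SimulationParameterError):
            synth.simulate_spike_trains(net, duration=10.0, coupling_scale=1.0,
                                        seed=12)


class TestFootprints:
    def test_deterministic_and_noise_free(self):
        net = synth.generate_topology(5, 0.0, 0.0, seed=13)
        a, pa = synth.synthesize_footprints(net, noise_sd=0.0, seed=14)
        b, pb = synth.synthesize_footprints(net, noise_sd=0.0, seed=14)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.waveforms, fb.waveforms)
        assert np.array_equal(pa["ptr"], pb["ptr"])

    def test_peak_electrode_nearest_position(self):
        net = synth.generate_topology(6, 0.0, 0.0, seed=15)
        fps, _ = synth.synthesize_footprints(net, noise_sd=0.0, seed=16)
        for i, fp in enumerate(fps):
            amp = fp.waveforms.max(1) - fp.waveforms.min(1)
            d = np.linalg.norm(fp.electrode_positions - net.positions[i], axis=1)
            assert np.argmax(amp) == np.argmin(d)

    def test_half_width_matches_template_geometry(self):
        """Trough half-width of the continuous template (closed form for a
        Gaussian trough: crossings at half depth) is recovered within one
        upsampled sample."""
        from fcpredict import features as ft

        fs, factor = 20000.0, 2
        t = np.arange(81) / fs * 1e3
        hw = 0.30
        w = synth.template_waveform(t, 2.0, 100.0, hw, 0.55, 0.65, 0.25, 0.45,
                                    0.22)
        up = ft.preprocess_waveform(w, factor)
        f = ft.waveform_features(up, fs * factor)
        assert abs(f.half_width - hw) <= 1e3 / (fs * factor) + 0.01

    def test_short_snippet_raises(self):
        net = synth.generate_topology(3, 0.0, 0.0, seed=17)
        with pytest.raises(ValueError):
            synth.synthesize_footprints(net, snippet_ms=1.0, seed=18)


class TestPlanting:
    def _setup(self, seed=19, n=40):
        net = synth.generate_topology(n, 0.2, 0.05, seed=seed)
        trains = [
            synth.simulate_spike_trains(net, duration=240.0, seed=seed + k)
            for k in range(2)
        ]
        _, params = synth.synthesize_footprints(net, seed=seed)
        feats = synth.true_feature_matrix(params, np.ones(n))
        fc = synth.true_coupling_graph(net)
        return net, trains, feats, fc

    def test_noiseless_feature_model_recovered(self):
        net, trains, feats, fc = self._setup()
        model = PlantedResponseModel(neighbor_weight=0.0, noise_sd=0.0)
        pert, resp = synth.plant_perturbation(net, trains, feats, fc, model,
                                              n_timepoints=7, seed=20)
        from fcpredict.types import StudyNetwork
        nw = StudyNetwork(truth=net, recordings=trains + pert,
                          true_response=resp)
        s = rate_series(nw, n_baseline=2)
        ids, dfp = neuron_fold_change(s, "maximum")
        truth = resp[ids]
        r2 = 1 - np.sum((dfp - truth) ** 2) / np.sum((truth - truth.mean()) ** 2)
        assert r2 > 0.99

    def test_decrease_fraction_on_large_population(self):
        rng = np.random.default_rng(21)
        feats = rng.normal(size=(1000, 7))
        model = PlantedResponseModel(decrease_fraction=0.09)
        resp = synth.planted_responses(feats, np.zeros((1000, 1000)), model, rng)
        n_neg = (resp < 0).sum()
        assert 60 <= n_neg <= 120  # ~90 of 1,000

    def test_zero_override_measures_near_zero(self):
        net, trains, feats, fc = self._setup(seed=23, n=20)
        model = PlantedResponseModel()
        pert, resp = synth.plant_perturbation(
            net, trains, feats, fc, model, n_timepoints=3, seed=24,
            planted_override=np.zeros(20),
        )
        assert np.all(resp == 0)
        from fcpredict.types import StudyNetwork
        nw = StudyNetwork(truth=net, recordings=trains + pert,
                          true_response=resp)
        s = rate_series(nw, n_baseline=2)
        _, dfp = neuron_fold_change(s, "maximum")
        # max of 3 Poisson re-draws sits slightly above 0 by construction
        assert abs(np.median(dfp)) < 0.2

    def test_graph_mismatch_raises(self):
        net, trains, feats, fc = self._setup(seed=25, n=10)
        bad = synth.true_coupling_graph(synth.generate_topology(10, 0.2, 0.05,
                                                                seed=26))
        bad.node_ids = bad.node_ids + 100
        with pytest.raises(ValueError, match="subset"):
            synth.plant_perturbation(net, trains, feats, bad,
                                     PlantedResponseModel(), seed=27)


class TestStudy:
    def test_study_shape_and_determinism(self, small_study):
        assert len(small_study.networks) == 6
        assert len({nw.truth.chip_id for nw in small_study.networks}) == 3
        for nw in small_study.networks:
            assert len(nw.recordings) == 9
        other = synth.generate_study(
            n_chips=3, networks_per_chip=2, n_neurons=(35, 45), duration=240.0,
            response_model=PlantedResponseModel(neighbor_weight=1.0,
                                                noise_sd=0.5),
            seed=101,
        )
        a = small_study.networks[0].recordings[0][0].spike_times
        b = other.networks[0].recordings[0][0].spike_times
        assert np.array_equal(a, b)

    def test_network_sizes_support_selection_rule(self, small_study):
        sizes = [nw.truth.n_neurons for nw in small_study.networks]
        assert np.mean([s >= 30 for s in sizes]) >= 0.9

    def test_single_chip_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_study(n_chips=1, networks_per_chip=2,
                                 n_neurons=(10, 12), duration=10.0)
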