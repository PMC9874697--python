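"""Functional-connectivity inference: PCC, STTC, surrogates, CCH."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcpredict import connectivity as cn
from fcpredict.synth import generate_topology, simulate_spike_trains
from fcpredict.types import RELATIONS, DirectedRelationalGraph, SpikeTrain


def sttc_oracle(ti, tj, dt, duration, grid=1e-4):
    """Brute-force STTC on a fine time lattice (tiling by enumeration)."""
    ti, tj = np.asarray(ti), np.asarray(tj)
    lattice = np.arange(0, duration, grid) + grid / 2

    def tiled(t):
        hit = np.zeros(lattice.size, dtype=bool)
        for s in t:
            hit |= np.abs(lattice - s) <= dt
        return hit.mean()

    def prop(a, b):
        return np.mean([np.any(np.abs(b - s) <= dt) for s in a])

    t_i, t_j = tiled(ti), tiled(tj)
    p_ij, p_ji = prop(ti, tj), prop(tj, ti)
    total = 0.0
    for p, t in ((p_ij, t_j), (p_ji, t_i)):
        if 1 - p * t != 0:
            total += (p - t) / (1 - p * t)
    return total / 2


class TestBinning:
    def test_half_open_convention(self):
        trains = [SpikeTrain(0, [0.019, 0.020], 1.0)]
        counts = cn.bin_trains(trains, 20.0)
        assert counts[0, 0] == 1 and counts[0, 1] == 1

    def test_conservation_with_partial_bin(self):
        t = np.array([0.001, 0.5, 0.9995])  # duration 1.0 s -> 50 full bins
        counts = cn.bin_trains([SpikeTrain(0, t, 1.0)], 20.0)
        assert counts.sum() == 3  # 1.0 s divides evenly into 20 ms bins

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 5000))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 2.0, 40))
        counts = cn.bin_trains([SpikeTrain(0, t, 2.0)], 20.0)
        brute = np.zeros(100, dtype=int)
        for s in t:
            b = int(s * 1e3 // 20)
            if b < 100:
                brute[b] += 1
        assert np.array_equal(counts[0], brute)

    def test_bad_bin_raises(self):
        with pytest.raises(ValueError):
            cn.bin_trains([SpikeTrain(0, [0.1], 1.0)], 0.0)


class TestPearson:
    def test_identical_and_inverted(self):
        rng = np.random.default_rng(0)
        b = rng.poisson(3, 200).astype(float)
        assert cn.pearson_pair(b, b) == pytest.approx(1.0)
        assert cn.pearson_pair(b, -b + 7) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        b1, b2 = rng.poisson(2, 500), rng.poisson(5, 500)
        cov = np.mean((b1 - b1.mean()) * (b2 - b2.mean()))
        expected = cov / (b1.std() * b2.std())
        assert cn.pearson_pair(b1, b2) == pytest.approx(expected, abs=1e-12)

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            cn.pearson_pair(np.ones(10), np.arange(10.0))


class TestSurrogate:
    def test_preserves_isis_count_and_rate(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 60, 100))
        tr = SpikeTrain(0, t, 60.0)
        sur = cn.surrogate_train(tr, np.random.default_rng(9))
        assert sur.n_spikes == tr.n_spikes
        assert np.allclose(np.sort(np.diff(sur.spike_times)),
                           np.sort(np.diff(t)))
        assert sur.spike_times[0] == t[0]

    def test_short_train_returned_unchanged(self):
        tr = SpikeTrain(0, [1.0, 2.0], 10.0)
        with pytest.warns(UserWarning):
            sur = cn.surrogate_train(tr, np.random.default_rng(0))
        assert np.array_equal(sur.spike_times, tr.spike_times)


class TestSTTC:
    def test_identical_trains_one(self):
        t = np.array([1.0, 5.0, 20.0, 44.0])
        tr = SpikeTrain(0, t, 100.0)
        assert cn.sttc_pair(tr, tr, 10.0) == pytest.approx(1.0)

    def test_symmetry(self):
        a = SpikeTrain(0, [1.0, 2.0, 30.0], 100.0)
        b = SpikeTrain(1, [1.005, 50.0], 100.0)
        assert cn.sttc_pair(a, b) == pytest.approx(cn.sttc_pair(b, a))

    def test_specified_pair_matches_lattice_oracle(self):
        a, b = [1.0, 2.0], [1.005, 50.0]
        got = cn.sttc_pair(SpikeTrain(0, a, 100.0), SpikeTrain(1, b, 100.0), 10.0)
        want = sttc_oracle(a, b, 0.010, 100.0)
        assert got == pytest.approx(want, abs=2e-3)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 5000))
    def test_random_pairs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = np.sort(rng.uniform(0, 20, rng.integers(3, 30)))
        b = np.sort(rng.uniform(0, 20, rng.integers(3, 30)))
        got = cn.sttc_pair(SpikeTrain(0, a, 20.0), SpikeTrain(1, b, 20.0), 10.0)
        want = sttc_oracle(a, b, 0.010, 20.0, grid=2e-4)
        assert got == pytest.approx(want, abs=5e-3)

    def test_empty_train_zero(self):
        a = SpikeTrain(0, [], 10.0)
        b = SpikeTrain(1, [1.0], 10.0)
        with pytest.warns(UserWarning):
            assert cn.sttc_pair(a, b) == 0.0


class TestSurrogateCorrectedFC:
    def test_independent_poisson_mostly_zero(self, poisson_trains):
        trains = poisson_trains(n=12, rate=2.0, duration=120.0, seed=5)
        g = cn.surrogate_corrected_fc(trains, "PCC", n_surrogates=100, seed=1,
                                      drop_isolated=False)
        frac = np.count_nonzero(np.triu(g.weights, 1)) / (12 * 11 / 2)
        assert frac < 0.05

    def test_cobursting_edge_retained(self):
        net = generate_topology(10, 0.0, 0.1, seed=2)
        trains = simulate_spike_trains(net, duration=120.0, seed=3)
        g = cn.surrogate_corrected_fc(trains, "PCC", seed=4, drop_isolated=False)
        assert np.count_nonzero(np.triu(g.weights, 1)) > 10

    def test_weights_positive_no_self_edges(self):
        net = generate_topology(8, 0.2, 0.1, seed=5)
        trains = simulate_spike_trains(net, duration=60.0, seed=6)
        for measure in ("PCC", "STTC"):
            g = cn.surrogate_corrected_fc(trains, measure, n_surrogates=20,
                                          seed=7, drop_isolated=True)
            assert np.all(np.diag(g.weights) == 0)
            assert np.all(g.weights >= 0)
            assert np.all(g.weights.sum(axis=0) > 0)  # no isolated survivors


class TestCCH:
    def test_normalized_bins_centered(self, poisson_trains):
        a, b = poisson_trains(n=2, rate=5.0, duration=60.0, seed=8)
        h = cn.cch(a, b)
        assert abs(h.normalized.sum()) < 1e-9
        assert h.normalized.size == 25

    def test_planted_edge_direction_and_lag(self):
        net = generate_topology(2, 0.0, 0.0, seed=0)
        net.adjacency[0, 1], net.delay[0, 1] = 1.5, 5.0
        trains = simulate_spike_trains(net, duration=300.0, base_rate=2.0,
                                       burst_rate=5.0, coupling_scale=0.4, seed=3)
        h = cn.cch(trains[0], trains[1])
        assert h.label == "excitatory"
        assert 3.0 <= h.peak_lag <= 7.0

    def test_no_spikes_label_none(self):
        h = cn.cch(SpikeTrain(0, [], 10.0), SpikeTrain(1, [1.0], 10.0))
        assert h.label == "none"

    def test_matches_bruteforce_counts(self):
        rng = np.random.default_rng(11)
        a = np.sort(rng.uniform(0, 10, 50))
        b = np.sort(rng.uniform(0, 10, 60))
        h = cn.cch(SpikeTrain(0, a, 10.0), SpikeTrain(1, b, 10.0))
        brute = np.zeros(50, dtype=int)
        for s in a:
            for t in b:
                lag = (t - s) * 1e3
                if -25 <= lag <= 25:
                    idx = min(max(int(np.floor(lag)) + 25, 0), 49)
                    brute[idx] += 1
        assert np.array_equal(h.raw, brute)


class TestVelocityFilter:
    @pytest.mark.parametrize(
        "dist,lag,keep",
        [(1000.0, 2.0, False), (700.0, 2.0, True), (800.0, 2.0, True)],
    )
    def test_reachability_rule(self, dist, lag, keep):
        assert cn.velocity_filter(dist, lag) is keep

    def test_nonpositive_lag_drops(self):
        with pytest.warns(UserWarning):
            assert cn.velocity_filter(10.0, 0.0) is False


class TestThresholdDale:
    def test_peer_threshold_hand_case(self):
        pairs = [(0, 1, "excitatory", v) for v in (1.0, 2.0, 3.0, 10.0)]
        # mu = 4, sigma = sqrt(12.5) -> threshold ~ 7.54: only 10 survives
        kept = cn.peer_threshold(pairs, gamma=1.0)
        assert [p[3] for p in kept] == [10.0]

    def test_gamma_zero_keeps_above_mean(self):
        pairs = [(0, 1, "inhibitory", -v) for v in (1.0, 2.0, 3.0)]
        kept = cn.peer_threshold(pairs, gamma=0.0)
        assert [abs(p[3]) for p in kept] == [3.0]

    def test_equal_values_sigma_zero_strict(self):
        pairs = [(0, 1, "excitatory", 2.0), (1, 2, "excitatory", 2.0)]
        assert cn.peer_threshold(pairs, gamma=1.0) == []

    def test_threshold_monotone_in_gamma(self):
        rng = np.random.default_rng(3)
        pairs = [(i, i + 1, "excitatory", rng.uniform(0, 5)) for i in range(30)]
        prev = None
        for gamma in (0.0, 0.5, 1.0, 1.5, 2.0):
            kept = {(p[0], p[1]) for p in cn.peer_threshold(pairs, gamma)}
            if prev is not None:
                assert kept <= prev
            prev = kept

    def _graph(self, exc_edges, inh_edges, n=5):
        adj = {r: np.zeros((n, n), dtype=int) for r in RELATIONS}
        for i, j in exc_edges:
            adj["excitatory"][i, j] = 1
        for i, j in inh_edges:
            adj["inhibitory"][i, j] = 1
        return DirectedRelationalGraph(np.arange(n), adj)

    def test_dale_minority_removed(self):
        g = self._graph([(0, 1), (0, 2), (0, 3)], [(0, 4)])
        out = cn.apply_dales_law(g)
        assert out.adjacency["inhibitory"].sum() == 0
        assert out.adjacency["excitatory"].sum() == 3

    def test_dale_idempotent_on_consistent(self):
        g = self._graph([(0, 1)], [(2, 3)])
        out = cn.apply_dales_law(g)
        assert np.array_equal(out.adjacency["excitatory"],
                              g.adjacency["excitatory"])
        assert np.array_equal(out.adjacency["inhibitory"],
                              g.adjacency["inhibitory"])

    def test_dale_tie_keeps_excitatory(self):
        g = self._graph([(0, 1), (0, 2)], [(0, 3), (0, 4)])
        out = cn.apply_dales_law(g)
        assert out.adjacency["excitatory"].sum() == 2
        assert out.adjacency["inhibitory"].sum() == 0

    def test_largest_component(self):
        g = self._graph([(0, 1), (1, 2)], [(3, 4)], n=6)
        out = cn.largest_component(g)
        assert set(out.node_ids.tolist()) == {0, 1, 2}
        assert out.n_nodes <= g.n_nodes


class TestDirectedInference:
    def test_output_invariants(self):
        net = generate_topology(15, 0.2, 0.1, seed=9)
        trains = simulate_spike_trains(net, duration=180.0, coupling_scale=0.3,
                                       seed=10)
        g = cn.infer_directed_fc(trains, net.positions, gamma=1.0)
        # Dale consistency
        exc_out = g.adjacency["excitatory"].sum(axis=1)
        inh_out = g.adjacency["inhibitory"].sum(axis=1)
        assert not np.any((exc_out > 0) & (inh_out > 0))
        # no pair in both relations
        assert not np.any(g.adjacency["excitatory"] & g.adjacency["inhibitory"])
        # weakly connected
        import networkx as nx
        G = nx.from_numpy_array(g.union(), create_using=nx.DiGraph)
        if g.n_nodes > 1:
            assert nx.is_weakly_connected(G)

    def test_gamma_monotone_before_pruning(self):
        net = generate_topology(12, 0.2, 0.1, seed=12)
        trains = simulate_spike_trains(net, duration=120.0, coupling_scale=0.3,
                                       seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labeled = cn.label_pairs(trains, net.positions)
            k0 = {(p[0], p[1]) for p in cn.peer_threshold(labeled, 0.0)}
            k2 = {(p[0], p[1]) for p in cn.peer_threshold(labeled, 2.0)}
        assert k2 <= k0
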