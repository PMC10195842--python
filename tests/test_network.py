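"""Connectivity construction and LIF simulation against independent oracles."""

import numpy as np
import pytest

from subsetnet.network import (Network, RecordSpec, build_plastic_connectivity,
                               build_static_connectivity, make_drives,
                               ou_stimulus, poisson_external, run_trial,
                               simulate, subseed, ExternalDrive)
from subsetnet.params import (NeuronParams, PopulationLayout, SynapseParams,
                              NetworkSpec, sine_network_spec)


class TestStaticConnectivity:
    def test_weights_follow_dale_and_scaling(self, tiny_spec):
        conn = build_static_connectivity(tiny_spec.layout, tiny_spec.syn, 0)
        w = conn.weights.tocsr()
        n_e = tiny_spec.layout.N_E
        for i in range(tiny_spec.layout.N):
            cols = w.indices[w.indptr[i]:w.indptr[i + 1]]
            vals = w.data[w.indptr[i]:w.indptr[i + 1]]
            a = 0 if i < n_e else 1
            exc = vals[cols < n_e]
            inh = vals[cols >= n_e]
            # per-row excitatory entries equal and positive, inhibitory
            # equal and negative
            if len(exc):
                assert np.allclose(exc, tiny_spec.syn.jbar[a, 0] / np.sqrt(8))
            if len(inh):
                assert np.allclose(inh, -tiny_spec.syn.jbar[a, 1] / np.sqrt(8))

    def test_no_self_connections(self, tiny_spec):
        conn = build_static_connectivity(tiny_spec.layout, tiny_spec.syn, 3)
        assert conn.weights.diagonal().sum() == 0

    def test_full_block_when_k_equals_pool(self):
        layout = PopulationLayout(6, 6)
        syn = SynapseParams(tau_bal=3.0, tau_plas=150.0,
                            jbar=np.ones((2, 2)), kbar=np.full((2, 2), 6.0))
        conn = build_static_connectivity(layout, syn, 0)
        # p = 1: complete graph minus the diagonal
        assert conn.weights.nnz == 12 * 11

    def test_k_exceeding_pool_rejected(self):
        layout = PopulationLayout(6, 6)
        syn = SynapseParams(tau_bal=3.0, tau_plas=150.0,
                            jbar=np.ones((2, 2)), kbar=np.full((2, 2), 7.0))
        with pytest.raises(ValueError):
            build_static_connectivity(layout, syn, 0)

    def test_in_degree_matches_binomial_sampling(self, tiny_spec):
        """Empirical mean in-degree across seeds within 3 SE of K = 8."""
        n_seeds = 60
        means = np.empty(n_seeds)
        for s in range(n_seeds):
            conn = build_static_connectivity(tiny_spec.layout, tiny_spec.syn,
                                             s)
            means[s] = conn.in_degrees()[:, 0].mean()
        k, pool = 8.0, 20
        se = np.sqrt(k * (1 - k / pool)) / np.sqrt(n_seeds * 40)
        assert abs(means.mean() - k) < 3 * se + 0.05


class TestPlasticConnectivity:
    def _build(self, tiny_spec, trained, l=3, l_x=2, seed=0):
        static = build_static_connectivity(tiny_spec.layout, tiny_spec.syn,
                                           seed)
        wbar = np.array([[2.0, 1.0], [2.0, 1.0]])
        pl = build_plastic_connectivity(tiny_spec.layout, static, trained,
                                        l, l_x, wbar, tiny_spec.syn,
                                        seed + 1)
        return static, pl

    def test_support_disjoint_from_static(self, tiny_spec):
        static, pl = self._build(tiny_spec, np.arange(0, 20))
        assert pl.verify_disjoint(static)

    def test_counts_and_pools_train_e(self, tiny_spec):
        trained = np.arange(0, 10)  # E subnetwork rule
        static, pl = self._build(tiny_spec, trained)
        n_e = tiny_spec.layout.N_E
        for m in range(pl.n_trained):
            pre_e = pl.pre_idx[m, :pl.l_per_pop]
            pre_i = pl.pre_idx[m, pl.l_per_pop:]
            assert np.all(pre_e < n_e)
            assert np.all(pre_i >= n_e)
            # E partners drawn from the other trained E neurons
            assert set(pre_e).issubset(set(trained) - {pl.trained[m]})

    def test_untrained_rows_empty(self, tiny_spec):
        static, pl = self._build(tiny_spec, np.arange(0, 10))
        indptr, rows, wj, pos = pl.to_csc(150.0)
        assert set(rows).issubset(set(range(10)))

    def test_initial_sign_convention(self, tiny_spec):
        static, pl = self._build(tiny_spec, np.arange(0, 10))
        assert np.all(pl.w[:, :pl.l_per_pop] > 0)
        assert np.all(pl.w[:, pl.l_per_pop:pl.l_rec] < 0)

    def test_infeasible_l_raises(self, tiny_spec):
        static = build_static_connectivity(tiny_spec.layout, tiny_spec.syn, 0)
        with pytest.raises(ValueError, match="neuron"):
            build_plastic_connectivity(
                tiny_spec.layout, static, np.arange(0, 4), 10, 0,
                np.ones((2, 2)), tiny_spec.syn, 1)


class TestOUStimulus:
    def test_zero_sigma_is_zero(self, rng):
        x = ou_stimulus(100, 3, 0.1, 20.0, 0.0, rng)
        assert np.all(x == 0)

    def test_stationary_variance(self, rng):
        tau, sigma, dt = 20.0, 0.2, 0.1
        x = ou_stimulus(400000, 4, dt, tau, sigma, rng)
        target = sigma ** 2 * tau / 2
        assert np.var(x[5000:]) == pytest.approx(target, rel=0.1)

    def test_frozen_across_trials_distinct_across_types(self):
        spec = sine_network_spec(40)
        spec.syn.kbar[:] = 8.0
        d1 = make_drives(spec, seed=5, trial_types=("R", "L"))
        d2 = make_drives(spec, seed=5, trial_types=("R", "L"))
        assert np.array_equal(d1.stim["R"], d2.stim["R"])
        assert not np.allclose(d1.stim["R"], d1.stim["L"])


class TestPoissonExternal:
    def test_zero_rate_no_spikes(self):
        spikes, filt = poisson_external(np.zeros((100, 2)), 0.1, 150.0, 0)
        assert spikes.sum() == 0 and np.all(filt == 0)

    def test_count_matches_rate(self):
        rate = np.full((100000, 1), 0.005)  # 5 Hz for 100 s
        spikes, _ = poisson_external(rate, 0.1, 150.0, 1)
        lam = 500.0
        assert abs(spikes.sum() - lam) < 3 * np.sqrt(lam)

    def test_filter_calibration_unit_integral(self):
        """Time-average of the filtered trace equals the rate in spikes/ms."""
        rate = np.full((50000, 1), 0.02)  # 20 Hz
        _, filt = poisson_external(rate, 0.1, 150.0, 2)
        assert filt[20000:].mean() == pytest.approx(0.02, rel=0.1)

    def test_coarse_step_rejected(self):
        with pytest.raises(ValueError, match="too coarse"):
            poisson_external(np.full((10, 1), 20.0), 0.1, 150.0, 0)


def _single_neuron_net(x_drive):
    layout = PopulationLayout(1, 1)
    syn = SynapseParams(tau_bal=3.0, tau_plas=150.0,
                        jbar=np.full((2, 2), 1e-12), kbar=np.ones((2, 2)))
    spec = NetworkSpec(neuron=NeuronParams(), layout=layout, syn=syn,
                       xbar=np.array([x_drive, x_drive]), input_gain=1.0)
    static = build_static_connectivity(layout, syn, 0)
    static.weights.data[:] = 0.0
    return Network(spec=spec, static=static)


class TestSimulate:
    def test_subthreshold_silent(self):
        net = _single_neuron_net(0.5)
        drives = make_drives(net.spec, 0)
        spk, _, _ = simulate(net, drives, 500.0, 2, 0)
        assert len(spk.neuron) == 0

    def test_isolated_neuron_closed_form_isi(self):
        """Constant suprathreshold drive: ISI = τ_m ln((X−v_r)/(X−v_θ))."""
        net = _single_neuron_net(2.0)
        drives = make_drives(net.spec, 0)
        spk, _, _ = simulate(net, drives, 2000.0, 1, 0)
        t = np.sort(spk.time_ms[spk.neuron == 0])
        isi = np.diff(t)
        expected = 10.0 * np.log((2.0 - 0.0) / (2.0 - 1.0))
        assert np.median(isi) == pytest.approx(expected, abs=0.15)

    def test_three_neuron_trajectory_matches_scalar_reimplementation(self):
        """Kernel dynamics equal an independent step-by-step oracle."""
        layout = PopulationLayout(2, 1)
        syn = SynapseParams(tau_bal=3.0, tau_plas=150.0,
                            jbar=np.full((2, 2), 0.5),
                            kbar=np.ones((2, 2)))
        spec = NetworkSpec(neuron=NeuronParams(), layout=layout, syn=syn,
                           xbar=np.array([1.5, 1.2]), input_gain=1.0)
        static = build_static_connectivity(layout, syn, 7)
        net = Network(spec=spec, static=static)
        drives = make_drives(spec, 0)
        rec = RecordSpec(neuron_ids=np.arange(3), stride_ms=0.1)
        seed = 11
        spk_n, spk_t, trace, _, _ = run_trial(net, drives, 5.0, seed,
                                              burn_ms=0.0, record=rec)

        # scalar oracle replicating the forward-Euler update order
        dt, tau_m, tau_b = 0.1, 10.0, 3.0
        v = np.random.default_rng(seed).uniform(0.0, 1.0, 3)
        u = np.zeros(3)
        w = static.weights.toarray()
        x = drives.x_bal.copy()
        u_rec, spikes = [], []
        for t in range(50):
            v += dt / tau_m * (u + x - v)
            sp = v >= 1.0
            v[sp] = 0.0
            u *= 1 - dt / tau_b
            for j in np.where(sp)[0]:
                u += w[:, j] / tau_b
                spikes.append((j, t))
            u_rec.append(u.copy())
        u_rec = np.array(u_rec)
        got_u = trace.u_bal()
        assert np.allclose(got_u, u_rec, atol=1e-12)
        assert [(int(a), int(b)) for a, b in zip(spk_n, spk_t / dt)] == \
            [(a, b) for a, b in spikes]

    def test_input_trace_additivity(self):
        spec = sine_network_spec(60, p=0.2)
        static = build_static_connectivity(spec.layout, spec.syn, 2,
                                           gain=spec.input_gain)
        net = Network(spec=spec, static=static)
        drives = make_drives(spec, 3, trial_types=("A",))
        rec = RecordSpec(neuron_ids=np.arange(0, 60, 7), stride_ms=1.0)
        _, trace, mean_u = simulate(net, drives, 300.0, 1, 5,
                                    trial_type="A", record=rec)
        total = trace.total()
        parts = (trace.u_bal() + trace.traces[:, :, 4]
                 + trace.traces[:, :, 5] + trace.traces[:, :, 6]
                 + trace.x_bal[None, :])
        assert np.allclose(total, parts, atol=1e-10)

    def test_trials_reproducible_and_independent(self):
        spec = sine_network_spec(80, p=0.2)
        static = build_static_connectivity(spec.layout, spec.syn, 2,
                                           gain=spec.input_gain)
        net = Network(spec=spec, static=static)
        drives = make_drives(spec, 3)
        s1, _, _ = simulate(net, drives, 300.0, 2, 9)
        s2, _, _ = simulate(net, drives, 300.0, 2, 9)
        assert np.array_equal(s1.time_ms, s2.time_ms)
        assert np.array_equal(s1.neuron, s2.neuron)
        t0 = s1.time_ms[s1.trial == 0]
        t1 = s1.time_ms[s1.trial == 1]
        assert len(t0) == 0 or len(t1) == 0 or \
            not np.array_equal(t0[:20], t1[:20])
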