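"""Population-analysis operations against hand and simulation oracles."""

import numpy as np
import pytest
from scipy import stats

from subsetnet import analysis as an
from subsetnet.network import SpikeData


def _spikes(trial, neuron, t, dur, n_trials, n_neurons):
    return SpikeData(trial=np.asarray(trial, dtype=np.int32),
                     neuron=np.asarray(neuron, dtype=np.int64),
                     time_ms=np.asarray(t, dtype=float),
                     duration_ms=dur, n_trials=n_trials, n_neurons=n_neurons)


class TestComputePSTH:
    def test_periodic_spikes_give_constant_rate(self):
        t = np.arange(10.0, 1000.0, 100.0)
        spk = _spikes(np.zeros(len(t)), np.zeros(len(t)), t, 1000.0, 1, 1)
        psth = an.compute_psth(spk, bin_ms=20.0, smooth_ms=300.0)
        assert psth.rates.mean() == pytest.approx(10.0, rel=0.05)

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(0)
        n_trials, rate, dur = 400, 20.0, 1000.0
        tr, tt = [], []
        for k in range(n_trials):
            n = rng.poisson(rate * dur / 1000.0)
            tr += [k] * n
            tt += list(rng.uniform(0, dur, n))
        spk = _spikes(tr, np.zeros(len(tr)), tt, dur, n_trials, 1)
        psth = an.compute_psth(spk)
        se = np.sqrt(rate * 1000.0 / (0.02 * n_trials)) / \
            np.sqrt(15)  # smoothing pools ~15 bins
        assert np.all(np.abs(psth.rates - rate) < 3 * np.sqrt(rate / (0.3 * n_trials)) + 1)

    def test_smoothing_window_equal_bin_is_identity(self):
        x = np.random.default_rng(1).random((30, 4))
        assert np.allclose(an.boxcar_smooth(x, 1), x)

    def test_empty_spikes_zero_matrix(self):
        spk = _spikes([], [], [], 200.0, 3, 5)
        psth = an.compute_psth(spk)
        assert psth.rates.shape == (10, 5)
        assert np.all(psth.rates == 0)


class TestPCA:
    def test_rank_one_single_component(self):
        t = np.linspace(0, 1, 50)
        r = np.outer(t, np.array([1.0, 2.0, 3.0]))
        res = an.pca_psth(r)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_direct_svd(self):
        rng = np.random.default_rng(2)
        r = rng.random((5, 4))
        res = an.pca_psth(r)
        rc = r - r.mean(axis=0, keepdims=True)
        s = np.linalg.svd(rc, compute_uv=False)
        assert np.allclose(res.singular_values, s, atol=1e-10)
        # reconstruction from components and loadings
        rec = (res.loadings @ res.components).T + res.mean_rates[None, :]
        assert np.allclose(rec, r, atol=1e-8)

    def test_variance_fractions_sum_to_one_components_orthonormal(self):
        rng = np.random.default_rng(3)
        r = rng.random((40, 20))
        res = an.pca_psth(r)
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        g = res.components @ res.components.T
        assert np.allclose(g, np.eye(g.shape[0]), atol=1e-8)

    def test_mean_subtraction_idempotent(self):
        rng = np.random.default_rng(4)
        r = rng.random((30, 10))
        res1 = an.pca_psth(r)
        res2 = an.pca_psth(r - r.mean(axis=0, keepdims=True))
        assert np.allclose(res1.singular_values, res2.singular_values)


class TestTransferredActivity:
    def test_identical_population_fidelity_one(self):
        rng = np.random.default_rng(5)
        r = rng.random((50, 30))
        a = an.pca_psth(r)
        fid = an.pc_fidelity(a, a, 4)
        assert np.allclose(fid, 1.0)

    def test_sign_flip_invariant(self):
        rng = np.random.default_rng(6)
        r = rng.random((50, 30))
        a = an.pca_psth(r)
        fid = an.pc_fidelity(a.components, -a.components, 3)
        assert np.allclose(fid, 1.0)

    def test_white_noise_fraction_near_k_over_t(self):
        rng = np.random.default_rng(7)
        t, m, k = 100, 400, 6
        r = rng.standard_normal((t, m))
        ref = an.pca_psth(rng.standard_normal((t, 20))).components
        frac = an.transferred_activity(r, k, reference_pcs=ref)
        assert frac == pytest.approx(k / t, rel=0.4)

    def test_k_beyond_rank_rejected(self):
        r = np.random.default_rng(8).random((4, 3))
        with pytest.raises(ValueError):
            an.transferred_activity(r, 10)


class TestSharedVariance:
    def test_duplicate_population_matches_direct_svd_oracle(self):
        rng = np.random.default_rng(9)
        base = np.outer(np.linspace(0, 1, 60), np.ones(20))
        f = base + 0.01 * rng.standard_normal(base.shape)
        res = an.shared_variance(f, f)
        # independent oracle: per-pair Pearson correlations, plain SVD
        c = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                c[i, j] = np.corrcoef(f[:, i], f[:, j])[0, 1]
        u, s, vt = np.linalg.svd(c)
        fc = f - f.mean(axis=0, keepdims=True)
        alpha = fc @ u
        fr = (alpha ** 2).sum(axis=0)
        assert res.fractions_f[0] == pytest.approx(fr[0] / fr.sum(),
                                                   rel=1e-6)
        assert res.fractions_f[0] > 0.95  # near-identical columns
        # alpha_1 and beta_1 proportional for identical populations
        cc = np.corrcoef(res.shared_f[:, 0], res.shared_g[:, 0])[0, 1]
        assert abs(cc) > 0.999

    def test_fractions_sum_to_one_and_permutation_invariant(self):
        rng = np.random.default_rng(10)
        f = rng.random((40, 12))
        g = rng.random((40, 8))
        res = an.shared_variance(f, g)
        assert res.fractions_f.sum() == pytest.approx(1.0)
        assert res.fractions_g.sum() == pytest.approx(1.0)
        perm = rng.permutation(12)
        res_p = an.shared_variance(f[:, perm], g)
        assert np.allclose(np.sort(res_p.singular_values),
                           np.sort(res.singular_values), atol=1e-10)

    def test_independent_noise_below_permutation_null(self):
        rng = np.random.default_rng(11)
        f = rng.standard_normal((100, 50))
        g = rng.standard_normal((100, 50))
        lead = an.shared_variance(f, g).singular_values[0]
        null = []
        for _ in range(20):
            gp = g[rng.permutation(100)]
            null.append(an.shared_variance(f, gp).singular_values[0])
        assert lead < np.percentile(null, 95) * 1.1

    def test_zero_variance_neuron_zeroed(self):
        f = np.random.default_rng(12).random((30, 3))
        f[:, 1] = 5.0
        res = an.shared_variance(f, f)
        assert np.all(res.correlations[1, :] == 0)


class TestChoiceSelectivity:
    def test_identical_conditions_zero(self):
        r = np.random.default_rng(13).random((20, 5)) + 1
        _, s = an.choice_selectivity(r, r)
        assert np.allclose(s, 0.0)

    def test_hand_case_two_thirds(self):
        r_l = np.full((10, 1), 6.0)
        r_r = 2 * r_l
        _, s = an.choice_selectivity(r_r, r_l)
        assert s[0] == pytest.approx(2.0 / 3.0)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(14)
        a = rng.random((20, 6)) + 0.5
        b = rng.random((20, 6)) + 0.5
        _, s1 = an.choice_selectivity(a, b)
        _, s2 = an.choice_selectivity(b, a)
        assert np.allclose(s1, -s2)

    def test_zero_rate_excluded(self):
        r = np.zeros((10, 2))
        r[:, 0] = 3.0
        _, s = an.choice_selectivity(r, r * 0.5)
        assert np.isnan(s[1]) and np.isfinite(s[0])


class TestChoiceMode:
    def _toy_rates(self):
        # 2 neurons, 4 trials each: R prefers neuron 0
        t = np.ones((4, 30, 2))
        r = t.copy()
        r[:, :, 0] = 10.0
        r[:, :, 1] = 2.0
        l = t.copy()
        l[:, :, 0] = 4.0
        l[:, :, 1] = 8.0
        return r, l

    def test_norm_is_inverse_sqrt_n(self):
        r, l = self._toy_rates()
        time = np.arange(30.0)
        # needs >= 10 neurons by default; relax for the toy case
        mode = an.choice_mode(np.tile(r, (1, 1, 6)), np.tile(l, (1, 1, 6)),
                              time, (10.0, 30.0))
        assert np.linalg.norm(mode.choice) == pytest.approx(
            1.0 / np.sqrt(12))

    def test_hand_projection(self):
        r, l = self._toy_rates()
        time = np.arange(30.0)
        mode = an.choice_mode(r, l, time, (0.0, 30.0), min_neurons=2)
        d = np.array([6.0, -6.0])
        expect = d / (np.sqrt(2) * np.linalg.norm(d))
        assert np.allclose(mode.choice, expect)
        p_c, p_h = an.project_modes(r, mode)
        assert p_c[0, 0] == pytest.approx(np.array([10, 2]) @ expect)
        assert p_h[0, 0] == pytest.approx(6.0)

    def test_uniform_population_homogeneous_is_rate(self):
        rates = np.full((3, 20, 15), 10.0)
        mode = an.ModeProjection(choice=np.ones(15) / np.sqrt(15) ** 2)
        _, p_h = an.project_modes(rates, mode)
        assert np.allclose(p_h, 10.0)

    def test_identical_averages_rejected(self):
        r = np.ones((4, 10, 12))
        with pytest.raises(ValueError):
            an.choice_mode(r, r, np.arange(10.0), (0.0, 10.0))


class TestRecoveryTime:
    def test_identical_ensembles_undefined(self):
        rng = np.random.default_rng(15)
        base = rng.standard_normal((20, 50))
        res = an.recovery_time(base, base + 0 * base, np.arange(50.0),
                               (10.0, 20.0), (20.0, 50.0))
        assert not res.included
        assert res.recovery_time_ms is None

    def test_fast_recovers_before_slow(self):
        """Step perturbations decaying with τ = 50 vs 500 ms: the estimated
        recovery time orders fast < slow in nearly all replicates."""
        t = np.arange(0, 1000.0, 20.0)
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            recs = {}
            for tau in (50.0, 500.0):
                step = np.where(t < 200, 1.0, np.exp(-(t - 200) / tau)) * 5.0
                pert = step[None, :] + rng.standard_normal((40, len(t))) * 0.5
                base = rng.standard_normal((40, len(t))) * 0.5
                res = an.recovery_time(pert, base, t, (0.0, 200.0),
                                       (200.0, 1000.0))
                recs[tau] = res.recovery_time_ms
            if recs[50.0] is not None and recs[500.0] is not None and \
                    recs[50.0] < recs[500.0]:
                wins += 1
        assert wins >= 0.95 * n_rep

    def test_exponential_fit_exact_on_noiseless_decay(self):
        t = np.arange(0, 500.0, 10.0)
        tau = 80.0
        delta = np.where(t < 100, 2.0, 2.0 * np.exp(-(t - 100) / tau))
        pert = np.tile(delta, (6, 1))
        base = np.zeros_like(pert)
        pert += np.random.default_rng(0).standard_normal(pert.shape) * 1e-9
        base += np.random.default_rng(1).standard_normal(base.shape) * 1e-9
        res = an.recovery_time(pert, base, t, (0.0, 100.0), (100.0, 500.0))
        assert res.decay_rate_per_ms == pytest.approx(1 / tau, rel=0.05)


class TestSpikeStats:
    def test_homogeneous_poisson_fano_and_cv_near_one(self):
        rng = np.random.default_rng(16)
        tr, nr, tt = [], [], []
        for k in range(60):
            for i in range(20):
                n = rng.poisson(30)
                tr += [k] * n
                nr += [i] * n
                tt += list(np.sort(rng.uniform(0, 1000.0, n)))
        spk = _spikes(tr, nr, tt, 1000.0, 60, 20)
        st = an.spike_stats(spk)
        assert st.fano == pytest.approx(1.0, abs=0.15)
        assert np.nanmedian(st.isi_cv) == pytest.approx(1.0, abs=0.15)

    def test_periodic_trains_zero(self):
        t = np.arange(5.0, 1000.0, 25.0)
        tr, nr, tt = [], [], []
        for k in range(10):
            tr += [k] * len(t)
            nr += [0] * len(t)
            tt += list(t)
        spk = _spikes(tr, nr, tt, 1000.0, 10, 1)
        st = an.spike_stats(spk)
        assert st.fano == pytest.approx(0.0, abs=1e-12)
        assert np.nanmax(st.isi_cv) == pytest.approx(0.0, abs=1e-12)

    def test_doubly_stochastic_matches_closed_form(self):
        """Rate drawn per trial from {10, 30} Hz: Fano = 1 + var(λ)T/mean(λT)."""
        rng = np.random.default_rng(17)
        tr, nr, tt = [], [], []
        n_trials = 2000
        for k in range(n_trials):
            lam = 10.0 if rng.random() < 0.5 else 30.0
            n = rng.poisson(lam)
            tr += [k] * n
            nr += [0] * n
            tt += list(rng.uniform(0, 1000.0, n))
        spk = _spikes(tr, nr, tt, 1000.0, n_trials, 1)
        st = an.spike_stats(spk)
        expected = 1.0 + 100.0 / 20.0  # var 100, mean 20 counts
        assert st.fano == pytest.approx(expected, rel=0.15)


class TestGaussianLoadingTest:
    def test_normal_samples_rarely_rejected(self):
        rej = 0
        for s in range(40):
            x = np.random.default_rng(s).standard_normal(300)
            _, p, _, _ = an.gaussian_loading_test(x)
            rej += p < 0.01
        assert rej <= 4

    def test_uniform_samples_rejected(self):
        rej = 0
        for s in range(40):
            x = np.random.default_rng(100 + s).uniform(size=500)
            _, p, _, _ = an.gaussian_loading_test(x)
            rej += p < 0.01
        assert rej >= 36

    def test_constant_degenerate(self):
        stat, p, mu, sd = an.gaussian_loading_test(np.full(100, 2.0))
        assert np.isnan(stat) and sd == 0.0
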