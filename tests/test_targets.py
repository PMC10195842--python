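"""Transfer-function, target-generation, and matching tests."""

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss
from scipy import stats
from scipy.special import erfcx

from subsetnet import targets as tg
from subsetnet.analysis import pca_psth
from subsetnet.params import PopulationLayout


def phi_gauss_legendre(m, sigma, tau_m=10.0, vthr=1.0, vr=0.0, deg=400):
    """Independent fixed-order quadrature oracle for the LIF transfer
    function (Gauss-Legendre, not adaptive)."""
    a, b = (vr - m) / sigma, (vthr - m) / sigma
    x, w = leggauss(deg)
    t = 0.5 * (b - a) * x + 0.5 * (a + b)
    integral = 0.5 * (b - a) * np.sum(w * erfcx(-t))
    return 1000.0 / (tau_m * np.sqrt(np.pi) * integral)


class TestRicciardi:
    def test_deep_subthreshold_is_zero_and_monotone(self):
        m = np.linspace(-30, 2.5, 60)
        r = tg.ricciardi_rate(m, 0.3)
        assert r[0] == 0.0
        assert np.all(np.diff(r[r > 0]) > 0)

    def test_small_sigma_approaches_deterministic_limit(self):
        m = 2.0
        expected = 1000.0 / (10.0 * np.log((m - 0.0) / (m - 1.0)))
        assert tg.ricciardi_rate(m, 1e-3) == pytest.approx(expected, rel=1e-3)

    def test_against_quadrature_oracle(self):
        # frozen from the independent Gauss-Legendre oracle
        assert tg.ricciardi_rate(0.9, 0.3) == pytest.approx(
            35.27376359688292, rel=1e-8)
        for m in (-0.5, 0.2, 0.7, 1.3):
            assert tg.ricciardi_rate(m, 0.4) == pytest.approx(
                phi_gauss_legendre(m, 0.4), rel=1e-8)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            tg.ricciardi_rate(0.5, 0.0)


class TestInvertTransfer:
    @pytest.mark.parametrize("rate", [0.5, 4.2, 11.0, 40.0])
    def test_round_trip(self, rate):
        m = tg.invert_transfer(rate, 0.3)
        assert tg.ricciardi_rate(m, 0.3) == pytest.approx(rate, rel=1e-6)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            tg.invert_transfer(0.0, 0.3)

    def test_monotone_in_rate(self):
        ms = [tg.invert_transfer(r, 0.25) for r in (0.2, 1, 5, 20, 60)]
        assert np.all(np.diff(ms) > 0)


class TestSineTargets:
    def test_zero_amplitude_constant_baselines(self):
        spec = tg.SineSpec(amplitude=0.0)
        ts = tg.make_sine_targets(spec, np.array([0.3, 0.7]),
                                  np.array([0, 1]), 0)
        assert np.allclose(ts.f, [[0.3] * 200, [0.7] * 200])

    def test_pca_yields_fourier_pair(self):
        """Centered random-phase sines span exactly {sin, cos}."""
        spec = tg.SineSpec(amplitude=0.5, freq_hz=2.0, t_target_ms=1000.0,
                           n_bins=100)
        b = np.zeros(80)
        ts = tg.make_sine_targets(spec, b, np.arange(80), 3)
        res = pca_psth(ts.f.T)
        assert res.variance_fractions[:2].sum() > 0.999

    def test_amplitude_and_offset(self):
        spec = tg.SineSpec(amplitude=0.5, freq_hz=1.0)
        ts = tg.make_sine_targets(spec, np.array([1.0]), np.array([0]), 1)
        assert ts.f.min() >= 0.5 - 1e-9
        assert ts.f.max() <= 1.5 + 1e-9


class TestPSTHToTargets:
    def test_constant_rate_single_inversion(self):
        psth = np.full((2, 10), 7.0)
        ts = tg.psth_to_targets(psth, 0.3, 2000.0, np.array([3, 4]))
        m = tg.invert_transfer(7.0, 0.3)
        assert np.allclose(ts.f, m, atol=1e-5)

    def test_monotone_ramp_preserved(self):
        psth = np.linspace(1, 30, 50)[None, :]
        ts = tg.psth_to_targets(psth, 0.3, 2000.0, np.array([0]))
        assert np.all(np.diff(ts.f[0]) > 0)

    def test_round_trip_rates(self):
        rng = np.random.default_rng(0)
        psth = rng.uniform(0.5, 40.0, size=(5, 20))
        ts = tg.psth_to_targets(psth, 0.35, 2000.0, np.arange(5))
        back = np.array([[tg.ricciardi_rate(v, 0.35) for v in row]
                         for row in ts.f])
        assert np.allclose(back, psth, rtol=1e-4)


class TestSyntheticPSTHs:
    def test_basis_orthonormal_with_ramp(self):
        spec = tg.pyramidal_spec()
        b = spec.basis()
        assert np.allclose(b @ b.T, np.eye(spec.d), atol=1e-10)
        assert b[0, -1] > b[0, 0]  # leading mode ramps upward

    def test_zero_multiplier_flat(self):
        spec = tg.SyntheticPSTHSpec(multiplier=0.0)
        pair = tg.make_synthetic_psths(spec, 20, 0)
        assert np.allclose(pair.r.std(axis=1), 0.0)

    def test_mode_count_captures_variance(self):
        """All centered variance lives in the d construction modes."""
        pair = tg.make_synthetic_psths(tg.pyramidal_spec(), 300, 1)
        res = pca_psth(pair.r.T)
        assert res.variance_fractions[:9].sum() > 0.95

    def test_six_mode_share_near_spec(self):
        spec = tg.pyramidal_spec()
        pair = tg.make_synthetic_psths(spec, 2000, 2)
        res = pca_psth(pair.r.T)
        assert res.variance_fractions[:6].sum() == pytest.approx(0.81,
                                                                 abs=0.06)

    def test_rate_distribution_lognormal(self):
        spec = tg.pyramidal_spec()
        pair = tg.make_synthetic_psths(spec, 2000, 3)
        mu_ln = np.log(4.2) - 0.5
        ref = np.random.default_rng(9).lognormal(mu_ln, 1.0, 4000)
        _, p = stats.ks_2samp(pair.rates_hz, ref)
        assert p > 0.01

    def test_loading_grows_with_rate(self):
        pair = tg.make_synthetic_psths(tg.pyramidal_spec(), 1000, 4)
        mod = pair.r.std(axis=1)
        rate = pair.r.mean(axis=1)
        assert np.corrcoef(rate, mod)[0, 1] > 0.5

    def test_selectivity_symmetric_across_seeds(self):
        """The construction has no built-in condition preference: within one
        draw the heavy-tailed rate sample shifts most pairs the same way,
        but the preferred side is symmetric across seeds."""
        means = []
        for s in range(16):
            pair = tg.make_synthetic_psths(tg.pyramidal_spec(), 400, s)
            means.append(np.mean(pair.r.mean(axis=1) - pair.l.mean(axis=1)))
        means = np.array(means)
        assert (means > 0).any() and (means < 0).any()
        assert abs(means.mean()) < 3 * means.std(ddof=1) / np.sqrt(len(means))

    def test_fast_spiking_spec_stronger(self):
        e = tg.make_synthetic_psths(tg.pyramidal_spec(), 500, 6)
        i = tg.make_synthetic_psths(tg.fast_spiking_spec(), 500, 6)
        assert i.r.mean() > e.r.mean()
        assert i.r.std(axis=1).mean() > e.r.std(axis=1).mean()


class TestMatching:
    def test_identical_multisets_zero_score(self):
        rates = np.array([3.0, 1.0, 7.0, 5.0])
        m = tg.match_neurons_by_rate(rates, np.arange(4),
                                     np.array([5.0, 7.0, 1.0, 3.0]))
        assert m.score == 0.0
        assert sorted(m.model_ids.tolist()) == [0, 1, 2, 3]

    def test_matches_exhaustive_greedy(self):
        rng = np.random.default_rng(2)
        model = rng.uniform(0, 20, 5)
        target = rng.uniform(0, 20, 5)
        got = tg.match_neurons_by_rate(model, np.arange(5), target)
        # independent re-enactment of the greedy procedure
        free = list(range(5))
        assign = {}
        for t in np.argsort(target)[::-1]:
            j = min(free, key=lambda j: abs(model[j] - target[t]))
            free.remove(j)
            assign[t] = j
        assert [assign[t] for t in range(5)] == got.model_ids.tolist()

    def test_disjoint_supports_still_bijective(self):
        m = tg.match_neurons_by_rate(np.array([0.1, 0.2, 0.3]),
                                     np.array([10, 11, 12]),
                                     np.array([50.0, 60.0]))
        assert len(set(m.model_ids)) == 2
        assert m.score > 0

    def test_pool_too_small(self):
        with pytest.raises(ValueError):
            tg.match_neurons_by_rate(np.array([1.0]), np.array([0]),
                                     np.array([1.0, 2.0]))
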