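"""Target synaptic-input generation.

Targets are the time courses the *total synaptic input* of each trained
neuron should follow.  Three routes are provided:

* random-phase sinusoids riding on each neuron's baseline input;
* conversion of firing-rate PSTHs to input targets by inverting the
  Ricciardi transfer function of the leaky integrate-and-fire neuron;
* a parametric generator of cortical-like PSTHs (log-normal rates,
  low-dimensional temporal structure dominated by a ramping mode, paired
  lick-left/lick-right conditions with choice selectivity) emulating
  delay-period activity in mouse anterior lateral motor cortex (ALM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize
from scipy.interpolate import PchipInterpolator
from scipy.special import erfcx

from .params import NeuronParams

__all__ = [
    "TransferFunction", "SineSpec", "TargetSet", "SyntheticPSTHSpec",
    "NeuronMatching", "PSTHPair",
    "ricciardi_rate", "invert_transfer", "estimate_sigma",
    "make_sine_targets", "psth_to_targets", "make_synthetic_psths",
    "match_neurons_by_rate", "pyramidal_spec", "fast_spiking_spec",
]

log = logging.getLogger(__name__)

_RATE_FLOOR_HZ = 0.1  # Ricciardi inversion is undefined at 0 Hz


@dataclass(frozen=True)
class TransferFunction:
    """LIF transfer function parameters: φ(m, σ) in Hz for mean input m."""

    tau_m: float = 10.0
    v_thr: float = 1.0
    v_reset: float = 0.0


def ricciardi_rate(m, sigma: float, tf: TransferFunction = TransferFunction()):
    """Mean first-passage-time firing rate of the LIF neuron, in Hz.

        φ(m, σ) = τ_m⁻¹ [ √π ∫_{(v_r−m)/σ}^{(v_θ−m)/σ} erfcx(−w) dw ]⁻¹

    using the scaled complementary error function erfcx(−w) = e^{w²}erfc(−w)
    so the integrand never overflows on the numerically relevant range;
    deep-subthreshold inputs return 0.  Strictly increasing in m.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    m_arr = np.atleast_1d(np.asarray(m, dtype=float))
    out = np.empty_like(m_arr)
    for k, mk in enumerate(m_arr):
        lo = (tf.v_reset - mk) / sigma
        hi = (tf.v_thr - mk) / sigma
        if lo > 25.0 or hi > 26.0:
            # integrand ~ 2 e^{w²}; the integral is astronomically large
            out[k] = 0.0
            continue
        val, _ = integrate.quad(lambda w: erfcx(-w), lo, hi, limit=200)
        out[k] = 1000.0 / (tf.tau_m * np.sqrt(np.pi) * val)
    return out[0] if np.isscalar(m) or np.ndim(m) == 0 else out


def invert_transfer(rate_hz: float, sigma: float,
                    tf: TransferFunction = TransferFunction(),
                    tol: float = 1e-10) -> float:
    """Mean input m with φ(m, σ) = rate, by bracketed root finding.

    Raises ``ValueError`` for rates outside the achievable bracket
    (rate ≤ 0, or beyond the expanding search bracket).
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    lo = tf.v_reset - 30.0 * sigma - 5.0
    hi = tf.v_thr + max(sigma, 0.5)
    for _ in range(60):
        if ricciardi_rate(hi, sigma, tf) >= rate_hz:
            break
        hi += max(sigma, 0.5)
    else:
        raise ValueError(f"rate {rate_hz} Hz outside achievable bracket")
    if ricciardi_rate(lo, sigma, tf) > rate_hz:
        raise ValueError(f"rate {rate_hz} Hz below bracket floor")
    return float(optimize.brentq(
        lambda m: ricciardi_rate(m, sigma, tf) - rate_hz, lo, hi, xtol=tol))


def estimate_sigma(trace, layout, highpass_ms: float = 100.0,
                   stride_ms: float = 1.0, effective: bool = True,
                   tau_m: float = 10.0,
                   tau_bal: float = 3.0) -> tuple[float, float]:
    """Per-population input-fluctuation size from recorded balanced inputs.

    For every recorded neuron the slow trend (moving average over
    ``highpass_ms``) is removed from u_bal and the standard deviation over
    time of the fast residual is taken; σ_α is the mean over recorded
    neurons of population α.  The recording must cover at least 1 s.

    With ``effective`` (default) the measured SD is converted to the
    white-noise-equivalent fluctuation the transfer function expects, via
    the colored-noise correction √(2·τ_bal/(τ_bal + τ_m)) — the input is
    filtered once more by the membrane, so its raw SD overstates the
    voltage noise.  Verified against the measured rate/input relation of
    the untrained network (see docs/methods.md).
    """
    u = trace.u_bal()
    if u.shape[0] * stride_ms < 1000.0:
        raise ValueError("recording too short to estimate sigma (need >= 1 s)")
    win = max(1, int(round(highpass_ms / stride_ms)))
    kern = np.ones(win) / win
    slow = np.apply_along_axis(
        lambda x: np.convolve(x, kern, mode="same"), 0, u)
    fast = u - slow
    sd = fast.std(axis=0)
    if effective:
        sd = sd * np.sqrt(2.0 * tau_bal / (tau_bal + tau_m))
    is_e = trace.neuron_ids < layout.N_E
    sig_e = float(sd[is_e].mean()) if is_e.any() else 0.0
    sig_i = float(sd[~is_e].mean()) if (~is_e).any() else 0.0
    return sig_e, sig_i


def fit_sigma_to_rates(mean_inputs: np.ndarray, rates_hz: np.ndarray,
                       tf: TransferFunction = TransferFunction(),
                       rate_floor_hz: float = 0.2,
                       bracket: tuple = (0.02, 2.0)) -> float:
    """Effective transfer-function fluctuation fitted to the network itself.

    Given per-neuron time-mean inputs and firing rates of the untrained
    network, finds the σ for which φ(m_i, σ) best reproduces the observed
    rates (least squares in log-rate, neurons below ``rate_floor_hz``
    excluded).  This self-calibration absorbs the colored-noise and
    finite-K corrections that an analytic fluctuation estimate misses; it
    is what the PSTH→input inversion should use.
    """
    m = np.asarray(mean_inputs, dtype=float)
    r = np.asarray(rates_hz, dtype=float)
    keep = r >= rate_floor_hz
    if keep.sum() < 5:
        raise ValueError("too few active neurons to fit sigma")
    m, r = m[keep], r[keep]

    def loss(sig):
        pred = np.asarray(ricciardi_rate(m, sig, tf))
        return np.mean((np.log(pred + 1e-3) - np.log(r + 1e-3)) ** 2)

    res = optimize.minimize_scalar(loss, bounds=bracket, method="bounded",
                                   options={"xatol": 1e-4})
    return float(res.x)


def fit_transfer_to_rates(mean_inputs: np.ndarray, rates_hz: np.ndarray,
                          tf: TransferFunction = TransferFunction(),
                          rate_floor_hz: float = 0.2) -> tuple[float, float]:
    """Two-parameter empirical transfer calibration: φ(m − δ, σ).

    Fits the fluctuation σ and an input offset δ so the LIF transfer
    function reproduces the untrained network's per-neuron (mean input,
    rate) relation; δ absorbs finite-K/shot-noise biases of the diffusion
    approximation.  Returns (σ, δ); a target input for rate r is then
    φ⁻¹(r; σ) + δ.
    """
    m = np.asarray(mean_inputs, dtype=float)
    r = np.asarray(rates_hz, dtype=float)
    keep = r >= rate_floor_hz
    if keep.sum() < 5:
        raise ValueError("too few active neurons to fit the transfer")
    m, r = m[keep], r[keep]

    def loss(theta):
        sig, delta = theta
        if sig <= 0.01:
            return 1e9
        pred = np.asarray(ricciardi_rate(m - delta, sig, tf))
        return np.mean((np.log(pred + 1e-3) - np.log(r + 1e-3)) ** 2)

    res = optimize.minimize(loss, x0=np.array([0.3, 0.0]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-8})
    sig, delta = res.x
    return float(sig), float(delta)


# ---------------------------------------------------------------------------
# target containers


@dataclass
class TargetSet:
    """Per-trained-neuron synaptic-input targets on a uniform grid."""

    f: np.ndarray                # (M, T_bins)
    t_target_ms: float
    neuron_ids: np.ndarray       # model-neuron index per row

    def __post_init__(self):
        if not np.all(np.isfinite(self.f)):
            raise ValueError("targets must be finite")

    @property
    def n_bins(self) -> int:
        return self.f.shape[1]

    def time_axis(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.t_target_ms / self.n_bins


@dataclass(frozen=True)
class SineSpec:
    amplitude: float = 0.5
    freq_hz: float = 1.0
    t_target_ms: float = 1000.0
    n_bins: int = 200

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


def make_sine_targets(spec: SineSpec, baselines: np.ndarray,
                      neuron_ids: np.ndarray, seed: int) -> TargetSet:
    """f_i(t) = a·sin(2πf·t + φ_i) + b_i with phases uniform on [0, 2π).

    ``baselines`` are the mean synaptic inputs of the neurons in the
    untrained network (offsets b_i).
    """
    rng = np.random.default_rng(seed)
    neuron_ids = np.asarray(neuron_ids)
    b = np.asarray(baselines, dtype=float)
    if len(b) != len(neuron_ids):
        raise ValueError("baselines must match neuron_ids")
    phases = rng.uniform(0, 2 * np.pi, len(b))
    t = (np.arange(spec.n_bins) + 0.5) * spec.t_target_ms / spec.n_bins
    omega = 2 * np.pi * spec.freq_hz / 1000.0
    f = spec.amplitude * np.sin(omega * t[None, :] + phases[:, None]) \
        + b[:, None]
    return TargetSet(f=f, t_target_ms=spec.t_target_ms, neuron_ids=neuron_ids)


def psth_to_targets(psth_hz: np.ndarray, sigma: float,
                    t_target_ms: float, neuron_ids: np.ndarray,
                    tf: TransferFunction = TransferFunction(),
                    n_grid: int = 2000, offset: float = 0.0) -> TargetSet:
    """Convert firing-rate PSTHs (M, T) in Hz to input targets.

    Each bin is inverted through the population's transfer function.  Rates
    below 0.1 Hz are clipped to that floor before inversion (the inverse is
    undefined at 0); clipping is logged.  The inverse is evaluated through a
    dense monotone (PCHIP) interpolant of φ, accurate to better than 1e-6
    relative over the tabulated range.
    """
    psth = np.asarray(psth_hz, dtype=float)
    n_clip = int(np.count_nonzero(psth < _RATE_FLOOR_HZ))
    if n_clip:
        log.info("psth_to_targets: clipped %d bins below %.1f Hz",
                 n_clip, _RATE_FLOOR_HZ)
    psth = np.clip(psth, _RATE_FLOOR_HZ, None)
    m_lo = invert_transfer(_RATE_FLOOR_HZ * 0.9, sigma, tf)
    m_hi = invert_transfer(psth.max() * 1.1, sigma, tf)
    m_grid = np.linspace(m_lo, m_hi, n_grid)
    r_grid = ricciardi_rate(m_grid, sigma, tf)
    inv = PchipInterpolator(r_grid, m_grid)
    f = inv(psth) + offset
    return TargetSet(f=f, t_target_ms=t_target_ms,
                     neuron_ids=np.asarray(neuron_ids))


# ---------------------------------------------------------------------------
# synthetic cortical-like PSTHs

# Per-mode variance shares of the default spectrum: a dominant ramp plus a
# slowly decaying tail; the first six modes carry ~81% of the centered
# variance, all nine carry it fully.
_DEFAULT_SHARES = np.array(
    [0.41, 0.105, 0.085, 0.075, 0.070, 0.065, 0.065, 0.063, 0.062])


@dataclass(frozen=True)
class SyntheticPSTHSpec:
    """Parametric model of delay-period cortical PSTHs.

    Rates are log-normal with the given mean; each neuron's centered PSTH is
    a random combination of ``d`` orthonormal temporal modes (mode 1 a ramp)
    with per-mode loading scale k_n = modulation·√share_n·rate-coupling, so
    that rate modulation grows with baseline rate and the leading mode
    dominates.  ``multiplier`` rescales all loadings (relative strength of
    modulation); 1 reproduces the baseline spec.
    """

    d: int = 9
    n_bins: int = 100
    t_target_ms: float = 2000.0
    mean_rate_hz: float = 4.2
    sigma_log: float = 1.0
    mod_frac: float = 0.5          # modulation SD / baseline rate at coupling 1
    shares: np.ndarray = field(default_factory=lambda: _DEFAULT_SHARES.copy())
    rate_coupling: float = 1.0     # exponent of rate in the loading scale
    multiplier: float = 1.0

    def __post_init__(self):
        shares = np.asarray(self.shares, dtype=float)
        object.__setattr__(self, "shares", shares)
        if self.d < 1 or len(shares) < self.d:
            raise ValueError("need at least d variance shares")
        if np.any(shares[:self.d] <= 0):
            raise ValueError("variance shares must be positive")

    def basis(self) -> np.ndarray:
        """Orthonormal temporal modes (d, T): ramp then smooth cosines."""
        t = np.linspace(0, 1, self.n_bins)
        cols = [t - t.mean()]
        for n in range(1, self.d):
            cols.append(np.cos(np.pi * n * t))
        q, _ = np.linalg.qr(np.stack(cols, axis=1))
        # fix signs: ramp increasing, cosines starting positive
        for n in range(self.d):
            if q[-1, n] < q[0, n]:
                q[:, n] = -q[:, n]
        return q.T


def pyramidal_spec(**kw) -> SyntheticPSTHSpec:
    """Excitatory (pyramidal-like) spec: mean rate 4.2 Hz."""
    kw.setdefault("mean_rate_hz", 4.2)
    return SyntheticPSTHSpec(**kw)


def fast_spiking_spec(**kw) -> SyntheticPSTHSpec:
    """Inhibitory (fast-spiking-like) spec: mean rate 11 Hz and uniformly
    1.5× stronger per-mode loadings than the pyramidal spec."""
    kw.setdefault("mean_rate_hz", 11.0)
    kw.setdefault("multiplier", 1.5)
    return SyntheticPSTHSpec(**kw)


@dataclass
class PSTHPair:
    """Paired lick-right / lick-left synthetic PSTHs (M, T), Hz."""

    r: np.ndarray
    l: np.ndarray
    t_target_ms: float
    rates_hz: np.ndarray     # per-pair mean rate (average of conditions)

    @property
    def n_neurons(self) -> int:
        return self.r.shape[0]


def _one_condition(spec: SyntheticPSTHSpec, m: int,
                   rng: np.random.Generator):
    mu_ln = np.log(spec.mean_rate_hz) - spec.sigma_log ** 2 / 2.0
    rates = rng.lognormal(mu_ln, spec.sigma_log, m)
    basis = spec.basis()[:spec.d] * np.sqrt(spec.n_bins)  # unit-RMS rows
    z = rng.standard_normal((m, spec.d))
    scale = rates * (rates / spec.mean_rate_hz) ** (spec.rate_coupling - 1.0)
    c = (spec.multiplier * spec.mod_frac * scale[:, None]
         * np.sqrt(spec.shares[:spec.d])[None, :] * z)
    psth = np.clip(rates[:, None] + c @ basis, 0.0, None)
    return psth, rates


def make_synthetic_psths(spec: SyntheticPSTHSpec, m: int,
                         seed: int) -> PSTHPair:
    """Paired lick-R / lick-L cortical-like PSTHs.

    The two conditions are generated independently, sorted by mean rate and
    paired rank-wise; zero-mean Gaussian noise with SD equal to the pair's
    mean-rate difference is then added to the lick-left member, injecting
    choice selectivity that is symmetric around zero across the population.
    """
    if m < 1:
        raise ValueError("need at least one neuron")
    rng = np.random.default_rng(seed)
    psth_r, rates_r = _one_condition(spec, m, rng)
    psth_l, rates_l = _one_condition(spec, m, rng)
    o_r = np.argsort(psth_r.mean(axis=1))
    o_l = np.argsort(psth_l.mean(axis=1))
    psth_r, psth_l = psth_r[o_r], psth_l[o_l]
    diff = np.abs(psth_r.mean(axis=1) - psth_l.mean(axis=1))
    noise = rng.standard_normal(psth_l.shape) * diff[:, None]
    psth_l = np.clip(psth_l + noise, 0.0, None)
    rates = 0.5 * (psth_r.mean(axis=1) + psth_l.mean(axis=1))
    return PSTHPair(r=psth_r, l=psth_l, t_target_ms=spec.t_target_ms,
                    rates_hz=rates)


# ---------------------------------------------------------------------------
# rate-based pairing of targets to model neurons


@dataclass
class NeuronMatching:
    """One-to-one assignment of target rows to model neurons."""

    model_ids: np.ndarray     # model-neuron id per target row
    score: float              # total |rate difference|


def match_neurons_by_rate(model_rates: np.ndarray, model_ids: np.ndarray,
                          target_rates: np.ndarray) -> NeuronMatching:
    """Greedy unique assignment of targets to model neurons by firing rate.

    Targets are processed in descending rate order; each takes the
    still-unassigned model neuron with the smallest absolute rate
    difference.
    """
    model_rates = np.asarray(model_rates, dtype=float)
    model_ids = np.asarray(model_ids)
    target_rates = np.asarray(target_rates, dtype=float)
    if len(model_rates) < len(target_rates):
        raise ValueError("model pool smaller than number of targets")
    free = np.ones(len(model_rates), dtype=bool)
    assign = np.empty(len(target_rates), dtype=model_ids.dtype)
    score = 0.0
    order = np.argsort(target_rates)[::-1]
    for t in order:
        d = np.abs(model_rates - target_rates[t])
        d[~free] = np.inf
        j = int(np.argmin(d))
        free[j] = False
        assign[t] = model_ids[j]
        score += abs(model_rates[j] - target_rates[t])
    return NeuronMatching(model_ids=assign, score=float(score))
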