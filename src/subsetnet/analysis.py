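"""Spike-train and population-activity analyses.

PSTH estimation, principal-component analysis of trial-averaged rates,
shared-variance analysis between two populations, choice selectivity,
transferred-activity quantification, coding-mode projections, perturbation
recovery times, spiking statistics, and decomposition of recorded synaptic
inputs.

Conventions: PSTHs are (time bins × neurons) in Hz; PCA removes each
neuron's time-mean before decomposing; components are sign-fixed so the
largest-magnitude time bin is positive; variance fractions are λ_k²/Σλ_i²
with λ_k the singular values of the centered matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .network import SpikeData, InputTrace, GROUP_NAMES

__all__ = [
    "PSTHMatrix", "PCAResult", "SharedVarianceResult", "ModeProjection",
    "RecoveryEstimate", "SpikeStats",
    "compute_psth", "boxcar_smooth", "pca_psth", "transferred_activity",
    "pc_fidelity", "shared_variance", "choice_selectivity", "choice_mode",
    "project_modes", "trial_rate_traces", "recovery_time", "spike_stats",
    "input_decomposition", "gaussian_loading_test",
]

log = logging.getLogger(__name__)


@dataclass
class PSTHMatrix:
    """Trial-averaged binned firing rates (time bins × neurons), Hz."""

    rates: np.ndarray
    bin_ms: float
    smooth_ms: float
    t0_ms: float = 0.0
    neuron_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    @property
    def n_bins(self) -> int:
        return self.rates.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[1]

    def time_axis(self) -> np.ndarray:
        return self.t0_ms + (np.arange(self.n_bins) + 0.5) * self.bin_ms


def boxcar_smooth(x: np.ndarray, window_bins: int) -> np.ndarray:
    """Moving average along axis 0, window truncated at the edges."""
    if window_bins <= 1:
        return x.copy()
    n = x.shape[0]
    c = np.cumsum(np.concatenate([np.zeros((1,) + x.shape[1:]), x]), axis=0)
    half_lo = (window_bins - 1) // 2
    half_hi = window_bins // 2
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return (c[hi] - c[lo]) / (hi - lo).reshape((-1,) + (1,) * (x.ndim - 1))


def compute_psth(spikes: SpikeData, neuron_ids=None, bin_ms: float = 20.0,
                 smooth_ms: float = 300.0, t0_ms: float = 0.0) -> PSTHMatrix:
    """Trial-averaged binned rate per neuron, boxcar-smoothed, in Hz."""
    if spikes.n_trials < 1:
        raise ValueError("need at least one trial")
    if neuron_ids is None:
        neuron_ids = np.arange(spikes.n_neurons)
    neuron_ids = np.asarray(neuron_ids)
    n_bins = int(round(spikes.duration_ms / bin_ms))
    slot = np.full(spikes.n_neurons, -1)
    slot[neuron_ids] = np.arange(len(neuron_ids))
    sel = slot[spikes.neuron] >= 0
    b = np.floor(spikes.time_ms[sel] / bin_ms).astype(int)
    ok = (b >= 0) & (b < n_bins)
    counts = np.zeros((n_bins, len(neuron_ids)))
    np.add.at(counts, (b[ok], slot[spikes.neuron[sel]][ok]), 1.0)
    rates = counts / (spikes.n_trials * bin_ms / 1000.0)
    rates = boxcar_smooth(rates, max(1, int(round(smooth_ms / bin_ms))))
    return PSTHMatrix(rates=rates, bin_ms=bin_ms, smooth_ms=smooth_ms,
                      t0_ms=t0_ms, neuron_ids=neuron_ids)


@dataclass
class PCAResult:
    """PCA of a population PSTH matrix over time profiles."""

    components: np.ndarray      # (n_comp, T) orthonormal time profiles
    singular_values: np.ndarray
    loadings: np.ndarray        # (n_neurons, n_comp)
    mean_rates: np.ndarray      # removed per-neuron means

    @property
    def variance_fractions(self) -> np.ndarray:
        s2 = self.singular_values ** 2
        tot = s2.sum()
        return s2 / tot if tot > 0 else s2

    def cumulative_variance(self, k: int) -> float:
        return float(self.variance_fractions[:k].sum())


def _sign_fix(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    for k in range(out.shape[0]):
        j = np.argmax(np.abs(out[k]))
        if out[k, j] < 0:
            out[k] = -out[k]
    return out


def pca_psth(psth: PSTHMatrix | np.ndarray) -> PCAResult:
    """PCA of centered PSTHs: eigen-decomposition of R·Rᵀ over time.

    Each neuron's time-mean is removed first; components are the orthonormal
    temporal eigenvectors, λ_k the singular values of the centered (T × M)
    matrix, and the variance explained by component k is λ_k²/Σλ_i².
    """
    r = psth.rates if isinstance(psth, PSTHMatrix) else np.asarray(psth)
    if r.shape[1] < 2:
        raise ValueError("need at least two neurons")
    means = r.mean(axis=0)
    rc = r - means[None, :]
    u, s, vt = np.linalg.svd(rc, full_matrices=False)
    comps = _sign_fix(u.T)
    # re-derive loadings under the fixed signs
    loadings = (rc.T @ comps.T)
    return PCAResult(components=comps, singular_values=s,
                     loadings=loadings, mean_rates=means)


def transferred_activity(psth: PSTHMatrix | np.ndarray, k: int = 6,
                         reference_pcs: np.ndarray | None = None) -> float:
    """Fraction of centered variance captured by the first k components.

    With ``reference_pcs`` (k' × T orthonormal rows) the centered activity
    is projected onto those fixed modes instead of its own leading PCs.
    """
    r = psth.rates if isinstance(psth, PSTHMatrix) else np.asarray(psth)
    rc = r - r.mean(axis=0, keepdims=True)
    tot = float((rc ** 2).sum())
    if tot == 0:
        return 0.0
    if reference_pcs is not None:
        proj = reference_pcs[:k] @ rc
        return float((proj ** 2).sum() / tot)
    res = pca_psth(PSTHMatrix(r, 0, 0))
    if k > len(res.singular_values):
        raise ValueError("k exceeds available rank")
    return res.cumulative_variance(k)


def pc_fidelity(pcs_a: PCAResult | np.ndarray, pcs_b: PCAResult | np.ndarray,
                n_modes: int = 2) -> np.ndarray:
    """Per-mode |correlation| between two sets of PC time profiles."""
    a = pcs_a.components if isinstance(pcs_a, PCAResult) else np.asarray(pcs_a)
    b = pcs_b.components if isinstance(pcs_b, PCAResult) else np.asarray(pcs_b)
    n = min(n_modes, a.shape[0], b.shape[0])
    out = np.empty(n)
    for k in range(n):
        out[k] = abs(np.corrcoef(a[k], b[k])[0, 1])
    return out


@dataclass
class SharedVarianceResult:
    correlations: np.ndarray       # (M1, M2)
    u: np.ndarray
    v: np.ndarray
    singular_values: np.ndarray
    shared_f: np.ndarray           # (T, n_comp) components of side F
    shared_g: np.ndarray
    fractions_f: np.ndarray
    fractions_g: np.ndarray


def shared_variance(f: np.ndarray, g: np.ndarray) -> SharedVarianceResult:
    """Shared-variance analysis between two populations.

    ``f`` (T × M1) and ``g`` (T × M2) are PSTH matrices on the same time
    grid.  The per-pair correlation matrix C is decomposed by SVD
    C = UΣVᵀ; the k-th shared components are α_k = F·u_k and β_k = G·v_k
    (on the centered matrices) with shared-variance fractions
    ‖α_k‖²/Σ‖α‖² per side.  Zero-variance neurons get zero correlation.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape[0] != g.shape[0]:
        raise ValueError("time grids differ")

    def _zscore(x):
        xc = x - x.mean(axis=0, keepdims=True)
        sd = xc.std(axis=0)
        dead = sd == 0
        if dead.any():
            log.info("shared_variance: %d zero-variance neurons",
                     int(dead.sum()))
        sd[dead] = 1.0
        z = xc / sd
        z[:, dead] = 0.0
        return xc, z

    fc, fz = _zscore(f)
    gc, gz = _zscore(g)
    c = fz.T @ gz / f.shape[0]
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    alpha = fc @ u
    beta = gc @ vt.T
    fa = (alpha ** 2).sum(axis=0)
    fb = (beta ** 2).sum(axis=0)
    return SharedVarianceResult(
        correlations=c, u=u, v=vt.T, singular_values=s,
        shared_f=alpha, shared_g=beta,
        fractions_f=fa / fa.sum() if fa.sum() else fa,
        fractions_g=fb / fb.sum() if fb.sum() else fb)


def choice_selectivity(psth_r: np.ndarray, psth_l: np.ndarray,
                       eps: float = 1e-12):
    """Per-neuron selectivity s_i(t) = (r_R − r_L)/mean rate and its
    time-averaged scalar (positive = lick-right preferring).

    The normalizer is the neuron's rate averaged over both conditions and
    time; zero-rate neurons are excluded (NaN) and logged.
    """
    r = np.asarray(psth_r, dtype=float)
    l = np.asarray(psth_l, dtype=float)
    mean_rate = 0.5 * (r.mean(axis=0) + l.mean(axis=0))
    dead = mean_rate <= eps
    if dead.any():
        log.info("choice_selectivity: %d zero-rate neurons excluded",
                 int(dead.sum()))
    denom = np.where(dead, np.nan, mean_rate)
    s_t = (r - l) / denom[None, :]
    return s_t, s_t.mean(axis=0)


# ---------------------------------------------------------------------------
# coding modes and perturbation recovery


@dataclass
class ModeProjection:
    choice: np.ndarray            # (N,) unit-normalized to ‖C‖ = 1/√N
    window_ms: tuple = (0.0, 0.0)


def trial_rate_traces(spikes: SpikeData, neuron_ids=None,
                      bin_ms: float = 1.0,
                      boxcar_ms: float = 200.0) -> np.ndarray:
    """Per-trial filtered rates (n_trials, T, M) in Hz."""
    if neuron_ids is None:
        neuron_ids = np.arange(spikes.n_neurons)
    neuron_ids = np.asarray(neuron_ids)
    n_bins = int(round(spikes.duration_ms / bin_ms))
    slot = np.full(spikes.n_neurons, -1)
    slot[neuron_ids] = np.arange(len(neuron_ids))
    sel = slot[spikes.neuron] >= 0
    b = np.floor(spikes.time_ms[sel] / bin_ms).astype(int)
    ok = (b >= 0) & (b < n_bins)
    counts = np.zeros((spikes.n_trials, n_bins, len(neuron_ids)))
    np.add.at(counts, (spikes.trial[sel][ok], b[ok],
                       slot[spikes.neuron[sel]][ok]), 1.0)
    rates = counts / (bin_ms / 1000.0)
    win = max(1, int(round(boxcar_ms / bin_ms)))
    for k in range(rates.shape[0]):
        rates[k] = boxcar_smooth(rates[k], win)
    return rates


def choice_mode(rates_r: np.ndarray, rates_l: np.ndarray,
                time_ms: np.ndarray, window_ms: tuple,
                min_neurons: int = 10) -> ModeProjection:
    """Choice mode: normalized lick-R minus lick-L trial-averaged rates
    averaged within the given window, with the 1/√N normalization
    C = Δr / (√N ‖Δr‖), so ‖C‖ = 1/√N.

    ``rates_*`` are per-trial traces (n_trials, T, N).
    """
    n = rates_r.shape[2]
    if n < min_neurons:
        raise ValueError(f"fewer than {min_neurons} neurons")
    sel = (time_ms >= window_ms[0]) & (time_ms < window_ms[1])
    d = (rates_r[:, sel].mean(axis=(0, 1))
         - rates_l[:, sel].mean(axis=(0, 1)))
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("identical R/L averages: zero-norm difference")
    return ModeProjection(choice=d / (np.sqrt(n) * norm),
                          window_ms=tuple(window_ms))


def project_modes(rates: np.ndarray, mode: ModeProjection):
    """Project per-trial rates (n_trials, T, N) on the choice and
    homogeneous modes.  Returns (P_C, P_H), each (n_trials, T)."""
    p_c = rates @ mode.choice
    p_h = rates.mean(axis=2)
    return p_c, p_h


@dataclass
class RecoveryEstimate:
    p_values: np.ndarray
    significant: np.ndarray
    included: bool
    recovery_time_ms: float | None
    decay_rate_per_ms: float | None


def recovery_time(proj_pert: np.ndarray, proj_base: np.ndarray,
                  time_ms: np.ndarray, pert_window_ms: tuple,
                  search_window_ms: tuple, alpha: float = 0.05,
                  min_sig_frac: float = 0.10,
                  deriv_thresh: float | None = None) -> RecoveryEstimate:
    """Per-bin two-sample t-test recovery estimate.

    A session is included if at least ``min_sig_frac`` of the bins inside
    the perturbation window differ significantly.  The recovery time is
    the last bin of the contiguous significant run that carries the
    perturbation response into the search window — isolated significant
    bins appearing later are treated as the false positives a per-bin
    α-level test produces and are ignored (with ``deriv_thresh`` such late
    bins are re-admitted only while the smoothed |dΔ/dt| still exceeds the
    threshold, i.e. while the trajectory is still moving).  If no
    significance extends past the perturbation window the mode has
    recovered immediately and the perturbation offset is returned.  An
    exponential decay rate is fitted to |Δprojection| after the
    perturbation window.
    """
    if proj_pert.shape[0] < 5 or proj_base.shape[0] < 5:
        raise ValueError("need at least 5 trials per condition")
    t_res = stats.ttest_ind(proj_pert, proj_base, axis=0)
    p = np.asarray(t_res.pvalue)
    sig = p < alpha
    in_pert = (time_ms >= pert_window_ms[0]) & (time_ms < pert_window_ms[1])
    included = bool(in_pert.any() and
                    sig[in_pert].mean() >= min_sig_frac)
    in_search = (time_ms >= search_window_ms[0]) & \
                (time_ms < search_window_ms[1])
    delta = proj_pert.mean(axis=0) - proj_base.mean(axis=0)
    rec = None
    if included:
        # walk the contiguous significant run out of the perturbation window
        pert_bins = np.where(in_pert)[0]
        start = pert_bins[-1] if len(pert_bins) else 0
        k = start
        dt = np.median(np.diff(time_ms)) if len(time_ms) > 1 else 1.0
        dd = np.abs(np.gradient(delta, dt))
        while k + 1 < len(sig):
            if sig[k + 1]:
                k += 1
            elif deriv_thresh is not None and dd[k + 1] > deriv_thresh:
                k += 1
            else:
                break
        if k > start and in_search[k]:
            rec = float(time_ms[k])
        else:
            rec = float(search_window_ms[0])  # recovered immediately

    decay = None
    after = time_ms >= pert_window_ms[1]
    y = np.abs(delta[after])
    t = time_ms[after] - pert_window_ms[1]
    if len(y) > 4 and y[0] > 0 and np.any(y > 0):
        yp = np.clip(y, y.max() * 1e-6, None)
        # linear fit in log space over the initial decay segment
        k = max(4, int(len(y) * 0.6))
        coef = np.polyfit(t[:k], np.log(yp[:k]), 1)
        decay = float(-coef[0])
    return RecoveryEstimate(p_values=p, significant=sig, included=included,
                            recovery_time_ms=rec, decay_rate_per_ms=decay)


# ---------------------------------------------------------------------------
# spiking statistics


@dataclass
class SpikeStats:
    fano: float
    fano_per_neuron: np.ndarray
    isi_cv: np.ndarray
    rates_hz: np.ndarray
    lognormal_stat: float | None
    lognormal_p: float | None
    normal_stat_raw: float | None


def spike_stats(spikes: SpikeData, count_window_ms: tuple | None = None,
                min_isis: int = 5) -> SpikeStats:
    """Fano factor, ISI CV, and firing-rate distribution diagnostics.

    Fano = var/mean of per-trial spike counts in the counting window
    (default: the full recorded window), averaged over neurons whose mean
    count is at least one.  The ISI CV is computed per neuron from
    within-trial intervals.  Log-rates are tested for normality
    (D'Agostino) along with the raw rates for comparison.
    """
    if count_window_ms is None:
        count_window_ms = (0.0, spikes.duration_ms)
    counts = spikes.counts(t_lo=count_window_ms[0], t_hi=count_window_ms[1])
    mean_c = counts.mean(axis=0)
    var_c = counts.var(axis=0, ddof=1) if spikes.n_trials > 1 else \
        np.zeros_like(mean_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        fano_pn = np.where(mean_c > 0, var_c / mean_c, np.nan)
    ok = mean_c >= 1.0
    fano = float(np.nanmean(fano_pn[ok])) if ok.any() else np.nan

    order = np.lexsort((spikes.time_ms, spikes.neuron, spikes.trial))
    tr, nr, tm = (spikes.trial[order], spikes.neuron[order],
                  spikes.time_ms[order])
    isi_sum = np.zeros(spikes.n_neurons)
    isi_sum2 = np.zeros(spikes.n_neurons)
    isi_n = np.zeros(spikes.n_neurons, dtype=int)
    if len(tm) > 1:
        same = (tr[1:] == tr[:-1]) & (nr[1:] == nr[:-1])
        d = tm[1:] - tm[:-1]
        np.add.at(isi_sum, nr[1:][same], d[same])
        np.add.at(isi_sum2, nr[1:][same], d[same] ** 2)
        np.add.at(isi_n, nr[1:][same], 1)
    cv = np.full(spikes.n_neurons, np.nan)
    has = isi_n >= min_isis
    mu = isi_sum[has] / isi_n[has]
    var = isi_sum2[has] / isi_n[has] - mu ** 2
    cv[has] = np.sqrt(np.clip(var, 0, None)) / mu

    rates = spikes.rates_hz()
    pos = rates > 0
    ln_stat = ln_p = raw_stat = None
    if pos.sum() >= 20:
        ln_stat, ln_p = stats.normaltest(np.log(rates[pos]))
        raw_stat, _ = stats.normaltest(rates[pos])
        ln_stat, ln_p, raw_stat = float(ln_stat), float(ln_p), float(raw_stat)
    return SpikeStats(fano=fano, fano_per_neuron=fano_pn, isi_cv=cv,
                      rates_hz=rates, lognormal_stat=ln_stat,
                      lognormal_p=ln_p, normal_stat_raw=raw_stat)


# ---------------------------------------------------------------------------
# input decomposition and Gaussian loading test


def input_decomposition(trace: InputTrace, bin_ms: float = 20.0,
                        groups=GROUP_NAMES):
    """Aggregate inputs per presynaptic group and their temporal modulations.

    For each recorded neuron the group-resolved static inputs are binned at
    ``bin_ms``; δu = u − time-mean.  Returns a dict with per-group binned
    aggregates (T, n_rec), modulations, and the time axis.
    """
    if len(set(groups) - set(GROUP_NAMES)) > 0:
        raise ValueError("grouping must be a subset of the recorded partition")
    stride = np.median(np.diff(trace.time_ms)) if len(trace.time_ms) > 1 else 1.0
    per_bin = max(1, int(round(bin_ms / stride)))
    out = {"time_ms": None, "groups": {}, "modulations": {}}
    for g in groups:
        u = trace.group(g)
        n_full = (u.shape[0] // per_bin) * per_bin
        ub = u[:n_full].reshape(-1, per_bin, u.shape[1]).mean(axis=1)
        out["groups"][g] = ub
        out["modulations"][g] = ub - ub.mean(axis=0, keepdims=True)
    t = trace.time_ms[:n_full].reshape(-1, per_bin).mean(axis=1)
    out["time_ms"] = t
    return out


def gaussian_loading_test(loadings: np.ndarray):
    """Lilliefors-corrected KS normality test of standardized PC loadings.

    Returns (statistic, p-value, fitted mean, fitted SD); degenerate
    (constant) loadings return NaN statistics with SD 0.
    """
    x = np.asarray(loadings, dtype=float)
    if len(x) < 50:
        raise ValueError("need at least 50 loadings")
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return np.nan, np.nan, float(mu), 0.0
    stat, p = lilliefors((x - mu) / sd, dist="norm")
    return float(stat), float(p), float(mu), float(sd)
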