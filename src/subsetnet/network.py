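"""Construction and simulation of the balanced excitatory-inhibitory network.

The untrained network is a sparse random E/I circuit in the balanced regime:
static weights ±J̄_αβ/√K_αβ on Erdős–Rényi connectivity with mean in-degree
K_αβ, constant external drives ∝ √K, and leaky integrate-and-fire dynamics.
On top of the static circuit a much sparser set of *plastic* synapses (of
order √K per trained neuron) carries the trained input; its support is
disjoint from the static synapses and fixed for the lifetime of a training
run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .params import NetworkSpec, PopulationLayout, SynapseParams

__all__ = [
    "StaticConnectivity",
    "PlasticConnectivity",
    "ExternalDrive",
    "Network",
    "SpikeData",
    "InputTrace",
    "RecordSpec",
    "build_static_connectivity",
    "build_plastic_connectivity",
    "ou_stimulus",
    "poisson_external",
    "make_drives",
    "simulate",
    "subseed",
]

GROUP_NAMES = ("E_trained", "E_untrained", "I_trained", "I_untrained")


def subseed(base: int, *salt: int) -> int:
    """Deterministic sub-seed derivation, always below 2**31."""
    mask = (1 << 64) - 1
    h = (int(base) * 2654435761) & mask
    for s in salt:
        h = ((h ^ int(s)) * 2246822519) & mask
    return h % (2**31 - 1)


# ---------------------------------------------------------------------------
# connectivity


@dataclass
class StaticConnectivity:
    """Signed static weight matrix, postsynaptic × presynaptic (CSC)."""

    weights: sp.csc_matrix
    layout: PopulationLayout

    @property
    def adjacency(self) -> sp.csc_matrix:
        a = self.weights.copy()
        a.data = np.ones_like(a.data)
        return a

    def in_degrees(self) -> np.ndarray:
        """Realized in-degree per neuron per presynaptic population (N, 2)."""
        csr = self.weights.tocsr()
        n_e = self.layout.N_E
        out = np.zeros((self.layout.N, 2), dtype=int)
        for i in range(self.layout.N):
            cols = csr.indices[csr.indptr[i]:csr.indptr[i + 1]]
            out[i, 0] = np.count_nonzero(cols < n_e)
            out[i, 1] = len(cols) - out[i, 0]
        return out


def build_static_connectivity(layout: PopulationLayout, syn: SynapseParams,
                              seed: int,
                              weight_scaling: str = "sqrt",
                              gain: float = 1.0) -> StaticConnectivity:
    """Erdős–Rényi static connectivity with Dale's-law weights.

    Each ordered pair (i, j), i ≠ j, with i in population α and j in β is
    connected independently with probability K_αβ/N_β; the weight is
    +J̄_αβ/√K_αβ for excitatory j and −J̄_αβ/√K_αβ for inhibitory j
    (``weight_scaling='linear'`` divides by K_αβ instead, the weak-coupling
    control).
    """
    rng = np.random.default_rng(seed)
    n_e, n = layout.N_E, layout.N
    sizes = (layout.N_E, layout.N_I)
    for a in range(2):
        for b in range(2):
            if syn.kbar[a, b] > sizes[b]:
                raise ValueError(
                    f"K[{a},{b}]={syn.kbar[a, b]} exceeds presynaptic pool "
                    f"size {sizes[b]}")

    rows_all, cols_all, vals_all = [], [], []
    starts = (0, n_e)
    for b in range(2):  # presynaptic block
        for a in range(2):  # postsynaptic block
            p = syn.kbar[a, b] / sizes[b]
            denom = (np.sqrt(syn.kbar[a, b]) if weight_scaling == "sqrt"
                     else syn.kbar[a, b])
            wval = gain * syn.jbar[a, b] / denom * (1.0 if b == 0 else -1.0)
            # sample column-chunks to bound memory at full scale
            chunk = max(1, min(sizes[b], 512))
            for c0 in range(0, sizes[b], chunk):
                c1 = min(c0 + chunk, sizes[b])
                mask = rng.random((sizes[a], c1 - c0)) < p
                r, c = np.nonzero(mask)
                r = r + starts[a]
                c = c + starts[b] + c0
                keep = r != c
                rows_all.append(r[keep])
                cols_all.append(c[keep])
                vals_all.append(np.full(keep.sum(), wval))
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    vals = np.concatenate(vals_all)
    mat = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))

    conn = StaticConnectivity(weights=mat, layout=layout)
    _check_in_degrees(conn, syn)
    return conn


def _check_in_degrees(conn: StaticConnectivity, syn: SynapseParams) -> None:
    deg = conn.in_degrees()
    layout = conn.layout
    sizes = (layout.N_E, layout.N_I)
    blocks = (layout.e_slice, layout.i_slice)
    for a in range(2):
        for b in range(2):
            k = syn.kbar[a, b]
            p = k / sizes[b]
            sd = np.sqrt(k * (1 - p)) / np.sqrt(sizes[a])
            mean_deg = deg[blocks[a], b].mean()
            if sd > 0 and abs(mean_deg - k) > 6 * sd + 1:
                raise RuntimeError(
                    f"realized in-degree {mean_deg:.1f} far from K={k}")


@dataclass
class PlasticConnectivity:
    """Sparse trainable synapses onto the trained subset.

    ``pre_idx[m]`` lists the recurrent presynaptic partners of trained neuron
    ``trained[m]`` — the first ``l_per_pop`` entries excitatory, the next
    ``l_per_pop`` inhibitory.  ``w[m]`` is the concatenated weight vector
    (recurrent then feedforward); only values change during training, the
    support is fixed.
    """

    trained: np.ndarray            # (M,) neuron ids
    pre_idx: np.ndarray            # (M, L_rec)
    w: np.ndarray                  # (M, L_rec + L_x)
    l_per_pop: int
    l_x: int
    layout: PopulationLayout

    @property
    def l_rec(self) -> int:
        return self.pre_idx.shape[1]

    @property
    def l_tot(self) -> int:
        return self.w.shape[1]

    @property
    def n_trained(self) -> int:
        return len(self.trained)

    def indicators(self) -> tuple[np.ndarray, np.ndarray]:
        """Binary E/I indicator vectors over the full weight vector."""
        ind_e = np.zeros(self.l_tot)
        ind_i = np.zeros(self.l_tot)
        if self.n_trained:
            is_e = self.pre_idx[0] < self.layout.N_E
            ind_e[:self.l_rec][is_e] = 1.0
            ind_i[:self.l_rec][~is_e] = 1.0
        return ind_e, ind_i

    def rowsums(self) -> np.ndarray:
        """Aggregate (E, I) plastic weight per trained neuron, (M, 2)."""
        is_e = self.pre_idx < self.layout.N_E
        w_rec = self.w[:, :self.l_rec]
        return np.stack([np.where(is_e, w_rec, 0).sum(1),
                         np.where(~is_e, w_rec, 0).sum(1)], axis=1)

    def to_csc(self, tau_plas: float):
        """Propagation structure: (indptr, rows, w/tau) CSC by presynaptic
        neuron plus the position of each (m, l) entry in the value array."""
        n = self.layout.N
        m, l = self.pre_idx.shape
        if m == 0:
            return (np.zeros(n + 1, dtype=np.int64),
                    np.zeros(0, dtype=np.int64), np.zeros(0),
                    np.zeros((0, 0), dtype=np.int64))
        pre = self.pre_idx.ravel()
        post = np.repeat(self.trained, l)
        order = np.lexsort((post, pre))
        rows = post[order].astype(np.int64)
        wj = (self.w[:, :l].ravel() / tau_plas)[order]
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(indptr, pre + 1, 1)
        indptr = np.cumsum(indptr)
        pos = np.empty(m * l, dtype=np.int64)
        pos[order] = np.arange(m * l)
        return indptr, rows, wj, pos.reshape(m, l)

    def verify_disjoint(self, static: StaticConnectivity) -> bool:
        csr = static.weights.tocsr()
        for m, i in enumerate(self.trained):
            partners = set(csr.indices[csr.indptr[i]:csr.indptr[i + 1]])
            if partners.intersection(self.pre_idx[m].tolist()):
                return False
            if i in self.pre_idx[m]:
                return False
        return True


def build_plastic_connectivity(layout: PopulationLayout,
                               static: StaticConnectivity,
                               trained: np.ndarray,
                               l_per_pop: int,
                               l_x: int,
                               wbar: np.ndarray,
                               syn: SynapseParams,
                               seed: int,
                               weight_scaling: str = "sqrt",
                               gain: float = 1.0) -> PlasticConnectivity:
    """Sparse plastic synapses onto each trained neuron.

    Each trained neuron receives ``l_per_pop`` excitatory and ``l_per_pop``
    inhibitory recurrent plastic synapses plus all ``l_x`` feedforward
    synapses from the external units.  Presynaptic pools follow the
    trained-subnetwork rule: same-population partners are drawn from the
    *other trained* neurons of that population, opposite-population partners
    from the entire opposite population.  Static partners and self are
    excluded so the supports are disjoint.

    ``wbar`` is the 2×2 table of initial weight magnitudes expressed as
    multiples of the realized static weights J_α = J̄/√K (rows postsynaptic,
    columns presynaptic); initial excitatory entries are positive, inhibitory
    negative. Signs are free to change during training.
    """
    trained = np.asarray(sorted(trained), dtype=np.int64)
    if trained.size == 0:
        raise ValueError("trained set must be non-empty")
    rng = np.random.default_rng(seed)
    wbar = np.asarray(wbar, dtype=float)
    n_e = layout.N_E
    csr = static.weights.tocsr()

    trained_e = trained[trained < n_e]
    trained_i = trained[trained >= n_e]
    all_e = np.arange(n_e)
    all_i = np.arange(n_e, layout.N)

    denom = np.sqrt(syn.kbar) if weight_scaling == "sqrt" else syn.kbar
    j_real = gain * syn.jbar / denom  # realized static magnitudes per block

    m = len(trained)
    pre_idx = np.empty((m, 2 * l_per_pop), dtype=np.int64)
    w = np.zeros((m, 2 * l_per_pop + l_x))
    for k, i in enumerate(trained):
        a = 0 if i < n_e else 1
        partners = set(csr.indices[csr.indptr[i]:csr.indptr[i + 1]].tolist())
        partners.add(int(i))
        pool_e = trained_e if a == 0 else all_e
        pool_i = all_i if a == 0 else trained_i
        cand_e = np.array([j for j in pool_e if j not in partners])
        cand_i = np.array([j for j in pool_i if j not in partners])
        if len(cand_e) < l_per_pop or len(cand_i) < l_per_pop:
            raise ValueError(
                f"neuron {i}: cannot place {l_per_pop} plastic synapses per "
                f"population after excluding static partners")
        pre_idx[k, :l_per_pop] = rng.choice(cand_e, l_per_pop, replace=False)
        pre_idx[k, l_per_pop:] = rng.choice(cand_i, l_per_pop, replace=False)
        w[k, :l_per_pop] = wbar[a, 0] * j_real[a, 0]
        w[k, l_per_pop:2 * l_per_pop] = -wbar[a, 1] * j_real[a, 1]
    return PlasticConnectivity(trained=trained, pre_idx=pre_idx, w=w,
                               l_per_pop=l_per_pop, l_x=l_x, layout=layout)


# ---------------------------------------------------------------------------
# drives


def ou_stimulus(n_steps: int, n_series: int, dt: float, tau: float,
                sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-reverting Ornstein–Uhlenbeck traces, zero initial condition.

    X(t+δt) = X(t) − τ⁻¹X(t)δt + σ√δt ξ.  Returns (n_steps, n_series).
    """
    if n_steps <= 0:
        raise ValueError("window length must be positive")
    out = np.empty((n_steps, n_series))
    x = np.zeros(n_series)
    decay = 1.0 - dt / tau
    noise = rng.standard_normal((n_steps, n_series))
    s = sigma * np.sqrt(dt)
    for t in range(n_steps):
        x = x * decay + s * noise[t]
        out[t] = x
    return out


def poisson_external(rate_ms: np.ndarray, dt: float,
                     tau_plas: float, seed: int):
    """Bernoulli-per-step external spike trains and their filtered traces.

    ``rate_ms`` is (n_ms, n_units) in spikes/ms.  Returns (spikes, filtered)
    where ``spikes`` is a boolean (n_steps, n_units) array and ``filtered``
    the τ_plas-filtered trace with 1/τ jumps (unit integral per spike).
    """
    rate_ms = np.atleast_2d(np.asarray(rate_ms, dtype=float))
    if np.any(rate_ms < 0):
        raise ValueError("rates must be non-negative")
    if np.any(rate_ms * dt > 1):
        raise ValueError("rate*dt exceeds 1; time step too coarse")
    rng = np.random.default_rng(seed)
    steps_per_ms = int(round(1.0 / dt))
    n_steps = rate_ms.shape[0] * steps_per_ms
    p = np.repeat(rate_ms, steps_per_ms, axis=0) * dt
    spikes = rng.random(p.shape) < p
    filt = np.zeros_like(p)
    x = np.zeros(p.shape[1])
    decay = 1.0 - dt / tau_plas
    for t in range(n_steps):
        x = x * decay + spikes[t] / tau_plas
        filt[t] = x
    return spikes, filt


@dataclass
class ExternalDrive:
    """Constant, stimulus, noise, and external-unit drives.

    ``x_bal`` is the per-neuron constant drive (already √K-scaled for the
    strong-coupling network).  ``stim`` maps trial type to a frozen
    (n_stim_steps, N) Ornstein–Uhlenbeck stimulus applied in a 200 ms window
    ending at the start of the target interval; the same traces are reused
    on every trial of that type.  ``ext_rate_ms`` holds the frozen
    time-varying rates (spikes/ms) of the external Poisson units.
    """

    x_bal: np.ndarray
    stim: dict = field(default_factory=dict)
    stim_ms: float = 200.0
    ext_rate_ms: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    noise_amp: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def l_x(self) -> int:
        return self.ext_rate_ms.shape[1]


def make_drives(spec: NetworkSpec, seed: int, l_x: int = 0,
                trial_types: tuple = ("A",), stim_ms: float = 200.0,
                stim_tau: float = 20.0, stim_sigma: float = 0.2,
                ext_mean_hz: float = 5.0, ext_tau: float = 100.0,
                ext_sigma_hz: float = 2.0,
                duration_ms: float = 3000.0) -> ExternalDrive:
    """Assemble the external drives for a network.

    The constant drive is X̄_bal,α·√K_I for the strong-coupling network and
    X̄_bal,α as given for the weak-coupling control.  One OU stimulus set is
    generated per trial type and frozen; external-unit rate patterns are OU
    around ``ext_mean_hz`` and likewise frozen.
    """
    layout = spec.layout
    dt = spec.neuron.dt
    rng = np.random.default_rng(subseed(seed, 11))
    scale = np.sqrt(spec.syn.kbar[1, 1]) if spec.weight_scaling == "sqrt" else 1.0
    x_bal = np.empty(layout.N)
    x_bal[layout.e_slice] = spec.xbar_eff[0] * scale
    x_bal[layout.i_slice] = spec.xbar_eff[1] * scale

    n_stim_steps = int(round(stim_ms / dt))
    stim = {}
    for k, tt in enumerate(trial_types):
        r = np.random.default_rng(subseed(seed, 101 + k))
        stim[tt] = ou_stimulus(n_stim_steps, layout.N, dt, stim_tau,
                               stim_sigma, r)

    if l_x > 0:
        n_ms = int(np.ceil(duration_ms)) + 1
        mean = ext_mean_hz / 1000.0
        sigma = (ext_sigma_hz / 1000.0) / np.sqrt(ext_tau / 2.0)
        ou = ou_stimulus(n_ms, l_x, 1.0, ext_tau, sigma, rng)
        ext_rate_ms = np.clip(mean + ou, 0.0, None)
    else:
        ext_rate_ms = np.zeros((0, 0))
    return ExternalDrive(x_bal=x_bal, stim=stim, stim_ms=stim_ms,
                         ext_rate_ms=ext_rate_ms)


# ---------------------------------------------------------------------------
# network bundle and simulation


@dataclass
class Network:
    spec: NetworkSpec
    static: StaticConnectivity
    plastic: PlasticConnectivity | None = None

    @property
    def layout(self) -> PopulationLayout:
        return self.spec.layout

    def trained_mask(self) -> np.ndarray:
        mask = np.zeros(self.layout.N, dtype=bool)
        if self.plastic is not None:
            mask[self.plastic.trained] = True
        return mask

    def presyn_groups(self) -> np.ndarray:
        """Group id per neuron: 0 E-trained, 1 E-untrained, 2 I-trained,
        3 I-untrained."""
        tm = self.trained_mask()
        g = np.where(self.layout.labels() == 0,
                     np.where(tm, 0, 1), np.where(tm, 2, 3))
        return g.astype(np.int8)


@dataclass
class SpikeData:
    """Spike events over repeated trials; times in ms from target onset."""

    trial: np.ndarray
    neuron: np.ndarray
    time_ms: np.ndarray
    duration_ms: float
    n_trials: int
    n_neurons: int

    def counts(self, neuron_ids=None, t_lo=0.0, t_hi=None) -> np.ndarray:
        """Per-trial spike counts in a window, (n_trials, len(neuron_ids))."""
        if t_hi is None:
            t_hi = self.duration_ms
        if neuron_ids is None:
            neuron_ids = np.arange(self.n_neurons)
        sel = (self.time_ms >= t_lo) & (self.time_ms < t_hi)
        out = np.zeros((self.n_trials, self.n_neurons))
        np.add.at(out, (self.trial[sel], self.neuron[sel]), 1)
        return out[:, neuron_ids]

    def rates_hz(self) -> np.ndarray:
        """Trial-averaged firing rate per neuron in Hz."""
        c = np.bincount(self.neuron, minlength=self.n_neurons)
        return c / (self.n_trials * self.duration_ms / 1000.0)


@dataclass
class InputTrace:
    """Decomposed synaptic inputs of recorded neurons.

    ``traces`` has shape (n_steps, n_rec, 7) with channels: static input from
    (E-trained, E-untrained, I-trained, I-untrained) presynaptic groups, then
    u_plas, X_plas, X_stim.  ``x_bal`` holds the constant drive of each
    recorded neuron, so the total input is the channel sum plus ``x_bal``.
    """

    neuron_ids: np.ndarray
    time_ms: np.ndarray
    traces: np.ndarray
    x_bal: np.ndarray

    def u_bal(self) -> np.ndarray:
        return self.traces[:, :, :4].sum(axis=2)

    def total(self) -> np.ndarray:
        return self.traces.sum(axis=2) + self.x_bal[None, :]

    def group(self, name: str) -> np.ndarray:
        return self.traces[:, :, GROUP_NAMES.index(name)]


@dataclass
class RecordSpec:
    neuron_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    stride_ms: float = 1.0


def _empty_learn_args(n: int):
    return dict(
        learn=False, learn_start=0, learn_stride=1,
        f_targets=np.zeros((0, 0)),
        trained=np.zeros(0, dtype=np.int64),
        pre_idx=np.zeros((0, 0), dtype=np.int64),
        w=np.zeros((0, 0)), P=np.zeros((0, 0, 0)),
        plas_pos=np.zeros((0, 0), dtype=np.int64),
    )


class SimulationError(RuntimeError):
    pass


def _kernel_status(status, bad_i, bad_t, dt):
    if status == _kernels.ERR_NONFINITE:
        raise SimulationError(
            f"non-finite membrane potential: neuron {bad_i} at step {bad_t} "
            f"(t={bad_t * dt:.2f} ms)")
    if status == _kernels.ERR_SPIKE_OVERFLOW:
        raise SimulationError("spike buffer overflow; network diverged?")
    if status == _kernels.ERR_RLS_DEFINITE:
        raise SimulationError(
            f"RLS denominator non-positive for neuron {bad_i} at step "
            f"{bad_t}: P lost positive definiteness")


def run_trial(network: Network, drives: ExternalDrive, duration_ms: float,
              seed: int, *, burn_ms: float = 500.0, trial_type=None,
              record: RecordSpec | None = None,
              learn_args: dict | None = None,
              wx: np.ndarray | None = None,
              plas_csc=None,
              spike_cap_hz: float = 400.0):
    """Run one trial: burn-in, optional stimulus window, target window.

    Returns (spk_neuron, spk_time_ms, traces, sum_u/steps, rls stats).
    Time 0 is the start of the target window; spikes are recorded for
    t ∈ [0, duration).
    """
    spec = network.spec
    dt = spec.neuron.dt
    layout = spec.layout
    n = layout.N
    rng = np.random.default_rng(seed)

    stim = drives.stim.get(trial_type, None) if trial_type is not None else None
    has_stim = stim is not None
    # the stimulus block starts at the end of burn-in and leads the target
    # window by drives.stim_ms; a longer array extends into the target window
    # (used to perturb trials during the delay)
    stim_lead = int(round(drives.stim_ms / dt)) if has_stim else 0
    burn_steps = int(round(burn_ms / dt))
    tgt_steps = int(round(duration_ms / dt))
    n_steps = burn_steps + stim_lead + tgt_steps
    tgt_start = burn_steps + stim_lead

    v = rng.uniform(spec.neuron.v_reset, spec.neuron.v_thr, n)
    u_bal = np.zeros(n)
    u_plas = np.zeros(n)
    x_plas = np.zeros(n)
    r_plas = np.zeros(n)

    stat = network.static.weights
    stat_wj = stat.data / spec.syn.tau_bal

    pl = network.plastic
    if pl is not None and pl.n_trained > 0:
        if plas_csc is None:
            plas_csc = pl.to_csc(spec.syn.tau_plas)
        plas_indptr, plas_rows, plas_wj, plas_pos = plas_csc
        l_x = pl.l_x
        if wx is None:
            wx = np.ascontiguousarray(pl.w[:, pl.l_rec:]).copy()
    else:
        plas_indptr = np.zeros(n + 1, dtype=np.int64)
        plas_rows = np.zeros(0, dtype=np.int64)
        plas_wj = np.zeros(0)
        plas_pos = np.zeros((0, 0), dtype=np.int64)
        l_x = 0
        wx = np.zeros((0, 0))
    r_x = np.zeros(l_x)
    ext_rate = drives.ext_rate_ms if l_x > 0 else np.zeros((0, 0))

    if record is not None and len(record.neuron_ids) > 0:
        rec_ids = np.asarray(record.neuron_ids, dtype=np.int64)
        rec_slot = np.full(n, -1, dtype=np.int64)
        rec_slot[rec_ids] = np.arange(len(rec_ids))
        rec_stride = max(1, int(round(record.stride_ms / dt)))
        n_rec_steps = tgt_steps // rec_stride
        rec_traces = np.zeros((n_rec_steps, len(rec_ids), 7))
        ub_groups = np.zeros((len(rec_ids), 4))
    else:
        rec_ids = np.zeros(0, dtype=np.int64)
        rec_slot = np.full(n, -1, dtype=np.int64)
        rec_stride = 1
        rec_traces = np.zeros((0, 0, 7))
        ub_groups = np.zeros((0, 4))

    cap = int(n * (n_steps * dt / 1000.0) * spike_cap_hz) + 1000
    spk_n = np.zeros(cap, dtype=np.int32)
    spk_t = np.zeros(cap, dtype=np.int64)
    sum_u = np.zeros(n)

    la = learn_args if learn_args is not None else _empty_learn_args(n)

    nspk, err_sum, n_err, status, bad_i, bad_t = _kernels.lif_run(
        subseed(seed, 7), n_steps, dt, spec.neuron.tau_m, spec.neuron.v_thr,
        spec.neuron.v_reset,
        1.0 - dt / spec.syn.tau_bal, 1.0 - dt / spec.syn.tau_plas,
        1.0 / spec.syn.tau_bal, 1.0 / spec.syn.tau_plas,
        v, u_bal, u_plas, x_plas, r_plas, r_x,
        stat.indptr.astype(np.int64), stat.indices.astype(np.int64), stat_wj,
        plas_indptr, plas_rows, plas_wj,
        drives.x_bal, drives.noise_amp,
        stim if has_stim else np.zeros((0, n)), burn_steps,
        ext_rate, wx,
        la["learn"], tgt_start + la["learn_start"], la["learn_stride"],
        la["f_targets"], la["trained"], la["pre_idx"], la["w"], la["P"],
        la["plas_pos"],
        rec_ids, rec_slot, network.presyn_groups(), ub_groups,
        tgt_start, rec_stride, rec_traces,
        tgt_start, spk_n, spk_t, sum_u,
    )
    _kernel_status(status, bad_i, bad_t, dt)

    spk_time_ms = (spk_t[:nspk] - tgt_start) * dt
    trace = None
    if len(rec_ids) > 0:
        trace = InputTrace(neuron_ids=rec_ids,
                           time_ms=np.arange(rec_traces.shape[0]) *
                           rec_stride * dt,
                           traces=rec_traces,
                           x_bal=drives.x_bal[rec_ids])
    mean_u = sum_u / tgt_steps + drives.x_bal
    return (spk_n[:nspk].copy(), spk_time_ms, trace, mean_u,
            (err_sum, n_err))


def simulate(network: Network, drives: ExternalDrive, duration_ms: float,
             n_trials: int, seed: int, *, burn_ms: float = 500.0,
             trial_type=None, record: RecordSpec | None = None,
             average_traces: bool = True):
    """Simulate repeated trials of the (possibly trained) network.

    Trials are independent given distinct sub-seeds: membrane potentials are
    re-randomized each trial while the stimulus and external-unit rate
    patterns stay frozen.  Returns (SpikeData, InputTrace | None, mean_u)
    where the trace is trial-averaged when ``average_traces`` and ``mean_u``
    is the per-neuron time-mean total input averaged over trials.
    """
    all_tr, all_n, all_t = [], [], []
    acc_trace = None
    acc_mean_u = np.zeros(network.layout.N)
    trace = None
    plas_csc = (network.plastic.to_csc(network.spec.syn.tau_plas)
                if network.plastic is not None and
                network.plastic.n_trained else None)
    for k in range(n_trials):
        spk_n, spk_t, trace, mean_u, _ = run_trial(
            network, drives, duration_ms, subseed(seed, 1000 + k),
            burn_ms=burn_ms, trial_type=trial_type, record=record,
            plas_csc=plas_csc)
        all_tr.append(np.full(len(spk_n), k, dtype=np.int32))
        all_n.append(spk_n)
        all_t.append(spk_t)
        acc_mean_u += mean_u / n_trials
        if trace is not None:
            if acc_trace is None:
                acc_trace = np.zeros_like(trace.traces)
            acc_trace += trace.traces / n_trials
    spikes = SpikeData(trial=np.concatenate(all_tr),
                       neuron=np.concatenate(all_n),
                       time_ms=np.concatenate(all_t),
                       duration_ms=duration_ms, n_trials=n_trials,
                       n_neurons=network.layout.N)
    out_trace = None
    if trace is not None:
        out_trace = InputTrace(neuron_ids=trace.neuron_ids,
                               time_ms=trace.time_ms,
                               traces=acc_trace if average_traces
                               else trace.traces,
                               x_bal=trace.x_bal)
    return spikes, out_trace, acc_mean_u
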