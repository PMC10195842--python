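"""Recursive-least-squares subset training with L2 and ROWSUM regularization.

Each trained neuron i minimizes its private cost

    C_i = ½ Σ_t (f_i(t) − u_i(t) − X_i(t))²
        + ½ [ λ‖w_i‖² + μ Σ_{α∈{E,I}} (w_i·1_α)² ]

over its plastic weight vector w_i (recurrent then feedforward entries).
The λ term is a ridge penalty that makes the online solution unique and sets
the effective learning rate; the μ (ROWSUM) term penalizes changes to the
aggregate excitatory and inhibitory plastic weight of the row, keeping the
plastic input near the spike threshold and the network in the balanced
regime.  The online update is the standard RLS recursion with
inverse-correlation matrix P initialized to (λI + μΣ1_α1_αᵀ)⁻¹.

``rls_step``/``init_P``/``cost_eval`` are the per-neuron reference
implementations (plain NumPy); ``train_subset`` drives the whole trained
population through the compiled network kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network, ExternalDrive, run_trial, subseed
from .params import TrainingConfig

__all__ = ["RLSState", "TrainingDiagnostics", "init_P", "rls_step",
           "cost_eval", "train_subset", "TrainingDivergence"]


def init_P(lam: float, mu: float, indicators) -> np.ndarray:
    """Initial inverse-correlation matrix P0 = (λI + μ Σ_α 1_α1_αᵀ)⁻¹.

    Computed in closed form via the Woodbury identity: because the indicator
    vectors are disjoint and binary,

        P0 = I/λ − Σ_α  μ / (λ(λ + μ‖1_α‖²)) · 1_α1_αᵀ .
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    inds = [np.asarray(v, dtype=float) for v in indicators]
    l_tot = len(inds[0]) if inds else 0
    p0 = np.eye(l_tot) / lam
    for v in inds:
        norm2 = v @ v
        if norm2 > 0 and mu > 0:
            p0 -= (mu / (lam * (lam + mu * norm2))) * np.outer(v, v)
    return p0


@dataclass
class RLSState:
    """Per-neuron online training state."""

    pre_idx: np.ndarray          # presynaptic ids (recurrent part)
    w: np.ndarray                # (L_tot,)
    P: np.ndarray                # (L_tot, L_tot)
    ind_e: np.ndarray
    ind_i: np.ndarray
    last_error: float = 0.0

    @classmethod
    def create(cls, pre_idx, w0, ind_e, ind_i, lam, mu) -> "RLSState":
        return cls(pre_idx=np.asarray(pre_idx),
                   w=np.array(w0, dtype=float),
                   P=init_P(lam, mu, (ind_e, ind_i)),
                   ind_e=np.asarray(ind_e, float),
                   ind_i=np.asarray(ind_i, float))


def rls_step(state: RLSState, r_n: np.ndarray, f_n: float,
             u_bal_n: float, x_bal_n: float) -> RLSState:
    """One online update: e = f − u_bal − X_bal − w·r; w += e·P_n·r.

    P is updated by the rank-1 Sherman–Morrison recursion
    P_n = P_{n−1} − P_{n−1}rrᵀP_{n−1}/(1 + rᵀP_{n−1}r) and re-symmetrized.
    """
    r = np.asarray(r_n, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite presynaptic vector")
    pr = state.P @ r
    c = 1.0 + r @ pr
    if c <= 0:
        raise FloatingPointError("1 + r'Pr <= 0: P lost positive definiteness")
    e = f_n - u_bal_n - x_bal_n - state.w @ r
    state.w = state.w + (e / c) * pr
    state.P = state.P - np.outer(pr, pr) / c
    state.P = 0.5 * (state.P + state.P.T)
    state.last_error = e
    return state


def cost_eval(w: np.ndarray, sequence, lam: float, mu: float,
              indicators) -> float:
    """Discrete-grid cost ½Σ(f − u_bal − X − w·r)² + ½[λ‖w‖² + μΣ(w·1_α)²].

    ``sequence`` is an iterable of (r_t, f_t, u_bal_t, x_bal) tuples.
    """
    w = np.asarray(w, dtype=float)
    sq = 0.0
    for r_t, f_t, u_t, x_t in sequence:
        err = f_t - u_t - x_t - w @ np.asarray(r_t)
        sq += err * err
    reg = lam * (w @ w)
    for v in indicators:
        reg += mu * (w @ np.asarray(v, float)) ** 2
    return 0.5 * sq + 0.5 * reg


@dataclass
class TrainingDiagnostics:
    """Per-iteration summaries of a training run."""

    mean_abs_error: np.ndarray = field(default_factory=lambda: np.zeros(0))
    trial_types: list = field(default_factory=list)
    rowsum_drift: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))


class TrainingDivergence(RuntimeError):
    pass


def train_subset(network: Network, targets: dict, drives: ExternalDrive,
                 config: TrainingConfig, *, burn_ms: float = 500.0,
                 reset_P: bool = False) -> TrainingDiagnostics:
    """FORCE-style online training of the selected subset.

    ``targets`` maps trial type to an (M, T_bins) target-input matrix on a
    uniform grid over [0, T_target], one row per trained neuron in the order
    of ``network.plastic.trained``.  Each iteration runs the network through
    burn-in, that type's stimulus, and the target window, applying the RLS
    update to every trained neuron every ``learn_every`` ms.  Iterations
    alternate trial types.  Final weights are written back into
    ``network.plastic``; P carries over across iterations unless ``reset_P``.
    """
    pl = network.plastic
    if pl is None or pl.n_trained == 0:
        raise ValueError("network has no plastic connectivity to train")
    types = list(targets.keys())
    for tt, f in targets.items():
        if f.shape[0] != pl.n_trained:
            raise ValueError(f"targets[{tt!r}] rows != number of trained "
                             f"neurons")

    dt = network.spec.neuron.dt
    stride = int(round(config.learn_every / dt))
    if abs(stride * dt - config.learn_every) > 1e-9:
        raise ValueError("learn_every must be a multiple of dt")
    n_learn = int(round(config.t_target / config.learn_every))
    t_learn = (np.arange(n_learn) + 1) * config.learn_every

    # resample targets onto the update grid
    f_grids = {}
    for tt, f in targets.items():
        t_bins = f.shape[1]
        bin_dt = config.t_target / t_bins
        t_axis = (np.arange(t_bins) + 0.5) * bin_dt
        f_grids[tt] = np.stack(
            [np.interp(t_learn, t_axis, f[m]) for m in range(pl.n_trained)],
            axis=1)  # (n_learn, M)

    ind_e, ind_i = pl.indicators()
    p0 = init_P(config.lam, config.mu, (ind_e, ind_i))
    P = np.repeat(p0[None, :, :], pl.n_trained, axis=0).copy()
    w = pl.w.copy()
    rowsum0 = pl.rowsums().sum(axis=0)

    plas_csc = pl.to_csc(network.spec.syn.tau_plas)
    wx = np.ascontiguousarray(w[:, pl.l_rec:]).copy()

    mean_err = np.zeros(config.n_iter)
    used_types = []
    drift = np.zeros((config.n_iter, 2))
    for it in range(config.n_iter):
        tt = types[it % len(types)]
        if reset_P:
            P[:] = p0[None, :, :]
        learn_args = dict(learn=True, learn_start=stride - 1,
                          learn_stride=stride, f_targets=f_grids[tt],
                          trained=pl.trained, pre_idx=pl.pre_idx,
                          w=w, P=P, plas_pos=plas_csc[3])
        _, _, _, _, (err_sum, n_err) = run_trial(
            network, drives, config.t_target,
            subseed(config.seed, 31, it), burn_ms=burn_ms,
            trial_type=tt if tt in drives.stim else None,
            learn_args=learn_args, wx=wx, plas_csc=plas_csc)
        mean_err[it] = err_sum / max(n_err, 1)
        used_types.append(tt)
        pl.w[:] = w  # kernel mutates w in place; mirror into the container
        drift[it] = pl.rowsums().sum(axis=0) - rowsum0
        if it >= 5 and mean_err[it] > 10.0 * max(mean_err[it - 5], 1e-12):
            raise TrainingDivergence(
                f"training diverged at iteration {it}: mean |e| "
                f"{mean_err[it]:.3g} vs {mean_err[it - 5]:.3g} five "
                f"iterations earlier")
    return TrainingDiagnostics(mean_abs_error=mean_err[:config.n_iter],
                               trial_types=used_types, rowsum_drift=drift)
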