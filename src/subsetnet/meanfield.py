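"""Balanced-regime mean-field theory and activity-spread predictions.

In the strong-coupling limit the E and I population rates solve the linear
"balanced equations"

    J̄_EE r_E − J̄_EI r_I + X̄_E ≈ 0
    J̄_IE r_E − J̄_II r_I + X̄_I ≈ 0

(J̄ stored as magnitudes; the inhibitory sign is explicit).  Rates are in
spikes/ms internally, converted to Hz at reporting boundaries.

The spread analysis treats the aggregate static input from a trained
population to an untrained neuron as a random projection of the trained
activity: writing the centered trained rates δφ = U√λVᵀ (SVD), the input's
loading on temporal mode V_n across untrained neurons is Gaussian with mean
zero and variance J̄²λ_n/N_pre; the across-neuron variance of the *time
mean* input is the quenched disorder q = J̄²[⟨φ⟩²].  These yield the
testable predictions: Gaussian per-mode loadings, loading variance growing
with the mode's singular value, vanishing transfer under 1/K (weak)
coupling, and choice-selectivity spread with variance set by the R/L
differences of quenched disorder and ramp loadings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (Network, ExternalDrive, StaticConnectivity,
                      build_static_connectivity)
from .params import NetworkSpec

__all__ = [
    "BalanceSolution", "SpreadPrediction", "solve_balance",
    "input_fluctuation", "quenched_disorder",
    "predict_loading_distribution", "selectivity_spread_prediction",
    "weak_coupling_network",
]


@dataclass
class BalanceSolution:
    r_e: float            # spikes/ms
    r_i: float
    physical: bool
    residual: float

    @property
    def rates_hz(self) -> tuple[float, float]:
        return self.r_e * 1000.0, self.r_i * 1000.0


def solve_balance(jbar: np.ndarray, xbar: np.ndarray) -> BalanceSolution:
    """Exact solve of the 2×2 balanced equations.

    ``jbar`` holds magnitudes [[J_EE, J_EI], [J_IE, J_II]]; ``xbar`` the
    unscaled external drives (X̄_E, X̄_I).  Rates scale linearly with the
    drives; negative solutions are flagged non-physical.
    """
    jbar = np.asarray(jbar, dtype=float)
    xbar = np.asarray(xbar, dtype=float)
    a = np.array([[jbar[0, 0], -jbar[0, 1]],
                  [jbar[1, 0], -jbar[1, 1]]])
    if abs(np.linalg.det(a)) < 1e-14:
        raise np.linalg.LinAlgError("balanced equations are singular")
    r = np.linalg.solve(a, -xbar)
    residual = float(np.max(np.abs(a @ r + xbar)))
    return BalanceSolution(r_e=float(r[0]), r_i=float(r[1]),
                           physical=bool(np.all(r >= 0)),
                           residual=residual)


def input_fluctuation(jbar: np.ndarray, rates_per_ms: np.ndarray,
                      tau_bal: float) -> np.ndarray:
    """Mean-field size of the fast static-input fluctuations per population.

    With the unit-integral filter convention the filtered static input has
    variance (J̄_αE² r_E + J̄_αI² r_I)/(2 τ_bal); this is the
    dimensionally explicit form of the fluctuation entering the transfer
    function (see docs/methods.md for the units discussion).
    """
    jbar = np.asarray(jbar, dtype=float)
    r = np.asarray(rates_per_ms, dtype=float)
    var = (jbar[:, 0] ** 2 * r[0] + jbar[:, 1] ** 2 * r[1]) / (2.0 * tau_bal)
    return np.sqrt(var)


def quenched_disorder(mean_rates_per_ms: np.ndarray, jbar_ab: float) -> float:
    """q = J̄² · mean over presynaptic neurons of (time-mean rate)².

    The across-neuron variance of the time-mean aggregate input a neuron
    receives from the population, arising from the frozen random
    connectivity.
    """
    r = np.asarray(mean_rates_per_ms, dtype=float)
    return float(jbar_ab ** 2 * np.mean(r ** 2))


@dataclass
class SpreadPrediction:
    singular_values: np.ndarray       # √λ_n of centered trained activity
    right_vectors: np.ndarray         # (n, T) temporal modes
    predicted_var: np.ndarray         # per-mode Gaussian variance of loadings
    quenched: float


def predict_loading_distribution(trained_rates_per_ms: np.ndarray,
                                 jbar_ab: float,
                                 n_pre: int | None = None) -> SpreadPrediction:
    """Predicted Gaussian loading distribution of inputs to untrained neurons.

    ``trained_rates_per_ms`` is (M, T): the trained population's PSTHs in
    spikes/ms.  The centered matrix is decomposed by SVD; the loading of the
    aggregate input to an untrained neuron on temporal mode n is predicted
    to be Gaussian with mean 0 and variance J̄²λ_n/N_pre where λ_n is the
    n-th eigenvalue (squared singular value) and N_pre the presynaptic pool
    size (defaults to M).
    """
    phi = np.asarray(trained_rates_per_ms, dtype=float)
    n_pre = phi.shape[0] if n_pre is None else n_pre
    dphi = phi - phi.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(dphi, full_matrices=False)
    pred = jbar_ab ** 2 * (s ** 2) / n_pre
    q = quenched_disorder(phi.mean(axis=1), jbar_ab)
    return SpreadPrediction(singular_values=s, right_vectors=vt,
                            predicted_var=pred, quenched=q)


def selectivity_spread_prediction(rates_r_per_ms: np.ndarray,
                                  rates_l_per_ms: np.ndarray,
                                  jbar_ab: float) -> tuple[float, float]:
    """Constants (A, B) of the predicted input selectivity of untrained
    neurons, SI_i(t) ≈ A·Δz_i + B·Δã_i·t.

    A² is the across-neuron variance of the R−L difference of time-mean
    aggregate inputs (quenched-disorder difference); B² the variance of the
    R−L difference of ramp-mode loadings.  Both follow the same
    random-projection argument as the loading prediction.
    """
    r = np.asarray(rates_r_per_ms, dtype=float)
    l = np.asarray(rates_l_per_ms, dtype=float)
    if r.shape != l.shape:
        raise ValueError("R/L shapes differ")
    m, t = r.shape
    a2 = jbar_ab ** 2 * np.mean((r.mean(axis=1) - l.mean(axis=1)) ** 2)
    ramp = np.arange(t) - (t - 1) / 2.0
    ramp = ramp / np.linalg.norm(ramp)
    dr = r - r.mean(axis=1, keepdims=True)
    dl = l - l.mean(axis=1, keepdims=True)
    c_r = dr @ ramp
    c_l = dl @ ramp
    b2 = jbar_ab ** 2 * np.mean((c_r - c_l) ** 2)
    return float(np.sqrt(a2)), float(np.sqrt(b2))


def weak_coupling_network(strong: Network, mean_inputs: np.ndarray,
                          sigma_meas: tuple[float, float],
                          x_weak: float = 0.35,
                          x_factors: tuple[float, float] = (1.5, 0.8),
                          seed: int = 0) -> tuple[Network, ExternalDrive]:
    """Weak-coupling control matched to a strong network.

    Same adjacency, weights rescaled from J̄/√K to J̄/K; each neuron
    receives (i) a uniform external drive X̄_α·x_weak, (ii) a per-neuron
    constant X^gaussian equal to the centered mean input it received in the
    strong untrained network (reproducing the heterogeneous operating
    points), and (iii) injected white noise whose amplitude is set so the
    membrane-potential variance matches that produced by the strong
    network's measured input fluctuations σ_α.
    """
    spec = strong.spec
    k = spec.syn.kbar
    weights = strong.static.weights.copy()
    # rescale: divide by √K per presynaptic block (J̄/√K → J̄/K)
    n_e = spec.layout.N_E
    cols = np.repeat(np.arange(spec.layout.N), np.diff(weights.indptr))
    scale = np.where(cols < n_e, 1.0 / np.sqrt(k[0, 0]), 1.0 / np.sqrt(k[0, 1]))
    weights = weights.copy()
    weights.data = weights.data * scale
    static = StaticConnectivity(weights=weights, layout=spec.layout)

    weak_spec = NetworkSpec(
        neuron=spec.neuron, layout=spec.layout, syn=spec.syn,
        xbar=np.array([x_factors[0] * x_weak, x_factors[1] * x_weak]),
        weight_scaling="linear", input_gain=spec.input_gain)
    net = Network(spec=weak_spec, static=static, plastic=strong.plastic)

    x_bal = np.empty(spec.layout.N)
    x_bal[spec.layout.e_slice] = spec.input_gain * x_factors[0] * x_weak
    x_bal[spec.layout.i_slice] = spec.input_gain * x_factors[1] * x_weak
    gaussian = mean_inputs - np.array(
        [mean_inputs[spec.layout.e_slice].mean()] * spec.layout.N_E
        + [mean_inputs[spec.layout.i_slice].mean()] * spec.layout.N_I)
    x_bal = x_bal + gaussian

    tau_m, tau_b = spec.neuron.tau_m, spec.syn.tau_bal
    # white current noise v += amp·√dt·ξ: stationary var amp²τ_m/2(dt-free);
    # match colored-input variance σ²·τ_b/(τ_b+τ_m)
    amp = np.empty(spec.layout.N)
    for a, sl in enumerate((spec.layout.e_slice, spec.layout.i_slice)):
        amp[sl] = sigma_meas[a] * np.sqrt(
            2.0 * tau_b / ((tau_b + tau_m) * tau_m))
    drives = ExternalDrive(x_bal=x_bal, noise_amp=amp)
    return net, drives


def calibrate_weak_drives(net: Network, drives: ExternalDrive,
                          target_rates_hz: tuple[float, float], seed: int,
                          n_iter: int = 4, sim_ms: float = 1500.0,
                          tol: float = 0.3) -> ExternalDrive:
    """Tune the weak network's uniform drives to match target rates.

    The 1/K-coupled network has no balanced cancellation, so its rates are
    set directly by the external drives; a short fixed-point iteration
    rescales the per-population uniform drive until the population rates
    are within ``tol`` (relative) of the strong network's.  Only the
    uniform component is adjusted; the per-neuron Gaussian inputs and the
    noise amplitude stay fixed.
    """
    from .network import simulate

    layout = net.layout
    slices = (layout.e_slice, layout.i_slice)
    gauss = drives.x_bal.copy()
    uni = np.array([drives.x_bal[s].mean() for s in slices])
    for s, u in zip(slices, uni):
        gauss[s] -= u
    target = np.asarray(target_rates_hz, dtype=float)
    for it in range(n_iter):
        x = gauss.copy()
        for s, u in zip(slices, uni):
            x[s] += u
        drives.x_bal = x
        spk, _, _ = simulate(net, drives, sim_ms, 1, seed + it,
                             burn_ms=500.0)
        r = spk.rates_hz()
        meas = np.array([r[s].mean() for s in slices])
        if np.all(np.abs(meas - target) <= tol * target):
            break
        ratio = np.clip(target / np.clip(meas, 0.05, None), 0.25, 4.0)
        uni = uni * ratio ** 0.7
    return drives
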