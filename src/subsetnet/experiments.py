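"""Config-driven experiment pipelines at user-chosen scale.

Each experiment builds a network, optionally trains a subset of neurons,
simulates trials, and runs the analyses; `run_experiment` wraps the
pipelines with artifact serialization and a hashed manifest.  Default
scales are desk-sized (hundreds to a few thousand neurons); the
construction is the same at full scale.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analysis, meanfield, targets as tg
from .analysis import (compute_psth, pca_psth, transferred_activity,
                       pc_fidelity, choice_selectivity, spike_stats,
                       trial_rate_traces, choice_mode, project_modes,
                       recovery_time, boxcar_smooth)
from .network import (Network, RecordSpec, build_plastic_connectivity,
                      build_static_connectivity, make_drives, simulate,
                      subseed)
from .params import (NetworkSpec, TrainingConfig, alm_network_spec,
                     sine_network_spec)
from .training import train_subset

__all__ = [
    "ExperimentConfig", "run_experiment", "make_fixture",
    "build_sine_network", "sine_experiment",
    "build_alm_network", "alm_training_experiment",
    "weak_control_experiment", "perturbation_recovery_experiment",
    "ei_transfer_sweep", "modulation_sweep",
]

log = logging.getLogger(__name__)

# plastic-synapse counts per √K_E for the two standard task setups:
# sine targets use 2·√K_E per presynaptic population and no feedforward
# units; the cortical-PSTH setups use 4·√K_E per population plus 3.65·√K_E
# feedforward synapses.
SINE_C_REC = 2.0
ALM_C_REC = 4.0
ALM_C_FFWD = 3.65
WBAR_SINE = np.array([[2.0, 1.0], [2.0, 1.0]])
WBAR_ALM = np.array([[1.0, 0.5], [1.0, 0.5]])


def _l_counts(spec: NetworkSpec, c_rec: float, c_ffwd: float):
    k_e = spec.syn.kbar[0, 0]
    l_per_pop = max(2, int(round(c_rec * np.sqrt(k_e))))
    l_x = int(round(c_ffwd * np.sqrt(k_e)))
    return l_per_pop, l_x


# ---------------------------------------------------------------------------
# sine-target pipeline (Fig-1/5 analog)


def build_sine_network(n: int = 2000, seed: int = 0,
                       trained: np.ndarray | None = None) -> Network:
    """Strong-coupling network with sine-task plastic synapses.

    By default every neuron is trained (the full-network sine protocol).
    """
    spec = sine_network_spec(n)
    static = build_static_connectivity(spec.layout, spec.syn,
                                      subseed(seed, 1), gain=spec.input_gain)
    if trained is None:
        trained = np.arange(spec.layout.N)
    l_per_pop, _ = _l_counts(spec, SINE_C_REC, 0.0)
    plastic = build_plastic_connectivity(
        spec.layout, static, trained, l_per_pop, 0, WBAR_SINE, spec.syn,
        subseed(seed, 2), gain=spec.input_gain)
    return Network(spec=spec, static=static, plastic=plastic)


def sine_experiment(n: int = 2000, n_iter: int = 100, freq_hz: float = 1.0,
                    amplitude: float = 0.5, t_target_ms: float = 1000.0,
                    n_trials: int = 30, seed: int = 0,
                    learn_every: float = 10.0,
                    record_sample: int = 400) -> dict:
    """Train every neuron on random-phase sine input targets and measure
    training fidelity and spiking statistics.

    Returns a dict with the median smoothed-input/target correlation over
    trained neurons, the population Fano factor over trials, ISI CV, the
    PCA of the trained PSTHs, and the diagnostics of the training run.
    """
    net = build_sine_network(n, seed)
    drives = make_drives(net.spec, subseed(seed, 3), trial_types=("A",))

    # baseline inputs of the untrained network
    untrained = Network(spec=net.spec, static=net.static)
    _, _, mean_u = simulate(untrained, drives, 2000.0, 1, subseed(seed, 4))

    # the tabulated amplitude is in the same input units as J̄ and X̄; the
    # efficacy normalization converts it to internal voltage units
    sine = tg.SineSpec(amplitude=amplitude * net.spec.input_gain,
                       freq_hz=freq_hz, t_target_ms=t_target_ms)
    tset = tg.make_sine_targets(sine, mean_u[net.plastic.trained],
                                net.plastic.trained, subseed(seed, 5))
    cfg = TrainingConfig(n_iter=n_iter, t_target=t_target_ms,
                         learn_every=learn_every, seed=subseed(seed, 6))
    diag = train_subset(net, {"A": tset.f}, drives, cfg)

    rng = np.random.default_rng(subseed(seed, 7))
    rec_ids = np.sort(rng.choice(net.plastic.trained,
                                 min(record_sample, net.plastic.n_trained),
                                 replace=False))
    rec = RecordSpec(neuron_ids=rec_ids, stride_ms=5.0)
    spikes, trace, _ = simulate(net, drives, t_target_ms, n_trials,
                                subseed(seed, 8), trial_type="A", record=rec)

    # correlation between the 200 ms-smoothed total input and the target
    tot = boxcar_smooth(trace.total(), int(round(200.0 / 5.0)))
    row_of = {int(i): m for m, i in enumerate(net.plastic.trained)}
    corr = np.empty(len(rec_ids))
    t_axis = tset.time_axis()
    for s, i in enumerate(rec_ids):
        f_i = np.interp(trace.time_ms, t_axis, tset.f[row_of[int(i)]])
        corr[s] = np.corrcoef(tot[:, s], f_i)[0, 1]

    stats_ = spike_stats(spikes)
    psth = compute_psth(spikes)
    pca = pca_psth(psth)
    return {"network": net, "drives": drives, "targets": tset,
            "spikes": spikes, "trace": trace, "diagnostics": diag,
            "median_corr": float(np.median(corr)),
            "stats": stats_, "psth": psth, "pca": pca}


# ---------------------------------------------------------------------------
# cortical-like (ALM) pipeline


def build_alm_network(n: int = 800, seed: int = 0) -> Network:
    spec = alm_network_spec(n)
    static = build_static_connectivity(spec.layout, spec.syn,
                                      subseed(seed, 1), gain=spec.input_gain)
    return Network(spec=spec, static=static)


def alm_training_experiment(scenario: str = "E", frac: float = 0.4,
                            n: int = 800, n_iter: int = 40,
                            n_trials: int = 60, seed: int = 0,
                            multiplier: float | None = None,
                            learn_every: float = 20.0,
                            record_inputs: int = 0,
                            psth_trials_cap: int | None = None) -> dict:
    """Train a fraction of one subnetwork on synthetic cortical-like PSTHs.

    ``scenario`` selects the trained subnetwork: "E" trains pyramidal-like
    targets on excitatory neurons, "I" fast-spiking-like targets on
    inhibitory neurons.  Measures the trained-subnetwork PC spectrum and
    the activity transferred to the untrained subnetwork.
    """
    if scenario not in ("E", "I"):
        raise ValueError("scenario must be 'E' or 'I'")
    net = build_alm_network(n, seed)
    spec = net.spec
    layout = spec.layout
    l_per_pop, l_x = _l_counts(spec, ALM_C_REC, ALM_C_FFWD)
    drives = make_drives(spec, subseed(seed, 3), l_x=l_x,
                         trial_types=("R", "L"))

    # untrained network: rates for matching, baselines, input fluctuations
    rng = np.random.default_rng(subseed(seed, 4))
    n_probe = min(60, layout.N_E)
    probe = np.concatenate([
        np.sort(rng.choice(layout.N_E, n_probe, replace=False)),
        np.sort(layout.N_E + rng.choice(layout.N_I, n_probe, replace=False))])
    spikes0, trace0, mean_u0 = simulate(
        Network(spec=spec, static=net.static), drives, 3000.0, 1,
        subseed(seed, 5), record=RecordSpec(neuron_ids=probe, stride_ms=1.0))
    rates0 = spikes0.rates_hz()
    sig_e, sig_i = tg.estimate_sigma(trace0, layout)
    # the inversion uses the self-calibrated effective fluctuation: fit the
    # transfer function to the untrained network's own input/rate relation
    tf0 = tg.TransferFunction(tau_m=spec.neuron.tau_m,
                              v_thr=spec.neuron.v_thr,
                              v_reset=spec.neuron.v_reset)
    sig_fit_e, delta_e = tg.fit_transfer_to_rates(
        mean_u0[layout.e_slice], rates0[layout.e_slice], tf0)
    sig_fit_i, delta_i = tg.fit_transfer_to_rates(
        mean_u0[layout.i_slice], rates0[layout.i_slice], tf0)

    # synthetic targets
    kw = {} if multiplier is None else {"multiplier": multiplier}
    tspec = tg.pyramidal_spec(**kw) if scenario == "E" else \
        tg.fast_spiking_spec(**kw)
    pool = np.arange(layout.N_E) if scenario == "E" else \
        np.arange(layout.N_E, layout.N)
    m = int(round(frac * len(pool)))
    pair = tg.make_synthetic_psths(tspec, m, subseed(seed, 6))
    match = tg.match_neurons_by_rate(rates0[pool], pool, pair.rates_hz)
    trained = match.model_ids
    sigma = sig_fit_e if scenario == "E" else sig_fit_i
    delta = delta_e if scenario == "E" else delta_i
    tf = tf0
    order = np.argsort(trained)
    tset_r = tg.psth_to_targets(pair.r[order], sigma, pair.t_target_ms,
                                trained[order], tf, offset=delta)
    tset_l = tg.psth_to_targets(pair.l[order], sigma, pair.t_target_ms,
                                trained[order], tf, offset=delta)

    net.plastic = build_plastic_connectivity(
        layout, net.static, trained, l_per_pop, l_x, WBAR_ALM, spec.syn,
        subseed(seed, 7), gain=spec.input_gain)
    cfg = TrainingConfig(n_iter=n_iter, t_target=pair.t_target_ms,
                         learn_every=learn_every, seed=subseed(seed, 8))
    diag = train_subset(net, {"R": tset_r.f, "L": tset_l.f}, drives, cfg)

    rec = None
    if record_inputs:
        untrained_pool = np.setdiff1d(
            np.arange(layout.N_E, layout.N) if scenario == "E"
            else np.arange(layout.N_E), trained)
        ids = np.sort(rng.choice(untrained_pool,
                                 min(record_inputs, len(untrained_pool)),
                                 replace=False))
        rec = RecordSpec(neuron_ids=ids, stride_ms=1.0)

    psth_trials = n_trials if psth_trials_cap is None else psth_trials_cap
    out_spikes, out_traces = {}, {}
    for tt in ("R", "L"):
        spk, trc, _ = simulate(net, drives, pair.t_target_ms, psth_trials,
                               subseed(seed, 9, ord(tt)), trial_type=tt,
                               record=rec)
        out_spikes[tt] = spk
        out_traces[tt] = trc

    # analysis: trained subnetwork and untrained opposite subnetwork
    tr_ids = trained
    untr_ids = np.setdiff1d(np.arange(layout.N_E, layout.N), trained) \
        if scenario == "E" else np.setdiff1d(np.arange(layout.N_E), trained)
    psth_tr = {tt: compute_psth(out_spikes[tt], tr_ids) for tt in ("R", "L")}
    psth_untr = {tt: compute_psth(out_spikes[tt], untr_ids)
                 for tt in ("R", "L")}

    def _concat(d):
        return np.concatenate([d["R"].rates, d["L"].rates], axis=0)

    trained_act = _concat(psth_tr)
    untr_act = _concat(psth_untr)
    res = {
        "network": net, "drives": drives, "pair": pair,
        "targets": {"R": tset_r, "L": tset_l},
        "trained_ids": tr_ids, "untrained_ids": untr_ids,
        "diagnostics": diag, "spikes": out_spikes, "traces": out_traces,
        "sigma": (sig_e, sig_i), "sigma_fit": (sig_fit_e, sig_fit_i),
        "delta_fit": (delta_e, delta_i),
        "rates0": rates0, "mean_u0": mean_u0,
        "psth_trained": psth_tr, "psth_untrained": psth_untr,
        "trained_var6": 100.0 * transferred_activity(trained_act, 6),
        "transferred_var6": 100.0 * transferred_activity(untr_act, 6),
        "pca_trained": pca_psth(trained_act),
        "pca_untrained": pca_psth(untr_act),
    }
    res["fidelity"] = pc_fidelity(res["pca_trained"], res["pca_untrained"],
                                  n_modes=4)
    _, sel = choice_selectivity(psth_untr["R"].rates, psth_untr["L"].rates)
    res["untrained_selectivity"] = sel
    return res


def weak_control_experiment(strong_result: dict, seed: int = 0,
                            n_iter: int | None = None,
                            n_trials: int = 60) -> dict:
    """Matched weak-coupling control for an ALM-style training run.

    Rebuilds the same network with 1/K weights, per-neuron Gaussian inputs
    copied from the strong untrained network and calibrated white noise,
    trains the same subset on the same targets, and measures the
    transferred activity.
    """
    strong_net = strong_result["network"]
    layout = strong_net.layout
    weak_net, weak_drives = meanfield.weak_coupling_network(
        strong_net, strong_result["mean_u0"], strong_result["sigma"],
        seed=seed)
    # fresh plastic weights at their initial values (the strong run mutated
    # the shared container): rebuild support identically
    spec = weak_net.spec
    l_per_pop, l_x = _l_counts(strong_net.spec, ALM_C_REC, ALM_C_FFWD)
    weak_net.plastic = build_plastic_connectivity(
        layout, strong_net.static, strong_result["trained_ids"], l_per_pop,
        l_x, WBAR_ALM, strong_net.spec.syn, subseed(seed, 7),
        gain=strong_net.spec.input_gain)
    weak_drives.stim = strong_result["drives"].stim
    weak_drives.stim_ms = strong_result["drives"].stim_ms
    weak_drives.ext_rate_ms = strong_result["drives"].ext_rate_ms
    rates0 = strong_result["rates0"]
    weak_drives = meanfield.calibrate_weak_drives(
        Network(spec=spec, static=weak_net.static), weak_drives,
        (rates0[layout.e_slice].mean(), rates0[layout.i_slice].mean()),
        subseed(seed, 15))

    tsets = strong_result["targets"]
    cfg = TrainingConfig(n_iter=n_iter if n_iter is not None
                         else len(strong_result["diagnostics"].mean_abs_error),
                         t_target=strong_result["pair"].t_target_ms,
                         learn_every=20.0, seed=subseed(seed, 8))
    diag = train_subset(weak_net, {"R": tsets["R"].f, "L": tsets["L"].f},
                        weak_drives, cfg)
    out = {}
    for tt in ("R", "L"):
        spk, _, _ = simulate(weak_net, weak_drives,
                             strong_result["pair"].t_target_ms, n_trials,
                             subseed(seed, 9, ord(tt)), trial_type=tt)
        out[tt] = spk
    untr = strong_result["untrained_ids"]
    act = np.concatenate([compute_psth(out[tt], untr).rates
                          for tt in ("R", "L")], axis=0)
    return {"network": weak_net, "drives": weak_drives, "spikes": out,
            "diagnostics": diag,
            "transferred_var6": 100.0 * transferred_activity(act, 6),
            "pca_untrained": pca_psth(act)}


# ---------------------------------------------------------------------------
# sweeps


def ei_transfer_sweep(fracs=(0.4, 0.7, 1.0), scenarios=("E", "I"),
                      seeds=(0, 1, 2), **kw) -> dict:
    """Transferred activity versus trained fraction for both scenarios.

    Returns {"table": rows, "difference": mean I-minus-E transferred
    variance in percentage points}.
    """
    rows = []
    for sc in scenarios:
        for fr in fracs:
            for sd in seeds:
                r = alm_training_experiment(scenario=sc, frac=fr,
                                            seed=subseed(sd, 77), **kw)
                rows.append({"scenario": sc, "frac": fr, "seed": sd,
                             "trained_var6": r["trained_var6"],
                             "transferred_var6": r["transferred_var6"]})
    by = {(row["scenario"], row["frac"], row["seed"]):
          row["transferred_var6"] for row in rows}
    diffs = [by[("I", fr, sd)] - by[("E", fr, sd)]
             for fr in fracs for sd in seeds
             if ("I", fr, sd) in by and ("E", fr, sd) in by]
    return {"table": rows,
            "difference": float(np.mean(diffs)) if diffs else np.nan}


def modulation_sweep(multipliers=(0.5, 1.0, 2.0), frac: float = 0.4,
                     seed: int = 0, **kw) -> dict:
    """Transferred activity versus modulation strength of I-trained targets."""
    rows = []
    for m in multipliers:
        r = alm_training_experiment(scenario="I", frac=frac, seed=seed,
                                    multiplier=m, **kw)
        rows.append({"multiplier": m,
                     "transferred_var6": r["transferred_var6"]})
    return {"table": rows}


# ---------------------------------------------------------------------------
# spread mechanism: inputs to untrained neurons vs the random-projection
# theory


def spread_mechanism_experiment(n: int = 800, freq_hz: float = 2.0,
                                n_iter: int = 30, n_trials: int = 30,
                                seed: int = 0, n_record: int = 100,
                                weak: bool = False) -> dict:
    """Train the whole E subnetwork on 2 Hz random-phase sines and analyze
    the aggregate synaptic inputs received by untrained I neurons.

    Returns the per-mode input loadings of the untrained neurons, the
    mean-field Gaussian prediction for their variances, and the quenched
    disorder.  With ``weak`` the same protocol runs on the matched
    1/K-coupled control.
    """
    spec = sine_network_spec(n)
    static = build_static_connectivity(spec.layout, spec.syn, subseed(seed, 1),
                                       gain=spec.input_gain)
    trained = np.arange(spec.layout.N_E)
    l_per_pop, _ = _l_counts(spec, SINE_C_REC, 0.0)
    plastic = build_plastic_connectivity(
        spec.layout, static, trained, l_per_pop, 0, WBAR_SINE, spec.syn,
        subseed(seed, 2), gain=spec.input_gain)
    net = Network(spec=spec, static=static, plastic=plastic)
    drives = make_drives(spec, subseed(seed, 3), trial_types=("A",))

    untr = Network(spec=spec, static=static)
    rec_probe = RecordSpec(
        neuron_ids=np.arange(0, spec.layout.N, max(1, spec.layout.N // 80)),
        stride_ms=1.0)
    spk0, trace0, mean_u = simulate(untr, drives, 2000.0, 1, subseed(seed, 4),
                                    record=rec_probe)
    if weak:
        sig = tg.estimate_sigma(trace0, spec.layout, effective=False)
        net, wdrives = meanfield.weak_coupling_network(net, mean_u, sig,
                                                       seed=subseed(seed, 5))
        wdrives.stim = drives.stim
        wdrives.stim_ms = drives.stim_ms
        r0 = spk0.rates_hz()
        drives = meanfield.calibrate_weak_drives(
            Network(spec=net.spec, static=net.static), wdrives,
            (r0[spec.layout.e_slice].mean(), r0[spec.layout.i_slice].mean()),
            subseed(seed, 16))

    ts = tg.make_sine_targets(
        tg.SineSpec(amplitude=0.5 * spec.input_gain, freq_hz=freq_hz,
                    t_target_ms=1000.0),
        mean_u[trained], trained, subseed(seed, 6))
    cfg = TrainingConfig(n_iter=n_iter, t_target=1000.0, learn_every=10.0,
                         seed=subseed(seed, 7))
    diag = train_subset(net, {"A": ts.f}, drives, cfg)

    rng = np.random.default_rng(subseed(seed, 8))
    rec_ids = np.sort(rng.choice(
        np.arange(spec.layout.N_E, spec.layout.N),
        min(n_record, spec.layout.N_I), replace=False))
    spk, trace, _ = simulate(net, drives, 1000.0, n_trials, subseed(seed, 9),
                             trial_type="A",
                             record=RecordSpec(neuron_ids=rec_ids,
                                               stride_ms=2.0))

    psth_tr = compute_psth(spk, trained, smooth_ms=100.0)
    phi = psth_tr.rates.T / 1000.0  # spikes/ms
    jbar_eff = net.spec.jbar_eff[1, 0]
    if net.spec.weight_scaling == "linear":
        # realized weak weights are J̄/K = (J̄/√K)/√K
        jbar_eff = jbar_eff / np.sqrt(spec.syn.kbar[1, 0])
    pred = meanfield.predict_loading_distribution(phi, jbar_eff,
                                                  spec.layout.N_E)
    dec = analysis.input_decomposition(trace, bin_ms=20.0)
    du = dec["modulations"]["E_trained"]
    loadings = pred.right_vectors[:6] @ du  # (6, n_rec)
    return {"network": net, "spikes": spk, "trace": trace,
            "prediction": pred, "loadings": loadings,
            "measured_var": loadings.var(axis=1),
            "diagnostics": diag, "psth_trained": psth_tr,
            "trained_pca": pca_psth(psth_tr)}


# ---------------------------------------------------------------------------
# perturbation recovery (Fig-6 model analog)


def perturbation_recovery_experiment(result: dict | None = None,
                                     n_sessions: int = 10,
                                     trials_per_cond: int = 15,
                                     neurons_per_session: int = 40,
                                     pert_window_ms=(400.0, 800.0),
                                     seed: int = 0, **train_kw) -> dict:
    """Perturb trained lick-R trials with the lick-L stimulus mid-delay and
    estimate recovery times of the homogeneous and choice modes.

    For each session a random subset of neurons is "recorded"; per-trial
    projections on the two modes are compared between perturbed and
    unperturbed trials bin by bin (two-sided t-tests), and the recovery
    time is the last significant bin after the perturbation.
    """
    if result is None:
        result = alm_training_experiment(seed=subseed(seed, 13), **train_kw)
    net = result["network"]
    drives = result["drives"]
    t_target = result["pair"].t_target_ms
    dt = net.spec.neuron.dt

    # perturbed trial type: lick-R trigger, then the lick-L stimulus traces
    # re-applied inside the delay window
    stim_r = drives.stim["R"]
    stim_l = drives.stim["L"]
    lead = stim_r.shape[0]
    p0 = lead + int(round(pert_window_ms[0] / dt))
    p1 = lead + int(round(pert_window_ms[1] / dt))
    pert = np.zeros((p1, net.layout.N))
    pert[:lead] = stim_r
    n_seg = p1 - p0
    seg = np.resize(stim_l, (n_seg, net.layout.N)) if n_seg > stim_l.shape[0] \
        else stim_l[:n_seg]
    pert[p0:p1] = seg
    drives.stim["R_pert"] = pert

    all_ids = np.concatenate([result["trained_ids"],
                              result["untrained_ids"]])
    rng = np.random.default_rng(subseed(seed, 21))
    sessions = []
    for s in range(n_sessions):
        ids = np.sort(rng.choice(all_ids,
                                 min(neurons_per_session, len(all_ids)),
                                 replace=False))
        spk = {}
        for tt in ("R", "L", "R_pert"):
            spk[tt], _, _ = simulate(net, drives, t_target, trials_per_cond,
                                     subseed(seed, 31, s, ord(tt[-1])),
                                     trial_type=tt)
        tr = {tt: trial_rate_traces(spk[tt], ids, bin_ms=20.0,
                                    boxcar_ms=200.0)
              for tt in spk}
        t_axis = (np.arange(tr["R"].shape[1]) + 0.5) * 20.0
        mode = choice_mode(tr["R"], tr["L"], t_axis,
                           (t_target - 1000.0, t_target))
        res = {}
        for name, idx in (("choice", 0), ("homogeneous", 1)):
            p_pert = project_modes(tr["R_pert"], mode)[idx]
            p_base = project_modes(tr["R"], mode)[idx]
            res[name] = recovery_time(
                p_pert, p_base, t_axis, pert_window_ms,
                (pert_window_ms[1], t_target))
        sessions.append(res)
    rec_h = [s["homogeneous"].recovery_time_ms for s in sessions]
    rec_c = [s["choice"].recovery_time_ms for s in sessions]
    return {"sessions": sessions, "recovery_homogeneous": rec_h,
            "recovery_choice": rec_c, "result": result}


# ---------------------------------------------------------------------------
# named experiments, fixtures, artifacts


@dataclass
class ExperimentConfig:
    name: str
    seed: int = 0
    outdir: str = "artifacts"
    overrides: dict = field(default_factory=dict)

    KNOWN = ("sine_demo", "subset_train_psth", "ei_transfer_sweep",
             "modulation_sweep", "spread_mechanism", "weak_control",
             "perturbation_recovery")

    def __post_init__(self):
        if self.name not in self.KNOWN:
            raise ValueError(f"unknown experiment {self.name!r}; "
                             f"choose from {self.KNOWN}")


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute a named pipeline end-to-end and write its artifacts."""
    from . import io as sio

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    ov = dict(config.overrides)
    files = {}
    summary: dict = {"experiment": config.name, "seed": config.seed}

    if config.name == "sine_demo":
        r = sine_experiment(seed=config.seed,
                            **{k: ov[k] for k in
                               ("n", "n_iter", "n_trials", "freq_hz")
                               if k in ov})
        sio.write_spikes(r["spikes"], out / "spikes.tsv")
        sio.write_psth(r["psth"], out / "psth.tsv")
        sio.write_targets(r["targets"], out / "targets.tsv")
        sio.write_diagnostics(r["diagnostics"], out / "training_log.tsv")
        sio.write_snapshot(out / "snapshot.h5",
                           plastic=r["network"].plastic, trace=r["trace"])
        files = {"spikes.tsv": out / "spikes.tsv",
                 "psth.tsv": out / "psth.tsv"}
        summary.update(median_corr=r["median_corr"],
                       fano=r["stats"].fano,
                       isi_cv_median=float(np.nanmedian(r["stats"].isi_cv)),
                       var2=float(r["pca"].cumulative_variance(2)))
    elif config.name == "spread_mechanism":
        r = spread_mechanism_experiment(seed=config.seed, **ov)
        summary.update(
            measured_var=[float(x) for x in r["measured_var"][:4]],
            predicted_var=[float(x)
                           for x in r["prediction"].predicted_var[:4]])
        sio.write_psth(r["psth_trained"], out / "psth_trained.tsv")
        files["psth_trained.tsv"] = out / "psth_trained.tsv"
    elif config.name == "subset_train_psth":
        r = alm_training_experiment(seed=config.seed, **ov)
        for tt in ("R", "L"):
            sio.write_spikes(r["spikes"][tt], out / f"spikes_{tt}.tsv")
            sio.write_psth(r["psth_trained"][tt], out / f"psth_trained_{tt}.tsv")
            sio.write_psth(r["psth_untrained"][tt],
                           out / f"psth_untrained_{tt}.tsv")
            files[f"spikes_{tt}.tsv"] = out / f"spikes_{tt}.tsv"
        sio.write_snapshot(out / "snapshot.h5", plastic=r["network"].plastic)
        summary.update(trained_var6=r["trained_var6"],
                       transferred_var6=r["transferred_var6"],
                       fidelity=[float(x) for x in r["fidelity"]])
    elif config.name == "weak_control":
        strong = alm_training_experiment(seed=config.seed, **ov)
        weak = weak_control_experiment(strong, seed=config.seed)
        summary.update(strong_transferred=strong["transferred_var6"],
                       weak_transferred=weak["transferred_var6"])
    elif config.name == "ei_transfer_sweep":
        r = ei_transfer_sweep(seeds=(config.seed,), **ov)
        (out / "sweep.json").write_text(json.dumps(r["table"], indent=2))
        files["sweep.json"] = out / "sweep.json"
        summary.update(difference=r["difference"])
    elif config.name == "modulation_sweep":
        r = modulation_sweep(seed=config.seed, **ov)
        (out / "sweep.json").write_text(json.dumps(r["table"], indent=2))
        files["sweep.json"] = out / "sweep.json"
    elif config.name == "perturbation_recovery":
        r = perturbation_recovery_experiment(seed=config.seed, **ov)
        summary.update(recovery_homogeneous=r["recovery_homogeneous"],
                       recovery_choice=r["recovery_choice"])

    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    files["summary.json"] = out / "summary.json"
    sio.write_manifest(out / "manifest.json", files,
                       {"experiment": config.name, "seed": config.seed,
                        "elapsed_s": round(time.time() - t0, 2)})
    return summary


def make_fixture(kind: str, seed: int = 0):
    """Deterministic toy objects for tests and examples."""
    if kind == "tiny_network":
        spec = sine_network_spec(40)
        spec.syn.kbar[:] = 8.0
        static = build_static_connectivity(spec.layout, spec.syn, seed)
        return Network(spec=spec, static=static)
    if kind == "toy_psth":
        rng = np.random.default_rng(seed)
        rates = np.clip(rng.normal(10, 3, size=(20, 5)), 0, None)
        return analysis.PSTHMatrix(rates=rates, bin_ms=20.0, smooth_ms=20.0,
                                   neuron_ids=np.arange(5))
    if kind == "toy_spikes":
        # two neurons, two trials, hand-written spike times
        from .network import SpikeData
        return SpikeData(trial=np.array([0, 0, 0, 1, 1]),
                         neuron=np.array([0, 0, 1, 0, 1]),
                         time_ms=np.array([10.0, 50.0, 30.0, 70.0, 90.0]),
                         duration_ms=100.0, n_trials=2, n_neurons=2)
    raise ValueError(f"unknown fixture kind {kind!r}")
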