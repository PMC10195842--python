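"""Numba inner loops for the leaky integrate-and-fire network.

One kernel advances the full network state (membrane potentials, static and
plastic synaptic filters, external units) with forward Euler at ``dt``, and
optionally applies the recursive-least-squares update to the plastic weights
of the trained neurons at a fixed cadence.  All synaptic filters use the
unit-integral jump convention: a spike increments its filtered trace by
``1/tau`` so the trace's time integral per spike is one and its time average
equals the rate in spikes/ms.

The kernel is deliberately monolithic: splitting the step loop across
function boundaries costs more in dispatch than it buys in clarity, and the
pure-Python reference used by the tests lives in ``network._reference_step``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by lif_run
OK = 0
ERR_NONFINITE = 1
ERR_SPIKE_OVERFLOW = 2
ERR_RLS_DEFINITE = 3


@njit(cache=True, fastmath=True)
def lif_run(
    seed,
    n_steps, dt, tau_m, v_thr, v_reset,
    d_bal, d_plas, inv_tau_bal, inv_tau_plas,
    # state (in/out)
    v, u_bal, u_plas, x_plas, r_plas, r_x,
    # static connectivity (CSC by presynaptic neuron, weights already / tau_bal)
    stat_indptr, stat_rows, stat_wj,
    # plastic connectivity (CSC by presynaptic neuron, weights already / tau_plas)
    plas_indptr, plas_rows, plas_wj,
    # drives
    x_bal, noise_amp,
    stim, stim_start,
    ext_rate, wx,
    # learning
    learn, learn_start, learn_stride, f_targets,
    trained, pre_idx, w, P, plas_pos,
    # recording
    rec_ids, rec_slot, group_of, ub_groups,
    rec_start, rec_stride, rec_traces,
    # spike output
    spike_record_start, spk_n, spk_t,
    # per-neuron mean-input accumulator (u_bal + u_plas + x_plas), from
    # spike_record_start onward
    sum_u,
):
    np.random.seed(seed)
    N = v.shape[0]
    n_rec = rec_ids.shape[0]
    M = trained.shape[0]
    L_rec = pre_idx.shape[1] if M > 0 else 0
    L_x = r_x.shape[0]
    L_tot = w.shape[1] if M > 0 else 0
    n_learn = f_targets.shape[0]
    n_stim = stim.shape[0]
    have_ext = ext_rate.shape[0] > 0 and L_x > 0

    sqrt_dt = np.sqrt(dt)
    a = dt / tau_m

    spiked = np.empty(N, dtype=np.int32)
    rbuf = np.empty(L_tot)
    prbuf = np.empty(L_tot)

    nspk = 0
    learn_k = 0
    err_sum = 0.0
    n_err = 0
    cap = spk_n.shape[0]

    for t in range(n_steps):
        in_stim = 0 <= t - stim_start < n_stim

        # --- integrate membrane potentials, detect threshold crossings
        nsp = 0
        if in_stim:
            srow = stim[t - stim_start]
            for i in range(N):
                v[i] += a * (u_bal[i] + u_plas[i] + x_plas[i] + x_bal[i]
                             + srow[i] - v[i])
        else:
            for i in range(N):
                v[i] += a * (u_bal[i] + u_plas[i] + x_plas[i] + x_bal[i]
                             - v[i])
        if noise_amp.shape[0] > 0:
            for i in range(N):
                v[i] += noise_amp[i] * sqrt_dt * np.random.normal()
        for i in range(N):
            if v[i] >= v_thr:
                v[i] = v_reset
                spiked[nsp] = i
                nsp += 1

        # --- decay synaptic filters
        for i in range(N):
            u_bal[i] *= d_bal
            u_plas[i] *= d_plas
            x_plas[i] *= d_plas
            r_plas[i] *= d_plas
        for j in range(L_x):
            r_x[j] *= d_plas
        if n_rec > 0:
            for s in range(n_rec):
                for g in range(4):
                    ub_groups[s, g] *= d_bal

        # --- propagate this step's spikes
        for k in range(nsp):
            j = spiked[k]
            r_plas[j] += inv_tau_plas
            g = group_of[j]
            for q in range(stat_indptr[j], stat_indptr[j + 1]):
                tgt = stat_rows[q]
                u_bal[tgt] += stat_wj[q]
                if n_rec > 0 and rec_slot[tgt] >= 0:
                    ub_groups[rec_slot[tgt], g] += stat_wj[q]
            for q in range(plas_indptr[j], plas_indptr[j + 1]):
                u_plas[plas_rows[q]] += plas_wj[q]
            if t >= spike_record_start:
                if nspk >= cap:
                    return nspk, err_sum, n_err, ERR_SPIKE_OVERFLOW, j, t
                spk_n[nspk] = j
                spk_t[nspk] = t
                nspk += 1

        # --- external Poisson units
        if have_ext:
            t_ms = int(t * dt)
            if t_ms >= ext_rate.shape[0]:
                t_ms = ext_rate.shape[0] - 1
            for j in range(L_x):
                if np.random.random() < ext_rate[t_ms, j] * dt:
                    r_x[j] += inv_tau_plas
                    for m in range(M):
                        x_plas[trained[m]] += wx[m, j] * inv_tau_plas

        # --- recursive least squares update of plastic weights
        if learn and learn_k < n_learn and t == learn_start + learn_k * learn_stride:
            for m in range(M):
                i = trained[m]
                for l in range(L_rec):
                    rbuf[l] = r_plas[pre_idx[m, l]]
                for l in range(L_x):
                    rbuf[L_rec + l] = r_x[l]
                wr = 0.0
                for l in range(L_tot):
                    wr += w[m, l] * rbuf[l]
                e = f_targets[learn_k, m] - u_bal[i] - x_bal[i] - wr
                for ai in range(L_tot):
                    acc = 0.0
                    for b in range(L_tot):
                        acc += P[m, ai, b] * rbuf[b]
                    prbuf[ai] = acc
                c = 1.0
                for ai in range(L_tot):
                    c += rbuf[ai] * prbuf[ai]
                if c <= 0.0:
                    return nspk, err_sum, n_err, ERR_RLS_DEFINITE, i, t
                inv_c = 1.0 / c
                for ai in range(L_tot):
                    w[m, ai] += e * prbuf[ai] * inv_c
                for ai in range(L_tot):
                    pa = prbuf[ai] * inv_c
                    for b in range(L_tot):
                        P[m, ai, b] -= pa * prbuf[b]
                err_sum += abs(e)
                n_err += 1
                # write weights back into the propagation structure and make
                # the plastic inputs exact under the new weights
                up = 0.0
                for l in range(L_rec):
                    plas_wj[plas_pos[m, l]] = w[m, l] * inv_tau_plas
                    up += w[m, l] * rbuf[l]
                u_plas[i] = up
                xp = 0.0
                for l in range(L_x):
                    wx[m, l] = w[m, L_rec + l]
                    xp += w[m, L_rec + l] * rbuf[L_rec + l]
                x_plas[i] = xp
            learn_k += 1

        # --- trace recording
        if n_rec > 0 and t >= rec_start and (t - rec_start) % rec_stride == 0:
            rt = (t - rec_start) // rec_stride
            if rt < rec_traces.shape[0]:
                for s in range(n_rec):
                    i = rec_ids[s]
                    for g in range(4):
                        rec_traces[rt, s, g] = ub_groups[s, g]
                    rec_traces[rt, s, 4] = u_plas[i]
                    rec_traces[rt, s, 5] = x_plas[i]
                    if in_stim:
                        rec_traces[rt, s, 6] = stim[t - stim_start, i]
                    else:
                        rec_traces[rt, s, 6] = 0.0

        if t >= spike_record_start:
            for i in range(N):
                sum_u[i] += u_bal[i] + u_plas[i] + x_plas[i]

        # --- divergence guard
        if t % 1000 == 0:
            for i in range(N):
                if not np.isfinite(v[i]):
                    return nspk, err_sum, n_err, ERR_NONFINITE, i, t

    return nspk, err_sum, n_err, OK, -1, -1
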