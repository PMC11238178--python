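"""Compiled inner loop of the simulation engine.

One numba-compiled routine advances the whole network a block of steps with
the exact same arithmetic and update order as the pure-numpy reference path
in :mod:`pqnfly.engine` (which remains the fallback for the fixed-point
emulation mode and for topologies whose ORN block does not factor through
glomeruli).  The ORN input enters through per-glomerulus sums; both
projection matrices are CSR.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_block"]


@njit(cache=True, fastmath=False)
def run_block(
    steps,
    rand_block,        # (steps, n_orn) uniforms
    p_spike_block,     # (steps, n_orn) spike probabilities
    s_orn,             # (n_orn,) ORN synaptic state, updated in place
    glom_idx,          # (n_orn,) glomerulus index per ORN
    n_glom,
    U_indptr, U_indices, U_data,      # modeled x glomerulus CSR
    Am_indptr, Am_indices, Am_data,   # modeled x modeled CSR
    v, n_var, q_var, v_s, u, spike_count_window, s_mod,  # state, in place
    a_fn, b_fn, c_fn, a_fp, b_fp, c_fp,
    a_gn, b_gn, c_gn, a_gp, b_gp, c_gp, r_g,
    a_hn, b_hn, c_hn, a_hp, b_hp, c_hp, r_h,
    k_I, m0, m1, I_b0,
    c_v, c_n, c_q, c_vs,
    k_0, alpha_leak, I_b1,
    is_pn, has_q, has_soma,
    kc_model, w_plastic, p_kc_mbon1, mbon1_model,
    inact_idx,
    alpha_dt, beta_dt,
    last_spike_time,   # (n_kc,) seconds, in place
    t0, dt,
    step_offset,       # global step count at block start (homeostasis phase)
    steps_per_second,
    kappa_over_tau, F_t, F_out,
    spikes_out,        # (steps, m) uint8
    lfp_idx, lfp_offsets, lfp_out,    # group-mean s recording
    trace_idx, trace_offsets, v_out, vs_out, str_out,
    u_out, record_u,
):
    m = v.shape[0]
    n_orn = s_orn.shape[0]
    glom_s = np.zeros(n_glom)
    I = np.zeros(m)
    n_groups = lfp_offsets.shape[0] - 1
    n_tr = trace_offsets.shape[0] - 1
    bad = -1

    for t in range(steps):
        # 1. ORN spikes and event-driven synapses
        for i in range(n_orn):
            s_orn[i] -= beta_dt * s_orn[i]
            if s_orn[i] < 1e-12:
                s_orn[i] = 0.0  # flush: avoids denormal-range slowdowns
            if rand_block[t, i] < p_spike_block[t, i]:
                s_orn[i] = 1.0
        # 2. input accumulation through glomerulus sums
        for g in range(n_glom):
            glom_s[g] = 0.0
        for i in range(n_orn):
            glom_s[glom_idx[i]] += s_orn[i]
        for i in range(m):
            acc = 0.0
            for jj in range(U_indptr[i], U_indptr[i + 1]):
                acc += U_data[jj] * glom_s[U_indices[jj]]
            for jj in range(Am_indptr[i], Am_indptr[i + 1]):
                acc += Am_data[jj] * s_mod[Am_indices[jj]]
            I[i] = acc
        plastic_drive = 0.0
        for kk in range(kc_model.shape[0]):
            plastic_drive += w_plastic[kk] * s_mod[kc_model[kk]]
        for jj in range(mbon1_model.shape[0]):
            I[mbon1_model[jj]] += p_kc_mbon1 * plastic_drive
        for jj in range(inact_idx.shape[0]):
            I[inact_idx[jj]] = 0.0

        # 3. synchronous neuron update (RHS at pre-step state)
        t_now = t0 + t * dt
        for i in range(m):
            vi = v[i]
            if vi < 0.0:
                f = a_fn[i] * (vi - b_fn[i]) ** 2 + c_fn[i]
            else:
                f = a_fp[i] * (vi - b_fp[i]) ** 2 + c_fp[i]
            if vi < r_g[i]:
                g_val = a_gn[i] * (vi - b_gn[i]) ** 2 + c_gn[i]
            else:
                g_val = a_gp[i] * (vi - b_gp[i]) ** 2 + c_gp[i]
            Ii = I[i]
            if Ii < m0[i]:
                Ii = m0[i]
            elif Ii > m1[i]:
                Ii = m1[i]
            m_in = k_I[i] * Ii
            if is_pn[i]:
                m_in *= u[i]
            rhs = f - n_var[i] + I_b0[i] + m_in
            if has_q:
                if vi < r_h[i]:
                    h_val = a_hn[i] * (vi - b_hn[i]) ** 2 + c_hn[i]
                else:
                    h_val = a_hp[i] * (vi - b_hp[i]) ** 2 + c_hp[i]
                rhs -= q_var[i]
                q_var[i] += c_q[i] * (h_val - q_var[i])
            if has_soma:
                I_c = k_0[i] * (vi - v_s[i])
                rhs -= I_c
                v_s[i] += c_vs[i] * (
                    -alpha_leak[i] * v_s[i] + I_b1[i] + I_c
                )
            v_new = vi + c_v[i] * rhs
            n_var[i] += c_n[i] * (g_val - n_var[i])
            spk = vi < 0.0 and v_new >= 0.0
            v[i] = v_new
            if spk:
                spikes_out[t, i] = 1
                spike_count_window[i] += 1
            # 4. chemical synapse from the committed potential
            if v_new >= 0.0:
                s_mod[i] += alpha_dt * (1.0 - s_mod[i])
            else:
                s_mod[i] -= beta_dt * s_mod[i]
                if s_mod[i] < 1e-12:
                    s_mod[i] = 0.0

        for kk in range(kc_model.shape[0]):
            if spikes_out[t, kc_model[kk]] == 1:
                last_spike_time[kk] = t_now

        # homeostasis on 1-s tumbling windows (global alignment)
        if (step_offset + t + 1) % steps_per_second == 0:
            for i in range(m):
                F_out[i] = float(spike_count_window[i])
                if is_pn[i]:
                    ui = u[i] + kappa_over_tau[i] * (F_t[i] - F_out[i])
                    if ui < 0.0:
                        ui = 0.0
                    elif ui > 1.0:
                        ui = 1.0
                    u[i] = ui
                spike_count_window[i] = 0
            # once-per-second overflow check
            for i in range(m):
                if not (np.isfinite(v[i]) and np.isfinite(n_var[i])):
                    bad = i
                    break
            if bad >= 0:
                return bad, t

        # recording
        for gidx in range(n_groups):
            acc = 0.0
            lo, hi = lfp_offsets[gidx], lfp_offsets[gidx + 1]
            for jj in range(lo, hi):
                acc += s_mod[lfp_idx[jj]]
            lfp_out[gidx, t] = acc / (hi - lo)
        for tr in range(n_tr):
            lo, hi = trace_offsets[tr], trace_offsets[tr + 1]
            acc = 0.0
            for jj in range(lo, hi):
                idx = trace_idx[jj]
                v_out[jj, t] = v[idx]
                vs_out[jj, t] = v_s[idx]
                acc += s_mod[idx]
            str_out[tr, t] = acc / (hi - lo)
        if record_u:
            acc = 0.0
            cnt = 0
            for i in range(m):
                if is_pn[i]:
                    acc += u[i]
                    cnt += 1
            u_out[t] = acc / max(cnt, 1)

    return bad, steps - 1
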