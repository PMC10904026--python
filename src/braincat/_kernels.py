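"""Numba-compiled simulation core.

One synchronous discrete-time update per step, for the concatenated e-cell
population of all areas (area a occupies indices [a*625, (a+1)*625)):

    V_e <- V_e + (1/tau_e) * (-V_e + k1*(exc - w_ie*O_i - kG*wG[area])
                              + noise + stim_drive)
    phi  = 1 if V_e > thresh + alpha*w_A else 0
    w_A <- w_A + (1/tau_adapt) * (-w_A + phi)
    w_E <- w_E + (1/tau_favg) * (-w_E + phi)
    wG  <- wG + (1/tau_fglob) * (-wG + sum(phi) per area)

i-cells (one per column) pool e-spikes in a square window, integrate with
tau_i, and emit a graded output clipped to [0, 1]. Plasticity, when enabled,
applies the LTP/LTD rule to every existing e->e synapse whose presynaptic
rate estimate exceeds theta_pre: potentiate if the postsynaptic dendritic
potential is at or above theta_plus, depress if it lies in
[theta_minus, theta_plus). The dendritic potential D integrates the same
drive as V but without the (perisomatic) inhibition terms:

    D <- D + (1/tau_e) * (-D + k1*exc + noise + stim_drive)

so inhibition regulates firing and network stability while synaptic
selection follows the excitatory input correlation structure.

Synaptic weights live in one sparse matrix over the global e-population,
stored in CSC order (column = presynaptic cell) with a parallel CSR view
(csr_perm maps CSR slots back into the CSC data array) so that the forward
pass iterates over firing presynaptic cells and the plasticity pass over
depolarized postsynaptic cells.
"""

from __future__ import annotations

import numpy as np
from numba import njit

GRID = 25
N_PER_AREA = GRID * GRID

# slots in the packed parameter vector
P_TAU_E, P_TAU_I, P_K1, P_KG, P_THRESH, P_ALPHA, P_TAU_ADAPT, P_TAU_FAVG, \
    P_TAU_FGLOB, P_TH_PLUS, P_TH_MINUS, P_TH_PRE, P_DW, P_W_MAX, P_W_IE, \
    P_W_EI, P_STIM, P_POOL, P_NOISE_I, P_RUNAWAY, P_GGLOB, P_FFI, P_TAU_FF = range(23)
N_PSLOTS = 23


def pack_params(p, tau_favg: float) -> np.ndarray:
    """ModelParams -> packed float vector (tau_favg differs between phases)."""
    v = np.zeros(N_PSLOTS)
    v[P_TAU_E] = p.tau_e
    v[P_TAU_I] = p.tau_i
    v[P_K1] = p.k1
    v[P_KG] = p.kG
    v[P_THRESH] = p.thresh
    v[P_ALPHA] = p.alpha
    v[P_TAU_ADAPT] = p.tau_adapt
    v[P_TAU_FAVG] = tau_favg
    v[P_TAU_FGLOB] = p.tau_fglob
    v[P_TH_PLUS] = p.theta_plus
    v[P_TH_MINUS] = p.theta_minus
    v[P_TH_PRE] = p.theta_pre
    v[P_DW] = p.delta_w
    v[P_W_MAX] = p.w_max
    v[P_W_IE] = p.w_ie
    v[P_W_EI] = p.w_ei
    v[P_STIM] = p.stim_strength
    v[P_POOL] = p.inhib_pool
    v[P_NOISE_I] = p.noise_amp
    v[P_RUNAWAY] = p.runaway_frac * N_PER_AREA
    v[P_GGLOB] = p.g_glob
    v[P_FFI] = p.ff_inhib
    v[P_TAU_FF] = p.tau_ff
    return v


@njit(cache=True)
def run_steps(n_steps, seed,
              Ve, De, phi, wA, wE, Vi, Oi, wG,
              csc_indptr, csc_rows, w_data,
              csr_indptr, csr_cols, csr_perm,
              n_areas,
              stim_mask, stim_on,
              noise_e_area,
              pv,
              plastic, dw_eff, gate_somatic,
              stop_below,
              spike_out, runaway_state):
    """Advance the network n_steps; returns (steps_taken, runaway_flag).

    stim_mask: per-e-cell 0/1 drive mask, applied while stim_on.
    noise_e_area: per-area uniform noise amplitude for e-cells.
    dw_eff: learning rate actually applied (delta_w, possibly rescaled).
    stop_below: if > 0, stop once k1*kG*wG < stop_below in every area.
    spike_out: int64[n_areas], accumulates spike counts over the call.
    """
    n_e = Ve.shape[0]
    if seed >= 0:
        np.random.seed(seed)
    inv_te = 1.0 / pv[P_TAU_E]
    inv_ti = 1.0 / pv[P_TAU_I]
    inv_ta = 1.0 / pv[P_TAU_ADAPT]
    inv_tf = 1.0 / pv[P_TAU_FAVG]
    inv_tg = 1.0 / pv[P_TAU_FGLOB]
    k1 = pv[P_K1]
    kG = pv[P_KG]
    thresh = pv[P_THRESH]
    alpha = pv[P_ALPHA]
    th_plus = pv[P_TH_PLUS]
    th_minus = pv[P_TH_MINUS]
    th_pre = pv[P_TH_PRE]
    w_max = pv[P_W_MAX]
    w_ie = pv[P_W_IE]
    w_ei = pv[P_W_EI]
    stim_amp = pv[P_STIM]
    pool_half = int(pv[P_POOL]) // 2
    noise_i_amp = pv[P_NOISE_I]
    runaway_ceil = pv[P_RUNAWAY]
    g_glob = pv[P_GGLOB]
    w_ffi = pv[P_FFI]
    inv_tff = 1.0 / pv[P_TAU_FF]

    exc = np.zeros(n_e)
    pool = np.zeros(n_e)
    s_fast = np.zeros(n_areas)
    for i in range(n_e):
        if phi[i] != 0:
            s_fast[i // N_PER_AREA] += 1.0
    runaway_run = runaway_state[0]
    runaway = False
    steps = 0

    for _t in range(n_steps):
        # synaptic input and inhibitory pooling from the previous step's spikes
        for i in range(n_e):
            exc[i] = 0.0
            pool[i] = 0.0
        for j in range(n_e):
            if phi[j] != 0:
                for k in range(csc_indptr[j], csc_indptr[j + 1]):
                    exc[csc_rows[k]] += w_data[k]
        for a in range(n_areas):
            base = a * N_PER_AREA
            for r in range(GRID):
                r0 = r - pool_half if r - pool_half > 0 else 0
                r1 = r + pool_half + 1 if r + pool_half + 1 < GRID else GRID
                for c in range(GRID):
                    c0 = c - pool_half if c - pool_half > 0 else 0
                    c1 = c + pool_half + 1 if c + pool_half + 1 < GRID else GRID
                    s = 0.0
                    for rr in range(r0, r1):
                        row0 = base + rr * GRID
                        for cc in range(c0, c1):
                            s += phi[row0 + cc]
                    pool[base + r * GRID + c] = s

        # membrane updates (e then i), synchronous in the previous outputs
        for a in range(n_areas):
            base = a * N_PER_AREA
            namp = noise_e_area[a]
            gterm = kG * wG[a] + w_ffi * s_fast[a]
            for ii in range(N_PER_AREA):
                i = base + ii
                dend = k1 * exc[i]
                if namp > 0.0:
                    dend += namp * (np.random.random() - 0.5)
                if stim_on and stim_mask[i] > 0.0:
                    dend += stim_amp
                inp = dend - k1 * (w_ie * Oi[i] + gterm)
                Ve[i] += inv_te * (-Ve[i] + inp)
                De[i] += inv_te * (-De[i] + dend)
        for i in range(n_e):
            inp_i = w_ei * pool[i]
            if noise_i_amp > 0.0:
                inp_i += noise_i_amp * (np.random.random() - 0.5)
            Vi[i] += inv_ti * (-Vi[i] + inp_i)
            o = Vi[i]
            if o < 0.0:
                o = 0.0
            elif o > 1.0:
                o = 1.0
            Oi[i] = o

        # threshold + adaptation + rate estimates + global inhibition
        any_runaway = False
        for a in range(n_areas):
            base = a * N_PER_AREA
            ns = 0
            for ii in range(N_PER_AREA):
                i = base + ii
                f = 1 if Ve[i] > thresh + alpha * wA[i] else 0
                phi[i] = f
                ns += f
                wA[i] += inv_ta * (-wA[i] + f)
                wE[i] += inv_tf * (-wE[i] + f)
            wG[a] += inv_tg * (-wG[a] + g_glob * ns)
            s_fast[a] += inv_tff * (-s_fast[a] + ns)
            if ns > s_fast[a]:
                s_fast[a] = ns
            spike_out[a] += ns
            if ns > runaway_ceil:
                any_runaway = True
        if any_runaway:
            runaway_run += 1
            if runaway_run > 100:
                runaway = True
                steps += 1
                break
        else:
            runaway_run = 0

        # Hebbian LTP/LTD over existing synapses (outer loop over the small
        # theta_pre-eligible presynaptic set)
        if plastic:
            for j in range(n_e):
                if wE[j] >= th_pre:
                    for k in range(csc_indptr[j], csc_indptr[j + 1]):
                        v = Ve[csc_rows[k]] if gate_somatic else De[csc_rows[k]]
                        if v >= th_plus:
                            w = w_data[k] + dw_eff
                            w_data[k] = w if w < w_max else w_max
                        elif v >= th_minus:
                            w = w_data[k] - dw_eff
                            w_data[k] = w if w > 0.0 else 0.0

        runaway_state[0] = runaway_run
        steps += 1
        if stop_below > 0.0:
            quiet = True
            for a in range(n_areas):
                if k1 * kG * wG[a] >= stop_below:
                    quiet = False
                    break
            if quiet:
                break

    return steps, runaway
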