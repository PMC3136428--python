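"""Numba kernels for the network and single-cell integrators.

All voltages in mV, times in ms, conductances in nS, currents in pA,
capacitances in pF.  Gate kinetics are evaluated through lookup tables
(steady state and per-step decay factor on a uniform voltage grid), the
same tabulation strategy classical compartmental simulators use.  Compartment
voltages advance by Crank-Nicolson (default) or exponential Euler with gates
updated semi-implicitly from the pre-step voltage; synaptic dual-exponential
states decay exactly and receive unit increments when presynaptic spikes
arrive, so a spike's conductance transient starts at zero on its arrival
step.  Spikes are upward crossings of 0 mV with a refractory lockout.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the kernels
OK = 0
ERR_NONFINITE = 1
ERR_SPIKE_OVERFLOW = 2

FULL_CHECK_EVERY = 5000  # steps between non-finite state sweeps


@njit(cache=True, inline="always")
def _interp(tab, x):
    # x is a fractional table index, pre-scaled by the caller
    if x <= 0.0:
        return tab[0]
    n = tab.shape[0]
    if x >= n - 1:
        return tab[n - 1]
    i = int(x)
    w = x - i
    return tab[i] * (1.0 - w) + tab[i + 1] * w


@njit(cache=True, inline="always")
def _gates(v, v0, inv_dv, minf, mfac, hinf, hfac, ninf, nfac, m, h, n):
    x = (v - v0) * inv_dv
    mi = _interp(minf, x)
    hi = _interp(hinf, x)
    ni = _interp(ninf, x)
    fm = _interp(mfac, x)
    fh = _interp(hfac, x)
    fn = _interp(nfac, x)
    return (mi + (m - mi) * fm, hi + (h - hi) * fh, ni + (n - ni) * fn)


@njit(cache=True, inline="always")
def _soma_voltage(V, C, dt, G, I, integrator):
    # C dV/dt = I - G V ; G, I frozen over the step
    if integrator == 0:  # Crank-Nicolson
        cdt = C / dt
        return (V * (cdt - 0.5 * G) + I) / (cdt + 0.5 * G)
    if integrator == 2:  # first-order explicit (forward) Euler
        return V + dt * (I - G * V) / C
    vinf = I / G
    return vinf + (V - vinf) * np.exp(-dt * G / C)


@njit(cache=True)
def run_granular_network(
    dt, n_steps, integrator, lockout_steps,
    # gate tables (shared kinetics)
    v0, inv_dv, minf, mfac, hinf, hfac, ninf, nfac,
    # grc parameters: C, gL, EL, gNa, ENa, gK, EK, ahp_inc, ahp_fac
    gp,
    # grc GABA synapse: decay factors and scale
    gaba_fr, gaba_fd, gaba_gnorm, e_gaba,
    # goc parameters: Cs, gL, gNa, ENa, gK, EK, ahp_inc, ahp_fac, Cd, gLd, gc
    op, goc_eleak,
    ampa_fr, ampa_fd, ampa_gnorm, e_ampa,
    nmda_fr, nmda_fd, nmda_gnorm, e_nmda,
    mg_over_k0, inv_vs,
    # per-target conductance scale (in-degree normalization; ones = off)
    gaba_scale, exc_scale,
    # stimulus: per-step currents (pA)
    i_grc, i_goc,
    # connectivity (CSR by source)
    pf_indptr, pf_targets, inh_indptr, inh_targets,
    # state (in/out)
    Vg, mg_, hg, ng_, ahpg, gaba_r, gaba_d,
    Vs, Vd, mo, ho, no, ahpo, ampa_r, ampa_d, nmda_r, nmda_d,
    # spike output buffers
    grc_sp_step, grc_sp_id, goc_sp_step, goc_sp_id,
    # voltage recording
    rec_grc, rec_goc, rec_every, tr_vg, tr_vs, tr_vd,
):
    n_grc = Vg.shape[0]
    n_goc = Vs.shape[0]
    cap_g = grc_sp_id.shape[0]
    cap_o = goc_sp_id.shape[0]
    ng_count = 0
    no_count = 0

    c_g, gl_g, el_g, gna_g, ena_g, gk_g, ek_g, ahpinc_g, ahpfac_g = \
        gp[0], gp[1], gp[2], gp[3], gp[4], gp[5], gp[6], gp[7], gp[8]
    vsh_g = gp[9]
    cs_o, gl_o, gna_o, ena_o, gk_o, ek_o, ahpinc_o, ahpfac_o, cd_o, gld_o, gc = \
        op[0], op[1], op[2], op[3], op[4], op[5], op[6], op[7], op[8], op[9], op[10]
    vsh_o = op[11]

    spiked_g = np.zeros(n_grc, np.bool_)
    spiked_o = np.zeros(n_goc, np.bool_)
    lock_g = np.zeros(n_grc, np.int32)
    lock_o = np.zeros(n_goc, np.int32)
    rec_count = 0

    for step in range(n_steps):
        ig = i_grc[step]
        io = i_goc[step]

        # --- granule cells -------------------------------------------------
        for i in range(n_grc):
            v = Vg[i]
            m, h, n = _gates(v - vsh_g, v0, inv_dv, minf, mfac, hinf, hfac,
                             ninf, nfac, mg_[i], hg[i], ng_[i])
            mg_[i] = m
            hg[i] = h
            ng_[i] = n
            gna = gna_g * m * m * m * h
            gk = gk_g * (n * n) * (n * n)
            g_gaba = gaba_gnorm * gaba_scale[i] * (gaba_d[i] - gaba_r[i])
            if g_gaba < 0.0:
                g_gaba = 0.0
            G = gl_g + gna + gk + ahpg[i] + g_gaba
            I = (gl_g * el_g + gna * ena_g + gk * ek_g + ahpg[i] * ek_g
                 + g_gaba * e_gaba + ig)
            vnew = _soma_voltage(v, c_g, dt, G, I, integrator)
            sp = False
            if lock_g[i] > 0:
                lock_g[i] -= 1
            elif v < 0.0 and vnew >= 0.0:
                sp = True
                lock_g[i] = lockout_steps
            spiked_g[i] = sp
            Vg[i] = vnew
            ahpg[i] *= ahpfac_g
            if sp:
                ahpg[i] += ahpinc_g
                if ng_count < cap_g:
                    grc_sp_step[ng_count] = step
                    grc_sp_id[ng_count] = i
                    ng_count += 1
                else:
                    return ERR_SPIKE_OVERFLOW, step, ng_count, no_count

        # --- Golgi cells ---------------------------------------------------
        for j in range(n_goc):
            vs = Vs[j]
            vd = Vd[j]
            m, h, n = _gates(vs - vsh_o, v0, inv_dv, minf, mfac, hinf, hfac,
                             ninf, nfac, mo[j], ho[j], no[j])
            mo[j] = m
            ho[j] = h
            no[j] = n
            gna = gna_o * m * m * m * h
            gk = gk_o * (n * n) * (n * n)
            el = goc_eleak[j]
            Gs = gl_o + gna + gk + ahpo[j]
            Is = (gl_o * el + gna * ena_o + gk * ek_o + ahpo[j] * ek_o + io)
            g_a = ampa_gnorm * exc_scale[j] * (ampa_d[j] - ampa_r[j])
            if g_a < 0.0:
                g_a = 0.0
            block = 1.0 / (1.0 + mg_over_k0 * np.exp(-vd * inv_vs))
            g_n = nmda_gnorm * exc_scale[j] * (nmda_d[j] - nmda_r[j]) * block
            if g_n < 0.0:
                g_n = 0.0
            Gd = gld_o + g_a + g_n
            Id = gld_o * el + g_a * e_ampa + g_n * e_nmda
            if integrator == 0:
                a11 = cs_o / dt + 0.5 * (Gs + gc)
                a22 = cd_o / dt + 0.5 * (Gd + gc)
                a12 = -0.5 * gc
                b1 = vs * (cs_o / dt - 0.5 * (Gs + gc)) + 0.5 * gc * vd + Is
                b2 = vd * (cd_o / dt - 0.5 * (Gd + gc)) + 0.5 * gc * vs + Id
                det = a11 * a22 - a12 * a12
                vs_new = (b1 * a22 - a12 * b2) / det
                vd_new = (a11 * b2 - a12 * b1) / det
            else:
                gs_tot = Gs + gc
                vs_inf = (Is + gc * vd) / gs_tot
                vs_new = vs_inf + (vs - vs_inf) * np.exp(-dt * gs_tot / cs_o)
                gd_tot = Gd + gc
                vd_inf = (Id + gc * vs) / gd_tot
                vd_new = vd_inf + (vd - vd_inf) * np.exp(-dt * gd_tot / cd_o)
            sp = False
            if lock_o[j] > 0:
                lock_o[j] -= 1
            elif vs < 0.0 and vs_new >= 0.0:
                sp = True
                lock_o[j] = lockout_steps
            spiked_o[j] = sp
            Vs[j] = vs_new
            Vd[j] = vd_new
            ahpo[j] *= ahpfac_o
            if sp:
                ahpo[j] += ahpinc_o
                if no_count < cap_o:
                    goc_sp_step[no_count] = step
                    goc_sp_id[no_count] = j
                    no_count += 1
                else:
                    return ERR_SPIKE_OVERFLOW, step, ng_count, no_count

        # --- synaptic state decay + spike propagation (zero delay) --------
        for i in range(n_grc):
            gaba_r[i] *= gaba_fr
            gaba_d[i] *= gaba_fd
        for j in range(n_goc):
            ampa_r[j] *= ampa_fr
            ampa_d[j] *= ampa_fd
            nmda_r[j] *= nmda_fr
            nmda_d[j] *= nmda_fd
        for i in range(n_grc):
            if spiked_g[i]:
                for e in range(pf_indptr[i], pf_indptr[i + 1]):
                    t = pf_targets[e]
                    ampa_r[t] += 1.0
                    ampa_d[t] += 1.0
                    nmda_r[t] += 1.0
                    nmda_d[t] += 1.0
        for j in range(n_goc):
            if spiked_o[j]:
                for e in range(inh_indptr[j], inh_indptr[j + 1]):
                    t = inh_targets[e]
                    gaba_r[t] += 1.0
                    gaba_d[t] += 1.0

        # --- recording and health checks ----------------------------------
        if rec_every > 0 and step % rec_every == 0:
            for k in range(rec_grc.shape[0]):
                tr_vg[k, rec_count] = Vg[rec_grc[k]]
            for k in range(rec_goc.shape[0]):
                tr_vs[k, rec_count] = Vs[rec_goc[k]]
                tr_vd[k, rec_count] = Vd[rec_goc[k]]
            rec_count += 1
        if step % FULL_CHECK_EVERY == 0:
            ok = True
            for i in range(n_grc):
                if not np.isfinite(Vg[i]):
                    ok = False
            for j in range(n_goc):
                if not np.isfinite(Vs[j]) or not np.isfinite(Vd[j]):
                    ok = False
            if not ok:
                return ERR_NONFINITE, step, ng_count, no_count

    return OK, n_steps, ng_count, no_count


@njit(cache=True)
def run_single_soma(
    dt, n_steps, integrator, lockout_steps,
    v0, inv_dv, minf, mfac, hinf, hfac, ninf, nfac,
    # params: C, gL, EL, gNa, ENa, gK, EK, ahp_inc, ahp_fac
    par,
    i_ext,          # per-step injected current, pA
    g_exc,          # per-step excitatory conductance, nS (reversal e_exc)
    e_exc,
    v_init,
    sp_step,        # spike output buffer
    record, v_trace,
):
    """One active compartment driven by a current and/or a conductance."""
    C, gl, el, gna_max, ena, gk_max, ek, ahp_inc, ahp_fac = \
        par[0], par[1], par[2], par[3], par[4], par[5], par[6], par[7], par[8]
    vsh = par[9]
    v = v_init
    x = (v - vsh - v0) * inv_dv
    m = _interp(minf, x)
    h = _interp(hinf, x)
    n = _interp(ninf, x)
    ahp = 0.0
    lock = 0
    count = 0
    for step in range(n_steps):
        m, h, n = _gates(v - vsh, v0, inv_dv, minf, mfac, hinf, hfac,
                         ninf, nfac, m, h, n)
        gna = gna_max * m * m * m * h
        gk = gk_max * (n * n) * (n * n)
        ge = g_exc[step]
        G = gl + gna + gk + ahp + ge
        I = (gl * el + gna * ena + gk * ek + ahp * ek + ge * e_exc
             + i_ext[step])
        vnew = _soma_voltage(v, C, dt, G, I, integrator)
        sp = False
        if lock > 0:
            lock -= 1
        elif v < 0.0 and vnew >= 0.0:
            sp = True
            lock = lockout_steps
        ahp *= ahp_fac
        if sp:
            ahp += ahp_inc
            if count < sp_step.shape[0]:
                sp_step[count] = step
                count += 1
            else:
                return ERR_SPIKE_OVERFLOW, step, count
        v = vnew
        if record:
            v_trace[step] = v
        if not np.isfinite(v):
            return ERR_NONFINITE, step, count
    return OK, n_steps, count
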