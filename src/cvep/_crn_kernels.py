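"""Numba kernels for the Courtemanche–Ramirez–Nattel (CRN) human atrial cell model.

All quantities are in the CRN paper's physical units: voltage mV, time ms,
currents pA/pF, concentrations mM.  Membrane dynamics at a point read
dV/dt = -I_ion + I_app with I_ion the total ionic current in pA/pF.

Voltage-dependent gate kinetics and current coefficients can either be
evaluated exactly or looked up in a precomputed table (0.05 mV grid, linear
interpolation); the tabled path exists purely for speed and is validated
against the exact path in the test suite.

State layout used throughout: 15 gates in the order
(m, h, j, oa, oi, ua, ui, xr, xs, d, f, f_ca, u_g, v_g, w_g)
and 5 concentrations (Na_i, K_i, Ca_i, Ca_up, Ca_rel).
"""
from __future__ import annotations

import numpy as np
from numba import njit

# --- physical constants (Courtemanche et al. 1998) ---
R_GAS = 8.3143          # J / (mol K)
T_BODY = 310.0          # K
FARADAY = 96.4867       # C / mmol
RTF = R_GAS * T_BODY / FARADAY  # ~26.71 mV
CM = 100.0              # pF

V_I = 13668.0           # um^3, intracellular volume
V_UP = 1109.52          # um^3, SR uptake compartment
V_REL = 96.48           # um^3, SR release compartment

K_O = 5.4               # mM
NA_O = 140.0
CA_O = 1.8

G_NA = 7.8              # nS/pF
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_BCA = 0.001131
G_BNA = 0.0006744375

I_NAK_MAX = 0.59933874  # pA/pF
KM_NAI = 10.0
KM_KO = 1.5
I_NACA_MAX = 1600.0     # pA/pF
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
I_PCA_MAX = 0.275

K_UP = 0.00092          # mM
I_UP_MAX = 0.005        # mM/ms
CA_UP_MAX = 15.0        # mM
K_REL = 30.0            # 1/ms
TAU_TR = 180.0          # ms
TAU_F_CA = 2.0
TAU_U = 8.0

CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

K_Q10 = 3.0

SIGMA_NAK = (np.exp(NA_O / 67.3) - 1.0) / 7.0

N_GATES = 15
N_CONC = 5

# voltage table parameters
TAB_VMIN = -120.0
TAB_VMAX = 80.0
TAB_DV = 0.05
TAB_NCOL = 30

_GUARD = 1e-6  # guard band around removable singularities (mV)


@njit(cache=True, fastmath=True)
def _vdep(v):
    """Exact voltage-dependent quantities.

    Returns a 30-tuple: (inf, tau) pairs for the 12 purely voltage-gated
    gates in order m,h,j,oa,oi,ua,ui,xr,xs,d,f,w_g followed by the current
    coefficients (c_k1, g_kur_v, c_kr, f_nak, e_gamma, e_gamma1).
    """
    # m gate (LR-type formulation used by CRN)
    dv = v + 47.13
    if abs(dv) < _GUARD:
        a_m = 3.2
    else:
        a_m = 0.32 * dv / (1.0 - np.exp(-0.1 * dv))
    b_m = 0.08 * np.exp(-v / 11.0)
    tau_m = 1.0 / (a_m + b_m)
    inf_m = a_m * tau_m

    # h and j gates
    if v >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    else:
        a_h = 0.135 * np.exp(-(v + 80.0) / 6.8)
        b_h = 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v)
        a_j = ((-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
               * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))))
        b_j = 0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    tau_h = 1.0 / (a_h + b_h)
    inf_h = a_h * tau_h
    tau_j = 1.0 / (a_j + b_j)
    inf_j = a_j * tau_j

    # transient outward gates
    a_oa = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    tau_oa = 1.0 / ((a_oa + b_oa) * K_Q10)
    inf_oa = 1.0 / (1.0 + np.exp(-(v + 20.47) / 17.54))

    a_oi = 1.0 / (18.53 + np.exp((v + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(v + 1.26) / 7.44))
    tau_oi = 1.0 / ((a_oi + b_oi) * K_Q10)
    inf_oi = 1.0 / (1.0 + np.exp((v + 43.1) / 5.3))

    # ultrarapid rectifier gates
    a_ua = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    tau_ua = 1.0 / ((a_ua + b_ua) * K_Q10)
    inf_ua = 1.0 / (1.0 + np.exp(-(v + 30.3) / 9.6))

    a_ui = 1.0 / (21.0 + np.exp(-(v - 185.0) / 28.0))
    b_ui = np.exp((v - 158.0) / 16.0)
    tau_ui = 1.0 / ((a_ui + b_ui) * K_Q10)
    inf_ui = 1.0 / (1.0 + np.exp((v - 99.45) / 27.48))

    # rapid delayed rectifier
    dv = v + 14.1
    if abs(dv) < _GUARD:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * dv / (1.0 - np.exp(-dv / 5.0))
    dv = v - 3.3328
    if abs(dv) < _GUARD:
        b_xr = 3.7836118e-4
    else:
        b_xr = 7.3898e-5 * dv / (np.exp(dv / 5.1237) - 1.0)
    tau_xr = 1.0 / (a_xr + b_xr)
    inf_xr = 1.0 / (1.0 + np.exp(-(v + 14.1) / 6.5))

    # slow delayed rectifier
    dv = v - 19.9
    if abs(dv) < _GUARD:
        a_xs = 6.8e-4
        b_xs = 3.15e-4
    else:
        a_xs = 4e-5 * dv / (1.0 - np.exp(-dv / 17.0))
        b_xs = 3.5e-5 * dv / (np.exp(dv / 9.0) - 1.0)
    tau_xs = 0.5 / (a_xs + b_xs)
    inf_xs = 1.0 / np.sqrt(1.0 + np.exp(-(v - 19.9) / 12.7))

    # L-type calcium activation/inactivation
    dv = v + 10.0
    e1 = np.exp(-dv / 6.24)
    if abs(dv) < _GUARD:
        tau_d = 1.0 / (0.035 * 6.24 * 2.0)
    else:
        tau_d = (1.0 - e1) / (0.035 * dv * (1.0 + e1))
    inf_d = 1.0 / (1.0 + np.exp(-dv / 8.0))

    tau_f = 9.0 / (0.0197 * np.exp(-(0.0337 * 0.0337) * dv * dv) + 0.02)
    inf_f = 1.0 / (1.0 + np.exp((v + 28.0) / 6.9))

    # SR release voltage gate w
    dv = v - 7.9
    if abs(dv) < _GUARD:
        tau_w = 6.0 * 0.2 / 1.3
    else:
        e1 = np.exp(-dv / 5.0)
        tau_w = 6.0 * (1.0 - e1) / ((1.0 + 0.3 * e1) * dv)
    inf_w = 1.0 - 1.0 / (1.0 + np.exp(-(v - 40.0) / 17.0))

    # voltage-only current coefficients
    c_k1 = 1.0 / (1.0 + np.exp(0.07 * (v + 80.0)))
    g_kur_v = 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0))
    c_kr = 1.0 / (1.0 + np.exp((v + 15.0) / 22.4))
    f_nak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / RTF)
                   + 0.0365 * SIGMA_NAK * np.exp(-v / RTF))
    e_g = np.exp(GAMMA * v / RTF)
    e_g1 = np.exp((GAMMA - 1.0) * v / RTF)

    return (inf_m, tau_m, inf_h, tau_h, inf_j, tau_j, inf_oa, tau_oa,
            inf_oi, tau_oi, inf_ua, tau_ua, inf_ui, tau_ui, inf_xr, tau_xr,
            inf_xs, tau_xs, inf_d, tau_d, inf_f, tau_f, inf_w, tau_w,
            c_k1, g_kur_v, c_kr, f_nak, e_g, e_g1)


@njit(cache=True)
def build_vtable():
    n = int(round((TAB_VMAX - TAB_VMIN) / TAB_DV)) + 1
    tab = np.empty((n, TAB_NCOL))
    for i in range(n):
        vals = _vdep(TAB_VMIN + i * TAB_DV)
        for k in range(TAB_NCOL):
            tab[i, k] = vals[k]
    return tab


@njit(cache=True, fastmath=True, inline="always")
def _vdep_lookup(tab, v, out):
    """Linear interpolation of all 30 tabled quantities into out[:30]."""
    x = (v - TAB_VMIN) / TAB_DV
    if x < 0.0:
        x = 0.0
    nmax = tab.shape[0] - 1.000001
    if x > nmax:
        x = nmax
    i = int(x)
    f = x - i
    for k in range(TAB_NCOL):
        out[k] = tab[i, k] + f * (tab[i + 1, k] - tab[i, k])


@njit(cache=True, fastmath=True, inline="always")
def _vdep_eval(tab, use_tab, v, out):
    if use_tab:
        _vdep_lookup(tab, v, out)
    else:
        vals = _vdep(v)
        for k in range(TAB_NCOL):
            out[k] = vals[k]


@njit(cache=True, fastmath=True, inline="always")
def _vdep_eval_currents(tab, use_tab, v, out):
    """Only the 6 current coefficients (columns 24..29); gate kinetics are
    not needed at quadrature points."""
    if use_tab:
        x = (v - TAB_VMIN) / TAB_DV
        if x < 0.0:
            x = 0.0
        nmax = tab.shape[0] - 1.000001
        if x > nmax:
            x = nmax
        i = int(x)
        f = x - i
        for k in range(24, TAB_NCOL):
            out[k] = tab[i, k] + f * (tab[i + 1, k] - tab[i, k])
    else:
        vals = _vdep(v)
        for k in range(24, TAB_NCOL):
            out[k] = vals[k]


@njit(cache=True, fastmath=True, inline="always")
def _currents(v, w, c, s_to, s_cal, s_kur, vd):
    """All CRN membrane currents and SR fluxes at one point.

    w: 15 gates, c: 5 concentrations, s_*: remodeling scale factors,
    vd: the 30 voltage-dependent quantities.  Returns a 16-tuple.
    """
    nai, ki, cai, caup, carel = c[0], c[1], c[2], c[3], c[4]
    e_na = RTF * np.log(NA_O / nai)
    e_k = RTF * np.log(K_O / ki)
    e_ca = 0.5 * RTF * np.log(CA_O / cai)

    i_na = G_NA * w[0] * w[0] * w[0] * w[1] * w[2] * (v - e_na)
    i_k1 = G_K1 * vd[24] * (v - e_k)
    i_to = G_TO * s_to * w[3] * w[3] * w[3] * w[4] * (v - e_k)
    i_kur = vd[25] * s_kur * w[5] * w[5] * w[5] * w[6] * (v - e_k)
    i_kr = G_KR * vd[26] * w[7] * (v - e_k)
    i_ks = G_KS * w[8] * w[8] * (v - e_k)
    i_cal = G_CAL * s_cal * w[9] * w[10] * w[11] * (v - 65.0)
    i_nak = (I_NAK_MAX * vd[27] * (K_O / (K_O + KM_KO))
             / (1.0 + (KM_NAI / nai) ** 1.5))
    i_naca = (I_NACA_MAX
              * (vd[28] * nai * nai * nai * CA_O - vd[29] * NA_O ** 3 * cai)
              / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                 * (1.0 + K_SAT * vd[29])))
    i_bna = G_BNA * (v - e_na)
    i_bca = G_BCA * (v - e_ca)
    i_pca = I_PCA_MAX * cai / (0.0005 + cai)

    i_up = I_UP_MAX / (1.0 + K_UP / cai)
    i_upleak = I_UP_MAX * caup / CA_UP_MAX
    i_tr = (caup - carel) / TAU_TR
    i_rel = K_REL * w[12] * w[12] * w[13] * w[14] * (carel - cai)

    return (i_na, i_k1, i_to, i_kur, i_kr, i_ks, i_cal, i_nak, i_naca,
            i_bna, i_bca, i_pca, i_up, i_upleak, i_tr, i_rel)


@njit(cache=True, fastmath=True, inline="always")
def _iion_total(cur):
    return (cur[0] + cur[1] + cur[2] + cur[3] + cur[4] + cur[5] + cur[6]
            + cur[7] + cur[8] + cur[9] + cur[10] + cur[11])


@njit(cache=True, fastmath=True, inline="always")
def _fn_gates(cur):
    """Calcium-release gate targets from the SR flux signal Fn.

    The sigmoid arguments routinely saturate; they are clamped to keep the
    exponentials finite.
    """
    fn = (1e-12 * V_REL * cur[15]
          - (5e-13 / FARADAY) * (0.5 * cur[6] - 0.2 * cur[8]) * CM)
    a1 = -(fn - 3.4175e-13) / 13.67e-16
    if a1 > 300.0:
        a1 = 300.0
    elif a1 < -300.0:
        a1 = -300.0
    a2 = -(fn - 6.835e-14) / 13.67e-16
    if a2 > 300.0:
        a2 = 300.0
    elif a2 < -300.0:
        a2 = -300.0
    e1 = np.exp(a1)
    inf_u = 1.0 / (1.0 + e1)
    inf_v = 1.0 - 1.0 / (1.0 + np.exp(a2))
    tau_v = 1.91 + 2.09 / (1.0 + e1)
    return inf_u, inf_v, tau_v


@njit(cache=True, fastmath=True, inline="always")
def _conc_rhs(cur, c):
    """Concentration time derivatives G (mM/ms); currents in pA/pF."""
    cai, caup, carel = c[2], c[3], c[4]
    f_vi = CM / (FARADAY * V_I)
    d_nai = (-3.0 * cur[7] - 3.0 * cur[8] - cur[9] - cur[0]) * f_vi
    d_ki = (2.0 * cur[7] - cur[1] - cur[2] - cur[3] - cur[4] - cur[5]) * f_vi
    b1 = ((2.0 * cur[8] - cur[11] - cur[6] - cur[10]) * 0.5 * f_vi
          + (V_UP * (cur[13] - cur[12]) + cur[15] * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / ((cai + KM_TRPN) * (cai + KM_TRPN))
          + CMDN_MAX * KM_CMDN / ((cai + KM_CMDN) * (cai + KM_CMDN)))
    d_cai = b1 / b2
    d_caup = cur[12] - cur[13] - cur[14] * V_REL / V_UP
    d_carel = ((cur[14] - cur[15])
               / (1.0 + CSQN_MAX * KM_CSQN / ((carel + KM_CSQN) * (carel + KM_CSQN))))
    return d_nai, d_ki, d_cai, d_caup, d_carel


@njit(cache=True, fastmath=True)
def ionic_step(v_ext, w_ext, c_ext, w_bdf, c_bdf, s_to, s_cal, s_kur,
               dt, alpha, w_new, c_new, tab, use_tab):
    """One segregated BDF step of the ionic model on every node.

    Gate ODEs dw/dt=(w_inf-w)/tau are linear in w, so the BDF update is
    solved in closed form (unconditionally stable); rate coefficients are
    evaluated at the extrapolated potential.  Concentration derivatives are
    evaluated at (v_ext, w_new, c_ext) and advanced with the same BDF
    combination.  alpha is the leading BDF coefficient, w_bdf/c_bdf the
    history combinations (already divided by nothing: update is
    x_new = (x_bdf + dt*rhs_or_inf_terms)/alpha as appropriate).
    """
    n = v_ext.shape[0]
    vd = np.empty(TAB_NCOL)
    w = np.empty(N_GATES)
    wn = np.empty(N_GATES)
    c = np.empty(N_CONC)
    for i in range(n):
        v = v_ext[i]
        _vdep_eval(tab, use_tab, v, vd)
        for k in range(N_GATES):
            w[k] = w_ext[k, i]
        for k in range(N_CONC):
            c[k] = c_ext[k, i]

        cur = _currents(v, w, c, s_to[i], s_cal[i], s_kur[i], vd)
        inf_u, inf_v, tau_v = _fn_gates(cur)
        inf_fca = 1.0 / (1.0 + c[2] / 0.00035)

        # implicit linear gate updates: (alpha w - w_bdf)/dt = (inf - w)/tau
        # tabled gate order is m,h,j,oa,oi,ua,ui,xr,xs,d,f (state 0..10)
        # followed by w_g (state 14)
        for k in range(12):
            kk = k if k < 11 else 14
            r = dt / vd[2 * k + 1]
            wk = (w_bdf[kk, i] + r * vd[2 * k]) / (alpha + r)
            if wk < 0.0:
                wk = 0.0
            elif wk > 1.0:
                wk = 1.0
            wn[kk] = wk
        r = dt / TAU_F_CA
        wn[11] = (w_bdf[11, i] + r * inf_fca) / (alpha + r)
        r = dt / TAU_U
        wn[12] = (w_bdf[12, i] + r * inf_u) / (alpha + r)
        r = dt / tau_v
        wn[13] = (w_bdf[13, i] + r * inf_v) / (alpha + r)
        for k in range(11, 14):
            if wn[k] < 0.0:
                wn[k] = 0.0
            elif wn[k] > 1.0:
                wn[k] = 1.0

        # concentrations with updated gates (segregated scheme)
        cur2 = _currents(v, wn, c, s_to[i], s_cal[i], s_kur[i], vd)
        g0, g1, g2, g3, g4 = _conc_rhs(cur2, c)
        c_new[0, i] = max((c_bdf[0, i] + dt * g0) / alpha, 1e-12)
        c_new[1, i] = max((c_bdf[1, i] + dt * g1) / alpha, 1e-12)
        c_new[2, i] = max((c_bdf[2, i] + dt * g2) / alpha, 1e-12)
        c_new[3, i] = max((c_bdf[3, i] + dt * g3) / alpha, 1e-12)
        c_new[4, i] = max((c_bdf[4, i] + dt * g4) / alpha, 1e-12)
        for k in range(N_GATES):
            w_new[k, i] = wn[k]


@njit(cache=True, fastmath=True)
def iion_nodal(v, w, c, s_to, s_cal, s_kur, out, tab, use_tab):
    """Total ionic current (pA/pF) at every node."""
    n = v.shape[0]
    vd = np.empty(TAB_NCOL)
    wi = np.empty(N_GATES)
    ci = np.empty(N_CONC)
    for i in range(n):
        _vdep_eval(tab, use_tab, v[i], vd)
        for k in range(N_GATES):
            wi[k] = w[k, i]
        for k in range(N_CONC):
            ci[k] = c[k, i]
        cur = _currents(v[i], wi, ci, s_to[i], s_cal[i], s_kur[i], vd)
        out[i] = _iion_total(cur)


@njit(cache=True, fastmath=True)
def currents_nodal(v, w, c, s_to, s_cal, s_kur, out, tab, use_tab):
    """Per-current breakdown at every node; out has shape (16, n)."""
    n = v.shape[0]
    vd = np.empty(TAB_NCOL)
    wi = np.empty(N_GATES)
    ci = np.empty(N_CONC)
    for i in range(n):
        _vdep_eval(tab, use_tab, v[i], vd)
        for k in range(N_GATES):
            wi[k] = w[k, i]
        for k in range(N_CONC):
            ci[k] = c[k, i]
        cur = _currents(v[i], wi, ci, s_to[i], s_cal[i], s_kur[i], vd)
        for k in range(16):
            out[k, i] = cur[k]


@njit(cache=True, fastmath=True)
def state_rhs(v, w, c, s_to, s_cal, s_kur, dw, dc, tab, use_tab):
    """Continuous-time right-hand sides H (gates) and G (concentrations)."""
    n = v.shape[0]
    vd = np.empty(TAB_NCOL)
    wi = np.empty(N_GATES)
    ci = np.empty(N_CONC)
    for i in range(n):
        _vdep_eval(tab, use_tab, v[i], vd)
        for k in range(N_GATES):
            wi[k] = w[k, i]
        for k in range(N_CONC):
            ci[k] = c[k, i]
        cur = _currents(v[i], wi, ci, s_to[i], s_cal[i], s_kur[i], vd)
        inf_u, inf_v, tau_v = _fn_gates(cur)
        inf_fca = 1.0 / (1.0 + ci[2] / 0.00035)
        for k in range(12):
            kk = k if k < 11 else 14  # 12th tabled gate is w_g
            dw[kk, i] = (vd[2 * k] - wi[kk]) / vd[2 * k + 1]
        dw[11, i] = (inf_fca - wi[11]) / TAU_F_CA
        dw[12, i] = (inf_u - wi[12]) / TAU_U
        dw[13, i] = (inf_v - wi[13]) / tau_v
        g = _conc_rhs(cur, ci)
        for k in range(N_CONC):
            dc[k, i] = g[k]


@njit(cache=True, fastmath=True)
def combine_states(w_ring, c_ring, slots, wts, ext,
                   w_bdf, w_ext, c_bdf, c_ext):
    """BDF history/extrapolation combinations of gate and concentration
    ring buffers.  slots[0] is the newest time level; wts/ext are the BDF
    history and extrapolation weights for the current order."""
    k = slots.shape[0]
    n = w_ring.shape[2]
    for g in range(N_GATES):
        for i in range(n):
            sb = 0.0
            se = 0.0
            for m in range(k):
                v = w_ring[slots[m], g, i]
                sb += wts[m] * v
                se += ext[m] * v
            w_bdf[g, i] = sb
            w_ext[g, i] = min(max(se, 0.0), 1.0)
    for g in range(N_CONC):
        for i in range(n):
            sb = 0.0
            se = 0.0
            for m in range(k):
                v = c_ring[slots[m], g, i]
                sb += wts[m] * v
                se += ext[m] * v
            c_bdf[g, i] = sb
            c_ext[g, i] = max(se, 1e-12)


@njit(cache=True, fastmath=True)
def svi_iion_load(elems, shape_q, detjw, v_ext, w, c, s_to, s_cal, s_kur,
                  out, tab, use_tab):
    """SVI ionic load vector: state variables are interpolated to the
    quadrature points with the element basis, the ionic current is evaluated
    there, then tested against the basis functions.

    elems: (ne, nn) connectivity; shape_q: (nq, nn) basis values at the
    quadrature points; detjw: (ne, nq) Jacobian-determinant times weight.
    out must be zero-initialized, shape (n_nodes,).
    """
    ne, nn = elems.shape
    nq = shape_q.shape[0]
    vd = np.empty(TAB_NCOL)
    wq = np.empty(N_GATES)
    cq = np.empty(N_CONC)
    local = np.empty((nn, N_GATES + N_CONC + 4))
    for e in range(ne):
        # gather the corner states once per element
        for a in range(nn):
            i = elems[e, a]
            local[a, 0] = v_ext[i]
            local[a, 1] = s_to[i]
            local[a, 2] = s_cal[i]
            local[a, 3] = s_kur[i]
            for k in range(N_GATES):
                local[a, 4 + k] = w[k, i]
            for k in range(N_CONC):
                local[a, 4 + N_GATES + k] = c[k, i]
        for q in range(nq):
            vq = 0.0
            stq = 0.0
            scq = 0.0
            skq = 0.0
            for k in range(N_GATES):
                wq[k] = 0.0
            for k in range(N_CONC):
                cq[k] = 0.0
            for a in range(nn):
                na = shape_q[q, a]
                vq += na * local[a, 0]
                stq += na * local[a, 1]
                scq += na * local[a, 2]
                skq += na * local[a, 3]
                for k in range(N_GATES):
                    wq[k] += na * local[a, 4 + k]
                for k in range(N_CONC):
                    cq[k] += na * local[a, 4 + N_GATES + k]
            _vdep_eval_currents(tab, use_tab, vq, vd)
            cur = _currents(vq, wq, cq, stq, scq, skq, vd)
            iiq = _iion_total(cur) * detjw[e, q]
            for a in range(nn):
                out[elems[e, a]] += iiq * shape_q[q, a]
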