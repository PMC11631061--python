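"""Numba kernels for the closed-loop integrator.

Internal units: seconds, mL, mmHg, mL/s.  The public API works in ms; the
packing code in :mod:`atriapace.model` converts.

State vector (length 9):
    0 V_la, 1 V_lv, 2 V_ra, 3 V_rv         chamber volumes [mL]
    4 V_sa, 5 V_sv, 6 V_pa, 7 V_pv          vascular volumes [mL]
    8 q_mit                                  mitral flow (inertial state) [mL/s]

Parameter vector ``P`` layout (length NP):
    0..27   four chamber blocks [LA, LV, RA, RV], 7 slots each:
            V0, E (= c * E_act), P_ref, k, onset_s, d_act_s, tau_s
    28..35  C_sa, V0_sa, C_sv, V0_sv, C_pa, V0_pa, C_pv, V0_pv
    36..44  R_mit, L_mit, R_ao, R_tri, R_pu, R_sys, R_ven, R_pul, R_pvn
    45..48  P_ref_peri, k_peri, V0_peri, peri_enabled
    49      cycle length [s]
    50      valves_open flag (1.0 -> bidirectional resistive valves)
"""
import math

import numpy as np
from numba import njit

NSTATE = 9
NAUX = 17
NP = 51

# aux layout
AUX_P_LA, AUX_P_LV, AUX_P_RA, AUX_P_RV = 0, 1, 2, 3
AUX_P_SA, AUX_P_SV, AUX_P_PA, AUX_P_PV = 4, 5, 6, 7
AUX_P_PERI = 8
AUX_Q_MIT, AUX_Q_AO, AUX_Q_TRI, AUX_Q_PU = 9, 10, 11, 12
AUX_Q_SYS, AUX_Q_VEN, AUX_Q_PUL, AUX_Q_PVN = 13, 14, 15, 16

I_CL = 49
I_OPEN = 50
I_RSYS = 41


@njit(cache=True)
def act_shape(t, d, tau):
    """Activation waveform: sin^2 rise over [0, d], exponential tail after d."""
    if t <= 0.0:
        return 0.0
    if t <= d:
        s = math.sin(0.5 * math.pi * t / d)
        return s * s
    return math.exp(-(t - d) / tau)


@njit(cache=True)
def act_cyclic(t, onset, d, tau, cl):
    """Periodic activation with the previous beat's tail carried across the wrap."""
    x = (t - onset) % cl
    a = act_shape(x, d, tau)
    b = act_shape(x + cl, d, tau)
    return a if a > b else b


@njit(cache=True)
def chamber_p(v, p, i, t, cl):
    """Chamber pressure, transmural (pericardium added by caller)."""
    b = 7 * i
    v0 = p[b]
    e = p[b + 1]
    pref = p[b + 2]
    kk = p[b + 3]
    a = act_cyclic(t, p[b + 4], p[b + 5], p[b + 6], cl)
    x = kk * (v / v0 - 1.0)
    if x > 40.0:
        x = 40.0
    return a * e * (v - v0) + pref * math.expm1(x)


@njit(cache=True)
def _derivs(t, y, p, dy, aux):
    cl = p[49]
    open_mode = p[50] > 0.5

    # pericardial pressure on total heart volume (slack below its rest volume)
    pperi = 0.0
    if p[48] > 0.5:
        x = p[46] * ((y[0] + y[1] + y[2] + y[3]) / p[47] - 1.0)
        if x > 0.0:
            if x > 40.0:
                x = 40.0
            pperi = p[45] * math.expm1(x)

    p_la = chamber_p(y[0], p, 0, t, cl) + pperi
    p_lv = chamber_p(y[1], p, 1, t, cl) + pperi
    p_ra = chamber_p(y[2], p, 2, t, cl) + pperi
    p_rv = chamber_p(y[3], p, 3, t, cl) + pperi
    p_sa = (y[4] - p[29]) / p[28]
    p_sv = (y[5] - p[31]) / p[30]
    p_pa = (y[6] - p[33]) / p[32]
    p_pv = (y[7] - p[35]) / p[34]

    r_mit = p[36]
    l_mit = p[37]
    r_ao = p[38]
    r_tri = p[39]
    r_pu = p[40]
    r_sys = p[41]
    r_ven = p[42]
    r_pul = p[43]
    r_pvn = p[44]

    q_mit = y[8]
    dq = (p_la - p_lv - r_mit * q_mit) / l_mit
    if open_mode:
        q_ao = (p_lv - p_sa) / r_ao
        q_tri = (p_ra - p_rv) / r_tri
        q_pu = (p_rv - p_pa) / r_pu
    else:
        dpa = p_lv - p_sa
        q_ao = dpa / r_ao if dpa > 0.0 else 0.0
        dpt = p_ra - p_rv
        q_tri = dpt / r_tri if dpt > 0.0 else 0.0
        dpp = p_rv - p_pa
        q_pu = dpp / r_pu if dpp > 0.0 else 0.0
        if q_mit <= 0.0 and dq < 0.0:
            dq = 0.0

    q_sys = (p_sa - p_sv) / r_sys
    q_ven = (p_sv - p_ra) / r_ven
    q_pul = (p_pa - p_pv) / r_pul
    q_pvn = (p_pv - p_la) / r_pvn

    dy[0] = q_pvn - q_mit
    dy[1] = q_mit - q_ao
    dy[2] = q_ven - q_tri
    dy[3] = q_tri - q_pu
    dy[4] = q_ao - q_sys
    dy[5] = q_sys - q_ven
    dy[6] = q_pu - q_pul
    dy[7] = q_pul - q_pvn
    dy[8] = dq

    aux[0] = p_la
    aux[1] = p_lv
    aux[2] = p_ra
    aux[3] = p_rv
    aux[4] = p_sa
    aux[5] = p_sv
    aux[6] = p_pa
    aux[7] = p_pv
    aux[8] = pperi
    aux[9] = q_mit
    aux[10] = q_ao
    aux[11] = q_tri
    aux[12] = q_pu
    aux[13] = q_sys
    aux[14] = q_ven
    aux[15] = q_pul
    aux[16] = q_pvn


@njit(cache=True)
def integrate_cycle(y0, p, dt):
    """Integrate exactly one cardiac cycle with fixed-step RK4.

    Returns (Y, AUX, ok): state and aux sampled on the dt grid including both
    endpoints (t = 0 .. CL), and ok=False if any volume went negative.
    """
    cl = p[49]
    n = int(round(cl / dt))
    Y = np.empty((n + 1, NSTATE))
    AUX = np.empty((n + 1, NAUX))
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    yt = np.empty(NSTATE)
    scratch = np.empty(NAUX)
    y = y0.copy()
    ok = True
    sixth = dt / 6.0
    half = 0.5 * dt
    for i in range(n + 1):
        t = i * dt
        _derivs(t, y, p, k1, scratch)
        for j in range(NSTATE):
            Y[i, j] = y[j]
        for j in range(NAUX):
            AUX[i, j] = scratch[j]
        if i == n:
            break
        for j in range(NSTATE):
            yt[j] = y[j] + half * k1[j]
        _derivs(t + half, yt, p, k2, scratch)
        for j in range(NSTATE):
            yt[j] = y[j] + half * k2[j]
        _derivs(t + half, yt, p, k3, scratch)
        for j in range(NSTATE):
            yt[j] = y[j] + dt * k3[j]
        _derivs(t + dt, yt, p, k4, scratch)
        for j in range(NSTATE):
            y[j] += sixth * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        if p[50] < 0.5 and y[8] < 0.0:
            y[8] = 0.0
        for j in range(8):
            if y[j] < 0.0:
                ok = False
    return Y, AUX, ok
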