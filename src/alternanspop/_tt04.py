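"""Numba kernels for the human ventricular epicardial myocyte model.

Hodgkin–Huxley-style formulation with 12 membrane currents, simplified
calcium-induced calcium release, and rapid-equilibrium cytosolic / SR
calcium buffering (epicardial parameterization of the 2004 human
ventricular cell model).  State layout and parameter layout are flat
float64 arrays so the integrator can be JIT-compiled.

State vector (length 17):
    0  V     membrane potential, mV
    1  m     fast Na+ activation
    2  h     fast Na+ fast inactivation
    3  j     fast Na+ slow inactivation
    4  d     L-type Ca2+ activation
    5  f     L-type Ca2+ voltage inactivation
    6  fca   L-type Ca2+ calcium-dependent inactivation
    7  r     transient outward activation
    8  s     transient outward inactivation
    9  xs    slow delayed rectifier activation
    10 xr1   rapid delayed rectifier activation
    11 xr2   rapid delayed rectifier inactivation
    12 g     SR calcium-release gate
    13 nai   intracellular Na+, mM
    14 ki    intracellular K+, mM
    15 cai   free cytosolic Ca2+, mM
    16 casr  free SR Ca2+, mM

Parameter vector (length 16): the 10 scalable maximal conductances in
Table-order (g_Ks, g_Kr, g_K1, g_Na, g_bNa, g_CaL, g_bCa, g_to, g_pCa,
g_pK) followed by the non-varied maxima (P_NaK, k_NaCa, Vmax_up, V_leak,
a_rel, c_rel).

Integration: Rush–Larsen exponential updates for the Hodgkin–Huxley
gates, forward Euler for V and the four concentrations.
"""

import numpy as np
from numba import njit

NSTATE = 17
NPARAM = 16

# physical constants (mV, ms, mM conventions)
R_GAS = 8314.472
TEMP = 310.0
FARADAY = 96485.3415
RTONF = R_GAS * TEMP / FARADAY

# extracellular concentrations, mM
K_O = 5.4
NA_O = 140.0
CA_O = 2.0

# cell geometry / capacitance (membrane currents are pA/pF)
V_C = 0.016404
V_SR = 0.001094
CAPACITANCE = 0.185

# fixed current parameters
P_KNA = 0.03
KM_NAI = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA_NCX = 0.35
ALPHA_NCX = 2.5
KM_K = 1.0
KM_NA = 40.0
KP_CA = 0.0005
B_REL = 0.25
K_UP = 0.00025
BUF_C = 0.15
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3
TAU_FCA = 2.0
TAU_G = 2.0

# reference quiescent-ish initial conditions of the published model
DEFAULT_Y0 = np.array(
    [
        -86.2,  # V
        0.0,  # m
        0.75,  # h
        0.75,  # j
        0.0,  # d
        1.0,  # f
        1.0,  # fca
        0.0,  # r
        1.0,  # s
        0.0,  # xs
        0.0,  # xr1
        1.0,  # xr2
        1.0,  # g
        11.6,  # nai
        138.3,  # ki
        0.0002,  # cai
        0.2,  # casr
    ]
)


@njit(cache=True)
def currents(y, p):
    """All 12 membrane currents in pA/pF, in the canonical sum order.

    Returns (I_Na, I_K1, I_to, I_Kr, I_Ks, I_CaL, I_NaCa, I_NaK, I_pCa,
    I_pK, I_bCa, I_bNa).
    """
    v = y[0]
    m = y[1]
    h = y[2]
    j = y[3]
    d = y[4]
    f = y[5]
    fca = y[6]
    r = y[7]
    s = y[8]
    xs = y[9]
    xr1 = y[10]
    xr2 = y[11]
    nai = y[13]
    ki = y[14]
    cai = y[15]

    g_ks = p[0]
    g_kr = p[1]
    g_k1 = p[2]
    g_na = p[3]
    g_bna = p[4]
    g_cal = p[5]
    g_bca = p[6]
    g_to = p[7]
    g_pca = p[8]
    g_pk = p[9]
    p_nak = p[10]
    k_naca = p[11]

    e_na = RTONF * np.log(NA_O / nai)
    e_k = RTONF * np.log(K_O / ki)
    e_ks = RTONF * np.log((K_O + P_KNA * NA_O) / (ki + P_KNA * nai))
    e_ca = 0.5 * RTONF * np.log(CA_O / cai)

    i_na = g_na * m * m * m * h * j * (v - e_na)

    # inward rectifier: voltage- and E_K-dependent open probability
    dvk = v - e_k
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (dvk - 200.0)))
    bk1 = (
        3.0 * np.exp(0.0002 * (dvk + 100.0)) + np.exp(0.1 * (dvk - 10.0))
    ) / (1.0 + np.exp(-0.5 * dvk))
    i_k1 = g_k1 * np.sqrt(K_O / 5.4) * (ak1 / (ak1 + bk1)) * dvk

    i_to = g_to * r * s * dvk
    i_kr = g_kr * np.sqrt(K_O / 5.4) * xr1 * xr2 * dvk
    i_ks = g_ks * xs * xs * (v - e_ks)

    # L-type Ca2+: GHK-like driving force; series limit at v == 0
    vfrt2 = 2.0 * v / RTONF
    if np.abs(vfrt2) < 1e-7:
        # exp(x) - 1 ~ x: limit of x/(exp(x)-1) -> 1
        drive = cai * (1.0 + vfrt2) - 0.341 * CA_O
        i_cal = g_cal * d * f * fca * 2.0 * FARADAY * drive
    else:
        ex = np.exp(vfrt2)
        i_cal = (
            g_cal
            * d
            * f
            * fca
            * 4.0
            * v
            * FARADAY
            / RTONF
            * (cai * ex - 0.341 * CA_O)
            / (ex - 1.0)
        )

    evg = np.exp(GAMMA_NCX * v / RTONF)
    evg1 = np.exp((GAMMA_NCX - 1.0) * v / RTONF)
    i_naca = (
        k_naca
        * (evg * nai**3 * CA_O - evg1 * NA_O**3 * cai * ALPHA_NCX)
        / (
            (KM_NAI**3 + NA_O**3)
            * (KM_CA + CA_O)
            * (1.0 + K_SAT * evg1)
        )
    )

    i_nak = (
        p_nak
        * K_O
        * nai
        / (
            (K_O + KM_K)
            * (nai + KM_NA)
            * (
                1.0
                + 0.1245 * np.exp(-0.1 * v / RTONF)
                + 0.0353 * np.exp(-v / RTONF)
            )
        )
    )

    i_pca = g_pca * cai / (KP_CA + cai)
    i_pk = g_pk * dvk / (1.0 + np.exp((25.0 - v) / 5.98))
    i_bca = g_bca * (v - e_ca)
    i_bna = g_bna * (v - e_na)

    return (
        i_na,
        i_k1,
        i_to,
        i_kr,
        i_ks,
        i_cal,
        i_naca,
        i_nak,
        i_pca,
        i_pk,
        i_bca,
        i_bna,
    )


@njit(cache=True)
def step_once(y, p, dt, i_stim):
    """Advance the state one dt in place.  i_stim in pA/pF (negative
    values depolarize, matching the stimulus sign convention)."""
    v = y[0]
    cai = y[15]
    casr = y[16]

    cur = currents(y, p)
    i_ion = (
        cur[0]
        + cur[1]
        + cur[2]
        + cur[3]
        + cur[4]
        + cur[5]
        + cur[6]
        + cur[7]
        + cur[8]
        + cur[9]
        + cur[10]
        + cur[11]
    )
    i_cal = cur[5]
    i_naca = cur[6]
    i_nak = cur[7]
    i_pca = cur[8]
    i_bca = cur[10]

    # --- gate kinetics -------------------------------------------------
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) + 0.10 / (
        1.0 + np.exp((v - 50.0) / 200.0)
    )
    tau_m = am * bm

    h_inf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    if v < -40.0:
        ah = 0.057 * np.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
    tau_h = 1.0 / (ah + bh)

    j_inf = h_inf
    if v < -40.0:
        aj = (
            (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + np.exp(0.311 * (v + 79.23)))
        )
        bj = 0.02424 * np.exp(-0.01052 * v) / (
            1.0 + np.exp(-0.1378 * (v + 40.14))
        )
    else:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    tau_j = 1.0 / (aj + bj)

    d_inf = 1.0 / (1.0 + np.exp((-5.0 - v) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    tau_d = ad * bd + gd

    f_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tau_f = (
        1125.0 * np.exp(-((v + 27.0) ** 2) / 240.0)
        + 80.0
        + 165.0 / (1.0 + np.exp((25.0 - v) / 10.0))
    )

    afca = 1.0 / (1.0 + (cai / 0.000325) ** 8)
    bfca = 0.1 / (1.0 + np.exp((cai - 0.0005) / 0.0001))
    gfca = 0.2 / (1.0 + np.exp((cai - 0.00075) / 0.0008))
    fca_inf = (afca + bfca + gfca + 0.23) / 1.46

    r_inf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    tau_r = 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    s_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
    tau_s = (
        85.0 * np.exp(-((v + 45.0) ** 2) / 320.0)
        + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0))
        + 3.0
    )

    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    axs = 1100.0 / np.sqrt(1.0 + np.exp((-10.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((v - 60.0) / 20.0))
    tau_xs = axs * bxs

    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
    tau_xr1 = axr1 * bxr1

    xr2_inf = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    tau_xr2 = axr2 * bxr2

    if cai < 0.00035:
        g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    else:
        g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 16)

    # --- calcium handling ---------------------------------------------
    v_max_up = p[12]
    v_leak = p[13]
    a_rel = p[14]
    c_rel = p[15]

    i_leak = v_leak * (casr - cai)
    i_up = v_max_up / (1.0 + (K_UP / cai) ** 2)
    i_rel = (a_rel * casr * casr / (B_REL * B_REL + casr * casr) + c_rel) * y[
        4
    ] * y[12]

    caibufc = 1.0 / (
        1.0 + BUF_C * K_BUF_C / ((cai + K_BUF_C) * (cai + K_BUF_C))
    )
    casrbufsr = 1.0 / (
        1.0 + BUF_SR * K_BUF_SR / ((casr + K_BUF_SR) * (casr + K_BUF_SR))
    )

    dcai = caibufc * (
        i_leak
        - i_up
        + i_rel
        - (i_cal + i_bca + i_pca - 2.0 * i_naca)
        * CAPACITANCE
        / (2.0 * V_C * FARADAY)
    )
    dcasr = casrbufsr * (V_C / V_SR) * (i_up - i_rel - i_leak)
    dnai = (
        -(cur[0] + cur[11] + 3.0 * i_nak + 3.0 * i_naca)
        * CAPACITANCE
        / (V_C * FARADAY)
    )
    dki = (
        -(cur[1] + cur[2] + cur[3] + cur[4] - 2.0 * i_nak + cur[9] + i_stim)
        * CAPACITANCE
        / (V_C * FARADAY)
    )

    # --- Rush–Larsen gate updates -------------------------------------
    y[1] = m_inf - (m_inf - y[1]) * np.exp(-dt / tau_m)
    y[2] = h_inf - (h_inf - y[2]) * np.exp(-dt / tau_h)
    y[3] = j_inf - (j_inf - y[3]) * np.exp(-dt / tau_j)
    y[4] = d_inf - (d_inf - y[4]) * np.exp(-dt / tau_d)
    y[5] = f_inf - (f_inf - y[5]) * np.exp(-dt / tau_f)
    y[7] = r_inf - (r_inf - y[7]) * np.exp(-dt / tau_r)
    y[8] = s_inf - (s_inf - y[8]) * np.exp(-dt / tau_s)
    y[9] = xs_inf - (xs_inf - y[9]) * np.exp(-dt / tau_xs)
    y[10] = xr1_inf - (xr1_inf - y[10]) * np.exp(-dt / tau_xr1)
    y[11] = xr2_inf - (xr2_inf - y[11]) * np.exp(-dt / tau_xr2)

    # conditional gates: may not recover while the membrane is depolarized
    fca_new = fca_inf - (fca_inf - y[6]) * np.exp(-dt / TAU_FCA)
    if not (fca_new > y[6] and v > -60.0):
        y[6] = fca_new
    g_new = g_inf - (g_inf - y[12]) * np.exp(-dt / TAU_G)
    if not (g_new > y[12] and v > -60.0):
        y[12] = g_new

    # --- Euler updates for V and concentrations -----------------------
    y[0] = v - dt * (i_ion + i_stim)
    y[13] = y[13] + dt * dnai
    y[14] = y[14] + dt * dki
    y[15] = cai + dt * dcai
    y[16] = casr + dt * dcasr
    return i_ion


@njit(cache=True)
def integrate(y, p, duration, dt, stim_amp, stim_dur, sample_every, out_v):
    """Integrate for `duration` ms with a stimulus applied on [0, stim_dur).

    Records V into out_v every `sample_every` steps (sample 0 is the state
    at t=0, before any step).  Returns the number of samples written, or
    -(1 + step index) if the state became non-finite.
    """
    nsteps = int(round(duration / dt))
    nsamp = 0
    cap = out_v.shape[0]
    for k in range(nsteps):
        if sample_every > 0 and k % sample_every == 0 and nsamp < cap:
            out_v[nsamp] = y[0]
            nsamp += 1
        t = k * dt
        i_stim = stim_amp if t < stim_dur else 0.0
        step_once(y, p, dt, i_stim)
        if not np.isfinite(y[0]):
            return -(1 + k)
    if sample_every > 0 and nsamp < cap:
        out_v[nsamp] = y[0]
        nsamp += 1
    return nsamp
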