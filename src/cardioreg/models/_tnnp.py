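"""ten Tusscher-Noble-Noble-Panfilov (2004) human ventricular myocyte model.

Epicardial subtype.  Seventeen states: voltage (mV), intracellular and
SR Ca2+, intracellular Na+ and K+ (mM), and twelve gating variables.
Sixteen scalable parameters: ten maximal conductances (nS/pF), the
sarcolemmal Ca2+ pump and Na+/K+ pump and Na+/Ca2+ exchanger maximal
rates, the SERCA uptake and SR leak rates, and the two SR release
parameters (a_rel and c_rel of the original formulation, exposed here
as K_rel1 / K_rel2).

Two gates carry conditional clamps from the source model: Ca-dependent
L-type inactivation (fCa) and the SR release gate (g) are prevented
from re-activating while the membrane is depolarised (V > -60 mV); the
kernel signals the hold with a very large time constant.
"""

import numpy as np
from numba import njit

from .._engine import make_integrator

MODEL_ID = "tnnp"
STATE_NAMES = ("V", "Cai", "CaSR", "Nai", "Ki",
               "m", "h", "j", "d", "f", "fCa", "r", "s",
               "xr1", "xr2", "xs", "g")
PARAM_NAMES = ("G_Na", "G_CaL", "G_to", "G_Kr", "G_Ks", "G_K1", "G_pK",
               "G_bNa", "G_bCa", "K_pCa", "K_NaK", "K_NCX", "K_up",
               "K_leak", "K_rel1", "K_rel2")
BASELINE = np.array([
    14.838,     # G_Na
    1.75e-4,    # G_CaL (L in litre/(F s) units of the source model)
    0.294,      # G_to (epicardial)
    0.096,      # G_Kr
    0.245,      # G_Ks (epicardial)
    5.405,      # G_K1
    0.0146,     # G_pK
    0.00029,    # G_bNa
    0.000592,   # G_bCa
    0.025,      # K_pCa (max sarcolemmal Ca pump current, pA/pF)
    1.362,      # K_NaK (max Na/K pump current, pA/pF)
    1000.0,     # K_NCX (Na/Ca exchanger scale, pA/pF)
    4.25e-4,    # K_up (Vmax of SERCA, mM/ms)
    8.0e-5,     # K_leak (SR leak rate, 1/ms)
    0.016464,   # K_rel1 (a_rel, mM/ms)
    0.008232,   # K_rel2 (c_rel, mM/ms)
])
N_STATE = 17
CAI_IDX = 1
V_IDX = 0
GATES = (5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16)
KO_DEFAULT = 5.4

NAO, CAO = 140.0, 2.0
RT_F = 8314.472 * 310.0 / 96485.3415
F = 96485.3415
CAP = 0.185 / (0.016404 * F)   # Cm / (V_c F): pA/pF -> mM/ms
VC_VSR = 0.016404 / 0.001094

INITIAL_STATE = np.array([
    -86.2,      # V
    2.0e-4,     # Cai
    0.2,        # CaSR
    11.6,       # Nai
    138.3,      # Ki
    0.0,        # m
    0.75,       # h
    0.75,       # j
    0.0,        # d
    1.0,        # f
    1.0,        # fCa
    0.0,        # r
    1.0,        # s
    0.0,        # xr1
    1.0,        # xr2
    0.0,        # xs
    1.0,        # g
])


@njit(cache=True)
def rates(y, p, Ko, stim, dy, inf, tau):
    V = y[0]
    Cai = y[1]
    CaSR = y[2]
    Nai = y[3]
    Ki = y[4]
    m = y[5]
    hh = y[6]
    jj = y[7]
    d = y[8]
    f = y[9]
    fCa = y[10]
    r = y[11]
    s = y[12]
    xr1 = y[13]
    xr2 = y[14]
    xs = y[15]
    g = y[16]

    if Cai < 1e-10:
        Cai = 1e-10

    E_Na = RT_F * np.log(NAO / Nai)
    E_K = RT_F * np.log(Ko / Ki)
    E_Ks = RT_F * np.log((Ko + 0.03 * NAO) / (Ki + 0.03 * Nai))
    E_Ca = 0.5 * RT_F * np.log(CAO / Cai)

    INa = p[0] * m * m * m * hh * jj * (V - E_Na)

    x = 2.0 * V / RT_F
    if abs(x) < 1e-8:
        xfac = 1.0
    else:
        xfac = x / np.expm1(x)
    ICaL = p[1] * d * f * fCa * 2.0 * F * xfac * (Cai * np.exp(x) - 0.341 * CAO)

    Ito = p[2] * r * s * (V - E_K)
    IKr = p[3] * np.sqrt(Ko / 5.4) * xr1 * xr2 * (V - E_K)
    IKs = p[4] * xs * xs * (V - E_Ks)

    aK1 = 0.1 / (1.0 + np.exp(0.06 * (V - E_K - 200.0)))
    bK1 = (3.0 * np.exp(0.0002 * (V - E_K + 100.0)) + np.exp(0.1 * (V - E_K - 10.0))) \
        / (1.0 + np.exp(-0.5 * (V - E_K)))
    IK1 = p[5] * np.sqrt(Ko / 5.4) * aK1 / (aK1 + bK1) * (V - E_K)

    IpK = p[6] * (V - E_K) / (1.0 + np.exp((25.0 - V) / 5.98))
    IbNa = p[7] * (V - E_Na)
    IbCa = p[8] * (V - E_Ca)
    IpCa = p[9] * Cai / (Cai + 0.0005)

    INaK = p[10] * Ko * Nai / ((Ko + 1.0) * (Nai + 40.0)
                               * (1.0 + 0.1245 * np.exp(-0.1 * V / RT_F)
                                  + 0.0353 * np.exp(-V / RT_F)))

    e1 = np.exp(0.35 * V / RT_F)
    e2 = np.exp(-0.65 * V / RT_F)
    INaCa = p[11] * (e1 * Nai ** 3 * CAO - e2 * NAO ** 3 * Cai * 2.5) \
        / ((87.5 ** 3 + NAO ** 3) * (1.38 + CAO) * (1.0 + 0.1 * e2))

    Iup = p[12] / (1.0 + (0.00025 / Cai) ** 2)
    Ileak = p[13] * (CaSR - Cai)
    Irel = (p[14] * CaSR * CaSR / (0.0625 + CaSR * CaSR) + p[15]) * d * g

    I_ion = INa + ICaL + Ito + IKr + IKs + IK1 + IpK + IbNa + IbCa + IpCa + INaK + INaCa

    dy[0] = -I_ion + stim
    bufc = 1.0 / (1.0 + 0.15 * 0.001 / ((Cai + 0.001) * (Cai + 0.001)))
    dy[1] = bufc * (-(ICaL + IbCa + IpCa - 2.0 * INaCa) * CAP * 0.5
                    + Ileak - Iup + Irel)
    bufsr = 1.0 / (1.0 + 10.0 * 0.3 / ((CaSR + 0.3) * (CaSR + 0.3)))
    dy[2] = bufsr * VC_VSR * (Iup - Irel - Ileak)
    dy[3] = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * CAP
    dy[4] = -(IK1 + Ito + IKr + IKs + IpK - 2.0 * INaK - stim) * CAP
    for idx in range(5):
        inf[idx] = 0.0
        tau[idx] = -1.0

    # --- gating variables -------------------------------------------------
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    inf[5] = m_inf
    tau[5] = am * bm

    h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V < -40.0:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    inf[6] = h_inf
    tau[6] = 1.0 / (ah + bh)

    if V < -40.0:
        aj = (-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V)) \
            * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23)))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    else:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    inf[7] = h_inf
    tau[7] = 1.0 / (aj + bj)

    d_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    inf[8] = d_inf
    tau[8] = ad * bd + gd

    inf[9] = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau[9] = 1125.0 * np.exp(-(V + 27.0) * (V + 27.0) / 240.0) + 80.0 \
        + 165.0 / (1.0 + np.exp((25.0 - V) / 10.0))

    afca = 1.0 / (1.0 + (Cai / 0.000325) ** 8)
    bfca = 0.1 / (1.0 + np.exp((Cai - 0.0005) / 0.0001))
    gfca = 0.2 / (1.0 + np.exp((Cai - 0.00075) / 0.0008))
    fca_inf = (afca + bfca + gfca + 0.23) / 1.46
    inf[10] = fca_inf
    if fca_inf > fCa and V > -60.0:
        tau[10] = 1.0e18   # held: no re-activation while depolarised
    else:
        tau[10] = 2.0

    inf[11] = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau[11] = 9.5 * np.exp(-(V + 40.0) * (V + 40.0) / 1800.0) + 0.8

    inf[12] = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
    tau[12] = 85.0 * np.exp(-(V + 45.0) * (V + 45.0) / 320.0) \
        + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0

    inf[13] = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    tau[13] = axr1 * bxr1

    inf[14] = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    tau[14] = axr2 * bxr2

    inf[15] = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1100.0 / np.sqrt(1.0 + np.exp((-10.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 60.0) / 20.0))
    tau[15] = axs * bxs

    if Cai < 0.00035:
        g_inf = 1.0 / (1.0 + (Cai / 0.00035) ** 6)
    else:
        g_inf = 1.0 / (1.0 + (Cai / 0.00035) ** 16)
    inf[16] = g_inf
    if g_inf > g and V > -60.0:
        tau[16] = 1.0e18
    else:
        tau[16] = 2.0

    for idx in range(5, 17):
        if tau[idx] > 1.0e17:
            dy[idx] = 0.0
        else:
            dy[idx] = (inf[idx] - y[idx]) / tau[idx]


integrate = make_integrator(rates, N_STATE, CAI_IDX)
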