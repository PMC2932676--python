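"""Luo-Rudy 1991 ("phase 1", LR1) guinea-pig ventricular myocyte model.

Eight states: membrane voltage V (mV), intracellular Ca2+ (mM), and six
Hodgkin-Huxley gates.  Six scalable maximal conductances (mS/cm^2 on a
1 uF/cm^2 membrane, so numerically equal to pA/pF per mV): fast Na+
current, slow inward (Ca2+) current, time-dependent K+ current,
inward-rectifier K+ current, plateau K+ current, and a linear background
current.  The K+ conductances scale with sqrt([K+]o / 5.4) and the K+
reversal potentials follow Nernst, so extracellular potassium is an
experimental input.
"""

import numpy as np
from numba import njit

from .._engine import make_integrator

MODEL_ID = "lr1"
STATE_NAMES = ("V", "Cai", "m", "h", "j", "d", "f", "X")
PARAM_NAMES = ("G_Na", "G_si", "G_K", "G_K1", "G_Kp", "G_b")
BASELINE = np.array([23.0, 0.09, 0.282, 0.6047, 0.0183, 0.03921])
N_STATE = 8
CAI_IDX = 1
V_IDX = 0
GATES = (2, 3, 4, 5, 6, 7)
KO_DEFAULT = 5.4

# fixed intracellular/extracellular concentrations (mM)
NAI, NAO, KI = 18.0, 140.0, 145.0
RT_F = 8314.472 * 310.15 / 96485.3415  # ~26.73 mV

INITIAL_STATE = np.array([
    -84.38,      # V
    1.78e-4,     # Cai
    1.67e-3,     # m
    0.9832,      # h
    0.9895,      # j
    3.0e-6,      # d
    1.0,         # f
    5.7e-3,      # X
])


@njit(cache=True)
def rates(y, p, Ko, stim, dy, inf, tau):
    V = y[0]
    Cai = y[1]
    m = y[2]
    h = y[3]
    j = y[4]
    d = y[5]
    f = y[6]
    X = y[7]

    E_Na = 54.4
    E_K = RT_F * np.log((Ko + 0.01833 * NAO) / (KI + 0.01833 * NAI))
    E_K1 = RT_F * np.log(Ko / KI)
    if Cai < 1e-10:
        Cai_safe = 1e-10
    else:
        Cai_safe = Cai
    E_si = 7.7 - 13.0287 * np.log(Cai_safe)

    gK = p[2] * np.sqrt(Ko / 5.4)
    gK1 = p[3] * np.sqrt(Ko / 5.4)

    INa = p[0] * m * m * m * h * j * (V - E_Na)
    Isi = p[1] * d * f * (V - E_si)

    # time-dependent K+ current with inward-rectification factor Xi
    if V > -100.0:
        num = V + 77.0
        if abs(num) < 1e-6:
            Xi = 2.837 * 0.04 / np.exp(0.04 * (V + 35.0))
        else:
            Xi = 2.837 * (np.exp(0.04 * (V + 77.0)) - 1.0) / (num * np.exp(0.04 * (V + 35.0)))
    else:
        Xi = 1.0
    IK = gK * X * Xi * (V - E_K)

    aK1 = 1.02 / (1.0 + np.exp(0.2385 * (V - E_K1 - 59.215)))
    bK1 = (0.49124 * np.exp(0.08032 * (V - E_K1 + 5.476))
           + np.exp(0.06175 * (V - E_K1 - 594.31))) / (1.0 + np.exp(-0.5143 * (V - E_K1 + 4.753)))
    IK1 = gK1 * aK1 / (aK1 + bK1) * (V - E_K1)

    Kp = 1.0 / (1.0 + np.exp((7.488 - V) / 5.98))
    IKp = p[4] * Kp * (V - E_K1)
    Ib = p[5] * (V + 59.87)

    dy[0] = -(INa + Isi + IK + IK1 + IKp + Ib) + stim
    dy[1] = -1.0e-4 * Isi + 0.07 * (1.0e-4 - Cai)
    inf[0] = 0.0
    tau[0] = -1.0
    inf[1] = 0.0
    tau[1] = -1.0

    # m gate
    num = V + 47.13
    if abs(num) < 1e-6:
        am = 3.2
    else:
        am = 0.32 * num / (1.0 - np.exp(-0.1 * num))
    bm = 0.08 * np.exp(-V / 11.0)
    # h, j gates
    if V < -40.0:
        ah = 0.135 * np.exp((80.0 + V) / -6.8)
        bh = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
        aj = (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V)) \
            * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23)))
        bj = 0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    else:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp((V + 10.66) / -11.1)))
        aj = 0.0
        bj = 0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    # d, f gates
    ad = 0.095 * np.exp(-0.01 * (V - 5.0)) / (1.0 + np.exp(-0.072 * (V - 5.0)))
    bd = 0.07 * np.exp(-0.017 * (V + 44.0)) / (1.0 + np.exp(0.05 * (V + 44.0)))
    af = 0.012 * np.exp(-0.008 * (V + 28.0)) / (1.0 + np.exp(0.15 * (V + 28.0)))
    bf = 0.0065 * np.exp(-0.02 * (V + 30.0)) / (1.0 + np.exp(-0.2 * (V + 30.0)))
    # X gate
    aX = 0.0005 * np.exp(0.083 * (V + 50.0)) / (1.0 + np.exp(0.057 * (V + 50.0)))
    bX = 0.0013 * np.exp(-0.06 * (V + 20.0)) / (1.0 + np.exp(-0.04 * (V + 20.0)))

    tau[2] = 1.0 / (am + bm)
    inf[2] = am * tau[2]
    tau[3] = 1.0 / (ah + bh)
    inf[3] = ah * tau[3]
    tau[4] = 1.0 / (aj + bj)
    inf[4] = aj * tau[4]
    tau[5] = 1.0 / (ad + bd)
    inf[5] = ad * tau[5]
    tau[6] = 1.0 / (af + bf)
    inf[6] = af * tau[6]
    tau[7] = 1.0 / (aX + bX)
    inf[7] = aX * tau[7]
    for idx in range(2, 8):
        dy[idx] = (inf[idx] - y[idx]) / tau[idx]


integrate = make_integrator(rates, N_STATE, CAI_IDX)
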