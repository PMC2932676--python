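"""Reduced six-variable human ventricular myocyte model (Bernus-type).

Follows the current roster and state reduction of the Bernus et al.
(2002) efficient human ventricular model, itself a reduction of the
Priebe-Beuckelmann model: a fast Na+ current with a single combined
slow-inactivation gate v, an L-type Ca2+ current with instantaneous
activation, the transient outward current, a delayed-rectifier and an
inward-rectifier K+ current, Na+/K+ pump and Na+/Ca2+ exchanger, and a
linear background current.  Intracellular concentrations are fixed
(Nai = 10, Ki = 140, Cai = 0.0004 mM), so the model carries no Ca2+
transient.  The exact refitted rate expressions of the source
publication are not reproduced here; gating kinetics are adapted from
the Luo-Rudy and ten Tusscher formulations and tuned once to the
published action-potential characteristics (resting potential near
-90 mV, APD90 near 285 ms at 1 Hz pacing, [K+]o = 4 mM default).

Eight scalable parameters: G_Na, G_Ca, G_to, G_K, G_K1, K_NaK, K_NCX,
G_b (nS/pF, pump/exchanger scales in pA/pF).
"""

import numpy as np
from numba import njit

from .._engine import make_integrator

MODEL_ID = "bernus"
STATE_NAMES = ("V", "m", "v", "f", "to", "X")
PARAM_NAMES = ("G_Na", "G_Ca", "G_to", "G_K", "G_K1", "K_NaK", "K_NCX", "G_b")
BASELINE = np.array([16.0, 0.064, 0.4, 0.15, 8.0, 1.3, 1000.0, 0.01])
N_STATE = 6
CAI_IDX = -1
V_IDX = 0
GATES = (1, 2, 3, 4, 5)
KO_DEFAULT = 4.0

NAI, NAO, KI, CAI, CAO = 10.0, 138.0, 140.0, 4.0e-4, 2.0
RT_F = 8314.472 * 310.0 / 96485.3415

INITIAL_STATE = np.array([
    -90.3,     # V
    2.0e-3,    # m
    0.99,      # v
    1.0,       # f
    1.0,       # to
    6.0e-3,    # X
])


@njit(cache=True)
def rates(y, p, Ko, stim, dy, inf, tau):
    V = y[0]
    m = y[1]
    v = y[2]
    f = y[3]
    to = y[4]
    X = y[5]

    E_Na = RT_F * np.log(NAO / NAI)
    E_K = RT_F * np.log(Ko / KI)
    E_Ca = 0.5 * RT_F * np.log(CAO / CAI)
    E_to = RT_F * np.log((Ko + 0.043 * NAO) / (KI + 0.043 * NAI))

    INa = p[0] * m * m * m * v * v * (V - E_Na)

    d_inf = 1.0 / (1.0 + np.exp(-(V + 6.6) / 6.6))
    fCa = 0.6  # Km/(Km + Cai) with fixed Cai
    ICa = p[1] * d_inf * f * fCa * (V - E_Ca)

    r_inf = 1.0 / (1.0 + np.exp((19.0 - V) / 13.0))
    Ito = p[2] * r_inf * to * (V - E_to)

    IK = p[3] * X * X * (V - E_K)

    aK1 = 0.1 / (1.0 + np.exp(0.06 * (V - E_K - 200.0)))
    bK1 = (3.0 * np.exp(0.0002 * (V - E_K + 100.0)) + np.exp(0.1 * (V - E_K - 10.0))) \
        / (1.0 + np.exp(-0.5 * (V - E_K)))
    IK1 = p[4] * np.sqrt(Ko / 4.0) * aK1 / (aK1 + bK1) * (V - E_K)

    INaK = p[5] * (Ko / (Ko + 1.5)) * (NAI ** 1.5 / (NAI ** 1.5 + 10.0 ** 1.5)) \
        / (1.0 + 0.1245 * np.exp(-0.1 * V / RT_F) + 0.0353 * np.exp(-V / RT_F))

    e1 = np.exp(0.35 * V / RT_F)
    e2 = np.exp(-0.65 * V / RT_F)
    INaCa = p[6] * (e1 * NAI ** 3 * CAO - e2 * NAO ** 3 * CAI * 2.5) \
        / ((87.5 ** 3 + NAO ** 3) * (1.38 + CAO) * (1.0 + 0.1 * e2))

    Ib = p[7] * (V + 59.87)

    dy[0] = -(INa + ICa + Ito + IK + IK1 + INaK + INaCa + Ib) + stim
    inf[0] = 0.0
    tau[0] = -1.0

    # m gate (Luo-Rudy kinetics)
    num = V + 47.13
    if abs(num) < 1e-6:
        am = 3.2
    else:
        am = 0.32 * num / (1.0 - np.exp(-0.1 * num))
    bm = 0.08 * np.exp(-V / 11.0)
    tau[1] = 1.0 / (am + bm)
    inf[1] = am * tau[1]

    # combined slow inactivation gate v
    inf[2] = 1.0 / (1.0 + np.exp((V + 75.6) / 6.0))
    tau[2] = 3.7 + 96.0 * np.exp(-((V + 75.0) / 15.0) ** 2)

    # L-type inactivation f
    inf[3] = 1.0 / (1.0 + np.exp((V + 25.0) / 6.0))
    tau[3] = 250.0 + 900.0 * np.exp(-((V + 30.0) / 35.0) ** 2)

    # transient-outward inactivation
    inf[4] = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
    tau[4] = 5.0 + 25.0 * np.exp(-((V + 30.0) / 40.0) ** 2)

    # delayed rectifier activation
    inf[5] = 1.0 / (1.0 + np.exp(-(V - 5.0) / 17.0))
    tau[5] = 600.0 + 900.0 * np.exp(-((V + 30.0) / 40.0) ** 2)

    for idx in range(1, 6):
        dy[idx] = (inf[idx] - y[idx]) / tau[idx]


integrate = make_integrator(rates, N_STATE, CAI_IDX)
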