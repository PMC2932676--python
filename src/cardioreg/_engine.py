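"""Adaptive Rush-Larsen integration engine shared by all cell models.

Hodgkin-Huxley gating variables are advanced with the exact exponential
(Rush-Larsen) update, which is unconditionally stable and keeps gates in
[0, 1] whenever their steady-state values are.  Membrane voltage and ion
concentrations are advanced with forward Euler.  The step size is adapted
so that the projected per-step change in voltage (and, where present,
intracellular Ca2+) stays below a configured bound; this resolves the
~1 ms upstroke at sub-microsecond resolution while taking millisecond
steps in diastole and multi-millisecond steps during quiescence.

Each model module builds its integrator once via :func:`make_integrator`,
passing its numba-compiled ``rates`` kernel.  The kernel contract is::

    rates(y, params, Ko, stim, dy, inf, tau)

filling ``dy`` (time derivatives for every state), and, for gating
variables, their steady state ``inf`` and time constant ``tau`` (ms).
Non-gate states are marked with ``tau <= 0``; a gate that is being held
(e.g. the Ca-dependent inactivation clamp in the ten Tusscher model)
signals this with a very large ``tau`` and ``dy = 0``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: default step-control settings (ms, mV, mM)
DT_MIN = 0.002
DT_MAX = 2.0
DV_MAX = 0.15
DCA_MAX = 6.0e-6
DT_SAMPLE = 0.5


def make_integrator(rates, n_state: int, cai_idx: int):
    """Compile an integrator specialised for one model's rate kernel."""

    @njit(fastmath=False)
    def integrate(y0, params, Ko, t_end, onsets, stim_dur, stim_amp,
                  dt_sample, dt_min, dt_max, dv_max, dca_max):
        n_samp = int(np.floor(t_end / dt_sample + 1e-9)) + 1
        T = np.empty(n_samp)
        S = np.empty((n_samp, n_state))
        DVDT = np.zeros(n_samp)

        y = y0.copy()
        y_old = np.empty(n_state)
        dy = np.empty(n_state)
        inf = np.empty(n_state)
        tau = np.empty(n_state)

        T[0] = 0.0
        S[0, :] = y
        k = 1
        t = 0.0
        si = 0
        n_on = onsets.shape[0]
        dvdt_acc = 0.0
        status = 0

        while k < n_samp and t < t_end - 1e-9:
            # stimulus bookkeeping: si points at the first onset whose
            # window has not yet closed
            while si < n_on and t >= onsets[si] + stim_dur - 1e-9:
                si += 1
            stim = 0.0
            t_event = t_end
            if si < n_on:
                if t >= onsets[si] - 1e-9:
                    stim = stim_amp
                    t_event = onsets[si] + stim_dur
                else:
                    t_event = onsets[si]

            rates(y, params, Ko, stim, dy, inf, tau)

            # proportional step control on projected dV and dCa
            h = dt_max
            av = abs(dy[0])
            if av > 0.0:
                h = 0.8 * dv_max / av
            if cai_idx >= 0:
                ac = abs(dy[cai_idx])
                if ac > 0.0:
                    hc = 0.8 * dca_max / ac
                    if hc < h:
                        h = hc
            if h > dt_max:
                h = dt_max
            if h < dt_min:
                h = dt_min
            if t + h > t_event - 1e-12:
                h = t_event - t
                if h <= 0.0:
                    h = 1e-9
            if t + h > t_end:
                h = t_end - t

            for jj in range(n_state):
                y_old[jj] = y[jj]
            for jj in range(n_state):
                if tau[jj] > 0.0:
                    y[jj] = inf[jj] + (y_old[jj] - inf[jj]) * np.exp(-h / tau[jj])
                else:
                    y[jj] = y_old[jj] + h * dy[jj]
            t_new = t + h

            if not np.isfinite(y[0]):
                status = 1
                break

            r = (y[0] - y_old[0]) / h
            if r > dvdt_acc:
                dvdt_acc = r

            # emit samples that fall inside (t, t_new]
            while k < n_samp:
                ts = k * dt_sample
                if ts > t_new + 1e-9:
                    break
                w = (ts - t) / h
                for jj in range(n_state):
                    S[k, jj] = y_old[jj] + w * (y[jj] - y_old[jj])
                T[k] = ts
                DVDT[k] = dvdt_acc
                dvdt_acc = 0.0
                k += 1
            t = t_new

        return T[:k], S[:k], DVDT[:k], y, status

    return integrate
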