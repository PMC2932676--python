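"""Extraction of physiological outputs from simulated traces.

The regression pipeline summarises every trial by a fixed vector of
physiological outputs: action-potential morphology (duration, resting
and peak voltage, maximal upstroke velocity, spike-and-dome shape
parameters), Ca2+ transient amplitude and kinetics, and the outputs of
the rate-change and potassium-change protocols.  All extraction is
pure: the same trace always yields the same features.

Missing values (failed beats, undetectable features) are represented by
a mask rather than NaN poisoning: downstream the masked entries are
mean-imputed in Z-space, which keeps the trial count fixed while
contributing no signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "OutputVector",
    "action_potential_features",
    "calcium_features",
    "assemble_output_vector",
    "TNNP_OUTPUT_NAMES",
]

#: Canonical output roster for the full human-ventricular (tnnp) suite,
#: in fixed order.  Units: ms for durations/times, mV for voltages,
#: mV/ms for upstroke velocity, uM for Ca transient amplitudes, pA/pF
#: for the stimulation threshold, mM for the quiescent concentrations;
#: the restitution slope and frequency adaptation are dimensionless.
TNNP_OUTPUT_NAMES = (
    "APD", "V_rest", "V_peak", "dVdt_max", "dCa",
    "V_maxmin", "V_minmax", "t_minmax",
    "BCL_alt", "I_thresh", "Maxslope",
    "Ca_ttp", "Ca_decay",
    "APD_pause", "dCa_pause",
    "V_maxmin_pause", "V_minmax_pause", "t_minmax_pause",
    "APD_diff", "dCa_diff",
    "APD_hypo", "APD_hyper",
    "V_maxmin_hypo", "V_minmax_hypo", "t_minmax_hypo",
    "V_maxmin_hyper", "V_minmax_hyper", "t_minmax_hyper",
    "Ca_quiesc", "Na_quiesc", "K_quiesc",
    "Freq_adapt",
)


@dataclass
class OutputVector:
    """Ordered output values with an explicit missing-value mask."""

    names: tuple[str, ...]
    values: np.ndarray
    mask: np.ndarray  # True where the output is missing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.names) == self.values.size == self.mask.size):
            raise ValueError("names, values and mask must have equal length")
        bad = ~self.mask & ~np.isfinite(self.values)
        if np.any(bad):
            raise ValueError(
                f"non-finite unmasked outputs: "
                f"{[self.names[i] for i in np.nonzero(bad)[0]]}")

    def __len__(self):
        return self.values.size

    def as_dict(self):
        return {n: (None if m else v)
                for n, v, m in zip(self.names, self.values, self.mask)}


def assemble_output_vector(names, entries: dict) -> OutputVector:
    """Build an :class:`OutputVector` from a name -> value mapping.

    Every name must be present in ``entries`` (``None`` or NaN marks a
    masked output); a missing key raises, so a protocol that silently
    never ran cannot produce a half-filled vector.
    """
    values = np.empty(len(names))
    mask = np.zeros(len(names), dtype=bool)
    for i, n in enumerate(names):
        if n not in entries:
            raise KeyError(f"output {n!r} was never recorded")
        v = entries[n]
        if v is None or not np.isfinite(v):
            values[i] = np.nan
            mask[i] = True
        else:
            values[i] = float(v)
    return OutputVector(tuple(names), values, mask)


def _beat_window(trace, beat_index):
    onsets = trace.beat_boundaries
    if not 0 <= beat_index < len(onsets):
        raise IndexError(f"beat {beat_index} out of range")
    i0 = onsets[beat_index]
    i1 = onsets[beat_index + 1] if beat_index + 1 < len(onsets) else len(trace.time)
    return i0, i1


def _interp_crossing(t0, v0, t1, v1, level):
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def _smooth(x, w):
    if w <= 1:
        return x
    k = np.ones(w) / w
    return np.convolve(x, k, mode="same")


def _refine_extremum(t, v, i):
    """Parabolic (three-point) refinement of an extremum at sample i."""
    if i <= 0 or i >= len(v) - 1:
        return float(t[i]), float(v[i])
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i]), float(v[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    dt = t[i + 1] - t[i]
    v_ref = y1 - 0.25 * (y0 - y2) * delta
    return float(t[i] + delta * dt), float(v_ref)


def _voltage_at_offset(t, v, t_ref, offset):
    """Linear interpolation of V at ``t_ref + offset`` (absolute ms)."""
    return float(np.interp(t_ref + offset, t, v))


def action_potential_features(trace, beat_index, repol_fraction=0.9,
                              capture_level=0.0, smooth_ms=1.0):
    """AP morphology features of one beat.

    Returns a dict with APD (at ``repol_fraction`` repolarisation toward
    the pre-stimulus diastolic voltage), V_rest, V_peak, dVdt_max, the
    spike-and-dome shape parameters (V_maxmin = phase-1 notch trough,
    V_minmax = dome, t_minmax = dome time minus upstroke time) and the
    bookkeeping fields ``captured``, ``shape_fallback``, ``t_up`` and
    ``t_end`` (absolute upstroke / repolarisation times).  A beat with
    no action potential returns ``captured=False`` and all features
    ``None``.
    """
    i0, i1 = _beat_window(trace, beat_index)
    t = trace.time[i0:i1]
    v = trace.voltage[i0:i1]
    dvdt = trace.dvdt[i0:i1]
    none = dict.fromkeys(
        ("APD", "APD50", "V_rest", "V_peak", "dVdt_max", "V_maxmin",
         "V_minmax", "t_minmax", "V_plus50", "V_plus100", "t_up", "t_end"))
    if len(t) < 5 or v.max() < capture_level:
        return {**none, "captured": False, "shape_fallback": False}

    v_rest = v[0]
    iup = int(np.argmax(dvdt))
    t_up = t[iup]
    dvdt_max = float(dvdt[iup])

    # phase-0 peak: maximum within 30 ms of the upstroke
    ipk_hi = int(np.searchsorted(t, t_up + 30.0))
    ipk = iup + int(np.argmax(v[iup:max(ipk_hi, iup + 2)]))
    v_peak = float(v[ipk])  # no sub-sample refinement: phase-0 peak is a cusp

    level = v_peak - repol_fraction * (v_peak - v_rest)
    above = v >= level
    above[:ipk] = False
    idx = np.nonzero(above)[0]
    if len(idx) == 0 or idx[-1] == len(v) - 1:
        # never repolarised inside the window
        return {**none, "V_rest": float(v_rest), "V_peak": v_peak,
                "dVdt_max": dvdt_max, "t_up": float(t_up),
                "captured": True, "shape_fallback": False}
    iend = idx[-1]
    t_end = _interp_crossing(t[iend], v[iend], t[iend + 1], v[iend + 1], level)
    apd = float(t_end - t_up)

    # 50% repolarisation (APD50 <= APD90 on any physiological AP)
    lvl50 = v_peak - 0.5 * (v_peak - v_rest)
    above50 = v >= lvl50
    above50[:ipk] = False
    idx50 = np.nonzero(above50)[0]
    apd50 = None
    if len(idx50) and idx50[-1] < len(v) - 1:
        i50 = idx50[-1]
        t50 = _interp_crossing(t[i50], v[i50], t[i50 + 1], v[i50 + 1], lvl50)
        apd50 = float(t50 - t_up)

    v_plus50 = _voltage_at_offset(t, v, t_up, 50.0)
    v_plus100 = _voltage_at_offset(t, v, t_up, 100.0)

    # notch / dome detection on a lightly smoothed trace
    dt = t[1] - t[0]
    w = max(int(round(smooth_ms / dt)), 1)
    vs = _smooth(v, w)
    sl = np.diff(vs[ipk:iend + 1])
    fallback = True
    v_maxmin = v_minmax = t_minmax = None
    sign = np.sign(sl)
    flips = np.nonzero(np.diff(sign) != 0)[0]
    if len(flips) >= 2:
        # first minimum then subsequent maximum
        i_notch = None
        for fidx in flips:
            if sign[fidx] < 0 <= sign[fidx + 1]:
                i_notch = ipk + fidx + 1
                break
        if i_notch is not None:
            rest_flips = flips[flips > i_notch - ipk]
            for fidx in rest_flips:
                if sign[fidx] > 0 >= sign[fidx + 1]:
                    i_dome = ipk + fidx + 1
                    _, v_maxmin = _refine_extremum(t, v, i_notch)
                    t_dome, v_minmax = _refine_extremum(t, v, i_dome)
                    t_minmax = float(t_dome - t_up)
                    fallback = False
                    break
    if fallback:
        # no notch/dome: sample fixed post-upstroke offsets instead
        j20 = min(int(np.searchsorted(t, t_up + 20.0)), len(v) - 1)
        j50 = min(int(np.searchsorted(t, t_up + 50.0)), len(v) - 1)
        v_maxmin = float(v[j20])
        v_minmax = float(v[j50])
        t_minmax = 50.0

    return {
        "APD": apd, "APD50": apd50, "V_rest": float(v_rest),
        "V_peak": v_peak, "dVdt_max": dvdt_max, "V_maxmin": v_maxmin,
        "V_minmax": v_minmax, "t_minmax": t_minmax,
        "V_plus50": v_plus50, "V_plus100": v_plus100,
        "t_up": float(t_up), "t_end": float(t_end),
        "captured": True, "shape_fallback": fallback,
    }


def calcium_features(trace, beat_index, decay_lag=20.0):
    """Ca2+ transient amplitude and kinetics of one beat.

    dCa = peak [Ca]i minus the pre-stimulus diastolic level (trace
    units), time-to-peak from stimulus onset (ms), and the time constant
    (ms) of a single-exponential fit from ``decay_lag`` ms after the
    peak to the end of the beat.  Degenerate transients (no [Ca]i
    signal, peak at the window start) are masked.
    """
    none = {"dCa": None, "Ca_ttp": None, "Ca_decay": None, "Ca_dia": None}
    if trace.Cai is None:
        return none
    i0, i1 = _beat_window(trace, beat_index)
    t = trace.time[i0:i1]
    ca = trace.Cai[i0:i1]
    if len(t) < 10:
        return none
    dia = float(ca[0])
    ipk = int(np.argmax(ca))
    if ipk == 0:
        return {**none, "Ca_dia": dia}
    t_pk, ca_pk = _refine_extremum(t, ca, ipk)
    amp = float(ca_pk - dia)
    ttp = float(t_pk - t[0])
    out = {"dCa": amp, "Ca_ttp": ttp, "Ca_decay": None, "Ca_dia": dia}
    if amp <= 0:
        return {"dCa": amp if amp == 0 else None, "Ca_ttp": None,
                "Ca_decay": None, "Ca_dia": dia}
    j0 = int(np.searchsorted(t, t[ipk] + decay_lag))
    if len(t) - j0 < 10:
        return out
    ts = t[j0:] - t[j0]
    cs = ca[j0:]

    def model(x, c_inf, a, tau):
        return c_inf + a * np.exp(-np.clip(x / tau, -50.0, 50.0))

    try:
        p0 = (float(cs[-1]), float(cs[0] - cs[-1]), max(ts[-1] / 3.0, 1.0))
        popt, _ = curve_fit(model, ts, cs, p0=p0, maxfev=2000)
        tau = float(popt[2])
        if 0 < tau < 10 * ts[-1]:
            out["Ca_decay"] = tau
    except RuntimeError:
        pass
    return out
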