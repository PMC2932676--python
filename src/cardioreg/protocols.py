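"""Stimulation protocols and iterative threshold searches.

Every protocol reduces to a list of stimulus onset times handed to the
model's integrator, so paced trains, pauses, quiescence and S1S2
restitution share a single simulation path.  The searches (stimulation
threshold by bisection, alternans threshold by a descending cycle-length
scan, restitution slope from an S1S2 curve) are split into pure cores
operating on callables/arrays — testable against analytic surrogates —
and thin model-facing wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models
from .features import action_potential_features

__all__ = [
    "ProtocolSpec",
    "Trace",
    "TrialFailure",
    "run_protocol",
    "find_stimulation_threshold",
    "find_alternans_threshold",
    "restitution_max_slope",
    "bisect_threshold",
    "scan_alternans",
    "detect_alternans",
    "max_centered_slope",
]


class TrialFailure(RuntimeError):
    """Solver failure or loss of a required feature within one trial."""

    def __init__(self, message, context=None):
        super().__init__(message)
        self.context = context or {}


@dataclass(frozen=True)
class ProtocolSpec:
    """Configuration of one stimulation protocol.

    ``protocol_id`` is one of ``paced``, ``pause`` or ``quiescence``
    (the scans and searches take their own grid arguments).  ``Ko`` of
    ``None`` means the model's default extracellular potassium.
    """

    protocol_id: str = "paced"
    bcl: float = 1000.0
    n_beats: int = 100
    stim_amplitude: float = 52.0
    stim_duration: float = 1.0
    Ko: float | None = None
    pause_duration: float = 5000.0
    quiescence_duration: float = 60000.0
    tail: float | None = None
    dt_sample: float = 0.5
    dt_min: float = 0.002
    dt_max: float = 2.0
    dv_max: float = 0.15
    dca_max: float = 6.0e-6

    def __post_init__(self):
        if self.protocol_id not in ("paced", "pause", "quiescence"):
            raise ValueError(f"unknown protocol {self.protocol_id!r}")
        if not (self.bcl > self.stim_duration > 0):
            raise ValueError("need bcl > stim_duration > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.Ko is not None and self.Ko <= 0:
            raise ValueError("Ko must be positive")


@dataclass
class Trace:
    """Sampled waveforms of one protocol run."""

    model_id: str
    time: np.ndarray          # ms, monotone
    voltage: np.ndarray       # mV
    Cai: np.ndarray | None    # mM (model units); None if not dynamic
    Nai: np.ndarray | None
    Ki: np.ndarray | None
    stim: np.ndarray          # pA/pF
    dvdt: np.ndarray          # max dV/dt within each sample interval
    beat_onset_times: np.ndarray
    beat_boundaries: np.ndarray  # sample indices of stimulus onsets
    final_state: np.ndarray

    def __post_init__(self):
        n = len(self.time)
        for arr in (self.voltage, self.stim, self.dvdt):
            if len(arr) != n:
                raise ValueError("trace arrays must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        bb = self.beat_boundaries
        if len(bb) and (np.any(np.diff(bb) <= 0) or bb[0] < 0 or bb[-1] >= n):
            raise ValueError("beat boundaries must be strictly increasing and in range")

    @property
    def n_beats(self):
        return len(self.beat_boundaries)

    def to_hdf5(self, path):
        """Archive the trace to an HDF5 file (datasets time/voltage/
        Cai/Nai/Ki/stim plus beat onsets and the final state)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["model_id"] = self.model_id
            for name in ("time", "voltage", "Cai", "Nai", "Ki", "stim",
                         "dvdt"):
                arr = getattr(self, name)
                if arr is not None:
                    f.create_dataset(name, data=arr)
            f.create_dataset("beat_onset_times", data=self.beat_onset_times)
            f.create_dataset("beat_boundaries", data=self.beat_boundaries)
            f.create_dataset("final_state", data=self.final_state)

    @classmethod
    def from_hdf5(cls, path):
        import h5py

        with h5py.File(path, "r") as f:
            def get(name):
                return f[name][...] if name in f else None

            return cls(model_id=str(f.attrs["model_id"]),
                       time=f["time"][...], voltage=f["voltage"][...],
                       Cai=get("Cai"), Nai=get("Nai"), Ki=get("Ki"),
                       stim=f["stim"][...], dvdt=f["dvdt"][...],
                       beat_onset_times=f["beat_onset_times"][...],
                       beat_boundaries=f["beat_boundaries"][...],
                       final_state=f["final_state"][...])


def _stimulus_onsets(spec: ProtocolSpec) -> tuple[np.ndarray, float]:
    if spec.protocol_id == "paced":
        onsets = np.arange(spec.n_beats) * spec.bcl
    elif spec.protocol_id == "pause":
        train = np.arange(spec.n_beats) * spec.bcl
        post = train[-1] + spec.pause_duration
        onsets = np.append(train, post)
    else:  # quiescence
        onsets = np.zeros(0)
    tail = spec.tail
    if tail is None:
        tail = spec.bcl if spec.protocol_id != "quiescence" else 0.0
    if spec.protocol_id == "quiescence":
        t_end = spec.quiescence_duration + tail
    else:
        t_end = onsets[-1] + tail
    return onsets, t_end


def run_protocol(model_id: str, params: models.ParameterSet,
                 spec: ProtocolSpec, initial_state=None) -> Trace:
    """Run one stimulation protocol and return the sampled trace."""
    mspec = models.get_model(model_id)
    if initial_state is None:
        initial_state = mspec.initial_state
    Ko = spec.Ko if spec.Ko is not None else mspec.Ko_default
    onsets, t_end = _stimulus_onsets(spec)
    T, S, DVDT, y_final, status = models._integrate(
        model_id, initial_state, params, Ko, t_end, onsets,
        spec.stim_duration, spec.stim_amplitude, spec.dt_sample,
        spec.dt_min, spec.dt_max, spec.dv_max, spec.dca_max)
    if status != 0 or not np.all(np.isfinite(S)):
        raise TrialFailure(
            f"integration failed (status={status})",
            context={"model_id": model_id, "protocol": spec.protocol_id})
    stim = np.zeros_like(T)
    for on in onsets:
        stim[(T >= on) & (T < on + spec.stim_duration)] = spec.stim_amplitude
    bb = np.searchsorted(T, onsets).astype(int)

    def col(idx):
        return S[:, idx].copy() if idx >= 0 else None

    return Trace(
        model_id=model_id, time=T, voltage=S[:, 0].copy(),
        Cai=col(mspec.cai_index), Nai=col(mspec.nai_index),
        Ki=col(mspec.ki_index), stim=stim, dvdt=DVDT,
        beat_onset_times=onsets, beat_boundaries=bb, final_state=y_final)


# --------------------------------------------------------------------------
# stimulation threshold
# --------------------------------------------------------------------------

def bisect_threshold(probe, lo: float, hi: float, tol: float = 0.1,
                     audit: list | None = None) -> float:
    """Bisect the firing threshold of a monotone ``probe(amplitude)``.

    ``probe`` returns True when the amplitude elicits a response.  The
    brackets must be valid: ``probe(lo)`` False and ``probe(hi)`` True.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    if probe(lo):
        raise ValueError("AP elicited at the lower bracket")
    if not probe(hi):
        raise ValueError("upper bound subthreshold")
    if audit is not None:
        audit.extend([(lo, False), (hi, True)])
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fired = probe(mid)
        if audit is not None:
            audit.append((mid, fired))
        if fired:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def find_stimulation_threshold(model_id: str, params: models.ParameterSet,
                               lo: float = 2.0, hi: float = 80.0,
                               tol: float = 0.1, initial_state=None,
                               Ko: float | None = None,
                               stim_duration: float = 1.0,
                               capture_window: float = 50.0,
                               audit: list | None = None) -> float:
    """Stimulation threshold (pA/pF) by bisection.

    A stimulus captures when voltage crosses 0 mV within
    ``capture_window`` ms of its onset.
    """
    mspec = models.get_model(model_id)
    state = mspec.initial_state if initial_state is None else np.asarray(initial_state)
    Ko_val = Ko if Ko is not None else mspec.Ko_default
    t_on = 5.0
    t_end = t_on + capture_window + 10.0

    def probe(amp):
        T, S, _, _, status = models._integrate(
            model_id, state, params, Ko_val, t_end, np.array([t_on]),
            stim_duration, amp, 0.5, 0.002, 2.0, 0.15, 6e-6)
        if status != 0:
            raise TrialFailure("integration failed during threshold probe")
        win = (T >= t_on) & (T <= t_on + capture_window)
        return bool(np.max(S[win, 0]) >= 0.0)

    return bisect_threshold(probe, lo, hi, tol, audit=audit)


# --------------------------------------------------------------------------
# alternans threshold
# --------------------------------------------------------------------------

def detect_alternans(apds, threshold: float = 1.0, n_final: int = 4) -> bool:
    """True if the final ``n_final`` APDs show a sustained long-short
    alternation with beat-to-beat differences above ``threshold`` ms."""
    a = np.asarray(apds, dtype=float)[-n_final:]
    if len(a) < n_final or np.any(~np.isfinite(a)):
        return False
    d = np.diff(a)
    if np.any(np.abs(d) <= threshold):
        return False
    return bool(np.all(d[:-1] * d[1:] < 0))


def scan_alternans(run_beats, bcl_max: float = 350.0, bcl_min: float = 150.0,
                   step: float = 5.0, threshold: float = 1.0,
                   n_final: int = 4, audit: list | None = None) -> float:
    """Descending cycle-length scan for the alternans threshold.

    ``run_beats(bcl)`` returns the APD sequence at that cycle length
    (NaN entries mark lost capture).  Returns the largest scanned BCL at
    which alternans is detected, or the sentinel ``bcl_min - step`` if
    alternans never appears before the scan ends or capture is lost.
    """
    sentinel = bcl_min - step
    for bcl in np.arange(bcl_max, bcl_min - step / 2, -step):
        apds = np.asarray(run_beats(bcl), dtype=float)
        captured = np.all(np.isfinite(apds[-n_final:]))
        alternans = detect_alternans(apds, threshold, n_final) if captured else False
        if audit is not None:
            audit.append((float(bcl), bool(captured), bool(alternans)))
        if not captured:
            return sentinel
        if alternans:
            return float(bcl)
    return sentinel


def find_alternans_threshold(model_id: str, params: models.ParameterSet,
                             initial_state=None, bcl_max: float = 350.0,
                             bcl_min: float = 150.0, step: float = 5.0,
                             n_beats: int = 10, n_final: int = 4,
                             stim_amplitude: float = 52.0,
                             Ko: float | None = None,
                             threshold: float = 1.0,
                             audit: list | None = None) -> float:
    """Alternans threshold BCL_alt (ms) on the model.

    The cell state carries over from one cycle length to the next, as
    in an experimental decremental-pacing run.
    """
    mspec = models.get_model(model_id)
    state = {"y": (mspec.initial_state if initial_state is None
                   else np.asarray(initial_state, dtype=float))}

    def run_beats(bcl):
        spec = ProtocolSpec(protocol_id="paced", bcl=bcl, n_beats=n_beats,
                            stim_amplitude=stim_amplitude, Ko=Ko)
        tr = run_protocol(model_id, params, spec, initial_state=state["y"])
        state["y"] = tr.final_state
        apds = []
        for b in range(tr.n_beats):
            f = action_potential_features(tr, b)
            apds.append(f["APD"] if f["captured"] and f["APD"] is not None
                        else np.nan)
        return apds

    return scan_alternans(run_beats, bcl_max, bcl_min, step, threshold,
                          n_final, audit=audit)


# --------------------------------------------------------------------------
# S1S2 restitution
# --------------------------------------------------------------------------

def max_centered_slope(di, apd) -> float:
    """Maximum centered finite-difference slope of APD(DI)."""
    di = np.asarray(di, dtype=float)
    apd = np.asarray(apd, dtype=float)
    if len(di) < 3:
        raise ValueError("need at least 3 restitution points")
    order = np.argsort(di)
    di, apd = di[order], apd[order]
    slopes = (apd[2:] - apd[:-2]) / (di[2:] - di[:-2])
    return float(np.max(slopes))


DEFAULT_DI_GRID = np.array(
    [20.0, 30.0, 40.0, 55.0, 70.0, 85.0, 100.0, 130.0, 170.0, 220.0,
     280.0, 350.0, 450.0, 600.0])


def restitution_max_slope(model_id: str, params: models.ParameterSet,
                          initial_state=None, di_grid=None,
                          bcl_s1: float = 1000.0,
                          stim_amplitude: float = 52.0,
                          Ko: float | None = None,
                          audit: list | None = None):
    """Maximum S1S2 restitution slope.

    From a steady paced state, one S1 beat is delivered; an S2 extra
    stimulus follows at each diastolic interval of the grid (measured
    from the S1 action potential's repolarisation time).  Grid points
    whose S2 fails to capture are dropped; fewer than 3 valid points
    marks the output missing (returns None).

    Returns ``(max_slope, di_used, apd_used)``.
    """
    if di_grid is None:
        di_grid = DEFAULT_DI_GRID
    mspec = models.get_model(model_id)
    state = mspec.initial_state if initial_state is None else np.asarray(initial_state)

    s1 = ProtocolSpec(protocol_id="paced", bcl=bcl_s1, n_beats=1,
                      stim_amplitude=stim_amplitude, Ko=Ko)
    tr1 = run_protocol(model_id, params, s1, initial_state=state)
    f1 = action_potential_features(tr1, 0)
    if not f1["captured"] or f1["APD"] is None:
        raise TrialFailure("S1 beat failed during restitution")
    t_repol = f1["t_end"]

    dis, apds = [], []
    for di in np.asarray(di_grid, dtype=float):
        t_s2 = t_repol + di
        t_end = t_s2 + 600.0
        spec = ProtocolSpec(protocol_id="paced", bcl=bcl_s1, n_beats=1,
                            stim_amplitude=stim_amplitude, Ko=Ko,
                            tail=t_end - 0.0)
        onsets = np.array([0.0, t_s2])
        Ko_val = Ko if Ko is not None else mspec.Ko_default
        T, S, DVDT, yf, status = models._integrate(
            model_id, state, params, Ko_val, t_end, onsets,
            spec.stim_duration, stim_amplitude, spec.dt_sample,
            spec.dt_min, spec.dt_max, spec.dv_max, spec.dca_max)
        if status != 0:
            continue
        tr = Trace(model_id=model_id, time=T, voltage=S[:, 0],
                   Cai=None, Nai=None, Ki=None,
                   stim=np.zeros_like(T), dvdt=DVDT,
                   beat_onset_times=onsets,
                   beat_boundaries=np.searchsorted(T, onsets).astype(int),
                   final_state=yf)
        f2 = action_potential_features(tr, 1)
        if f2["captured"] and f2["APD"] is not None:
            dis.append(di)
            apds.append(f2["APD"])
        if audit is not None:
            audit.append((float(di), f2["captured"], f2["APD"]))
    if len(dis) < 3:
        return None, np.asarray(dis), np.asarray(apds)
    return max_centered_slope(dis, apds), np.asarray(dis), np.asarray(apds)
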