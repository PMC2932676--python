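"""Population generation: randomized parameters, per-trial output suites,
and the X/Y dataset consumed by the regression stages.

A population is built by multiplicatively randomizing the scalable
parameters of one cell model (lognormal factors, median 1), running the
full protocol suite on every variant, and collecting the natural-log
scale factors as the input matrix X (n x p) and the physiological
outputs as the output matrix Y (n x m).  A synthetic linear fixture
with a known coefficient matrix is provided so the statistical stages
can be tested without any ODE solving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models, protocols
from .features import (TNNP_OUTPUT_NAMES, OutputVector,
                       action_potential_features, assemble_output_vector,
                       calcium_features)
from .protocols import ProtocolSpec, TrialFailure

__all__ = [
    "PopulationConfig",
    "PopulationDataset",
    "sample_scale_factors",
    "build_population_dataset",
    "run_trial",
    "synthetic_linear_fixture",
    "DEFAULT_SIGMA",
    "REDUCED_OUTPUT_NAMES",
    "condition_output_names",
]

log = logging.getLogger(__name__)

#: Default spread of the lognormal parameter randomization: the standard
#: deviation of the natural-log scale factor, ln(1.2), i.e. one-sigma
#: variation of x1.2 / /1.2 around baseline.  This is the spread
#: convention of the regression-based sensitivity approach this package
#: extends; it keeps the population inside the locally-linear regime
#: that the method assumes while still spanning a wide output range.
DEFAULT_SIGMA = float(np.log(1.2))

#: Output roster for the models without detailed Ca2+ handling
#: (LR1 keeps its simple Ca transient; the Bernus-type model has fixed
#: [Ca]i, so its Ca outputs are dropped).
REDUCED_OUTPUT_NAMES = {
    "lr1": ("APD", "APD50", "V_rest", "V_peak", "dVdt_max",
            "dCa", "Ca_dia", "Ca_ttp", "Ca_decay",
            "V_maxmin", "V_minmax", "t_minmax", "V_plus50", "V_plus100",
            "I_thresh", "APD_diff", "Maxslope",
            "APD_hypo", "V_rest_hypo", "V_peak_hypo",
            "APD_hyper", "V_rest_hyper", "V_peak_hyper",
            "Freq_adapt"),
    "bernus": ("APD", "APD50", "V_rest", "V_peak", "dVdt_max",
               "V_maxmin", "V_minmax", "t_minmax", "V_plus50", "V_plus100",
               "I_thresh", "APD_diff", "Maxslope",
               "APD_hypo", "V_rest_hypo", "V_peak_hypo", "dVdt_max_hypo",
               "APD_hyper", "V_rest_hyper", "V_peak_hyper", "dVdt_max_hyper",
               "Freq_adapt"),
}

#: Core per-pacing-run outputs used (at each of several [K+]o levels)
#: for condition reconstruction.
_CONDITION_CORE = ("APD", "V_rest", "V_peak", "dVdt_max", "dCa",
                   "V_maxmin", "V_minmax", "t_minmax", "Ca_ttp",
                   "Ca_decay", "APD_diff")


def condition_output_names(model_id: str, Ko_levels=(None, 3.0, 8.0)):
    core = [n for n in _CONDITION_CORE
            if models.get_model(model_id).cai_index >= 0
            or not n.startswith(("dCa", "Ca_"))]
    names = []
    for i, _ in enumerate(Ko_levels):
        suffix = ("", "_hypo", "_hyper")[i] if len(Ko_levels) == 3 else f"_K{i}"
        names.extend(n + suffix for n in core)
    return tuple(names)


@dataclass(frozen=True)
class PopulationConfig:
    """Problem sizes and protocol settings of one population run.

    The pre-pacing length (40 beats at BCL 1000 ms) is
    convergence-checked in the test suite: beat-to-beat APD change of
    the baseline cell is far below 0.1% at the final beat.
    """

    n_pace: int = 40
    bcl: float = 1000.0
    stim_duration: float = 1.0
    stim_safety: float = 1.5       # pacing amplitude = safety * threshold
    thresh_lo: float = 2.0
    thresh_hi: float = 80.0
    alternans_bcl_max: float = 350.0
    alternans_bcl_min: float = 150.0
    alternans_step: float = 5.0
    alternans_beats: int = 10
    pause_duration: float = 5000.0
    Ko_hypo: float = 3.0
    Ko_hyper: float = 8.0
    n_beats_ko: int = 15
    quiescence_duration: float = 60000.0
    freq_bcl_slow: float = 2000.0
    freq_bcl_fast: float = 500.0
    n_beats_freq_slow: int = 25
    n_beats_freq_fast: int = 30
    max_failure_fraction: float = 0.2


def sample_scale_factors(n: int, p: int, sigma: float, seed: int) -> np.ndarray:
    """Lognormal multiplicative scale factors, median 1.

    ``sigma`` is the standard deviation of the natural-log factor.
    Each trial draws from its own substream (``seed XOR trial index``)
    so single trials can be reproduced in isolation.
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    out = np.empty((n, p))
    for i in range(n):
        rng = np.random.default_rng(seed ^ i)
        out[i] = np.exp(sigma * rng.standard_normal(p))
    return out


@dataclass
class PopulationDataset:
    """Input/output matrices of one population with metadata."""

    model_id: str
    X: np.ndarray                 # n x p natural-log scale factors
    Y: np.ndarray                 # n x m outputs, NaN where masked
    mask: np.ndarray              # n x m, True where missing
    parameter_names: tuple[str, ...]
    output_names: tuple[str, ...]
    seed: int
    sigma: float
    failures: dict = field(default_factory=dict)   # trial id -> reason

    def __post_init__(self):
        n, p = self.X.shape
        if self.Y.shape[0] != n or self.Y.shape[1] != len(self.output_names):
            raise ValueError("inconsistent dataset shapes")
        if self.mask.shape != self.Y.shape:
            raise ValueError("mask shape must match Y")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        if p != len(self.parameter_names):
            raise ValueError("X columns must match parameter names")

    @property
    def n(self):
        return self.X.shape[0]

    def to_frames(self):
        Xf = pd.DataFrame(self.X, columns=list(self.parameter_names))
        Yf = pd.DataFrame(np.where(self.mask, np.nan, self.Y),
                          columns=list(self.output_names))
        return Xf, Yf


# --------------------------------------------------------------------------
# per-trial protocol suites
# --------------------------------------------------------------------------

def _ap_entries(trace, beat, prefix=""):
    f = action_potential_features(trace, beat)
    keys = ("APD", "APD50", "V_rest", "V_peak", "dVdt_max",
            "V_maxmin", "V_minmax", "t_minmax", "V_plus50", "V_plus100")
    return {k + prefix: f[k] for k in keys}, f


def _ca_entries(trace, beat, prefix=""):
    c = calcium_features(trace, beat)
    out = {"dCa" + prefix: None if c["dCa"] is None else c["dCa"] * 1e3}
    out["Ca_ttp" + prefix] = c["Ca_ttp"]
    out["Ca_decay" + prefix] = c["Ca_decay"]
    out["Ca_dia" + prefix] = c["Ca_dia"]
    return out


def _paced_apd(model_id, params, state, bcl, n_beats, amp, Ko, cfg):
    spec = ProtocolSpec(protocol_id="paced", bcl=bcl, n_beats=n_beats,
                        stim_amplitude=amp, stim_duration=cfg.stim_duration,
                        Ko=Ko)
    tr = protocols.run_protocol(model_id, params, spec, initial_state=state)
    f = action_potential_features(tr, n_beats - 1)
    return tr, f


def run_trial(model_id: str, params: models.ParameterSet,
              cfg: PopulationConfig | None = None,
              output_names=None) -> OutputVector:
    """Run the full protocol suite for one model variant.

    Per-trial sequencing: the stimulation threshold is measured first
    (from the model's published initial conditions); all subsequent
    pacing uses ``stim_safety`` times that threshold, guaranteeing
    capture across the randomized population.  A steady 1-Hz train then
    provides the core morphology outputs and the launch state for the
    rate- and potassium-change protocols.
    """
    cfg = cfg or PopulationConfig()
    if output_names is None:
        output_names = (TNNP_OUTPUT_NAMES if model_id == "tnnp"
                        else REDUCED_OUTPUT_NAMES[model_id])
    needed = set(output_names)
    e: dict = {}

    thr = protocols.find_stimulation_threshold(
        model_id, params, lo=cfg.thresh_lo, hi=cfg.thresh_hi,
        stim_duration=cfg.stim_duration)
    e["I_thresh"] = thr
    amp = cfg.stim_safety * thr

    # steady pacing from the quiescent published initial state
    spec = ProtocolSpec(protocol_id="paced", bcl=cfg.bcl, n_beats=cfg.n_pace,
                        stim_amplitude=amp, stim_duration=cfg.stim_duration)
    tr = protocols.run_protocol(model_id, params, spec)
    last = cfg.n_pace - 1
    ap, f_last = _ap_entries(tr, last)
    e.update(ap)
    first = action_potential_features(tr, 0)
    if f_last["captured"] and first["captured"] and \
            f_last["APD"] is not None and first["APD"] is not None:
        e["APD_diff"] = f_last["APD"] - first["APD"]
    else:
        e["APD_diff"] = None
    if models.get_model(model_id).cai_index >= 0:
        e.update(_ca_entries(tr, last))
        ca_last = calcium_features(tr, last)
        ca_first = calcium_features(tr, 0)
        if ca_last["dCa"] is not None and ca_first["dCa"] is not None:
            e["dCa_diff"] = (ca_last["dCa"] - ca_first["dCa"]) * 1e3
        else:
            e["dCa_diff"] = None
    steady = tr.final_state

    if "BCL_alt" in needed:
        e["BCL_alt"] = protocols.find_alternans_threshold(
            model_id, params, initial_state=steady,
            bcl_max=cfg.alternans_bcl_max, bcl_min=cfg.alternans_bcl_min,
            step=cfg.alternans_step, n_beats=cfg.alternans_beats,
            stim_amplitude=amp)

    if "Maxslope" in needed:
        slope, _, _ = protocols.restitution_max_slope(
            model_id, params, initial_state=steady, bcl_s1=cfg.bcl,
            stim_amplitude=amp)
        e["Maxslope"] = slope

    if "APD_pause" in needed:
        pspec = ProtocolSpec(protocol_id="pause", bcl=cfg.bcl, n_beats=1,
                             stim_amplitude=amp,
                             stim_duration=cfg.stim_duration,
                             pause_duration=cfg.pause_duration)
        trp = protocols.run_protocol(model_id, params, pspec,
                                     initial_state=steady)
        ap_p, _ = _ap_entries(trp, 1, "_pause")
        e.update({k: v for k, v in ap_p.items()
                  if k in ("APD_pause", "V_maxmin_pause", "V_minmax_pause",
                           "t_minmax_pause")})
        if "dCa_pause" in needed:
            e["dCa_pause"] = _ca_entries(trp, 1, "_pause")["dCa_pause"]

    for tag, Ko in (("_hypo", cfg.Ko_hypo), ("_hyper", cfg.Ko_hyper)):
        if "APD" + tag not in needed:
            continue
        # excitability shifts with [K+]o, so re-measure the threshold
        thr_k = protocols.find_stimulation_threshold(
            model_id, params, lo=cfg.thresh_lo, hi=cfg.thresh_hi,
            stim_duration=cfg.stim_duration, initial_state=steady, Ko=Ko)
        amp_k = cfg.stim_safety * thr_k
        trk, fk = _paced_apd(model_id, params, steady, cfg.bcl,
                             cfg.n_beats_ko, amp_k, Ko, cfg)
        ap_k, _ = _ap_entries(trk, cfg.n_beats_ko - 1, tag)
        e.update(ap_k)

    if "Ca_quiesc" in needed:
        qspec = ProtocolSpec(protocol_id="quiescence",
                             quiescence_duration=cfg.quiescence_duration,
                             stim_amplitude=0.0, dt_sample=5.0, dt_max=5.0)
        trq = protocols.run_protocol(model_id, params, qspec)
        e["Ca_quiesc"] = trq.Cai[-1] if trq.Cai is not None else None
        e["Na_quiesc"] = trq.Nai[-1] if trq.Nai is not None else None
        e["K_quiesc"] = trq.Ki[-1] if trq.Ki is not None else None

    if "Freq_adapt" in needed:
        _, f_slow = _paced_apd(model_id, params, steady, cfg.freq_bcl_slow,
                               cfg.n_beats_freq_slow, amp, None, cfg)
        _, f_fast = _paced_apd(model_id, params, steady, cfg.freq_bcl_fast,
                               cfg.n_beats_freq_fast, amp, None, cfg)
        if f_slow["APD"] is not None and f_fast["APD"] not in (None, 0.0):
            e["Freq_adapt"] = f_slow["APD"] / f_fast["APD"]
        else:
            e["Freq_adapt"] = None

    return assemble_output_vector(output_names, e)


def run_condition_trial(model_id: str, params: models.ParameterSet,
                        cfg: PopulationConfig | None = None,
                        Ko_levels=(None, 3.0, 8.0)) -> OutputVector:
    """Reduced suite for condition reconstruction: the core pacing
    outputs evaluated at several [K+]o levels."""
    cfg = cfg or PopulationConfig()
    names = condition_output_names(model_id, Ko_levels)
    has_ca = models.get_model(model_id).cai_index >= 0
    thr = protocols.find_stimulation_threshold(
        model_id, params, lo=cfg.thresh_lo, hi=cfg.thresh_hi,
        stim_duration=cfg.stim_duration)
    amp = cfg.stim_safety * thr
    e: dict = {}
    for i, Ko in enumerate(Ko_levels):
        suffix = ("", "_hypo", "_hyper")[i] if len(Ko_levels) == 3 else f"_K{i}"
        if Ko is None:
            amp_k = amp
        else:
            thr_k = protocols.find_stimulation_threshold(
                model_id, params, lo=cfg.thresh_lo, hi=cfg.thresh_hi,
                stim_duration=cfg.stim_duration, Ko=Ko)
            amp_k = cfg.stim_safety * thr_k
        spec = ProtocolSpec(protocol_id="paced", bcl=cfg.bcl,
                            n_beats=cfg.n_pace, stim_amplitude=amp_k,
                            stim_duration=cfg.stim_duration, Ko=Ko)
        tr = protocols.run_protocol(model_id, params, spec)
        last = cfg.n_pace - 1
        ap, f_last = _ap_entries(tr, last, suffix)
        e.update(ap)
        first = action_potential_features(tr, 0)
        if f_last["captured"] and first["captured"] and \
                f_last["APD"] is not None and first["APD"] is not None:
            e["APD_diff" + suffix] = f_last["APD"] - first["APD"]
        else:
            e["APD_diff" + suffix] = None
        if has_ca:
            e.update(_ca_entries(tr, last, suffix))
    return assemble_output_vector(names, e)


def build_population_dataset(model_id: str, n: int = 300,
                             sigma: float | None = None, seed: int = 0,
                             cfg: PopulationConfig | None = None,
                             output_names=None,
                             trial_runner=None,
                             progress: bool = False) -> PopulationDataset:
    """Randomize parameters, run the suite per trial, assemble X and Y.

    Failed trials are logged and their Y rows fully masked (downstream
    they are mean-imputed in Z-space).  More than
    ``cfg.max_failure_fraction`` failures aborts: that signals an
    unstable configuration rather than occasional bad luck.
    """
    cfg = cfg or PopulationConfig()
    if sigma is None:
        sigma = DEFAULT_SIGMA
    spec = models.get_model(model_id)
    runner = trial_runner or run_trial
    factors = sample_scale_factors(n, spec.n_parameters, sigma, seed)
    base = models.baseline_parameters(model_id)

    rows, masks = [], []
    names = output_names
    failures: dict[int, str] = {}
    for i in range(n):
        pset = models.scale_parameters(base, factors[i])
        try:
            ov = runner(model_id, pset, cfg)
            if names is None:
                names = ov.names
            rows.append(ov.values)
            masks.append(ov.mask)
        except (TrialFailure, ValueError) as err:
            failures[i] = str(err)
            rows.append(None)
            masks.append(None)
        if progress and (i + 1) % 25 == 0:
            log.info("%s population: %d/%d trials (%d failed)",
                     model_id, i + 1, n, len(failures))
        if len(failures) > cfg.max_failure_fraction * n:
            raise TrialFailure(
                f"{len(failures)} of {i + 1} trials failed; configuration "
                f"looks unstable", context={"failures": failures})
    if names is None:
        raise TrialFailure("all trials failed", context={"failures": failures})
    m = len(names)
    Y = np.full((n, m), np.nan)
    mask = np.ones((n, m), dtype=bool)
    for i, (r, mk) in enumerate(zip(rows, masks)):
        if r is not None:
            Y[i] = r
            mask[i] = mk
    return PopulationDataset(
        model_id=model_id, X=np.log(factors), Y=Y, mask=mask,
        parameter_names=spec.parameter_names, output_names=tuple(names),
        seed=seed, sigma=sigma, failures=failures)


# --------------------------------------------------------------------------
# synthetic linear fixture
# --------------------------------------------------------------------------

def synthetic_linear_fixture(n: int, p: int, m: int, noise_sd: float = 0.0,
                             seed: int = 0, cond_max: float = 10.0):
    """Standardized linear generative fixture: Y = X B_true + noise.

    X is standard normal; B_true is drawn with a controlled condition
    number (singular values log-spaced between 1 and ``cond_max`` on
    the leading p x p block).  Used as the exact oracle for the
    regression machinery.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    A = rng.standard_normal((p, m))
    U, _, Vt = np.linalg.svd(A, full_matrices=False)
    k = min(p, m)
    svals = np.logspace(0, np.log10(cond_max), k)
    B_true = (U * svals) @ Vt
    Y = X @ B_true
    if noise_sd > 0:
        Y = Y + noise_sd * rng.standard_normal((n, m))
    return X, Y, B_true
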