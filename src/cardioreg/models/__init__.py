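"""Cell-model registry and parameter containers.

Three ventricular myocyte models are provided behind a uniform
interface: the Luo-Rudy 1991 "phase 1" model (``lr1``, 6 scalable
parameters), the ten Tusscher et al. 2004 human epicardial model
(``tnnp``, 16 parameters) and a reduced six-variable Bernus-type human
model (``bernus``, 8 parameters).  Every scalable parameter is a
maximal conductance or transport rate; a model variant is expressed as
the vector of multiplicative scale factors applied to the published
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _bernus, _lr1, _tnnp

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "MODELS",
    "get_model",
    "baseline_parameters",
    "scale_parameters",
    "evaluate_derivatives",
]


@dataclass(frozen=True)
class ModelSpec:
    """Static description of one cell model."""

    model_id: str
    state_names: tuple[str, ...]
    parameter_names: tuple[str, ...]
    baseline_values: np.ndarray
    initial_state: np.ndarray
    Ko_default: float
    cai_index: int           # -1 if the model has no dynamic [Ca]i
    nai_index: int
    ki_index: int
    gate_indices: tuple[int, ...]
    _module: object = field(repr=False, default=None)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def voltage_index(self) -> int:
        return 0

    def __post_init__(self):
        if np.any(self.baseline_values <= 0):
            raise ValueError(f"{self.model_id}: baseline values must be positive")
        if self.state_names.count("V") != 1:
            raise ValueError(f"{self.model_id}: exactly one membrane-voltage state required")


@dataclass
class ParameterSet:
    """Parameter values of one model variant.

    ``values = baseline * scale_factors`` elementwise; both views are
    kept so that populations can be expressed in log scale-factor space
    while simulations consume absolute values.
    """

    model_id: str
    values: np.ndarray
    scale_factors: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.scale_factors = np.asarray(self.scale_factors, dtype=float)
        spec = get_model(self.model_id)
        if self.values.shape != (spec.n_parameters,) or \
                self.scale_factors.shape != (spec.n_parameters,):
            raise ValueError(
                f"{self.model_id}: expected {spec.n_parameters} parameters")
        if not np.all(np.isfinite(np.log(self.scale_factors))):
            raise ValueError("scale factors must be positive and finite")
        expected = spec.baseline_values * self.scale_factors
        if not np.allclose(self.values, expected, rtol=1e-12, atol=0.0):
            raise ValueError("values inconsistent with baseline * scale_factors")

    @property
    def names(self) -> tuple[str, ...]:
        return get_model(self.model_id).parameter_names

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _spec_from_module(mod) -> ModelSpec:
    names = list(mod.STATE_NAMES)
    return ModelSpec(
        model_id=mod.MODEL_ID,
        state_names=tuple(names),
        parameter_names=tuple(mod.PARAM_NAMES),
        baseline_values=mod.BASELINE.copy(),
        initial_state=mod.INITIAL_STATE.copy(),
        Ko_default=mod.KO_DEFAULT,
        cai_index=names.index("Cai") if "Cai" in names else -1,
        nai_index=names.index("Nai") if "Nai" in names else -1,
        ki_index=names.index("Ki") if "Ki" in names else -1,
        gate_indices=tuple(mod.GATES),
        _module=mod,
    )


MODELS: dict[str, ModelSpec] = {
    m.MODEL_ID: _spec_from_module(m) for m in (_lr1, _tnnp, _bernus)
}


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; available: {sorted(MODELS)}") from None


def baseline_parameters(model_id: str) -> ParameterSet:
    """Published baseline conductances with all scale factors equal to 1."""
    spec = get_model(model_id)
    ones = np.ones(spec.n_parameters)
    return ParameterSet(model_id, spec.baseline_values.copy(), ones)


def scale_parameters(base: ParameterSet, factors) -> ParameterSet:
    """Apply multiplicative scale factors to a parameter set."""
    spec = get_model(base.model_id)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (spec.n_parameters,):
        raise ValueError(
            f"expected {spec.n_parameters} factors, got shape {factors.shape}")
    bad = ~(np.isfinite(factors) & (factors > 0))
    if np.any(bad):
        name = spec.parameter_names[int(np.nonzero(bad)[0][0])]
        raise ValueError(f"non-positive or non-finite scale factor for {name}")
    new_factors = base.scale_factors * factors
    return ParameterSet(base.model_id, spec.baseline_values * new_factors,
                        new_factors)


def evaluate_derivatives(model_id: str, state, params: ParameterSet,
                         stim: float = 0.0, Ko: float | None = None) -> np.ndarray:
    """Evaluate d(state)/dt at one point (stim in pA/pF, Ko in mM)."""
    spec = get_model(model_id)
    if params.model_id != model_id:
        raise ValueError(
            f"parameter set is for {params.model_id!r}, not {model_id!r}")
    y = np.asarray(state, dtype=float)
    if y.shape != (spec.n_states,):
        raise ValueError(f"expected state of length {spec.n_states}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite entries in state")
    if Ko is None:
        Ko = spec.Ko_default
    dy = np.empty(spec.n_states)
    inf = np.empty(spec.n_states)
    tau = np.empty(spec.n_states)
    spec._module.rates(y, params.values, Ko, stim, dy, inf, tau)
    return dy


def _integrate(model_id: str, y0, params: ParameterSet, Ko, t_end,
               onsets, stim_dur, stim_amp, dt_sample, dt_min, dt_max,
               dv_max, dca_max):
    """Low-level integration hook used by the protocols module."""
    spec = get_model(model_id)
    return spec._module.integrate(
        np.asarray(y0, dtype=float), params.values, Ko, t_end,
        np.asarray(onsets, dtype=float), stim_dur, stim_amp,
        dt_sample, dt_min, dt_max, dv_max, dca_max)
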