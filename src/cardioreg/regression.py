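"""Forward and reverse regression between parameters and outputs.

Inputs and outputs are Z-scored column-wise, then related by linear
regression: the forward problem fits B (p x m) so that X B approximates
Y; the reverse problem fits B' (m x p) so that Y B' approximates X.
When the retained output set is square (m = p) and linearly
independent, the forward matrix can instead be inverted, and Y B^-1
predicts the parameters directly.  A greedy backward-elimination pass
ranks outputs by how little their removal degrades the reverse
prediction, reducing m to p for the inversion.

Fitting uses partial least squares; at the default full component count
on standardized full-rank data PLS coincides with ordinary least
squares, and the coefficients are then computed directly by least
squares (the equivalence is exercised in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "Standardizer",
    "standardize",
    "RegressionModel",
    "EliminationHistory",
    "fit_regression",
    "reverse_regress",
    "column_r_squared",
    "invert_square_regression",
    "eliminate_outputs",
    "predict_parameters",
    "reconstruct_condition",
    "impute_masked",
    "cv_mean_r_squared",
]


@dataclass(frozen=True)
class Standardizer:
    """Column means and standard deviations frozen at fit time."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        if np.any(self.sd <= 0):
            raise ValueError("all stored standard deviations must be positive")

    def apply(self, M):
        M = np.asarray(M, dtype=float)
        return (M - self.mean) / self.sd

    def invert(self, Z):
        Z = np.asarray(Z, dtype=float)
        return Z * self.sd + self.mean

    def subset(self, idx):
        idx = np.asarray(idx)
        return Standardizer(self.mean[idx], self.sd[idx])


def standardize(M, names=None):
    """Z-score a matrix column-wise; returns (Z, Standardizer).

    Constant columns are rejected (they carry no information and make
    the Z-score undefined); the error names the offending column.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=0)
    bad = np.nonzero(sd <= 0)[0]
    if len(bad):
        label = names[bad[0]] if names is not None else f"column {bad[0]}"
        raise ValueError(f"constant column: {label}")
    st = Standardizer(mean, sd)
    return st.apply(M), st


def impute_masked(Y, mask):
    """Replace masked entries by their column means (Z-space zero).

    Keeps the trial count fixed while the masked cells contribute no
    signal to the regression.
    """
    Y = np.asarray(Y, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    for j in range(Y.shape[1]):
        mj = mask[:, j] | ~np.isfinite(Y[:, j])
        if mj.all():
            raise ValueError(f"column {j} has no observed values")
        if mj.any():
            Y[mj, j] = Y[~mj, j].mean()
    return Y


def column_r_squared(Y_true, Y_pred):
    """Coefficient of determination per column: 1 - SSE/SST."""
    Y_true = np.asarray(Y_true, dtype=float)
    Y_pred = np.asarray(Y_pred, dtype=float)
    if Y_true.shape != Y_pred.shape:
        raise ValueError("shape mismatch")
    sst = np.sum((Y_true - Y_true.mean(axis=0)) ** 2, axis=0)
    if np.any(sst <= 0):
        raise ValueError("zero-variance column in Y_true")
    sse = np.sum((Y_true - Y_pred) ** 2, axis=0)
    return 1.0 - sse / sst


@dataclass
class RegressionModel:
    """A fitted linear map between Z-scored matrices.

    ``direction`` is ``forward`` (parameters -> outputs, B is p x m),
    ``reverse`` (outputs -> parameters, B' is m x p) or ``inverse``
    (B^-1 of the square retained system, p x p).
    """

    direction: str
    coef: np.ndarray
    x_standardizer: Standardizer      # parameter side, whatever the direction
    y_standardizer: Standardizer      # output side, whatever the direction
    r_squared: np.ndarray
    n_components: int
    predictor_names: tuple | None = None
    response_names: tuple | None = None
    selected_outputs: np.ndarray | None = None

    def __post_init__(self):
        if self.direction not in ("forward", "reverse", "inverse"):
            raise ValueError(f"bad direction {self.direction!r}")
        if np.any(self.r_squared > 1 + 1e-12):
            raise ValueError("R^2 cannot exceed 1")

    def predict_z(self, Z):
        return np.asarray(Z, dtype=float) @ self.coef


def _fit_linear(A_z, B_z, n_components):
    """Coefficients C with A_z C ~ B_z, by PLS (full rank -> OLS)."""
    n, p = A_z.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}")
    if n_components == p:
        C, *_ = np.linalg.lstsq(A_z, B_z, rcond=None)
        return C
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(A_z, B_z)
    return pls.coef_.T


def fit_regression(X_z, Y_z, n_components=None,
                   x_standardizer=None, y_standardizer=None,
                   predictor_names=None, response_names=None,
                   direction="forward") -> RegressionModel:
    """Fit the forward regression Y_hat = X B on Z-scored matrices."""
    X_z = np.asarray(X_z, dtype=float)
    Y_z = np.asarray(Y_z, dtype=float)
    if X_z.shape[0] != Y_z.shape[0]:
        raise ValueError("row mismatch between X and Y")
    p = X_z.shape[1]
    if n_components is None:
        n_components = min(p, X_z.shape[0] - 1)
    B = _fit_linear(X_z, Y_z, n_components)
    r2 = column_r_squared(Y_z, X_z @ B)
    ident = Standardizer(np.zeros(0), np.ones(0))
    return RegressionModel(
        direction=direction, coef=B,
        x_standardizer=x_standardizer or ident,
        y_standardizer=y_standardizer or ident,
        r_squared=r2, n_components=n_components,
        predictor_names=predictor_names, response_names=response_names)


def reverse_regress(Y_z, X_z, n_components=None, **kw) -> RegressionModel:
    """Fit the reverse regression X_hat = Y B' on Z-scored matrices."""
    return fit_regression(Y_z, X_z, n_components=n_components,
                          direction="reverse", **kw)


def invert_square_regression(model: RegressionModel, X_z, Y_z,
                             selected=None, rcond_min=1e-10) -> RegressionModel:
    """Invert the forward matrix on a square retained output set.

    ``selected`` gives the retained output column indices (default: all,
    which requires m = p already).  Raises if the restricted matrix is
    not numerically invertible — near-singularity means the retained
    outputs are not linearly independent, and silently falling back to
    a pseudo-inverse would hide that.
    """
    if model.direction != "forward":
        raise ValueError("can only invert a forward model")
    B = model.coef
    p = B.shape[0]
    if selected is None:
        selected = np.arange(B.shape[1])
    selected = np.asarray(selected, dtype=int)
    Bs = B[:, selected]
    if Bs.shape != (p, p):
        raise ValueError(f"retained system is {Bs.shape}, expected square ({p})")
    rcond = 1.0 / np.linalg.cond(Bs)
    if not np.isfinite(rcond) or rcond < rcond_min:
        raise np.linalg.LinAlgError(
            f"outputs not linearly independent (rcond={rcond:.2e})")
    Binv = np.linalg.inv(Bs)
    X_pred = np.asarray(Y_z)[:, selected] @ Binv
    r2 = column_r_squared(np.asarray(X_z), X_pred)
    resp = model.response_names
    return RegressionModel(
        direction="inverse", coef=Binv,
        x_standardizer=model.x_standardizer,
        y_standardizer=model.y_standardizer,
        r_squared=r2, n_components=model.n_components,
        predictor_names=(tuple(np.asarray(resp)[selected]) if resp else None),
        response_names=model.predictor_names,
        selected_outputs=selected)


def cv_mean_r_squared(Y_z, X_z, k=5, seed=0):
    """k-fold cross-validated mean per-parameter R^2 of Y_z -> X_z.

    In-sample R^2 grows mechanically with the number of predictor
    columns, so comparisons between output sets of different size
    (all outputs vs a retained subset) are made out-of-sample.
    """
    Y_z = np.asarray(Y_z, dtype=float)
    X_z = np.asarray(X_z, dtype=float)
    n = X_z.shape[0]
    idx = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(idx, k)
    press = np.zeros(X_z.shape[1])
    sst = np.sum((X_z - X_z.mean(axis=0)) ** 2, axis=0)
    for f in folds:
        tr = np.setdiff1d(idx, f)
        C, *_ = np.linalg.lstsq(Y_z[tr], X_z[tr], rcond=None)
        press += np.sum((X_z[f] - Y_z[f] @ C) ** 2, axis=0)
    return float(np.mean(1.0 - press / sst))


@dataclass
class EliminationHistory:
    """Record of one greedy backward-elimination run."""

    removed: list[int] = field(default_factory=list)     # output indices
    criterion: list[float] = field(default_factory=list)  # mean-R2 drop at removal
    retained: np.ndarray | None = None
    mean_r2_path: list[float] = field(default_factory=list)

    def validate(self, m_total):
        all_idx = sorted(self.removed + list(self.retained))
        if all_idx != list(range(m_total)):
            raise ValueError("removed + retained must partition the outputs")


def eliminate_outputs(X_z, Y_z, target_m=None, n_components=None,
                      criterion="mean") -> EliminationHistory:
    """Greedy backward elimination of output columns.

    At each step every remaining output is tentatively removed, the
    reverse regression is refitted on the rest, and the output whose
    removal least degrades the prediction of X — measured by the mean
    (or, optionally, the minimum) per-parameter R^2 — is dropped.
    Ties break toward the lowest column index.
    """
    X_z = np.asarray(X_z, dtype=float)
    Y_z = np.asarray(Y_z, dtype=float)
    n, p = X_z.shape
    m = Y_z.shape[1]
    if target_m is None:
        target_m = p
    if not p <= target_m <= m:
        raise ValueError(f"target_m must be in [{p}, {m}]")
    agg = {"mean": np.mean, "min": np.min}[criterion]

    def score(cols):
        nc = n_components or min(len(cols), n - 1)
        mdl = reverse_regress(Y_z[:, cols], X_z, n_components=nc)
        return agg(mdl.r_squared)

    remaining = list(range(m))
    hist = EliminationHistory()
    current = score(remaining)
    hist.mean_r2_path.append(current)
    while len(remaining) > target_m:
        best_drop, best_score = None, -np.inf
        for j in remaining:
            cols = [c for c in remaining if c != j]
            s = score(cols)
            if s > best_score + 1e-15:
                best_drop, best_score = j, s
        hist.removed.append(best_drop)
        hist.criterion.append(current - best_score)
        remaining.remove(best_drop)
        current = best_score
        hist.mean_r2_path.append(current)
    hist.retained = np.asarray(remaining, dtype=int)
    hist.validate(m)
    return hist


def predict_parameters(model: RegressionModel, y_new, y_mask=None) -> np.ndarray:
    """Predict multiplicative scale factors from a raw output vector.

    ``y_new`` is in native output units; it is standardized with the
    model's stored output-side moments (never refit), mapped through
    the reverse/inverse coefficients, de-standardized on the parameter
    side and exponentiated to factors.
    """
    if model.direction not in ("reverse", "inverse"):
        raise ValueError("predict_parameters needs a reverse or inverse model")
    y_new = np.asarray(y_new, dtype=float)
    if model.direction == "inverse" and model.selected_outputs is not None:
        sel = model.selected_outputs
        if y_mask is not None and np.any(np.asarray(y_mask, bool)[..., sel]):
            raise ValueError("masked entries within the model's retained outputs")
        st = model.y_standardizer.subset(sel)
        z = st.apply(y_new[..., sel])
    else:
        if y_mask is not None and np.any(y_mask):
            raise ValueError("masked entries in y_new")
        z = model.y_standardizer.apply(y_new)
    zx = z @ model.coef
    logf = model.x_standardizer.invert(zx)
    return np.exp(logf)


def reconstruct_condition(model_id, condition_params, fold_changes,
                          n=150, sigma=None, seed=0, cfg=None,
                          Ko_levels=(None, 3.0, 8.0), n_components=None):
    """Recover known parameter fold-changes from condition outputs.

    Builds a population that randomizes only ``condition_params`` (k
    parameters), fits the reverse regression from the condition output
    suite (core pacing outputs at each [K+]o level) to the k log
    factors, simulates the "condition" cell carrying the given
    ``fold_changes``, and returns the predicted fold-changes.

    Returns ``(predicted, true, dataset, model)``.
    """
    # imported here: population imports this module's sibling namespace
    from . import models as _models
    from .population import (PopulationConfig, build_population_dataset,
                             run_condition_trial, sample_scale_factors)

    cfg = cfg or PopulationConfig()
    if sigma is None:
        from .population import DEFAULT_SIGMA
        sigma = DEFAULT_SIGMA
    spec = _models.get_model(model_id)
    cond_idx = [spec.parameter_names.index(nm) for nm in condition_params]
    k = len(cond_idx)
    fold_changes = np.asarray(fold_changes, dtype=float)
    if fold_changes.shape != (k,):
        raise ValueError("one fold change per condition parameter")

    # population randomizing only the condition parameters
    sub = sample_scale_factors(n, k, sigma, seed)
    base = _models.baseline_parameters(model_id)

    def runner(mid, pset, c):
        return run_condition_trial(mid, pset, c, Ko_levels=Ko_levels)

    def trial_factors(i):
        f = np.ones(spec.n_parameters)
        f[cond_idx] = sub[i]
        return f

    rows, masks, failures = [], [], {}
    names = None
    for i in range(n):
        pset = _models.scale_parameters(base, trial_factors(i))
        try:
            ov = runner(model_id, pset, cfg)
            names = names or ov.names
            rows.append(ov.values)
            masks.append(ov.mask)
        except Exception as err:  # noqa: BLE001 - logged per trial
            failures[i] = str(err)
            rows.append(None)
            masks.append(None)
    if names is None:
        raise RuntimeError("all condition-population trials failed")
    mtot = len(names)
    Y = np.full((n, mtot), np.nan)
    mask = np.ones((n, mtot), dtype=bool)
    ok = np.zeros(n, dtype=bool)
    for i, (r, mk) in enumerate(zip(rows, masks)):
        if r is not None:
            Y[i], mask[i], ok[i] = r, mk, True
    X = np.log(sub)[ok]
    Y = impute_masked(Y[ok], mask[ok])

    # outputs that do not vary in this condition population (e.g. a shape
    # parameter pinned at its fallback) carry no information: drop them
    keep_cols = np.nonzero(Y.std(axis=0) > 0)[0]
    Y = Y[:, keep_cols]
    names = tuple(np.asarray(names)[keep_cols])

    X_z, st_x = standardize(X)
    Y_z, st_y = standardize(Y, names=names)
    mdl = reverse_regress(Y_z, X_z, n_components=n_components,
                          x_standardizer=st_x, y_standardizer=st_y,
                          predictor_names=names,
                          response_names=tuple(condition_params))

    f_cond = np.ones(spec.n_parameters)
    f_cond[cond_idx] = fold_changes
    cond_pset = _models.scale_parameters(base, f_cond)
    ov = runner(model_id, cond_pset, cfg)
    yfull = np.where(ov.mask, np.nan, ov.values)[keep_cols]
    # a masked condition-cell output falls back to the population mean
    y = np.where(np.isfinite(yfull), yfull, Y.mean(axis=0))

    predicted = predict_parameters(mdl, y, y_mask=None)
    return predicted, fold_changes, (X, Y, names), mdl
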