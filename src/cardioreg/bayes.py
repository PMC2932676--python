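"""Bayesian sequential conditioning of parameter distributions.

The second route to parameter constraint: with event A = "a parameter
lies in a given range" and event B = "an output lies in a given range",
Bayes's theorem P(A|B) = P(B|A) P(A) / P(B) is estimated empirically
from the simulation ensemble.  Conditioning on successive output
windows — centred on the trial whose outputs the forward regression
reproduces best — selects nested sub-populations whose parameter
histograms narrow as more outputs are considered.

Histograms share fixed bin edges per parameter across all stages, so
narrowing is directly comparable, and each histogram is normalized to
its own subset size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BayesAnalysis",
    "select_best_trial",
    "conditional_subset",
    "sequential_constraint_analysis",
    "percentile_window",
]

N_BINS = 20


def select_best_trial(Y, Y_hat) -> int:
    """Trial with the smallest squared residual between Y and Y_hat.

    Both matrices must be in Z-space (so outputs are comparable);
    ties break toward the lowest index.
    """
    Y = np.asarray(Y, dtype=float)
    Y_hat = np.asarray(Y_hat, dtype=float)
    if Y.shape != Y_hat.shape:
        raise ValueError("shape mismatch")
    if Y.size == 0:
        raise ValueError("empty matrices")
    resid = np.sum((Y - Y_hat) ** 2, axis=1)
    return int(np.argmin(resid))


def percentile_window(values, center_value, fraction=0.10):
    """Window around ``center_value`` covering ``fraction`` of ``values``.

    The window spans from the (q - f/2) to the (q + f/2) empirical
    quantile, where q is the quantile rank of the centre (clipped so
    the window stays inside [0, 1]).
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    q = np.searchsorted(values, center_value) / n
    lo_q = np.clip(q - fraction / 2.0, 0.0, 1.0 - fraction)
    hi_q = lo_q + fraction
    return (float(np.quantile(values, lo_q)),
            float(np.quantile(values, hi_q)))


def _histograms(X, idx, edges):
    out = []
    for j in range(X.shape[1]):
        h, _ = np.histogram(X[idx, j], bins=edges[j])
        total = h.sum()
        out.append(h / total if total else h.astype(float))
    return out


def conditional_subset(X, Y, constraint, output_names=None, edges=None):
    """Trials satisfying one output window, with parameter histograms.

    ``constraint`` is ``(output, (lower, upper))`` where ``output`` is a
    column index or a name resolved through ``output_names``.  Returns
    ``(indices, histograms)``; histograms use shared ``edges`` (default:
    20 bins spanning each parameter's marginal range) and are
    normalized to the subset size.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    output, (lo, hi) = constraint
    if not lo < hi:
        raise ValueError("window lower bound must be below upper bound")
    if isinstance(output, str):
        if output_names is None:
            raise ValueError("output names needed to resolve a named output")
        output = list(output_names).index(output)
    col = Y[:, output]
    idx = np.nonzero((col >= lo) & (col <= hi))[0]
    if len(idx) == 0:
        raise ValueError(
            f"no trials satisfy constraint on output {output} in [{lo}, {hi}]")
    if edges is None:
        edges = default_bin_edges(X)
    return idx, _histograms(X, idx, edges)


def default_bin_edges(X, n_bins=N_BINS):
    X = np.asarray(X, dtype=float)
    return [np.linspace(X[:, j].min(), X[:, j].max(), n_bins + 1)
            for j in range(X.shape[1])]


@dataclass
class BayesAnalysis:
    """Result of one sequential conditioning run."""

    best_trial: int
    constraints: list          # (output name/index, (lo, hi))
    subsets: list              # surviving index arrays, one per stage
    histograms: list           # list of per-parameter histogram lists
    bin_edges: list
    parameter_names: tuple | None = None

    def __post_init__(self):
        prev = None
        for s in self.subsets:
            s = np.asarray(s)
            if prev is not None and not np.all(np.isin(s, prev)):
                raise ValueError("surviving subsets must be nested")
            prev = s
        for stage in self.histograms:
            for h in stage:
                if len(h) and abs(h.sum() - 1.0) > 1e-12 and h.sum() != 0:
                    raise ValueError("histograms must sum to 1")

    def subset_sizes(self):
        return [len(s) for s in self.subsets]

    def parameter_sd(self, X, j):
        """Conditional SD of parameter column j at every stage."""
        X = np.asarray(X, dtype=float)
        return [float(np.std(X[s, j])) for s in self.subsets]


def sequential_constraint_analysis(X, Y, Y_hat, constraint_outputs,
                                   window_mode="percentile",
                                   fraction=0.10, rel=0.05,
                                   output_names=None,
                                   parameter_names=None) -> BayesAnalysis:
    """Apply output windows in sequence and track distribution narrowing.

    Windows are centred on the best trial (the one whose outputs the
    forward regression reproduces most closely).  ``window_mode``:

    - ``percentile``: each window covers ``fraction`` of the samples
      around the best trial's value (default 10%);
    - ``relative``: each window is the best-trial value +/- ``rel``
      (default +/-5%), in the output's native units.

    Constraints intersect: stage k keeps trials satisfying the first k
    windows.  An empty intermediate subset raises, naming the
    constraint responsible.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not constraint_outputs:
        raise ValueError("need at least one constraint output")
    if window_mode not in ("percentile", "relative"):
        raise ValueError(f"unknown window mode {window_mode!r}")
    best = select_best_trial(
        (Y - Y.mean(axis=0)) / Y.std(axis=0),
        (np.asarray(Y_hat) - Y.mean(axis=0)) / Y.std(axis=0))
    edges = default_bin_edges(X)

    def resolve(o):
        if isinstance(o, str):
            if output_names is None:
                raise ValueError("output names needed to resolve named outputs")
            return list(output_names).index(o), o
        return int(o), (output_names[o] if output_names else o)

    subsets = [np.arange(X.shape[0])]
    hists = [_histograms(X, subsets[0], edges)]
    constraints = []
    surviving = subsets[0]
    for o in constraint_outputs:
        j, label = resolve(o)
        y_star = Y[best, j]
        if window_mode == "percentile":
            lo, hi = percentile_window(Y[:, j], y_star, fraction)
        else:
            half = rel * abs(y_star)
            lo, hi = y_star - half, y_star + half
        keep = surviving[(Y[surviving, j] >= lo) & (Y[surviving, j] <= hi)]
        if len(keep) == 0:
            raise ValueError(f"constraint on {label!r} leaves no trials")
        constraints.append((label, (lo, hi)))
        surviving = keep
        subsets.append(surviving)
        hists.append(_histograms(X, surviving, edges))

    return BayesAnalysis(best_trial=best, constraints=constraints,
                         subsets=subsets, histograms=hists, bin_edges=edges,
                         parameter_names=tuple(parameter_names)
                         if parameter_names else None)
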