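"""Plotting hooks: coefficient heat maps and conditioning histograms."""

from __future__ import annotations

import numpy as np


def coefficient_heatmap(model, ax=None, cmap="RdBu_r"):
    """Heat map of a regression coefficient matrix.

    Rows/columns are labelled from the model's predictor/response names;
    white is zero, blue/red are positive/negative (symmetric scale).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    C = model.coef
    lim = np.max(np.abs(C))
    im = ax.imshow(C, cmap=cmap, vmin=-lim, vmax=lim, aspect="auto")
    if model.response_names:
        ax.set_xticks(range(C.shape[1]))
        ax.set_xticklabels(model.response_names, rotation=90, fontsize=7)
    if model.predictor_names:
        ax.set_yticks(range(C.shape[0]))
        ax.set_yticklabels(model.predictor_names, fontsize=7)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(f"{model.direction} regression coefficients")
    return ax


def conditioning_histograms(analysis, X, parameter, parameter_names=None,
                            axes=None):
    """One row of histograms per conditioning stage for one parameter,
    in the style of a sequential-constraint figure."""
    import matplotlib.pyplot as plt

    names = parameter_names or analysis.parameter_names
    j = (list(names).index(parameter)
         if isinstance(parameter, str) else int(parameter))
    n_stage = len(analysis.histograms)
    if axes is None:
        _, axes = plt.subplots(1, n_stage, figsize=(3 * n_stage, 2.5),
                               sharey=True)
    edges = analysis.bin_edges[j]
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    labels = ["all trials"] + [f"+ {c[0]}" for c in analysis.constraints]
    for ax, stage, lab in zip(np.atleast_1d(axes), analysis.histograms,
                              labels):
        ax.bar(centers, stage[j], width=width)
        ax.set_title(lab, fontsize=8)
    return axes
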