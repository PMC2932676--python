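"""Shared fixtures.

Population builds are expensive (hundreds of ODE trials), so they are
session-scoped and shared between the module tests and the acceptance
suite.  Sizes are chosen to keep the whole run well inside a desk-scale
budget; the methods note records the sizes used.
"""

import numpy as np
import pytest

from cardioreg import models, population, regression


POP_SEED = 17


@pytest.fixture(scope="session")
def lr1_population():
    return population.build_population_dataset(
        "lr1", n=300, sigma=population.DEFAULT_SIGMA, seed=POP_SEED)


@pytest.fixture(scope="session")
def bernus_population():
    return population.build_population_dataset(
        "bernus", n=300, sigma=population.DEFAULT_SIGMA, seed=POP_SEED)


@pytest.fixture(scope="session")
def tnnp_population():
    return population.build_population_dataset(
        "tnnp", n=300, sigma=population.DEFAULT_SIGMA, seed=POP_SEED)


def fit_both(ds):
    """Forward and reverse fits (plus standardized matrices) for a dataset."""
    Y = regression.impute_masked(ds.Y, ds.mask)
    X_z, st_x = regression.standardize(ds.X, names=ds.parameter_names)
    Y_z, st_y = regression.standardize(Y, names=ds.output_names)
    fwd = regression.fit_regression(
        X_z, Y_z, x_standardizer=st_x, y_standardizer=st_y,
        predictor_names=ds.parameter_names, response_names=ds.output_names)
    rev = regression.reverse_regress(
        Y_z, X_z, x_standardizer=st_x, y_standardizer=st_y,
        predictor_names=ds.output_names, response_names=ds.parameter_names)
    return {"Y": Y, "X_z": X_z, "Y_z": Y_z, "st_x": st_x, "st_y": st_y,
            "fwd": fwd, "rev": rev}


@pytest.fixture(scope="session")
def tnnp_fits(tnnp_population):
    return fit_both(tnnp_population)


@pytest.fixture(scope="session")
def lr1_fits(lr1_population):
    return fit_both(lr1_population)


@pytest.fixture(scope="session")
def bernus_fits(bernus_population):
    return fit_both(bernus_population)


@pytest.fixture(scope="session")
def tnnp_steady_trace():
    """Baseline TNNP paced to steady state at BCL 1000 ms."""
    from cardioreg import protocols
    p = models.baseline_parameters("tnnp")
    spec = protocols.ProtocolSpec(protocol_id="paced", n_beats=40,
                                  stim_amplitude=52.0)
    return protocols.run_protocol("tnnp", p, spec)
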