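"""Regression machinery against exact linear-algebra oracles."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from cardioreg import regression as rg
from cardioreg.population import synthetic_linear_fixture


@pytest.fixture()
def square_fixture():
    X, Y, B = synthetic_linear_fixture(200, 5, 5, noise_sd=0.0, seed=4,
                                       cond_max=5.0)
    X_z, st_x = rg.standardize(X)
    Y_z, st_y = rg.standardize(Y)
    return X, Y, B, X_z, Y_z, st_x, st_y


class TestStandardize:
    def test_moments(self):
        M = np.random.default_rng(0).normal(5.0, 3.0, size=(100, 4))
        Z, st = rg.standardize(M)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_already_standardized_is_fixed_point(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((500, 3))
        Z1, _ = rg.standardize(M)
        Z2, _ = rg.standardize(Z1)
        np.testing.assert_allclose(Z1, Z2, atol=1e-10)

    def test_round_trip(self):
        M = np.random.default_rng(2).normal(2.0, 0.5, size=(50, 3))
        Z, st = rg.standardize(M)
        np.testing.assert_allclose(st.invert(Z), M, atol=1e-10)

    def test_constant_column_named(self):
        M = np.ones((10, 2))
        M[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="flat_output"):
            rg.standardize(M, names=("x", "flat_output"))

    def test_apply_never_refits(self):
        M = np.random.default_rng(3).normal(size=(50, 2))
        _, st = rg.standardize(M)
        other = np.random.default_rng(4).normal(5.0, 2.0, size=(50, 2))
        Z = st.apply(other)
        # moments of the new matrix are NOT zero/one: stored moments used
        assert abs(Z.mean()) > 0.5


class TestColumnRSquared:
    def test_perfect_and_mean_prediction(self):
        Y = np.random.default_rng(0).normal(size=(40, 3))
        np.testing.assert_allclose(rg.column_r_squared(Y, Y), 1.0)
        Ybar = np.tile(Y.mean(axis=0), (40, 1))
        np.testing.assert_allclose(rg.column_r_squared(Y, Ybar), 0.0,
                                   atol=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        Yt = rng.normal(size=(30, 4))
        Yp = Yt + 0.3 * rng.normal(size=(30, 4))
        got = rg.column_r_squared(Yt, Yp)
        for j in range(4):
            sse = np.sum((Yt[:, j] - Yp[:, j]) ** 2)
            sst = np.sum((Yt[:, j] - Yt[:, j].mean()) ** 2)
            assert got[j] == pytest.approx(1 - sse / sst, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rg.column_r_squared(np.ones((10, 1)), np.ones((10, 1)))


class TestFitRegression:
    def test_identity_problem(self):
        Z = np.random.default_rng(6).standard_normal((100, 4))
        mdl = rg.fit_regression(Z, Z)
        np.testing.assert_allclose(mdl.coef, np.eye(4), atol=1e-8)
        np.testing.assert_allclose(mdl.r_squared, 1.0)

    def test_noiseless_recovery(self):
        X, Y, B = synthetic_linear_fixture(300, 6, 12, noise_sd=0.0, seed=7)
        mdl = rg.fit_regression(X, Y)
        assert np.max(np.abs(mdl.coef - B)) < 1e-8

    def test_full_rank_pls_equals_ols(self):
        """At n_components = p, PLS and the least-squares path agree."""
        X, Y, _ = synthetic_linear_fixture(200, 5, 8, noise_sd=0.3, seed=8)
        X_z, _ = rg.standardize(X)
        Y_z, _ = rg.standardize(Y)
        ours = rg.fit_regression(X_z, Y_z, n_components=5).coef
        pls = PLSRegression(n_components=5, scale=False).fit(X_z, Y_z)
        np.testing.assert_allclose(ours, pls.coef_.T, atol=1e-6)

    def test_n_components_out_of_range(self):
        X, Y, _ = synthetic_linear_fixture(50, 4, 6, seed=9)
        with pytest.raises(ValueError):
            rg.fit_regression(X, Y, n_components=0)
        with pytest.raises(ValueError):
            rg.fit_regression(X, Y, n_components=5)


class TestInversion:
    def test_identity_inverse(self):
        Z = np.random.default_rng(10).standard_normal((100, 4))
        fwd = rg.fit_regression(Z, Z)
        inv = rg.invert_square_regression(fwd, Z, Z)
        np.testing.assert_allclose(inv.coef, np.eye(4), atol=1e-8)

    def test_well_conditioned_inverse(self, square_fixture):
        X, Y, B, X_z, Y_z, st_x, st_y = square_fixture
        fwd = rg.fit_regression(X_z, Y_z, x_standardizer=st_x,
                                y_standardizer=st_y)
        inv = rg.invert_square_regression(fwd, X_z, Y_z)
        np.testing.assert_allclose(fwd.coef @ inv.coef, np.eye(5),
                                   atol=1e-10)
        assert np.all(inv.r_squared > 0.999)

    def test_duplicate_columns_rejected(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((100, 3))
        Y = X @ rng.standard_normal((3, 3))
        Y[:, 2] = Y[:, 1]  # exactly collinear outputs
        X_z, _ = rg.standardize(X)
        Y_z, _ = rg.standardize(Y)
        fwd = rg.fit_regression(X_z, Y_z)
        with pytest.raises(np.linalg.LinAlgError,
                           match="not linearly independent"):
            rg.invert_square_regression(fwd, X_z, Y_z)

    def test_forward_inverse_consistency(self, square_fixture):
        """On Y_hat = X B rows, the inverse returns X exactly."""
        X, Y, B, X_z, Y_z, st_x, st_y = square_fixture
        fwd = rg.fit_regression(X_z, Y_z, x_standardizer=st_x,
                                y_standardizer=st_y)
        inv = rg.invert_square_regression(fwd, X_z, Y_z)
        Y_hat_z = X_z @ fwd.coef
        np.testing.assert_allclose(Y_hat_z @ inv.coef, X_z, atol=1e-8)


class TestReverse:
    def test_square_noiseless_gives_inverse_of_truth(self, square_fixture):
        X, Y, B, X_z, Y_z, st_x, st_y = square_fixture
        rev = rg.reverse_regress(Y_z, X_z)
        # in Z-space the forward map is B_z = diag(sx) B diag(1/sy)
        B_z = B * st_x.sd[:, None] / st_y.sd[None, :]
        np.testing.assert_allclose(rev.coef, np.linalg.inv(B_z), atol=1e-6)

    def test_r2_invariant_to_output_rescaling(self):
        """Affine rescaling of any output column leaves reverse R^2
        unchanged (Z-scoring guarantees)."""
        X, Y, _ = synthetic_linear_fixture(150, 4, 7, noise_sd=0.2, seed=12)
        X_z, _ = rg.standardize(X)
        Y_z, _ = rg.standardize(Y)
        r1 = rg.reverse_regress(Y_z, X_z).r_squared
        Y2 = Y.copy()
        Y2[:, 3] = -5.0 + 42.0 * Y2[:, 3]
        Y2_z, _ = rg.standardize(Y2)
        r2 = rg.reverse_regress(Y2_z, X_z).r_squared
        np.testing.assert_allclose(r1, r2, atol=1e-10)


class TestElimination:
    def test_greedy_matches_exhaustive_every_step(self):
        """p=3, m=6: each greedy removal equals the best single removal
        found by brute force over all candidates."""
        X, Y, _ = synthetic_linear_fixture(80, 3, 6, noise_sd=0.1, seed=5)
        X_z, _ = rg.standardize(X)
        Y_z, _ = rg.standardize(Y)
        hist = rg.eliminate_outputs(X_z, Y_z, target_m=3)

        remaining = list(range(6))
        for removed in hist.removed:
            scores = {}
            for j in remaining:
                cols = [c for c in remaining if c != j]
                mdl = rg.reverse_regress(Y_z[:, cols], X_z)
                scores[j] = mdl.r_squared.mean()
            best = max(scores, key=lambda j: (scores[j], -j))
            assert removed == best
            remaining.remove(removed)

    def test_duplicate_column_removed_first_with_zero_cost(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((100, 3))
        Y = np.column_stack([X @ rng.standard_normal(3) for _ in range(5)])
        Y = np.column_stack([Y, Y[:, 0]])  # exact duplicate of column 0
        X_z, _ = rg.standardize(X)
        Y_z, _ = rg.standardize(Y)
        hist = rg.eliminate_outputs(X_z, Y_z, target_m=5)
        assert hist.removed[0] in (0, 5)
        assert hist.criterion[0] == pytest.approx(0.0, abs=1e-10)

    def test_noise_columns_eliminated_before_informative(self):
        """Pure-noise outputs never outrank informative ones."""
        rng = np.random.default_rng(14)
        X = rng.standard_normal((200, 3))
        B = rng.standard_normal((3, 4))
        Y = np.column_stack([X @ B, rng.standard_normal((200, 3))])
        X_z, _ = rg.standardize(X)
        Y_z, _ = rg.standardize(Y)
        hist = rg.eliminate_outputs(X_z, Y_z, target_m=3)
        assert set(hist.retained) <= {0, 1, 2, 3}

    def test_partition_invariant(self):
        X, Y, _ = synthetic_linear_fixture(60, 3, 8, noise_sd=0.2, seed=15)
        X_z, _ = rg.standardize(X)
        Y_z, _ = rg.standardize(Y)
        hist = rg.eliminate_outputs(X_z, Y_z, target_m=4)
        assert sorted(list(hist.retained) + hist.removed) == list(range(8))
        assert len(hist.retained) == 4


class TestPredictParameters:
    def test_training_row_round_trip(self, square_fixture):
        X, Y, B, X_z, Y_z, st_x, st_y = square_fixture
        fwd = rg.fit_regression(X_z, Y_z, x_standardizer=st_x,
                                y_standardizer=st_y)
        inv = rg.invert_square_regression(fwd, X_z, Y_z)
        factors = rg.predict_parameters(inv, Y[3])
        np.testing.assert_allclose(factors, np.exp(X[3]), rtol=1e-6)

    def test_population_mean_maps_to_unit_factors(self, square_fixture):
        X, Y, B, X_z, Y_z, st_x, st_y = square_fixture
        fwd = rg.fit_regression(X_z, Y_z, x_standardizer=st_x,
                                y_standardizer=st_y)
        inv = rg.invert_square_regression(fwd, X_z, Y_z)
        factors = rg.predict_parameters(inv, Y.mean(axis=0))
        np.testing.assert_allclose(factors, np.exp(X.mean(axis=0)),
                                   rtol=1e-8)

    def test_masked_retained_entry_rejected(self, square_fixture):
        X, Y, B, X_z, Y_z, st_x, st_y = square_fixture
        fwd = rg.fit_regression(X_z, Y_z, x_standardizer=st_x,
                                y_standardizer=st_y)
        inv = rg.invert_square_regression(fwd, X_z, Y_z)
        with pytest.raises(ValueError, match="masked"):
            rg.predict_parameters(inv, Y[0], y_mask=np.array([True] + [False] * 4))


class TestImputeMasked:
    def test_masked_entries_get_column_mean(self):
        Y = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]])
        mask = np.isnan(Y)
        out = rg.impute_masked(Y, mask)
        assert out[1, 1] == pytest.approx(4.0)
        assert np.all(np.isfinite(out))

    def test_fully_masked_column_rejected(self):
        Y = np.full((3, 1), np.nan)
        with pytest.raises(ValueError):
            rg.impute_masked(Y, np.isnan(Y))
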