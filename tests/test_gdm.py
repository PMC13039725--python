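"""GDM core: I-spline basis, fitting, transform, prediction, deviance."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.stats import spearmanr

import betafutures as bf
from betafutures.community import SitePairTable
from betafutures.gdm import _design_matrix, _wls_objective


def _pair_table(d, w, x1, x2, name="v"):
    n = len(d)
    frame = pd.DataFrame(
        {
            "site_i": np.arange(n),
            "site_j": np.arange(n) + n,
            "distance": d,
            "weight": w,
            f"s1.{name}": x1,
            f"s2.{name}": x2,
        }
    )
    return SitePairTable(table=frame, predictors=[name])


class TestISplineBasis:
    def test_boundary_values(self):
        basis = bf.SplineBasisDef(knots=(0.0, 0.5, 1.0))
        np.testing.assert_allclose(bf.ispline_basis(0.0, basis), [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(bf.ispline_basis(1.0, basis), [1, 1, 1], atol=1e-12)

    def test_clamping_outside_training_range(self):
        basis = bf.SplineBasisDef(knots=(0.0, 0.5, 1.0))
        np.testing.assert_allclose(bf.ispline_basis(-5.0, basis), [0, 0, 0])
        np.testing.assert_allclose(bf.ispline_basis(7.0, basis), [1, 1, 1])

    def test_monotone_continuous_and_bounded(self):
        basis = bf.SplineBasisDef(knots=(0.0, 0.3, 1.0))
        x = np.linspace(-0.1, 1.1, 500)
        vals = bf.ispline_basis(x, basis)
        assert np.all(vals >= 0) and np.all(vals <= 1)
        assert np.all(np.diff(vals, axis=0) >= -1e-12)
        assert np.abs(np.diff(vals, axis=0)).max() < 0.02  # no jumps on a fine grid

    def test_matches_mspline_quadrature_oracle(self):
        # independent oracle: each I-spline is the normalised integral of an
        # order-2 M-spline density (a degree-1 B-spline on the same knots)
        t1, t2, t3 = 0.0, 0.3, 1.0
        basis = bf.SplineBasisDef(knots=(t1, t2, t3))
        tau = np.array([t1, t1, t2, t3, t3])
        for k in range(3):
            coef = np.zeros(3)
            coef[k] = 1.0
            dens = BSpline(tau, coef, 1, extrapolate=False)

            def f(u):
                return float(np.nan_to_num(dens(u)))

            area, _ = quad(f, t1, t3, points=[t2])
            for x in (0.05, 0.3, 0.55, 0.9):
                expected, _ = quad(f, t1, x, points=[t2])
                ours = bf.ispline_basis(x, basis)[k]
                assert ours == pytest.approx(expected / area, abs=1e-9)

    def test_constant_predictor_degenerates_inert(self):
        basis = bf.SplineBasisDef(knots=(2.0, 2.0, 2.0))
        assert basis.inert
        np.testing.assert_array_equal(bf.ispline_basis(2.0, basis), [0, 0, 0])


class TestFit:
    def test_degenerate_table_intercept_only(self):
        d = np.zeros(30)
        x = np.full(30, 1.0)
        pairs = _pair_table(d, np.ones(30), x, x)
        with pytest.warns(UserWarning):
            model = bf.fit_gdm(pairs)
        assert model.intercept == pytest.approx(0.0, abs=1e-8)
        assert model.explained_deviance_pct == pytest.approx(0.0, abs=1e-6)

    def test_single_predictor_recovery(self, single_predictor_pairs):
        model = bf.fit_gdm(single_predictor_pairs)
        assert model.predictor_total("v") == pytest.approx(1.2, rel=0.10)

    def test_predictions_bounded_by_link_range(self, single_predictor_pairs):
        model = bf.fit_gdm(single_predictor_pairs)
        frame = single_predictor_pairs.table
        basis = model.bases["v"]
        f1 = bf.ispline_basis(frame["s1.v"].to_numpy(), basis) @ model.coefficients["v"]
        f2 = bf.ispline_basis(frame["s2.v"].to_numpy(), basis) @ model.coefficients["v"]
        preds = bf.predict_dissimilarity(
            model, f1[:, None], f2[:, None], include_intercept=True
        )
        floor = 1 - np.exp(-model.intercept)
        assert np.all(preds >= floor - 1e-12)
        assert np.all(preds < 1.0)

    def test_matches_bounded_optimiser_oracle_on_tiny_problem(self):
        rng = np.random.default_rng(8)
        n = 20
        x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        d = np.clip(0.2 + 0.5 * np.abs(x1 - x2) + rng.normal(0, 0.05, n), 0, 0.95)
        w = rng.uniform(0.5, 1.0, n)
        pairs = _pair_table(d, w, x1, x2)
        model = bf.fit_gdm(pairs)
        X, active = _design_matrix(pairs, model.bases)
        ours = _wls_objective(
            np.concatenate([[model.intercept], model.coefficients["v"]]), X, d, w
        )
        # independent oracle: multistart bounded quasi-Newton on the same objective
        best = np.inf
        for start in range(8):
            r = np.random.default_rng(start)
            res = minimize(
                _wls_objective, r.uniform(0, 2, X.shape[1]), args=(X, d, w),
                method="L-BFGS-B", bounds=[(0, None)] * X.shape[1],
            )
            best = min(best, res.fun)
        assert ours <= best + 1e-6

    def test_community_fit_recovers_turnover_structure(self, filled_landscape,
                                                       fitted_community_gdm):
        model, pairs = fitted_community_gdm
        assert model.explained_deviance_pct > 0
        # transformed-space distance tracks niche-space (standardised env) distance
        grid = bf.gdm_transform(model, filled_landscape)
        F = grid.stack()
        sites = grid.valid_indices()
        zcols = []
        for v in filled_landscape.variables:
            col = filled_landscape.data[v].ravel()[sites]
            zcols.append((col - col.mean()) / max(col.std(), 1e-9))
        Z = np.column_stack(zcols)
        rng = np.random.default_rng(2)
        idx = rng.choice(len(F), size=(600, 2))
        idx = idx[idx[:, 0] != idx[:, 1]]
        df = np.abs(F[idx[:, 0]] - F[idx[:, 1]]).sum(axis=1)
        dz = np.linalg.norm(Z[idx[:, 0]] - Z[idx[:, 1]], axis=1)
        rho, _ = spearmanr(df, dz)
        assert rho > 0.5

    def test_serialisation_round_trips_bit_exactly(self, single_predictor_pairs,
                                                   tmp_path):
        model = bf.fit_gdm(single_predictor_pairs)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = bf.GDMModel.load(path)
        assert loaded.intercept == model.intercept
        np.testing.assert_array_equal(loaded.coefficients["v"], model.coefficients["v"])
        assert loaded.bases["v"].knots == model.bases["v"].knots
        path2 = tmp_path / "model2.json"
        loaded.save(path2)
        assert path.read_text() == path2.read_text()


class TestTransform:
    def test_boundary_cells_map_to_zero_and_total(self, single_predictor_pairs):
        model = bf.fit_gdm(single_predictor_pairs)
        basis = model.bases["v"]
        lo = model.transform_values("v", np.array([basis.knots[0]]))
        hi = model.transform_values("v", np.array([basis.knots[2]]))
        assert lo[0] == pytest.approx(0.0, abs=1e-12)
        assert hi[0] == pytest.approx(model.predictor_total("v"))

    def test_transform_is_monotone(self, single_predictor_pairs):
        model = bf.fit_gdm(single_predictor_pairs)
        x = np.sort(np.random.default_rng(1).uniform(0, 1, 200))
        f = model.transform_values("v", x)
        assert np.all(np.diff(f) >= -1e-12)

    def test_missing_predictor_column_rejected(self, fitted_community_gdm,
                                               filled_landscape):
        model, _ = fitted_community_gdm
        env = filled_landscape.copy()
        del env.data[model.predictors[0]]
        with pytest.raises(KeyError):
            bf.gdm_transform(model, env)

    def test_masked_cells_stay_masked(self, fitted_community_gdm, filled_landscape):
        model, _ = fitted_community_gdm
        env = filled_landscape.copy()
        env.mask = env.mask.copy()
        env.mask[0, 0] = False
        grid = bf.gdm_transform(model, env)
        assert not grid.mask[0, 0]
        assert np.isnan(grid.data[model.predictors[0]][0, 0])


class TestPredict:
    def test_no_change_without_intercept(self, fitted_community_gdm):
        model, _ = fitted_community_gdm
        f = np.array([0.1, 0.2, 0.3])
        assert bf.predict_dissimilarity(model, f, f, include_intercept=False) == 0.0

    def test_closed_form_with_intercept(self):
        model = bf.GDMModel(
            intercept=0.1,
            coefficients={"v": np.array([0.5, 0.0, 0.0])},
            bases={"v": bf.SplineBasisDef(knots=(0.0, 0.5, 1.0))},
        )
        f_a, f_b = np.array([0.0]), np.array([0.5])
        assert bf.predict_dissimilarity(model, f_a, f_b) == pytest.approx(
            1 - np.exp(-0.6)
        )

    def test_saturates_below_one(self, fitted_community_gdm):
        model, _ = fitted_community_gdm
        f_a = np.zeros(len(model.predictors))
        f_b = np.full(len(model.predictors), 2.0)
        d = bf.predict_dissimilarity(model, f_a, f_b)
        assert 0.999 < d < 1.0

    def test_monotone_in_each_separation(self, fitted_community_gdm):
        model, _ = fitted_community_gdm
        base = np.zeros(len(model.predictors))
        prev = 0.0
        for delta in np.linspace(0, 2, 20):
            other = base.copy()
            other[0] = delta
            d = bf.predict_dissimilarity(model, base, other, include_intercept=False)
            assert d >= prev - 1e-12
            prev = d


class TestExplainedDeviance:
    def test_perfect_model_reaches_hundred(self):
        rng = np.random.default_rng(5)
        n = 200
        x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        basis = bf.SplineBasisDef(knots=(0.0, 0.5, 1.0))
        eta = 0.9 * np.abs(
            bf.ispline_basis(x1, basis)[:, 0] - bf.ispline_basis(x2, basis)[:, 0]
        )
        d = 1 - np.exp(-eta)  # noise-free
        pairs = _pair_table(d, np.ones(n), x1, x2)
        model = bf.fit_gdm(pairs)
        assert model.explained_deviance_pct == pytest.approx(100.0, abs=1.0)

    def test_null_model_scores_zero(self):
        rng = np.random.default_rng(6)
        n = 100
        d = np.clip(rng.normal(0.4, 0.05, n), 0.01, 0.99)
        x = np.full(n, 0.5)
        pairs = _pair_table(d, np.ones(n), x, x)
        with pytest.warns(UserWarning):
            model = bf.fit_gdm(pairs)
        assert model.explained_deviance_pct == pytest.approx(0.0, abs=1e-6)

    def test_adding_predictor_never_decreases_fit(self):
        rng = np.random.default_rng(7)
        n = 400
        x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        y1, y2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        d = np.clip(
            0.3 * np.abs(x1 - x2) + 0.2 * np.abs(y1 - y2) + rng.normal(0, 0.03, n),
            0.0, 1.0,
        )
        small = _pair_table(d, np.ones(n), x1, x2)
        frame = small.table.copy()
        frame["s1.w"], frame["s2.w"] = y1, y2
        big = SitePairTable(table=frame, predictors=["v", "w"])
        dev_small = bf.fit_gdm(small).explained_deviance_pct
        dev_big = bf.fit_gdm(big).explained_deviance_pct
        assert dev_big >= dev_small - 0.5  # convergence tolerance
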