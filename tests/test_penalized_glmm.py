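import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from polyomic.errors import DegenerateGridError
from polyomic.penalized_glmm import (
    LambdaPath,
    LambdaPathEntry,
    MixedModelSpec,
    ModelData,
    build_model_data,
    fit_lasso_glmm,
    lambda_grid,
    lasso_path,
    refit_glmm,
    select_lambda_elbow,
)

from conftest import make_count_table, make_metadata


def plain_data(X, y, feature_prefix="f"):
    n, p = X.shape
    return ModelData(
        y=y,
        X=X,
        C=np.ones((n, 1)),
        feature_ids=[f"{feature_prefix}{j}" for j in range(p)],
        covariate_names=["(intercept)"],
        groups={},
        group_levels={},
        sample_ids=[str(i) for i in range(n)],
    )


def grouped_data(X, y, participant, site):
    data = plain_data(X, y)
    site_levels, site_codes = np.unique(site, return_inverse=True)
    part_levels, part_codes = np.unique(participant, return_inverse=True)
    data.groups = {"site": site_codes, "participant_id": part_codes}
    data.group_levels = {
        "site": list(site_levels),
        "participant_id": list(part_levels),
    }
    return data


def simulate_logistic(rng, n, p, beta, intercept=0.3):
    X = rng.normal(size=(n, p))
    eta = intercept + X @ beta
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return X, y


def no_penalty_spec(data, standardize=True, intercept=True):
    return MixedModelSpec(
        feature_ids=data.feature_ids,
        covariates=(),
        random_factors=(),
        standardize=standardize,
        include_intercept=intercept,
    )


class TestLambdaGrid:
    def test_two_points_are_endpoints(self):
        rng = np.random.default_rng(0)
        X, y = simulate_logistic(rng, 60, 3, np.array([1.0, 0.0, -0.5]))
        data = plain_data(X, y)
        grid = lambda_grid(no_penalty_spec(data), data, n_points=2, min_ratio=0.1)
        assert len(grid) == 2
        np.testing.assert_allclose(grid[1], grid[0] * 0.1)

    def test_no_selection_at_lambda_max(self):
        rng = np.random.default_rng(1)
        X, y = simulate_logistic(rng, 80, 5, np.array([1.5, -1.0, 0.5, 0, 0]))
        data = plain_data(X, y)
        spec = no_penalty_spec(data)
        grid = lambda_grid(spec, data, n_points=5, min_ratio=0.01)
        fit = fit_lasso_glmm(spec, data, lam=float(grid[0]))
        assert fit.selected == []

    def test_lambda_max_scales_with_unstandardized_features(self):
        rng = np.random.default_rng(2)
        X, y = simulate_logistic(rng, 70, 4, np.array([0.8, -0.8, 0, 0]))
        data = plain_data(X, y)
        spec = no_penalty_spec(data, standardize=False)
        g1 = lambda_grid(spec, data, n_points=3, min_ratio=0.1)
        data2 = plain_data(2.0 * X, y)
        g2 = lambda_grid(spec, data2, n_points=3, min_ratio=0.1)
        np.testing.assert_allclose(g2[0], 2.0 * g1[0], rtol=1e-10)

    def test_constant_features_degenerate(self):
        y = np.array([0.0, 1.0] * 10)
        X = np.ones((20, 2))
        data = plain_data(X, y)
        with pytest.raises(DegenerateGridError):
            lambda_grid(no_penalty_spec(data), data, n_points=3, min_ratio=0.1)


class TestFitLassoGlmm:
    def test_unpenalized_no_grouping_matches_plain_logistic(self):
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(5):
            X, y = simulate_logistic(rng, 60, 4, rng.normal(scale=0.7, size=4))
            if y.sum() in (0, len(y)):
                continue
            data = plain_data(X, y)
            fit = fit_lasso_glmm(no_penalty_spec(data), data, lam=0.0, tol=1e-10)
            ref = sm.Logit(y, np.column_stack([np.ones(len(y)), X])).fit(disp=0)
            ours = np.concatenate(
                [fit.covariate_coefs.to_numpy(), fit.beta.to_numpy()]
            )
            worst = max(worst, float(np.abs(ours - ref.params).max()))
        assert worst < 1e-4

    def test_identity_design_matches_scalar_soft_threshold_oracle(self):
        # with X = I, no intercept and no grouping, the penalized problem
        # decouples into independent scalar problems solvable by brute force
        rng = np.random.default_rng(4)
        n = 30
        y = (rng.random(n) < 0.5).astype(float)
        lam = 0.3
        data = plain_data(np.eye(n), y)
        spec = no_penalty_spec(data, standardize=False, intercept=False)
        data.C = np.zeros((n, 0))
        data.covariate_names = []
        fit = fit_lasso_glmm(spec, data, lam=lam, tol=1e-12)

        def scalar_solution(yi):
            obj = lambda b: -(yi * b - np.logaddexp(0, b)) + lam * abs(b)
            res = minimize_scalar(
                obj, bounds=(-20, 20), method="bounded",
                options={"xatol": 1e-12},
            )
            return res.x if abs(res.x) > 1e-7 else 0.0

        oracle = np.array([scalar_solution(yi) for yi in y])
        np.testing.assert_allclose(fit.beta.to_numpy(), oracle, atol=1e-6)

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(5)
        n = 120
        X = rng.normal(size=(n, 6))
        part = rng.integers(0, 30, size=n)
        site = rng.integers(0, 3, size=n)
        eta = 0.8 * X[:, 0] + rng.normal(0, 0.5, 30)[part]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        data = grouped_data(X, y, part, site)
        spec = MixedModelSpec(feature_ids=data.feature_ids, covariates=())
        grid = lambda_grid(spec, data, n_points=6, min_ratio=0.05)
        for lam in (grid[0], grid[3], grid[5]):
            fit = fit_lasso_glmm(spec, data, lam=float(lam))
            trace = np.array(fit.objective_trace)
            assert np.all(np.diff(trace) <= 1e-9)

    def test_rejects_single_class(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        data = plain_data(X, np.ones(10))
        with pytest.raises(ValueError):
            fit_lasso_glmm(no_penalty_spec(data), data, lam=1.0)


class TestLassoPath:
    def _grouped(self, seed=6):
        rng = np.random.default_rng(seed)
        n = 150
        X = rng.normal(size=(n, 8))
        part = rng.integers(0, 30, size=n)
        site = rng.integers(0, 4, size=n)
        eta = 0.9 * X[:, 0] - 0.9 * X[:, 1] + rng.normal(0, 0.5, 30)[part]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return grouped_data(X, y, part, site)

    def test_endpoint_counts_and_warm_start_quality(self):
        data = self._grouped()
        spec = MixedModelSpec(feature_ids=data.feature_ids, covariates=())
        grid = lambda_grid(spec, data, n_points=8, min_ratio=0.02)
        path = lasso_path(spec, data, grid)
        counts = path.counts
        assert counts[0] == 0
        assert counts[-1] >= counts[0]
        # warm-started objective no worse than a cold start at the same
        # (null-estimated) variances
        for i in (2, 5, 7):
            cold = fit_lasso_glmm(
                spec, data, lam=float(grid[i]), estimate_variance=False
            )
            assert path.entries[i].objective <= cold.objective + 1e-6


class TestSelectLambdaElbow:
    @staticmethod
    def path_with_counts(counts):
        grid = np.geomspace(10, 0.1, len(counts))
        entries = [
            LambdaPathEntry(
                lam=float(l), n_selected=int(c), selected=[],
                objective=0.0, converged=True,
            )
            for l, c in zip(grid, counts)
        ]
        return LambdaPath(grid=grid, entries=entries)

    def test_worked_example_jump(self):
        path = self.path_with_counts([0, 0, 1, 8, 9, 9, 9])
        lam = select_lambda_elbow(path)
        assert lam == pytest.approx(path.grid[3])  # the count-8 point

    def test_flat_curve_falls_back_with_warning(self):
        path = self.path_with_counts([4, 4, 4, 4])
        with pytest.warns(UserWarning):
            select_lambda_elbow(path)

    def test_linear_curve_falls_back(self):
        path = self.path_with_counts([0, 5, 10])
        with pytest.warns(UserWarning):
            lam = select_lambda_elbow(path)
        assert lam == pytest.approx(path.grid[1])  # count closest to max/2

    def test_tie_breaks_toward_larger_penalty(self):
        path = self.path_with_counts([0, 0, 4, 4, 8, 8])
        lam = select_lambda_elbow(path)
        # jumps at index 2 and 4 have equal curvature; the sparser one wins
        assert lam == pytest.approx(path.grid[2])


class TestRefitGlmm:
    def test_no_grouping_matches_plain_logistic(self):
        rng = np.random.default_rng(8)
        X, y = simulate_logistic(rng, 90, 3, np.array([0.8, -0.4, 0.0]))
        data = plain_data(X, y)
        spec = no_penalty_spec(data)
        fit = refit_glmm(spec, data, data.feature_ids)
        ref = sm.Logit(y, np.column_stack([np.ones(len(y)), X])).fit(disp=0)
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), ref.params, atol=1e-4
        )
        np.testing.assert_allclose(fit.se.to_numpy(), ref.bse, rtol=0.05)

    def test_singleton_participants_reduce_to_plain_logistic(self, meta6):
        # one sample per participant, one site: both factors drop
        meta = make_metadata(n_participants=40, samples_each=1, n_cases=20,
                             sites=("MGH",))
        table = make_count_table(meta, n_features=6, seed=9)
        from polyomic.preprocess import clr_transform

        # a strict subset of the CLR features keeps the design full rank
        proc = clr_transform(table, 0.5).subset_features(
            ["MGN_F0", "MGN_F2", "MGN_F4"]
        )
        spec = MixedModelSpec(feature_ids=proc.feature_ids, covariates=())
        data = build_model_data(proc, meta, spec)
        assert data.groups == {}
        fit = refit_glmm(spec, data, proc.feature_ids)
        X = proc.values
        y = meta.ibd_labels().to_numpy(dtype=float)
        ref = sm.Logit(y, np.column_stack([np.ones(len(y)), X])).fit(disp=0)
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), ref.params, atol=1e-4
        )

    def test_zero_selected_returns_covariate_only_fit(self):
        rng = np.random.default_rng(10)
        X, y = simulate_logistic(rng, 50, 2, np.zeros(2))
        data = plain_data(X, y)
        with pytest.warns(UserWarning):
            fit = refit_glmm(no_penalty_spec(data), data, [])
        assert fit.feature_ids == []
        assert list(fit.coefficients.index) == ["(intercept)"]

    def test_parametric_bootstrap_recovery(self):
        # simulate from a fitted model's own coefficients; the refit should
        # recover them within 2 SE for >= 90% of coefficients
        rng = np.random.default_rng(11)
        n, p = 400, 4
        X = rng.normal(size=(n, p))
        part = np.repeat(np.arange(100), 4)
        site = rng.integers(0, 4, size=n)
        true_beta = np.array([0.6, -0.6, 0.3, 0.0])
        b_true = rng.normal(0, 0.4, 100)
        eta = 0.2 + X @ true_beta + b_true[part]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        data = grouped_data(X, y, part, site)
        spec = MixedModelSpec(feature_ids=data.feature_ids, covariates=())
        base = refit_glmm(spec, data, data.feature_ids)

        hits = total = 0
        sd_part = np.sqrt(base.sigma2.get("participant_id", 0.0))
        for rep in range(8):
            rr = np.random.default_rng(100 + rep)
            b = rr.normal(0, sd_part, 100)
            eta_rep = (
                base.coefficients["(intercept)"]
                + X @ base.feature_coefs.to_numpy()
                + b[part]
            )
            y_rep = (rr.random(n) < 1 / (1 + np.exp(-eta_rep))).astype(float)
            data_rep = grouped_data(X, y_rep, part, site)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = refit_glmm(spec, data_rep, data.feature_ids)
            for name in ["(intercept)"] + data.feature_ids:
                total += 1
                err = abs(fit.coefficients[name] - base.coefficients[name])
                hits += err <= 2.0 * fit.se[name] + 1e-12
        assert hits / total >= 0.9


class TestBuildModelData:
    def test_covariate_encoding_and_grouping(self, meta6, counts6):
        from polyomic.preprocess import clr_transform

        proc = clr_transform(counts6, 0.5)
        spec = MixedModelSpec(feature_ids=proc.feature_ids)
        data = build_model_data(proc, meta6, spec)
        assert data.covariate_names[0] == "(intercept)"
        assert "age" in data.covariate_names
        assert any(c.startswith("sex[") for c in data.covariate_names)
        assert set(data.groups) == {"site", "participant_id"}
        assert len(data.y) == len(meta6.sample_ids)

    def test_encoder_reused_for_new_samples(self, meta6, counts6):
        from polyomic.penalized_glmm import CovariateEncoder

        enc = CovariateEncoder(["age", "sex", "race"]).fit(
            meta6.data.set_index("sample_id")
        )
        new = meta6.data.iloc[:2].copy()
        new["race"] = "Martian"  # unseen level maps to all-zero dummies
        out = enc.transform(new.set_index("sample_id"))
        assert list(out.columns) == enc.columns_
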