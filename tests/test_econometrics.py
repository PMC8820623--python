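import numpy as np
import pandas as pd
import pytest

from agridiet.econometrics import (
    DesignSpec,
    default_design,
    liml_fit,
    ols_fit,
    run_models,
    standardized_coefficient,
    wealth_index,
)


def iv_frame(rng, n=200, pi=0.5, rho=0.6, n_instruments=2, beta=0.5):
    """Simple linear IV data with known structure."""
    Z = rng.normal(size=(n, n_instruments))
    u = rng.normal(size=n)
    eps = rho * u + np.sqrt(1 - rho**2) * rng.normal(size=n)
    w = rng.normal(size=n)
    x = pi * Z.sum(axis=1) + 0.3 * w + u
    y = 1.0 + beta * x + 0.2 * w + eps
    df = pd.DataFrame(Z, columns=[f"z{i}" for i in range(n_instruments)])
    df["x"], df["y"], df["w"] = x, y, w
    return df


class TestWealthIndex:
    def test_monotone_in_perfectly_correlated_assets(self):
        assets = pd.DataFrame({"a": [0, 0, 1, 1, 1], "b": [0, 0, 1, 1, 1],
                               "c": [0, 1, 0, 1, 1]})
        w = wealth_index(assets)
        # richer asset profiles never score lower
        order = assets.sum(axis=1).argsort()
        assert (np.diff(w.iloc[order]) >= -1e-9).all()

    def test_rescaled_to_0_100(self):
        rng = np.random.default_rng(0)
        assets = pd.DataFrame(rng.integers(0, 2, size=(50, 5)))
        w = wealth_index(assets)
        assert w.min() == pytest.approx(0.0)
        assert w.max() == pytest.approx(100.0)

    def test_matches_eigendecomposition_oracle(self):
        assets = pd.DataFrame(
            {"a": [1.0, 0.0, 1.0, 0.0], "b": [1.0, 0.0, 1.0, 1.0],
             "c": [0.8, 0.1, 0.9, 0.3]}
        )
        X = (assets - assets.mean()) / assets.std(ddof=1)
        cov = np.cov(X.T, ddof=1)
        vals, vecs = np.linalg.eigh(cov)
        pc1 = X.values @ vecs[:, -1]
        expected = 100 * (pc1 - pc1.min()) / (pc1.max() - pc1.min())
        got = wealth_index(assets).to_numpy()
        if not np.allclose(got, expected, atol=1e-8):
            expected = expected.max() - expected  # sign flip
        assert np.allclose(got, expected, atol=1e-8)

    def test_constant_column_dropped(self):
        assets = pd.DataFrame({"a": [1, 1, 1, 1], "b": [0, 1, 0, 1], "c": [1, 0, 1, 0]})
        w = wealth_index(assets)
        assert len(w) == 4


class TestOLS:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = 2.0 + 3.0 * X["a"] - 1.5 * X["b"]
        res = ols_fit(y, X)
        assert res.params["const"] == pytest.approx(2.0)
        assert res.params["a"] == pytest.approx(3.0)
        assert res.params["b"] == pytest.approx(-1.5)
        assert np.abs(res.resid).max() < 1e-10

    def test_intercept_only_is_mean(self):
        y = pd.Series([1.0, 2.0, 6.0])
        res = ols_fit(y, pd.DataFrame(index=y.index))
        assert res.params["const"] == pytest.approx(3.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        y = rng.normal(size=20)
        res = ols_fit(y, X)
        Xm = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_collinear_column_named(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "twice_a": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="twice_a"):
            ols_fit(pd.Series([1.0, 2, 3, 4]), X)


class TestStandardizedCoefficient:
    def test_direct(self):
        assert standardized_coefficient(2.0, 1.5, 3.0) == pytest.approx(1.0)

    def test_zero_beta(self):
        assert standardized_coefficient(0.0, 5.0, 1.0) == 0.0

    def test_zero_sdy_rejected(self):
        with pytest.raises(ValueError):
            standardized_coefficient(1.0, 1.0, 0.0)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        y = 0.7 * x + rng.normal(size=100)
        df = pd.DataFrame({"x": x})
        b = float(ols_fit(y, df).params["x"])
        sb = standardized_coefficient(b, x.std(ddof=1), y.std(ddof=1))
        df2 = pd.DataFrame({"x": 10 * x})
        b2 = float(ols_fit(y, df2).params["x"])
        sb2 = standardized_coefficient(b2, (10 * x).std(ddof=1), y.std(ddof=1))
        assert sb == pytest.approx(sb2)


def oracle_liml(df, spec):
    """Independent LIML oracle: explicit projection matrices, eigenvalue of
    the inverted pencil, then the k-class formula."""
    y = df[spec.outcome].to_numpy()
    Y2 = df[[spec.endogenous]].to_numpy()
    n = len(y)
    X = np.column_stack([np.ones(n), df[list(spec.included_exogenous)].to_numpy()])
    Z = np.column_stack([X, df[list(spec.excluded_instruments)].to_numpy()])
    P = lambda A: A @ np.linalg.pinv(A.T @ A) @ A.T
    MX, MZ = np.eye(n) - P(X), np.eye(n) - P(Z)
    W = np.column_stack([y, Y2])
    kappa = np.min(np.real(np.linalg.eigvals(
        np.linalg.inv(W.T @ MZ @ W) @ (W.T @ MX @ W)
    )))
    R = np.column_stack([Y2, X])
    A = R.T @ (np.eye(n) - kappa * MZ) @ R
    b = np.linalg.solve(A, R.T @ (np.eye(n) - kappa * MZ) @ y)
    return kappa, b


class TestLIML:
    def test_just_identified_equals_2sls_kappa_one(self):
        rng = np.random.default_rng(4)
        df = iv_frame(rng, n_instruments=1)
        spec = DesignSpec("y", "x", ("w",), ("z0",))
        fit = liml_fit(spec, df)
        assert fit.kappa == pytest.approx(1.0, abs=1e-8)
        # manual 2SLS: (Z'R)^-1 Z'y in the just-identified case
        n = len(df)
        R = np.column_stack([df["x"], np.ones(n), df["w"]])
        Z = np.column_stack([np.ones(n), df["w"], df["z0"]])
        b = np.linalg.solve(Z.T @ R, Z.T @ df["y"])
        assert np.allclose(fit.params.to_numpy(), b, atol=1e-8)
        assert fit.overid_df == 0
        assert np.isnan(fit.overid_stat)

    def test_overidentified_matches_oracle_n40(self):
        rng = np.random.default_rng(1234)
        df = iv_frame(rng, n=40, n_instruments=3)
        spec = DesignSpec("y", "x", ("w",), ("z0", "z1", "z2"))
        fit = liml_fit(spec, df)
        kappa, b = oracle_liml(df, spec)
        assert fit.kappa == pytest.approx(kappa, abs=1e-8)
        assert np.allclose(fit.params.to_numpy(), b, atol=1e-8)
        assert fit.kappa > 1.0

    def test_underidentified_spec_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec("y", "x", ("w",), ())

    def test_sandwich_close_to_classical_when_homoskedastic(self):
        rng = np.random.default_rng(5)
        df = iv_frame(rng, n=1000, n_instruments=2)
        spec = DesignSpec("y", "x", ("w",), ("z0", "z1"))
        fit = liml_fit(spec, df)
        # classical (homoskedastic) k-class covariance on the same fit
        n = len(df)
        R = np.column_stack([df["x"], np.ones(n), df["w"]])
        Z = np.column_stack([np.ones(n), df["w"], df["z0"], df["z1"]])
        MZ = np.eye(n) - Z @ np.linalg.pinv(Z.T @ Z) @ Z.T
        Rt = (np.eye(n) - fit.kappa * MZ) @ R
        e = df["y"].to_numpy() - R @ fit.params.to_numpy()
        s2 = e @ e / (n - 3)
        V = s2 * np.linalg.inv(R.T @ Rt)
        classical = np.sqrt(np.diag(V))
        assert np.allclose(fit.bse.to_numpy(), classical, rtol=0.05)

    def test_cragg_donald_equals_first_stage_t_squared(self):
        rng = np.random.default_rng(6)
        df = iv_frame(rng, n=150, n_instruments=1)
        spec = DesignSpec("y", "x", ("w",), ("z0",))
        fit = liml_fit(spec, df)
        import statsmodels.api as sm

        Xfs = sm.add_constant(df[["w", "z0"]])
        fs = sm.OLS(df["x"], Xfs).fit()  # homoskedastic first stage
        assert fit.cragg_donald_F == pytest.approx(float(fs.tvalues["z0"] ** 2), rel=1e-6)

    def test_underid_statistic_nonnegative(self):
        rng = np.random.default_rng(7)
        df = iv_frame(rng, n=100, n_instruments=2)
        fit = liml_fit(DesignSpec("y", "x", ("w",), ("z0", "z1")), df)
        assert fit.underid_stat >= 0
        assert 0 <= fit.underid_p <= 1

    def test_stock_yogo_reference_reported(self):
        rng = np.random.default_rng(8)
        df = iv_frame(rng, n=120, n_instruments=4)
        fit = liml_fit(DesignSpec("y", "x", ("w",), ("z0", "z1", "z2", "z3")), df)
        assert fit.stock_yogo_reference["default_LIML_size10"] == pytest.approx(5.44)


class TestRunModels:
    def test_five_plus_five_model_rows(self, small_dataset):
        from agridiet.pipeline import build_analysis_frame, production_group_flags, score_dataset

        ds, _ = small_dataset
        analysis = build_analysis_frame(ds)
        scores = score_dataset(ds)
        tables = run_models(analysis, scores["diet"], production_group_flags(ds))
        assert len(tables["table3"]) == 5
        assert len(tables["table4"]) == 5
        assert len(tables["diagnostics"]) == 5
        assert len(tables["table2"]) == 11  # 10 groups + olive oil
        assert set(tables["table3"]["index"]) == {"pdi", "sdi", "gpdi", "gsdi", "nfd"}
        assert "orientation_comparison" in tables
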