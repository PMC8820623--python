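"""OLS and LIML instrumental-variable estimation with weak-instrument
diagnostics, plus the asset-based wealth index.

The structural equation regresses a woman's annual WDDS-10 on one (endogenous)
farm production-diversity index and exogenous woman, household and market
covariates. Production diversity is instrumented by agro-climatic zone
dummies and farm seniority. LIML is the k-class estimator with k set to the
smallest root kappa of det(W'M_X W - kappa W'M_Z W) = 0, where W = [y,
endogenous], M_X annihilates the included exogenous regressors and M_Z
annihilates the full instrument set; kappa >= 1, and in a just-identified
model kappa = 1 so LIML coincides with 2SLS. Standard errors are
heteroskedasticity-robust (Huber-White sandwich, HC1 small-sample scaling).

Diagnostics mirror the usual IV battery: Anderson canonical-correlation LM
test of underidentification, the Cragg-Donald minimum-eigenvalue F compared
against Stock-Yogo critical values, and Sargan / robust Hansen J tests of
the overidentifying restrictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats

from .reference_data import StockYogoNotTabulated, stock_yogo_lookup, stock_yogo_row

PRODUCTION_INDICES = ("pdi", "sdi", "gpdi", "gsdi", "nfd")

#: Eq-5 covariate blocks (analysis-frame column names).
WOMAN_BLOCK = (
    "woman_age", "edu_primary", "edu_secondary", "edu_superior",
    "domestic_hours", "responsibility", "nonfarm_income",
    "offfarm_ag_income", "onfarm_activity",
)
HOUSEHOLD_BLOCK = ("head_age", "household_size", "wealth_score")
MARKET_BLOCK = ("hamdi", "nearest_market_km")
ZONE_DUMMIES = ("zone_cool_semiarid_N", "zone_upper_arid_mild_E", "zone_lower_arid_mild_S")
INSTRUMENTS = ZONE_DUMMIES + ("seniority_years",)


@dataclass(frozen=True)
class DesignSpec:
    outcome: str
    endogenous: str
    included_exogenous: tuple[str, ...]
    excluded_instruments: tuple[str, ...]
    add_constant: bool = True

    def __post_init__(self):
        overlap = set(self.included_exogenous) & set(self.excluded_instruments)
        if overlap:
            raise ValueError(f"columns in both instrument and included sets: {sorted(overlap)}")
        if self.endogenous in self.included_exogenous:
            raise ValueError("endogenous regressor cannot be in the included set")
        if not self.excluded_instruments:
            raise ValueError("at least one excluded instrument is required")


def default_design(index: str = "pdi") -> DesignSpec:
    """The full adjusted model for one production-diversity index."""
    if index not in PRODUCTION_INDICES:
        raise ValueError(f"unknown production index {index!r}")
    return DesignSpec(
        outcome="annual_wdds",
        endogenous=index,
        included_exogenous=WOMAN_BLOCK + HOUSEHOLD_BLOCK + MARKET_BLOCK,
        excluded_instruments=INSTRUMENTS,
    )


@dataclass
class IVFitResult:
    params: pd.Series
    bse: pd.Series
    kappa: float
    nobs: int
    endogenous: str
    underid_stat: float
    underid_p: float
    cragg_donald_F: float
    stock_yogo_reference: dict[str, float]
    sargan_stat: float
    sargan_p: float
    overid_stat: float  # Hansen J (headline)
    overid_p: float
    overid_df: int
    std_beta1: float
    cov_params: pd.DataFrame = field(repr=False, default=None)

    @property
    def beta1(self) -> float:
        return float(self.params[self.endogenous])

    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def pvalues(self) -> pd.Series:
        z = np.abs(self.params / self.bse)
        return pd.Series(2 * stats.norm.sf(z), index=self.params.index)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

import logging

log = logging.getLogger("agridiet.econometrics")


def _drop_constant(data: pd.DataFrame, cols: tuple[str, ...], role: str) -> tuple[str, ...]:
    """Remove zero-variance columns (a rare flag can be empty in a small
    sample); they are indistinguishable from the constant."""
    keep, dropped = [], []
    for c in cols:
        (keep if data[c].nunique() > 1 else dropped).append(c)
    if dropped:
        log.warning("dropping constant %s column(s): %s", role, dropped)
    return tuple(keep)


def _matrix(data: pd.DataFrame, cols: tuple[str, ...], add_constant: bool) -> tuple[np.ndarray, list[str]]:
    X = data[list(cols)].to_numpy(dtype=float)
    names = list(cols)
    if add_constant:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["const"] + names
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify offending columns by greedy QR elimination
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _residual_maker(A: np.ndarray):
    """Return a function computing M_A v = v - A (A'A)^+ A'v via least squares."""
    def annihilate(V: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(A, V, rcond=None)
        return V - A @ coef
    return annihilate


def wealth_index(assets: pd.DataFrame) -> pd.Series:
    """Asset-based wealth score: first principal component of the
    standardized asset indicators, affinely rescaled to [0, 100].

    Constant asset columns are dropped (they carry no information). The
    component sign is fixed so that more assets means a higher score.
    """
    if assets.shape[1] < 2 or assets.shape[0] < 3:
        raise ValueError("need >= 2 asset indicators and >= 3 households")
    X = assets.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any() or keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant asset indicators")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # first PC from the SVD of the standardized matrix
    _, _, vt = np.linalg.svd(Xs, full_matrices=False)
    pc1 = Xs @ vt[0]
    total = Xs.sum(axis=1)
    if float((pc1 - pc1.mean()) @ (total - total.mean())) < 0:
        pc1 = -pc1
    lo, hi = pc1.min(), pc1.max()
    if hi == lo:
        raise ValueError("degenerate wealth index (no variation)")
    return pd.Series(100.0 * (pc1 - lo) / (hi - lo), index=assets.index, name="wealth_score")


def ols_fit(y: np.ndarray | pd.Series, X: pd.DataFrame, add_constant: bool = True):
    """OLS with HC1 (Huber-White) standard errors; statsmodels results object."""
    if len(X.columns):
        X = X[list(_drop_constant(X, tuple(X.columns), "regressor"))]
    Xm = sm.add_constant(X, has_constant="add") if add_constant else X
    _check_rank(np.asarray(Xm, dtype=float), list(Xm.columns))
    return sm.OLS(np.asarray(y, dtype=float), Xm).fit(cov_type="HC1")


def standardized_coefficient(beta1: float, sd_x: float, sd_y: float) -> float:
    """Scale-free slope: beta1 * sd_x / sd_y."""
    if sd_y <= 0:
        raise ValueError("sd_y must be positive")
    return beta1 * sd_x / sd_y


# ---------------------------------------------------------------------------
# LIML and diagnostics
# ---------------------------------------------------------------------------

def _liml_kappa(y: np.ndarray, Y2: np.ndarray, X: np.ndarray, Z: np.ndarray) -> float:
    W = np.column_stack([y, Y2])
    MX, MZ = _residual_maker(X), _residual_maker(Z)
    A = W.T @ MX(W)
    B = W.T @ MZ(W)
    eigs = linalg.eigvals(A, B)
    eigs = np.real(eigs[np.isfinite(eigs)])
    return float(np.min(eigs))


def liml_fit(spec: DesignSpec, data: pd.DataFrame) -> IVFitResult:
    """LIML estimate of the structural equation with robust (HC1) sandwich
    standard errors and the full diagnostic battery."""
    y = data[spec.outcome].to_numpy(dtype=float)
    Y2 = data[[spec.endogenous]].to_numpy(dtype=float)
    incl = _drop_constant(data, spec.included_exogenous, "included exogenous")
    excl = _drop_constant(data, spec.excluded_instruments, "instrument")
    if not excl:
        raise ValueError("all excluded instruments are constant in this sample")
    X, x_names = _matrix(data, incl, spec.add_constant)
    Zx, _ = _matrix(data, excl, add_constant=False)
    Z = np.column_stack([X, Zx])
    n = len(y)
    m = Y2.shape[1]
    L = Zx.shape[1]
    if L < m:
        raise ValueError("underidentified: fewer excluded instruments than endogenous regressors")
    _check_rank(Z, x_names + list(excl))
    if n <= Z.shape[1] + m:
        raise ValueError("not enough observations for the instrument set")

    kappa = _liml_kappa(y, Y2, X, Z)
    if kappa < 1 - 1e-8:
        raise FloatingPointError(f"LIML kappa {kappa} < 1; numerical failure")
    kappa = max(kappa, 1.0)

    R = np.column_stack([Y2, X])
    r_names = [spec.endogenous] + x_names
    MZ = _residual_maker(Z)
    Rt = R - kappa * MZ(R)          # (I - kappa M_Z) R
    yt = y - kappa * MZ(y[:, None])[:, 0]
    Ainv = np.linalg.inv(R.T @ Rt)
    beta = Ainv @ (R.T @ yt)
    e = y - R @ beta

    p = R.shape[1]
    meat = (Rt * (e**2)[:, None]).T @ Rt
    V = Ainv @ meat @ Ainv.T * (n / (n - p))
    bse = np.sqrt(np.diag(V))

    # --- diagnostics on the first stage ---------------------------------
    MX = _residual_maker(X)
    Y2x = MX(Y2)
    Y2z = MZ(Y2)
    S_mx = Y2x.T @ Y2x
    S_mz = Y2z.T @ Y2z
    diff = S_mx - S_mz  # Y2'(P_Z - P_X)Y2
    K = Z.shape[1]
    cd_eigs = np.real(linalg.eigvals(diff, S_mz))
    cragg_donald = float(np.min(cd_eigs)) * (n - K) / L
    lm_eigs = np.real(linalg.eigvals(diff, S_mx))  # canonical correlations^2
    underid_stat = float(n * np.min(lm_eigs))
    underid_df = L - m + 1
    underid_p = float(stats.chi2.sf(underid_stat, underid_df))

    # --- overidentification ---------------------------------------------
    overid_df = L - m
    if overid_df > 0:
        # Sargan: n R^2 of IV residuals on the full instrument set
        ez = _residual_maker(Z)(e[:, None])[:, 0]
        sargan = float(n * (1 - (ez @ ez) / (e @ e)))
        sargan_p = float(stats.chi2.sf(sargan, overid_df))
        # Hansen J: minimized two-step GMM criterion (first-step weight from
        # the consistent LIML residuals)
        S = (Z * (e**2)[:, None]).T @ Z
        Si = np.linalg.pinv(S)  # robust to near-singular weights at small n
        ZR, Zy = Z.T @ R, Z.T @ y
        SiZR = Si @ ZR
        b_gmm, *_ = np.linalg.lstsq(ZR.T @ SiZR, SiZR.T @ Zy, rcond=None)
        g = Z.T @ (y - R @ b_gmm)
        j_stat = float(g @ Si @ g)
        j_p = float(stats.chi2.sf(j_stat, overid_df))
    else:
        sargan = sargan_p = j_stat = j_p = float("nan")

    try:
        sy = {
            "default_LIML_size10": stock_yogo_lookup("LIML", "size10", m, L),
            **{f"{est}_{crit}": v
               for est in ("LIML", "TSLS")
               for crit, v in stock_yogo_row(est, m, L).items()},
        }
    except StockYogoNotTabulated:
        sy = {}

    sd_x = float(np.std(Y2[:, 0], ddof=1))
    sd_y = float(np.std(y, ddof=1))
    params = pd.Series(beta, index=r_names)
    return IVFitResult(
        params=params,
        bse=pd.Series(bse, index=r_names),
        kappa=float(kappa),
        nobs=n,
        endogenous=spec.endogenous,
        underid_stat=underid_stat,
        underid_p=underid_p,
        cragg_donald_F=cragg_donald,
        stock_yogo_reference=sy,
        sargan_stat=sargan,
        sargan_p=sargan_p,
        overid_stat=j_stat,
        overid_p=j_p,
        overid_df=overid_df,
        std_beta1=standardized_coefficient(float(params[spec.endogenous]), sd_x, sd_y),
        cov_params=pd.DataFrame(V, index=r_names, columns=r_names),
    )


def cragg_donald_F(spec: DesignSpec, data: pd.DataFrame) -> float:
    return liml_fit(spec, data).cragg_donald_F


def underid_test(spec: DesignSpec, data: pd.DataFrame) -> tuple[float, float]:
    fit = liml_fit(spec, data)
    return fit.underid_stat, fit.underid_p


def overid_test(spec: DesignSpec, data: pd.DataFrame) -> tuple[float, float] | None:
    """Hansen J (robust) statistic and p-value; None when just-identified."""
    fit = liml_fit(spec, data)
    if fit.overid_df == 0:
        return None
    return fit.overid_stat, fit.overid_p


def _stars(p: float) -> str:
    return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""


def run_models(
    analysis: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    production_flags: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Fit, for each of the five production-diversity indices, the simple
    OLS model and the full adjusted LIML model, with diagnostics.

    ``analysis`` is the tidy per-woman frame carrying the outcome, the five
    indices, all Eq-5 covariates and the instruments. If per-woman
    consumption ``scores`` and per-farm ``production_flags`` are given, the
    producing-vs-not comparison and the orientation Kruskal-Wallis block
    are appended.
    """
    simple_rows, full_rows, diag_rows = [], [], []
    sd_y = analysis["annual_wdds"].std(ddof=1)
    for index in PRODUCTION_INDICES:
        res = ols_fit(analysis["annual_wdds"], analysis[[index]])
        b1 = float(res.params[index])
        simple_rows.append(
            {
                "index": index,
                "beta1": b1,
                "se": float(res.bse[index]),
                "p_value": float(res.pvalues[index]),
                "stars": _stars(float(res.pvalues[index])),
                "std_beta1": standardized_coefficient(
                    b1, analysis[index].std(ddof=1), sd_y
                ),
                "constant": float(res.params["const"]),
            }
        )
        fit = liml_fit(default_design(index), analysis)
        pvals = fit.pvalues()
        row = {"index": index, "beta1": fit.beta1, "se": float(fit.bse[index]),
               "p_value": float(pvals[index]), "stars": _stars(float(pvals[index])),
               "std_beta1": fit.std_beta1, "kappa": fit.kappa}
        for name in fit.params.index:
            if name != index:
                row[f"b_{name}"] = float(fit.params[name])
        full_rows.append(row)
        diag_rows.append(
            {
                "index": index,
                "underid_stat": fit.underid_stat,
                "underid_p": fit.underid_p,
                "cragg_donald_F": fit.cragg_donald_F,
                "stock_yogo_liml_size10": fit.stock_yogo_reference.get("default_LIML_size10", np.nan),
                "hansen_j": fit.overid_stat,
                "hansen_j_p": fit.overid_p,
                "sargan": fit.sargan_stat,
                "sargan_p": fit.sargan_p,
                "overid_df": fit.overid_df,
            }
        )
    out = {
        "table3": pd.DataFrame(simple_rows),
        "table4": pd.DataFrame(full_rows),
        "diagnostics": pd.DataFrame(diag_rows),
    }
    if scores is not None and production_flags is not None:
        from .diet_diversity import producing_vs_not

        out["table2"] = producing_vs_not(scores, production_flags)
    if "orientation" in analysis.columns:
        groups = [g["annual_wdds"].to_numpy() for _, g in analysis.groupby("orientation")]
        if len(groups) > 1:
            kw_stat, kw_p = stats.kruskal(*groups)
        else:
            kw_stat, kw_p = np.nan, np.nan
        out["orientation_comparison"] = pd.DataFrame(
            [
                {
                    "orientation": name,
                    "n": len(g),
                    "mean_annual_wdds": g["annual_wdds"].mean(),
                    "kruskal_stat": kw_stat,
                    "kruskal_p": kw_p,
                }
                for name, g in analysis.groupby("orientation")
            ]
        )
    return out
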