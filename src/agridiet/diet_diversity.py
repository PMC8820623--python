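"""Women's dietary-diversity scoring from quarterly 24-hour recalls.

Each woman contributes four seasonal recalls. A seasonal WDDS-10 counts the
scorable MDD-W food groups consumed (olive oil never counts); the annual
WDDS-10 is the mean of the four seasonal scores; MDD-W is reached at an
annual score of five or more groups. Per-group annual consumption scores
take values {0, 0.25, 0.5, 0.75, 1} = consuming recalls / 4.

Seasonal comparisons follow the survey conventions: a generalized
Cochran-Mantel-Haenszel test (women as strata) for per-group consumer
percentages across the four seasons, and paired Wilcoxon signed-rank tests
for pairwise seasonal WDDS-10 contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .reference_data import SCORABLE_GROUPS, FoodGroup

SEASONS = ("autumn", "winter", "spring", "summer")
MDDW_THRESHOLD = 5.0


@dataclass(frozen=True)
class Recall:
    woman_id: str
    season: str
    consumed_groups: frozenset[FoodGroup]
    olive_oil_consumed: bool = False

    def __post_init__(self):
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        if any(not g.scorable for g in self.consumed_groups):
            raise ValueError("consumed_groups may not contain UNCLASSIFIED")


@dataclass(frozen=True)
class DietScores:
    woman_id: str
    seasonal_wdds: dict[str, int]
    annual_wdds: float
    mddw: bool
    consumption_scores: dict[str, float]  # per group name + "olive_oil"


def wdds10(recall: Recall) -> int:
    """Seasonal WDDS-10: count of distinct scorable groups consumed."""
    return len(recall.consumed_groups)


def _check_four_seasons(recalls: list[Recall]) -> dict[str, Recall]:
    by_season = {r.season: r for r in recalls}
    if len(recalls) != 4 or set(by_season) != set(SEASONS):
        missing = sorted(set(SEASONS) - {r.season for r in recalls})
        raise ValueError(
            f"need exactly one recall per season; missing/duplicated: {missing or 'duplicates'}"
        )
    return by_season


def annual_wdds(recalls: list[Recall]) -> float:
    """Annual WDDS-10: mean of the four seasonal scores."""
    by_season = _check_four_seasons(recalls)
    return float(np.mean([wdds10(by_season[s]) for s in SEASONS]))


def mddw_flag(recalls: list[Recall], threshold: float = MDDW_THRESHOLD) -> bool:
    """Minimum dietary diversity: annual WDDS-10 of five or more groups."""
    return annual_wdds(recalls) >= threshold


def consumption_score(recalls: list[Recall], group: FoodGroup | str) -> float:
    """Fraction of the four recalls in which the group (or olive oil) appears."""
    by_season = _check_four_seasons(recalls)
    if isinstance(group, str) and group == "olive_oil":
        hits = sum(by_season[s].olive_oil_consumed for s in SEASONS)
    else:
        if not isinstance(group, FoodGroup) or not group.scorable:
            raise ValueError(f"not a scorable group: {group!r}")
        hits = sum(group in by_season[s].consumed_groups for s in SEASONS)
    return hits / 4.0


def score_woman(recalls: list[Recall]) -> DietScores:
    by_season = _check_four_seasons(recalls)
    seasonal = {s: wdds10(by_season[s]) for s in SEASONS}
    annual = float(np.mean(list(seasonal.values())))
    scores = {g.value: consumption_score(recalls, g) for g in SCORABLE_GROUPS}
    scores["olive_oil"] = consumption_score(recalls, "olive_oil")
    return DietScores(
        woman_id=recalls[0].woman_id,
        seasonal_wdds=seasonal,
        annual_wdds=annual,
        mddw=annual >= MDDW_THRESHOLD,
        consumption_scores=scores,
    )


# ---------------------------------------------------------------------------
# Tabular interface (recalls frame: woman_id, season, one 0/1 column per
# group, olive_oil)
# ---------------------------------------------------------------------------

GROUP_COLUMNS = tuple(g.value for g in SCORABLE_GROUPS)


def recalls_to_frame(recalls: list[Recall]) -> pd.DataFrame:
    rows = []
    for r in recalls:
        row = {"woman_id": r.woman_id, "season": r.season}
        for g in SCORABLE_GROUPS:
            row[g.value] = int(g in r.consumed_groups)
        row["olive_oil"] = int(r.olive_oil_consumed)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_recalls(frame: pd.DataFrame) -> list[Recall]:
    recalls = []
    for r in frame.itertuples():
        groups = frozenset(g for g in SCORABLE_GROUPS if getattr(r, g.value))
        recalls.append(Recall(str(r.woman_id), r.season, groups, bool(r.olive_oil)))
    return recalls


def score_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-woman scores from a recalls frame (one row per woman)."""
    out = []
    for wid, sub in frame.groupby("woman_id", sort=True):
        sc = score_woman(frame_to_recalls(sub))
        row = {"woman_id": wid}
        row.update({f"wdds_{s}": sc.seasonal_wdds[s] for s in SEASONS})
        row["annual_wdds"] = sc.annual_wdds
        row["mddw"] = int(sc.mddw)
        row.update({f"cs_{k}": v for k, v in sc.consumption_scores.items()})
        out.append(row)
    return pd.DataFrame(out)


def seasonal_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Percent of women consuming each group per season, plus per-season
    WDDS-10 mean and SD."""
    rows = []
    wdds = frame[list(GROUP_COLUMNS)].sum(axis=1)
    for season in SEASONS:
        mask = frame["season"] == season
        sub = frame[mask]
        for col in GROUP_COLUMNS + ("olive_oil",):
            rows.append(
                {
                    "season": season,
                    "group": col,
                    "pct_consumers": 100.0 * sub[col].mean(),
                }
            )
        rows.append(
            {"season": season, "group": "WDDS10_mean", "pct_consumers": np.nan,
             "wdds_mean": wdds[mask].mean(), "wdds_sd": wdds[mask].std(ddof=1)}
        )
    return pd.DataFrame(rows)


def cmh_test(binary_by_season: pd.DataFrame) -> tuple[float, float, int]:
    """Generalized Cochran-Mantel-Haenszel test of association between
    season and a binary consumption outcome, stratified by woman.

    Parameters
    ----------
    binary_by_season : frame indexed by woman with one 0/1 column per season.

    Returns
    -------
    (statistic, p_value, n_dropped) where n_dropped counts degenerate
    strata (women consuming in all four seasons or none) that carry no
    information and are excluded.

    Notes
    -----
    With one observation per season per stratum this is the classic
    repeated-binary design; the statistic is T' V^-1 T over the first
    S-1 seasons with multivariate-hypergeometric stratum covariances,
    chi-square with S-1 degrees of freedom.
    """
    X = binary_by_season[list(SEASONS)].to_numpy(dtype=float)
    m = X.sum(axis=1)
    keep = (m > 0) & (m < 4)
    n_dropped = int((~keep).sum())
    X = X[keep]
    m = m[keep]
    S = 4
    if X.shape[0] == 0:
        return 0.0, 1.0, n_dropped
    # per-stratum expectation m/4 per season; hypergeometric covariance
    T = (X - m[:, None] / S)[:, : S - 1].sum(axis=0)
    w = m * (S - m) / (S * S * (S - 1))  # variance weight per stratum
    V = np.sum(w) * (S * np.eye(S - 1) - np.ones((S - 1, S - 1)))
    stat = float(T @ np.linalg.solve(V, T))
    p = float(stats.chi2.sf(stat, df=S - 1))
    return stat, p, n_dropped


def seasonal_tests(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-group CMH tests across seasons and pairwise paired Wilcoxon
    signed-rank comparisons of seasonal WDDS-10."""
    wide = {}
    for col in GROUP_COLUMNS + ("olive_oil",):
        wide[col] = frame.pivot(index="woman_id", columns="season", values=col)
    cmh_rows = []
    for col, tab in wide.items():
        stat, p, dropped = cmh_test(tab)
        cmh_rows.append({"group": col, "cmh_stat": stat, "p_value": p,
                         "n_degenerate_dropped": dropped})

    wdds_col = frame[list(GROUP_COLUMNS)].sum(axis=1)
    wdds = frame[["woman_id", "season"]].assign(wdds=wdds_col).pivot(
        index="woman_id", columns="season", values="wdds"
    )
    pair_rows = []
    for a, b in combinations(SEASONS, 2):
        diff = wdds[a] - wdds[b]
        if np.allclose(diff, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(wdds[a], wdds[b], zero_method="wilcox")
        pair_rows.append({"season_a": a, "season_b": b,
                          "mean_a": wdds[a].mean(), "mean_b": wdds[b].mean(),
                          "wilcoxon_stat": float(stat), "p_value": float(p)})
    return {"cmh": pd.DataFrame(cmh_rows), "pairwise_wdds": pd.DataFrame(pair_rows)}


def producing_vs_not(
    scores: pd.DataFrame, production_flags: pd.DataFrame
) -> pd.DataFrame:
    """Annual consumption score of each food group (plus olive oil) among
    women on farms producing vs not producing that group.

    Both an independent-samples rank-sum (Mann-Whitney) test and a
    signed-rank-style comparison are reported; the survey tables label this
    contrast a signed-rank test although the two groups are independent, so
    the rank-sum p-value is the headline.
    """
    merged = scores.merge(production_flags, on="woman_id", how="inner")
    rows = []
    for col in GROUP_COLUMNS + ("olive_oil",):
        flag = f"produces_{col}"
        cs = f"cs_{col}"
        prod = merged.loc[merged[flag] == 1, cs]
        nonprod = merged.loc[merged[flag] == 0, cs]
        if len(prod) == 0 or len(nonprod) == 0:
            u_p = np.nan
        else:
            _, u_p = stats.mannwhitneyu(prod, nonprod, alternative="two-sided")
        rows.append(
            {
                "group": col,
                "pct_producing": 100.0 * merged[flag].mean(),
                "mean_score_producing": prod.mean() if len(prod) else np.nan,
                "sd_score_producing": prod.std(ddof=1) if len(prod) > 1 else np.nan,
                "mean_score_not": nonprod.mean() if len(nonprod) else np.nan,
                "sd_score_not": nonprod.std(ddof=1) if len(nonprod) > 1 else np.nan,
                "ranksum_p": u_p,
            }
        )
    return pd.DataFrame(rows)
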