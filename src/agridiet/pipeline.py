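"""Orchestration: simulate -> score -> analyze -> report.

`build_analysis_frame` turns a raw dataset into the tidy per-woman frame the
econometric models expect (diet scores, production indices, market access,
wealth index, covariates and instruments). `run_all` writes the full,
reproducible output bundle; `replicate_study` runs the Monte-Carlo recovery
design that underpins the estimator checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diet_diversity, econometrics, market_access, production_diversity
from .synthetic_data import GroundTruth, SimConfig, SyntheticDataset, generate_dataset, write_dataset

log = logging.getLogger("agridiet")

_REF_DENDRO: dict[str, production_diversity.Dendrogram] = {}


def _reference_dendrogram(linkage_method: str) -> production_diversity.Dendrogram:
    if linkage_method not in _REF_DENDRO:
        _REF_DENDRO[linkage_method] = production_diversity.reference_dendrogram(linkage_method)
    return _REF_DENDRO[linkage_method]


@dataclass(frozen=True)
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    linkage_method: str = "average"
    nfd_include_root_path: bool = True
    stock_yogo_estimator: str = "LIML"
    stock_yogo_criterion: str = "size10"
    out_dir: str = "agridiet_run"
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("zone_probs", "zone_effects", "effect_education", "education_probs",
                    "region_center"):
            if key in sim_raw and isinstance(sim_raw[key], list):
                sim_raw[key] = tuple(sim_raw[key])
        return RunConfig(sim=SimConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_dataset(
    dataset: SyntheticDataset,
    linkage_method: str = "average",
    nfd_include_root_path: bool = True,
    compute_nfd: bool = True,
) -> dict[str, pd.DataFrame]:
    """Diet scores, production indices, market access and wealth index."""
    diet = diet_diversity.score_frame(dataset.recalls)

    farms = dataset.farm_objects()
    groups = production_diversity.product_group_map()
    if compute_nfd:
        dendro = _reference_dendrogram(linkage_method)
        prod = production_diversity.score_farms(
            farms, dendro, groups, nfd_include_root_path
        )
    else:
        rows = []
        for f in farms:
            gv = production_diversity._group_values(f, groups)
            rows.append({
                "farm_id": f.farm_id, "household_id": f.household_id,
                "pdi": production_diversity.pdi(f),
                "sdi": production_diversity.sdi(f),
                "gpdi": len(gv),
                "gsdi": (production_diversity.gsdi(f, groups)
                         if sum(gv.values()) > 0 else 0.0),
                "nfd": np.nan,
                "self_consumption_share": production_diversity.self_consumption_share(f),
                "orientation": production_diversity.classify_orientation(f),
                "total_value_usd": f.total_value,
            })
        prod = pd.DataFrame(rows)

    access = market_access.score_households(
        dataset.households[["household_id", "lat", "lon"]], dataset.market_objects()
    )
    asset_cols = [c for c in dataset.households.columns if c.startswith("asset_")]
    wealth = econometrics.wealth_index(
        dataset.households.set_index("household_id")[asset_cols]
    ).rename_axis("household_id").reset_index()
    return {"diet": diet, "production": prod, "access": access, "wealth": wealth}


def production_group_flags(dataset: SyntheticDataset) -> pd.DataFrame:
    """Per-woman 0/1 flags: does her farm produce each food group / olive oil."""
    groups = production_diversity.product_group_map()
    merged = dataset.farm_products.merge(
        dataset.farms[["farm_id", "household_id"]], on="farm_id"
    )
    merged["group"] = merged["product_id"].map(lambda p: groups[p].value)
    rows = {}
    for hid, sub in merged.groupby("household_id"):
        flags = {f"produces_{g}": int((sub["group"] == g).any())
                 for g in diet_diversity.GROUP_COLUMNS}
        flags["produces_olive_oil"] = int((sub["product_id"] == "olive_oil").any())
        rows[hid] = flags
    flags_df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("household_id").reset_index()
    return dataset.women[["woman_id", "household_id"]].merge(flags_df, on="household_id").drop(
        columns="household_id"
    )


def build_analysis_frame(
    dataset: SyntheticDataset,
    linkage_method: str = "average",
    nfd_include_root_path: bool = True,
    compute_nfd: bool = True,
) -> pd.DataFrame:
    """Tidy per-woman frame with outcome, indices, covariates and instruments."""
    scores = score_dataset(dataset, linkage_method, nfd_include_root_path, compute_nfd)
    women = dataset.women.copy()
    for level in ("primary", "secondary", "superior"):
        women[f"edu_{level}"] = (women["education"] == level).astype(int)
    women = women.rename(columns={"age": "woman_age", "domestic_hours": "domestic_hours"})

    farms = dataset.farms.copy()
    for zone in econometrics.ZONE_DUMMIES:
        zname = zone.removeprefix("zone_")
        farms[zone] = (farms["climate_zone"] == zname).astype(int)

    df = (
        women[["woman_id", "household_id", "woman_age", "edu_primary", "edu_secondary",
               "edu_superior", "domestic_hours", "responsibility", "nonfarm_income",
               "offfarm_ag_income", "onfarm_activity"]]
        .merge(scores["diet"][["woman_id", "annual_wdds", "mddw"]], on="woman_id")
        .merge(dataset.households[["household_id", "household_size", "head_age"]],
               on="household_id")
        .merge(scores["wealth"].rename(columns={"wealth_score": "wealth_score"}),
               on="household_id")
        .merge(scores["access"][["household_id", "hamdi", "nearest_market_km"]],
               on="household_id")
        .merge(scores["production"][["household_id", "pdi", "sdi", "gpdi", "gsdi", "nfd",
                                     "orientation", "self_consumption_share"]],
               on="household_id")
        .merge(farms[["household_id", "seniority_years", *econometrics.ZONE_DUMMIES]],
               on="household_id")
    )
    return df


# ---------------------------------------------------------------------------
# descriptives (Table 1 analog)
# ---------------------------------------------------------------------------

def descriptives(analysis: pd.DataFrame) -> pd.DataFrame:
    def med_iqr(s):
        return {"median": s.median(), "q1": s.quantile(0.25), "q3": s.quantile(0.75)}

    rows = []
    add = lambda name, **kw: rows.append({"variable": name, **kw})
    add("annual_wdds", mean=analysis["annual_wdds"].mean(), sd=analysis["annual_wdds"].std(ddof=1))
    add("mddw_pct", pct=100 * analysis["mddw"].mean())
    add("household_size", mean=analysis["household_size"].mean(),
        sd=analysis["household_size"].std(ddof=1))
    add("head_age", mean=analysis["head_age"].mean(), sd=analysis["head_age"].std(ddof=1))
    add("woman_age", mean=analysis["woman_age"].mean(), sd=analysis["woman_age"].std(ddof=1))
    for var in ("seniority_years", "pdi", "sdi", "gpdi", "gsdi", "nfd", "wealth_score",
                "hamdi", "nearest_market_km", "self_consumption_share"):
        add(var, **med_iqr(analysis[var]))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_all(config: RunConfig) -> dict:
    """Simulate, score, analyze and write the reproducible report bundle."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        dataset, truth = generate_dataset(config.sim)
        write_dataset(dataset, out / "dataset", truth)

        stage = "score"
        scores = score_dataset(dataset, config.linkage_method, config.nfd_include_root_path)
        for name, frame in scores.items():
            frame.to_csv(out / f"scores_{name}.csv", index=False)

        stage = "analyze"
        analysis = build_analysis_frame(dataset, config.linkage_method,
                                        config.nfd_include_root_path)
        analysis.to_csv(out / "analysis_frame.csv", index=False)
        flags = production_group_flags(dataset)
        tables = econometrics.run_models(analysis, scores["diet"], flags)

        stage = "report"
        descriptives(analysis).to_csv(out / "table1.csv", index=False)
        tables["table2"].to_csv(out / "table2.csv", index=False)
        tables["table3"].to_csv(out / "table3.csv", index=False)
        tables["table4"].to_csv(out / "table4.csv", index=False)
        tables["orientation_comparison"].to_csv(out / "orientation_comparison.csv", index=False)
        seasonal = diet_diversity.seasonal_summary(dataset.recalls)
        seasonal.to_csv(out / "seasonal_summary.csv", index=False)
        stests = diet_diversity.seasonal_tests(dataset.recalls)
        stests["cmh"].to_csv(out / "seasonal_cmh.csv", index=False)
        stests["pairwise_wdds"].to_csv(out / "seasonal_pairwise_wdds.csv", index=False)
        tables["diagnostics"].to_csv(out / "diagnostics.csv", index=False)
        tables["diagnostics"].set_index("index").to_json(out / "diagnostics.json", indent=1)
        manifest = {
            "seed": config.sim.seed,
            "config_hash": config.config_hash(),
            "n_households": config.sim.n_households,
            "config": config.to_dict(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return manifest


def replicate_study(
    config: SimConfig,
    n_replicates: int,
    indices: tuple[str, ...] = ("pdi",),
    compute_nfd: bool = False,
    estimators: tuple[str, ...] = ("ols", "liml"),
) -> pd.DataFrame:
    """Monte-Carlo replicates of the full pipeline: per replicate and
    production index, the adjusted-model OLS and LIML slope estimates plus
    the IV diagnostic statistics. Replicate seeds derive deterministically
    from config.seed."""
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(config.seed).spawn(n_replicates)]
    rows = []
    for rep, seed in enumerate(seeds):
        cfg = replace(config, seed=seed)
        try:
            dataset, truth = generate_dataset(cfg)
            analysis = build_analysis_frame(dataset, compute_nfd=compute_nfd)
            for index in indices:
                spec = econometrics.default_design(index)
                row = {"replicate": rep, "seed": seed, "index": index,
                       "true_beta1": truth.true_beta1}
                if "ols" in estimators:
                    X = analysis[[index, *spec.included_exogenous]]
                    ols = econometrics.ols_fit(analysis["annual_wdds"], X)
                    row["ols_beta1"] = float(ols.params[index])
                if "liml" in estimators:
                    fit = econometrics.liml_fit(spec, analysis)
                    row.update(
                        liml_beta1=fit.beta1, kappa=fit.kappa,
                        cragg_donald_F=fit.cragg_donald_F,
                        underid_p=fit.underid_p, hansen_j_p=fit.overid_p,
                    )
                rows.append(row)
        except Exception as exc:
            raise RuntimeError(f"replicate {rep} (seed {seed}) failed: {exc}") from exc
    return pd.DataFrame(rows)


def summarize_replicates(reps: pd.DataFrame) -> pd.DataFrame:
    out = []
    for index, sub in reps.groupby("index"):
        row = {"index": index, "n_replicates": len(sub),
               "true_beta1": sub["true_beta1"].iloc[0]}
        for col in ("ols_beta1", "liml_beta1", "cragg_donald_F"):
            if col in sub:
                row[f"median_{col}"] = sub[col].median()
                row[f"q1_{col}"] = sub[col].quantile(0.25)
                row[f"q3_{col}"] = sub[col].quantile(0.75)
        out.append(row)
    return pd.DataFrame(out)
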