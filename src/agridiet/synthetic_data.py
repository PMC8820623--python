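"""Synthetic survey generator for the farm-diversity / dietary-diversity study.

Generates complete, typed survey-style datasets — farms with product
portfolios and monetary values, households, one woman of reproductive age
per household with four quarterly 24-hour recalls, and weekly food markets
on a spatial region — with *known ground truth*: the structural effect of
production diversity on the latent annual dietary-diversity score is a
config parameter, and an unobserved household confounder loads on both
production diversity and diet, making production diversity endogenous by
construction. Agro-climatic zone and farm seniority shift production
diversity but (conditional on the included covariates) not diet, so they
are valid instruments.

Default parameters are calibrated once to the published survey moments of
the Sidi Bouzid study population (mean annual WDDS-10 6.53, spring mean
6.70, household size 5.31, median seniority 25 y, median nearest-market
distance 11.04 km, 81.4% of farms producing the meat group, median HAMDI
1.48) and then frozen; see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special

from .diet_diversity import GROUP_COLUMNS, SEASONS
from .market_access import Market, frame_to_markets, markets_to_frame
from .production_diversity import CLIMATE_ZONES, Farm, ProductHolding
from .reference_data import FoodGroup, load_product_table

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Table-calibrated probability that a farm produces each scorable food
#: group, plus per-product prevalences for the five unclassified products.
DEFAULT_GROUP_PREVALENCES: dict[str, float] = {
    "GRAINS_ROOTS_TUBERS": 0.062,
    "PULSES": 0.021,
    "NUTS_SEEDS": 0.069,
    "DAIRY": 0.197,
    "MEAT_POULTRY_FISH": 0.814,
    "EGGS": 0.317,
    "DARK_GREEN_LEAFY": 0.007,
    "VITA_FRUITS_VEG": 0.038,
    "OTHER_VEG": 0.114,
    "OTHER_FRUITS": 0.007,
}
DEFAULT_UNCLASSIFIED_PREVALENCES: dict[str, float] = {
    "olive_oil": 0.535,
    "table_olive": 0.25,
    "hot_pepper": 0.08,
    "garlic": 0.06,
    "honey": 0.05,
}

#: Within-group product weights used when a group is produced.
WITHIN_GROUP_WEIGHTS: dict[str, dict[str, float]] = {
    "GRAINS_ROOTS_TUBERS": {"wheat": 0.45, "barley": 0.30, "potato": 0.15, "oat": 0.10},
    "PULSES": {"bean": 1.0},
    "NUTS_SEEDS": {"almond": 1.0},
    "DAIRY": {"milk": 1.0},
    "MEAT_POULTRY_FISH": {"sheep_meat": 0.45, "goat_meat": 0.20, "poultry_meat": 0.18,
                          "beef_meat": 0.12, "camel_meat": 0.05},
    "EGGS": {"egg": 1.0},
    "DARK_GREEN_LEAFY": {"chard": 1.0},
    "VITA_FRUITS_VEG": {"carrot": 0.60, "parsley": 0.40},
    "OTHER_VEG": {"tomato": 0.35, "onion": 0.25, "squash": 0.12, "cucumber": 0.12,
                  "pea": 0.08, "fennel": 0.08},
    "OTHER_FRUITS": {"grape": 0.60, "lemon": 0.40},
}

#: Seasonal offsets of the latent dietary score (sum to zero; spring diets
#: are the most diverse, summer the least).
SEASON_OFFSETS: dict[str, float] = {
    "autumn": -0.10, "winter": 0.06, "spring": 0.17, "summer": -0.13,
}

#: Relative sampling weight of each food group when a seasonal recall of a
#: given size is decomposed into concrete groups (grains dominate every
#: diet; nuts/seeds and eggs are rarely consumed).
DIET_GROUP_WEIGHTS: dict[str, float] = {
    "GRAINS_ROOTS_TUBERS": 400.0,
    "MEAT_POULTRY_FISH": 12.0,
    "OTHER_VEG": 25.0,
    "VITA_FRUITS_VEG": 12.0,
    "PULSES": 7.0,
    "OTHER_FRUITS": 5.0,
    "DAIRY": 4.0,
    "DARK_GREEN_LEAFY": 3.0,
    "EGGS": 1.0,
    "NUTS_SEEDS": 0.08,
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator. Defaults are the frozen calibration."""

    seed: int = 0
    n_households: int = 290
    diet_model: str = "LINEAR"  # or "BERNOULLI_GROUPS"

    # structural diet equation (LINEAR mode)
    true_beta1: float = 0.10          # effect of PDI on latent annual WDDS
    diet_intercept: float = 5.989     # calibrated to mean annual WDDS 6.53
    diet_noise_sd: float = 0.85
    season_dev_sd: float = 0.95
    seasonal_correlation: float = 0.3  # within-woman persistence of group tastes

    # endogeneity
    confounder_sd: float = 1.0
    loading_on_diversity: float = 0.35
    loading_on_diet: float = 0.25

    # instruments
    zone_probs: tuple[float, ...] = (0.15, 0.55, 0.20, 0.10)
    zone_effects: tuple[float, ...] = (-0.50, 0.0, 0.36, -0.25)
    seniority_effect: float = 0.78
    seniority_median: float = 25.0
    seniority_log_sd: float = 0.55

    # production portfolio
    production_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PREVALENCES)
    )
    unclassified_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UNCLASSIFIED_PREVALENCES)
    )
    extra_product_rate: float = 0.15   # extra products within a produced group
    diversity_noise_sd: float = 0.30   # idiosyncratic farm propensity noise
    value_median_usd: float = 1960.0
    value_log_sd: float = 1.39
    value_diversity_coef: float = 0.50  # ln-value slope on (PDI - 3)
    invalid_instrument_loading: float = 0.0  # direct seniority -> diet leak (for power studies)

    # covariate effects on diet (latent scale)
    effect_education: tuple[float, float, float] = (0.33, 0.53, 0.96)
    effect_wealth_latent: float = 0.30
    effect_household_size: float = 0.104
    effect_head_age: float = -0.007
    effect_woman_age: float = -0.005
    effect_domestic_hours: float = -0.007
    effect_responsibility: float = 0.09
    effect_nonfarm_income: float = -0.22
    effect_offfarm_ag: float = -0.095
    effect_onfarm: float = -0.02

    # demography
    education_probs: tuple[float, ...] = (0.231, 0.348, 0.310, 0.111)
    household_size_rate: float = 4.31  # size = 1 + Poisson(rate); mean 5.31

    # spatial / markets
    market_count: int = 24
    region_extent_km: float = 111.3    # calibrated to median nearest-market 11.04 km
    region_center: tuple[float, float] = (35.0, 9.4)
    n_market_species: int = 12
    market_entropy_mean: float = 1.48
    market_entropy_sd: float = 0.08

    def validate(self) -> None:
        problems = []
        if self.n_households < 2:
            problems.append("n_households must be >= 2")
        if self.market_count < 2:
            problems.append("market_count must be >= 2 (HAMDI needs two markets)")
        if abs(sum(self.zone_probs) - 1.0) > 1e-9 or min(self.zone_probs) < 0:
            problems.append("zone_probs must be a probability vector summing to 1")
        if len(self.zone_probs) != 4 or len(self.zone_effects) != 4:
            problems.append("zone_probs and zone_effects must have 4 entries")
        for name, p in {**self.production_prevalences, **self.unclassified_prevalences}.items():
            if not 0 <= p <= 1:
                problems.append(f"prevalence {name}={p} outside [0,1]")
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            problems.append("education_probs must sum to 1")
        if self.diet_model not in ("LINEAR", "BERNOULLI_GROUPS"):
            problems.append(f"unknown diet_model {self.diet_model!r}")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class GroundTruth:
    true_beta1: float
    diet_intercept: float
    loading_on_diversity: float
    loading_on_diet: float
    confounder: list[float]
    config: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    farms: pd.DataFrame
    farm_products: pd.DataFrame
    households: pd.DataFrame
    women: pd.DataFrame
    recalls: pd.DataFrame
    markets: pd.DataFrame

    def farm_objects(self) -> list[Farm]:
        """Typed Farm objects for the production_diversity module."""
        by_farm = dict(tuple(self.farm_products.groupby("farm_id", sort=False)))
        out = []
        for r in self.farms.itertuples():
            prods = {
                p.product_id: ProductHolding(
                    p.value_usd, p.frac_sold, p.frac_donated, p.frac_selfconsumed
                )
                for p in by_farm[r.farm_id].itertuples()
            }
            out.append(
                Farm(r.farm_id, r.household_id, prods, r.seniority_years,
                     r.size_ha, r.climate_zone, (r.lat, r.lon))
            )
        return out

    def market_objects(self) -> list[Market]:
        return frame_to_markets(self.markets)


# ---------------------------------------------------------------------------
# calibration helpers
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)


def _propensity_sd(cfg: SimConfig) -> float:
    return float(np.sqrt(
        (cfg.seniority_effect * cfg.seniority_log_sd) ** 2
        + (cfg.loading_on_diversity * cfg.confounder_sd) ** 2
        + cfg.diversity_noise_sd**2
    ))


def _solve_group_intercepts(cfg: SimConfig) -> dict[str, float]:
    """Logit intercepts per (pseudo-)group such that the marginal production
    prevalence *conditional on a non-empty portfolio* (farms without any
    production are excluded from the study population, and the generator
    redraws them) equals the calibrated target exactly.

    The farm diversity propensity is a zone mixture of normals; expectations
    are Gauss-Hermite quadrature, and the empty-portfolio correction is a
    deterministic fixed point (it converges in a handful of iterations
    because the empty probability is only a few percent)."""
    s = _propensity_sd(cfg)
    probs = np.asarray(cfg.zone_probs)
    zeff = np.asarray(cfg.zone_effects)
    zeff = zeff - probs @ zeff  # center so the propensity has mean zero

    # flattened quadrature grid over the zone mixture
    eta_nodes = np.concatenate([mz + s * _GH_NODES for mz in zeff])
    weights = np.concatenate(
        [pz * _GH_WEIGHTS / np.sqrt(2 * np.pi) for pz in probs]
    )

    targets = {**cfg.production_prevalences, **cfg.unclassified_prevalences}
    for name, p in targets.items():
        if not 0 < p < 1:
            raise ValueError(f"prevalence for {name} must be in (0,1), got {p}")

    names = list(targets)
    alphas = {n: float(special.logit(targets[n])) for n in names}
    for _ in range(60):
        p_empty = np.ones_like(eta_nodes)
        for n in names:
            p_empty *= 1.0 - special.expit(alphas[n] + eta_nodes)
        denom = 1.0 - p_empty
        max_move = 0.0
        for n in names:
            def cond_prev(a: float) -> float:
                return float(weights @ (special.expit(a + eta_nodes) / denom))

            new = float(optimize.brentq(
                lambda a: cond_prev(a) - targets[n], -30, 30, xtol=1e-12
            ))
            max_move = max(max_move, abs(new - alphas[n]))
            alphas[n] = new
        if max_move < 1e-10:
            break
    return alphas


def _entropy_vector(target_h: float, k: int, rng: np.random.Generator) -> np.ndarray:
    """A k-species proportion vector with Shannon entropy exactly target_h,
    from the one-dominant-species family, randomly permuted."""
    h_max = np.log(k)
    target_h = float(np.clip(target_h, 1e-6, h_max - 1e-9))

    def ent(a: float) -> float:
        rest = (1 - a) / (k - 1)
        e = -a * np.log(a)
        if rest > 0:
            e -= (1 - a) * np.log(rest)
        return e

    a = optimize.brentq(lambda x: ent(x) - target_h, 1.0 / k, 1 - 1e-12, xtol=1e-14)
    p = np.full(k, (1 - a) / (k - 1))
    p[0] = a
    rng.shuffle(p)
    return p / p.sum()


def _km_to_gps(x_km: np.ndarray, y_km: np.ndarray, center: tuple[float, float]):
    lat = center[0] + y_km / 111.19
    lon = center[1] + x_km / (111.19 * np.cos(np.radians(center[0])))
    return lat, lon


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_markets(config: SimConfig, rng: np.random.Generator | None = None) -> list[Market]:
    """Weekly markets placed uniformly on the region with species-sale
    proportion vectors carrying a N(mean, sd)-distributed Shannon MDI."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    L = config.region_extent_km
    xy = rng.uniform(-L / 2, L / 2, size=(config.market_count, 2))
    lat, lon = _km_to_gps(xy[:, 0], xy[:, 1], config.region_center)
    markets = []
    for i in range(config.market_count):
        h = rng.normal(config.market_entropy_mean, config.market_entropy_sd)
        p = _entropy_vector(h, config.n_market_species, rng)
        markets.append(Market(f"M{i+1:02d}", (float(lat[i]), float(lon[i])), tuple(p)))
    return markets


def _draw_farm_products(
    cfg: SimConfig, eta: float, alphas: dict[str, float], rng: np.random.Generator,
    group_products: dict[str, list[str]],
) -> list[str]:
    for _ in range(200):
        chosen: list[str] = []
        for gname, members in group_products.items():
            if rng.uniform() < special.expit(alphas[gname] + eta):
                if len(members) == 1:
                    chosen.append(members[0])
                else:
                    w = np.array([WITHIN_GROUP_WEIGHTS[gname][m] for m in members])
                    first = members[int(rng.choice(len(members), p=w / w.sum()))]
                    chosen.append(first)
                    p_extra = special.expit(
                        special.logit(cfg.extra_product_rate) + eta
                    )
                    for m in members:
                        if m != first and rng.uniform() < p_extra:
                            chosen.append(m)
        for pname in cfg.unclassified_prevalences:
            if rng.uniform() < special.expit(alphas[pname] + eta):
                chosen.append(pname)
        if chosen:
            return chosen
    raise RuntimeError("failed to draw a non-empty product set")


def _self_consumption_share(rng: np.random.Generator) -> float:
    # U-shaped outlet distribution: most farms sell nearly everything,
    # a substantial minority keeps nearly everything
    if rng.uniform() < 0.70:
        return float(rng.beta(0.55, 2.6))
    return float(rng.beta(3.2, 0.75))


def _allocate_seasonal_scores(
    total: int, devs: np.ndarray, cap: int = 10
) -> np.ndarray:
    """Split an annual total (0..4*cap) into four integer seasonal scores
    summing exactly to `total`, tilted by per-season deviations."""
    t = total / 4.0 + devs - devs.mean()
    t = np.clip(t, 0.0, float(cap))
    x = np.floor(t).astype(int)
    rem = t - x
    deficit = total - int(x.sum())
    order = np.argsort(-rem, kind="stable")
    i = 0
    while deficit > 0 and (x < cap).any():
        s = order[i % 4]
        if x[s] < cap:
            x[s] += 1
            deficit -= 1
        i += 1
    while deficit < 0:
        x[int(np.argmax(x))] -= 1
        deficit += 1
    return np.clip(x, 0, cap)


def _decompose_recalls_linear(
    woman_id: str, annual_total: int, cfg: SimConfig,
    produces_dairy: bool, produces_olive: bool, rng: np.random.Generator,
) -> list[dict]:
    devs = np.array([SEASON_OFFSETS[s] for s in SEASONS]) + rng.normal(
        0, cfg.season_dev_sd, 4
    )
    devs -= devs.mean() - np.array([SEASON_OFFSETS[s] for s in SEASONS]).mean()
    seasonal = _allocate_seasonal_scores(annual_total, devs)

    group_names = list(DIET_GROUP_WEIGHTS)
    base_w = np.array([DIET_GROUP_WEIGHTS[g] for g in group_names])
    # persistent woman-level taste, mixed with seasonal noise (corr ~ cfg.seasonal_correlation)
    rho = np.sqrt(cfg.seasonal_correlation)
    persist = rng.normal(0, 1, len(group_names))
    rows = []
    for s, k in zip(SEASONS, seasonal):
        taste = rho * persist + np.sqrt(1 - rho**2) * rng.normal(0, 1, len(group_names))
        w = base_w * np.exp(0.8 * taste)
        if produces_dairy:
            w[group_names.index("DAIRY")] *= 4.0
        idx = rng.choice(len(group_names), size=int(k), replace=False, p=w / w.sum())
        consumed = {group_names[i] for i in idx}
        row = {"woman_id": woman_id, "season": s}
        for g in GROUP_COLUMNS:
            row[g] = int(g in consumed)
        p_oil = 0.95 if produces_olive else 0.90
        row["olive_oil"] = int(rng.uniform() < p_oil)
        rows.append(row)
    return rows


def _decompose_recalls_bernoulli(
    woman_id: str, linear_pred: float, cfg: SimConfig,
    produces_dairy: bool, produces_olive: bool, rng: np.random.Generator,
) -> list[dict]:
    """BERNOULLI_GROUPS mode: per-group per-season logistic draws whose
    intercepts reflect the observed consumer percentages; the WDDS is
    whatever the draws imply."""
    base_logits = {
        "GRAINS_ROOTS_TUBERS": 6.0, "MEAT_POULTRY_FISH": 1.4, "OTHER_VEG": 3.0,
        "VITA_FRUITS_VEG": 1.6, "PULSES": 1.2, "OTHER_FRUITS": 0.5, "DAIRY": 0.2,
        "DARK_GREEN_LEAFY": 0.1, "EGGS": -0.8, "NUTS_SEEDS": -3.2,
    }
    shift = 0.35 * (linear_pred - 6.5)  # woman-level diet quality
    rho = np.sqrt(cfg.seasonal_correlation)
    persist = rng.normal(0, 1, len(base_logits))
    rows = []
    for s in SEASONS:
        spring_boost = 0.25 if s == "spring" else 0.0
        taste = rho * persist + np.sqrt(1 - rho**2) * rng.normal(0, 1, len(base_logits))
        row = {"woman_id": woman_id, "season": s}
        for i, (g, a) in enumerate(base_logits.items()):
            logit = a + shift + spring_boost + 0.6 * taste[i]
            if g == "DAIRY" and produces_dairy:
                logit += 1.2
            row[g] = int(rng.uniform() < special.expit(logit))
        row["olive_oil"] = int(rng.uniform() < (0.95 if produces_olive else 0.90))
        rows.append(row)
    return rows


def generate_dataset(config: SimConfig) -> tuple[SyntheticDataset, GroundTruth]:
    """Generate one complete survey-style dataset plus its ground truth.

    Identical config (including seed) yields byte-identical output.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(5)
    rng_mkt, rng_farm, rng_hh, rng_woman, rng_diet = (np.random.default_rng(s) for s in ss)
    n = config.n_households

    markets = generate_markets(config, rng_mkt)

    # --- households & spatial placement ---------------------------------
    L = config.region_extent_km
    xy = rng_hh.uniform(-L / 2, L / 2, size=(n, 2))
    lat, lon = _km_to_gps(xy[:, 0], xy[:, 1], config.region_center)
    hh_size = 1 + rng_hh.poisson(config.household_size_rate, n)
    head_age = np.clip(rng_hh.normal(44.6, 12.3, n), 25, 85)
    wealth_z = rng_hh.normal(0, 1, n)
    asset_loadings = np.array([0.9, 1.1, 0.8, 1.2, 1.0, 0.7, 1.3, 0.9])
    asset_cuts = np.array([-1.0, -0.4, 0.0, 0.3, 0.7, 1.1, -0.7, 1.5])
    assets = (
        rng_hh.uniform(size=(n, 8))
        < special.expit(asset_loadings * wealth_z[:, None] - asset_cuts)
    ).astype(int)

    households = pd.DataFrame(
        {
            "household_id": [f"H{i+1:03d}" for i in range(n)],
            "household_size": hh_size,
            "head_age": np.round(head_age, 1),
            "lat": lat,
            "lon": lon,
            **{f"asset_{j+1}": assets[:, j] for j in range(8)},
        }
    )

    # --- farms -----------------------------------------------------------
    zones = rng_farm.choice(4, size=n, p=config.zone_probs)
    seniority = config.seniority_median * np.exp(
        rng_farm.normal(0, config.seniority_log_sd, n)
    )
    u = rng_farm.normal(0, config.confounder_sd, n)
    zeff = np.asarray(config.zone_effects)
    zeff_centered = zeff - np.asarray(config.zone_probs) @ zeff
    eta = (
        zeff_centered[zones]
        + config.seniority_effect * np.log(seniority / config.seniority_median)
        + config.loading_on_diversity * u
        + rng_farm.normal(0, config.diversity_noise_sd, n)
    )
    alphas = _solve_group_intercepts(config)
    group_products: dict[str, list[str]] = {}
    for p in load_product_table():
        if p.group is not FoodGroup.UNCLASSIFIED:
            group_products.setdefault(p.group.value, []).append(p.product_id)

    farm_rows, product_rows = [], []
    pdi_counts = np.zeros(n, dtype=int)
    produces_dairy = np.zeros(n, dtype=bool)
    produces_olive = np.zeros(n, dtype=bool)
    for i in range(n):
        fid = f"F{i+1:03d}"
        prods = _draw_farm_products(config, eta[i], alphas, rng_farm, group_products)
        pdi_counts[i] = len(prods)
        produces_dairy[i] = "milk" in prods
        produces_olive[i] = "olive_oil" in prods
        total_value = config.value_median_usd * np.exp(
            config.value_diversity_coef * (len(prods) - 3)
            + rng_farm.normal(0, config.value_log_sd)
        )
        shares = rng_farm.dirichlet(np.full(len(prods), 0.45))
        s_self = _self_consumption_share(rng_farm)
        for pid, share in zip(prods, shares):
            c = 25.0
            f_self = rng_farm.beta(max(s_self, 0.02) * c, max(1 - s_self, 0.02) * c)
            f_don = min(0.02 * rng_farm.uniform(), 1 - f_self)
            f_self_r = round(float(f_self), 6)
            f_don_r = round(float(f_don), 6)
            product_rows.append(
                {
                    "farm_id": fid, "product_id": pid,
                    "value_usd": max(round(float(total_value * share), 2), 0.01),
                    "frac_sold": round(1.0 - f_self_r - f_don_r, 6),
                    "frac_donated": f_don_r,
                    "frac_selfconsumed": f_self_r,
                }
            )
        farm_rows.append(
            {
                "farm_id": fid,
                "household_id": f"H{i+1:03d}",
                "seniority_years": round(float(seniority[i]), 1),
                "size_ha": round(float(2.0 * np.exp(rng_farm.normal(0, 1.0))), 2),
                "climate_zone": CLIMATE_ZONES[zones[i]],
                "lat": lat[i],
                "lon": lon[i],
            }
        )
    farms = pd.DataFrame(farm_rows)
    farm_products = pd.DataFrame(product_rows)

    # --- women -----------------------------------------------------------
    age = np.clip(rng_woman.normal(35.0, 7.9, n), 20, 49.9)
    education = rng_woman.choice(4, size=n, p=config.education_probs)
    domestic = np.exp(rng_woman.normal(np.log(25.3), 0.406, n))
    responsibility = (rng_woman.uniform(size=n) < 0.041).astype(int)
    onfarm = (rng_woman.uniform(size=n) < 0.855).astype(int)
    offfarm_ag = (rng_woman.uniform(size=n) < 0.228).astype(int)
    nonfarm = (rng_woman.uniform(size=n) < 0.093).astype(int)
    bmi = np.clip(rng_woman.normal(25.7, 5.0, n), 15, 45)

    women = pd.DataFrame(
        {
            "woman_id": [f"W{i+1:03d}" for i in range(n)],
            "household_id": households["household_id"],
            "age": np.round(age, 1),
            "education": pd.Categorical.from_codes(
                education, categories=["none", "primary", "secondary", "superior"]
            ).astype(str),
            "domestic_hours": np.round(domestic, 1),
            "responsibility": responsibility,
            "onfarm_activity": onfarm,
            "offfarm_ag_income": offfarm_ag,
            "nonfarm_income": nonfarm,
            "bmi": np.round(bmi, 1),
        }
    )

    # --- diet ------------------------------------------------------------
    edu_effect = np.concatenate([[0.0], config.effect_education])[education]
    linear_pred = (
        config.diet_intercept
        + config.true_beta1 * pdi_counts
        + edu_effect
        + config.effect_wealth_latent * wealth_z
        + config.effect_household_size * hh_size
        + config.effect_head_age * head_age
        + config.effect_woman_age * age
        + config.effect_domestic_hours * domestic
        + config.effect_responsibility * responsibility
        + config.effect_nonfarm_income * nonfarm
        + config.effect_offfarm_ag * offfarm_ag
        + config.effect_onfarm * onfarm
        + config.loading_on_diet * u
        + config.invalid_instrument_loading * np.log(seniority / config.seniority_median)
    )
    recall_rows: list[dict] = []
    for i in range(n):
        wid = women["woman_id"].iloc[i]
        if config.diet_model == "LINEAR":
            ystar = linear_pred[i] + rng_diet.normal(0, config.diet_noise_sd)
            quarters = 4.0 * np.clip(ystar, 0.0, 10.0)
            total = int(np.floor(quarters))
            if rng_diet.uniform() < quarters - total:
                total += 1
            recall_rows.extend(
                _decompose_recalls_linear(
                    wid, total, config, produces_dairy[i], produces_olive[i], rng_diet
                )
            )
        else:
            recall_rows.extend(
                _decompose_recalls_bernoulli(
                    wid, linear_pred[i] + rng_diet.normal(0, config.diet_noise_sd),
                    config, produces_dairy[i], produces_olive[i], rng_diet
                )
            )
    recalls = pd.DataFrame(recall_rows)

    dataset = SyntheticDataset(
        farms=farms,
        farm_products=farm_products,
        households=households,
        women=women,
        recalls=recalls,
        markets=markets_to_frame(markets),
    )
    cfg_dict = asdict(config)
    truth = GroundTruth(
        true_beta1=config.true_beta1,
        diet_intercept=config.diet_intercept,
        loading_on_diversity=config.loading_on_diversity,
        loading_on_diet=config.loading_on_diet,
        confounder=[float(x) for x in u],
        config=cfg_dict,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_TABLES = ("farms", "farm_products", "households", "women", "recalls", "markets")


def write_dataset(dataset: SyntheticDataset, directory: str | Path,
                  truth: GroundTruth | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(dataset, name).to_csv(directory / f"{name}.csv", index=False)
    if truth is not None:
        (directory / "ground_truth.json").write_text(truth.to_json())


def read_dataset(directory: str | Path) -> SyntheticDataset:
    directory = Path(directory)
    frames = {}
    for name in _TABLES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing dataset table: {path.name}")
        frames[name] = pd.read_csv(path)
    expected = {
        "farms": ["farm_id", "household_id", "seniority_years", "climate_zone"],
        "farm_products": ["farm_id", "product_id", "value_usd"],
        "households": ["household_id", "household_size", "lat", "lon"],
        "women": ["woman_id", "household_id", "education"],
        "recalls": ["woman_id", "season"] + list(GROUP_COLUMNS) + ["olive_oil"],
        "markets": ["market_id", "lat", "lon"],
    }
    for name, cols in expected.items():
        missing = set(cols) - set(frames[name].columns)
        if missing:
            raise ValueError(f"{name}.csv is missing column(s) {sorted(missing)}")
    return SyntheticDataset(**frames)


def read_ground_truth(directory: str | Path) -> dict:
    return json.loads((Path(directory) / "ground_truth.json").read_text())
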