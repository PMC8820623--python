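"""Fixed reference tables: MDD-W food groups, the 29-product catalogue,
the product-nutrient fixture and Stock-Yogo critical values.

The product catalogue covers the crop and animal products recorded in the
Sidi Bouzid farm survey, each mapped to one of the 10 scorable MDD-W food
groups or to ``UNCLASSIFIED`` (products such as olive oil, garlic or honey
that carry no MDD-W group and never enter group-based scores).

The nutrient matrix shipped here is a *synthetic* stand-in for the Tunisian
food-composition table (which is not publicly deposited): magnitudes are
plausible per-portion values with the right group structure, but they are
not measured compositions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

#: Column order of the nutrient matrix. 17 nutrients are named in the source
#: listing while 18 columns are stated; vitamin B6 fills the 18th slot (a
#: documented ambiguity, see docs/methods.md).
NUTRIENT_COLUMNS: tuple[str, ...] = (
    "protein_g", "vitamin_a_ug", "vitamin_e_mg", "thiamin_mg", "riboflavin_mg",
    "niacin_mg", "pantothenic_acid_mg", "folate_ug", "vitamin_b12_ug",
    "vitamin_c_mg", "calcium_mg", "copper_mg", "iron_mg", "magnesium_mg",
    "potassium_mg", "sodium_mg", "zinc_mg", "vitamin_b6_mg",
)

N_PRODUCTS = 29
N_NUTRIENTS = 18


class FoodGroup(enum.Enum):
    """The 10 scorable MDD-W food groups plus an UNCLASSIFIED sentinel."""

    GRAINS_ROOTS_TUBERS = "GRAINS_ROOTS_TUBERS"
    PULSES = "PULSES"
    NUTS_SEEDS = "NUTS_SEEDS"
    DAIRY = "DAIRY"
    MEAT_POULTRY_FISH = "MEAT_POULTRY_FISH"
    EGGS = "EGGS"
    DARK_GREEN_LEAFY = "DARK_GREEN_LEAFY"
    VITA_FRUITS_VEG = "VITA_FRUITS_VEG"
    OTHER_VEG = "OTHER_VEG"
    OTHER_FRUITS = "OTHER_FRUITS"
    UNCLASSIFIED = "UNCLASSIFIED"

    @property
    def scorable(self) -> bool:
        return self is not FoodGroup.UNCLASSIFIED


SCORABLE_GROUPS: tuple[FoodGroup, ...] = tuple(
    g for g in FoodGroup if g.scorable
)


@dataclass(frozen=True)
class ProductDef:
    product_id: str
    name: str
    group: FoodGroup


class StockYogoNotTabulated(LookupError):
    """Requested Stock-Yogo cell is outside the published tables."""


def _data_path(name: str):
    return resources.files("agridiet.data").joinpath(name)


def load_product_table() -> list[ProductDef]:
    """Return the 29-product catalogue in its stable fixture order."""
    df = pd.read_csv(_data_path("products.csv"))
    products = [
        ProductDef(r.product_id, r.name, FoodGroup(r.group))
        for r in df.itertuples()
    ]
    if len(products) != N_PRODUCTS:
        raise ValueError(f"product catalogue has {len(products)} entries, expected {N_PRODUCTS}")
    return products


def product_group_map() -> dict[str, FoodGroup]:
    """product_id -> FoodGroup for the full catalogue."""
    return {p.product_id: p.group for p in load_product_table()}


def load_nutrient_fixture() -> tuple[pd.DataFrame, pd.Series]:
    """Load the synthetic 29x18 product-nutrient matrix and the WHO
    recommended-intake vector for adult women.

    Returns
    -------
    nutrients : DataFrame indexed by product_id, columns NUTRIENT_COLUMNS.
    rni : Series indexed by NUTRIENT_COLUMNS, strictly positive.
    """
    nut = pd.read_csv(_data_path("nutrients_synthetic.csv")).set_index("product_id")
    rni = pd.read_csv(_data_path("who_rni.csv")).set_index("nutrient")["rni"]

    catalogue = [p.product_id for p in load_product_table()]
    missing = set(catalogue) - set(nut.index)
    if missing:
        raise ValueError(f"nutrient fixture missing rows for products: {sorted(missing)}")
    nut = nut.loc[catalogue, list(NUTRIENT_COLUMNS)]
    if nut.isna().any().any():
        bad = nut.columns[nut.isna().any()].tolist()
        raise ValueError(f"nutrient fixture has missing cells in columns {bad}")
    if (nut.values < 0).any():
        raise ValueError("nutrient fixture contains negative values")
    rni = rni.reindex(list(NUTRIENT_COLUMNS))
    if rni.isna().any() or (rni <= 0).any():
        raise ValueError("WHO recommendations must be present and strictly positive")
    return nut, rni


def load_stock_yogo_table() -> pd.DataFrame:
    return pd.read_csv(_data_path("stock_yogo.csv"))


def stock_yogo_lookup(
    estimator: str = "LIML",
    criterion: str = "size10",
    n_endog: int = 1,
    n_excl: int = 1,
) -> float:
    """Critical value for the first-stage Cragg-Donald F statistic,
    transcribed from the published Stock-Yogo (2005) tables.

    criterion: 'size10'/'size15'/'size20'/'size25' (maximal size of a 5%
    Wald test) or 'bias5'/'bias10'/'bias20'/'bias30' (maximal relative
    bias, TSLS only).

    Raises StockYogoNotTabulated for cells outside the published tables;
    values are never interpolated.
    """
    tab = load_stock_yogo_table()
    hit = tab[
        (tab.estimator == estimator.upper())
        & (tab.criterion == criterion)
        & (tab.n_endog == n_endog)
        & (tab.n_excl == n_excl)
    ]
    if hit.empty:
        raise StockYogoNotTabulated(
            f"no published critical value for ({estimator}, {criterion}, "
            f"n_endog={n_endog}, n_excl={n_excl})"
        )
    return float(hit.critical_value.iloc[0])


def stock_yogo_row(estimator: str, n_endog: int, n_excl: int) -> dict[str, float]:
    """All tabulated criteria for one (estimator, n_endog, n_excl) cell."""
    tab = load_stock_yogo_table()
    hit = tab[
        (tab.estimator == estimator.upper())
        & (tab.n_endog == n_endog)
        & (tab.n_excl == n_excl)
    ]
    return dict(zip(hit.criterion, hit.critical_value.astype(float)))


def group_counts() -> dict[FoodGroup, int]:
    counts: dict[FoodGroup, int] = {}
    for p in load_product_table():
        counts[p.group] = counts.get(p.group, 0) + 1
    return counts
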