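"""Farm production-diversity indices.

Five indices summarise what a farm produces:

* PDI   - count of distinct products (0/1 coding, monetary value ignored);
* SDI   - Simpson index 1 - sum(s_i^2) over monetary value shares of products;
* GPDI  - count of distinct scorable MDD-W food groups produced (0-10,
          unclassified products such as olive oil excluded);
* GSDI  - Simpson index over monetary value shares of the 10 food groups
          (unclassified value excluded from numerator and denominator);
* NFD   - Nutritional Functional Diversity: the share (0-100%) of the total
          branch length of a product-nutrient dendrogram spanned by the
          farm's products.

The NFD dendrogram is built in four steps: divide the product-nutrient
matrix by the WHO recommended intakes, z-score each nutrient column across
products, convert to a Euclidean product-product distance matrix, and
cluster hierarchically (average linkage by default). Branch lengths follow
the standard ultrametric reading: a leaf sits at height 0 and an internal
node at half its cophenetic merge distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .reference_data import (
    FoodGroup,
    load_nutrient_fixture,
    load_product_table,
    product_group_map,
)

CLIMATE_ZONES = (
    "cool_semiarid_N",
    "upper_arid_temperate",
    "upper_arid_mild_E",
    "lower_arid_mild_S",
)


@dataclass(frozen=True)
class ProductHolding:
    """One product line of a farm: annual monetary value and outlet split."""

    value_usd: float
    frac_sold: float = 0.0
    frac_donated: float = 0.0
    frac_selfconsumed: float = 1.0

    def __post_init__(self):
        if self.value_usd < 0:
            raise ValueError("value_usd must be >= 0")
        tot = self.frac_sold + self.frac_donated + self.frac_selfconsumed
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(f"outlet fractions must sum to 1, got {tot}")


@dataclass
class Farm:
    farm_id: str
    household_id: str
    products: dict[str, ProductHolding]
    seniority_years: float = 0.0
    size_ha: float = 0.0
    climate_zone: str = "upper_arid_temperate"
    gps: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not self.products:
            raise ValueError(f"farm {self.farm_id} has no products")
        if self.climate_zone not in CLIMATE_ZONES:
            raise ValueError(f"unknown climate zone {self.climate_zone!r}")

    @property
    def total_value(self) -> float:
        return sum(p.value_usd for p in self.products.values())


def pdi(farm: Farm) -> int:
    """Production Diversity Index: number of distinct products."""
    return len(farm.products)


def sdi(farm: Farm) -> float:
    """Simpson Diversity Index over monetary value shares of products."""
    total = farm.total_value
    if total <= 0:
        raise ValueError(f"farm {farm.farm_id}: total production value is zero")
    shares = np.array([p.value_usd for p in farm.products.values()]) / total
    return float(1.0 - np.sum(shares**2))


def _group_values(farm: Farm, groups: dict[str, FoodGroup]) -> dict[FoodGroup, float]:
    out: dict[FoodGroup, float] = {}
    for pid, holding in farm.products.items():
        try:
            g = groups[pid]
        except KeyError:
            raise KeyError(f"unknown product {pid!r} on farm {farm.farm_id}") from None
        if g.scorable:
            out[g] = out.get(g, 0.0) + holding.value_usd
    return out


def gpdi(farm: Farm, groups: dict[str, FoodGroup] | None = None) -> int:
    """Group Production Diversity Index: distinct scorable MDD-W groups (0-10)."""
    groups = groups or product_group_map()
    return len(_group_values(farm, groups))


def gsdi(farm: Farm, groups: dict[str, FoodGroup] | None = None) -> float:
    """Simpson index over monetary value shares of the 10 MDD-W groups."""
    groups = groups or product_group_map()
    gv = _group_values(farm, groups)
    total = sum(gv.values())
    if not gv:
        raise ValueError(f"farm {farm.farm_id}: no production in any scorable group")
    if total <= 0:
        raise ValueError(f"farm {farm.farm_id}: zero value over scorable groups")
    shares = np.array(list(gv.values())) / total
    return float(1.0 - np.sum(shares**2))


def self_consumption_share(farm: Farm) -> float:
    """Monetary fraction of annual production kept for own consumption."""
    total = farm.total_value
    if total <= 0:
        raise ValueError(f"farm {farm.farm_id}: total production value is zero")
    kept = sum(p.value_usd * p.frac_selfconsumed for p in farm.products.values())
    return kept / total


def classify_orientation(farm: Farm, threshold: float = 0.8) -> str:
    """SELF_CONSUMPTION / MARKET_ORIENTED / MIXED at the 80% value rule."""
    total = farm.total_value
    if total <= 0:
        raise ValueError(f"farm {farm.farm_id}: total production value is zero")
    kept = sum(p.value_usd * p.frac_selfconsumed for p in farm.products.values()) / total
    sold = sum(p.value_usd * p.frac_sold for p in farm.products.values()) / total
    if kept > threshold:
        return "SELF_CONSUMPTION"
    if sold > threshold:
        return "MARKET_ORIENTED"
    return "MIXED"


# ---------------------------------------------------------------------------
# NFD: nutrient standardization, distances, dendrogram, score
# ---------------------------------------------------------------------------

def standardize_nutrients(nutrients: pd.DataFrame, rni: pd.Series) -> pd.DataFrame:
    """Divide by recommended intakes, then z-score each nutrient column
    across products (mean 0, SD 1, ddof=1)."""
    if list(nutrients.columns) != list(rni.index):
        raise ValueError("nutrient columns and recommendation vector are misaligned")
    ratio = nutrients / rni
    sd = ratio.std(ddof=1)
    zero_var = sd.index[sd <= 0].tolist()
    if zero_var:
        raise ValueError(f"zero-variance nutrient column(s): {zero_var}")
    return (ratio - ratio.mean()) / sd


def distance_matrix(standardized: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between product rows."""
    d = squareform(pdist(standardized.values, metric="euclidean"))
    return pd.DataFrame(d, index=standardized.index, columns=standardized.index)


@dataclass
class Dendrogram:
    """Ultrametric merge tree over products.

    Nodes 0..n-1 are leaves (in ``leaves`` order, height 0); node n+i is the
    i-th merge of the linkage at height ``heights[n+i]`` (half the cophenetic
    merge distance). ``parent[j]`` is -1 for the root; the edge j->parent has
    length heights[parent[j]] - heights[j].
    """

    leaves: list[str]
    children: dict[int, tuple[int, int]]
    heights: np.ndarray
    parent: np.ndarray
    linkage_method: str = "average"
    _leaf_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._leaf_index = {p: i for i, p in enumerate(self.leaves)}

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def edge_length(self, node: int) -> float:
        p = self.parent[node]
        if p < 0:
            return 0.0
        return float(self.heights[p] - self.heights[node])

    @property
    def total_branch_length(self) -> float:
        return float(sum(self.edge_length(j) for j in range(self.n_nodes - 1)))

    def to_newick(self) -> str:
        def rec(node: int) -> str:
            bl = self.edge_length(node)
            if node < self.n_leaves:
                return f"{self.leaves[node]}:{bl:.10g}"
            a, b = self.children[node]
            return f"({rec(a)},{rec(b)}):{bl:.10g}"

        a, b = self.children[self.root]
        return f"({rec(a)},{rec(b)});"


def build_dendrogram(
    distances: pd.DataFrame, linkage_method: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of the product-product distance matrix.

    Ultrametric node heights are half the cophenetic merge distances, so the
    tree distance between two leaves equals their cophenetic distance.
    """
    if linkage_method not in ("average", "single", "complete", "ward"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    d = distances.values
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage_method)

    heights = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=int)
    children: dict[int, tuple[int, int]] = {}
    for i in range(n - 1):
        a, b, h, _ = Z[i]
        node = n + i
        children[node] = (int(a), int(b))
        heights[node] = h / 2.0
        parent[int(a)] = node
        parent[int(b)] = node
    # guard the ultrametric reading (all four supported linkages are monotone)
    for node, (a, b) in children.items():
        if heights[node] < max(heights[a], heights[b]) - 1e-9:
            raise ValueError("non-monotone linkage heights; dendrogram not ultrametric")
    return Dendrogram(
        leaves=list(distances.index),
        children=children,
        heights=heights,
        parent=parent,
        linkage_method=linkage_method,
    )


def reference_dendrogram(linkage_method: str = "average") -> Dendrogram:
    """Dendrogram over the full 29-product catalogue from the bundled fixture."""
    nut, rni = load_nutrient_fixture()
    return build_dendrogram(distance_matrix(standardize_nutrients(nut, rni)), linkage_method)


def nfd(
    farm: Farm | set[str],
    dendrogram: Dendrogram,
    include_root_path: bool = True,
) -> float:
    """Nutritional Functional Diversity of a farm, 0-100.

    Sums the branch lengths of the subtree linking the farm's products and
    expresses them as a percentage of the dendrogram's total branch length.
    By default the subtree includes the path up to the root, so a
    single-product farm scores > 0 and adding a product can never lower the
    score; ``include_root_path=False`` restricts to the minimal subtree
    spanning the farm's leaves only.
    """
    product_ids = set(farm.products) if isinstance(farm, Farm) else set(farm)
    unknown = product_ids - set(dendrogram.leaves)
    if unknown:
        raise KeyError(f"products not in dendrogram: {sorted(unknown)}")
    if not product_ids:
        raise ValueError("empty product set")

    n = dendrogram.n_leaves
    marked = np.zeros(dendrogram.n_nodes, dtype=int)
    for pid in product_ids:
        marked[dendrogram._leaf_index[pid]] = 1
    for node in range(n, dendrogram.n_nodes):
        a, b = dendrogram.children[node]
        marked[node] = marked[a] + marked[b]

    k = len(product_ids)
    length = 0.0
    for node in range(dendrogram.n_nodes - 1):  # root has no parent edge
        if marked[node] >= 1 and (include_root_path or marked[node] < k):
            length += dendrogram.edge_length(node)
    return 100.0 * length / dendrogram.total_branch_length


def score_farms(
    farms: list[Farm],
    dendrogram: Dendrogram | None = None,
    groups: dict[str, FoodGroup] | None = None,
    include_root_path: bool = True,
) -> pd.DataFrame:
    """All five indices plus orientation for a list of farms (tidy frame)."""
    dendrogram = dendrogram or reference_dendrogram()
    groups = groups or product_group_map()
    rows = []
    for f in farms:
        gv = _group_values(f, groups)
        rows.append(
            {
                "farm_id": f.farm_id,
                "household_id": f.household_id,
                "pdi": pdi(f),
                "sdi": sdi(f),
                "gpdi": len(gv),
                # population convention: no scorable production => GSDI 0
                # (maximal concentration), so full-sample regressions are defined
                "gsdi": gsdi(f, groups) if sum(gv.values()) > 0 else 0.0,
                "nfd": nfd(f, dendrogram, include_root_path),
                "self_consumption_share": self_consumption_share(f),
                "orientation": classify_orientation(f),
                "total_value_usd": f.total_value,
            }
        )
    return pd.DataFrame(rows)


def all_products_farm() -> Farm:
    """Utility: a farm producing every catalogue product at unit value."""
    return Farm(
        farm_id="all",
        household_id="all",
        products={p.product_id: ProductHolding(1.0, 0.0, 0.0, 1.0) for p in load_product_table()},
    )
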