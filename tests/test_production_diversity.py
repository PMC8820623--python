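from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agridiet.production_diversity import (
    ProductHolding,
    all_products_farm,
    build_dendrogram,
    classify_orientation,
    distance_matrix,
    gpdi,
    gsdi,
    nfd,
    pdi,
    sdi,
    self_consumption_share,
    standardize_nutrients,
)
from agridiet.reference_data import load_nutrient_fixture

from conftest import make_farm


class TestCountIndices:
    def test_pdi_counts_products(self):
        assert pdi(make_farm({"wheat": 10, "milk": 5, "olive_oil": 2})) == 3

    def test_pdi_full_catalogue(self):
        assert pdi(all_products_farm()) == 29

    def test_gpdi_excludes_unclassified(self):
        assert gpdi(make_farm({"olive_oil": 100, "garlic": 10})) == 0

    def test_gpdi_same_group_counts_once(self):
        assert gpdi(make_farm({"wheat": 1, "barley": 1, "oat": 1})) == 1

    def test_gpdi_all_groups(self):
        assert gpdi(all_products_farm()) == 10


class TestSimpsonIndices:
    def test_single_product_zero(self):
        assert sdi(make_farm({"wheat": 100})) == 0.0

    def test_two_equal_products(self):
        assert sdi(make_farm({"wheat": 50, "milk": 50})) == pytest.approx(0.5)

    def test_three_shares(self):
        farm = make_farm({"wheat": 50, "milk": 30, "egg": 20})
        assert sdi(farm) == pytest.approx(0.62)

    def test_gsdi_aggregates_within_group(self):
        # wheat+barley share one group; milk the other -> equal group shares
        farm = make_farm({"wheat": 60, "barley": 40, "milk": 100})
        assert gsdi(farm) == pytest.approx(0.5)

    def test_gsdi_one_group_zero(self):
        assert gsdi(make_farm({"wheat": 10, "barley": 90})) == 0.0

    def test_gsdi_no_scorable_is_distinct_error(self):
        with pytest.raises(ValueError, match="scorable"):
            gsdi(make_farm({"olive_oil": 100}))

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.01, 1e6))
    def test_currency_rescaling_invariance(self, c):
        base = {"wheat": 50.0, "milk": 30.0, "egg": 20.0}
        farm_a = make_farm(base)
        farm_b = make_farm({k: v * c for k, v in base.items()})
        assert sdi(farm_a) == pytest.approx(sdi(farm_b), rel=1e-9)
        assert gsdi(farm_a) == pytest.approx(gsdi(farm_b), rel=1e-9)

    def test_gpdi_never_exceeds_pdi(self, small_dataset):
        ds, _ = small_dataset
        for farm in ds.farm_objects():
            assert gpdi(farm) <= pdi(farm)


class TestStandardization:
    def test_columns_mean_zero_sd_one(self):
        nut, rni = load_nutrient_fixture()
        z = standardize_nutrients(nut, rni)
        assert np.abs(z.mean()).max() < 1e-10
        assert np.abs(z.std(ddof=1) - 1).max() < 1e-10

    def test_rni_rescaling_invariance(self):
        nut, rni = load_nutrient_fixture()
        nut2, rni2 = nut.copy(), rni.copy()
        nut2.iloc[:, 0] *= 2
        rni2.iloc[0] *= 2
        pd.testing.assert_frame_equal(
            standardize_nutrients(nut, rni), standardize_nutrients(nut2, rni2)
        )

    def test_three_product_hand_example(self):
        nut = pd.DataFrame({"n1": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        rni = pd.Series({"n1": 2.0})
        z = standardize_nutrients(nut, rni)
        # ratios .5, 1, 1.5 -> z-scores -1, 0, 1 with sd(ddof=1)=0.5
        assert z["n1"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_variance_column_named(self):
        nut = pd.DataFrame({"flat": [1.0, 1.0, 1.0]}, index=list("abc"))
        with pytest.raises(ValueError, match="flat"):
            standardize_nutrients(nut, pd.Series({"flat": 1.0}))


class TestDistances:
    def test_three_four_five(self):
        df = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        d = distance_matrix(df)
        assert d.loc["a", "b"] == pytest.approx(5.0)
        assert d.loc["a", "a"] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"))
        d = distance_matrix(df)
        for i in df.index:
            for j in df.index:
                expected = np.sqrt(((df.loc[i] - df.loc[j]) ** 2).sum())
                assert d.loc[i, j] == pytest.approx(expected)
                assert d.loc[i, j] == d.loc[j, i]


class TestDendrogram:
    def test_two_leaf_total_branch_length(self):
        d = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        dend = build_dendrogram(d)
        # ultrametric: each leaf sits d/2 below the single merge
        assert dend.total_branch_length == pytest.approx(3.0)

    def test_three_equidistant_total_length_stable(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        dend = build_dendrogram(d)
        # any pairing gives two leaf edges of 1/2, one of 1/2, one internal of 0
        assert dend.total_branch_length == pytest.approx(1.5)

    def test_heights_non_decreasing_rootward(self, ref_dendrogram):
        dend = ref_dendrogram
        for node in range(dend.n_nodes - 1):
            parent = dend.parent[node]
            assert dend.heights[parent] >= dend.heights[node] - 1e-9

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            build_dendrogram(d)

    def test_newick_export_parses(self, toy_dendrogram):
        newick = toy_dendrogram.to_newick()
        assert newick.endswith(";") and newick.count("(") == 5
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(newick), "newick")
        assert {t.name for t in tree.get_terminals()} == set(toy_dendrogram.leaves)
        assert tree.total_branch_length() == pytest.approx(
            toy_dendrogram.total_branch_length
        )


def brute_force_nfd(leaf_set, dend, include_root_path=True):
    """Independent oracle: explicitly enumerate the edges on each leaf's
    path to the root and take the union."""
    idx = {p: i for i, p in enumerate(dend.leaves)}
    edges = set()
    for leaf in leaf_set:
        node = idx[leaf]
        while dend.parent[node] >= 0:
            edges.add(node)
            node = dend.parent[node]
    if not include_root_path:
        # drop edges shared by *all* leaf paths (the common root path)
        shared = None
        for leaf in leaf_set:
            node, path = idx[leaf], set()
            while dend.parent[node] >= 0:
                path.add(node)
                node = dend.parent[node]
            shared = path if shared is None else shared & path
        edges -= shared
    total = sum(dend.edge_length(e) for e in range(dend.n_nodes - 1))
    return 100.0 * sum(dend.edge_length(e) for e in edges) / total


class TestNFD:
    def test_full_catalogue_scores_100(self, ref_dendrogram):
        assert nfd(all_products_farm(), ref_dendrogram) == pytest.approx(100.0)

    def test_single_product_positive(self, ref_dendrogram):
        farm = make_farm({"wheat": 10})
        assert 0 < nfd(farm, ref_dendrogram) < 100

    def test_unknown_product_rejected(self, toy_dendrogram):
        with pytest.raises(KeyError):
            nfd({"nope"}, toy_dendrogram)

    def test_all_subsets_match_oracle(self, toy_dendrogram):
        leaves = toy_dendrogram.leaves
        for r in range(1, 7):
            for subset in combinations(leaves, r):
                s = set(subset)
                assert nfd(s, toy_dendrogram) == pytest.approx(
                    brute_force_nfd(s, toy_dendrogram)
                )
                assert nfd(s, toy_dendrogram, include_root_path=False) == pytest.approx(
                    brute_force_nfd(s, toy_dendrogram, include_root_path=False)
                )

    def test_monotone_under_product_addition(self, toy_dendrogram):
        leaves = toy_dendrogram.leaves
        for r in range(1, 6):
            for subset in combinations(leaves, r):
                base = nfd(set(subset), toy_dendrogram)
                for extra in set(leaves) - set(subset):
                    assert nfd(set(subset) | {extra}, toy_dendrogram) >= base - 1e-12

    def test_value_invariance(self, ref_dendrogram):
        a = make_farm({"wheat": 1.0, "milk": 1.0})
        b = make_farm({"wheat": 500.0, "milk": 0.01})
        assert nfd(a, ref_dendrogram) == nfd(b, ref_dendrogram)


class TestOrientation:
    def test_all_self_consumed(self):
        farm = make_farm({"wheat": 100}, self_frac=1.0)
        assert self_consumption_share(farm) == 1.0
        assert classify_orientation(farm) == "SELF_CONSUMPTION"

    def test_mostly_sold(self):
        farm = make_farm({"wheat": 100}, self_frac=0.1)
        assert classify_orientation(farm) == "MARKET_ORIENTED"

    def test_balanced_is_mixed(self):
        farm = make_farm({"wheat": 100}, self_frac=0.5)
        assert classify_orientation(farm) == "MIXED"

    def test_share_is_value_weighted(self):
        holdings = {
            "wheat": ProductHolding(90, 0.0, 0.0, 1.0),
            "milk": ProductHolding(10, 1.0, 0.0, 0.0),
        }
        from agridiet.production_diversity import Farm

        farm = Farm("f", "h", holdings)
        assert self_consumption_share(farm) == pytest.approx(0.9)
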