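"""The five production-diversity indices for a typical smallholder farm.

A Sidi Bouzid-style farm: sheep and milk production, olive oil, and a small
wheat plot. PDI counts products, SDI weights them by monetary value, GPDI
and GSDI work on the 10 MDD-W food groups (olive oil excluded), and NFD
measures how much of the nutrient-composition dendrogram the farm spans.
"""

from agridiet.production_diversity import (
    Farm,
    ProductHolding,
    classify_orientation,
    gpdi,
    gsdi,
    nfd,
    pdi,
    reference_dendrogram,
    sdi,
    self_consumption_share,
)

farm = Farm(
    farm_id="F001",
    household_id="H001",
    products={
        "sheep_meat": ProductHolding(1200.0, frac_sold=0.9, frac_selfconsumed=0.1),
        "milk": ProductHolding(400.0, frac_sold=0.5, frac_selfconsumed=0.5),
        "olive_oil": ProductHolding(700.0, frac_sold=0.8, frac_selfconsumed=0.2),
        "wheat": ProductHolding(150.0, frac_sold=0.0, frac_selfconsumed=1.0),
    },
    seniority_years=30,
    climate_zone="upper_arid_temperate",
)

dendro = reference_dendrogram()  # average linkage over the 29-product fixture
print(f"PDI  = {pdi(farm)}    (distinct products)")
print(f"SDI  = {sdi(farm):.3f} (Simpson over value shares of products)")
print(f"GPDI = {gpdi(farm)}    (distinct MDD-W groups; olive oil excluded)")
print(f"GSDI = {gsdi(farm):.3f} (Simpson over value shares of groups)")
print(f"NFD  = {nfd(farm, dendro):.1f}  (% of dendrogram branch length spanned)")
print(f"self-consumption share = {self_consumption_share(farm):.2f}")
print("orientation =", classify_orientation(farm), "(80% value rule)")
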