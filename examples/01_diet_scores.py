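"""Score one woman's four quarterly 24-hour recalls.

The seasonal WDDS-10 counts the scorable MDD-W food groups consumed (olive
oil never counts); the annual score is the mean of the four seasonal
scores, and MDD-W is reached at five or more groups.
"""

from agridiet.diet_diversity import Recall, score_woman
from agridiet.reference_data import FoodGroup as G

recalls = [
    Recall("tunisia_w001", "autumn",
           frozenset({G.GRAINS_ROOTS_TUBERS, G.DAIRY, G.MEAT_POULTRY_FISH,
                      G.OTHER_VEG, G.VITA_FRUITS_VEG, G.PULSES}),
           olive_oil_consumed=True),
    Recall("tunisia_w001", "winter",
           frozenset({G.GRAINS_ROOTS_TUBERS, G.DAIRY, G.MEAT_POULTRY_FISH,
                      G.OTHER_VEG, G.PULSES, G.OTHER_FRUITS, G.EGGS}),
           olive_oil_consumed=True),
    Recall("tunisia_w001", "spring",
           frozenset({G.GRAINS_ROOTS_TUBERS, G.DAIRY, G.MEAT_POULTRY_FISH,
                      G.OTHER_VEG, G.VITA_FRUITS_VEG, G.DARK_GREEN_LEAFY,
                      G.OTHER_FRUITS}),
           olive_oil_consumed=True),
    Recall("tunisia_w001", "summer",
           frozenset({G.GRAINS_ROOTS_TUBERS, G.MEAT_POULTRY_FISH,
                      G.OTHER_VEG, G.VITA_FRUITS_VEG, G.OTHER_FRUITS}),
           olive_oil_consumed=False),
]

scores = score_woman(recalls)
print("seasonal WDDS-10:", scores.seasonal_wdds)
print(f"annual WDDS-10:   {scores.annual_wdds}  (mean of the four seasons)")
print("reaches MDD-W:    ", scores.mddw, " (annual score >= 5 groups)")
print("dairy consumption score:", scores.consumption_scores["DAIRY"],
      "-> consumed dairy in 3 of 4 recalls")
print("olive oil score:        ", scores.consumption_scores["olive_oil"],
      "-> tracked separately, never part of WDDS-10")
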