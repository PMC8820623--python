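"""Market diversity and household market access.

Each market's MDI is the Shannon entropy (nats) of its species-sale
proportions; a household's HAMDI is the mean MDI of its two nearest
markets as the crow flies, with the distance to the closer one reported.
"""

import numpy as np

from agridiet.market_access import Market, hamdi, mdi

markets = [
    Market("souk_A", (35.03, 9.48), (0.55, 0.20, 0.15, 0.10)),
    Market("souk_B", (35.10, 9.60), (0.25, 0.25, 0.25, 0.25)),
    Market("souk_C", (34.85, 9.30), (0.90, 0.05, 0.03, 0.02)),
]
for m in markets:
    print(f"{m.market_id}: MDI = {mdi(m):.3f} nats "
          f"(max ln 4 = {np.log(4):.3f} for a uniform market)")

home = (35.00, 9.45)
value, chosen, nearest_km = hamdi(home, markets)
print(f"\nhousehold at {home}:")
print(f"two nearest markets: {chosen}, nearest at {nearest_km:.1f} km")
print(f"HAMDI = {value:.3f} (mean MDI of the two nearest markets)")
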