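"""Market diversity and household market access.

Each weekly market carries a vector of proportions of crop/animal species
sold; its Market Diversity Index (MDI) is the Shannon entropy
-sum(P_i ln P_i) in nats. A household's HAMDI is the mean MDI of the two
markets nearest to its home as the crow flies (exclusive-frequentation
hypothesis), and the distance to the closer of the two is reported
alongside. Crow-flies distances are great-circle (haversine) kilometres;
at governorate scale this is indistinguishable from planar distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class Market:
    market_id: str
    gps: tuple[float, float]  # (lat, lon) degrees
    species_proportions: tuple[float, ...]

    def __post_init__(self):
        p = np.asarray(self.species_proportions, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"market {self.market_id}: proportions must be >= 0 and sum to 1"
            )


def mdi(market: Market | np.ndarray) -> float:
    """Shannon market diversity index, -sum(P_i ln P_i), with 0 ln 0 = 0."""
    p = np.asarray(
        market.species_proportions if isinstance(market, Market) else market,
        dtype=float,
    )
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be >= 0 and sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def distance_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points."""
    for lat, lon in (a, b):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(np.radians, (*a, *b))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def hamdi(
    household_gps: tuple[float, float], markets: list[Market], k: int = 2
) -> tuple[float, list[str], float]:
    """Mean MDI of the k (default 2) nearest markets as the crow flies.

    Returns (hamdi, selected market_ids nearest-first, distance to the
    nearest market in km). Distance ties at the selection boundary are
    broken by market_id so results are order-independent.
    """
    if len(markets) < k:
        raise ValueError(f"need at least {k} markets, got {len(markets)}")
    ranked = sorted(
        markets, key=lambda m: (distance_km(household_gps, m.gps), m.market_id)
    )
    chosen = ranked[:k]
    value = float(np.mean([mdi(m) for m in chosen]))
    nearest_km = distance_km(household_gps, chosen[0].gps)
    return value, [m.market_id for m in chosen], nearest_km


def score_households(
    households: pd.DataFrame, markets: list[Market], k: int = 2
) -> pd.DataFrame:
    """Per-household HAMDI and nearest-market distance.

    ``households`` needs columns household_id, lat, lon.
    """
    rows = []
    for r in households.itertuples():
        value, ids, near = hamdi((r.lat, r.lon), markets, k=k)
        rows.append(
            {
                "household_id": r.household_id,
                "hamdi": value,
                "nearest_market_km": near,
                "market_1": ids[0],
                "market_2": ids[1] if len(ids) > 1 else ids[0],
            }
        )
    return pd.DataFrame(rows)


def markets_to_frame(markets: list[Market]) -> pd.DataFrame:
    n_species = len(markets[0].species_proportions)
    rows = []
    for m in markets:
        row = {"market_id": m.market_id, "lat": m.gps[0], "lon": m.gps[1]}
        row.update({f"sp_{i}": p for i, p in enumerate(m.species_proportions)})
        rows.append(row)
    assert all(len(m.species_proportions) == n_species for m in markets)
    return pd.DataFrame(rows)


def frame_to_markets(frame: pd.DataFrame) -> list[Market]:
    sp_cols = [c for c in frame.columns if c.startswith("sp_")]
    return [
        Market(str(r.market_id), (r.lat, r.lon),
               tuple(float(getattr(r, c)) for c in sp_cols))
        for r in frame.itertuples()
    ]
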