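import numpy as np
import pandas as pd
import pytest

from agridiet.production_diversity import (
    Dendrogram,
    Farm,
    ProductHolding,
    build_dendrogram,
    reference_dendrogram,
)
from agridiet.synthetic_data import SimConfig, generate_dataset


def make_farm(products: dict[str, float], self_frac: float = 1.0, **kw) -> Farm:
    holdings = {
        pid: ProductHolding(v, 1.0 - self_frac, 0.0, self_frac)
        for pid, v in products.items()
    }
    kw.setdefault("farm_id", "F1")
    kw.setdefault("household_id", "H1")
    return Farm(products=holdings, **kw)


@pytest.fixture(scope="session")
def ref_dendrogram() -> Dendrogram:
    return reference_dendrogram()


@pytest.fixture(scope="session")
def toy_dendrogram() -> Dendrogram:
    """Six leaves with a well-spread, non-degenerate distance structure."""
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(6, 3)) * [1.0, 2.0, 0.5]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    labels = [f"p{i}" for i in range(6)]
    return build_dendrogram(pd.DataFrame(d, index=labels, columns=labels))


@pytest.fixture(scope="session")
def small_dataset():
    ds, truth = generate_dataset(SimConfig(seed=11, n_households=30))
    return ds, truth
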