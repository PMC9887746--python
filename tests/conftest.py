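import numpy as np
import pandas as pd
import pytest

from gcsi.cfa import CfaModelSpec
from gcsi.table import IndicatorMeta, IndicatorTable


@pytest.fixture
def rng():
    return np.random.default_rng(20190101)


@pytest.fixture
def small_table():
    """4 crises x 3 indicators with two missing cells."""
    metas = tuple(IndicatorMeta(id=f"x{j}", pillar="impact") for j in (1, 2, 3))
    values = np.array(
        [
            [2.0, 1.0, 0.0],
            [np.nan, 3.0, 1.0],
            [4.0, np.nan, 2.0],
            [4.0, 3.0, 5.0],
        ]
    )
    return IndicatorTable(("C1", "C2", "C3", "C4"), metas, values)


def make_second_order_data(
    rng,
    n,
    construct_spec,
    gammas,
    *,
    residual_pairs=(),
    missing_rate=0.0,
):
    """Direct draw from the second-order factor model; returns (df, severity).

    Kept deliberately separate from gcsi.synthetic so generator tests have an
    independent construction to compare against.
    """
    gammas = np.asarray(gammas, dtype=float)
    k = len(construct_spec)
    sev = rng.standard_normal(n)
    factors = gammas * sev[:, None] + np.sqrt(1 - gammas**2) * rng.standard_normal((n, k))
    cols = {}
    shared = {}
    for a, b, c in residual_pairs:
        u = rng.standard_normal(n)
        shared[a] = (u, c)
        shared[b] = (u, c)
    for ci, (cname, lams) in enumerate(construct_spec.items()):
        for j, lam in enumerate(lams):
            name = f"{cname}_{j + 1}"
            u, c = shared.get(name, (None, 0.0))
            y = lam * factors[:, ci] + np.sqrt(1 - lam**2 - c) * rng.standard_normal(n)
            if u is not None:
                y = y + np.sqrt(c) * u
            cols[name] = y
    df = pd.DataFrame(cols)
    if missing_rate:
        mask = rng.random(df.shape) < missing_rate
        df = df.mask(mask)
    return df, sev


@pytest.fixture
def three_construct_spec():
    return CfaModelSpec(
        {
            "a": ("a_1", "a_2", "a_3", "a_4", "a_5"),
            "b": ("b_1", "b_2", "b_3"),
            "c": ("c_1", "c_2", "c_3"),
        }
    )
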