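"""Built-in item parameter tables and item-parameter CSV I/O.

The PISA 2015 mathematics clusters M1 (10 dichotomous items) and M2
(9 dichotomous items) in the slope/intercept parametrization. In the
original scaling the 2PL model was only used for items that fit the Rasch
model poorly, which is why several slopes are exactly 1.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .families import ItemParametrization

_PISA_M1 = """item,a,d
1,1.00,0.96
2,1.00,0.67
3,1.00,0.67
4,1.00,0.28
5,1.43,0.11
6,0.69,-0.04
7,1.70,-0.87
8,1.48,-0.65
9,1.00,-0.25
10,1.00,0.09
"""

_PISA_M2 = """item,a,d
1,0.62,-0.09
2,1.00,0.02
3,1.00,0.61
4,0.59,0.91
5,1.78,-0.91
6,2.30,-1.80
7,0.76,-0.25
8,1.00,-0.03
9,0.63,0.03
"""


def pisa_m1() -> pd.DataFrame:
    """PISA 2015 M1 mathematics cluster (10 items, columns item/a/d)."""
    return pd.read_csv(io.StringIO(_PISA_M1))


def pisa_m2() -> pd.DataFrame:
    """PISA 2015 M2 mathematics cluster (9 items, columns item/a/d)."""
    return pd.read_csv(io.StringIO(_PISA_M2))


def beta_from_table(table: pd.DataFrame) -> np.ndarray:
    """Interleave a 2PL item table (columns a, d) into beta = (a1,d1,...,aI,dI)."""
    a = np.asarray(table["a"], dtype=float)
    d = np.asarray(table["d"], dtype=float)
    beta = np.empty(2 * len(a))
    beta[0::2], beta[1::2] = a, d
    return beta


def read_item_parameters(path) -> pd.DataFrame:
    """Read an item-parameter CSV (columns item, optional group, a, d or d1..dK-1)."""
    df = pd.read_csv(path)
    if "a" not in df.columns:
        raise ValueError("item parameter table must have an 'a' column")
    return df


def write_item_parameters(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def beta_to_table(param: ItemParametrization, beta: np.ndarray) -> pd.DataFrame:
    """Item-parameter table for a beta vector in the given layout."""
    rows = []
    if param.family == "two_pl":
        a, d = param.item_params(beta)
        for i in range(param.n_items):
            rows.append({"item": i + 1, "a": a[i], "d": d[i]})
    elif param.family == "gpcm":
        a, d = param.item_params(beta)
        for i in range(param.n_items):
            row = {"item": i + 1, "a": a[i]}
            for k in range(1, param.n_categories):
                row[f"d{k}"] = d[i, k]
            rows.append(row)
    else:
        for g, gname in ((0, "A"), (1, "B")):
            a, d = param.item_params(beta, group=g)
            for i in range(param.n_items):
                rows.append({"item": i + 1, "group": gname, "a": a[i], "d": d[i]})
    return pd.DataFrame(rows)
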