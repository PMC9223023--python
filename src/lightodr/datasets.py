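"""Packaged reference data.

One small table ships with the package: the published municipal prediction
list for the 65 large and medium-sized Chinese cities — each city's zonal
SUM of nighttime-light DN and its Sigmoid-predicted ODR (%). It anchors the
reconstruction of the published Sigmoid coefficients (any two rows determine
them exactly) and the large-city filter thresholds (ODR >= 13.71, SUM >=
115,762, exactly the 65th row's values).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_city_predictions", "city_anchor_pair"]


def load_city_predictions() -> pd.DataFrame:
    """The 65-city reference table: columns rank, city, sum_dn, odr."""
    ref = resources.files("lightodr") / "data" / "city_odr_predictions.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def city_anchor_pair(city1: str, city2: str):
    """(sum_dn, odr) pairs for two named cities, for the two-point solve."""
    df = load_city_predictions().set_index("city")
    out = []
    for name in (city1, city2):
        if name not in df.index:
            raise KeyError(f"city {name!r} not in the reference table")
        row = df.loc[name]
        out.append((float(row["sum_dn"]), float(row["odr"])))
    return tuple(out)
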