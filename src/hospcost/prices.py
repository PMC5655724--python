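"""Construction of exogenous input-price proxies.

Unit labor values (cost per FTE) are partly endogenous — an expensive
hospital pays itself high wages — so the labor price entering the cost system
is the region x year systematic component of the unit value: the fitted value
from a least-squares regression of unit values on region and year indicator
sets, run separately per labor category.  Materials carry a national CPI
index (base year one, no regional variation).  The capital price is capital
cost divided by a capital volume index, a weighted aggregate of beds, IC
beds, radiotherapists (a proxy for large treatment machines) and operating
theatres whose weights come from an intercept-free regression of capital
costs on those components.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "labor_price_proxy", "material_price_index", "capital_volume_index",
    "capital_price", "CAPITAL_COMPONENTS",
]

CAPITAL_COMPONENTS = ("beds", "ic_beds_n", "radiotherapists", "theatres")


def labor_price_proxy(table: pd.DataFrame,
                      value_col: str = "unit_value") -> pd.Series:
    """Region x year fitted unit values per labor category.

    ``table`` has one row per hospital-year-category with columns
    ``category``, ``region``, ``year`` and the unit value (cost / FTE).
    Returns the fitted values aligned on ``table``'s index; hospitals in the
    same region, year and category receive identical prices by construction.
    """
    out = pd.Series(index=table.index, dtype=float, name="price")
    for cat, sub in table.groupby("category"):
        vals = sub[value_col]
        if vals.isna().all():
            raise ValueError(f"labor category {cat!r} has no unit values")
        sub = sub.assign(_v=vals)
        if sub["region"].nunique() == 1 and sub["year"].nunique() == 1:
            out.loc[sub.index] = vals.mean()
            continue
        fit = smf.ols("_v ~ C(region) + C(year)", data=sub).fit()
        out.loc[sub.index] = fit.fittedvalues
    return out


def material_price_index(cpi: pd.Series, base_year: int) -> pd.Series:
    """Per-year material price index, one in the base year: ``cpi_t / cpi_base``."""
    cpi = cpi.astype(float)
    if base_year not in cpi.index:
        raise KeyError(f"base year {base_year} missing from the CPI series")
    return cpi / cpi.loc[base_year]


def capital_volume_index(capital_costs: pd.Series,
                         components: pd.DataFrame
                         ) -> tuple[pd.Series, pd.Series]:
    """Weights and mean-one capital volume from an intercept-free regression.

    The intercept is excluded so a hospital without any capital components
    has zero volume.  Collinear components are reported and dropped (weight
    zero) before the fit.  The volume is rescaled to mean one so the implied
    capital price is on the scale of capital cost for the average hospital.
    """
    X = components.astype(float).copy()
    if (X.to_numpy() < 0).any():
        raise ValueError("capital components must be non-negative")
    keep = list(X.columns)
    # drop columns until full column rank, preferring to keep earlier columns
    while keep and np.linalg.matrix_rank(X[keep].to_numpy()) < len(keep):
        for col in reversed(keep):
            trial = [c for c in keep if c != col]
            if np.linalg.matrix_rank(X[trial].to_numpy()) == \
                    np.linalg.matrix_rank(X[keep].to_numpy()):
                warnings.warn(f"capital component {col!r} is collinear; "
                              f"dropped from the volume index")
                keep = trial
                break
    coef, *_ = np.linalg.lstsq(X[keep].to_numpy(),
                               capital_costs.to_numpy(dtype=float), rcond=None)
    weights = pd.Series(0.0, index=components.columns, name="weight")
    weights[keep] = coef
    raw = X.to_numpy() @ weights.to_numpy()
    mean = raw.mean()
    if mean <= 0:
        raise ValueError("capital volume index has non-positive mean")
    return weights, pd.Series(raw / mean, index=components.index, name="volume")


def capital_price(capital_cost: pd.Series, volume: pd.Series) -> pd.Series:
    """Capital price: cost of capital divided by the volume of capital."""
    volume = volume.astype(float)
    if (volume <= 0).any():
        raise ValueError("capital volume must be strictly positive")
    return (capital_cost.astype(float) / volume).rename("price_capital")
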