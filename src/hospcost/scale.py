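"""Scale-economy measures: overall, product-specific and chain elasticities.

All measures are defined on the cost function in levels (EUR / year):

* overall (ray) scale elasticity ``v = [sum_m dlogC/dlogy_m]^(-1)``,
  equivalently total cost over the output-weighted sum of marginal costs —
  ``v > 1`` means economies of scale;
* product-specific scale elasticity of service *m*: the average incremental
  cost of producing *m* above the smallest observed volume ``y_min_m``
  (holding everything else fixed) divided by its marginal cost;
* chain scale elasticity of two sequential services (an ER visit followed by
  an admission or an outpatient treatment): the average incremental cost of
  the joint volume ``y12``, removed from *both* services, divided by the sum
  of the two marginal costs at the actual point.

The measures are implemented against a minimal level-space cost interface
(:class:`LevelCost`) so closed-form cost functions can exercise them
directly; :class:`TranslogLevelCost` adapts a fitted translog system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import model as _m
from .params import OUTPUTS, NormalizationPoint, TranslogParameters

__all__ = [
    "ChainLink", "LevelCost", "TranslogLevelCost",
    "overall_scale_elasticity", "product_specific_scale_elasticity",
    "chain_scale_elasticity", "conditional_elasticity_derivative",
    "quartile_report", "default_chain_links",
]


@dataclass
class ChainLink:
    """A sequential-service pair with its joint volume.

    ``y12`` counts upstream events (ER visits) followed by the downstream
    service; it is part of both service volumes.
    """

    upstream: str
    downstream: str
    y12: float

    def __post_init__(self) -> None:
        for s in (self.upstream, self.downstream):
            if s not in OUTPUTS:
                raise KeyError(f"unknown service id {s!r}")
        if self.upstream == self.downstream:
            raise ValueError("chain requires two distinct services")
        if self.y12 <= 0:
            raise ValueError("joint volume y12 must be positive")


class LevelCost:
    """Level-space cost interface: ``cost(y)`` in EUR and its output gradient."""

    def cost(self, y: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def marginal(self, y: np.ndarray, m: int) -> float:
        """Marginal cost dC/dy_m; default central finite difference."""
        h = 1e-6 * y[m]
        up, dn = y.copy(), y.copy()
        up[m] += h
        dn[m] -= h
        return (self.cost(up) - self.cost(dn)) / (2 * h)


class TranslogLevelCost(LevelCost):
    """Level-space view of a translog system with prices/hedonics/year fixed."""

    def __init__(self, params: TranslogParameters, point: _m.Point,
                 norm: NormalizationPoint):
        self.params = params
        self.point = point
        self.norm = norm

    def cost(self, y: np.ndarray) -> float:
        p = self.point
        return float(_m.total_cost(self.params, y, p.w, p.z, p.year, self.norm))

    def marginal(self, y: np.ndarray, m: int) -> float:
        p = self.point
        return _m.marginal_cost(self.params, y, p.w, p.z, p.year, self.norm, m)

    def elasticities(self, y: np.ndarray) -> np.ndarray:
        p = self.point
        return _m.cost_elasticities(self.params, y, p.w, p.z, p.year, self.norm)


class RegularityError(ValueError):
    """The point violates a regularity condition of the measure."""


# -------------------------------------------------------------------- overall
def _overall_from_levelcost(lc: LevelCost, y: np.ndarray,
                            outputs: Sequence[int]) -> float:
    c = lc.cost(y)
    wsum = sum(y[m] * lc.marginal(y, m) for m in outputs)
    if wsum <= 0:
        raise RegularityError("sum of cost elasticities is non-positive")
    return c / wsum


def overall_scale_elasticity(params: TranslogParameters, point: _m.Point,
                             norm: NormalizationPoint) -> float:
    """Ray scale elasticity ``v`` at a point.

    Computed both as the inverse elasticity sum and as total cost over the
    output-weighted marginal costs; the two definitional forms are asserted
    to agree to 1e-10.
    """
    lc = TranslogLevelCost(params, point, norm)
    eps_sum = float(lc.elasticities(point.y).sum())
    if eps_sum <= 0:
        raise RegularityError(
            "sum of cost elasticities is non-positive (regularity violation)")
    v_inv_sum = 1.0 / eps_sum
    v_ratio = _overall_from_levelcost(lc, point.y, range(len(OUTPUTS)))
    assert abs(v_inv_sum - v_ratio) < 1e-10 * max(1.0, abs(v_inv_sum))
    return v_inv_sum


# ------------------------------------------------------------ product-specific
def product_specific_scale_elasticity_lc(lc: LevelCost, y: np.ndarray,
                                         m: int, y_min_m: float) -> float:
    """Product-specific scale elasticity on a generic level-space cost."""
    if y_min_m <= 0:
        raise ValueError("y_min must be positive")
    if y_min_m >= y[m]:
        raise ValueError("y_min must be below the evaluated service level")
    y_cf = y.copy()
    y_cf[m] = y_min_m
    aic = (lc.cost(y) - lc.cost(y_cf)) / (y[m] - y_min_m)
    return aic / lc.marginal(y, m)


def product_specific_scale_elasticity(params: TranslogParameters,
                                      point: _m.Point,
                                      norm: NormalizationPoint,
                                      output: str | int,
                                      y_min: float) -> float:
    """Average-incremental over marginal cost for one service.

    The counterfactual replaces the service level by the smallest volume
    observed in the sample (zero production is never observed — every Dutch
    general hospital runs an ER), holding all other services, prices,
    hedonics and the year fixed.  Values above one signal product-specific
    economies of scale, with a downward bias from the fixed costs still
    embedded in the minimum-volume counterfactual.
    """
    m = OUTPUTS.index(output) if isinstance(output, str) else output
    lc = TranslogLevelCost(params, point, norm)
    return product_specific_scale_elasticity_lc(lc, point.y, m, y_min)


# ------------------------------------------------------------------- chain
def chain_scale_elasticity_lc(lc: LevelCost, y: np.ndarray,
                              m1: int, m2: int, y12: float) -> float:
    if y12 <= 0:
        raise ValueError("y12 must be positive")
    y_cf = y.copy()
    y_cf[m1] -= y12
    y_cf[m2] -= y12
    if y_cf[m1] <= 0 or y_cf[m2] <= 0:
        raise RegularityError(
            "counterfactual output non-positive; reduce the joint volume y12 "
            "below both service levels")
    aic = (lc.cost(y) - lc.cost(y_cf)) / y12
    mc = lc.marginal(y, m1) + lc.marginal(y, m2)
    return aic / mc


def chain_scale_elasticity(params: TranslogParameters, point: _m.Point,
                           norm: NormalizationPoint,
                           link: ChainLink) -> float:
    """Scale elasticity of the joint volume of two sequential services.

    The numerator is the average incremental cost of the ``y12`` patients who
    consume both services (both volumes reduced by ``y12`` in the
    counterfactual); the denominator is the sum of the two marginal costs at
    the actual point.  ``v12 > 1`` means chain economies.
    """
    m1 = OUTPUTS.index(link.upstream)
    m2 = OUTPUTS.index(link.downstream)
    if not (0 < link.y12 < min(point.y[m1], point.y[m2])):
        raise ValueError("y12 must lie strictly between 0 and both service "
                         "levels")
    lc = TranslogLevelCost(params, point, norm)
    return chain_scale_elasticity_lc(lc, point.y, m1, m2, link.y12)


# -------------------------------------------------- conditional derivative
def conditional_elasticity_derivative(params: TranslogParameters,
                                      point: _m.Point,
                                      norm: NormalizationPoint,
                                      output: str | int,
                                      conditioning: str | int,
                                      y_min: float,
                                      rel_step: float = 1e-4) -> float:
    """Numeric ``d v(y_m | .) / d y_n`` by central finite difference.

    The analytic derivative of the product-specific elasticity with respect
    to a conditioning service volume is unwieldy for a translog, so it is
    evaluated numerically; a negative value means the service's increasing
    returns diminish as the conditioning service grows.
    """
    m = OUTPUTS.index(output) if isinstance(output, str) else output
    n = OUTPUTS.index(conditioning) if isinstance(conditioning, str) else conditioning
    if n == m:
        raise ValueError("conditioning service must differ from the service "
                         "whose elasticity is evaluated")
    h = rel_step * point.y[n]
    vals = []
    for sgn in (+1.0, -1.0):
        pt = point.replace_output(n, point.y[n] + sgn * h)
        vals.append(product_specific_scale_elasticity(
            params, pt, norm, m, y_min))
    return (vals[0] - vals[1]) / (2 * h)


# ------------------------------------------------------------------ reporting
def default_chain_links(row) -> list[ChainLink]:
    """ER->admission and ER->outpatient links from a hospital's disposition shares.

    The joint admission volume counts ordinary ward admissions plus direct
    IC/stroke-unit/CCU admissions.
    """
    er = float(row["er_visits"])
    adm_share = float(row["disp_admission"]) + float(row["disp_admission_ic"])
    out_share = float(row["disp_outpatient"])
    return [
        ChainLink("er_visits", "admissions", round(adm_share * er)),
        ChainLink("er_visits", "outpatients", round(out_share * er)),
    ]


def quartile_report(params: TranslogParameters, panel: pd.DataFrame,
                    norm: NormalizationPoint,
                    y_min: dict[str, float] | None = None,
                    links: Callable | None = default_chain_links,
                    year: int | None = None) -> pd.DataFrame:
    """Quartiles over hospitals of marginal costs and all scale measures.

    Each hospital is evaluated at its own observed point.  ``y_min`` defaults
    to the per-service minimum over the panel.  Hospitals violating
    regularity (non-positive elasticity sum, infeasible counterfactual, or a
    non-positive predicted share) are excluded; the report carries the count
    in ``df.attrs["n_excluded"]``.

    Returns a table with rows ``mc_<service>``, ``overall``,
    ``product_specific_<service>``, ``chain_<up>_<down>`` and columns
    ``q1 / median / q3`` (linear interpolation), plus ``n`` hospitals used.
    """
    df = panel
    use_er = "er_visits" in df and df["er_visits"].notna().any() \
        and params.beta[OUTPUTS.index("er_visits")] != 0
    services = [o for o in OUTPUTS if use_er or o != "er_visits"]
    if not use_er:
        df = df.copy()
        df["er_visits"] = norm.outputs[OUTPUTS.index("er_visits")]
    else:
        df = df[df["er_visits"].notna()]
    if y_min is None:
        # smallest volumes observed anywhere in the estimation sample
        y_min = {o: float(df[o].min()) for o in services}
    if year is not None:
        df = df[df["year"] == year]

    rows: dict[str, list[float]] = {}
    n_excluded = 0
    for _, row in df.iterrows():
        point = _m.Point.from_row(row)
        try:
            shares = _m.predicted_shares(params, point.y, point.w, point.z,
                                         point.year, norm)
            if np.any(shares <= 0):
                raise RegularityError("non-positive predicted share")
            measures: dict[str, float] = {}
            lc = TranslogLevelCost(params, point, norm)
            for o in services:
                m = OUTPUTS.index(o)
                measures[f"mc_{o}"] = lc.marginal(point.y, m)
            measures["overall"] = overall_scale_elasticity(params, point, norm)
            for o in services:
                measures[f"product_specific_{o}"] = \
                    product_specific_scale_elasticity(
                        params, point, norm, o, y_min[o])
            if use_er and links is not None:
                for link in links(row):
                    measures[f"chain_{link.upstream}_{link.downstream}"] = \
                        chain_scale_elasticity(params, point, norm, link)
        except (RegularityError, ValueError):
            n_excluded += 1
            continue
        for k, v in measures.items():
            rows.setdefault(k, []).append(v)

    out = pd.DataFrame(
        {"q1": {k: np.percentile(v, 25) for k, v in rows.items()},
         "median": {k: np.percentile(v, 50) for k, v in rows.items()},
         "q3": {k: np.percentile(v, 75) for k, v in rows.items()},
         "n": {k: len(v) for k, v in rows.items()}})
    out.attrs["n_excluded"] = n_excluded
    return out
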