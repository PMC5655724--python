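"""Exact analytic evaluation of the translog cost system.

All functions operate on levels (service counts, prices in EUR, hedonic
characteristics) and standardize internally against a
:class:`~hospcost.params.NormalizationPoint`.  Inputs broadcast: pass 1-d
arrays for a single hospital-year or ``(n, k)`` arrays for a panel.

Model form (standardized variables ``yhat = log(y/ymean)``,
``what = log(w/wmean)``, centered hedonics ``zc = z - zmean``, trend ``t``)::

    log(C/Cmean) = a0 + year_effect
                 + beta'yhat + 1/2 yhat'B yhat
                 + gamma'what + 1/2 what'G what
                 + yhat' delta what + t * tau'what
                 + yhat_adm * theta'zc

Shephard's lemma gives the input cost shares as the price gradient of log
cost, and the output cost elasticities are its output gradient; both are
evaluated analytically below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (HEDONICS, IDX_ADMISSIONS, INPUTS, N_HEDONICS, N_INPUTS,
                     N_OUTPUTS, OUTPUTS, ModelDomainError, NormalizationPoint,
                     TranslogParameters)

__all__ = [
    "Point", "log_cost", "total_cost", "cost_elasticities", "cost_elasticity",
    "predicted_shares", "marginal_costs", "marginal_cost",
]


@dataclass
class Point:
    """A single evaluation point: levels of outputs, prices, hedonics, year."""

    y: np.ndarray
    w: np.ndarray
    z: np.ndarray
    year: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).reshape(N_OUTPUTS)
        self.w = np.asarray(self.w, dtype=float).reshape(N_INPUTS)
        self.z = np.asarray(self.z, dtype=float).reshape(N_HEDONICS)

    @classmethod
    def mean(cls, norm: NormalizationPoint, year: int | None = None) -> "Point":
        """The normalization point itself (the 'average' hospital, base year)."""
        return cls(norm.outputs.copy(), norm.prices.copy(), norm.hedonics.copy(),
                   norm.base_year if year is None else year)

    @classmethod
    def from_row(cls, row) -> "Point":
        return cls(
            y=np.array([row[c] for c in OUTPUTS], dtype=float),
            w=np.array([row[f"price_{c}"] for c in INPUTS], dtype=float),
            z=np.array([row[c] for c in HEDONICS], dtype=float),
            year=int(row["year"]),
        )

    def replace_output(self, m: int | str, value: float) -> "Point":
        m = OUTPUTS.index(m) if isinstance(m, str) else m
        y = self.y.copy()
        y[m] = value
        return Point(y, self.w, self.z, self.year)


def _check_positive(a: np.ndarray, names) -> None:
    a = np.atleast_2d(a)
    bad = ~(a > 0) | ~np.isfinite(a)
    if bad.any():
        j = int(np.argwhere(bad)[0, 1])
        raise ModelDomainError(
            f"'{names[j]}' must be strictly positive and finite for "
            f"log standardization")


def _standardize(y, w, z, year, norm: NormalizationPoint):
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    _check_positive(y, OUTPUTS)
    _check_positive(w, [f"price_{i}" for i in INPUTS])
    yhat = np.log(y / norm.outputs)
    what = np.log(w / norm.prices)
    zc = z - norm.hedonics
    t = norm.trend(year)
    return yhat, what, zc, t


def _year_effects(params: TranslogParameters, year):
    year = np.asarray(year)
    if year.ndim == 0:
        return params.year_effect(int(year))
    return np.array([params.year_effect(int(v)) for v in year.ravel()]
                    ).reshape(year.shape)


def log_cost(params: TranslogParameters, y, w, z, year,
             norm: NormalizationPoint):
    """Standardized log total cost, ``log(C / Cmean)``."""
    yh, wh, zc, t = _standardize(y, w, z, year, norm)
    val = (params.alpha0
           + _year_effects(params, year)
           + yh @ params.beta
           + 0.5 * np.einsum("...m,mn,...n->...", yh, params.B, yh)
           + wh @ params.gamma
           + 0.5 * np.einsum("...i,ij,...j->...", wh, params.G, wh)
           + np.einsum("...m,mi,...i->...", yh, params.delta, wh)
           + t * (wh @ params.tau)
           + yh[..., IDX_ADMISSIONS] * (zc @ params.theta))
    return val if np.ndim(val) else float(val)


def total_cost(params, y, w, z, year, norm):
    """Predicted total cost in levels (EUR / year)."""
    return np.exp(log_cost(params, y, w, z, year, norm)) * norm.total_cost


def cost_elasticities(params: TranslogParameters, y, w, z, year,
                      norm: NormalizationPoint):
    """Analytic ``d log C / d log y_m`` for all four services, shape ``(..., 4)``."""
    yh, wh, zc, _ = _standardize(y, w, z, year, norm)
    eps = (params.beta
           + yh @ params.B
           + wh @ params.delta.T)
    hed = zc @ params.theta
    eps = np.array(eps, dtype=float, copy=True)
    eps[..., IDX_ADMISSIONS] += hed
    return eps


def cost_elasticity(params, y, w, z, year, norm, output: str | int) -> float:
    """Cost elasticity with respect to one service (by name or index)."""
    if isinstance(output, str):
        if output not in OUTPUTS:
            raise KeyError(f"unknown service id {output!r}; expected one of "
                           f"{OUTPUTS}")
        output = OUTPUTS.index(output)
    return float(np.asarray(
        cost_elasticities(params, y, w, z, year, norm))[..., output])


def predicted_shares(params: TranslogParameters, y, w, z, year,
                     norm: NormalizationPoint):
    """Predicted input cost shares (Shephard), shape ``(..., 6)``.

    Sums to one exactly whenever ``params`` satisfies linear price
    homogeneity.
    """
    yh, wh, _, t = _standardize(y, w, z, year, norm)
    return (params.gamma
            + wh @ params.G
            + yh @ params.delta
            + np.multiply.outer(np.asarray(t, dtype=float), params.tau))


def marginal_costs(params, y, w, z, year, norm,
                   total_cost_level=None):
    """Marginal cost of each service in EUR per unit: ``eps_m * C / y_m``.

    ``total_cost_level`` defaults to the model-predicted cost at the point;
    pass observed cost to price out at actuals.
    """
    y = np.asarray(y, dtype=float)
    if total_cost_level is None:
        total_cost_level = total_cost(params, y, w, z, year, norm)
    eps = cost_elasticities(params, y, w, z, year, norm)
    return eps * np.expand_dims(np.asarray(total_cost_level, dtype=float), -1) / y


def marginal_cost(params, y, w, z, year, norm, output: str | int,
                  total_cost_level=None) -> float:
    m = OUTPUTS.index(output) if isinstance(output, str) else output
    y = np.asarray(y, dtype=float)
    if y[..., m] <= 0:
        raise ModelDomainError(f"'{OUTPUTS[m]}' level must be positive")
    return float(np.asarray(marginal_costs(
        params, y, w, z, year, norm, total_cost_level))[..., m])
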