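"""Parameter and normalization containers for the translog hospital cost system.

The cost system describes a multiproduct hospital producing four services
(inpatient admissions, outpatient visits, other — non-patient — revenues and
emergency-room visits) from six priced inputs (four labor categories, material
supplies and capital).  Total cost is a translog function of service volumes
and input prices, with year intercepts, trend-biased technical change in the
price terms, and hedonic case-mix interactions on the admissions elasticity.

Every variable entering the model is standardized at its arithmetic sample
mean before logging, so first-order coefficients are elasticities for the
"average" hospital.  The :class:`NormalizationPoint` freezes those means so
counterfactual evaluations reuse the estimation-sample standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import IO, Mapping

import numpy as np
import yaml

#: Service (output) identifiers, fixed order used by every array in the package.
OUTPUTS = ("admissions", "outpatients", "other_revenues", "er_visits")
#: Input identifiers: four labor categories, materials, capital.
INPUTS = ("man_adm", "nursing", "paramedical", "auxiliary", "material", "capital")
#: Hedonic case-mix characteristics interacting with (log) admissions.
HEDONICS = (
    "surgery_ortho",
    "psych_beds",
    "ic_beds",
    "expected_los",
    "neurosurgery",
    "cardiothoracic",
)

N_OUTPUTS = len(OUTPUTS)
N_INPUTS = len(INPUTS)
N_HEDONICS = len(HEDONICS)

IDX_ADMISSIONS = OUTPUTS.index("admissions")
IDX_ER = OUTPUTS.index("er_visits")


class ModelDomainError(ValueError):
    """A variable lies outside the model's domain (e.g. a non-positive level)."""


def _sym(a: np.ndarray, name: str, tol: float) -> None:
    if not np.allclose(a, a.T, atol=tol, rtol=0.0):
        raise ValueError(f"{name} is not symmetric (max asymmetry "
                         f"{np.abs(a - a.T).max():.3g})")


@dataclass
class TranslogParameters:
    """All coefficients of the translog cost system.

    Attributes
    ----------
    alpha0
        Intercept of the standardized log-cost equation (base year, mean point).
    year_effects
        Additive intercept shift per calendar year; the base (first) year is
        zero and may be omitted.
    beta
        First-order output coefficients, shape ``(4,)`` in :data:`OUTPUTS`
        order.  Equal to the cost elasticities at the normalization point.
    B
        Symmetric second-order output matrix, ``(4, 4)``; enters as
        ``1/2 yhat' B yhat``.
    gamma
        First-order price coefficients ``(6,)``; the predicted cost shares at
        the normalization point in the base year.
    G
        Symmetric second-order price matrix ``(6, 6)``; ``1/2 what' G what``.
    delta
        Output x price interactions ``(4, 6)``.
    tau
        Trend x price interactions ``(6,)``.
    theta
        Admissions x hedonic interactions ``(6,)`` in :data:`HEDONICS` order.

    Linear homogeneity of degree one in input prices requires
    ``sum(gamma) == 1`` and zero row sums of ``G``, ``delta`` (over inputs)
    and ``tau``; :meth:`validate` checks these and the symmetry of ``B``/``G``.
    """

    alpha0: float
    beta: np.ndarray
    B: np.ndarray
    gamma: np.ndarray
    G: np.ndarray
    delta: np.ndarray
    tau: np.ndarray
    theta: np.ndarray
    year_effects: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).reshape(N_OUTPUTS)
        self.B = np.asarray(self.B, dtype=float).reshape(N_OUTPUTS, N_OUTPUTS)
        self.gamma = np.asarray(self.gamma, dtype=float).reshape(N_INPUTS)
        self.G = np.asarray(self.G, dtype=float).reshape(N_INPUTS, N_INPUTS)
        self.delta = np.asarray(self.delta, dtype=float).reshape(N_OUTPUTS, N_INPUTS)
        self.tau = np.asarray(self.tau, dtype=float).reshape(N_INPUTS)
        self.theta = np.asarray(self.theta, dtype=float).reshape(N_HEDONICS)
        self.year_effects = {int(k): float(v) for k, v in self.year_effects.items()}

    # ------------------------------------------------------------------ checks
    def homogeneity_residuals(self) -> dict[str, np.ndarray]:
        """Residuals of the degree-one price-homogeneity restrictions.

        All entries are zero for a parameter set that is exactly linearly
        homogeneous in prices.
        """
        return {
            "gamma_sum": np.array([self.gamma.sum() - 1.0]),
            "G_row_sums": self.G.sum(axis=1),
            "delta_row_sums": self.delta.sum(axis=1),
            "tau_sum": np.array([self.tau.sum()]),
        }

    def is_homogeneous(self, tol: float = 1e-10) -> bool:
        return all(np.abs(v).max() <= tol
                   for v in self.homogeneity_residuals().values())

    def validate(self, tol: float = 1e-10) -> "TranslogParameters":
        """Check symmetry and homogeneity; raise ``ValueError`` on failure."""
        _sym(self.B, "B", tol)
        _sym(self.G, "G", tol)
        if not self.is_homogeneous(tol):
            worst = max(np.abs(v).max()
                        for v in self.homogeneity_residuals().values())
            raise ValueError(
                f"parameters violate linear price homogeneity (max residual "
                f"{worst:.3g} > tol {tol:.3g})")
        return self

    def year_effect(self, year: int) -> float:
        return self.year_effects.get(int(year), 0.0)

    # -------------------------------------------------------------- projection
    def exactify_homogeneity(self) -> "TranslogParameters":
        """Project onto the homogeneity constraint set (least-squares).

        Rounding in published coefficient tables leaves row sums of order
        1e-3; this spreads each residual uniformly over the six inputs
        (double-centering for ``G``, preserving symmetry).
        """
        n = N_INPUTS
        gamma = self.gamma - (self.gamma.sum() - 1.0) / n
        r = self.G.sum(axis=1)
        s = self.G.sum()
        G = self.G - r[:, None] / n - r[None, :] / n + s / n**2
        G = 0.5 * (G + G.T)      # remove float-order asymmetry (~1e-18)
        delta = self.delta - self.delta.sum(axis=1, keepdims=True) / n
        tau = self.tau - self.tau.sum() / n
        return replace(self, gamma=gamma, G=G, delta=delta, tau=tau)

    # ----------------------------------------------------------- serialization
    def to_dict(self) -> dict[str, float]:
        """Flat key-value form mirroring the published coefficient-table rows."""
        d: dict[str, float] = {"constant": float(self.alpha0)}
        for year in sorted(self.year_effects):
            d[f"year {year}"] = self.year_effects[year]
        for m, om in enumerate(OUTPUTS):
            d[om] = float(self.beta[m])
        for m in range(N_OUTPUTS):
            for nn in range(m, N_OUTPUTS):
                d[f"{OUTPUTS[m]} x {OUTPUTS[nn]}"] = float(self.B[m, nn])
        for i, ii in enumerate(INPUTS):
            d[f"price {ii}"] = float(self.gamma[i])
        for i in range(N_INPUTS):
            for j in range(i, N_INPUTS):
                d[f"price {INPUTS[i]} x price {INPUTS[j]}"] = float(self.G[i, j])
        for m, om in enumerate(OUTPUTS):
            for i, ii in enumerate(INPUTS):
                d[f"{om} x price {ii}"] = float(self.delta[m, i])
        for i, ii in enumerate(INPUTS):
            d[f"trend x price {ii}"] = float(self.tau[i])
        for k, hk in enumerate(HEDONICS):
            d[f"admissions x {hk}"] = float(self.theta[k])
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "TranslogParameters":
        """Inverse of :meth:`to_dict`; absent keys default to zero."""
        d = dict(d)
        beta = np.array([d.pop(o, 0.0) for o in OUTPUTS], dtype=float)
        B = np.zeros((N_OUTPUTS, N_OUTPUTS))
        for m in range(N_OUTPUTS):
            for nn in range(m, N_OUTPUTS):
                B[m, nn] = B[nn, m] = d.pop(f"{OUTPUTS[m]} x {OUTPUTS[nn]}", 0.0)
        gamma = np.array([d.pop(f"price {i}", 0.0) for i in INPUTS])
        G = np.zeros((N_INPUTS, N_INPUTS))
        for i in range(N_INPUTS):
            for j in range(i, N_INPUTS):
                G[i, j] = G[j, i] = d.pop(
                    f"price {INPUTS[i]} x price {INPUTS[j]}", 0.0)
        delta = np.array([[d.pop(f"{o} x price {i}", 0.0) for i in INPUTS]
                          for o in OUTPUTS])
        tau = np.array([d.pop(f"trend x price {i}", 0.0) for i in INPUTS])
        theta = np.array([d.pop(f"admissions x {h}", 0.0) for h in HEDONICS])
        alpha0 = float(d.pop("constant", 0.0))
        years = {}
        for key in list(d):
            if key.startswith("year "):
                years[int(key.split()[1])] = float(d.pop(key))
        if d:
            raise KeyError(f"unrecognized coefficient keys: {sorted(d)}")
        return cls(alpha0=alpha0, beta=beta, B=B, gamma=gamma, G=G,
                   delta=delta, tau=tau, theta=theta, year_effects=years)

    def to_yaml(self, stream: IO[str] | None = None) -> str | None:
        return yaml.safe_dump(self.to_dict(), stream, sort_keys=False)

    @classmethod
    def from_yaml(cls, stream: str | IO[str]) -> "TranslogParameters":
        return cls.from_dict(yaml.safe_load(stream))


@dataclass
class NormalizationPoint:
    """Arithmetic sample means used to standardize every model variable.

    ``trend(year) = (year - first_year) / trend_span`` is zero in the first
    sample year and one in the last, so trend-interaction coefficients are
    per-sample-span drifts.
    """

    outputs: np.ndarray          # (4,) mean service levels
    prices: np.ndarray           # (6,) mean input prices
    hedonics: np.ndarray         # (6,) mean hedonic characteristics
    total_cost: float            # mean total cost (EUR / year)
    base_year: int               # first sample year; year effect and trend zero
    trend_span: float            # years from first to last sample year

    def __post_init__(self) -> None:
        self.outputs = np.asarray(self.outputs, dtype=float).reshape(N_OUTPUTS)
        self.prices = np.asarray(self.prices, dtype=float).reshape(N_INPUTS)
        self.hedonics = np.asarray(self.hedonics, dtype=float).reshape(N_HEDONICS)
        if np.any(self.outputs <= 0) or np.any(self.prices <= 0) \
                or self.total_cost <= 0:
            raise ModelDomainError(
                "normalization means of log-transformed variables must be "
                "strictly positive")
        if self.trend_span <= 0:
            raise ValueError("trend_span must be positive")

    def trend(self, year) -> np.ndarray | float:
        return (np.asarray(year, dtype=float) - self.base_year) / self.trend_span

    @classmethod
    def from_panel(cls, panel, cost_col: str = "total_cost") -> "NormalizationPoint":
        """Means over a hospital-year panel (column names per :mod:`hospcost.simulate`).

        ER-visit means are taken over the ER-complete rows only.
        """
        outputs = np.array([panel[c].dropna().mean() for c in OUTPUTS])
        prices = np.array([panel[f"price_{c}"].mean() for c in INPUTS])
        hedonics = np.array([panel[c].mean() for c in HEDONICS])
        years = panel["year"].astype(int)
        return cls(outputs=outputs, prices=prices, hedonics=hedonics,
                   total_cost=float(panel[cost_col].mean()),
                   base_year=int(years.min()),
                   trend_span=float(max(years.max() - years.min(), 1)))
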