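"""Synthetic hospital-year panels with the structure the cost system assumes.

The generator emulates the Dutch general-hospital study setting: a panel of
hospitals over 2003-2011 with right-skewed, cross-correlated service volumes
matched to the published 2011 moments, region x year labor unit values, a
CPI-driven material index, capital components tied to admissions, ER
disposition shares near the published survey means, and — in
:func:`generate_costs` — total costs and input cost shares generated from a
known translog parameter set with correlated, adding-up-consistent noise.

ER-visit data are observed for only a fraction of hospitals (the study's
249-of-682 subsample); the true volumes still drive generated costs, as every
hospital operates an ER whether or not it reported the survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import model as _m
from . import prices as _prices
from . import reference as _ref
from .params import (HEDONICS, INPUTS, OUTPUTS, NormalizationPoint,
                     TranslogParameters)

__all__ = ["SimulationConfig", "generate_panel", "generate_costs",
           "calibrate_cost_noise"]

LABOR_CATEGORIES = ("man_adm", "nursing", "paramedical", "auxiliary")

#: Log-scale cross-service correlations; admissions and ER visits co-move
#: strongly (0.8), the remaining pairs moderately.  Configurable — the study
#: reports no joint output distribution, only marginal moments.
DEFAULT_OUTPUT_CORR = np.array([
    [1.0, 0.7, 0.4, 0.8],
    [0.7, 1.0, 0.4, 0.6],
    [0.4, 0.4, 1.0, 0.3],
    [0.8, 0.6, 0.3, 1.0],
])


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic panel.

    Moment targets are the published 2011 descriptive statistics; sample
    dimensions reproduce the 682-observation panel (76 hospitals x 9 years)
    with ER data for roughly the 249-observation subsample.
    """

    n_hospitals: int = 76
    years: Sequence[int] = _ref.SAMPLE_YEARS
    er_coverage: float = _ref.N_ER / _ref.N_PANEL
    region_count: int = 8
    seed: int = 0

    output_means: Mapping[str, float] = field(
        default_factory=lambda: dict(_ref.OUTPUT_MEANS))
    output_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(_ref.OUTPUT_SDS))
    output_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_OUTPUT_CORR.copy())
    #: Share of log-output variance carried by the permanent hospital effect.
    panel_persistence: float = 0.8

    hedonic_means: Mapping[str, float] = field(
        default_factory=lambda: dict(_ref.HEDONIC_MEANS))
    hedonic_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(_ref.HEDONIC_SDS))

    disposition_means: Mapping[str, float] = field(
        default_factory=lambda: dict(_ref.DISPOSITION_MEANS))
    disposition_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(_ref.DISPOSITION_SDS))

    # input-price construction raw material
    labor_base: Mapping[str, float] = field(default_factory=lambda: dict(
        man_adm=55_000.0, nursing=52_000.0, paramedical=48_000.0,
        auxiliary=35_000.0))
    region_price_sd: float = 0.03      # log-scale regional wage differentials
    wage_growth: float = 0.025         # per year
    unit_value_noise_sd: float = 0.02  # idiosyncratic (endogenous) component
    cpi_growth: float = 0.018          # per year
    capital_weights: Mapping[str, float] = field(default_factory=lambda: dict(
        beds=20_000.0, ic_beds_n=60_000.0, radiotherapists=300_000.0,
        theatres=400_000.0))
    capital_noise_sd: float = 0.05

    # cost / share generation
    mean_total_cost: float = _ref.MEAN_TOTAL_COST
    cost_noise_sd: float | None = None   # None: calibrate to target_r2
    target_r2: float = 0.98
    share_noise_sd: float = 0.02

    def validate(self) -> "SimulationConfig":
        if not 0 < self.er_coverage <= 1:
            raise ConfigError("er_coverage must lie in (0, 1]")
        if self.n_hospitals < 1 or self.region_count < 1:
            raise ConfigError("n_hospitals and region_count must be positive")
        if not 0 <= self.panel_persistence <= 1:
            raise ConfigError("panel_persistence must lie in [0, 1]")
        for o in OUTPUTS:
            m, s = self.output_means[o], self.output_sds[o]
            if m <= 0 or s < 0:
                raise ConfigError(f"output {o}: mean must be > 0, sd >= 0")
            if s > m:
                raise ConfigError(
                    f"output {o}: sd {s} exceeds mean {m}; coefficients of "
                    f"variation above one are outside the calibrated "
                    f"lognormal range")
        for d, s in self.disposition_sds.items():
            if s < 0 or self.disposition_means[d] < 0:
                raise ConfigError(f"disposition {d}: negative mean or sd")
        if any(s < 0 for s in self.hedonic_sds.values()):
            raise ConfigError("hedonic sds must be non-negative")
        np.linalg.cholesky(np.asarray(self.output_corr)
                           + 1e-12 * np.eye(len(OUTPUTS)))
        return self


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_panel(config: SimulationConfig | None = None,
                   seed: int | None = None) -> pd.DataFrame:
    """Hospital-year panel of outputs, hedonics, dispositions and prices.

    Returns one row per hospital-year with service volumes, hedonic
    characteristics, disposition shares, region/year identifiers, the raw
    price-construction material (unit values, CPI, capital cost and
    components) and the constructed ``price_*`` columns.  ``er_visits`` is
    masked (NaN) for hospitals outside the ER survey; the generated volume is
    kept in ``er_visits_true`` so cost generation can use it.
    """
    config = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, years = config.n_hospitals, list(config.years)
    y0 = years[0]
    nobs = n * len(years)

    hospital = np.repeat(np.arange(n), len(years))
    year = np.tile(years, n)
    region = np.repeat(rng.integers(0, config.region_count, size=n), len(years))

    # --- outputs: correlated lognormal with a permanent hospital component
    corr = np.asarray(config.output_corr, dtype=float)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(len(OUTPUTS)))
    rho = config.panel_persistence
    u = rng.standard_normal((n, len(OUTPUTS))) @ L.T
    e = rng.standard_normal((nobs, len(OUTPUTS))) @ L.T
    zlat = np.sqrt(rho) * np.repeat(u, len(years), axis=0) \
        + np.sqrt(1.0 - rho) * e
    Y = np.empty((nobs, len(OUTPUTS)))
    for j, o in enumerate(OUTPUTS):
        mu, sig = _lognormal_params(config.output_means[o],
                                    config.output_sds[o])
        Y[:, j] = np.exp(mu + sig * zlat[:, j])
    panel = pd.DataFrame({"hospital": hospital, "year": year, "region": region})
    for j, o in enumerate(OUTPUTS):
        panel[o] = Y[:, j]

    # --- hedonics: hospital-level characteristics, constant over years
    lo = dict(surgery_ortho=0.005, psych_beds=0.0, ic_beds=0.0,
              expected_los=1.5, neurosurgery=0.0, cardiothoracic=0.0)
    hi = dict(surgery_ortho=0.5, psych_beds=np.inf, ic_beds=np.inf,
              expected_los=np.inf, neurosurgery=0.5, cardiothoracic=0.5)
    for h in HEDONICS:
        vals = rng.normal(config.hedonic_means[h], config.hedonic_sds[h], n)
        panel[h] = np.repeat(np.clip(vals, lo[h], hi[h]), len(years))

    # --- ER disposition shares: near the survey means, renormalized to one
    disp = np.column_stack([
        rng.normal(config.disposition_means[d], config.disposition_sds[d], n)
        for d in _ref.DISPOSITIONS])
    disp = np.clip(disp, 0.002, None)
    disp /= disp.sum(axis=1, keepdims=True)
    for k, d in enumerate(_ref.DISPOSITIONS):
        panel[f"disp_{d}"] = np.repeat(disp[:, k], len(years))

    # --- labor unit values and their region x year price proxies
    region_fx = rng.normal(0.0, config.region_price_sd,
                           (config.region_count, len(LABOR_CATEGORIES)))
    t = (year - y0).astype(float)
    for k, cat in enumerate(LABOR_CATEGORIES):
        uv = config.labor_base[cat] * np.exp(
            region_fx[region, k] + config.wage_growth * t
            + rng.normal(0.0, config.unit_value_noise_sd, nobs))
        panel[f"unit_value_{cat}"] = uv
    long = panel.melt(
        id_vars=["hospital", "year", "region"],
        value_vars=[f"unit_value_{c}" for c in LABOR_CATEGORIES],
        var_name="category", value_name="unit_value")
    long["category"] = long["category"].str.removeprefix("unit_value_")
    long["price"] = _prices.labor_price_proxy(long)
    wide = long.pivot_table(index=["hospital", "year"], columns="category",
                            values="price")
    for cat in LABOR_CATEGORIES:
        panel[f"price_{cat}"] = wide[cat].reindex(
            pd.MultiIndex.from_arrays([hospital, year])).to_numpy()

    # --- material price: national CPI path, base one in the first year
    cpi = pd.Series((1.0 + config.cpi_growth) ** np.arange(len(years)),
                    index=years)
    index = _prices.material_price_index(cpi, y0)
    panel["cpi"] = index.reindex(panel["year"]).to_numpy()
    panel["price_material"] = panel["cpi"]

    # --- capital: components tied to admissions, regression-weighted volume
    elos = panel["expected_los"].to_numpy()
    beds = np.round(panel["admissions"].to_numpy() * elos / 365.0 / 0.85)
    ic_n = np.round(panel["ic_beds"].to_numpy()
                    * panel["admissions"].to_numpy() / 1000.0)
    radio = np.round(2.0 * panel["admissions"].to_numpy()
                     / config.output_means["admissions"])
    theatres = np.maximum(np.round(beds / 40.0), 1.0)
    comp = pd.DataFrame(dict(beds=beds, ic_beds_n=ic_n,
                             radiotherapists=radio, theatres=theatres))
    w_true = np.array([config.capital_weights[c]
                       for c in _prices.CAPITAL_COMPONENTS])
    panel[list(_prices.CAPITAL_COMPONENTS)] = comp
    panel["capital_cost"] = (comp.to_numpy() @ w_true) * np.exp(
        rng.normal(0.0, config.capital_noise_sd, nobs))
    _, volume = _prices.capital_volume_index(
        panel["capital_cost"], panel[list(_prices.CAPITAL_COMPONENTS)])
    panel["capital_volume"] = volume
    panel["price_capital"] = _prices.capital_price(
        panel["capital_cost"], volume).to_numpy()

    # --- ER survey coverage mask (by hospital)
    n_covered = int(round(config.er_coverage * n))
    covered = np.zeros(n, dtype=bool)
    covered[rng.permutation(n)[:n_covered]] = True
    panel["er_observed"] = covered[hospital]
    panel["er_visits_true"] = panel["er_visits"]
    panel.loc[~panel["er_observed"], "er_visits"] = np.nan
    return panel


def calibrate_cost_noise(log_cost_clean: np.ndarray, target_r2: float) -> float:
    """Noise sd such that the cost equation's population R^2 hits the target."""
    if not 0 < target_r2 < 1:
        raise ConfigError("target_r2 must lie in (0, 1)")
    var = float(np.var(log_cost_clean))
    return float(np.sqrt(var * (1.0 - target_r2) / target_r2))


def generate_costs(panel: pd.DataFrame, true_params: TranslogParameters,
                   config: SimulationConfig | None = None,
                   seed: int | None = None
                   ) -> tuple[pd.DataFrame, NormalizationPoint]:
    """Add total cost and observed cost shares generated from ``true_params``.

    Log cost is the exact translog evaluation plus Gaussian noise (sd either
    fixed in the config or calibrated so the cost equation's R^2 matches the
    target); observed shares are the predicted shares plus mean-zero noise
    projected to sum to zero per row, preserving the adding-up (singular
    covariance) structure the system estimator assumes.  Returns the extended
    panel and the normalization point used, which estimation should reuse.
    """
    config = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    true_params.validate(tol=1e-8)

    panel = panel.copy()
    er = panel["er_visits_true"] if "er_visits_true" in panel \
        else panel["er_visits"]
    Y = np.column_stack([er if o == "er_visits" else panel[o]
                         for o in OUTPUTS])
    W = np.column_stack([panel[f"price_{i}"] for i in INPUTS])
    Z = np.column_stack([panel[h] for h in HEDONICS])
    years = panel["year"].to_numpy()

    norm = NormalizationPoint(
        outputs=Y.mean(axis=0), prices=W.mean(axis=0),
        hedonics=Z.mean(axis=0), total_cost=config.mean_total_cost,
        base_year=int(years.min()),
        trend_span=float(max(years.max() - years.min(), 1)))

    logc = _m.log_cost(true_params, Y, W, Z, years, norm)
    sd = config.cost_noise_sd
    if sd is None:
        sd = calibrate_cost_noise(logc, config.target_r2)
    logc_obs = logc + rng.normal(0.0, sd, len(panel))
    panel["total_cost"] = config.mean_total_cost * np.exp(logc_obs)

    shares = _m.predicted_shares(true_params, Y, W, Z, years, norm)
    noise = rng.normal(0.0, config.share_noise_sd, shares.shape)
    noise -= noise.mean(axis=1, keepdims=True)   # adding-up projection
    shares_obs = shares + noise
    for i, inp in enumerate(INPUTS):
        panel[f"share_{inp}"] = shares_obs[:, i]
        panel[f"cost_{inp}"] = shares_obs[:, i] * panel["total_cost"]
    return panel, norm
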