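"""Published reference coefficients and study-scale normalization.

Ships the coefficient estimates of a two-stage translog cost-system fit to
the Dutch general-hospital panel (annual-report data 2003-2011, n = 682;
ER-survey subsample, n = 249) as a packaged fixture, together with the
descriptive 2011 sample moments (means, dispersions, ER disposition shares)
that anchor the synthetic-data generator.

Stage 1 excludes ER visits; stage 2 re-estimates the output terms on the
ER-complete subsample with every price term fixed at its stage-1 value.
``reference_parameters(stage=2)`` therefore returns the merged set a user
would evaluate: stage-2 output coefficients over the carried-over stage-1
price structure.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .params import (HEDONICS, INPUTS, OUTPUTS, NormalizationPoint,
                     TranslogParameters)

__all__ = [
    "reference_parameters", "ground_truth_parameters",
    "reference_normalization", "OUTPUT_MEANS", "OUTPUT_SDS", "HEDONIC_MEANS",
    "HEDONIC_SDS", "DISPOSITIONS", "DISPOSITION_MEANS", "DISPOSITION_SDS",
    "SHARE_MEANS", "MEAN_TOTAL_COST", "SAMPLE_YEARS", "N_PANEL", "N_ER",
]

# ----------------------------------------------------------- descriptive 2011
#: Mean service volumes per hospital-year (counts; other_revenues in EUR).
OUTPUT_MEANS = dict(zip(OUTPUTS, (44_767.0, 76_347.0, 14_896.0, 24_115.0)))
OUTPUT_SDS = dict(zip(OUTPUTS, (20_854.0, 29_048.0, 10_079.0, 12_771.0)))
OUTPUT_MINS = dict(zip(OUTPUTS, (16_768.0, 31_247.0, 1_982.0, 7_943.0)))

HEDONIC_MEANS = dict(zip(HEDONICS, (0.117, 0.27, 0.23, 3.3, 0.008, 0.003)))
HEDONIC_SDS = dict(zip(HEDONICS, (0.024, 0.40, 0.09, 0.3, 0.019, 0.009)))

#: Treatment disposition following an ER visit (shares of ER patients).
DISPOSITIONS = ("none", "outpatient", "admission", "admission_ic",
                "admission_other_hospital", "other")
DISPOSITION_MEANS = dict(zip(
    DISPOSITIONS, (0.35, 0.27, 0.32, 0.03, 0.01, 0.03)))
DISPOSITION_SDS = dict(zip(
    DISPOSITIONS, (0.19, 0.17, 0.08, 0.03, 0.01, 0.03)))

#: Observed mean input cost shares.
SHARE_MEANS = dict(zip(INPUTS, (0.10, 0.34, 0.03, 0.09, 0.34, 0.09)))

MEAN_TOTAL_COST = 147.8e6          # EUR / hospital-year
SAMPLE_YEARS = tuple(range(2003, 2012))
N_PANEL = 682                      # cost/production panel observations
N_ER = 249                         # ER-complete observations

# Plausible mean input-price levels (EUR/FTE-year for labor; materials index
# base 1; capital price = mean capital cost per unit of mean-one volume).
# Evaluations at the normalization point do not depend on these levels.
_PRICE_MEANS = dict(
    man_adm=55_000.0, nursing=52_000.0, paramedical=48_000.0,
    auxiliary=35_000.0, material=1.0,
    capital=SHARE_MEANS["capital"] * MEAN_TOTAL_COST,
)


def _load(name: str) -> dict:
    with resources.files("hospcost.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def reference_parameters(stage: int = 2) -> TranslogParameters:
    """The packaged published coefficient set.

    ``stage=1``: the full-panel fit without ER terms (ER coefficients zero).
    ``stage=2``: the ER-subsample re-fit merged over the fixed stage-1 price
    structure, year effects, cross-output and hedonic terms.

    Printed coefficients are rounded to three decimals, so homogeneity holds
    only to about 1e-3 on this set; see :func:`ground_truth_parameters` for an
    exactly regular variant.
    """
    d = _load("reference_stage1.yaml")
    if stage == 2:
        d.update(_load("reference_stage2.yaml"))
    elif stage != 1:
        raise ValueError("stage must be 1 or 2")
    return TranslogParameters.from_dict(d)


def ground_truth_parameters() -> TranslogParameters:
    """Regularized stage-2 parameter set used as simulation ground truth.

    Two adjustments make the published values an exactly well-behaved cost
    function: (i) homogeneity residuals from table rounding are projected out
    (:meth:`TranslogParameters.exactify_homogeneity`); (ii) the price Hessian
    ``H = G + s s' - diag(s)`` at the mean shares, which has one small
    positive eigenvalue on the printed values, is clipped to negative
    semi-definite and ``G`` rebuilt from it.  The clip leaves the unit null
    vector of ``H`` intact, so homogeneity survives; curvature away from that
    eigendirection is unchanged.
    """
    p = reference_parameters(stage=2).exactify_homogeneity()
    s = p.gamma
    H = p.G + np.outer(s, s) - np.diag(s)
    lam, V = np.linalg.eigh(H)
    # the unit vector spans H's structural null space (homogeneity); clip the
    # remaining eigenvalues to a -0.01 margin so curvature also holds in a
    # neighborhood of the mean, not only at the point itself
    ones = np.ones(len(s)) / np.sqrt(len(s))
    structural = np.argmax(np.abs(V.T @ ones))
    clipped = np.minimum(lam, -0.01)
    clipped[structural] = 0.0
    H_nsd = (V * clipped) @ V.T
    G = H_nsd - np.outer(s, s) + np.diag(s)
    G = 0.5 * (G + G.T)
    p.G = G
    return p.validate(tol=1e-8)


def reference_normalization() -> NormalizationPoint:
    """Normalization point built from the published 2011 sample moments."""
    return NormalizationPoint(
        outputs=np.array([OUTPUT_MEANS[o] for o in OUTPUTS]),
        prices=np.array([_PRICE_MEANS[i] for i in INPUTS]),
        hedonics=np.array([HEDONIC_MEANS[h] for h in HEDONICS]),
        total_cost=MEAN_TOTAL_COST,
        base_year=SAMPLE_YEARS[0],
        trend_span=float(SAMPLE_YEARS[-1] - SAMPLE_YEARS[0]),
    )
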