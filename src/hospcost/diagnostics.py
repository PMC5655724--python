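"""Regularity diagnostics and fit-quality reporting.

A well-behaved cost function is monotone in input prices (positive input
demands, i.e. positive predicted cost shares) and concave in input prices.
For a translog, concavity at a point is equivalent to negative
semi-definiteness of ``H = G + s s' - diag(s)`` where ``s`` are the predicted
shares at that point; the Allen partial elasticities of substitution are
``sigma_ij = H_ij / (s_i s_j)``, and negativity of the own (diagonal) Allen
elasticities is the necessary first check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import model as _m
from .params import HEDONICS, INPUTS, OUTPUTS, NormalizationPoint, \
    TranslogParameters

__all__ = ["monotonicity_check", "concavity_check", "fit_summary",
           "allen_substitution_matrix"]


def _panel_arrays(params, panel, norm):
    df = panel.copy()
    if "er_visits" in df and df["er_visits"].isna().any():
        # an unused (stage-1) or unobserved ER level: neutral at the mean
        df = df.copy()
        df["er_visits"] = df["er_visits"].fillna(
            norm.outputs[OUTPUTS.index("er_visits")])
    Y = np.column_stack([df[o] for o in OUTPUTS]).astype(float)
    W = np.column_stack([df[f"price_{i}"] for i in INPUTS]).astype(float)
    Z = np.column_stack([df[h] for h in HEDONICS]).astype(float)
    years = df["year"].to_numpy()
    return Y, W, Z, years


def monotonicity_check(params: TranslogParameters, panel: pd.DataFrame,
                       norm: NormalizationPoint
                       ) -> tuple[pd.Series, float]:
    """Positive predicted input demand at every observation.

    Returns a per-observation boolean (all six predicted shares strictly
    positive) and the fraction of observations passing.
    """
    Y, W, Z, years = _panel_arrays(params, panel, norm)
    shares = _m.predicted_shares(params, Y, W, Z, years, norm)
    ok = pd.Series((shares > 0).all(axis=1), index=panel.index,
                   name="monotone")
    return ok, float(ok.mean())


def allen_substitution_matrix(params: TranslogParameters,
                              shares: np.ndarray) -> np.ndarray:
    """Allen partial substitution elasticities at given predicted shares."""
    s = np.asarray(shares, dtype=float)
    H = params.G + np.outer(s, s) - np.diag(s)
    return H / np.outer(s, s)


def concavity_check(params: TranslogParameters, panel: pd.DataFrame,
                    norm: NormalizationPoint,
                    tol: float = 1e-8) -> pd.DataFrame:
    """Own-substitution negativity and negative semi-definiteness per row.

    ``own_negative``: every own Allen substitution elasticity (equivalently
    every diagonal of ``H``) below zero.  ``nsd``: largest eigenvalue of
    ``H`` at most ``tol`` — the loose default tolerates the tiny positive
    eigenvalues that arise from rounded coefficients; pass ``tol=0`` for
    strict curvature.  Rows with a non-positive predicted share are marked
    invalid (monotonicity must pass first).
    """
    Y, W, Z, years = _panel_arrays(params, panel, norm)
    shares = _m.predicted_shares(params, Y, W, Z, years, norm)
    out = []
    for s in np.atleast_2d(shares):
        if np.any(s <= 0):
            out.append((False, False, False, np.nan))
            continue
        H = params.G + np.outer(s, s) - np.diag(s)
        lam = np.linalg.eigvalsh(H)
        out.append((True, bool(np.all(np.diag(H) < 0)),
                    bool(lam.max() <= tol), float(lam.max())))
    return pd.DataFrame(out, index=panel.index,
                        columns=["valid", "own_negative", "nsd",
                                 "max_eigenvalue"])


def fit_summary(results) -> dict:
    """Headline fit quality of a :class:`TranslogCostResults`.

    Cost-equation R^2 (on standardized log cost), the share of free
    coefficients significant at the 5% level (two-sided z test), and
    convergence information.
    """
    pv = results.pvalues
    return dict(
        r2_cost=float(results.rsquared["cost"]),
        frac_significant=float((pv < 0.05).mean()),
        n_free=len(results.free_names),
        n_obs=len(results.model.panel),
        n_iterations=len(results.iterations),
        converged=bool(results.converged),
    )
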