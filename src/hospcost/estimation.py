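"""System estimation of the translog cost function with share equations.

The system stacks, per hospital-year, the standardized log-cost equation and
five of the six input cost-share equations (shares add to one, making the
full share-error covariance singular, so one equation is dropped).  Symmetry
of the second-order matrices and linear price homogeneity are imposed by
reparameterization — each full coefficient is an affine function of the free
parameter vector — and the cross-equation-correlated errors are handled by
iterated feasible GLS (Zellner/SUR with cross-equation restrictions, a
standard minimum-distance implementation).  At convergence the estimates do
not depend on which share equation was dropped.

The entry points follow the statsmodels pattern: build a
:class:`TranslogCostModel` from a panel ``DataFrame`` and call :meth:`fit`,
which returns a :class:`TranslogCostResults` carrying the estimates, their
covariance, diagnostics and a ``summary()`` table.  :func:`two_stage_fit`
runs the study's two-stage procedure: stage 1 without ER terms on the full
panel, stage 2 on the ER-complete subsample with every price-structure
coefficient fixed at its stage-1 value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import diagnostics as _diag
from . import scale as _scale
from .params import (HEDONICS, INPUTS, OUTPUTS, ModelDomainError,
                     NormalizationPoint, TranslogParameters)

__all__ = ["SystemSpec", "TranslogCostModel", "TranslogCostResults",
           "two_stage_fit", "build_design", "constraint_map"]

_CAP = "capital"


class SingularSystemError(np.linalg.LinAlgError):
    pass


@dataclass
class SystemSpec:
    """Which coefficients are estimated, fixed, or eliminated.

    ``fixed`` maps free-coefficient names (as in
    :meth:`TranslogParameters.to_dict`) to values; coefficients made
    redundant by homogeneity (everything involving the capital price) follow
    automatically and cannot be fixed directly.
    """

    outputs: tuple[str, ...] = OUTPUTS
    include_hedonics: bool = True
    include_year_effects: bool = True
    dropped_share: str = _CAP
    fixed: dict[str, float] = field(default_factory=dict)
    tol: float = 1e-8
    max_iter: int = 500

    def __post_init__(self) -> None:
        unknown = set(self.outputs) - set(OUTPUTS)
        if unknown:
            raise ValueError(f"unknown outputs {sorted(unknown)}")
        if self.dropped_share not in INPUTS:
            raise ValueError(f"unknown share equation {self.dropped_share!r}")


# ------------------------------------------------------------ coefficient map
def _full_names(spec: SystemSpec, years: list[int]) -> list[str]:
    names = ["constant"]
    if spec.include_year_effects:
        names += [f"year {y}" for y in years[1:]]
    names += list(spec.outputs)
    for a, om in enumerate(spec.outputs):
        for on in spec.outputs[a:]:
            names.append(f"{om} x {on}")
    names += [f"price {i}" for i in INPUTS]
    for a, ii in enumerate(INPUTS):
        for jj in INPUTS[a:]:
            names.append(f"price {ii} x price {jj}")
    for om in spec.outputs:
        names += [f"{om} x price {ii}" for ii in INPUTS]
    names += [f"trend x price {ii}" for ii in INPUTS]
    if spec.include_hedonics:
        names += [f"admissions x {h}" for h in HEDONICS]
    return names


def _dependent_expression(name: str) -> dict[str, float] | None:
    """Affine expression (in other full names) for homogeneity-eliminated
    coefficients; the key ``""`` holds the constant term."""
    others = [i for i in INPUTS if i != _CAP]
    if name == f"price {_CAP}":
        return {"": 1.0, **{f"price {i}": -1.0 for i in others}}
    if name == f"price {_CAP} x price {_CAP}":
        # g_cc = sum_{i,j != cap} g_ij, off-diagonal pairs counted twice
        expr: dict[str, float] = {"": 0.0}
        for a, ii in enumerate(others):
            for jj in others[a:]:
                expr[f"price {ii} x price {jj}"] = 2.0 if ii != jj else 1.0
        return expr
    if name.startswith("price ") and name.endswith(f" x price {_CAP}"):
        ii = name[len("price "):-len(f" x price {_CAP}")]
        expr = {"": 0.0}
        for jj in others:
            a, b = sorted((INPUTS.index(ii), INPUTS.index(jj)))
            expr_key = f"price {INPUTS[a]} x price {INPUTS[b]}"
            expr[expr_key] = expr.get(expr_key, 0.0) - 1.0
        return expr
    if name.endswith(f" x price {_CAP}") and not name.startswith("price "):
        om = name[:-len(f" x price {_CAP}")]
        return {"": 0.0, **{f"{om} x price {i}": -1.0 for i in others}}
    if name == f"trend x price {_CAP}":
        return {"": 0.0, **{f"trend x price {i}": -1.0 for i in others}}
    return None


def constraint_map(spec: SystemSpec, years: list[int]
                   ) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Affine map from free parameters to the full coefficient vector.

    Returns ``(full_names, free_names, A, c)`` with ``full = A @ free + c``.
    Symmetry is structural (one name per unordered pair); homogeneity
    eliminates every capital-price coefficient; ``spec.fixed`` entries move
    into the constant part.
    """
    full = _full_names(spec, years)
    free, fixed_vals = [], {}
    exprs: dict[str, dict[str, float]] = {}
    for name in full:
        expr = _dependent_expression(name)
        if expr is not None:
            exprs[name] = expr
        elif name in spec.fixed:
            fixed_vals[name] = float(spec.fixed[name])
        else:
            free.append(name)
    bad = set(spec.fixed) - set(full)
    if bad:
        raise KeyError(f"fixed coefficients not in this specification: "
                       f"{sorted(bad)}")
    for name in spec.fixed:
        if name in exprs:
            raise ValueError(
                f"{name!r} is determined by homogeneity and cannot be fixed")
    A = np.zeros((len(full), len(free)))
    c = np.zeros(len(full))
    free_idx = {n: k for k, n in enumerate(free)}
    for r, name in enumerate(full):
        if name in exprs:
            for key, coef in exprs[name].items():
                if key == "":
                    c[r] += coef
                elif key in free_idx:
                    A[r, free_idx[key]] += coef
                elif key in fixed_vals:
                    c[r] += coef * fixed_vals[key]
                else:  # dependent-on-dependent never occurs by construction
                    raise AssertionError(key)
        elif name in fixed_vals:
            c[r] = fixed_vals[name]
        else:
            A[r, free_idx[name]] = 1.0
    return full, free, A, c


# ------------------------------------------------------------------- design
def build_design(panel: pd.DataFrame, spec: SystemSpec,
                 norm: NormalizationPoint):
    """Stacked system design in the full coefficient space.

    Returns ``(X, Y, full_names, equations)`` where ``X`` has shape
    ``(n, 7, n_full)`` — equation 0 is the cost equation, equations 1..6 the
    six share equations in :data:`INPUTS` order — and ``Y`` the matching
    responses (standardized log cost; observed shares).
    """
    years = sorted(panel["year"].astype(int).unique())
    full = _full_names(spec, years)
    col = {n: k for k, n in enumerate(full)}
    n = len(panel)

    out_idx = [OUTPUTS.index(o) for o in spec.outputs]
    Yv = np.column_stack([panel[o] for o in spec.outputs]).astype(float)
    Wv = np.column_stack([panel[f"price_{i}"] for i in INPUTS]).astype(float)
    if np.any(~np.isfinite(Yv)) or np.any(Yv <= 0):
        raise ModelDomainError("outputs must be present and strictly positive")
    if np.any(~np.isfinite(Wv)) or np.any(Wv <= 0):
        raise ModelDomainError("prices must be present and strictly positive")
    yh = np.log(Yv / norm.outputs[out_idx])
    wh = np.log(Wv / norm.prices)
    t = np.asarray(norm.trend(panel["year"].to_numpy()), dtype=float)
    yr = panel["year"].astype(int).to_numpy()

    X = np.zeros((n, 1 + len(INPUTS), len(full)))
    cost = 0
    X[:, cost, col["constant"]] = 1.0
    if spec.include_year_effects:
        for y in years[1:]:
            X[:, cost, col[f"year {y}"]] = (yr == y).astype(float)
    for a, om in enumerate(spec.outputs):
        X[:, cost, col[om]] = yh[:, a]
        for b in range(a, len(spec.outputs)):
            on = spec.outputs[b]
            X[:, cost, col[f"{om} x {on}"]] = \
                0.5 * yh[:, a] ** 2 if a == b else yh[:, a] * yh[:, b]
    for a, ii in enumerate(INPUTS):
        X[:, cost, col[f"price {ii}"]] = wh[:, a]
        for b in range(a, len(INPUTS)):
            jj = INPUTS[b]
            X[:, cost, col[f"price {ii} x price {jj}"]] = \
                0.5 * wh[:, a] ** 2 if a == b else wh[:, a] * wh[:, b]
        X[:, cost, col[f"trend x price {ii}"]] = t * wh[:, a]
    for a, om in enumerate(spec.outputs):
        for b, ii in enumerate(INPUTS):
            X[:, cost, col[f"{om} x price {ii}"]] = yh[:, a] * wh[:, b]
    if spec.include_hedonics:
        if "admissions" not in spec.outputs:
            raise ValueError("hedonic terms require admissions in outputs")
        zc = np.column_stack([panel[h] for h in HEDONICS]) - norm.hedonics
        ya = yh[:, spec.outputs.index("admissions")]
        for k, h in enumerate(HEDONICS):
            X[:, cost, col[f"admissions x {h}"]] = ya * zc[:, k]

    for a, ii in enumerate(INPUTS):
        eq = 1 + a
        X[:, eq, col[f"price {ii}"]] = 1.0
        for b, jj in enumerate(INPUTS):
            lo, hi = sorted((a, b))
            X[:, eq, col[f"price {INPUTS[lo]} x price {INPUTS[hi]}"]] += wh[:, b]
        for m, om in enumerate(spec.outputs):
            X[:, eq, col[f"{om} x price {ii}"]] = yh[:, m]
        X[:, eq, col[f"trend x price {ii}"]] = t

    Yresp = np.zeros((n, 1 + len(INPUTS)))
    Yresp[:, 0] = np.log(panel["total_cost"].to_numpy() / norm.total_cost)
    for a, ii in enumerate(INPUTS):
        Yresp[:, 1 + a] = panel[f"share_{ii}"].to_numpy()
    return X, Yresp, full, ["cost"] + [f"share_{i}" for i in INPUTS]


# -------------------------------------------------------------------- model
class TranslogCostModel:
    """Translog cost system on a hospital-year panel.

    Parameters
    ----------
    panel
        Hospital-year table with output, ``price_*``, hedonic, ``year``,
        ``total_cost`` and ``share_*`` columns (see :mod:`hospcost.simulate`
        for the column contract).  Rows with missing required values are
        dropped.
    spec
        Estimation specification; defaults to the full four-output system.
    norm
        Standardization means.  Defaults to the panel's arithmetic means;
        pass the stored normalization of the generating or earlier-stage
        sample to keep counterfactuals on a common scale.
    """

    def __init__(self, panel: pd.DataFrame, spec: SystemSpec | None = None,
                 norm: NormalizationPoint | None = None):
        self.spec = spec or SystemSpec()
        required = list(self.spec.outputs) \
            + [f"price_{i}" for i in INPUTS] \
            + [f"share_{i}" for i in INPUTS] + ["year", "total_cost"] \
            + (list(HEDONICS) if self.spec.include_hedonics else [])
        self.panel = panel.dropna(subset=required).reset_index(drop=True)
        if not len(self.panel):
            raise ValueError("no complete observations in the panel")
        self.norm = norm if norm is not None \
            else NormalizationPoint.from_panel(self.panel)
        self.years = sorted(self.panel["year"].astype(int).unique())
        (self.X_full, self.Y, self.full_names, self.equations) = \
            build_design(self.panel, self.spec, self.norm)
        (_, self.free_names, self.A, self.c) = \
            constraint_map(self.spec, self.years)

    @classmethod
    def from_dataframe(cls, panel, **kwargs):
        return cls(panel, **kwargs)

    # ------------------------------------------------------------------ fit
    def fit(self) -> "TranslogCostResults":
        """Iterated feasible GLS on the stacked system.

        Starts from pooled least squares (identity weighting), re-estimates
        the residual covariance each iteration (no degrees-of-freedom
        correction), and stops when the largest coefficient change falls
        below ``spec.tol``.  A noiseless system converges at the first step.
        """
        spec = self.spec
        keep = [0] + [1 + a for a, ii in enumerate(INPUTS)
                      if ii != spec.dropped_share]
        X = self.X_full[:, keep, :] @ self.A         # (n, k, p)
        yadj = self.Y[:, keep] - self.X_full[:, keep, :] @ self.c
        n, k, p = X.shape
        if n * k < p:
            raise ValueError(f"{p} free parameters but only {n * k} stacked "
                             f"observations")
        self._check_identification(X)

        Om = np.eye(k)
        beta = self._gls_step(X, yadj, Om)
        log: list[dict] = []
        converged = False
        for it in range(spec.max_iter):
            resid = yadj - np.einsum("nkp,p->nk", X, beta)
            if float(np.sqrt(np.mean(resid ** 2))) < 1e-12:
                converged = True           # noiseless: exact at first step
                Sigma = resid.T @ resid / n
                break
            Sigma = resid.T @ resid / n
            Om = self._invert_sigma(Sigma, keep)
            obj_before = float(np.einsum("nk,kl,nl->", resid, Om, resid))
            beta_new = self._gls_step(X, yadj, Om)
            resid_new = yadj - np.einsum("nkp,p->nk", X, beta_new)
            obj_after = float(np.einsum("nk,kl,nl->", resid_new, Om, resid_new))
            step = float(np.max(np.abs(beta_new - beta)))
            log.append(dict(iteration=it, objective_before=obj_before,
                            objective_after=obj_after, max_step=step))
            beta = beta_new
            if step < spec.tol:
                converged = True
                resid = resid_new
                Sigma = resid.T @ resid / n
                break
        if not converged:
            raise RuntimeError(
                f"FGLS did not converge in {spec.max_iter} iterations "
                f"(last step {log[-1]['max_step']:.3g})")

        XtWX = np.einsum("nkp,kl,nlq->pq", X, Om, X)
        cov_free = np.linalg.pinv(XtWX)
        full_vec = self.A @ beta + self.c
        cov_full = self.A @ cov_free @ self.A.T

        fitted = np.einsum("nkp,p->nk", self.X_full[:, keep, :],
                           full_vec)
        r2 = {}
        for j, idx in enumerate(keep):
            yy = self.Y[:, keep][:, j]
            r2[self.equations[idx]] = float(
                1.0 - np.sum((yy - fitted[:, j]) ** 2)
                / np.sum((yy - yy.mean()) ** 2))

        params = TranslogParameters.from_dict(
            dict(zip(self.full_names, full_vec)))
        return TranslogCostResults(
            model=self, params=params, free_names=self.free_names,
            free_values=beta, cov_free=cov_free, cov_full=cov_full,
            sigma_resid=Sigma, kept_equations=[self.equations[j] for j in keep],
            rsquared=r2, iterations=log, converged=converged)

    def _check_identification(self, X: np.ndarray) -> None:
        flat = X.reshape(-1, X.shape[-1])
        sd = flat.std(axis=0)
        dead = [self.free_names[j] for j in np.nonzero(sd < 1e-14)[0]
                if self.free_names[j] != "constant"]
        if dead:
            raise SingularSystemError(
                f"regressors with no variation — coefficients not "
                f"identified: {dead}")

    @staticmethod
    def _gls_step(X, y, Om):
        XtWX = np.einsum("nkp,kl,nlq->pq", X, Om, X)
        XtWy = np.einsum("nkp,kl,nl->p", X, Om, y)
        try:
            return np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError as err:
            raise SingularSystemError(
                "normal equations singular; check for collinear regressors"
            ) from err

    def _invert_sigma(self, Sigma, keep):
        eig = np.linalg.eigvalsh(Sigma)
        if eig.min() <= eig.max() * 1e-12:
            names = np.array(self.equations)[keep]
            worst = names[np.argsort(np.diag(Sigma))[:2]]
            raise SingularSystemError(
                f"residual covariance is singular (equations {list(worst)}); "
                f"was a redundant share equation included?")
        return np.linalg.inv(Sigma)


@dataclass
class TranslogCostResults:
    """Fit of the translog cost system.

    ``params`` is the full, restriction-satisfying
    :class:`TranslogParameters` (dropped-equation and capital-price
    coefficients recovered from the adding-up identities); ``bse`` /
    ``tvalues`` / ``pvalues`` cover the free coefficients.
    """

    model: TranslogCostModel
    params: TranslogParameters
    free_names: list[str]
    free_values: np.ndarray
    cov_free: np.ndarray
    cov_full: np.ndarray
    sigma_resid: np.ndarray
    kept_equations: list[str]
    rsquared: dict[str, float]
    iterations: list[dict]
    converged: bool

    @property
    def norm(self) -> NormalizationPoint:
        return self.model.norm

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_free)),
                         index=self.free_names, name="std_err")

    @property
    def tvalues(self) -> pd.Series:
        return pd.Series(self.free_values, index=self.free_names) / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * _stats.norm.sf(np.abs(self.tvalues)),
                         index=self.free_names, name="p_value")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = _stats.norm.ppf(1 - alpha / 2)
        est = pd.Series(self.free_values, index=self.free_names)
        return pd.DataFrame({"lower": est - q * self.bse,
                             "upper": est + q * self.bse})

    def coefficients(self) -> pd.DataFrame:
        """Free coefficients with standard errors and z statistics."""
        return pd.DataFrame({
            "estimate": pd.Series(self.free_values, index=self.free_names),
            "std_err": self.bse,
            "z": self.tvalues,
            "p": self.pvalues,
        })

    def summary(self) -> str:
        head = ["Translog cost system — iterated FGLS",
                f"observations: {len(self.model.panel)}   "
                f"equations: {', '.join(self.kept_equations)}",
                f"converged: {self.converged} "
                f"({len(self.iterations)} iterations)",
                "R^2: " + "  ".join(f"{k}={v:.4f}"
                                    for k, v in self.rsquared.items()),
                ""]
        return "\n".join(head) + self.coefficients().round(4).to_string()

    # ------------------------------------------------------- derived measures
    def scale_report(self, panel: pd.DataFrame | None = None,
                     **kwargs) -> pd.DataFrame:
        """Quartile table of marginal costs and scale/chain elasticities."""
        panel = self.model.panel if panel is None else panel
        return _scale.quartile_report(self.params, panel, self.norm, **kwargs)

    def monotonicity(self, panel: pd.DataFrame | None = None):
        panel = self.model.panel if panel is None else panel
        return _diag.monotonicity_check(self.params, panel, self.norm)

    def concavity(self, panel: pd.DataFrame | None = None, **kwargs):
        panel = self.model.panel if panel is None else panel
        return _diag.concavity_check(self.params, panel, self.norm, **kwargs)

    def fit_summary(self) -> dict:
        return _diag.fit_summary(self)

    def bootstrap_bse(self, n_draws: int = 200, seed: int = 0) -> pd.Series:
        """Nonparametric (observation-resampling) bootstrap standard errors."""
        rng = np.random.default_rng(seed)
        draws = []
        panel = self.model.panel
        for _ in range(n_draws):
            idx = rng.integers(0, len(panel), len(panel))
            m = TranslogCostModel(panel.iloc[idx], spec=self.model.spec,
                                  norm=self.norm)
            draws.append(m.fit().free_values)
        return pd.Series(np.std(np.array(draws), axis=0, ddof=1),
                         index=self.free_names, name="bootstrap_se")


# ---------------------------------------------------------------- two stages
_STAGE1_OUTPUTS = tuple(o for o in OUTPUTS if o != "er_visits")


def two_stage_fit(panel: pd.DataFrame,
                  er_panel: pd.DataFrame | None = None,
                  norm: NormalizationPoint | None = None,
                  spec: SystemSpec | None = None
                  ) -> tuple[TranslogCostResults, TranslogCostResults]:
    """The study's two-stage procedure.

    Stage 1 estimates the three-output system (admissions, outpatients,
    other revenues) on the complete panel.  Stage 2 re-estimates, on the
    ER-complete subsample, the constant, all first-order output terms (now
    including ER visits), the own-quadratic output terms and the
    output x price interactions, with the entire price structure
    (first/second-order price terms and trend x price), year effects,
    cross-output and hedonic coefficients fixed at their stage-1 values and
    ER cross-output terms excluded (zero).
    """
    base = spec or SystemSpec()
    spec1 = _dc_replace(base, outputs=_STAGE1_OUTPUTS, fixed=dict(base.fixed))
    model1 = TranslogCostModel(panel, spec=spec1, norm=norm)
    res1 = model1.fit()

    if er_panel is None:
        er_panel = panel[panel["er_visits"].notna()]
    if not set(panel.columns) <= set(er_panel.columns):
        raise ValueError("er_panel must carry the full panel's columns")

    stage1 = dict(zip(model1.full_names, res1.model.A @ res1.free_values
                      + res1.model.c))
    fixed: dict[str, float] = dict(base.fixed)
    others = [i for i in INPUTS if i != _CAP]
    for i in others:
        fixed[f"price {i}"] = stage1[f"price {i}"]
    for a, ii in enumerate(others):
        for jj in others[a:]:
            fixed[f"price {ii} x price {jj}"] = \
                stage1[f"price {ii} x price {jj}"]
        fixed[f"trend x price {ii}"] = stage1[f"trend x price {ii}"]
    if base.include_year_effects:
        for name in model1.full_names:
            if name.startswith("year "):
                fixed[name] = stage1[name]
    if base.include_hedonics:
        for h in HEDONICS:
            fixed[f"admissions x {h}"] = stage1[f"admissions x {h}"]
    for a, om in enumerate(_STAGE1_OUTPUTS):       # cross-output carried over
        for on in _STAGE1_OUTPUTS[a + 1:]:
            fixed[f"{om} x {on}"] = stage1[f"{om} x {on}"]
    for om in _STAGE1_OUTPUTS:                     # no ER cross-output terms
        fixed[f"{om} x er_visits"] = 0.0

    spec2 = _dc_replace(base, outputs=OUTPUTS, fixed=fixed)
    model2 = TranslogCostModel(er_panel, spec=spec2, norm=norm or res1.norm)
    res2 = model2.fit()
    return res1, res2
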