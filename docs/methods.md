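# Methods

## The model

`hospcost` treats a general hospital as a multiproduct firm producing four
services — inpatient admissions, outpatient visits, other (non-patient)
revenues, and emergency-room (ER) visits — from six priced inputs: four labor
categories (management/administration, nursing, paramedical, auxiliary),
material supplies, and capital.  Physician costs are excluded throughout: in
the Dutch institutional setting most specialists are self-employed and their
costs are not in hospital accounts, and there is essentially no substitution
between physicians and other personnel.

Total cost is a translog function of service volumes `y`, input prices `w`,
a hedonic case-mix vector `z` interacting with admissions, year intercepts,
and trend-biased technical change in the price terms:

    ln(C/C̄) = α₀ + d_year + Σₘ βₘ ŷₘ + ½ Σₘₙ Bₘₙ ŷₘ ŷₙ
             + Σᵢ γᵢ ŵᵢ + ½ Σᵢⱼ Gᵢⱼ ŵᵢ ŵⱼ + Σₘᵢ δₘᵢ ŷₘ ŵᵢ
             + t Σᵢ τᵢ ŵᵢ + ŷ_adm Σₖ θₖ (zₖ − z̄ₖ)

with `ŷ = ln(y/ȳ)`, `ŵ = ln(w/w̄)`, every variable standardized at its
arithmetic sample mean.  Standardization makes each first-order coefficient
the cost elasticity (for outputs) or the cost share (for inputs) of the
"average" hospital.  Cost minimization is assumed (hospitals are non-profit
and face fixed budgets or negotiated prices); services are demand-determined
and hence exogenous.

By Shephard's lemma the input cost shares are the price gradient of log
cost, giving the share-equation system

    sᵢ = γᵢ + Σⱼ Gᵢⱼ ŵⱼ + Σₘ δₘᵢ ŷₘ + τᵢ t .

Symmetry (`B = Bᵀ`, `G = Gᵀ`) and linear homogeneity in prices
(`Σγ = 1`, zero row sums of `G`, `δ`, `τ`) are maintained exactly by
reparameterization, never by penalty.

### Hedonic case-mix adjustment

Case-mix enters as first-order interactions between log admissions and six
centered characteristics: surgery/orthopedics physician share, psychiatric
beds per 1 000 admissions, IC beds per 1 000 admissions, expected length of
stay, neurosurgery share, and cardiothoracic share.  The admissions cost
elasticity therefore varies with case mix, while at the sample mean it
equals β_adm.  The interaction form (rather than re-weighting admissions
before taking logs) matches the printed term list of the reference
coefficient table exactly.

### Trend units

The trend is linear in the calendar year, zero in the first sample year, and
measured in *sample spans*: `t = (year − 2003)/8` for the 2003–2011 panel.
Trend coefficients are therefore total drifts over the sample period.  With
the published `τ` values (e.g. −0.251 on materials) a per-year unit would
push fitted shares far outside the unit interval within the sample; per-span
units keep every mean share positive through 2011 and leave all
normalization-point quantities (evaluated at `t = 0`) unchanged.

## Estimation

The cost equation and five of the six share equations are stacked per
observation (shares add to one, so the six-equation error covariance is
singular and one share equation — capital by default — is dropped) and
estimated by iterated feasible GLS: pooled least squares start, residual
covariance re-estimated each iteration without a degrees-of-freedom
correction (ML-style), stop when the largest coefficient change is below
1e-8 (at most 500 iterations).  The GLS criterion is non-increasing at every
β-update, and at convergence the estimates are invariant (tested to 1e-6) to
which share equation was dropped, so the choice is immaterial.  Coefficients
eliminated by homogeneity are recovered from the adding-up identities, and
the parameter covariance is mapped through the same affine constraint map.

**Two-stage procedure.**  ER volumes exist only for a subsample, so stage 1
fits the three-output system on the full panel; stage 2 re-fits, on the
ER-complete rows, the constant, all first-order output terms (now including
ER visits), the own-quadratic output terms and the output×price
interactions, holding the whole price structure (γ, G, τ), year effects,
cross-output and hedonic terms fixed at stage-1 values.  ER cross-output
quadratic terms are excluded (zero) in stage 2, mirroring the reference
specification.  Stage-1 year effects are carried into stage 2 as fixed
values (they could alternatively be re-estimated; fixing keeps the stage-2
parameter count small on the subsample, which is the point of the
procedure).

## Scale and chain measures

All measures are computed in cost *levels* (euros), converting from
standardized log space via the stored mean cost:

* **Overall (ray) scale elasticity** `v = [Σₘ ∂lnC/∂ln yₘ]⁻¹`, equivalently
  total cost over the output-weighted sum of marginal costs; the
  implementation computes both forms and asserts agreement to 1e-10.
  `v > 1` means economies of scale.
* **Product-specific scale elasticity**: average incremental cost of a
  service, relative to producing it at the smallest volume observed in the
  sample, divided by its marginal cost.  The sample minimum replaces zero
  production because no hospital in the data operates without any of the
  four services; the fixed costs still embedded in the minimum-volume
  counterfactual bias the measure downward, so it understates product-specific
  economies if anything.
* **Chain scale elasticity** of two sequential services (ER visit followed
  by admission, or by outpatient treatment): average incremental cost of the
  joint volume `y₁₂` — subtracted from *both* services in the counterfactual
  — divided by the sum of the two marginal costs.  Marginal costs in the
  denominator are evaluated at the actual point, not the counterfactual;
  the two conventions coincide as `y₁₂ → 0` and the actual-point form keeps
  the denominator identical to the marginal costs already reported.
  `y₁₂` defaults to disposition shares times ER visits: (ordinary admission
  share + IC/stroke/CCU share) for the admission chain, outpatient share for
  the outpatient chain, rounded to integers; per-hospital overrides are
  supported.
* **Conditional derivative** `∂v(yₘ|·)/∂yₙ` is computed by central finite
  difference (relative step 1e-4): the analytic expression is unwieldy for a
  translog, and the numeric version is oracle-checked against local
  polynomial slopes.

The quartile report evaluates every hospital at its own observed point,
excludes (and counts) hospitals that violate regularity — a non-positive
predicted share, a non-positive elasticity sum, or an infeasible
counterfactual — and summarizes with linearly interpolated quartiles.

## Regularity diagnostics

Monotonicity requires all six predicted shares to be positive.  Concavity in
prices is checked through `H = G + ssᵀ − diag(s)` at the predicted shares:
own-substitution negativity is `diag(H) < 0` (equivalently negative own
Allen elasticities `Hᵢᵢ/sᵢ²`), and full concavity is negative
semi-definiteness of `H`.  Allen form is used because it is the standard
substitution-elasticity representation for translog share systems.  The
default eigenvalue tolerance of 1e-8 tolerates the tiny positive eigenvalues
that rounded coefficient tables produce; `tol=0` gives the strict check.
`H` always has the unit vector in its null space when shares sum to one, so
a zero top eigenvalue is structural, not a violation.

## Reference coefficient fixtures

The package ships the published two-stage coefficient estimates for Dutch
general hospitals (2003–2011 panel, ER subsample) as YAML fixtures with keys
mirroring the printed row labels.  Two variants are exposed:

* `reference_parameters(stage)` — the values exactly as printed.  Printed
  rounding (three decimals) leaves homogeneity residuals of order 1e-3 and
  one slightly positive eigenvalue (~0.011) of `H` at the mean.
* `ground_truth_parameters()` — the simulation ground truth: the stage-2
  merged set with homogeneity residuals projected out (uniform spreading /
  double-centering, which moves no coefficient by more than ~5e-4) and the
  positive curvature eigenvalue clipped to −0.01 while preserving the
  structural null vector.  This makes the generating cost function exactly
  regular at (and near) the mean, so diagnostics pass on clean data.

Stage-2 blank cells in the published table are interpreted as "fixed at the
stage-1 value" (for price, year, cross-output and hedonic terms) rather than
"dropped"; this is the only reading consistent with evaluating the stage-2
model at all.

## Synthetic data generator

`generate_panel` emulates the study conditions; its defaults *are* those
conditions and are not tuned:

* 76 hospitals × 9 years (2003–2011) ≈ the 682-observation panel; ER data
  observed for 249/682 ≈ 36.5% of hospitals (masking is by hospital — the
  true ER volume still drives generated costs, since every hospital runs an
  ER whether surveyed or not).
* Service volumes are lognormal with the published 2011 means and standard
  deviations, cross-correlated on the log scale (admissions–ER 0.8, other
  pairs 0.3–0.7; the study reports no joint distribution, so these are
  configurable assumptions) and persistent within hospital (80% of log
  variance from a permanent hospital effect).
* Hedonics are hospital-constant normal draws at the published moments,
  clipped to their domains; disposition shares are normal draws at the
  published survey moments, clipped away from zero and renormalized to sum
  to one (clipping biases the small categories slightly upward, which is why
  the admission-share mean lands near 0.34 rather than exactly 0.32).
* Labor unit values are base wages (realistic Dutch FTE-year costs) times
  region effects (log-sd 0.03), 2.5%/year wage growth and 2% idiosyncratic
  noise; the price proxies are then *constructed by the package's own
  region×year regression*, exactly as on real data.  Materials follow a
  1.8%/year CPI path with base one; capital components (beds, IC beds,
  radiotherapist count, theatres) scale with admissions and case mix, and
  the capital price comes from the intercept-free weights regression.
* `generate_costs` evaluates the exact translog at a normalization point
  frozen from the generated sample, adds Gaussian cost noise — by default
  calibrated so the cost equation's population R² is 0.98, the fit quality
  the reference estimates report — and adds mean-zero share noise projected
  to sum to zero per row, preserving the singular adding-up structure the
  estimator assumes.

What the generator does *not* emulate: patient-level (DBC) billing
micro-data, entry/exit of hospitals, output growth trends over the panel,
endogenous price-setting, or inefficiency terms.  Passing recovery tests on
these panels therefore shows the estimator is correct under the model's own
assumptions — exogenous regressors, iid cross-equation-correlated noise —
not that those assumptions hold in real hospital data.

## Problem sizes and numerical choices

Monte-Carlo suites use 50 replicates at the study scale (684 observations)
for coefficient recovery and 15 replicates for the two-stage ER-coefficient
check; smaller panels (30–45 hospitals, 3–5 years) back the invariance,
bootstrap (200 draws) and type-I-rate suites.  Finite-difference oracles use
central differences with relative steps 1e-5 to 1e-6 and tolerances 1e-6
(log space) or 0.1% (levels).  Derivative-free reconstruction identities
(free → full → free coefficient maps) are exact.

## Known limitations

* Quality of care and geographic ER access are outside the model, as in the
  reference analysis; closing or concentrating ERs trades off against travel
  time in ways the cost function cannot see.
* Elasticity uncertainty is not propagated (no delta-method CIs); a
  nonparametric bootstrap hook (`TranslogCostResults.bootstrap_bse`) is the
  supported route.
* The published fixtures carry three-decimal rounding; anchor evaluations at
  the normalization point are exact, but derived quantities away from the
  mean inherit rounding noise of order 1e-3.
* The estimator assumes strictly positive volumes and prices; zero-output
  hospitals must be handled upstream.
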