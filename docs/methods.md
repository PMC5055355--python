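# Methods

## The model

`cd4traj` models immune reconstitution after antiretroviral therapy (ART)
starts. For patient *j* at visit time *t<sub>ij</sub>* (years since ART
initiation), the log CD4+ cell count follows a negative-exponential
asymptotic curve

    log CD4_ij = Asym_j − (Asym_j − Int_j) · exp(−c_j · t_ij) + ε_ij,
    ε_ij ~ N(0, σ²)

with three patient-level parameters: `Int_j`, the log count at initiation;
`Asym_j`, the log of the long-term plateau; and `c_j > 0`, the exponential
approach rate in 1/year (carried internally as `log c_j`). Each parameter
decomposes into a cell-level fixed effect (one of four designs — overall
constant, sex, age stratum in {19–29, 30–39, 40–49, 50–59, 60+}, or
age-by-sex cell) plus a patient-level random effect; the three random
effects per patient are jointly normal with an unstructured 3×3 covariance
Ψ. Candidate fixed-effect structures (4³ = 64) are compared by AIC with
`k = p + 7` (p fixed effects, 6 covariance parameters, 1 residual SD), and
a winner is called *clearly distinguishable* when every other converged
candidate is more than 2 AIC units worse.

Clinically interpretable outputs are back-transformed: initial and
asymptotic counts are exponentiated coefficients (cells/mm³); recovery
speed is summarised by the half-life of the log-scale gain
`t50 = 12·ln 2 / c` months (and `t90 = 12·ln 10 / c`, so `t90/t50 = ln 10 /
ln 2` identically); `time_to_gain(Δ)` solves for the first time the
cell-scale count exceeds baseline by Δ cells/mm³ in closed form. Group
contrasts are Wald intervals on the log scale, exponentiated
(`exp((β_a − β_b) ± 1.96·SE)`).

Note on `t50`: it is defined on the **log** scale (time to half of the
log-scale gain), exactly as the formula above states. Under the published
group values for men aged 19–29 (initial 83.4, asymptote 301 cells/mm³,
t50 = 3.72 months), the closed-form time to gain 50 cells/mm³ is
2.44 months; the 1.4 months printed in the source analysis is not
reproducible from its own printed group parameters under either the
log-scale or cell-scale convention, and we implement the closed form
without adjustment.

## Estimation

The marginal likelihood integrates the 3-dimensional random effect out of
each patient's contribution. Two evaluators are provided:

* **Plain Laplace** (`agq_nodes=1`): an inner damped Gauss-Newton finds
  each patient's posterior mode; the exact 3×3 Hessian (Gauss-Newton
  fallback if indefinite) supplies the curvature correction. All patients
  are processed on padded arrays with batched 3×3 solves.
* **Rate-conditional quadrature** (default): conditional on the rate's
  random effect *v*, the curve is **linear** in (Int, Asym), so that
  Gaussian pair integrates in closed form (Woodbury identities; every
  matrix involved is 2×2). The remaining one-dimensional integral over
  *v* uses importance-corrected Gauss-Hermite quadrature (21 nodes),
  centered by an 11-point scan over ±4 prior SDs followed by parabolic
  refinement of the exact profile. Against 48³-node brute-force
  quadrature the worst per-patient error observed is ~3×10⁻³ (typical
  ~10⁻⁶).

The default is the quadrature evaluator because replicate simulations
showed plain Laplace systematically underestimates the rate-related
variance components (σ for log c recovered ≈ 0.59 when the generating
value was 0.74, a bias that does not shrink with more patients); with the
near-exact likelihood the same experiments recover all components within
Monte-Carlo error. Laplace remains available for speed comparisons.

The outer optimisation is L-BFGS-B over the fixed effects, the
log-Cholesky factor of Ψ (log diagonal, free off-diagonal — positive
definiteness by construction), and log σ. Gradients are central finite
differences; a fixed-effect coefficient only re-evaluates the patients in
its cell (one-hot designs), which keeps the gradient cost near that of a
handful of function evaluations. Starting values: per-patient nonlinear
least squares (Levenberg-Marquardt; crude first/last-visit fallback when a
patient's fit fails), cell means for β, winsorized sample covariance of
the per-patient estimates (shrunk 30% toward its diagonal) for Ψ.
Convergence is the optimizer's relative-reduction/projected-gradient
criterion (ftol 1e-12, pgtol 1e-3, ≤500 iterations); an abnormal
line-search exit is still accepted when the gradient max-norm at the
solution is below 1 (a negligible slope against a curvature of order the
sample size). `converged=False` is a reported state, never an exception.

Fixed effects are coded as cell means (one coefficient per design level),
so coefficients are directly the group-level parameter values; contrasts
and fold changes use the coefficient covariance, computed from the GLS
information matrix Σ<sub>j</sub> F′V⁻¹F with V = ZΨZ′ + σ²I evaluated at
the empirical-Bayes modes and variance parameters held at their estimates
(the standard NLME convention — no uncertainty is propagated from Ψ̂, σ̂
into fixed-effect SEs). Empirical-Bayes per-patient parameters are the
joint posterior mode: the rate coordinate maximises the profiled joint
density, and (Int, Asym) are its exact conditional Gaussian solution.

## Synthetic cohorts

The generator emulates the national treatment-database cohort the analysis
assumes, since the real database is not public:

* **Fixed effects** are the published group estimates, with log-linear
  interpolation for never-printed cells: male initial CD4 83.4 → 121
  cells/mm³ rising with age, female 107 → 136; asymptotes anchored at 301
  (male 19–29; printed), 323 (male midlife peak), 377 (female 19–29,
  printed), 389 (female 50–59 peak), with interpolated values elsewhere —
  recovery tests only use printed anchors; half-lives 3.72 months (19–29)
  slowing log-linearly to 4.99 months (60+), shared between sexes.
* **Random effects**: SDs (0.90, 0.51, 0.74) with corr(Int, Asym) = 0.40,
  corr(Asym, log c) = −0.60; the never-printed corr(Int, log c) defaults
  to 0 and is configurable. Residual SD 0.58 on the log scale.
* **Composition** follows the published margins: age-stratum sizes
  proportional to (5155, 13927, 9038, 3152, 797) with female shares
  (87%, 74.3%, 62%, 54.9%, 51.4%), allocated by largest remainder.
* **Visit schedules**: the count is 5 + Poisson(1.9) (mean exactly 6.9,
  minimum 5); the first visit is uniform in the baseline window [−2, +3]
  months; the last visit sits at first + span, with the span log-normal
  (median 3.7 years, log-SD 0.384 chosen to match the published IQR
  2.8–4.7, clipped to [0.5, 9] years — the study window); interior visits
  are uniform in between. Median follow-up and mean visit count therefore
  match the published table by construction, which the calibration tests
  confirm empirically.
* **Reproducibility**: one root seed, one spawned substream per patient,
  so enlarging a cohort never perturbs existing patients.

What the generator does **not** emulate: mortality and loss to follow-up,
ART regimen or adherence, WHO-stage progression, pregnancy, calendar-time
effects, or measurement rounding. A green recovery test therefore
establishes that the estimator recovers the stated generative world — not
that the real database would yield the same estimates.

## Convergence experiment

Per-patient three-parameter fits use multi-start (3 rate starts)
Levenberg-Marquardt on the log scale. "Converged" requires optimizer
success, an estimated rate within [1e-4, 1e3]/year, and a Jacobian whose
smallest relative singular value exceeds 1e-8 (finite standard errors);
the criterion is explicit because the original analysis never states one,
and the published failure percentages (38.5% simulated / 18% real) are
optimizer-specific context, not targets. At the default residual SD
(0.58), roughly 35–40% of simulated, truly asymptotic patients fail —
reproducing the qualitative point that non-convergence reflects noise and
sparsity, not model inadequacy. Failure rates rise with noise and fall
with visit count (tested on a common-random-numbers factorial grid). At
zero noise, every fit converges *when the schedule is informative for the
patient's rate*; with full rate heterogeneity, ~1–2% of patients draw
rates so fast (c > 5/year) that no visit falls on the rising limb and the
rate is numerically unidentifiable — these are reported as failures, which
is the designed behavior of the singular-Jacobian rule.

## Eligibility filtering

Filters mirror the study inclusion rules, applied in a fixed, logged
order: parse/coerce → drop visits with missing CD4 → drop visits more
than 2 months pre-ART → require age ≥ 19 at initiation → require a
baseline CD4 within [−2, +3] months (the earliest in-window measurement
is "baseline"; the source is silent on which to use) → require ≥ 5
remaining CD4 visits. Months are 1/12 year with closed interval ends.
The exclusion log satisfies an exact conservation identity, and the
pipeline is idempotent. Baseline CD4 bands use the published labels with
closed upper bounds (a baseline of exactly 200 falls in "51–200").

## Numerical choices and limitations

* Exponentials inside the curve are clipped (|exponent| ≤ 30; growth side
  ≤ 8 inside the 2×2 Woodbury algebra) so extreme rate excursions stay
  finite; those regions carry no posterior mass at any realistic
  parameter value.
* AIC ties break toward fewer parameters, then enumeration order.
  Non-converged candidates are excluded from ranking but kept in the
  table.
* Variance-component SEs are not reported (the source constructs CIs for
  fixed-effect combinations only); the random-effect correlation CIs it
  prints are not reproduced.
* ML (not REML) estimation: variance components carry the usual small
  downward finite-sample bias, visible as ~2–5% underestimation of the
  random-effect SDs at 500 patients and shrinking with cohort size.
* Fits assume every patient has ≥ 1 usable visit and at least one patient
  occupies every cell its design references (a missing cell raises a
  "degenerate design" error up front).

## Power of AIC structure selection at reduced cohort sizes

The default generative world uses the published group effects, which are
small for age: intercept age trends of ~0.09 log units per stratum and
asymptote differences of ~0.07 log units in total, against patient-level
SDs of 0.90 and 0.51. At 1,000 patients an age-by-sex structure improves
the log-likelihood by only ~9 units while costing 20 extra parameters, so
AIC prefers the sex-only structure; the full age-by-sex structure only
becomes AIC-optimal at cohort sizes in the tens of thousands (the
log-likelihood separation scales linearly with n while the penalty is
fixed). Selection-consistency experiments at simulation scale therefore
recover the sex effects reliably but not the age interaction, and the
corresponding acceptance test documents this as an expected failure of
the scaled-down experiment, not of the selection machinery (whose
mechanics — nested log-likelihood ordering, ranking, distinguishability —
are tested independently).
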