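# Methods

## Centile charts

Each chart estimates the conditional quantiles of one dimensionless
fundus feature given spherical equivalent refraction (SER) on the
closed domain [−12, 0] diopters, at the 19 levels τ = 0.05…0.95 in
steps of 0.05. Curves are cubic B-splines on a clamped, equally spaced
knot vector with basis dimension 10 (6 interior knots). The fitting
criterion per chart is the sum over all 19 levels of the pinball loss
of that level's curve, plus a roughness penalty per curve, minimised
jointly subject to an ordering constraint.

**Joint estimation and noncrossing.** All 19 coefficient vectors are
estimated in a single optimisation. The ordering constraint — curve
τ_{j+1} ≥ curve τ_j at each of 201 equally spaced SER grid points — is
imposed through one-sided exact-penalty rows: each constraint becomes a
pinball row at τ = 1 with weight 2n (n = observations), which charges a
linear penalty only when the pair of curves crosses at that grid point.
For a linear program this penalty is exact once the weight exceeds the
constraint's dual value, so at the optimum the constraints hold up to
solver tolerance; remaining violations (≈1e−10) are removed by minimal
constant upward shifts applied outward from the median curve, after
which grid noncrossing holds exactly. Joint estimation was preferred
over sequential per-level fitting with isotonic repair because it
treats all levels symmetrically.

**Roughness penalty.** The penalty is λ · Σ |Δ²_g c| per curve, where
Δ²_g are second *divided* differences of the spline coefficients taken
at the Greville abscissae (scaled by the squared mean Greville
spacing). With clamped knots the Greville sites are unequally spaced
near the boundary, and plain second differences of the coefficients do
not vanish on straight lines there; the divided-difference form does,
so the penalty shrinks toward linearity without boundary bias. The L1
form keeps the whole problem a weighted pinball regression. Default
λ = 0.1 (per unit of mean pinball loss); the fit is insensitive to λ
over 0.01–1 on linear-trend data, and λ = 0 gives the unpenalized fit
used when cross-checking against textbook quantile regression.

**Solver.** The weighted pinball problem — heterogeneous τ and weights
per row — is solved by a Mehrotra predictor–corrector primal–dual
interior-point method on the bounded-variable dual LP (the
Frisch–Newton approach). Each iteration costs one P×P Cholesky solve
(P = 190 coefficients for a full chart) plus sparse products over the
stacked rows, so a joint 19-curve fit takes ≈1.5 s at n = 5,000 and
≈8 s at n = 20,000 on one core. Convergence is declared at a relative
complementarity gap of 1e−10 with primal feasibility 1e−5 relative;
against statsmodels QuantReg on unpenalized single-level problems the
achieved loss agrees to better than 1e−8. Degenerate inputs: constant
response gives flat curves (to ≈1e−8); constant SER or fewer
observations than basis dimensions raise a fit error.

**Centile lookup.** An eye's decimal centile position is the τ of the
curve value closest to the observation at the eye's own SER, evaluated
discretely over the 19 curves (no interpolation between curves). This
caps positions at 0.05/0.95 automatically; exact ties between adjacent
curves resolve to the lower τ, a deterministic choice that is
conservative for features whose worst centile is the 95th. SER outside
the chart domain is clamped to the boundary with a warning at scoring
time (such eyes are excluded at fitting time).

## The index

Centsum sums Cent for the four features that increase with myopia
(arterial/venous concavity, DFD:DML, disc tilt) and 1 − Cent for the
six that decrease (arterial/venous fractal dimension, AVR,
arterial/venous tortuosity, absolute disc torsion). FunSI is the
min-max normalisation (Centsum − 0.05k)/(0.9k) over the k features in
use; at k = 10 this is exactly (Centsum − 0.5)/9. Leave-one-feature-out
variants recompute with k = 9, preserving the [0, 1] range and the 0.5
interpretation (the renormalised form is this package's choice for
"recomputing" with one feature removed). Standardisation for hazard
models uses the sample SD (n − 1); quartile grouping uses empirical
quantile cuts with ties collapsing downward.

## Filters and eye selection

Eligibility keeps eyes with −12 ≤ SER ≤ 0 (exactly 0 is kept; the
excluded categories are hyperopic SER > 0 and extreme myopia < −12)
and all 10 features finite, in that screening order. The outlier filter
then removes eyes strictly outside the per-feature empirical quantiles
at tail fraction 0.001 (numpy's linear-interpolation quantile
definition), applied at the eye level before per-person selection;
0.0001 gives the sensitivity variant. Per-person selection policies:
one seeded random eye (chart fitting), the across-eye mean of SER and
features (survival analyses), or the more myopic eye (sensitivity);
the random policy operates on a canonically sorted table so it is
order-invariant and reproducible.

## Synthetic cohorts

The generator emulates the study conditions rather than images:

* SER: person-level Normal(−2.12, 2.23²) truncated to [−12, 0]
  (exact rejection sampling); each eye adds anisometropia noise
  (SD 0.25 D), redrawn if it leaves the domain.
* Features: linear in SER with Gaussian noise; intercepts, slopes and
  noise SDs (`DEFAULT_TRENDS`) are plausible magnitudes for adult
  fundus metrics, with slope signs matching each feature's direction of
  change with myopia. Linearity is a generator convenience the chart
  fitter does not exploit.
* Latent stretch: one standard-normal factor per person shifts every
  feature toward its worst direction with loading 0.4 × that feature's
  noise SD. This single-factor structure is a modelling convenience;
  real inter-feature correlations are not known here. The loading is
  chosen so the fitted index clearly recovers the factor
  (Spearman ≈ 0.85 at n = 10,000); it implies SD(FunSI) ≈ 0.15,
  above the ≈0.100 independence floor that any positively loaded
  single-factor design must exceed.
* Covariates: age truncated-normal 54.3 (8.1) on [40, 69], 54% female,
  90.9% White, Townsend −1.03 (2.95), diabetes 4.4%, hypertension 22%,
  ocular trauma 0.5%, IOP 15.9 (3.5) clipped to (0, 45], corneal
  hysteresis 10.5 (1.7) clipped to (0, 15], half-normal cylindrical
  power (SD 0.75 D).
* Events: exponential proportional hazards with the covariate linear
  predictor centred at cohort means, so the baseline rate is the
  approximate marginal rate — 4.9×10⁻⁴/yr for the retinal-detachment
  model and 1.5×10⁻³/yr for the glaucoma model, with the respective
  published-scale hazard ratios as defaults. Independent exponential
  processes for the competing event (2×10⁻⁴/yr), death/loss to
  follow-up (6×10⁻³/yr) and cataract surgery (1.2×10⁻²/yr), with
  administrative censoring at 13 years. Death and loss to follow-up are
  folded into one process.

What passing tests on these cohorts show: the chart fitter is
calibrated and noncrossing, the index arithmetic is exact, and the
survival pipeline recovers known hazard ratios at realistic event
rates. What they do not show: behaviour under real conditional feature
distributions (skewness, heteroscedasticity beyond the generator),
camera or segmentation artefacts, or informative censoring.

## Survival validation

Follow-up is assembled per analysis as the earliest of the event,
administrative end, death/loss, the competing event, and — for
retinal-detachment analyses only — cataract surgery; the status is an
event only when the event time is earliest. Competing events censor
(matching the right-censoring design being validated), and cumulative
incidence is [1 − Kaplan–Meier survival] × 100 rather than an
Aalen–Johansen estimator — fidelity to the validated design over
competing-risk optimality. Cox models are fitted with lifelines (Efron
tie handling, Wald CIs, damped Newton steps for rare-event stability);
polynomial extensions add squared/cubed standardised-FunSI terms.
Harrell's C-index summarises discrimination. Variants: baseline, 1-year
event lag, cylindrical power ≤ 2 D, more-myopic-eye rescoring, and the
0.01% outlier cut.

## Problem sizes

Default test and acceptance runs use 5,000-person cohorts for chart
fitting and scoring, 20,000 observations for calibration checks,
10,000 persons for end-to-end factor recovery, and 200 replicates of
n = 5,000 for Cox parameter recovery — sizes at which the Monte Carlo
error of each check is several times smaller than its tolerance.

## Known limitations

* The exact-penalty ordering weight (2n) is heuristic; a pathological
  chart could in principle need a larger weight, though the post-fit
  repair bounds any effect at solver-tolerance magnitude.
* Between-curve interpolation of centile positions is deliberately not
  performed; positions live on the 0.05 grid.
* The generator's single-factor correlation structure cannot reproduce
  an arbitrary feature covariance, and feature values are unbounded
  (e.g. disc tilt may dip below 1 in the noise tails).
* No multiple imputation, proportional-hazards diagnostics, or
  image-based feature extraction; features enter as numbers except the
  three disc-geometry features computed from ellipse parameters.
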