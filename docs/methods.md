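# Methods

## Structural model

The plasma submodel is a transit-compartment absorption chain (N transit
compartments, rate `ktr = (N + 1)/MTT`, the convention that counts the
absorption step in the chain) feeding an absorption compartment with rate
`ka`, then a one-compartment disposition model. Oral clearance is
time-varying through an enzyme-turnover autoinduction model: the enzyme
pool E has zero-order production `k_enz · (1 + Emax·Cp/(EC50 + Cp))` and
first-order loss `k_enz · E`, normalised so that E = 1 at the pre-induced
baseline (production equals elimination when no drug is on board), and
`CL(t) = TV(CL/F) · e^η · E(t)`. The concentration driving induction is
the current central-compartment concentration, with no delay. All
clearances and volumes are apparent (per-F); no separate bioavailability
parameter exists. Units are fixed throughout: mg, L, h, mg/L.

With `Emax = 1.04` the induction multiplier saturates at 2.04-fold; with
`k_enz = 0.0036 h⁻¹` the pool approaches its induced steady state over
about five turnover half-lives, ~40 days, so a 5-day study observes only
the early rise (which is why the induction parameters are fixed, not
estimated, in the reference analysis).

Lung exposure is modelled by two effect compartments driven by the plasma
concentration (`dC/dt = k · (R · Cp − C)`), one for epithelial lining
fluid and one for alveolar cells. The rate constants are fixed at
41.58 h⁻¹. Interpreted as an equilibration half-life this is about one
minute (`ln 2 / 41.58 h⁻¹ = 1.0002 min`); the printed constant is kept
as-is rather than recomputed from an exact one-minute half-life
(41.59 h⁻¹), a sub-0.1 % distinction with no observable consequence. The
extent parameters `R_ELF/plasma` and `R_AC/plasma` are the pseudo-steady-
state total concentration ratios; dividing by the plasma free fraction
`fu = 0.2` gives unbound ratios. `unbound_ratio` returns the exact
quotient — 0.26/0.2 = 1.30, 1.1/0.2 = 5.5. (A reference value of 1.28
for the ELF ratio arises from an unrounded estimate near 0.2566; the
package does not attempt to reproduce rounding artefacts.) No protein-
binding correction is applied inside ELF or AC: reported ELF protein
content is a small fraction of plasma's, so total ≈ unbound there.

Body-size scaling uses fixed allometric exponents (0.75 for clearance,
1 for volume) standardised to 70 kg, with four selectable size
descriptors: none, total bodyweight, fat-free mass (FFM, the
sex-specific weight-height-squared saturation formula with constants
42.92/30.93 kg·m⁻² for men and 37.99/35.98 for women), or normal fat
mass `NFM = FFM + Ffat·(WT − FFM)` with separate estimable fat-mass
contributions for CL and V, bounded to [0, 1] and initialised at 0.5.
Note the FFM formula can exceed total bodyweight for extreme
(weight, height) combinations far outside the physiologic range; the
covariate generator's truncation bounds keep simulated subjects well
inside the valid region.

## Stochastic model

Between-subject variability is a single lognormal random effect on
clearance (the sparse design does not support IIV on other parameters).
The IIV magnitude is stored as the SD ω; `iiv_percent` reports either
100·ω (the convention used for comparison with the reference table,
88.8 %) or the exact lognormal CV `100·sqrt(exp(ω²) − 1)`. Residual
error is proportional per observation matrix (plasma 35.2 %, ELF 40.7 %,
AC 37.1 % as SDs of the multiplicative normal deviate). Negative
simulated observations are possible at these magnitudes (~0.5 % of
draws) and are deliberately retained — truncation would make the
simulation model inconsistent with the likelihood used in estimation.
The study generator reports their frequency in the truth sidecar.

## Estimation

The marginal likelihood over the single random effect is approximated
subject-by-subject: the joint −2 log-likelihood

    J(η) = Σ_obs [ log(2π v) + (y − f(η))² / v ] + η²/ω² + log(2π ω²),
    v = f(η)² σ²_matrix   (interaction: variance at the conditional prediction)

is minimised over η by a bounded Brent search (bounds ±(8ω + 0.1),
x-tolerance 1e−5), and the Laplace correction `log J''(η̂) − log 4π` is
added with the curvature from a central second difference (step 1e−3).
The variance is floored at (1e−10 mg/L)² so pre-dose zero predictions
cannot produce infinite terms. A per-subject flag records non-positive
curvature (the fallback uses the prior curvature 2/ω²). On one-subject
instances with model-consistent data this approximation agrees with
adaptive quadrature over η to well under 0.5 OFV units (0.09 on a
noise-free 2-observation toy; the gap closes by an order of magnitude as
ω shrinks); data implying extreme conditional modes degrade it, as
expected of any Laplace-type method.

The outer problem optimises the free parameters on a log scale (logit for
the bounded fat-mass fractions): bounded L-BFGS-B with finite-difference
gradients (step 1e−5) followed by a short Nelder-Mead polish, which
guards against finite-difference artefacts; a pure simplex option exists.
The (CL, Vc) likelihood surface of the two-point-per-subject plasma
design has a flat ridge, so the formal convergence flag occasionally
trips while the estimates are statistically equivalent to the optimum;
the flag is reported, not raised. Standard errors come from the numeric
Hessian of the OFV at the optimum (covariance = 2·H⁻¹ on the internal
scale, delta method to the natural scale, RSE% = 100·SE/|estimate|); SEs
are withheld when the Hessian is not positive definite. No attempt is
made to match any external software's OFV constant: all model comparisons
are internal OFV differences, which is all the likelihood-ratio test
needs (χ²₀.₉₅ thresholds; 3.84 for one parameter).

Freeing `k_elf`/`k_ac` is refused unless the design carries at least two
distinct BAL sampling times (nominal times where recorded): with a single
shared lavage time only the extent of distribution is identifiable, not
the rate. The scaling-mode comparison fits all four descriptors and
selects the model with the fewest free parameters among those within
3.84 OFV of the minimum (OFV as tie break) — extra parameters must buy a
significant improvement.

## Numerics

Two integration routes exist, deliberately distinct:

* **Reference path** (simulation, study generation): LSODA with
  rtol 1e−8 / atol 1e−10, doses as bolus events into the first transit
  compartment with the integration restarted at each event, samples at a
  dose time read pre-dose. The enzyme (0.0036 h⁻¹) and lung (41.58 h⁻¹)
  rates span four orders of magnitude, hence the stiff-capable solver.
* **Estimation kernel** (also used for VPC replicate simulation): a
  numba-compiled split scheme. The autonomous transit/absorption
  subsystem is integrated once per subject per objective evaluation
  (RK4 on a half-step grid, with stability substeps if `ka` or `ktr` are
  pushed high) and reused across all random-effect evaluations. The
  central/enzyme pair advances by RK4 with the precomputed absorption
  forcing while `CL·E/Vc · h ≤ 0.8`, and otherwise switches to an exact
  exponential-integrator step (forcing linear within the step,
  elimination rate frozen) that is unconditionally stable — necessary
  because the profiled random effect and the outer optimiser explore
  clearances far beyond the stable range of any explicit method. The
  fast effect states always use the exact exponential update and are
  integrated with unit ratios, predictions being scaled by R afterwards
  (the equations are linear in R). At the default 0.1 h step the kernel
  agrees with the reference path to ~1e−3 relative (8e−5 at 0.025 h),
  far below the 35–41 % residual noise; the agreement is asserted in the
  test suite. The self-consistency (noise-free) fit uses a 0.01 h step
  so integration mismatch sits below its 0.1 % recovery criterion.

Random numbers: one master seed; each subject draws covariates, random
effect, jitter and residual errors from `default_rng([seed, subject_id])`,
so datasets are bit-reproducible and invariant to subject ordering;
study-level censoring uses the `[seed, 0]` stream.

## Synthetic-study generator

The generator emulates the 40-subject BAL design: four 10-subject
sex-by-AIDS groups (the AIDS label is carried but drives nothing —
covariate effects are out of scope), 600 mg once daily for five days,
plasma at nominal 2 and 4 h after the day-5 dose, one BAL at nominal 4 h
yielding an ELF and an AC concentration (the pair shares its time
jitter, as one lavage would). Nominal times are jittered uniformly
within ±0.25 h ("approximately" sampled times, no distribution stated —
a package choice). Of the nominal 80/40/40 observations, 76/32/36 are
retained by missing-completely-at-random censoring; no missingness
mechanism is documented for the emulated study, so MCAR is an assumption.
Covariate distributions are plausible adult values, explicitly not
derived from the emulated study: male weight ~ N(77, 10²) kg and height
~ N(1.76, 0.07²) m; female N(64, 9²) and N(1.62, 0.06²); truncated to
[40, 120] kg and [1.40, 2.05] m.

What the generator does not emulate: assay quantification limits (none
reported), BAL methodological variability (urea-dilution volume error,
macrophage lysis contaminating ELF), disease effects on covariates or
parameters, and inter-occasion variability. Passing recovery tests
therefore show that the estimator recovers the generating model under
the stated design — not that the model is correct for real BAL data.

## Recovery experiment (the acceptance surface)

Because the clinical data are not deposited, the quantitative acceptance
surface is parameter recovery: simulate a rich-BAL design — 50 subjects,
plasma at 2 and 4 h post-dose on day 5, one BAL pair per subject cycled
over 1, 4 and 8 h post-dose, no jitter or censoring — under the published
parameter values, refit from neutral starts (CL 5 L/h, Vc 50 L, ratios
0.5, ω 0.5, σ 0.3), and take medians across 10 seeded replicates
(`scripts/acceptance.py`). Problem sizes (50 subjects, 10 seeds; a
25-subject × 20-replicate variant for the SE-coverage check; 200–300 VPC
replicates in tests, 1000 by default) are chosen to keep the full suite
in the minutes range on a single CPU while leaving Monte-Carlo error
well inside the 15 % recovery criterion.

## Prediction-corrected VPC

Observations and simulated replicates are rescaled by
`median(PRED in bin) / PRED_ij` before percentile comparison, removing
covariate- and design-driven variability; observations with PRED = 0 are
excluded with a logged warning. Binning is by nominal sampling time —
with two plasma and at most three BAL support points, data-driven
binning would be unstable — and bins with fewer than three observations
merge into their neighbour. The 5th/50th/95th observed percentiles are
plotted against 95 % confidence bands formed by the 2.5–97.5 %
envelope of the same percentiles across n_sim simulated replicates
(default 1000, minimum 200); the numeric summary is always emitted
alongside the figure so nothing needs to parse images.

## Known limitations

* The Laplace approximation carries the usual sparse-data/large-ω bias;
  at the study scale the recovery medians sit within a few percent of
  truth, but single replicates scatter widely along the flat CL–Vc
  ridge of the two-sample plasma design.
* Only CL/F carries between-subject variability; correlated random
  effects, IOV, and SAEM-type estimators are out of scope.
* The bootstrap is left as a documented extension; uncertainty comes
  from the asymptotic Hessian.
* ka is unidentifiable from the emulated design and has no published
  value; it is a required configuration input.
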