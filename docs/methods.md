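# Methods

## Epidemic signal processing

Cumulative confirmed-case series are assumed daily and contiguous; province
rows of one country are summed before analysis. Daily incidence is the first
difference, with the first day keeping the full cumulative count and
negative differences (retrospective corrections by reporting agencies)
clipped to zero, since incidence is non-negative by definition. Clipping
means re-accumulation recovers the monotone envelope of the input rather
than the input itself; for monotone series the round trip is exact.

Smoothing uses a low-pass Butterworth filter. The filter order and cutoff
are tunable; the defaults are order 2 and cutoff 1/14 cycles/day, chosen
because weekly reporting periodicity is the dominant artefact in raw counts
and a two-week cutoff suppresses it while leaving multi-week epidemic waves
essentially untouched. The filter is applied forward then backward
(`filtfilt`), so the smoothed series has zero phase lag and wave maxima are
not displaced in time — essential when peak dates anchor exposure windows.
Unit DC gain makes constant series fixed points. Negative filter outputs
are clipped to zero.

A peak is a local maximum of the smoothed series whose width is at least 7
days and whose height reaches at least 15% of the series maximum. Those two
thresholds are the detection rule proper; what "width" means was an open
choice, resolved as width at half prominence — the standard scale-free
convention, measured by linear interpolation at height − prominence/2.
Series endpoints are not eligible peaks (their width is undefined), plateau
maxima are reported at their midpoint, and ties in height are all reported.
Because the height rule is relative and the width rule is scale-free, the
peak set is invariant to uniform rescaling of the series. The reference
maximum for the 15% rule is taken from the *smoothed* series over the loaded
range (the alternative, raw maximum, differs only by noise spikes).

## Exposure tertiles

Tertile bands are thirds of the study-period *maximum* smoothed incidence
(bands of magnitude, as drawn against an incidence curve), not empirical
tertiles of the daily-value distribution; the empirical variant is
available via `mode="empirical"`. Values exactly on a boundary belong to
the upper band. The exposure window is surgery day through surgery day + 30,
inclusive on both ends, and a single window day at or above the upper
threshold makes the patient top-tertile exposed. Patients from countries
with no qualifying peak in the study period are excluded from the exposure
comparison but kept in all other tabulations.

The 2×2 exposure-outcome comparison uses Pearson chi-square without
continuity correction by default, falling back to Fisher's exact test when
any expected cell count is below 5; both are selectable because the
published analysis does not name its variant. The rate ratio carries a Katz
log-scale interval, with a 0.5 continuity correction applied only when a
zero cell occurs.

## Cohort tabulation and univariate tests

Clavien-Dindo grades are ordered NONE < I < II < IIIa < IIIb < IVa < IVb < V;
a patient with several complications is summarised by the highest grade.
Minor = I–II, major = III–V, intensive care = IVa/IVb/V, death = V.
Specific complication types count a patient once per type. Percentages are
exact count/stratum-n ratios; printed precision is formatting only.

Univariate comparisons: categorical variables get Pearson chi-square
(correction off by default, available by flag); continuous variables get
Welch's t-test when a per-group Shapiro-Wilk screen at α = 0.05 passes
(subsampled at 500 for stability of the screen) and the asymptotic,
tie-corrected Mann-Whitney U otherwise. The screen is rule-based because
"depending on data distribution" needed an operational definition; the test
can be forced per call. Missing covariates are handled complete-case per
analysis.

## Proportional-odds model

The cumulative-logit likelihood ℓ = Σᵢ log[F(α_{yᵢ} − xᵢβ) − F(α_{yᵢ−1} − xᵢβ)]
(α₀ = −∞, α_J = +∞) is maximised by BFGS on the unconstrained
parametrization (β, α₁, log Δα₂, …), which enforces strictly increasing
cutpoints without a constrained solver; an L-BFGS-B polish step handles the
rare precision-loss stall near the optimum. The gradient is analytic;
starting values are the analytic intercept-only cutpoints (logits of the
empirical cumulative frequencies) with β = 0, so the intercept-only model
converges immediately to its closed form. Convergence demands a vanishing
gradient (tolerance 1e-8); non-convergence is flagged and downstream odds
ratios refuse to report. The covariance is the inverse observed information
in the natural (β, α) coordinates, obtained by central finite differences
of the analytic score (step 1e-5, relative); category probabilities are
clipped at 1e-300 before logging.

Outcome coding keeps all eight CD levels (NONE lowest) by default, with
optional collapsing via a grade-label mapping since the published model's
granularity is not stated; modelling "no complication" as the lowest level
is the natural reading of odds "of increasing from one complication level
to a higher one". Covariates are dummy-coded against the cohort's reference
levels (female, white, no diabetes, no OSA, non-smoker, primary LSG,
district general hospital, smallest bed/experience bands). Inference is
Wald only. AIC = −2ℓ + 2(p + J − 1); the screen fits each candidate set and
reports Δ-AIC to the best, recording per-set failures instead of raising.
The link test refits on (η, η²) where η = Xβ̂ and reports the Wald p of the
η² term, flagging misspecification at p < 0.05; it refuses a constant η.

## Synthetic data generator

Epidemic curves are Gaussian mixtures in daily intensity — chosen so
integrals and peak locations have closed forms — optionally Poisson-sampled,
then accumulated. Cohort covariate prevalences default to the elective
primary study population (26.6% male, 25.6% non-white, 30.9% hypertensive,
…); severity is drawn from a proportional-odds model whose default
cutpoints reproduce the published highest-grade distribution at the
reference covariate pattern and whose default coefficients equal the
published odds ratios; infection risk follows a logistic model with
baseline logit(0.001) in the bottom bands and a top-band effect of
logit(0.007) − logit(0.001), i.e. the published 0.7% vs 0.1% contrast
(rate ratio 7), plus a non-white effect equal to the published ethnicity
odds ratio (≈ 2.2). The true exposure band of each patient is computed from
the generating curve with the same thirds-of-maximum/any-window-day rule
the classifier uses. One master seed spawns independent substreams for
covariates, dates, severity and infection, so adding a component does not
perturb the others; identical spec + seed gives identical output.

What the generator does *not* emulate: weekend reporting dips beyond
Poisson noise, country-specific testing regimes, within-country spatial
structure, correlated comorbidities, or informative missingness. Passing
tests therefore demonstrate the pipeline's correctness and calibration
under the stated generating models, not robustness to those real-data
features.

The printed-table fixtures are deterministic patient lists whose marginal
counts equal the published tables cell by cell (grade counts per procedure
group, protocol counts, exposure×outcome and ethnicity×outcome margins);
unconstrained fields are filled deterministically and carry no information.
They are synthetic stand-ins for an undeposited registry, faithful only in
those margins — joint distributions across fixture columns are arbitrary.

## Problem sizes and numerical checks

The verification suite uses: 200 random multi-wave curves for the peak
detector against a brute-force local-maxima scan; 1000 random windows for
the classifier against a day-by-day scan; 20 seeds at n = 5000 for
coefficient recovery (bias within 3 Monte-Carlo standard errors); 20 random
datasets against an independently implemented ordinal fitter (1e-4
relative); 200 null and 20 quadratic-alternative simulations for link-test
calibration and power; 1000 null replicates per univariate path for type-I
error; and 50 seeded pipeline runs at n = 6000 for rate-ratio interval
coverage under the generating ratio of 7. These sizes keep the full suite
in the low minutes on a single core while leaving Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

- The exposure analysis is retrospective by construction: tertile bands
  need the whole study period, so the classification cannot be computed in
  real time.
- Tertile thresholds and the 2×2 test variant are interpretation choices
  (documented above) where the source analysis is ambiguous; both are
  configurable.
- The ordinal model assumes proportional odds; only the link test guards
  against gross violations. No random effects for centre or country.
- With a rare outcome (~0.1% baseline) single-run rate-ratio estimates are
  noisy and the Katz interval is wide; pooled or multi-seed summaries are
  more stable.
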