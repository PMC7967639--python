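# Methods

## Scope and data model

The package analyses particle-bound PAH exposure at the school level. The
atomic record is a `CongenerProfile`: the 16 USEPA priority congener
concentrations (ng m⁻³) of one PM2.5 sample, keyed by school, zone
(exposed near industry vs comparative) and site (indoor/outdoor), with
per-congener method detection limits (MDL). Extract readings convert to air
concentrations as `C = C_determined × dilution / air_volume` with the
sampler's 7.2 m³ per 24 h run as the default volume. Non-detects and
missing values are imputed at MDL/2 (idempotent; values recorded below
their MDL are treated the same). Low-molecular-weight (LMW) congeners are
the 2–3-ring species {NAP, ACY, ACP, FLU, PHE, ANT}; the ten 4–6-ring
species are HMW; the split conserves the total exactly.

## Toxicity equivalence and cancer risk

TEQ (BaP-equivalent, ng m⁻³) is the TEF-weighted congener sum under the
Nisbet–LaGoy scheme: 0.001 for {NAP, ACP, ACY, FLU, PHE, PYR}, 0.01 for
{ANT, BgP, CYR}, 0.1 for {BaA, BbF, BkF, IcP}, 1.0 for {BaP, DbA}. FLA is
absent from the grouped published form of the sum; its standard
Nisbet–LaGoy value 0.001 is the default and is overridable per run.

Incremental lifetime cancer risk uses the USEPA inhalation form with
cube-root body-weight extrapolation of the BaP slope factor:

    ILCR = TEQ × 10⁻⁶ × CSF × (BW/70)^(1/3) × IR × ED × EF / (BW × AT)

Units and defaults: inhalation rate IR = 12 m³ day⁻¹ (child), exposure
frequency EF = 250 day yr⁻¹ (school days), exposure duration ED = 6 yr
(primary school), averaging time AT = 70 × 365 = 25,550 days, slope factor
CSF = 3.85 (mg kg⁻¹ day⁻¹)⁻¹, 10⁻⁶ converts ng to mg. The model is strictly
increasing in TEQ and strictly decreasing in BW (∝ BW^(−2/3)), so for fixed
TEQ it inverts in closed form — `calibrate_body_weight` solves
BW = (K/ILCR)^{3/2}. Body weights outside 10–120 kg warn rather than fail.

## Probabilistic risk

`monte_carlo_ilcr` pushes n independent (TEQ, BW) pairs through the model
from a single seeded `numpy` generator. Supported families:

* constant;
* logistic(mean, scale) — TEQ in the exposed zone; draws are left-clipped
  at 0 (clipped mass ≈ 5 × 10⁻⁵ at the default configuration);
* log-normal parameterized by its *arithmetic* mean and sd, inverted to
  (μ, σ) by σ² = ln(1 + (sd/mean)²), μ = ln(mean) − σ²/2 — TEQ in the
  comparative zone;
* negative binomial(p, r) for body weight, truncated to ≥ 1 kg.

Two spread parameters are not part of the study configuration and are
defaulted by calibration, both exposed as config knobs:

* the exposed logistic *scale* is set from the dispersion of the three
  exposed school TEQs (20.01, 16.89, 13.69 ng m⁻³): s = sd·√3/π ≈ 1.742;
* the negative-binomial *r* per group is set so the distribution mean
  equals the group body weight obtained by inverting the deterministic
  model at the group-mean TEQ against the group-mean risk
  (exposed: 17.35 ng m⁻³ ↔ 1.13 × 10⁻⁶ → 32.1 kg, r ≈ 8.33 at p = 0.206;
  comparative: 2.21 ↔ 1.6 × 10⁻⁷ → 27.4 kg, r ≈ 12.14 at p = 0.307).

Percentiles use linear interpolation between order statistics (the numpy
`linear` convention, noted in the CLI output). Sensitivity analysis reports
the Spearman rank correlation of each varying input with the simulated
risk and a contribution-to-variance defined as the squared rank correlation
normalized across varying inputs (the convention of spreadsheet risk
simulators); contributions sum to 1 by construction.

A structural note: with the comparative TEQ log-normal matched to
arithmetic mean 2.21, any simulation mean is pinned near the deterministic
group-mean risk (≈ 1.6–1.7 × 10⁻⁷). A published comparative simulation
mean of ≈ 8 × 10⁻⁸ under this same configuration would require a mean child
body weight near 72 kg and is not reproducible from the stated inputs; the
package reports what the configuration implies.

## Source apportionment

Six diagnostic congener ratios are classified against literature threshold
bands. Intervals are half-open `[low, high)` — a value on a breakpoint
takes the label of the band it opens; the choice is a convention, made
explicit because published taxonomies rarely state boundary handling.
BaA/CYR below 0.2 is labelled `unclassified` (the literature defines only
coal combustion in [0.2, 0.35) and vehicular above). A zero denominator
flags the ratio `undefined` and the sample is excluded from that rule's
tallies.

`SourcePCA` z-scores the samples-by-congeners matrix, gates with KMO > 0.5
and a significant Bartlett chi-square (warnings, not failures — small
campaigns are common), retains correlation-matrix eigenvalues > 1, and
varimax-rotates with Kaiser row-normalization (rows scaled to unit
communality before rotation and rescaled after, so communalities are
preserved exactly; the rotation itself is delegated to statsmodels).
With a single retained component rotation is skipped with a warning.
Component signs are fixed so each component's dominant loading is
positive. Loadings are bucketed by absolute value: heavy > 0.75, moderate
0.50–0.75, weak 0.30–0.50, below 0.30 none. KMO uses the anti-image
(matrix-inverse) partial correlations; an all-zero off-diagonal correlation
structure raises rather than silently returning 0.

## Genotoxicity statistics

Group comparison uses Welch's (unequal-variance) t-test. At the study's
group moments (sd 8.21 with n = 85 vs sd 4.88 with n = 120) the
pooled-variance test is anticonservative (type-I error ≈ 0.07), so Welch is
the package's parametric default; a Shapiro–Wilk gate (α = 0.05) attaches a
Mann–Whitney / Kruskal–Wallis p-value whenever normality is rejected, and
both results are reported. School effects use one-way ANOVA within each
zone. Stratified comparisons run the same machinery per covariate level
within each group; levels with fewer than 2 subjects are flagged and
excluded.

Tail-moment prediction is ordinary least squares with backward elimination
at p < 0.05 (worst predictor removed first); the selection algorithm is a
design choice — published reports typically state only which predictors
were excluded for violating the p-threshold. Collinear designs (condition
number > 10⁸) fail with the most correlated predictor pair named. Four
published fixed-coefficient models (tail moment from school-level total or
carcinogenic, indoor or outdoor PAHs, plus open burning) ship as a
registry for exact affine evaluation. Their open-burning slopes are
negative even though the accompanying narrative describes open burning as
increasing DNA damage; the package evaluates the printed coefficients and
surfaces the contradiction in its report rather than resolving it.

## Synthetic data

The generators exist so the pipeline's statistical structure is testable
without field data; their defaults are the study conditions.

**Congener profiles.** Six hand-built source signatures (vehicle exhaust,
gasoline, diesel, wood combustion, coke oven, petrogenic) are relative
16-congener weight vectors chosen to satisfy each source's declared
diagnostic-ratio bands (self-checked at registry construction) and to plant
recoverable factor structure; they are fixtures, not emission-inventory
estimates. A sample is `total_mean × [(1−b)·Σ f_s w_s A_s + b·activity·u]
× ε`: per-signature day-to-day amplitudes A_s are independent unit-mean
log-normals (cv 0.5, mimicking the large day-to-day sds of real
campaigns), u is a flat urban baseline of mass b = 3% that tracks overall
activity, and ε is unit-mean log-normal per-congener noise (log-sd 0.2).
An optional additive Gaussian floor emulates near-detection-limit
instrument noise; it is what makes minor congeners relatively noisier, the
regime in which a signature's marker congeners dominate factor loadings.
Concentrations below the MDL (0.1 ng m⁻³ default) are censored to missing
so imputation is exercised.

Per-sample source calling (`best_matching_signature`) votes over the
discriminating rules — those whose labels differ between the candidate
sources — with a log-ratio nearest-distance tie-break. Ratio diagnostics
degrade under mixing: ratios blend non-linearly, so a petroleum-dominant
mixture with ≳ 25% combustion admixture reads pyrogenic, and source pairs
sharing all six labels (e.g. gasoline vs vehicle exhaust) are inherently
inseparable by these rules. Recovery properties are therefore asserted on
the contrasts the rules are designed for (`SEPARABLE_MIXTURES`), and those
failure modes are considered expected behaviour, not defects.

**Population.** Two groups (85 exposed / 120 comparative) with
truncated-normal (≥ 0) tail moments at means ± sd 27.20 ± 8.21 and
21.03 ± 4.88; truncation bias at these moments is < 0.5% and ignored.
Binary lifestyle covariates are Bernoulli (prevalences are synthetic
defaults: tobacco smoke 0.40, grilled food 0.50, supplement 0.50, mosquito
coil 0.15, open burning 0.30); the mosquito-coil carriers are shifted
+3.34 (exposed) / +2.07 (comparative), the published level differences,
with the base level recentred so the group mean stays on target. Body
weights come from the group's calibrated negative-binomial spec. Each
subject inherits their school's mean indoor and outdoor PAH totals
(published values); carcinogenic fractions default to 0.45 of the totals —
a synthetic stand-in, as per-school carcinogen splits are not published.

All generators are pure functions of (spec, seed).

## Problem sizes and numerical choices

Tests run the Monte Carlo at 10,000 iterations (the study's size), the
power/type-I simulations at 2,000 replicates (vectorized Welch tests), and
planted-recovery checks at 100 samples × 10 seeds per mixture — sizes at
which every stochastic assertion has comfortable margin while the whole
suite stays fast. Tolerances: exact arithmetic claims at 1e−12; moment
inversions at 1e−4 against 4-digit references; matrix statistics against
brute-force oracles at 1e−8; communality preservation at 1e−8.

## Known limitations

* Inhalation-only risk; dermal/ingestion routes and age-segmented ILCR
  summation are out of scope.
* The comparative Monte Carlo mean is structurally tied to the arithmetic
  mean of its TEQ distribution (see the note above).
* Diagnostic-ratio source calls are unreliable for label-sharing source
  pairs and for petroleum-dominant mixtures (see above); PCA loadings
  reflect planted amplitude structure only when congener noise is not
  purely multiplicative.
* Synthetic populations carry no within-school exposure variability:
  exposure covariates are school-level constants, so fitted exposure
  slopes on synthetic data reflect the planted school contrasts only.
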