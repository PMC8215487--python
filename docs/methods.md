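# Methods

## Signal model of the synthetic generator

Each printed spot's raw fluorescence is modelled as

    raw = signal + assay_background + local_background
    signal = baseline · effect(endpoint, group) · loading(sample) · conc_scale · ε

with multiplicative log-normal spot noise ε of unit mean and user-set
coefficient of variation (CV); `log ε ~ N(−σ²/2, σ²)`, `σ² = ln(1 + CV²)`.
The components emulate the physics of the assay:

- **Print-concentration scaling** is proportional to total-protein
  concentration (`conc_scale = conc / max(conc)`), so 0.125 mg/mL spots carry
  one quarter of the 0.5 mg/mL signal — mass-loading proportionality.
- **Loading** is a per-sample log-normal multiplier (default CV 0.1) shared by
  the antibody, total-protein *and* negative-control channels of that sample,
  because all three print the same lysate. This is exactly the variation
  total-protein (Sypro) normalization is meant to cancel.
- **Assay background** is the antibody-independent secondary-antibody signal;
  the same level (default 50 A.U. against a 1000 A.U. baseline) appears
  additively in antibody-channel spots and is what the negative-control slide
  measures, so negative-control subtraction removes it exactly in the
  noiseless limit.
- **Local background** (default 20 A.U.) is a per-spot additive offset
  reported in its own column, removed by the first correction step.

Consequence used throughout the tests: with spot noise 0, the full chain
recovers programmed group effects exactly (group-mean ratio = programmed
fold-change), regardless of loading variation.

The generator emulates triplicate spots, two print concentrations, 10-point
reference curves, cohort group structure with endpoint-specific multiplicative
effects, and two-source mixture series whose expected intensity is affine in
the positive fraction. It does **not** emulate spatial slide artifacts,
antibody cross-reactivity, batch/slide effects, heavy-tailed outliers, or
censored/saturated intensities — so green tests certify the pipeline's
statistical machinery under the declared noise model, not robustness to every
failure mode of real arrays. No spot-level noise magnitudes are published for
the assay; the default CVs (0.15 cohort, 0.05 mixture) are chosen as typical
fluorescence-array values, not estimates of the study's instrument.

## Normalization chain

Steps run in a fixed order per (sample, endpoint, print concentration):
local background subtraction → negative-control subtraction → replicate
averaging → total-protein normalization; the analyzed matrix is the 0.5 mg/mL
print (the 0.125 mg/mL print is retained for linearity QC). Negative
intermediate values are floored at 0 (A.U. intensities are non-negative by
construction). Negative-control matching defaults to per-spot (sample,
concentration, replicate) granularity with a per-sample-mean fallback option,
since the original software's granularity is not documented. Total-protein
normalization divides by the sample's Sypro value rescaled by the cohort
median (so a median-loading sample is unchanged); a pure-ratio mode
(`sypro_rescale="none"`) is available and makes single-sample loading
invariance exact irrespective of the cohort composition.

## Calibration and detection limits

Reference curves are fit by unweighted OLS of log10(intensity) on
log10(amount) with replicates entered individually; adjusted R² and the
regression p-value summarize fit quality. Sub-background (non-positive)
replicates are dropped, not floored, before the log transform. Inverse
prediction `amount = 10^((log10 I − b)/m)` reports a status flag
(`in_range`/`below_curve`/`above_curve`) instead of suppressing extrapolated
estimates, since serum-EV levels routinely fall below the lowest dilution
point. Four/five-parameter logistic models are out of scope.

The mixture-series limit of detection uses a conventional immunoassay rule:
a fraction is detected when ≥ `min_detect_reps` (default 2 of 3) replicates
exceed background mean + k·SD (default k = 3); the LOD is the smallest
nonzero fraction above which detection is uninterrupted. Both knobs are
exposed; increasing k can only shrink the detected set (monotonicity tested).

## Group comparisons and clinical rules

Student's t (equal-variance, matching the classical two-sample test) and the
Wilcoxon rank-sum (Mann–Whitney) test are both exposed; t is the default for
pivotal/training-style analyses and Wilcoxon for the risk cohort. Raw
p ≤ 0.05 is the primary significance call, Benjamini–Hochberg q-values are
reported alongside. log2 fold-change is the log ratio of arithmetic group
means; a zero denominator yields an infinite sentinel with a warning.
Intersection counts follow UpSet semantics (elements significant in *exactly*
a combination), so counts partition the union.

The risk rule is evaluated in strict precedence: pTNM ≥ T3a → high;
Gleason 7(4+3) with T2c → high; Gleason ≤ 7(3+4) with T2b–T2c →
low/intermediate; Gleason 6 with ≤ T2a → low. The Gleason ordering encodes
7(3+4) < 7(4+3). Grid cells the rule does not cover (e.g. Gleason 8 with
T2a, Gleason 7(4+3) with T2b) return `unclassified` — never a silent default.
Percentile flags use linear interpolation between order statistics and a
strictly-greater-than rule; trend-vs-stage analyses are exposed only as
Spearman correlation, explicitly labelled exploratory.

## ROC, cut-offs and composite scores

The AUC is the tie-aware empirical statistic, computed from midranks
(equivalent to pair counting with half-credit for ties); direction is chosen
so AUC ≥ 0.5. The optimal cut-off maximizes Youden's J over midpoints
between adjacent distinct scores — the conventional "optimal criterion" of
clinical ROC software — with ties broken toward higher specificity (a
diagnostic context favors fewer false positives), then toward the lower
cut-off for determinism. The 95% CI and the p-value against AUC = 0.5 use
DeLong's structural-components variance; when that variance degenerates
(perfect separation, extreme ties) the CI falls back to a seeded bootstrap
and the p-value to the exact rank-sum test. Constant score vectors are
flagged degenerate (AUC 0.5, no cut-off).

Candidate combination defaults to the directional-exceedance count — each
marker contributes 1 when beyond its univariate cut-off in its case-enriched
direction — which is the same primitive as the k-of-n prognostic rule
(default 5 markers, k = 3); an in-sample logistic-regression combination is
provided as a labelled, non-canonical alternative. A constant marker receives
an unattainable cut-off and therefore never contributes. Missing values
contribute 0 to the score and are tallied per sample.

## Unsupervised views

Z scores use the sample-SD (n−1) convention per endpoint; zero-variance
endpoints are dropped with a warning. Two-way clustering applies Ward's
method on Euclidean distances to rows and columns of the standardized matrix
(scipy's nearest-neighbor-chain agglomeration; tests verify its merge heights
against a naive quadratic-time Lance–Williams oracle). Matrices with missing
cells are rejected rather than silently imputed; callers drop incomplete
endpoints explicitly. PCA eigen-decomposes the covariance (not correlation)
matrix of column-centered data; components are ordered by decreasing
eigenvalue with the sign fixed so each component's largest-magnitude loading
is positive.

## Study presets and problem sizes

Three presets mirror the study designs: *pivotal* (16 healthy donors vs 12
tumours, 37 endpoints, six programmed 2-fold tumour effects), *training*
(18 HD / 41 hypertrophic / 44 disease-free / 57 tumours with diagnostic
effects including a halved phospho-c-Myc in tumours), and *risk* (11
non-recurrent vs 7 recurrent + 6 advanced, 2-fold effects on the five
prognostic endpoints). One top-level seed drives all randomness; sub-streams
are derived deterministically (CRC-stable tags), and the run manifest records
every effective parameter and output hash.

Simulation-based checks use problem sizes chosen to give stable estimates at
interactive runtimes: 200 seeds per calibration condition, 500 mixture series
for the LOD oracle, 1,000 null endpoints at n = 20 + 20 for type-I error,
100 cohorts for signature recovery, 200 label permutations for the
permutation null, and 200 random 8×5 matrices for the clustering oracle.

## Known limitations

- The composite-score improvement check is a ceiling-limited comparison: at
  2-fold effects with CV 0.2 the individual candidate markers already reach
  AUC ≈ 1, so the composite can only be shown non-inferior to its components
  and strictly better than the typical (median) assayed endpoint.
- DeLong p-values are asymptotic; at the study's cohort sizes they are
  adequate for ranking but the exact rank-sum fallback is preferred when the
  variance degenerates.
- The negative-control model treats secondary-antibody signal as
  endpoint-independent; real slides can show antibody-specific nonspecific
  binding that this chain would not remove.
- Survival/Cox modelling, covariate adjustment, cross-validated model
  selection and inter-assay bridging are out of scope.
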