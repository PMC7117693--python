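# Methods

This note documents the models, defaults and numerical choices behind
`epicesdif`, what the synthetic cohorts do and do not emulate, and the
known limitations.

## Measurement model and estimation

Binary items are modelled with the unidimensional graded response model,
which for two response categories reduces to the two-parameter logistic:
`P(y=1|θ) = logistic(a(θ − b))`, slope `a > 0`, difficulty `b` on the
latent (logit) scale. Orientation is fixed so that the endorsed response
is the *less* precarious answer on every item and higher θ means lower
deprivation; inversely worded items must be reversed first
(`reverse_items`, tracked as state so descriptive tables can still use the
raw coding). Consequently the weighted 0–100 deprivation sum score
correlates *negatively* with θ.

Estimation is marginal maximum likelihood by Bock–Aitkin EM:

* θ prior fixed at N(0, 1) for identification; 49 probabilists'
  Gauss–Hermite nodes by default (estimates change by < 1e-6 between 41
  and 81 nodes on the reference cohort — asserted in tests);
* M-step per item: Newton–Raphson with step halving on the slope/intercept
  parametrization; slope bounded to [0.05, 10] and difficulty to [−6, 6]
  to stabilize near-degenerate items. If projecting onto the bounds would
  reduce the expected complete-data likelihood, the previous iterate is
  kept, which preserves EM monotonicity (the marginal log-likelihood is
  asserted non-decreasing on every run);
* convergence when |Δ log-likelihood| < 1e-5 (default), non-convergence
  flagged on the returned item bank, never silent;
* constant (single-category) items are rejected by name.

Person scores are expected-a-posteriori means on a 121-point grid over
[−6, 6] with the N(0, 1) prior; posterior SDs are returned. EAP agrees
with 10,001-point dense-grid integration to 1e-4 (tested). Identical
response patterns score identically to machine precision (~1e-15; exact
bitwise equality is not guaranteed because of SIMD batching in the
underlying matrix products).

At the reference scale (n = 1553, 10 items) parameter-recovery RMSEs from
a 20-seed pilot run are ≤ 0.16 for slopes and ≤ 0.28 for difficulties;
the acceptance tolerances (0.25 / 0.35) add headroom for seed-to-seed
variation. EAP-vs-truth correlation runs 0.80–0.84: this is the
measurement ceiling of a 10-item binary scale with slopes around 1 (the
marginal reliability is ~0.67), not an estimation deficiency.

## Condition checks

Standardized Pearson residuals `z = (y − P)/sqrt(P(1−P))` are evaluated at
the EAP point estimates, with probabilities clamped at 1e-10. Item fit
uses outfit (plain mean square of z) and infit (information-weighted with
`W = P(1−P)`), conventional acceptance band 0.7–1.3.

**Known behaviour:** evaluated at shrunken EAP point estimates, both mean
squares run below 1 even under a perfectly specified model, and *outfit*
can dip below 0.7 for the steepest items (a ≳ 1.5) because the point
estimate partially encodes the item's own response. The statistics remain
sharp in the direction that matters — a misfitting item (e.g. responses
independent of θ but claimed discriminant) pushes outfit well above 1.3 —
so the band should be read as an underfit detector here.
Posterior-integrated mean squares would recenter the null value at the
cost of a less transparent residual definition; the point-estimate form
was kept.

Unidimensionality: eigenvalues of the residual correlation matrix,
descending; the configurable verdict is "no dominant component" when the
first eigenvalue is below 2× the second (the published decision was
qualitative; this rule is an explicit operationalization and is
configurable). Local independence: Spearman correlations between residual
columns, overall and per group; |r| ≥ 0.4 flags a pair (0.4 being the
level the field calls strong residual dependence) and the later-indexed
item of a flagged pair is recommended for removal — codifying the
convention of dropping the later near-duplicate; the rule is overridable.
Removing the recommended item demonstrably lowers the maximum off-diagonal
residual correlation on the reference cohort (tested).

## DIF screening

Hybrid ordinal logistic regression: because items are binary the ordinal
models reduce to binary logistic regression (the design-matrix layout
follows the cumulative-logit form so ordered categories can be added
later). For each item and group pair, with θ̂ the EAP score:

* M1 `~ θ̂`, M2 `~ θ̂ + group`, M3 `~ θ̂ + group + θ̂:group`, plus an
  intercept-only null for McFadden R² = 1 − ll/ll₀;
* treatment coding with the alphabetically first group as reference — LRT
  statistics and ΔR² are invariant to the reference choice (tested);
* the logistic fits use a dedicated Newton–Raphson routine (step-halved,
  ridge-guarded); it matches `statsmodels.Logit` log-likelihoods to 1e-8
  (tested) and exists because the simulation studies run tens of thousands
  of small fits. (Quasi-)complete separation — a diverging linear
  predictor — marks the comparison unstable rather than failing;
* *detection flag*: omnibus LRT M3-vs-M1, df = 2(G−1), at α = 0.01 — a
  single α-level test, so the false-flag rate is interpretable;
* *classification*: non-uniform if the 3-vs-2 LRT is significant
  (magnitude from ΔR²₃₂), else uniform if 2-vs-1 is (magnitude from
  ΔR²₂₁), else no DIF with magnitude "not assessed". Magnitude bands:
  < 0.035 negligible, [0.035, 0.07) moderate, ≥ 0.07 important — band
  boundaries belong to the higher band, and values within 1e-6 of a
  boundary are logged;
* *purification* (default on): θ̂ re-estimated from currently unflagged
  anchor items, iterated until the flag set stabilizes (max 10 passes).
  With a single DIF item among nine anchors, purified and unpurified ΔR²
  agree at r > 0.95 (tested); purification matters more as the DIF share
  grows;
* multi-category covariates are analysed pairwise, as published practice
  for the three areas; an omnibus all-groups mode exists.

**Test size (limitation).** Monte-Carlo checks at n = 300/group, 10 items,
α = 0.01: under a clean null the per-item flag rate sits at the nominal
level (20/2000 at the committed seeds). Under *impact only* — groups'
latent means one SD apart, identical item parameters — the rate is
slightly inflated (25/2000 at the committed seeds; a larger independent
probe puts the true rate near 0.015). The inflation is intrinsic to
conditioning on an error-prone θ̂ at short test length: with the true θ
the rate is exactly nominal, with EAP from true item parameters ~0.012,
and the measurement error of a 10-item scale contributes the rest. Users
screening highly impacted groups with short scales should expect mildly
conservative α choices (e.g. 0.005) to restore the intended size;
empirical (Monte-Carlo) thresholds are deliberately out of scope.

Power, for calibration: with two groups of ~776 and the preset items, a
1-logit uniform shift is detected and correctly labelled in ≈ 95–100% of
replicates, a doubled slope on a near-zero-difficulty item in ≈ 85–90%.

## Impact assessment

Flagged items (by default those with moderate or important DIF in any
comparison; configurable down to all LRT-significant items) receive
group-specific parameters in a multi-group EM: anchor items share
parameters across groups and identify a common scale, group latent means
and SDs are freed except the reference group (first category), fixed at
N(0, 1). EAP then uses each respondent's group prior and parameters. With
no flagged items this reduces exactly to the single-group fit (tested);
with ground-truth flags it never degrades θ recovery relative to the
naïve fit (tested). All items flagged = no anchors = error.

The report gives three Pearson correlations — score vs θ̂ (naïve), score
vs θ̂ (DIF-aware), θ̂ vs θ̂ — with signs preserved (score and θ run in
opposite directions).

## Classical psychometrics

Cronbach's α on direction-aligned codes, `J/(J−1)·(1 − Σvar_j/var_total)`
with ddof = 1. Chi-square endorsement comparisons use the Pearson statistic
without Yates correction by default (toggle provided). MCA is the
correspondence analysis of the complete disjunctive table (two categories
per binary item): uniform row masses, SVD of the standardized residual
matrix; eigenvalue sum equals the total inertia (= 1 for all-binary
items, asserted to 1e-8). Percentages of variance are raw inertia shares;
the Benzécri adjustment is available behind a flag (the published tables
do not state which was used). The top `n_keep` dimensions (default 4, a
configuration choice, not an automatic rule) are rotated by an orthogonal
varimax of the mass-weighted category loadings
(`statsmodels.factor_rotation`); rotated dimension variances are the
column sums of squared loadings, re-sorted descending, and the retained
block's total variance is rotation-invariant (asserted to 1e-10). An
item's contribution to a dimension is the sum of its two categories'
contributions (each dimension's contributions sum to 1); display tables
blank entries below 0.2 while machine outputs keep everything.

## Synthetic cohorts

The generator draws θ per group from N(μ_g, σ_g²) ("impact") and responses
from the 2PL with per-(item, group) difficulty offsets (uniform DIF)
and/or slope multipliers (non-uniform DIF). The logistic link is used
without the 1.7 normal-ogive scaling constant, matching the models used
downstream. Local dependence is produced by response copying — the
dependent item copies its partner with probability `copy_prob`, else
redraws from its own 2PL — rather than a second latent factor, which
directly reproduces the observed "same answer" statistic. Identical
configurations are bitwise reproducible.

The reference preset emulates the three-area study: groups of 496/289/768
(total 1553), slopes 0.8–1.7 (values typical of health questionnaires;
the source study reports none), difficulties solved by quadrature so each
item's no-DIF marginal yes-rate matches the observed whole-sample rate
(9–94% band), items 1 and 5 stored inversely worded, extra gender and
age-band covariates at the observed frequencies, a latent-mean spread of
0.7 SD across areas, DIF on five items echoing the published pattern, and
`copy_prob` calibrated by quadrature (≈ 0.67) so the dependent pair's
*observed* same-answer proportion is ~93% — note the observed proportion
exceeds the copy probability because independently redrawn responses also
often agree.

What the generator does **not** emulate: multidimensional structure beyond
the one dependent pair, missing data (the pipeline is complete-case by
design), response styles, item weights (the published EPICES weights live
in the original validation study; scoring uses a clearly labelled
equal-weight placeholder unless a weight file is supplied), and any
clinical covariate structure. Passing tests therefore demonstrate the
statistical machinery under the stated generating assumptions, not
robustness to real-data pathologies such as guessing or drifting item
meaning.

## Pipeline and reproducibility

`run_pipeline` executes: load/simulate → descriptive table (raw codes,
*before* reversal, so the descriptive table matches the questionnaire as
asked) → reversal → GRM fit → diagnostics → removal of recommended items →
re-fit and re-diagnose → pairwise DIF per covariate → impact → α on full
and reduced sets → rotated MCA (whole sample and per primary-covariate
group). One run directory per invocation, a manifest with package
version, seed, configuration hash (analysis parameters only — output
location excluded) and stage log; identical configuration + seed
reproduces machine outputs byte for byte (tested). Any stage failure
aborts with a stage-named error and keeps partial outputs.

Simulation sizes used by the test and acceptance suites (chosen to
exercise the study scale while keeping runs desk-sized): parameter
recovery at n = 1553; test-size checks at 200 replicates × 2 conditions
(n = 600 each); power at 100 replicates × 2 DIF types (n = 1553 each);
the acceptance script uses 100/50 replicates for the same quantities.
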