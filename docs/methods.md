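# Methods

`milkspot` implements an end-to-end untargeted metabolomics workflow for
discriminating two groups of dairy cows (lame vs healthy controls) from
direct-infusion mass spectra of dried milk spots, together with a
synthetic-data generator that emulates the study design the workflow was
built for. This note records the statistical models, the numerical
choices, and what the synthetic data can and cannot establish.

## The study design being emulated

The workflow assumes a small two-arm design: 10 lame and 11 control cows
(n = 21), milk spotted on cards and extracted on two days (day 8 and
day 16 of room-temperature storage), each extract infused for both
ionisation polarities, with pooled QC samples run alongside. With 3 QCs
per day this gives 48 observations per polarity. Class discrimination is
performed on the first extraction day's 21 cow samples; the full 48 are
used for unsupervised QC assessment.

## Synthetic data generator

Per polarity, `n_features_per_polarity` true m/z values are drawn
uniformly over the scan range (default 70–1050 Th) and held fixed. Log
intensities are Gaussian:

    log I_ij = b_j + c_i + delta_j * 1[lame_i] + d_j * 1[day2_i] + e_ij

* `b_j ~ N(mu0, feature_log_sd)` — per-feature baseline (default
  mu0 = 14 ≈ 1.2e6 counts, sd 1.0, giving a realistic dynamic range over
  the 100 000-count picking threshold);
* `c_i ~ N(0, cow_log_sd)` — a per-cow size factor (default 0.3). It is
  deliberately global across features, so TIC normalisation removes it
  exactly, as it should;
* `delta_j = ln(2) * log2FC` on planted discriminative features, applied
  to lame cows (default 10 features at |log2 FC| = 1.5, mirroring the
  ~dozen discriminative ions of the emulated study);
* `d_j = ln(day_attenuation) * g_j` with `g_j = exp(N(0, 1))` — storage
  degradation. The global factor (default 0.7) reproduces the overall
  day-16 signal reduction; the per-feature modulation `g_j` is essential:
  a uniform per-sample attenuation is cancelled exactly by TIC
  normalisation and would be invisible to PCA, whereas differential
  degradation (the realistic mechanism) survives it and separates the
  extraction days along PC1;
* `e_ij ~ N(0, base_intensity_log_sd)` — residual biological + technical
  noise. The default 0.35 (≈36% CV) was calibrated so that the default
  planted effects reproduce the scale of the model statistics the
  workflow is expected to produce on real data of this kind: a planted
  |log2 FC| = 1.5 has standardised effect size d ≈ 3, giving
  near-perfect single-ion ROC behaviour and LOOCV Q² above 0.5 at
  moderate matrix widths (Q² is diluted towards ~0.35–0.4 when the full
  ~1000-feature matrix enters the model, since most columns are noise).

Observed m/z jitters multiplicatively by N(0, 1 ppm). QC samples are the
day's mean biological profile (linear scale) times a deterministic drift
ramp (default ±2%) and multiplicative log-normal noise (sd 0.03), which
places them centrally within the day's sample cloud in scores space.
Dropout is missing-not-at-random: a peak is deleted with probability
`max_rate * sigmoid(-(log I - mid)/scale)` (default 0.25, mid = 12.2,
scale = 1), monotone non-increasing in intensity, so that the >20%
missingness filter and knn imputation are exercised realistically.

What the generator does **not** emulate: isotope patterns, adducts of the
same metabolite, chimeric/overlapping peaks, profile-mode peak shapes,
retention or mobility dimensions, batch effects beyond the QC drift ramp,
and correlated metabolite modules (features are independent given the
cow). Passing tests therefore demonstrate that the statistical machinery
behaves as specified under the assumed model — not that the workflow is
robust to every artefact of real spectra.

## Feature extraction

Peaks are kept if intensity is strictly above 100 000 counts. Alignment
pools all samples' peaks, sorts by m/z, splits at consecutive relative
gaps above 5 ppm (computed against the lower value), and recursively
re-splits any block whose members deviate more than 5 ppm from the
block's intensity-weighted centroid (splitting at the largest internal
gap). If one sample contributes several peaks to a feature the most
intense is kept, and centroids are recomputed from the kept peaks. The
procedure is deterministic and order-independent.

Features missing in strictly more than 20% of all samples (QCs included)
are removed. Remaining gaps are imputed feature-wise with k-nearest
neighbours (k = 10): the neighbours of a feature are other features
ranked by Euclidean distance over mutually observed samples, restricted
to features observed at the sample being imputed; the imputed value is
their unweighted mean (ties broken by feature order; fewer than k
eligible neighbours → use all; none → the feature's observed mean). The
two polarities are then concatenated column-wise.

## Chemometrics

Preprocessing follows the TIC → log → Pareto chain. TIC normalisation
divides each row by its total ion count; before the log the fractions are
rescaled by a fixed 1e6 (counts-per-million) so that the +1 offset used
for zeros is small relative to signal; Pareto scaling divides centred
columns by the square root of the column standard deviation. Because the
rescaling constant is fixed, every post-TIC statistic is invariant to
per-sample rescaling of the raw intensities.

OPLS-DA uses the orthogonal-filtering NIPALS sequence for a single
binary response coded 0/1: the predictive weight vector is fixed from
the response; each orthogonal component captures X-variation orthogonal
to it and is deflated; one predictive component is fitted on the
filtered matrix (default 1 + 1 components). For a single response this
spans the same subspace as 2-component PLS, and the test suite asserts
prediction equality to 1e-8 against an independent PLS implementation.
VIP is computed from the predictive component(s) only — the convention
matching selection by "VIP > 1" on predictive variation — and satisfies
mean(VIP²) = 1 exactly; an option includes orthogonal components
weighted by explained X-variance. The S-plot reports each column's
covariance and Pearson correlation with the predictive score.

Q² is leave-one-out: Q² = 1 − PRESS/SS, with column means and Pareto
scales refitted inside every fold. SS is the PRESS of the fold-wise
training-mean predictor, so a constant predictor scores exactly 0.
The permutation test refits the model (and its LOOCV Q²) under label
permutations and reports p = (1 + #{null ≥ observed})/(n_perm + 1),
which cannot return zero.

Univariate screening is a per-feature two-sample Student's t-test
(pooled variance; Welch optional) with Benjamini–Hochberg q-values.
Discriminative ions require VIP > 1 AND p < 0.05 AND q < 0.05. The
single-feature ROC sweeps midpoint thresholds, computes the trapezoidal
AUC (equal to the Mann–Whitney concordance probability with half-credit
for ties), and reports the Youden-optimal operating point.

## Machine-learning triangulation

Four classifiers — random forest (500 trees), elastic-net logistic
regression (L1 ratio 0.5, C by inner 3-fold CV), PLS-DA (2 components,
0.5 cut) and a linear SVM (C = 1) — are assessed by leave-one-cow-out
cross-validation. TIC normalisation is row-wise; column standardisation
and all recursive-feature-elimination ranking are refitted inside each
training fold, so the held-out cow never influences selection. RFE
halves the feature set while ≥20 features remain, then steps by one;
importance is impurity importance for the forest and |coefficient| for
the linear models (a non-linear SVM kernel is rejected). Among subset
sizes tied for maximum accuracy the smallest wins. Stochastic learners
(the forest) are averaged over seeded repeats (default 20) for the
reported accuracy; a rank-once-on-all-data RFE variant is kept behind a
flag for comparison but is selection-biased and not the default.

A conventional-workflow feature (OPLS-DA + t-test) supported only by
PLS-family evidence — the PLS-DA top-k and/or the OPLS-based selection
itself — is flagged *model-dependent*; support from distinct model
families marks a consensus predictor.

## Stability selection

Three penalised logistic models (elastic net with mixing 0.5, Lasso,
MCP with γ = 3) are refitted on stratified bootstrap resamples of the
cows (class counts preserved, so a resample never loses a class). A
feature's stability score is the percentage of resamples in which its
coefficient is non-zero (default 500 bootstraps). The null threshold
permutes the outcome (default 20 times), repeats the bootstrap on each
permuted dataset (default 50), and takes the highest score any feature
reaches — an extreme-value null. The bootstrap p-value of a feature is
the fraction of its non-zero coefficients on the minority side of zero.
Stable features need a score strictly above the threshold and p below
0.05. A logistic outcome model is used because the response is a class
label; a linear mode exists.

The solver is an in-repo coordinate descent covering all three
penalties for logistic (IRLS / majorize-minimise) and linear responses.
Numerical choices that matter:

* **Penalty strength** is chosen per bootstrap by cross-validated
  deviance over a geometric path of 8 values down to 5% of the smallest
  fully-sparsifying λ, using 7 folds (the largest fold count that keeps
  ~3 samples per validation fold at n = 21) and the deviance-minimising
  rule; a 1-SE rule and a fixed-λ mode are available. The 1-SE rule is
  not the default because, with honest fold assignment, it suppresses
  permuted-data (null) scores more than real-data scores, which lowers
  the threshold and admits roughly three times as many false selections
  in the planted-effect recovery experiments.
* **Fold assignment is grouped by original observation**: all bootstrap
  copies of a cow go to the same CV fold. Without this, duplicates sit
  in both training and validation folds and the inner CV systematically
  overfits on resampled data — on permuted outcomes the chance-best
  feature is then "validated" by its own copies and the permutation
  threshold saturates at 96–100%, destroying the method.
* **MCP under separation**: bootstrap samples of n = 21 are frequently
  perfectly separable, and beyond |β| > γλ the MCP applies no shrinkage,
  so the maximiser drifts without bound while the selection pattern is
  frozen. The logistic MCP therefore uses the constant-curvature (1/4)
  majorizer, which is monotone in the penalised deviance, and stops when
  the objective stalls, the deviance saturates, or the sign pattern has
  been unchanged for 25 consecutive small-relative-step iterations —
  selection, not the drifting magnitude, is the estimand. The MCP
  coordinate update uses the curvature-aware threshold operator, with a
  hard-threshold branch when γ·v ≤ 1; on orthonormal designs (linear
  mode) it reproduces the closed-form MCP operator to machine precision,
  and as γ → ∞ it converges to the Lasso.

### Problem sizes used in the checks

The planted-effect recovery experiment runs at 50 features per polarity
(~100 aligned features) with 3 planted effects at |log2 FC| = 1.5,
n = 21, and reduced resampling counts (100 bootstraps, 10 permutations,
25 permutation bootstraps); under these conditions all three planted
features clear the threshold in ≥80% of 20 replicates with <1 false
selection per replicate on average. At the full default dimensionality
(~1000 features) the same planted signal does not reliably clear the
extreme-value threshold: chance features reach 50–80% selection among
1000 nulls while bootstrap L1 selection splits across the
interchangeable planted predictors. This is a property of the method at
n = 21, not of the implementation; real studies at this scale succeed
when the discriminative signal is very strong, which is exactly the
regime the generator's defaults emulate. The end-to-end demonstration
runs the full pipeline at the default scale with the reduced resampling
counts and a 150-tree forest so a complete run fits comfortably in a
few minutes on one CPU; the printed-parameter defaults (500 trees,
500/20/50 resampling) remain the package defaults for real analyses.

## Annotation

Monoisotopic masses use IUPAC/AME values at ≥9 decimal places (C = 12
exactly, H = 1.00782503207, electron = 0.000548579909 Da). Adduct m/z is
(M + Δm)/|z| with one electron subtracted (cations) or added (anions)
per charge unit — without the electron correction the glucosamine sodium
adduct, for example, is mis-estimated by ≈3 ppm. Mass error is signed,
(measured − theoretical)/theoretical × 1e6. Matching accepts either a
ppm tolerance (default 5) or an absolute m/z window (default ±0.001,
lipid-search style); hits are sorted by |ppm error|. The bundled
compound table lists the discriminative milk metabolites of the emulated
study with formulas that reproduce the printed monoisotopic masses
(CAR 13:3;O3 as C20H33NO7; PG 35:4 as its neutral species C41H71O10P).

## Pipeline determinism

Every source of randomness descends from the single config seed; output
tables are written with a fixed float format and carry a hash of the
scientific configuration in a header comment, so identical config + seed
reruns are byte-identical. Stages run strictly in order (simulate/ingest
→ extract → chemometrics → ML → stability → annotation → candidate
table); a stage failure aborts with a stage-named error and retains the
partial outputs.

## Known limitations

* Alignment is a global pooled clustering; it does not model
  within-sample mass-calibration drift over an acquisition.
* The knn imputation is O(missing cells × features) in Python and is
  sized for DIMS matrices (tens of samples × ~10³ features), not
  LC-MS-scale feature counts.
* The triangulation's PLS-family logic covers exactly the four bundled
  model kinds; adding learners requires deciding their family.
* The permutation threshold is an extreme-value statistic; with few
  permutation bootstraps its granularity is coarse (4% at 25 resamples),
  which makes small threshold differences meaningless.
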