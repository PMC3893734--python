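# Methods

## Model and assumptions

Each intrinsic subtype gets an independent one-vs-rest classifier built on
its own 10-gene panel (the five panels partition the 50 PAM50 signature
genes).  The classifier assumes that, after per-gene centering and scaling
within a study, subtype membership is expressed as a mean shift along a
small number of directions in panel-gene space; PLS1 extracts exactly those
directions by maximizing covariance between the gene matrix and the binary
membership indicator.  The logistic layer converts latent scores to a
calibrated membership probability; the 0.5 call threshold encodes an
uninformative prior over membership in each binary problem.  No constraint
ties the five classifiers together — mutual exclusivity is imposed only at
assembly time (argmax with a reject option), which is what makes ambiguous
and unclassified outcomes possible and informative.

The SSP comparator assumes each subtype is adequately summarized by the
per-gene mean centroid of its training samples, and that Spearman rank
correlation (midrank ties) to those centroids orders subtypes correctly for
a new sample.

## Algorithmic choices

- **NIPALS, single response.**  One pass per component is exact for a
  single y column, so no inner-iteration tolerance matters.  X is deflated
  by t p′ and y by t c after each component.  Weight vectors are normalized
  to unit length; score vectors are not rescaled.  Sign convention: each
  weight vector is flipped so its largest-magnitude entry is positive
  (signs are otherwise arbitrary and data-dependent).
- **Component bound.**  k may reach min(n, p).  Cross-validation folds are
  not re-centered (the input is the globally centered matrix), so no
  degree of freedom is lost to centering inside a fold; this also keeps
  single-observation training folds well-posed.
- **Projection.**  New samples are scored via the deflation-corrected
  rotation R = W(P′W)⁻¹, so projecting the training matrix reproduces the
  training scores to machine precision.
- **PRESS cross-validation.**  Systematic assignment (observation i to fold
  i mod n_folds), 7 folds by default.  If a fold's training data exhausts
  its predictive structure before max_k components, larger candidates reuse
  the last extractable component's prediction rather than failing.
- **van der Voet test.**  Statistic C = Σ(r²_k − r²_ref); the null flips
  the sign of each paired difference.  Full enumeration of all 2ⁿ sign
  patterns when n ≤ 20 (exact, unsmoothed); otherwise Monte Carlo with
  add-one smoothing, 2000 draws by default, seed mandatory.  Selection
  level α = 0.10 by default.
- **Logistic fit.**  Newton/IRLS to |step| < 1e-10.  Divergence (perfect or
  quasi-separation) triggers a refit with ridge penalty 1e-6 on the slope
  coefficients, logged.  Predicted probabilities are clipped to
  [1e-12, 1−1e-12] to preserve the open-interval contract under saturation.
- **LOOCV.**  Per held-out sample, the per-gene means/sds, the PLS
  decomposition (k fixed, not re-selected) and the logistic regression are
  all refit on the remaining n−1 samples — the scaling refit prevents the
  held-out sample from leaking into its own prediction.
- **Metrics.**  AUC is the midrank (Mann–Whitney) statistic; "adjusted R²"
  is Nagelkerke's pseudo-R², computed from whichever probability vector
  (cross-validated or resubstitution) is under evaluation.  Cross-validated
  metrics are primary; resubstitution metrics are reported alongside in the
  training report.
- **Weighted kappa.**  Linear (Cicchetti–Allison) weights with categories
  in the canonical order (Basal-like, HER2-enriched, Luminal-A, Luminal-B,
  Normal breast-like, Unclassified last); this scheme-and-order pair
  reproduces all three published agreement values to three decimals,
  pinning the convention (quadratic weights do not).  SE is the
  Fleiss–Cohen–Everitt large-sample formula; the 95% CI is Wald, truncated
  to [−1, 1], and is property-tested (bracketing, 1/√n scaling) rather
  than checked against published intervals, whose formula is not
  documented.
- **EM imputation.**  Missing entries start at the gene's observed mean,
  then iterate to the rank-k reconstruction (truncated SVD by default; PLS
  x-reconstruction when a response is supplied) until the largest change
  falls below 1e-6 or 100 iterations.  Observed entries are never altered.
- **Probeset collapse.**  Linear-interpolation quantiles for the IQR; ties
  keep the first probeset in input order with a warning.
- **Thresholds.**  Positive call > 0.5 (strict); forced-mode floor > 0.1
  (strict); SSP unclassified iff every rho < 0.1 (so a maximal rho exactly
  at 0.1 is assigned).  Exact argmax ties break to the canonical subtype
  order and set the ambiguous flag.
- **Multiple-comparison level.**  A global significance level of 0.01
  (0.05/5, one test per subtype classifier) is the configurable default for
  reporting coefficient significance; it does not modify the 0.5 call
  threshold.

## Synthetic-data generator

`generate_cohort` draws gene g of a sample in subtype s as
shift(g, s) + N(0, noise_sd), with shift = effect_size when g lies on s's
own panel, an optional cross-effect for other panels, and 0 for background
genes (named BG0001…); entries are then masked missing uniformly at
random.  Defaults mirror the prototype training cohort: 57/35/23/12/12
samples per subtype, effect size 2 (in units of the noise sd), unit noise,
no missingness.  An effect size of 2 with unit noise makes single genes
noisy but 10-gene panels highly informative — the regime the classifier is
designed for.

What the generator does **not** emulate: gene–gene correlation within and
across panels, heavy-tailed or heteroscedastic noise, platform/batch
effects, probe-level artifacts, or the continuum between Luminal-A and
Luminal-B that makes real subtype boundaries soft.  Tests passing on this
generator therefore demonstrate correctness of the algorithms under the
model's own assumptions, not clinical-grade performance on real arrays;
the published confusion tables shipped as fixtures are the only contact
with real data, and only the agreement statistics computed from them are
asserted.

## Problem sizes in the test and acceptance runs

Synthetic checks use cohorts of 40 samples per subtype (parameter
recovery, 10 seeds), 12 per subtype (null-AUC control, 100 replicates) and
smaller unit-test instances — sizes at which every property under test is
already stable.  The published-table statistics involve no simulation.

## Known limitations

- The per-subtype panels are fixed inputs; the gene-selection procedure
  that produced them (nearest-centroid class-specific selection) is out of
  scope.
- Probabilities are not calibrated across the five classifiers; the
  assembly argmax compares raw one-vs-rest probabilities.
- Direct multiclass models (multinomial/ordinal logistic on PLS scores,
  multi-response PLS2) are deliberately excluded.
- The kappa CI assumes the large-sample normal approximation; bootstrap
  intervals are not provided.
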