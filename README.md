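# plssubtype

Multiclass intrinsic-subtype prediction for gene-expression data by
one-vs-rest partial least squares (PLS) regression, with a centroid-based
single-sample predictor (SSP) as comparator and weighted-kappa agreement
statistics.

## The problem

Breast-cancer "intrinsic" taxonomy assigns a tumor to one of five molecular
subtypes — Basal-like, HER2-enriched, Luminal-A, Luminal-B, Normal
breast-like — from the expression of the 50 PAM50 signature genes.  The
standard assignment method (SSP) correlates each sample against per-subtype
mean-expression centroids.  Multiclass prediction from expression data is
awkward for classical statistics because the number of genes p exceeds the
number of samples n and genes are strongly collinear.  `plssubtype`
implements an alternative: dimension reduction by supervised latent factors
plus one binary classifier per subtype, with an explicit reject option.

## The method

For each subtype, a one-vs-rest classifier is built on that subtype's
10-gene panel:

1. **Latent gene components (PLS1/NIPALS).**  With X₀ the centered and
   scaled sample × gene matrix and y₀ the centered binary membership
   indicator, components are extracted one at a time: weight
   w ∝ X₀′y₀ (normalized to unit length), x-scores t = X₀w, x-loadings
   p′ = (t′t)⁻¹t′X₀, then X₀ and y₀ are deflated by tp′ and tc.  Successive
   score vectors are orthogonal; each component maximizes the covariance
   between predictor and response residuals.
2. **Component count.**  Split-sample cross-validation PRESS, then van der
   Voet's sign-flip randomization test: the selected k is the smallest
   candidate not significantly worse (p ≥ 0.10) than the PRESS minimizer.
3. **Logistic regression on scores.**  P(member) =
   (1 + exp −(β₀ + β₁x₁ + … + β_k x_k))⁻¹, fit by IRLS with a
   ridge-stabilized fallback under perfect separation.  On a training
   cohort, probabilities are leave-one-out cross-validated (scaling, PLS
   and LR all refit per fold).
4. **Assembly.**  A sample is called for the subtype with the highest
   probability provided it exceeds 0.5; ambiguous if two or more
   classifiers exceed 0.5; Unclassified if none does.  Forced mode instead
   calls the argmax whenever it exceeds 0.1.

Agreement between two call sets is quantified by weighted Cohen's kappa
with linear weights w_ij = 1 − |i−j|/(R−1) over the canonical category
order, with the large-sample (Fleiss–Cohen–Everitt) standard error.

Missing expression values are filled by an EM loop around a low-rank
reconstruction; multiple probesets per gene collapse to the most variable
one by inter-quartile range.

## Worked example

Simulate a 60-sample cohort (12 per subtype, 2-sd panel shifts, unit
noise), train the five classifiers, call the cohort with leave-one-out
probabilities, run SSP on the same data, and measure agreement:

```
plssubtype simulate --seed 42 --out-prefix demo --n-per-subtype 12 --effect-size 2.0
plssubtype train   --expression demo_expression.tsv --labels demo_labels.tsv \
                   --out-bundle demo_bundle.json --report demo_report.tsv --seed 7
plssubtype predict --bundle demo_bundle.json --expression demo_expression.tsv \
                   --loocv-labels demo_labels.tsv --out demo_calls.tsv
plssubtype ssp     --expression demo_expression.tsv --labels demo_labels.tsv --out demo_ssp.tsv
plssubtype agree   --calls-a demo_ssp.tsv --calls-b demo_calls.tsv
```

Training logs one line per classifier — the chosen component count and the
cumulative fractions of predictor (X) and response (Y) variance the latent
components capture:

```
Basal-like: k=1, X-var 46.7%, Y-var 92.2%
HER2-enriched: k=1, X-var 47.8%, Y-var 88.4%
Luminal-A: k=1, X-var 44.2%, Y-var 86.0%
Luminal-B: k=1, X-var 43.7%, Y-var 87.8%
Normal breast-like: k=1, X-var 41.6%, Y-var 87.7%
```

One component per subtype suffices at this separation.  The final command
cross-tabulates SSP against the PLS calls and prints

```
weighted kappa (linear): 1.000 (SE 0.0000, 95% CI 1.000-1.000, n=60)
```

— perfect agreement on this well-separated cohort (0 ambiguous,
0 unclassified).  At lower effect sizes or with forced-mode calling the two
methods begin to diverge, which is exactly what the kappa machinery is for.

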