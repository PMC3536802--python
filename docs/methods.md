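# Methods

## Quantification model

All expression quantities derive from cycle-threshold (Ct) values, the PCR
cycle at which a well's fluorescence crosses a fixed threshold; one cycle ≈
a two-fold abundance difference, lower Ct = more template.

- **Replicate aggregation.** Wells are run in duplicate; the working Ct per
  (sample, assay, timepoint) is the arithmetic mean of the *present*
  replicates. Pairs whose range exceeds `discord_limit` (default 1.0 cycle)
  are flagged in a QC report but kept — flag-but-keep surfaces pipetting
  problems without silently discarding data. Undetected wells
  ("Undetermined") stay missing and are never imputed to the 40-cycle run
  ceiling; downstream operations skip missing samples and report the count
  skipped. Imputation policies only matter when detection fails, and the
  plasma assays this pipeline targets detect essentially always.
- **Normalization.** ΔCt = Ct(target) − Ct(reference gene); the default
  reference is RNU6B, constitutively expressed in plasma. ΔΔCt subtracts
  the *control-group mean* ΔCt (the natural calibrator in a cohort design,
  where no single calibrator sample exists), and fold change is 2^−ΔΔCt
  exactly — no amplification-efficiency (Pfaffl) correction, since the
  assays are assumed near-100% efficient.
- **Combined two-marker score.** 2^−(Ct_num − Ct_den) divides one marker's
  abundance by another's within the same sample. No reference gene enters
  it, and any additive per-sample Ct offset (input amount, pipetting)
  cancels exactly — a property the tests assert.
- **Feature scale.** Logistic-regression features and ROC scores use the
  log2 quantities (−ΔCt, log2 score), not the exponentiated values: ROC
  analysis is invariant to the monotone transform, and the log scale keeps
  the regression numerically well-behaved.

## Screening rules

- **Discovery (concordance filter).** A miRNA passes "up" iff its
  case/control fold change strictly exceeds the cutoff (default 2.0) in
  *both* plasma and tumor tissue; "down" iff both folds are strictly below
  1/cutoff. Strict inequality means a fold of exactly 2.0 fails.
  Concordance between plasma and tumor rules out circulating miRNAs that
  originate from sources other than the tumor. Fold changes are computed
  group-wise (cancer vs control means); a patient-matched tumor-vs-adjacent
  mode was considered and not implemented because the group-wise form is
  what the downstream rules consume.
- **Training screen.** Up-regulated candidates must show (i) case vs
  control Mann–Whitney p < α with a higher case median and (ii) pre- vs
  post-operative Wilcoxon signed-rank p < α with a lower post-operative
  median — a marker that does not fall after tumor resection is not
  tumor-derived. Down-regulated candidates are exempt from (ii): a
  depressed tumor-suppressor signal need not rebound within two weeks of
  surgery, so requiring it would discard biologically valid markers.
  α defaults to 0.05 and is configurable. Direction calls use medians,
  consistent with the nonparametric tests.

## Combination selection

Exhaustive enumeration of all non-empty marker subsets up to `max_size`
(the trained panels here have ≤ 6 markers, so 2^k − 1 fits are cheap).
Each subset's logistic model is fit by iteratively reweighted least squares
(Newton with step-halving; convergence at 1e-8 max coefficient change,
≤ 100 iterations). Step-halving guarantees the log-likelihood is monotone
non-decreasing over iterations, which the tests assert. Quasi-complete
separation — fitted probabilities within 1e-6 of their labels with
diverging coefficients — is detected and flagged rather than reported as a
converged fit; no regularization or Firth correction is applied, so a
flagged fit is the honest outcome on separable data.

Subsets are ranked by the AUC of pooled leave-one-out held-out
probabilities (cross-validated deviance available via a flag); ties break
toward fewer markers, then lexicographic names, so parsimonious panels win
when discrimination is equal. LOOCV is fully deterministic. A fold whose
training labels collapse to one class scores that sample at the training
prevalence and is flagged.

**Known property: null LOOCV AUC is pessimistic.** On label-independent
features the pooled LOOCV AUC centers near 0.40, not 0.50 — leaving out a
case shifts the refit toward controls, anti-correlating held-out scores
with the left-out label. An independent sklearn
`LogisticRegression + LeaveOneOut` pipeline reproduces the same value, and
one acceptance test recording the chance-level expectation therefore fails
by design. The bias is conservative for model selection (it never inflates
apparent discrimination) and affects all plain LOOCV pipelines equally.

## Diagnostics

Empirical ROC over all distinct thresholds, predicted positive when
score ≥ threshold, tied scores grouped into one vertex; the trapezoidal AUC
then equals the Mann–Whitney U (ties counted 1/2) divided by
n_pos · n_neg, an identity the tests check to machine precision on random
data. AUC 95% CIs: Hanley–McNeil (Q1/Q2 variance approximation) by default,
DeLong's placement-value estimator as the modern alternative; both clipped
to [0, 1]. The optimal cutoff maximizes Youden's J = sensitivity +
specificity − 1 (closest-to-top-left available), ties broken toward higher
specificity, and is reported as the midpoint between the adjacent distinct
scores straddling the optimum so any ≥-thresholding implementation
reproduces the same confusion table. Proportion CIs are exact
Clopper–Pearson (Wilson by flag); the odds ratio (tp·tn)/(fp·fn) gets a
Woolf log-normal CI with the Haldane–Anscombe +0.5 correction applied to
all cells when any cell is zero.

## Rank tests

Mann–Whitney, Wilcoxon signed-rank, Kruskal–Wallis and Pearson χ² wrap
scipy.stats behind one result type; all p-values are two-sided.
Exact-vs-approximate switching: Mann–Whitney enumerates exactly when both
groups have ≤ 10 tie-free observations; the signed-rank test enumerates all
2^n sign patterns whenever ≤ 20 non-zero pairs remain, using midranks with
a generating-function convolution so tied |differences| are handled
exactly; larger samples use tie- and continuity-corrected normal
approximations. Zero differences are dropped (Wilcoxon's convention; Pratt
out of scope). χ² applies no Yates correction by default. These conventions
are this package's documented defaults, not claims about any particular
commercial implementation. No multiple-testing correction is applied in
the screening stages; a Bonferroni helper exists as an off-by-default
extension.

## Synthetic cohorts

The generator emulates a three-stage case–control study design so every
pipeline stage is testable without patient data. Noise is Gaussian on the
Ct scale (log-normal expression), the standard qPCR error model. Each
sample carries a random offset shared by all of its assays including the
reference gene — global RNA input variation — which cancels under ΔCt and
in the combined score; each paired patient carries an additional offset
shared between their pre- and post-operative samples. Duplicate wells are
drawn so the *aggregated* Ct has SD exactly `noise_sd` (biological SD is
reduced by the technical replicate share), keeping the closed-form planted
truths exact: expected fold = 2^−shift and expected combined-score AUC =
Φ(Δμ/σ√2).

Default study conditions:

| stage | n | effects | noise_sd |
|---|---|---|---|
| discovery | 5 BC (plasma+tumor+adjacent) + 5 N | 8 assays −2 Ct in cancer plasma *and* tumor, miR-145 +2 Ct, 20 null assays | 0.3 |
| training | 15 paired pre/post BC + 15 N | miR-16/21/451 −2 Ct tumor-derived (post-op recovery 0.8); miR-145 +2 Ct, not tumor-derived; other candidates null | 1.0 |
| validation | 170 BC, 100 N, 95 other cancers | miR-451 −2.5 Ct, miR-145 +1.0 Ct in BC (log2-score separation 3.5 ⇒ AUC Φ(1.75) ≈ 0.960); lung cancer +1.0 Ct on miR-451 | 1.0 |
| blind | 70 BC, 50 N | as validation | 1.0 |

The tight discovery noise reflects the profiling stage's within-array
precision at n = 5 per class; the single-assay qPCR stages use a full cycle
of between-subject variation. Validation stage labels follow the cohort's
stage distribution (DCIS 27 : I 31 : II 34 : III 23 : IV 5); controls are
60:40 female:male. What the generator does *not* model: haemolysis
contamination of miR-451, array normalization artifacts, age/sex
confounding, assay-by-patient interactions, or correlated markers — so
passing recovery tests demonstrates the pipeline's correctness under its
stated model, not robustness to those real-data complications. In
particular, with independent markers the LOOCV search can occasionally
rank a signal+noise triplet above the true pair at realistic sample sizes;
the tests pin the planted-pair result at fixed seeds and separately assert
the pair is always contained in the top set.

## Numerical and interface choices

- Ct validity ceiling 40 cycles (standard run length), configurable.
- Generated Ct values are rounded to 4 decimals (instrument-like precision)
  so emitted CSV files are byte-stable across platforms.
- CSV dialects: Ct tables `sample_id,assay,specimen,group,timepoint,
  replicate,ct` with missing Ct as empty or "Undetermined"; metadata
  `sample_id,age,sex,stage,dcis_grade`.
- The blind stage *requires* the serialized model artifact (marker pair,
  orientation, cutoff) written by the validation stage and never refits;
  a missing artifact aborts rather than silently re-deriving a cutoff.
- Problem sizes in the test-suite simulations (100 discovery seeds, 10,000
  null replicates, 30 LOOCV null seeds, 500 DeLong coverage datasets) are
  chosen to bound Monte-Carlo error well below each assertion's tolerance
  while keeping a full run in tens of seconds.

## Known limitations

- Single reference gene only (no geNorm-style multi-reference averaging).
- No partial or time-dependent ROC, no cost-weighted cutoffs.
- The logistic search is exhaustive and intended for small panels (≤ 6
  markers); it is not a penalized/stepwise selector.
- Exact rank-test enumeration limits (10 / 20) are desk-scale choices;
  beyond them the normal approximations are used.
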