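# Methods

This note documents the statistical model, the tunable parameters, the
synthetic-data generator, and the numerical/design choices behind
`iciscreen`.

## The screening model

The screen treats each gene independently as a diagnostic marker for
therapy response. For a gene with expression values `X_NR` in `n_NR`
non-responders and `X_R` in `n_R` responders, the raw area under the ROC
curve is the two-sample rank probability

    AUC_raw = P(X_NR > X_R) + ½ P(X_NR = X_R),

estimated with midranks, and is related to the Mann–Whitney statistic by
`U = AUC_raw · n_NR · n_R`. This identity is property-tested (ties
included) and is the reason a single rank computation yields both the test
statistic and the effect size.

**Orientation.** `AUC_raw` uses non-responders as the positive class (the
resistance reading: higher expression predicts treatment failure). Reported
AUCs are oriented, `max(AUC_raw, 1 − AUC_raw)`, with a `direction` field:
`higher_in_nonresponder` (resistance candidate), `higher_in_responder`
(sensitivity candidate), or `tie` exactly when `AUC_raw = 0.5`. Direction
therefore follows the *rank* statistic; the fold change is the oriented
ratio of class *means* (≥ 1). In rare discordant genes (means and ranks
disagreeing about which class is higher) the result row keeps the AUC-based
direction — ranks drive the test, so they drive the headline orientation.

**P-values.** Two-sided. For tie-free data with at most 8 observations per
group the null distribution of U is enumerated exactly; otherwise a normal
approximation with tie-corrected variance and continuity correction is used
(delegated to `scipy.stats.mannwhitneyu`, whose conventions match this
rule). Constant pooled data short-circuit to `U = n_NR·n_R/2, p = 1`. The
cohorts this package targets have hundreds of samples per arm, where the
choice of variant is numerically irrelevant; the explicit rule exists for
determinism. Exhaustive enumeration over every achievable U shows the
approximation stays within 0.03 of the exact p for groups of ≥ 5; the gap
grows to 0.031 at 4 per group and 0.088 at 2 per group, which is why the
exact path takes precedence whenever it applies.

**Multiple testing.** Bonferroni at family level α = 0.05 (configurable).
`m` counts the genes *actually tested in that cohort* — genes need
`min_class_size` (default 3) non-missing observations per class, and an
optional gene filter (e.g. a protein-coding whitelist) is applied first —
so the threshold is arm-specific. Display strings floor the threshold to
two significant digits (0.05/29755 = 1.68E-06 prints as `1.6E-06`);
filtering always uses the exact value. `min_class_size ≥ 3` prevents
degenerate perfect AUCs driven by one or two samples on small panels.

## Harmonization

Datasets are merged into the union gene space; a platform's absent genes
are *missing*, never zero. Quantile normalization is performed once,
jointly across all datasets: the reference quantile function is the
across-sample mean of per-sample empirical quantile functions evaluated at
the order-statistic positions `(r − ½)/n`. Complete samples get classical
quantile normalization (rank r ↦ mean rank-r order statistic; ties receive
the mean of the reference values their ranks span — conventions differ
between implementations, so this dialect is pinned by tests, including an
independent cross-check against `limma::normalizeQuantiles(ties=TRUE)` on
tie-free data). Samples with missing genes are mapped through the reference
quantile function at their own empirical quantiles by linear interpolation.

"Scaled to 1000" is implemented as a single global multiplicative constant
bringing the overall mean of the normalized table to the target. A global
constant is the only scaling that fixes the unit while leaving every rank
statistic, AUC and fold change untouched (asserted by screening before and
after scaling); both the target and the centering statistic are
configurable. The union gene space (rather than the gene intersection) is
deliberate: it is what lets different arms test different gene counts, and
panel samples simply contribute missing values for genes they lack.

No batch correction beyond quantile normalization is applied, and no log
transform: the screen is rank-based, so any monotone per-dataset transform
is already immaterial after normalization. Whether joint or
per-technology-group normalization is more faithful for a given study is an
open question; joint is the default and a per-group split is a config
choice left to the user.

## Response dichotomization

Rule order per sample (all parameters in `LabelConfig`):

1. RECIST present: CR/PR → responder, SD/PD → non-responder. RECIST takes
   priority over survival because the radiological category is the direct
   response measurement; no conflict resolution between the two is
   attempted (so SD with long PFS stays a non-responder).
2. Else PFS (with RFS/PFI treated as synonyms upstream): time > 12 months →
   responder; event at ≤ 12 months → non-responder; censored at or before
   12 months → uninformative.
3. Else — or when PFS was uninformative — the same rule on OS, if
   `allow_os_fallback` (default on; OS-only cohorts exist and would
   otherwise drop out entirely). The fallback is config-gated because OS is
   a noisier surrogate for response.
4. Otherwise unevaluable (`basis = none`).

Boundary cases are strict and deterministic: "longer than 12 months" is a
strict `>`, an event at exactly 12 months is a non-responder, a censoring
at exactly 12 months is unevaluable. The cutoff unit is months throughout.

## Cohorts

Six canonical cohorts: {anti-PD-1, anti-PD-L1, anti-CTLA-4} ×
{pre-treatment, on-treatment}. A combination-therapy sample belongs to
every arm matching one of its drug classes — the double-counting reading
under which summed arm sizes minus extra memberships equals the distinct
sample total (877 + 488 + 124 − 55 = 1434 in the motivating pooled
database). Patients with multiple biopsies contribute each sample to its
timing-matched cohort; no per-patient collapsing. Unevaluable samples never
enter a cohort; a cohort with zero responders or zero non-responders is
degenerate (an error when requested directly, a flagged row in the
six-group summary). On-treatment cohorts are built but not screened by
default — they are small and biologically post-exposure.

## Synthetic data generator

`simulate_database` emulates the structure of a pooled ICI database:

- **Null genes**: per-gene baseline `μ_g ~ N(3.0, 1.2)` on the natural-log
  scale, per-sample noise `N(0, 1)`, values `exp(·)`. These defaults give
  positive, right-skewed, RNA-seq-magnitude values; they are arbitrary
  units and nothing downstream depends on them (the screen is rank-based).
- **Planted markers**: binormal construction — the labeled class's log
  values are shifted by `Δ = √2·Φ⁻¹(AUC_target)·σ`, so the population AUC
  is exactly `Φ(Δ/(σ√2)) = AUC_target`, giving recovery tests closed-form
  targets. Direction chooses which class is shifted.
- **Platform distortion**: per dataset, `value ↦ scale · value^exponent` —
  strictly monotone, hence harmless within a dataset but ruinous across
  datasets until quantile normalization removes it. This is what makes the
  harmonization step's value empirically measurable (the acceptance suite
  compares post-normalization combined-cohort AUCs against an undistorted
  paired run sharing the same random stream; residuals stay within ±0.05).
- **Panel-like datasets** keep a random fraction of the gene universe and
  round values to integers — tie-heavy, NanoString-like — deliberately
  stress-testing midrank handling and the missing-gene path.
- **Clinical annotation** per dataset: RECIST-only, PFS-only, OS-only or
  mixed; survival times are drawn consistent with the true label (responders
  `> 12` months, non-responders progressing before 12 with an event), and a
  configurable fraction of survival-only samples is censored before 12
  months, making them unevaluable by construction. Drug classes (including
  an anti-PD-1 + anti-CTLA-4 combination fraction) and biopsy timing are
  assigned per sample.
- **Truth table**: per-sample true label, arm memberships and timing; per
  planted gene the target AUC and direction.

The default configuration is six datasets (~280 samples, two panel-like,
one OS-only anti-CTLA-4 dataset, five planted markers with AUC 0.65–0.80 in
both directions) — the same *structure* as a real 19-dataset pooled study
at a size convenient for routine runs; tests that need exact class sizes
use `balanced_labels` to fix the responder count. What the generator does
**not** emulate: gene–gene correlation, tumor-type expression programs,
realistic survival shapes beyond the 12-month rule, or library-size /
count-depth artifacts. Passing recovery tests therefore demonstrate the
statistics and plumbing, not robustness to correlated biology.

## Numerical choices

- Duplicate gene rows in an input table collapse by per-sample maximum
  (deterministic, and conservative for a "higher expression = resistance"
  reading); a warning is logged.
- A gene whose class mean is exactly zero (possible on integer panels)
  reports fold change `inf` inside a screen instead of aborting the whole
  run; the standalone `fold_change` raises, since a lone ratio on a zero
  mean is meaningless.
- Quantile normalization of tie-free complete data is idempotent to 1e-9;
  with cross-sample ties it is not exactly idempotent (tied values receive
  spanned-reference means, which feed back into the next reference) — a
  property of the method, not of this implementation.
- ROC plot paths use the empirical step convention with ties moved
  simultaneously, so the trapezoidal area equals the midrank AUC exactly;
  the annotation is recomputed from the cohort object, never re-read from
  disk, and an internal consistency check enforces agreement to 1e-9.
- All simulation entry points take integer seeds; identical seeds yield
  byte-identical output files.

## Problem sizes used in validation

The validation suite runs at sizes chosen to make its statistical
guarantees sharp yet routine to execute: 200 replicate null screens of
m = 1000 genes at 40/40 samples for family-wise error; 100 replicate
screens of m = 1000 genes at 300/300 for planted-marker recovery (50 seeds
for AUC calibration of the 0.75 marker); and a 400-gene, 2 × 150-sample
paired run for distortion neutralization. At these sizes the binomial and
Hanley–McNeil standard errors are small relative to every asserted
tolerance.

## Known limitations

- Gene identifiers are opaque symbols; no alias mapping is attempted, so
  cross-dataset symbol drift must be resolved upstream.
- Deduplication of samples shared between source repositories is
  manifest-driven (exclude the record), not inferred from the data.
- No survival modelling (no Cox/Kaplan–Meier): time-to-event data enter
  only through the dichotomization rule.
- The Bonferroni-only control is deliberate; there is no FDR mode.
- Pooling tumor types within an arm trades confounding for power; per-type
  sub-screens are out of scope beyond the `tumor_types` cohort filter.
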