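# iciscreen

Genome-wide screening for transcriptomic biomarkers of **immune-checkpoint
inhibitor (ICI) response** across pooled, heterogeneous tumor expression
cohorts.

Only a handful of clinically usable biomarkers exist for anti-PD-1,
anti-PD-L1 and anti-CTLA-4 therapy. Individual ICI trial cohorts are small,
but many public datasets report both tumor gene expression and clinical
response; pooling them buys statistical power at the cost of severe platform
heterogeneity (RNA-seq pipelines vs. NanoString counting panels, different
gene sets, different value scales). `iciscreen` implements that pooled
screening workflow end to end, for bioinformaticians and translational
researchers who want to rank genes as candidate resistance or sensitivity
markers:

1. **Harmonization** — per-dataset genes × samples tables are merged into a
   union gene space, quantile normalized jointly (removing any monotone
   per-platform distortion) and rescaled by one global constant so the
   overall mean is 1000.
2. **Response dichotomization** — each patient becomes a responder
   (RECIST CR/PR, or progression-free survival > 12 months), a non-responder
   (SD/PD, or progression within 12 months), or unevaluable (censored before
   12 months). An optional overall-survival fallback covers OS-only cohorts.
3. **Cohort stratification** — six drug-class × biopsy-timing groups;
   combination-therapy samples enter every matching arm; only pre-treatment
   cohorts are screened by default.
4. **Per-gene screen** — for every gene *g* with expression *X*, the
   Mann–Whitney U test between non-responders (NR) and responders (R), using
   the identity with the empirical ROC AUC (midranks for ties):

       AUC_raw = P(X_NR > X_R) + ½·P(X_NR = X_R) = U / (n_NR · n_R)

   Reported per gene: oriented AUC = max(AUC_raw, 1 − AUC_raw) with an
   explicit direction, the two-sided *P* (exact enumeration for tie-free
   groups of ≤ 8, tie-corrected normal approximation otherwise), and the
   oriented fold change of class means. Family-wise error over the *m*
   genes actually tested in an arm is Bonferroni-controlled at α/m
   (e.g. 0.05 / 29 755 prints as 1.6E-06).
5. **Panel evaluation, ranking, druggability** — fixed biomarker panels with
   panel-wise Bonferroni, AUC-based ranking of a gene against the rest of a
   screen, and joining a user-supplied druggable-gene list to flag
   significant, druggable resistance markers.

A fully synthetic multi-dataset generator (`iciscreen.simulate`) emulates
the pooled-database structure — mixed platforms, integer tie-heavy panels,
reduced gene sets, mixed outcome annotation, censoring, combination therapy
— with planted markers of known AUC (binormal construction,
Δ = √2·Φ⁻¹(AUC)), so the whole pipeline is testable without any download.

The core statistics follow the scikit-learn estimator API:
`QuantileNormalizer` is a transformer and `ResponseScreen` a supervised
feature-selection-style estimator (`fit(X, y)`, `get_support()`,
`transform`), so both compose with sklearn pipelines.

## Worked example

The built-in fixture is a 6-gene × 12-sample two-dataset database with one
combination-therapy patient, one censored (unevaluable) patient and one
on-treatment biopsy:

```python
import iciscreen as ic

db = ic.simulate_worked_example()
combined = ic.merge_datasets(db.matrices)
labels, summary = ic.label_cohort(db.annotations)
cohort = ic.build_cohort(combined, db.annotations, labels,
                         ic.CohortSpec("anti-PD-1", "pre-treatment"))
res = ic.screen_cohort(cohort)

print("label summary:", summary)
print(f"cohort: {cohort.n_responder} responders / {cohort.n_nonresponder} non-responders")
print(f"m_tested={res.m_tested}  threshold={res.threshold:.3e} (display {res.threshold_display})")
for r in sorted(res.results, key=lambda r: r.p_raw):
    print(f"{r.gene:7s} AUC={r.auc:.3f} {r.direction:22s} FC={r.fold_change:.2f} "
          f"P={r.p_raw:.4f} {'*' if r.significant else ''}")
```

which prints (`summary`, cohort sizes, then one row per gene sorted by *P*):

```
label summary: {'responder': 6, 'non_responder': 5, 'unevaluable': 1,
                'by_basis': {'recist': 7, 'pfs_rule': 4, 'os_rule': 0, 'none': 1}}
cohort: 5 responders / 5 non-responders
m_tested=6  threshold=8.333e-03 (display 8.3E-03)
RES1    AUC=1.000 higher_in_nonresponder FC=4.00 P=0.0079 *
SEN1    AUC=0.880 higher_in_responder    FC=2.29 P=0.0556
EXTRA1  AUC=0.778 higher_in_nonresponder FC=1.07 P=0.4000
HOUSE1  AUC=0.620 higher_in_nonresponder FC=1.00 P=0.5876
VAR1    AUC=0.560 higher_in_responder    FC=1.13 P=0.8413
NULL1   AUC=0.500 tie                    FC=1.00 P=1.0000
```

`RES1` — every non-responder expresses it above every responder — reaches
oriented AUC 1.0 with the exact two-sided *P* = 2/252 ≈ 0.0079, below the
Bonferroni threshold 0.05/6, so it is flagged significant (`*`): a
resistance-marker candidate. `SEN1` is higher in responders (a sensitivity
marker, AUC 0.88) but misses the family-wise threshold at this sample size;
`NULL1` is constant, hence AUC 0.5 and *P* = 1.

The same flow from a shell, on a synthetic database:

```bash
iciscreen simulate --seed 4 --out-dir db/
iciscreen run --manifest db/manifest.yaml --out-dir out/ \
    --arm pd1 --timing pre --plot-gene RESIST1
```

writes `out/results.tsv` (one row per tested gene, metadata in `#` header
lines), `out/run.log`, and ROC/boxplot panels for `RESIST1`.

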