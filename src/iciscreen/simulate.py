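"""Synthetic multi-cohort ICI databases with known ground truth.

The generator emulates the structure of a pooled checkpoint-inhibitor
expression database: several datasets on different platforms (RNA-seq-like
continuous values vs panel-like integer counts on a reduced gene set),
per-dataset monotone scale distortions, mixed clinical annotation (RECIST
only, progression-free survival only, overall survival only, or mixed),
right-censoring, combination-therapy samples shared between screening arms,
and a handful of planted response-associated genes of known effect size.

Effects are planted on the log scale with the binormal ROC model: a class
mean shift of ``delta = sqrt(2) * Phi^{-1}(AUC)`` (unit log-scale noise)
yields the requested AUC in closed form, ``AUC = Phi(delta / sqrt(2))``,
giving parameter-recovery tests analytic targets.  Per-dataset distortions
are strictly monotone (power then scale) so that quantile normalization can
remove them exactly in distribution — which is precisely what makes the
harmonization step's value measurable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import (
    NON_RESPONDER,
    RESPONDER,
    UNEVALUABLE,
    ExpressionMatrix,
    HIGHER_IN_NONRESPONDER,
    HIGHER_IN_RESPONDER,
    SampleAnnotation,
)
from .errors import ValidationError
from .io import DatasetRecord, write_clinical, write_expression, write_manifest

OUTCOME_MODES = ("recist_only", "pfs_only", "os_only", "mixed")

#: drug assignment categories: the last one is anti-PD-1 + anti-CTLA-4 combination
_DRUG_CHOICES = (
    ("anti-PD-1",),
    ("anti-PD-L1",),
    ("anti-CTLA-4",),
    ("anti-PD-1", "anti-CTLA-4"),
)

_TUMOR_TYPES = ("melanoma", "urothelial", "gastric", "NSCLC", "HNSCC", "esophageal")


@dataclass(frozen=True)
class PlantedMarker:
    """A gene given a known class separation (target oriented AUC)."""

    gene: str
    target_auc: float
    direction: str = HIGHER_IN_NONRESPONDER

    def __post_init__(self) -> None:
        if not 0.5 < self.target_auc < 1.0:
            raise ValidationError("target_auc must be in (0.5, 1)")
        if self.direction not in (HIGHER_IN_NONRESPONDER, HIGHER_IN_RESPONDER):
            raise ValidationError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class DatasetConfig:
    """Shape of one synthetic dataset."""

    dataset_id: str
    n_samples: int
    platform_kind: str = "rnaseq_like"  # or "panel_like"
    gene_subset_fraction: float = 1.0
    scale_factor: float = 1.0
    distortion_exponent: float = 1.0
    responder_fraction: float = 0.35
    outcome_mode: str = "recist_only"
    censoring_fraction: float = 0.15
    drug_class_probs: tuple[float, float, float, float] = (0.60, 0.25, 0.10, 0.05)
    timing_pre_fraction: float = 0.85
    balanced_labels: bool = False

    def __post_init__(self) -> None:
        if self.platform_kind not in ("rnaseq_like", "panel_like"):
            raise ValidationError(f"bad platform_kind {self.platform_kind!r}")
        if self.outcome_mode not in OUTCOME_MODES:
            raise ValidationError(f"bad outcome_mode {self.outcome_mode!r}")
        if not 0 < self.gene_subset_fraction <= 1:
            raise ValidationError("gene_subset_fraction must be in (0, 1]")
        if not 0 < self.responder_fraction < 1:
            raise ValidationError("responder_fraction must be in (0, 1)")
        if not 0 <= self.censoring_fraction < 1:
            raise ValidationError("censoring_fraction must be in [0, 1)")
        if abs(sum(self.drug_class_probs) - 1.0) > 1e-9:
            raise ValidationError("drug_class_probs must sum to 1")


@dataclass
class SyntheticConfig:
    """Full generator configuration; defaults emulate a pooled ICI study at desk scale."""

    seed: int = 0
    n_genes: int = 500
    datasets: list[DatasetConfig] = field(default_factory=list)
    planted_markers: list[PlantedMarker] = field(default_factory=list)
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.2
    noise_log_sd: float = 1.0


def default_config(seed: int = 0) -> SyntheticConfig:
    """Six mixed-platform datasets (~280 samples) with five planted markers."""
    datasets = [
        DatasetConfig("SYN-RNA-A", 70, outcome_mode="mixed",
                      scale_factor=1.0, distortion_exponent=1.0),
        DatasetConfig("SYN-RNA-B", 60, outcome_mode="recist_only",
                      scale_factor=4.0, distortion_exponent=1.2),
        DatasetConfig("SYN-RNA-C", 45, outcome_mode="pfs_only",
                      scale_factor=0.5, distortion_exponent=0.9),
        DatasetConfig("SYN-OS-D", 25, outcome_mode="os_only",
                      scale_factor=2.0, distortion_exponent=1.1,
                      drug_class_probs=(0.0, 0.0, 0.9, 0.1)),
        DatasetConfig("SYN-PANEL-E", 50, platform_kind="panel_like",
                      gene_subset_fraction=0.4, scale_factor=30.0,
                      outcome_mode="recist_only"),
        DatasetConfig("SYN-PANEL-F", 30, platform_kind="panel_like",
                      gene_subset_fraction=0.3, scale_factor=20.0,
                      distortion_exponent=1.15, outcome_mode="mixed"),
    ]
    markers = [
        PlantedMarker("RESIST1", 0.80, HIGHER_IN_NONRESPONDER),
        PlantedMarker("RESIST2", 0.70, HIGHER_IN_NONRESPONDER),
        PlantedMarker("RESIST3", 0.65, HIGHER_IN_NONRESPONDER),
        PlantedMarker("SENS1", 0.75, HIGHER_IN_RESPONDER),
        PlantedMarker("SENS2", 0.68, HIGHER_IN_RESPONDER),
    ]
    return SyntheticConfig(seed=seed, n_genes=500, datasets=datasets,
                           planted_markers=markers)


@dataclass
class TruthTable:
    """Generator bookkeeping: true labels, arm memberships, planted effects."""

    samples: pd.DataFrame  # sample_id, dataset_id, true_label, drug_classes, timing, outcome_mode
    markers: pd.DataFrame  # gene, target_auc, direction


@dataclass
class SyntheticDatabase:
    matrices: list[ExpressionMatrix]
    annotations: list[SampleAnnotation]
    truth: TruthTable
    config: SyntheticConfig


def binormal_shift(target_auc: float) -> float:
    """Log-scale class-mean shift realizing ``target_auc`` under unit noise."""
    return float(np.sqrt(2.0) * scipy.stats.norm.ppf(target_auc))


def _draw_labels(rng: np.random.Generator, ds: DatasetConfig) -> np.ndarray:
    n = ds.n_samples
    if ds.balanced_labels:
        n_resp = int(round(ds.responder_fraction * n))
        labels = np.array([RESPONDER] * n_resp + [NON_RESPONDER] * (n - n_resp),
                          dtype=object)
        rng.shuffle(labels)
    else:
        labels = np.where(rng.random(n) < ds.responder_fraction,
                          RESPONDER, NON_RESPONDER).astype(object)
    return labels


def _outcome_modes(rng: np.random.Generator, ds: DatasetConfig) -> np.ndarray:
    n = ds.n_samples
    if ds.outcome_mode == "mixed":
        return rng.choice(["recist", "pfs", "both"], size=n, p=[0.4, 0.3, 0.3])
    return np.repeat({"recist_only": "recist", "pfs_only": "pfs",
                      "os_only": "os"}[ds.outcome_mode], n)


def simulate_database(cfg: SyntheticConfig) -> SyntheticDatabase:
    """Generate expression matrices, clinical records and the truth table.

    Reproducible: the same config (seed included) yields identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    planted = {m.gene: m for m in cfg.planted_markers}
    if len(planted) != len(cfg.planted_markers):
        raise ValidationError("duplicated planted marker gene")
    n_null = cfg.n_genes - len(planted)
    if n_null < 0:
        raise ValidationError("n_genes smaller than the number of planted markers")
    genes = list(planted) + [f"GENE{i:05d}" for i in range(1, n_null + 1)]
    gene_index = pd.Index(genes, name="gene_id")
    mu = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)

    matrices: list[ExpressionMatrix] = []
    annotations: list[SampleAnnotation] = []
    truth_rows: list[dict] = []
    marker_seen: dict[str, bool] = {g: False for g in planted}

    for ds in cfg.datasets:
        n = ds.n_samples
        sample_ids = [f"{ds.dataset_id}-S{i:03d}" for i in range(1, n + 1)]
        labels = _draw_labels(rng, ds)
        modes = _outcome_modes(rng, ds)
        # survival-only samples may be censored before the cutoff -> unevaluable
        censor = rng.random(n) < ds.censoring_fraction
        for i in range(n):
            if modes[i] in ("pfs", "os") and censor[i]:
                labels[i] = UNEVALUABLE

        drug_idx = rng.choice(len(_DRUG_CHOICES), size=n, p=ds.drug_class_probs)
        timing = np.where(rng.random(n) < ds.timing_pre_fraction,
                          "pre-treatment", "on-treatment")
        tumor = rng.choice(_TUMOR_TYPES, size=n)

        # expression on the log scale, then planted shifts, then distortion
        log_vals = mu[:, None] + rng.standard_normal((cfg.n_genes, n)) * cfg.noise_log_sd
        for gi, g in enumerate(genes):
            marker = planted.get(g)
            if marker is None:
                continue
            delta = binormal_shift(marker.target_auc) * cfg.noise_log_sd
            shifted = NON_RESPONDER if marker.direction == HIGHER_IN_NONRESPONDER else RESPONDER
            log_vals[gi, labels == shifted] += delta
        vals = np.exp(log_vals)
        vals = ds.scale_factor * vals ** ds.distortion_exponent

        if ds.platform_kind == "panel_like":
            k = max(1, int(round(ds.gene_subset_fraction * cfg.n_genes)))
            subset = np.sort(rng.choice(cfg.n_genes, size=k, replace=False))
            vals = np.rint(vals[subset])
            index = gene_index[subset]
            platform = "NanoString-like panel"
        else:
            index = gene_index
            platform = "RNA-Seq-like"
        for g in index:
            if g in marker_seen:
                marker_seen[g] = True

        matrices.append(
            ExpressionMatrix(
                dataset_id=ds.dataset_id,
                values=pd.DataFrame(vals, index=index, columns=sample_ids),
                platform=platform,
            )
        )

        for i in range(n):
            lab = labels[i]
            mode = modes[i]
            recist = None
            pfs = pfs_event = osm = os_event = None
            if mode in ("recist", "both"):
                if lab == RESPONDER:
                    recist = str(rng.choice(["CR", "PR"], p=[0.25, 0.75]))
                else:
                    recist = str(rng.choice(["SD", "PD"], p=[0.4, 0.6]))
            if mode in ("pfs", "both", "os"):
                if lab == RESPONDER:
                    months = 12.0 + float(rng.exponential(10.0)) + 0.1
                    event = int(rng.integers(0, 2))
                elif lab == NON_RESPONDER:
                    months = float(rng.uniform(0.5, 11.5))
                    event = 1
                else:  # unevaluable: censored before the cutoff
                    months = float(rng.uniform(0.5, 11.5))
                    event = 0
                if mode == "os":
                    osm, os_event = months, event
                else:
                    pfs, pfs_event = months, event
            annotations.append(
                SampleAnnotation(
                    sample_id=sample_ids[i],
                    dataset_id=ds.dataset_id,
                    patient_id=f"{ds.dataset_id}-P{i:03d}",
                    tumor_type=str(tumor[i]),
                    drug_classes=_DRUG_CHOICES[drug_idx[i]],
                    timing=str(timing[i]),
                    recist=recist,
                    pfs_months=pfs,
                    pfs_event=pfs_event,
                    os_months=osm,
                    os_event=os_event,
                )
            )
            truth_rows.append(
                {
                    "sample_id": sample_ids[i],
                    "dataset_id": ds.dataset_id,
                    "true_label": lab,
                    "drug_classes": ";".join(_DRUG_CHOICES[drug_idx[i]]),
                    "timing": str(timing[i]),
                    "outcome_mode": mode,
                }
            )

    absent = [g for g, seen in marker_seen.items() if not seen]
    if absent:
        raise ValidationError(
            f"planted marker(s) {absent} ended up on no dataset's platform"
        )
    truth = TruthTable(
        samples=pd.DataFrame(truth_rows),
        markers=pd.DataFrame(
            [
                {"gene": m.gene, "target_auc": m.target_auc, "direction": m.direction}
                for m in cfg.planted_markers
            ]
        ),
    )
    return SyntheticDatabase(matrices, annotations, truth, cfg)


def undistorted(cfg: SyntheticConfig) -> SyntheticConfig:
    """The same study with all platform distortions switched off.

    Shares the random stream with ``cfg`` (distortion is applied after all
    random draws), so paired runs are sample-for-sample comparable.
    """
    datasets = [
        replace(ds, scale_factor=1.0, distortion_exponent=1.0,
                platform_kind="rnaseq_like", gene_subset_fraction=1.0)
        for ds in cfg.datasets
    ]
    return replace(cfg, datasets=datasets)


def write_database(db: SyntheticDatabase, out_dir) -> Path:
    """Write TSVs + manifest + truth tables; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for m in db.matrices:
        expr = f"{m.dataset_id}.expression.tsv"
        write_expression(m, out / expr)
        records.append(
            DatasetRecord(
                dataset_id=m.dataset_id,
                expression_path=expr,
                clinical_path="clinical.tsv",
                platform=m.platform,
            )
        )
    write_clinical(db.annotations, out / "clinical.tsv")
    manifest = out / "manifest.yaml"
    write_manifest(records, manifest)
    db.truth.samples.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
    db.truth.markers.to_csv(out / "truth_markers.tsv", sep="\t", index=False)
    return manifest


def simulate_worked_example() -> SyntheticDatabase:
    """Tiny fixed two-dataset fixture (6 genes x 12 samples), hand-checkable.

    ``RES1`` separates non-responders from responders completely (oriented
    AUC 1.0), ``SEN1`` is higher in responders (oriented AUC 0.88), ``NULL1``
    is constant (AUC 0.5, p = 1).  Sample WX1-S05 received combination
    anti-PD-1 + anti-CTLA-4 therapy, WX1-S04 is censored at 8 months
    (unevaluable) and WX1-S08 is an on-treatment biopsy.
    """
    ds1_samples = [f"WX1-S{i:02d}" for i in range(1, 9)]
    ds2_samples = [f"WX2-S{i:02d}" for i in range(9, 13)]
    ds1 = pd.DataFrame(
        {
            "RES1":   [1, 2, 3, 6, 10, 11, 12, 7],
            "SEN1":   [20, 22, 21, 10, 5, 6, 7, 11],
            "NULL1":  [7, 7, 7, 7, 7, 7, 7, 7],
            "HOUSE1": [100, 101, 99, 100, 98, 102, 100, 101],
            "VAR1":   [3, 14, 8, 2, 9, 5, 11, 6],
            "EXTRA1": [50, 60, 55, 52, 58, 61, 57, 53],
        },
        index=ds1_samples,
    ).T
    ds2 = pd.DataFrame(
        {
            "RES1":   [4, 5, 13, 14],
            "SEN1":   [25, 24, 8, 23],
            "NULL1":  [7, 7, 7, 7],
            "HOUSE1": [99, 100, 101, 100],
            "VAR1":   [7, 12, 4, 10],
        },
        index=ds2_samples,
    ).T
    matrices = [
        ExpressionMatrix("WX1", ds1, platform="RNA-Seq-like"),
        ExpressionMatrix("WX2", ds2, platform="NanoString-like panel"),
    ]
    pd1 = ("anti-PD-1",)
    combo = ("anti-PD-1", "anti-CTLA-4")
    ann = [
        SampleAnnotation("WX1-S01", "WX1", "P01", "melanoma", pd1, "pre-treatment", recist="CR"),
        SampleAnnotation("WX1-S02", "WX1", "P02", "melanoma", pd1, "pre-treatment", recist="PR"),
        SampleAnnotation("WX1-S03", "WX1", "P03", "gastric", pd1, "pre-treatment",
                         pfs_months=20.0, pfs_event=0),
        SampleAnnotation("WX1-S04", "WX1", "P04", "gastric", pd1, "pre-treatment",
                         pfs_months=8.0, pfs_event=0),
        SampleAnnotation("WX1-S05", "WX1", "P05", "melanoma", combo, "pre-treatment", recist="PD"),
        SampleAnnotation("WX1-S06", "WX1", "P06", "urothelial", pd1, "pre-treatment", recist="SD"),
        SampleAnnotation("WX1-S07", "WX1", "P07", "urothelial", pd1, "pre-treatment",
                         pfs_months=6.0, pfs_event=1),
        SampleAnnotation("WX1-S08", "WX1", "P01", "melanoma", pd1, "on-treatment", recist="PR"),
        SampleAnnotation("WX2-S09", "WX2", "P09", "NSCLC", pd1, "pre-treatment", recist="CR"),
        SampleAnnotation("WX2-S10", "WX2", "P10", "NSCLC", pd1, "pre-treatment",
                         pfs_months=15.0, pfs_event=1),
        SampleAnnotation("WX2-S11", "WX2", "P11", "melanoma", pd1, "pre-treatment", recist="PD"),
        SampleAnnotation("WX2-S12", "WX2", "P12", "melanoma", pd1, "pre-treatment",
                         pfs_months=4.0, pfs_event=1),
    ]
    truth_rows = []
    true_labels = {
        "WX1-S01": RESPONDER, "WX1-S02": RESPONDER, "WX1-S03": RESPONDER,
        "WX1-S04": UNEVALUABLE, "WX1-S05": NON_RESPONDER, "WX1-S06": NON_RESPONDER,
        "WX1-S07": NON_RESPONDER, "WX1-S08": RESPONDER,
        "WX2-S09": RESPONDER, "WX2-S10": RESPONDER,
        "WX2-S11": NON_RESPONDER, "WX2-S12": NON_RESPONDER,
    }
    for a in ann:
        truth_rows.append(
            {
                "sample_id": a.sample_id,
                "dataset_id": a.dataset_id,
                "true_label": true_labels[a.sample_id],
                "drug_classes": ";".join(a.drug_classes),
                "timing": a.timing,
                "outcome_mode": "recist" if a.recist else "pfs",
            }
        )
    truth = TruthTable(
        samples=pd.DataFrame(truth_rows),
        markers=pd.DataFrame(
            [
                {"gene": "RES1", "target_auc": 1.0, "direction": HIGHER_IN_NONRESPONDER},
                {"gene": "SEN1", "target_auc": 0.88, "direction": HIGHER_IN_RESPONDER},
            ]
        ),
    )
    cfg = SyntheticConfig(seed=0, n_genes=6, datasets=[], planted_markers=[])
    return SyntheticDatabase(matrices, ann, truth, cfg)
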