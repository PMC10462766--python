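"""Readers and writers for the on-disk formats.

All tables are plain UTF-8 TSV.  Expression files have gene symbols in the
first column and sample identifiers in the header; empty cells are missing
values.  Clinical tables use the documented column names (unknown columns are
ignored).  The dataset manifest is YAML (JSON is a YAML subset and parses
too).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .datatypes import ExpressionMatrix, GeneResult, SampleAnnotation
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

CLINICAL_REQUIRED = (
    "sample_id",
    "dataset_id",
    "patient_id",
    "tumor_type",
    "drug_classes",
    "timing",
)
CLINICAL_OPTIONAL = ("recist", "pfs_months", "pfs_event", "os_months", "os_event")

_DRUG_ALIASES = {
    "anti-pd-1": "anti-PD-1",
    "anti-pd1": "anti-PD-1",
    "anti-pd-l1": "anti-PD-L1",
    "anti-pdl1": "anti-PD-L1",
    "anti-ctla-4": "anti-CTLA-4",
    "anti-ctla4": "anti-CTLA-4",
}
_TIMING_ALIASES = {
    "pre-treatment": "pre-treatment",
    "pretreatment": "pre-treatment",
    "pre": "pre-treatment",
    "on-treatment": "on-treatment",
    "ontreatment": "on-treatment",
    "on": "on-treatment",
}

RESULT_COLUMNS = (
    "gene",
    "n_responder",
    "n_nonresponder",
    "u_statistic",
    "auc",
    "direction",
    "p_raw",
    "fold_change",
    "significant",
)


def read_expression(path, dataset_id: str, platform: str = "") -> ExpressionMatrix:
    """Read one dataset's genes x samples TSV into an :class:`ExpressionMatrix`.

    Duplicated gene rows are collapsed by the per-sample maximum (a warning is
    logged); a negative value raises :class:`ValidationError` naming the gene
    and sample.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2 or any(h == "" for h in header[1:]):
        raise FormatError(
            f"{path}: expected a tab-separated header 'gene_id<TAB>sample...'"
        )
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicated sample identifiers in header")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    try:
        df = df.apply(pd.to_numeric)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from None
    # keep original names (read_csv mangles nothing here: header checked above)
    df.columns = samples
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        logger.warning(
            "%s: collapsing %d duplicated gene row(s) by per-sample max (e.g. %s)",
            path,
            len(dupes),
            dupes[:5],
        )
        df = df.groupby(level=0, sort=False).max()
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return ExpressionMatrix(dataset_id=dataset_id, values=df, platform=platform)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write an :class:`ExpressionMatrix` back to the TSV dialect."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def _parse_drug_classes(cell: str, sample_id: str) -> tuple[str, ...]:
    parts = [p.strip() for p in str(cell).split(";") if p.strip()]
    classes = []
    for p in parts:
        canon = _DRUG_ALIASES.get(p.lower())
        if canon is None:
            raise ValidationError(
                f"sample {sample_id!r}: unknown drug class {p!r}"
            )
        classes.append(canon)
    return tuple(classes)


def _opt_float(cell) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    if not s:
        return None
    return float(s)


def read_clinical(path) -> list[SampleAnnotation]:
    """Read a clinical TSV into validated :class:`SampleAnnotation` records."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        recist = row.get("recist")
        recist = None if recist is None or not str(recist).strip() or pd.isna(recist) else str(recist).strip().upper()
        timing_raw = str(row["timing"]).strip().lower()
        timing = _TIMING_ALIASES.get(timing_raw)
        if timing is None:
            raise ValidationError(f"sample {sid!r}: unknown timing {row['timing']!r}")
        pfs_event = _opt_float(row.get("pfs_event"))
        os_event = _opt_float(row.get("os_event"))
        records.append(
            SampleAnnotation(
                sample_id=sid,
                dataset_id=str(row["dataset_id"]).strip(),
                patient_id=str(row["patient_id"]).strip(),
                tumor_type=str(row["tumor_type"]).strip(),
                drug_classes=_parse_drug_classes(row["drug_classes"], sid),
                timing=timing,
                recist=recist,
                pfs_months=_opt_float(row.get("pfs_months")),
                pfs_event=None if pfs_event is None else int(pfs_event),
                os_months=_opt_float(row.get("os_months")),
                os_event=None if os_event is None else int(os_event),
            )
        )
    dupes = pd.Index([r.sample_id for r in records])
    if dupes.has_duplicates:
        raise ValidationError(
            f"{path}: duplicated sample_id(s) "
            f"{sorted(set(dupes[dupes.duplicated()]))[:5]}"
        )
    return records


def write_clinical(annotations: list[SampleAnnotation], path) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "sample_id": a.sample_id,
                "dataset_id": a.dataset_id,
                "patient_id": a.patient_id,
                "tumor_type": a.tumor_type,
                "drug_classes": ";".join(a.drug_classes),
                "timing": a.timing,
                "recist": a.recist or "",
                "pfs_months": "" if a.pfs_months is None else f"{a.pfs_months:.6g}",
                "pfs_event": "" if a.pfs_event is None else str(a.pfs_event),
                "os_months": "" if a.os_months is None else f"{a.os_months:.6g}",
                "os_event": "" if a.os_event is None else str(a.os_event),
            }
        )
    pd.DataFrame(rows, columns=CLINICAL_REQUIRED + CLINICAL_OPTIONAL).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class DatasetRecord:
    """One manifest entry pointing at a dataset's expression + clinical files."""

    dataset_id: str
    expression_path: str
    clinical_path: str
    platform: str = ""
    include: bool = True
    exclusion_reason: str | None = None


def read_manifest(path) -> list[DatasetRecord]:
    """Read a YAML/JSON manifest; paths are resolved relative to the manifest."""
    path = Path(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if isinstance(data, dict):
        data = data.get("datasets", data)
    if not isinstance(data, list):
        raise FormatError(f"{path}: manifest must be a list of dataset records")
    base = path.parent
    records = []
    for entry in data:
        try:
            rec = DatasetRecord(**entry)
        except TypeError as exc:
            raise FormatError(f"{path}: bad manifest record {entry!r} ({exc})") from None
        rec.expression_path = str((base / rec.expression_path).resolve())
        rec.clinical_path = str((base / rec.clinical_path).resolve())
        records.append(rec)
    ids = [r.dataset_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicated dataset_id in manifest")
    for rec in records:
        if not rec.include:
            continue
        for p in (rec.expression_path, rec.clinical_path):
            if not Path(p).is_file():
                raise ValidationError(
                    f"manifest dataset {rec.dataset_id!r}: missing file {p}"
                )
    return records


def write_manifest(records: list[DatasetRecord], path) -> None:
    entries = []
    for r in records:
        entry = {
            "dataset_id": r.dataset_id,
            "expression_path": r.expression_path,
            "clinical_path": r.clinical_path,
            "platform": r.platform,
            "include": r.include,
        }
        if r.exclusion_reason:
            entry["exclusion_reason"] = r.exclusion_reason
        entries.append(entry)
    Path(path).write_text(yaml.safe_dump(entries, sort_keys=False), encoding="utf-8")


def write_results(results: list[GeneResult], metadata: dict, path) -> None:
    """Write screen results as TSV sorted by raw P ascending.

    Metadata (cohort, number of genes tested, alpha, threshold, ...) goes into
    ``# key: value`` header lines so the file is self-describing.
    """
    if not results:
        raise ValidationError("refusing to write an empty result table")
    ordered = sorted(results, key=lambda r: (r.p_raw, r.gene))
    rows = []
    has_drug = any(r.druggable is not None for r in ordered)
    for r in ordered:
        row = {c: getattr(r, c) for c in RESULT_COLUMNS}
        if has_drug:
            row["druggable"] = bool(r.druggable)
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in metadata.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_results(path) -> tuple[dict, pd.DataFrame]:
    """Read a result table; returns (metadata, DataFrame)."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    return meta, df


@dataclass
class CombinedMeta:
    sample_datasets: pd.Series
    normalization_state: str = "raw"


def combined_meta_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.tsv")


def write_combined(values: pd.DataFrame, sample_datasets: pd.Series,
                   normalization_state: str, path) -> None:
    """Write a combined matrix plus its sample->dataset sidecar table."""
    out = values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
    meta = pd.DataFrame(
        {"sample_id": sample_datasets.index, "dataset_id": sample_datasets.values}
    )
    with open(combined_meta_path(path), "w", encoding="utf-8") as fh:
        fh.write(f"# normalization_state: {normalization_state}\n")
        meta.to_csv(fh, sep="\t", index=False)


def read_combined(path):
    """Read a combined matrix written by :func:`write_combined`.

    Returns ``(values, sample_datasets, normalization_state)``.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = combined_meta_path(path)
    state = "raw"
    with open(meta_path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            state = first.partition(":")[2].strip()
    meta = pd.read_csv(meta_path, sep="\t", comment="#")
    sample_datasets = pd.Series(
        meta["dataset_id"].values, index=meta["sample_id"].astype(str)
    )
    return values, sample_datasets, state
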