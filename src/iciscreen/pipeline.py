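"""End-to-end composition: manifest -> harmonize -> label -> cohort -> screen."""
from __future__ import annotations

import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

from .cohorts import CohortSpec, build_cohort, standard_cohorts
from .errors import IciScreenError
from .harmonize import harmonize
from .io import read_clinical, read_expression, read_manifest, write_combined, write_results
from .labeling import LabelConfig, label_cohort
from .plotting import PlotRequest, plot_gene
from .screen import ScreenResult, annotate_druggable, screen_cohort

logger = logging.getLogger(__name__)


def _package_version() -> str:
    try:
        return version("iciscreen")
    except PackageNotFoundError:
        return "unknown"


def load_database(manifest_path):
    """Read every included dataset of a manifest.

    Returns ``(matrices, annotations)``; clinical files shared between
    datasets are read once and rows are matched by ``dataset_id``.
    """
    records = [r for r in read_manifest(manifest_path) if r.include]
    if not records:
        raise IciScreenError(f"manifest {manifest_path} includes no dataset")
    matrices = [
        read_expression(r.expression_path, r.dataset_id, r.platform) for r in records
    ]
    included = {r.dataset_id for r in records}
    annotations = []
    seen_samples = set()
    for path in dict.fromkeys(r.clinical_path for r in records):
        for a in read_clinical(path):
            if a.dataset_id in included and a.sample_id not in seen_samples:
                annotations.append(a)
                seen_samples.add(a.sample_id)
    return matrices, annotations


def run_pipeline(
    manifest_path,
    out_dir,
    spec: CohortSpec,
    label_cfg: LabelConfig = LabelConfig(),
    alpha: float = 0.05,
    min_class_size: int | None = None,
    target: float | None = 1000.0,
    gene_filter=None,
    druggable=None,
    plot_genes: list[str] | None = None,
    plot_format: str = "png",
) -> ScreenResult:
    """Run the full screen for one cohort and write results (and plots).

    Deterministic: identical inputs produce byte-identical result tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("iciscreen")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        logger.info("iciscreen version %s", _package_version())
        matrices, annotations = load_database(manifest_path)
        logger.info(
            "loaded %d dataset(s), %d samples, %d clinical records",
            len(matrices), sum(m.n_samples for m in matrices), len(annotations),
        )
        combined = harmonize(matrices, target=target)
        write_combined(
            combined.values, combined.sample_datasets,
            combined.normalization_state, out / "combined.tsv",
        )
        labels, summary = label_cohort(annotations, label_cfg)
        logger.info("label summary: %s", summary)
        _, cohort_summary = standard_cohorts(combined, annotations, labels)
        logger.info("cohort sizes:\n%s", cohort_summary.to_string(index=False))
        cohort = build_cohort(combined, annotations, labels, spec)
        screen = screen_cohort(
            cohort, alpha=alpha, min_class_size=min_class_size, gene_filter=gene_filter
        )
        logger.info(
            "screen %s: m_tested=%d threshold=%.6e (display %s), %d significant",
            spec.describe(), screen.m_tested, screen.threshold,
            screen.threshold_display, len(screen.significant),
        )
        if druggable is not None:
            hits = annotate_druggable(screen, druggable)
            logger.info(
                "druggable resistance hits: %s", [r.gene for r in hits]
            )
        write_results(screen.results, screen.metadata(), out / "results.tsv")
        for gene in plot_genes or []:
            plot_gene(cohort, gene, PlotRequest(gene, str(out / "plots"), plot_format))
        return screen
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
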