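"""Stratification of the labeled database into drug-class x timing cohorts.

Six canonical cohorts exist (three drug classes, pre-/on-treatment biopsy).
A combination-therapy sample belongs to every arm matching one of its drug
classes, so arm sizes can sum to more than the number of distinct samples;
``overlap_adjusted_total`` expresses the bookkeeping identity relating the
two.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import (
    DRUG_CLASSES,
    NON_RESPONDER,
    RESPONDER,
    TIMINGS,
    SampleAnnotation,
)
from .errors import DegenerateCohortError, ValidationError
from .harmonize import CombinedMatrix
from .labeling import ResponseLabel


@dataclass(frozen=True)
class CohortSpec:
    """Which samples enter a screen: one drug class, one biopsy timing."""

    drug_class: str
    timing: str = "pre-treatment"
    tumor_types: tuple[str, ...] | None = None
    min_class_size: int = 3

    def __post_init__(self) -> None:
        if self.drug_class not in DRUG_CLASSES:
            raise ValidationError(f"unknown drug class {self.drug_class!r}")
        if self.timing not in TIMINGS:
            raise ValidationError(f"unknown timing {self.timing!r}")
        if self.min_class_size < 2:
            raise ValidationError("min_class_size must be >= 2")

    def describe(self) -> str:
        return f"{self.timing} {self.drug_class}"


@dataclass
class Cohort:
    """Analysis-ready cohort: expression restriction + binary labels only."""

    spec: CohortSpec
    values: pd.DataFrame  # genes x cohort samples
    y: pd.Series  # sample_id -> responder / non_responder
    n_responder: int
    n_nonresponder: int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def build_cohort(
    m: CombinedMatrix,
    annotations: list[SampleAnnotation],
    labels: list[ResponseLabel],
    spec: CohortSpec,
) -> Cohort:
    """Select the samples matching ``spec`` with an evaluable response label.

    Raises :class:`DegenerateCohortError` when either class is empty.
    """
    ann_by_id = {a.sample_id: a for a in annotations}
    lab_by_id = {l.sample_id: l.label for l in labels}
    selected = []
    for s in m.sample_ids:
        a = ann_by_id.get(s)
        if a is None:
            continue
        if spec.drug_class not in a.drug_classes or a.timing != spec.timing:
            continue
        if spec.tumor_types is not None and a.tumor_type not in spec.tumor_types:
            continue
        if lab_by_id.get(s) not in (RESPONDER, NON_RESPONDER):
            continue
        selected.append(s)
    y = pd.Series({s: lab_by_id[s] for s in selected}, dtype=object)
    n_r = int((y == RESPONDER).sum())
    n_nr = int((y == NON_RESPONDER).sum())
    if n_r == 0 or n_nr == 0:
        raise DegenerateCohortError(
            f"cohort {spec.describe()!r} is degenerate: "
            f"{n_r} responder(s), {n_nr} non-responder(s)"
        )
    return Cohort(spec, m.values[selected], y, n_r, n_nr)


def standard_cohorts(
    m: CombinedMatrix,
    annotations: list[SampleAnnotation],
    labels: list[ResponseLabel],
    min_class_size: int = 3,
) -> tuple[dict[tuple[str, str], Cohort | None], pd.DataFrame]:
    """Build the six canonical drug-class x timing cohorts.

    Degenerate cohorts are reported in the summary table (not raised); the
    returned mapping holds ``None`` for them.
    """
    cohorts: dict[tuple[str, str], Cohort | None] = {}
    rows = []
    for drug in DRUG_CLASSES:
        for timing in TIMINGS:
            spec = CohortSpec(drug, timing, min_class_size=min_class_size)
            try:
                c = build_cohort(m, annotations, labels, spec)
                rows.append(
                    {
                        "drug_class": drug,
                        "timing": timing,
                        "n_responder": c.n_responder,
                        "n_nonresponder": c.n_nonresponder,
                        "n_total": c.n_responder + c.n_nonresponder,
                        "degenerate": False,
                    }
                )
            except DegenerateCohortError:
                c = None
                rows.append(
                    {
                        "drug_class": drug,
                        "timing": timing,
                        "n_responder": 0,
                        "n_nonresponder": 0,
                        "n_total": 0,
                        "degenerate": True,
                    }
                )
            cohorts[(drug, timing)] = c
    return cohorts, pd.DataFrame(rows)


def overlap_adjusted_total(arm_sizes, n_shared: int) -> int:
    """Distinct-sample total implied by per-arm sizes and multi-arm overlaps.

    Each sample assigned to ``k`` arms contributes ``k`` to the summed arm
    sizes but only once to the database, so the distinct total is the arm-size
    sum minus the number of extra memberships.
    """
    total = int(sum(arm_sizes)) - int(n_shared)
    if total < 0:
        raise ValidationError("overlaps exceed summed arm sizes")
    return total


def arm_membership_summary(
    annotations: list[SampleAnnotation], labels: list[ResponseLabel]
) -> dict:
    """Per-arm labeled sample counts and the sum-rule bookkeeping.

    Counts every labeled (responder or non-responder) sample once per drug
    class it received, mirroring how combination-therapy samples enter every
    matching screening arm.
    """
    lab_by_id = {l.sample_id: l.label for l in labels}
    arm_sizes = {d: 0 for d in DRUG_CLASSES}
    extra_memberships = 0
    n_distinct = 0
    for a in annotations:
        if lab_by_id.get(a.sample_id) not in (RESPONDER, NON_RESPONDER):
            continue
        n_distinct += 1
        for d in a.drug_classes:
            arm_sizes[d] += 1
        extra_memberships += len(a.drug_classes) - 1
    return {
        "arm_sizes": arm_sizes,
        "extra_memberships": extra_memberships,
        "n_distinct_labeled": n_distinct,
        "overlap_adjusted_total": overlap_adjusted_total(
            arm_sizes.values(), extra_memberships
        ),
    }
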