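"""Core data containers shared across the pipeline.

An :class:`ExpressionMatrix` is one study's genes x samples table (missing
entries mean "gene not on this platform", never zero expression).  A
:class:`SampleAnnotation` carries the clinical record needed to dichotomize a
patient into responder / non-responder, and a :class:`GeneResult` is one row
of a screen: group sizes, Mann-Whitney U, oriented ROC AUC, raw P and fold
change.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The three immune-checkpoint inhibitor drug classes screened.
DRUG_CLASSES = ("anti-PD-1", "anti-PD-L1", "anti-CTLA-4")

#: Biopsy timing relative to therapy induction.
TIMINGS = ("pre-treatment", "on-treatment")

#: RECIST radiological response categories.
RECIST_CATEGORIES = ("CR", "PR", "SD", "PD")

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
UNEVALUABLE = "unevaluable"

HIGHER_IN_NONRESPONDER = "higher_in_nonresponder"
HIGHER_IN_RESPONDER = "higher_in_responder"
TIE = "tie"


def _first_negative(values: pd.DataFrame):
    neg = values < 0  # NaN compares False
    if not neg.to_numpy().any():
        return None
    gene = neg.index[neg.any(axis=1)][0]
    sample = neg.columns[neg.loc[gene]][0]
    return gene, sample


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression table for one dataset.

    Parameters
    ----------
    dataset_id :
        Identifier of the originating study (e.g. a GEO accession).
    values :
        DataFrame indexed by gene symbol with sample identifiers as columns.
        ``NaN`` marks a gene absent from the platform.
    platform :
        Free-text platform label (e.g. "RNA-Seq", "NanoString").
    """

    dataset_id: str
    values: pd.DataFrame
    platform: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = sorted(set(v.index[v.index.duplicated()]))
            raise ValidationError(
                f"dataset {self.dataset_id!r}: duplicated gene ids {dupes[:5]}"
            )
        if v.columns.has_duplicates:
            dupes = sorted(set(v.columns[v.columns.duplicated()]))
            raise ValidationError(
                f"dataset {self.dataset_id!r}: duplicated sample ids {dupes[:5]}"
            )
        try:
            v = v.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"dataset {self.dataset_id!r}: non-numeric expression value ({exc})"
            ) from None
        hit = _first_negative(v)
        if hit is not None:
            raise ValidationError(
                f"dataset {self.dataset_id!r}: negative expression value for "
                f"gene {hit[0]!r}, sample {hit[1]!r}"
            )
        arr = v.to_numpy()
        empty = np.isnan(arr).all(axis=0)
        if empty.any():
            sample = v.columns[empty][0]
            raise ValidationError(
                f"dataset {self.dataset_id!r}: sample {sample!r} has no "
                "non-missing values"
            )
        self.values = v

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SampleAnnotation:
    """Clinical record for one tumor sample.

    ``drug_classes`` is a non-empty subset of :data:`DRUG_CLASSES`; more than
    one entry models combination therapy.  Survival times are in months, with
    the paired event flag (1 = progression/death observed, 0 = censored)
    mandatory whenever the time is present.
    """

    sample_id: str
    dataset_id: str
    patient_id: str
    tumor_type: str
    drug_classes: tuple[str, ...]
    timing: str
    recist: str | None = None
    pfs_months: float | None = None
    pfs_event: int | None = None
    os_months: float | None = None
    os_event: int | None = None

    def __post_init__(self) -> None:
        classes = tuple(self.drug_classes)
        if not classes:
            raise ValidationError(f"sample {self.sample_id!r}: empty drug_classes")
        for c in classes:
            if c not in DRUG_CLASSES:
                raise ValidationError(
                    f"sample {self.sample_id!r}: unknown drug class {c!r}"
                )
        if len(set(classes)) != len(classes):
            raise ValidationError(
                f"sample {self.sample_id!r}: repeated drug class in {classes}"
            )
        object.__setattr__(
            self, "drug_classes", tuple(sorted(classes, key=DRUG_CLASSES.index))
        )
        if self.timing not in TIMINGS:
            raise ValidationError(
                f"sample {self.sample_id!r}: timing must be one of {TIMINGS}, "
                f"got {self.timing!r}"
            )
        if self.recist is not None and self.recist not in RECIST_CATEGORIES:
            raise ValidationError(
                f"sample {self.sample_id!r}: invalid RECIST {self.recist!r}"
            )
        for name in ("pfs", "os"):
            months = getattr(self, f"{name}_months")
            event = getattr(self, f"{name}_event")
            if (months is None) != (event is None):
                raise ValidationError(
                    f"sample {self.sample_id!r}: {name}_months and {name}_event "
                    "must be present together"
                )
            if months is not None:
                if months < 0:
                    raise ValidationError(
                        f"sample {self.sample_id!r}: negative {name}_months"
                    )
                if event not in (0, 1):
                    raise ValidationError(
                        f"sample {self.sample_id!r}: {name}_event must be 0 or 1"
                    )


@dataclass
class GeneResult:
    """One gene's screen output.

    ``auc`` is oriented: it is ``max(raw, 1 - raw)`` of the raw AUC defined
    with non-responders as the positive class, so it is always >= 0.5 and the
    ``direction`` field says which class had stochastically larger expression.
    ``fold_change`` is the oriented ratio of class means (>= 1, ``inf`` when
    one class mean is exactly zero).
    """

    gene: str
    n_responder: int
    n_nonresponder: int
    u_statistic: float
    auc: float
    direction: str
    p_raw: float
    fold_change: float
    significant: bool
    druggable: bool | None = None
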