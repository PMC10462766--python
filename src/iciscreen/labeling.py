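"""Responder / non-responder dichotomization.

A patient is a responder on radiological grounds (RECIST complete or partial
response) or by surviving progression-free for longer than a cutoff (12
months by default); progressive/stable disease or progression within the
cutoff makes a non-responder.  A censored follow-up shorter than the cutoff
carries no information and leaves the sample unevaluable.  When no
progression endpoint exists, the same rule can optionally be applied to
overall survival (some cohorts report only OS).
"""
from __future__ import annotations

from dataclasses import dataclass

from .datatypes import (
    NON_RESPONDER,
    RESPONDER,
    UNEVALUABLE,
    SampleAnnotation,
)

BASIS_RECIST = "recist"
BASIS_PFS = "pfs_rule"
BASIS_OS = "os_rule"
BASIS_NONE = "none"

_RECIST_RESPONDER = {"CR", "PR"}
_RECIST_NONRESPONDER = {"SD", "PD"}


@dataclass(frozen=True)
class LabelConfig:
    """Tunable parameters of the dichotomization rule.

    survival_cutoff_months :
        Progression-free survival longer than this makes a responder
        (strict ">"); an event at or before it makes a non-responder.
    allow_os_fallback :
        Apply the same rule to overall survival when no progression endpoint
        is informative (needed for OS-only cohorts).
    recist_priority :
        Evaluate RECIST before the survival rule when both are present.
    """

    survival_cutoff_months: float = 12.0
    allow_os_fallback: bool = True
    recist_priority: bool = True

    def __post_init__(self) -> None:
        if self.survival_cutoff_months <= 0:
            raise ValueError("survival_cutoff_months must be positive")


@dataclass(frozen=True)
class ResponseLabel:
    sample_id: str
    label: str
    basis: str


def _recist_label(recist: str) -> str:
    return RESPONDER if recist in _RECIST_RESPONDER else NON_RESPONDER


def _survival_label(months: float, event: int, cutoff: float) -> str | None:
    """Apply the cutoff rule to one time-to-event endpoint.

    Returns None when the observation is uninformative (censored at or before
    the cutoff).
    """
    if months > cutoff:
        return RESPONDER
    if event == 1:
        return NON_RESPONDER
    return None


def label_response(a: SampleAnnotation, cfg: LabelConfig = LabelConfig()) -> ResponseLabel:
    """Dichotomize one sample; total on valid annotations, never raises."""
    cutoff = cfg.survival_cutoff_months
    if cfg.recist_priority and a.recist is not None:
        return ResponseLabel(a.sample_id, _recist_label(a.recist), BASIS_RECIST)
    if a.pfs_months is not None:
        lab = _survival_label(a.pfs_months, a.pfs_event, cutoff)
        if lab is not None:
            return ResponseLabel(a.sample_id, lab, BASIS_PFS)
    if cfg.allow_os_fallback and a.os_months is not None:
        lab = _survival_label(a.os_months, a.os_event, cutoff)
        if lab is not None:
            return ResponseLabel(a.sample_id, lab, BASIS_OS)
    if not cfg.recist_priority and a.recist is not None:
        return ResponseLabel(a.sample_id, _recist_label(a.recist), BASIS_RECIST)
    return ResponseLabel(a.sample_id, UNEVALUABLE, BASIS_NONE)


def label_cohort(
    annotations: list[SampleAnnotation], cfg: LabelConfig = LabelConfig()
) -> tuple[list[ResponseLabel], dict]:
    """Label every sample and summarize counts per label and per basis."""
    labels = [label_response(a, cfg) for a in annotations]
    summary = {
        RESPONDER: 0,
        NON_RESPONDER: 0,
        UNEVALUABLE: 0,
        "by_basis": {BASIS_RECIST: 0, BASIS_PFS: 0, BASIS_OS: 0, BASIS_NONE: 0},
    }
    for lab in labels:
        summary[lab.label] += 1
        summary["by_basis"][lab.basis] += 1
    return labels, summary
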