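"""Per-gene association screen: Mann-Whitney U, ROC AUC, fold change, Bonferroni.

The screen exploits the identity between the Mann-Whitney U statistic and the
empirical ROC AUC: with midranks for ties,

    U = AUC_raw * n_nr * n_r,

where the raw AUC is the probability that a randomly chosen non-responder
expresses the gene higher than a randomly chosen responder (ties counted
half).  Reported AUCs are oriented to max(raw, 1 - raw) with an explicit
direction, so resistance markers (higher in non-responders) and sensitivity
markers (higher in responders) both display as AUC > 0.5.  Family-wise error
across a screen of m tested genes is controlled by Bonferroni at
alpha / m.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator

from .cohorts import Cohort, CohortSpec
from .datatypes import (
    HIGHER_IN_NONRESPONDER,
    HIGHER_IN_RESPONDER,
    NON_RESPONDER,
    RESPONDER,
    TIE,
    GeneResult,
)
from .errors import ValidationError

__all__ = [
    "roc_auc",
    "mann_whitney",
    "fold_change",
    "bonferroni_threshold",
    "screen_cohort",
    "evaluate_panel",
    "rank_against",
    "annotate_druggable",
    "ScreenResult",
    "ResponseScreen",
]


def _check_group(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError(f"{name} group is empty")
    if not np.isfinite(v).all():
        raise ValidationError(f"{name} group contains non-finite values")
    return v


def roc_auc(nonresp, resp) -> float:
    """Raw ROC AUC: P(non-responder value > responder value), ties half-counted."""
    x = _check_group(nonresp, "non-responder")
    y = _check_group(resp, "responder")
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    u1 = ranks[: x.size].sum() - x.size * (x.size + 1) / 2
    return float(u1 / (x.size * y.size))


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of ``x`` against ``y``.

    Returns ``(U, p)`` with U the midrank statistic for ``x`` (so
    ``U = roc_auc(x, y) * n_x * n_y``).  The null distribution is enumerated
    exactly for tie-free samples with at most 8 observations per group;
    otherwise a tie-corrected normal approximation with continuity correction
    is used.  Constant pooled data give ``U = n_x n_y / 2`` and ``p = 1``.
    """
    x = _check_group(x, "x")
    y = _check_group(y, "y")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fold_change(nonresp, resp) -> tuple[float, str]:
    """Oriented ratio of class means: ``(fc >= 1, direction)``.

    Both class means must be positive (the normalized expression scale is
    non-negative; a zero mean leaves no meaningful ratio).
    """
    x = _check_group(nonresp, "non-responder")
    y = _check_group(resp, "responder")
    mean_nr = float(x.mean())
    mean_r = float(y.mean())
    if mean_nr <= 0 or mean_r <= 0:
        raise ValidationError("fold change needs positive class means")
    if mean_nr > mean_r:
        return mean_nr / mean_r, HIGHER_IN_NONRESPONDER
    if mean_r > mean_nr:
        return mean_r / mean_nr, HIGHER_IN_RESPONDER
    return 1.0, TIE


def _truncate_two_sig(x: float) -> str:
    """Floor to two significant digits, scientific notation (1.68e-6 -> '1.6E-06')."""
    exponent = math.floor(math.log10(x))
    mantissa = x / 10.0 ** exponent
    mantissa = math.floor(mantissa * 10 + 1e-12) / 10
    return f"{mantissa:.1f}E{exponent:+03d}"


def bonferroni_threshold(m: int, alpha: float = 0.05) -> tuple[float, str]:
    """Family-wise threshold ``alpha / m`` plus its two-significant-digit display.

    The display string is truncated (floored), matching the convention of
    printing 0.05 / 29755 = 1.68E-06 as "1.6E-06"; filtering always uses the
    exact value.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    exact = alpha / m
    return exact, _truncate_two_sig(exact)


# ---------------------------------------------------------------------------
# screen core


def _row_tie_term(row: np.ndarray) -> float:
    _, counts = np.unique(row, return_counts=True)
    c = counts[counts > 1].astype(float)
    return float((c ** 3 - c).sum())


def _mwu_asymptotic_batch(X: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tie-corrected normal-approximation Mann-Whitney.

    ``X`` is rows x pooled-samples with the first ``n1`` columns forming
    group 1 and no missing values.  Returns ``(U1, p_two_sided)`` identical
    to the scalar :func:`mann_whitney` asymptotic path.
    """
    n = X.shape[1]
    n2 = n - n1
    ranks = scipy.stats.rankdata(X, axis=1)
    u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2.0
    tie_terms = np.fromiter((_row_tie_term(row) for row in X), float, count=X.shape[0])
    var = n1 * n2 / 12.0 * ((n + 1) - tie_terms / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    u_big = np.maximum(u1, n1 * n2 - u1)
    p = np.ones(X.shape[0])
    ok = sd > 0
    z = (u_big[ok] - mu - 0.5) / sd[ok]
    p[ok] = np.clip(2.0 * scipy.stats.norm.sf(z), 0.0, 1.0)
    return u1, p


def _screen_values(
    values: pd.DataFrame,
    y: pd.Series,
    alpha: float = 0.05,
    min_class_size: int = 3,
    gene_filter=None,
):
    """Screen every testable gene row of ``values`` (genes x samples).

    ``y`` maps each sample column to responder / non_responder.  Returns
    ``(results, m_tested, threshold, threshold_display, untested)``.
    """
    if gene_filter is not None:
        if callable(gene_filter):
            keep = [g for g in values.index if gene_filter(g)]
        else:
            allowed = set(gene_filter)
            keep = [g for g in values.index if g in allowed]
        values = values.loc[keep]
    y = y.reindex(values.columns)
    if y.isna().any():
        raise ValidationError("every cohort sample needs a response label")
    is_nr = (y == NON_RESPONDER).to_numpy()
    is_r = (y == RESPONDER).to_numpy()
    if not is_nr.any() or not is_r.any():
        raise ValidationError("cohort must contain both responders and non-responders")

    X = values.to_numpy(dtype=float)
    Xnr = X[:, is_nr]
    Xr = X[:, is_r]
    nn_nr = (~np.isnan(Xnr)).sum(axis=1)
    nn_r = (~np.isnan(Xr)).sum(axis=1)
    tested = (nn_nr >= min_class_size) & (nn_r >= min_class_size)
    m_tested = int(tested.sum())
    untested = [g for g, t in zip(values.index, tested) if not t]
    if m_tested == 0:
        raise ValidationError("no gene meets the per-class minimum sample size")
    threshold, display = bonferroni_threshold(m_tested, alpha)

    genes = np.asarray(values.index)
    n1, n2 = Xnr.shape[1], Xr.shape[1]
    u = np.full(len(genes), np.nan)
    p = np.full(len(genes), np.nan)

    complete = ~np.isnan(X).any(axis=1)
    # rows eligible for exact enumeration must go through the scalar path
    small = n1 <= 8 and n2 <= 8
    fast = tested & complete
    if small:
        tie_free = np.zeros(len(genes), dtype=bool)
        for i in np.where(fast)[0]:
            pooled = np.concatenate([Xnr[i], Xr[i]])
            tie_free[i] = np.unique(pooled).size == pooled.size
        fast = fast & ~tie_free
    fast_idx = np.where(fast)[0]
    if fast_idx.size:
        pooled = np.concatenate([Xnr[fast_idx], Xr[fast_idx]], axis=1)
        constant = (pooled == pooled[:, :1]).all(axis=1)
        sub = fast_idx[~constant]
        if sub.size:
            u_sub, p_sub = _mwu_asymptotic_batch(
                np.concatenate([Xnr[sub], Xr[sub]], axis=1), n1
            )
            u[sub] = u_sub
            p[sub] = p_sub
        const_idx = fast_idx[constant]
        u[const_idx] = n1 * n2 / 2.0
        p[const_idx] = 1.0
    for i in np.where(tested & ~fast)[0]:
        vnr = Xnr[i][~np.isnan(Xnr[i])]
        vr = Xr[i][~np.isnan(Xr[i])]
        u[i], p[i] = mann_whitney(vnr, vr)

    with np.errstate(invalid="ignore"):
        mean_nr = np.nanmean(Xnr, axis=1)
        mean_r = np.nanmean(Xr, axis=1)

    results = []
    for i in np.where(tested)[0]:
        raw = u[i] / (nn_nr[i] * nn_r[i])
        if raw > 0.5:
            direction = HIGHER_IN_NONRESPONDER
        elif raw < 0.5:
            direction = HIGHER_IN_RESPONDER
        else:
            direction = TIE
        hi, lo = max(mean_nr[i], mean_r[i]), min(mean_nr[i], mean_r[i])
        fc = 1.0 if hi == lo else (math.inf if lo == 0 else hi / lo)
        results.append(
            GeneResult(
                gene=str(genes[i]),
                n_responder=int(nn_r[i]),
                n_nonresponder=int(nn_nr[i]),
                u_statistic=float(u[i]),
                auc=float(max(raw, 1.0 - raw)),
                direction=direction,
                p_raw=float(p[i]),
                fold_change=float(fc),
                significant=bool(p[i] <= threshold),
            )
        )
    return results, m_tested, threshold, display, untested


@dataclass
class ScreenResult:
    """Outcome of one cohort-wide screen."""

    spec: CohortSpec | None
    m_tested: int
    alpha: float
    threshold: float
    threshold_display: str
    results: list[GeneResult]
    untested: list[str] = field(default_factory=list)

    def get(self, gene: str) -> GeneResult:
        for r in self.results:
            if r.gene == gene:
                return r
        raise ValidationError(f"gene {gene!r} was not tested in this screen")

    @property
    def significant(self) -> list[GeneResult]:
        return [r for r in self.results if r.significant]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": r.gene,
                "n_responder": r.n_responder,
                "n_nonresponder": r.n_nonresponder,
                "u_statistic": r.u_statistic,
                "auc": r.auc,
                "direction": r.direction,
                "p_raw": r.p_raw,
                "fold_change": r.fold_change,
                "significant": r.significant,
                "druggable": r.druggable,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows).set_index("gene")

    def metadata(self) -> dict:
        meta = {
            "m_tested": self.m_tested,
            "alpha": self.alpha,
            "threshold_exact": f"{self.threshold:.6e}",
            "threshold_display": self.threshold_display,
        }
        if self.spec is not None:
            meta["cohort"] = self.spec.describe()
        return meta


def screen_cohort(
    c: Cohort,
    alpha: float = 0.05,
    min_class_size: int | None = None,
    gene_filter=None,
) -> ScreenResult:
    """Genome-wide screen of one cohort.

    Every gene with at least ``min_class_size`` non-missing values per class
    (after the optional ``gene_filter`` — a predicate or a whitelist such as a
    protein-coding gene list) is tested; the Bonferroni threshold divides
    ``alpha`` by the number of genes actually tested in this cohort.
    """
    if min_class_size is None:
        min_class_size = c.spec.min_class_size
    results, m_tested, thr, disp, untested = _screen_values(
        c.values, c.y, alpha=alpha, min_class_size=min_class_size,
        gene_filter=gene_filter,
    )
    return ScreenResult(c.spec, m_tested, alpha, thr, disp, results, untested)


def evaluate_panel(
    c: Cohort,
    genes: list[str],
    alpha: float = 0.05,
    min_class_size: int | None = None,
) -> ScreenResult:
    """Evaluate a fixed biomarker panel with panel-wise Bonferroni control.

    ``m_tested`` counts only the testable panel genes; panel genes absent
    from the matrix (or with too few observations) are reported as untested.
    """
    genes = list(genes)
    present = [g for g in genes if g in c.values.index]
    if not present:
        raise ValidationError("no panel gene is present in the cohort matrix")
    if min_class_size is None:
        min_class_size = c.spec.min_class_size
    results, m_tested, thr, disp, untested = _screen_values(
        c.values.loc[present], c.y, alpha=alpha, min_class_size=min_class_size,
    )
    untested = sorted(set(untested) | (set(genes) - set(present)))
    return ScreenResult(c.spec, m_tested, alpha, thr, disp, results, untested)


def rank_against(screen: ScreenResult, gene: str) -> int:
    """Number of other tested genes with strictly higher oriented AUC."""
    target = screen.get(gene)
    return sum(1 for r in screen.results if r.gene != gene and r.auc > target.auc)


def annotate_druggable(screen: ScreenResult, druggable) -> list[GeneResult]:
    """Flag results against a druggable-gene list.

    Returns the headline category — significant, druggable genes upregulated
    in non-responders — ordered by raw P ascending.
    """
    druggable = set(druggable)
    for r in screen.results:
        r.druggable = r.gene in druggable
    hits = [
        r
        for r in screen.results
        if r.significant and r.druggable and r.direction == HIGHER_IN_NONRESPONDER
    ]
    return sorted(hits, key=lambda r: (r.p_raw, r.gene))


class ResponseScreen(BaseEstimator):
    """Univariate response-association screen as a scikit-learn estimator.

    ``fit(X, y)`` tests every feature (gene) of ``X`` (samples x genes) for a
    distributional difference between responders and non-responders via the
    Mann-Whitney U test, records the oriented ROC AUC and fold change, and
    applies Bonferroni control over the features actually tested.
    ``transform`` keeps the significant features, so the estimator composes
    as a supervised feature-selection step in sklearn pipelines.

    Parameters
    ----------
    alpha :
        Family-wise error level for the Bonferroni threshold.
    min_class_size :
        Minimum non-missing observations per class for a feature to be tested.

    Attributes
    ----------
    results_ : DataFrame indexed by feature name with the per-gene statistics.
    m_tested_ : number of features tested.
    threshold_ : exact Bonferroni threshold alpha / m_tested_.
    threshold_display_ : the threshold floored to two significant digits.
    significant_ : boolean mask over input features (untested -> False).
    pvalues_, aucs_ : arrays aligned to input features (untested -> NaN).
    """

    def __init__(self, alpha: float = 0.05, min_class_size: int = 3):
        self.alpha = alpha
        self.min_class_size = min_class_size

    @staticmethod
    def _coerce_y(y, n: int) -> pd.Series:
        y = np.asarray(y).ravel()
        if y.size != n:
            raise ValidationError("X and y have inconsistent lengths")
        out = np.empty(y.size, dtype=object)
        for i, v in enumerate(y):
            if v in (RESPONDER, NON_RESPONDER):
                out[i] = v
            elif v in (1, True, "1"):
                out[i] = RESPONDER
            elif v in (0, False, "0"):
                out[i] = NON_RESPONDER
            else:
                raise ValidationError(f"unrecognized response label {v!r}")
        return pd.Series(out)

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            features = [str(c) for c in X.columns]
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValidationError("X must be 2-D samples x genes")
            features = [f"x{i}" for i in range(arr.shape[1])]
        values = pd.DataFrame(
            arr.T, index=features, columns=[f"s{i}" for i in range(arr.shape[0])]
        )
        ys = self._coerce_y(y, arr.shape[0])
        ys.index = values.columns
        results, m_tested, thr, disp, untested = _screen_values(
            values, ys, alpha=self.alpha, min_class_size=self.min_class_size,
        )
        self.n_features_in_ = len(features)
        self.feature_names_in_ = np.asarray(features, dtype=object)
        self.m_tested_ = m_tested
        self.threshold_ = thr
        self.threshold_display_ = disp
        by_gene = {r.gene: r for r in results}
        self.results_ = pd.DataFrame(
            [
                {
                    "gene": g,
                    "tested": g in by_gene,
                    "n_responder": by_gene[g].n_responder if g in by_gene else 0,
                    "n_nonresponder": by_gene[g].n_nonresponder if g in by_gene else 0,
                    "u_statistic": by_gene[g].u_statistic if g in by_gene else np.nan,
                    "auc": by_gene[g].auc if g in by_gene else np.nan,
                    "direction": by_gene[g].direction if g in by_gene else "",
                    "p_raw": by_gene[g].p_raw if g in by_gene else np.nan,
                    "fold_change": by_gene[g].fold_change if g in by_gene else np.nan,
                    "significant": by_gene[g].significant if g in by_gene else False,
                }
                for g in features
            ]
        ).set_index("gene")
        self.pvalues_ = self.results_["p_raw"].to_numpy()
        self.aucs_ = self.results_["auc"].to_numpy()
        self.significant_ = self.results_["significant"].to_numpy(dtype=bool)
        self._gene_results = results
        return self

    def get_support(self, indices: bool = False):
        mask = self.significant_
        return np.where(mask)[0] if indices else mask

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.significant_]
        return np.asarray(X)[:, self.significant_]
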