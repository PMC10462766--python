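"""Cross-platform harmonization: merge, quantile normalization, global scaling.

The integration recipe is deliberately simple: all per-dataset tables are
stacked into one genes x samples matrix (union gene space, missing where a
platform lacks the gene), every sample is quantile normalized against a
common reference distribution, and the whole table is rescaled by one global
constant so the overall mean equals a fixed target (1000 by default).
Quantile normalization removes any monotone per-platform distortion of the
value scale, which is exactly the class of batch effect that differing
RNA-seq pipelines and counting platforms introduce; the global rescale fixes
the unit without touching any rank statistic downstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import ExpressionMatrix
from .errors import MergeError, StateError, ValidationError

logger = logging.getLogger(__name__)

STATE_RAW = "raw"
STATE_QUANTILE = "quantile_normalized"
STATE_SCALED = "scaled"


@dataclass
class CombinedMatrix:
    """Union-gene-space matrix over several datasets.

    ``values`` is genes x samples with ``NaN`` where a sample's platform does
    not measure the gene; ``sample_datasets`` maps each sample id to its
    dataset of origin.
    """

    values: pd.DataFrame
    sample_datasets: pd.Series
    normalization_state: str = STATE_RAW

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile-normalize samples (rows) onto a common reference distribution.

    The reference quantile function is the across-sample mean of per-sample
    empirical quantile functions evaluated at the order-statistic positions
    ``(r - 1/2) / n_features``.  For samples with no missing values this is
    classical quantile normalization: the value of rank ``r`` becomes the
    mean of all samples' rank-``r`` order statistics, and tied values receive
    the mean of the reference values their tied ranks span.  Samples with
    missing entries (platforms with reduced gene sets) are mapped through the
    reference quantile function at their own empirical quantiles, linearly
    interpolated.

    Follows the scikit-learn transformer API; ``X`` is samples x features
    with ``NaN`` allowed.
    """

    def fit(self, X, y=None):
        X = self._as_array(X)
        n = X.shape[1]
        self._grid_ = (np.arange(1, n + 1) - 0.5) / n
        curves = np.empty((X.shape[0], n))
        for i, row in enumerate(X):
            v = np.sort(row[~np.isnan(row)])
            if v.size == 0:
                raise ValidationError(f"sample row {i} has no non-missing values")
            xp = (np.arange(1, v.size + 1) - 0.5) / v.size
            curves[i] = np.interp(self._grid_, xp, v)
        self.reference_ = curves.mean(axis=0)
        self.n_features_in_ = n
        return self

    def transform(self, X):
        X = self._as_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        out = np.full_like(X, np.nan)
        for i, row in enumerate(X):
            mask = ~np.isnan(row)
            out[i, mask] = self._transform_sample(row[mask])
        return out

    def _transform_sample(self, v: np.ndarray) -> np.ndarray:
        k = v.size
        # reference value assigned to each within-sample rank 1..k
        q = np.interp((np.arange(1, k + 1) - 0.5) / k, self._grid_, self.reference_)
        order = np.argsort(v, kind="mergesort")
        sv = v[order]
        run_id = np.concatenate(([0], np.cumsum(sv[1:] != sv[:-1])))
        run_mean = np.bincount(run_id, weights=q) / np.bincount(run_id)
        out = np.empty(k)
        out[order] = run_mean[run_id]
        return out

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("expected a 2-D samples x features array")
        return X


def merge_datasets(matrices: list[ExpressionMatrix]) -> CombinedMatrix:
    """Stack per-dataset matrices into one union-gene-space table.

    Sample identifiers must be globally unique; genes absent from a dataset's
    platform become missing for its samples.
    """
    if not matrices:
        raise MergeError("no datasets to merge")
    seen: dict[str, str] = {}
    for m in matrices:
        for s in m.sample_ids:
            if s in seen:
                raise MergeError(
                    f"sample id {s!r} appears in both dataset {seen[s]!r} "
                    f"and {m.dataset_id!r}"
                )
            seen[s] = m.dataset_id
    combined = pd.concat([m.values for m in matrices], axis=1).sort_index()
    sample_datasets = pd.Series(
        {s: ds for m in matrices for s, ds in zip(m.sample_ids, [m.dataset_id] * m.n_samples)}
    ).reindex(combined.columns)
    for m in matrices:
        logger.info(
            "merged dataset %s: %d genes x %d samples (%s)",
            m.dataset_id, m.n_genes, m.n_samples, m.platform or "unknown platform",
        )
    return CombinedMatrix(combined, sample_datasets, STATE_RAW)


def quantile_normalize(m: CombinedMatrix) -> CombinedMatrix:
    """Quantile-normalize all samples of a raw combined matrix jointly."""
    if m.normalization_state != STATE_RAW:
        raise StateError(
            f"quantile_normalize expects state {STATE_RAW!r}, "
            f"got {m.normalization_state!r}"
        )
    qn = QuantileNormalizer().fit(m.values.T)
    out = qn.transform(m.values.T).T
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return CombinedMatrix(values, m.sample_datasets.copy(), STATE_QUANTILE)


def scale_to_target(m: CombinedMatrix, target: float = 1000.0) -> CombinedMatrix:
    """Multiply the whole table by one constant so its mean equals ``target``."""
    if m.normalization_state != STATE_QUANTILE:
        raise StateError(
            f"scale_to_target expects state {STATE_QUANTILE!r}, "
            f"got {m.normalization_state!r}"
        )
    if target <= 0:
        raise ValidationError("target must be positive")
    overall = np.nanmean(m.values.to_numpy())
    if not np.isfinite(overall) or overall == 0:
        raise ValidationError("cannot scale a matrix with zero overall mean")
    values = m.values * (target / overall)
    return CombinedMatrix(values, m.sample_datasets.copy(), STATE_SCALED)


def harmonize(matrices: list[ExpressionMatrix], target: float | None = 1000.0) -> CombinedMatrix:
    """Full recipe: merge, quantile-normalize, scale (skip scaling if ``target`` is None)."""
    m = quantile_normalize(merge_datasets(matrices))
    if target is not None:
        m = scale_to_target(m, target)
    return m
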