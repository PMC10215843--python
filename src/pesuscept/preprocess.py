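"""Expression preprocessing: sample filtering, quantile normalization,
batch-effect removal and pathway subsetting.

The pipeline assumes the matrix is already background-corrected,
log2-transformed and probe-summarized (the usual output of RMA); the
quantile-normalization step here reproduces RMA's across-array quantile
step on an existing matrix, and batch correction re-implements the
``removeBatchEffect``-style per-gene additive means model.

Transformer classes follow the sklearn convention (X is samples x features);
the dataset-level functions operate on :class:`~pesuscept.datasets.ExpressionDataset`
(genes x samples) and are the interface the rest of the package uses.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datasets import EmptyDatasetError, ExpressionDataset, GeneSet

__all__ = [
    "ConfoundingError",
    "CoverageError",
    "QuantileNormalizer",
    "BatchEffectRemover",
    "filter_samples",
    "quantile_normalize",
    "remove_batch_effects",
    "extract_pathway",
]


class ConfoundingError(ValueError):
    """A batch is perfectly confounded with the biological group."""


class CoverageError(ValueError):
    """The gene set does not intersect the dataset's genes."""


def _quantile_normalize_columns(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a genes x samples matrix.

    Every column is mapped onto the across-column mean of order statistics;
    ties within a column receive the mean of their tied reference quantiles.
    """
    n_genes, n_samples = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty(n_genes)
        ranked[order] = reference
        # average reference values over runs of tied input values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_genes]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                ranked[order[s:e]] = reference[s:e].mean()
        out[:, j] = ranked
    return out


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization as an sklearn transformer (X: samples x features).

    ``fit`` stores the reference distribution (mean of order statistics over
    the fitted samples is not meaningful across axes here, so fit is
    stateless apart from shape checks); ``transform`` normalizes the given
    samples jointly, matching the batch-style usage of microarray pipelines.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[0] < 2:
            warnings.warn("quantile normalization needs >=2 samples; returning input")
            return X.copy()
        return _quantile_normalize_columns(X.T).T


def filter_samples(ds: ExpressionDataset, exclude_groups) -> ExpressionDataset:
    """Drop all samples whose group label is in ``exclude_groups``.

    Unknown labels are permitted (no-op); removing every sample raises
    :class:`EmptyDatasetError`. Gene axis and sample order are preserved.
    """
    exclude = set(exclude_groups)
    keep = np.array([g not in exclude for g in ds.groups], dtype=bool)
    if not keep.any():
        raise EmptyDatasetError("excluding these groups removes every sample")
    if keep.all():
        return ds.copy()
    return ds.select_samples(keep)


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalize the samples of a dataset (columns of the matrix)."""
    if ds.n_samples < 2:
        warnings.warn("quantile normalization needs >=2 samples; returning input")
        return ds.copy()
    out = ds.copy()
    out.values = _quantile_normalize_columns(ds.values)
    return out


def _batch_design(groups, batches, preserve_groups):
    """Build the OLS design matrix and the column slice holding batch terms."""
    n = len(batches)
    cols = [np.ones(n)]
    if preserve_groups:
        levels = list(dict.fromkeys(groups))
        for g in levels[1:]:
            cols.append((np.asarray(groups) == g).astype(float))
    n_cov = len(cols)
    batch_levels = list(dict.fromkeys(batches))
    last = batch_levels[-1]
    for b in batch_levels[:-1]:
        col = (np.asarray(batches) == b).astype(float) - (
            np.asarray(batches) == last
        ).astype(float)
        cols.append(col)
    X = np.column_stack(cols)
    return X, slice(n_cov, X.shape[1]), batch_levels


def remove_batch_effects(
    ds: ExpressionDataset, preserve_groups: bool = True
) -> ExpressionDataset:
    """Remove additive per-gene batch effects by a two-way linear means model.

    Per gene, ``expression ~ group (optional) + batch`` is fit by least
    squares with sum-to-zero batch coding; only the fitted batch terms are
    subtracted, after centering them to their sample-weighted mean so the
    per-gene grand mean is preserved exactly even for unbalanced batches.
    A single batch is a no-op. A batch perfectly confounded with group (when
    ``preserve_groups``) raises :class:`ConfoundingError` naming the batch.
    """
    batches = np.asarray(ds.batches)
    levels = list(dict.fromkeys(batches))
    if len(levels) < 2:
        return ds.copy()
    X, batch_slice, batch_levels = _batch_design(ds.groups, batches, preserve_groups)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        if preserve_groups:
            for b in batch_levels:
                in_b = batches == b
                gset = set(np.asarray(ds.groups)[in_b])
                if len(gset) == 1:
                    g = next(iter(gset))
                    if set(np.unique(batches[np.asarray(ds.groups) == g])) == {b}:
                        raise ConfoundingError(
                            f"batch {b!r} is perfectly confounded with group {g!r}"
                        )
        raise ConfoundingError("design matrix is rank deficient (batch/group aliasing)")
    coef, *_ = np.linalg.lstsq(X, ds.values.T, rcond=None)
    batch_fit = X[:, batch_slice] @ coef[batch_slice, :]  # samples x genes
    batch_fit -= batch_fit.mean(axis=0, keepdims=True)
    out = ds.copy()
    out.values = ds.values - batch_fit.T
    return out


class BatchEffectRemover(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around :func:`remove_batch_effects`.

    ``fit_transform(X, y=groups, batches=...)`` adjusts X (samples x
    features). Because the adjustment is estimated jointly over the given
    samples, only ``fit_transform`` is supported.
    """

    def __init__(self, preserve_groups: bool = True):
        self.preserve_groups = preserve_groups

    def fit_transform(self, X, y=None, batches=None):
        X = check_array(X)
        if batches is None:
            raise ValueError("batches must be provided")
        groups = y if y is not None else np.zeros(X.shape[0], dtype=int)
        ds = ExpressionDataset(
            X.T,
            [f"g{i}" for i in range(X.shape[1])],
            [f"s{i}" for i in range(X.shape[0])],
            np.asarray(groups),
            np.asarray(batches),
        )
        preserve = self.preserve_groups and y is not None
        return remove_batch_effects(ds, preserve_groups=preserve).values.T


def extract_pathway(ds: ExpressionDataset, gs: GeneSet):
    """Restrict the dataset to the pathway genes, in gene-set order.

    Returns ``(subset, missing)`` where ``missing`` lists gene-set members
    absent from the dataset. An empty intersection raises
    :class:`CoverageError`. Identifiers are matched on their string form so
    integer Entrez ids and their text representation interoperate.
    """
    by_str = {str(g): g for g in ds.gene_ids}
    kept = [by_str[str(g)] for g in gs.gene_ids if str(g) in by_str]
    missing = [g for g in gs.gene_ids if str(g) not in by_str]
    if not kept:
        raise CoverageError(
            f"gene set {gs.name!r} shares no genes with the dataset"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} of {len(gs)} gene-set members absent from dataset"
        )
    return ds.select_genes(kept), missing
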