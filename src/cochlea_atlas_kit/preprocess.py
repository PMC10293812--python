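"""Depth normalization and quality-control filtering.

Normalization is the dominant 10x convention: each cell's counts are
scaled to a common target depth and log1p-transformed,

    value = log(1 + count * T / cell_total),

which makes the transform invariant to per-cell sequencing depth and maps
zero counts to exactly zero.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

DEFAULT_TARGET_DEPTH = 10_000.0


class DepthNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: depth-scale each row to ``target_depth``
    then log1p. Stateless (``fit`` only validates); works on dense or
    sparse matrices and preserves sparsity."""

    def __init__(self, target_depth: float = DEFAULT_TARGET_DEPTH):
        self.target_depth = target_depth

    def fit(self, X, y=None):
        if self.target_depth <= 0:
            raise ValueError("target_depth must be > 0")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if self.target_depth <= 0:
            raise ValueError("target_depth must be > 0")
        if sparse.issparse(X):
            X = X.tocsr().astype(float)
            totals = np.asarray(X.sum(axis=1)).ravel()
            n_zero = int((totals == 0).sum())
            if n_zero:
                logger.warning("%d all-zero cell(s) pass through unnormalized", n_zero)
            scale = np.divide(
                self.target_depth, totals, out=np.zeros_like(totals), where=totals > 0
            )
            out = sparse.diags(scale) @ X
            out.data = np.log1p(out.data)
            return out.tocsr()
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=1)
        n_zero = int((totals == 0).sum())
        if n_zero:
            logger.warning("%d all-zero cell(s) pass through unnormalized", n_zero)
        scale = np.divide(
            self.target_depth, totals, out=np.zeros_like(totals), where=totals > 0
        )
        return np.log1p(X * scale[:, None])


def normalize(adata: ad.AnnData, target_depth: float = DEFAULT_TARGET_DEPTH) -> ad.AnnData:
    """Return a copy of ``adata`` with normalized ``X``; raw counts are
    kept in ``layers['counts']``."""
    out = adata.copy()
    out.layers["counts"] = adata.X.copy()
    out.X = DepthNormalizer(target_depth).fit(adata.X).transform(adata.X)
    out.uns["normalization"] = {"target_depth": target_depth}
    return out


def qc_filter(
    adata: ad.AnnData, min_genes_per_cell: int = 1, min_cells_per_gene: int = 1
) -> ad.AnnData:
    """Remove low-complexity cells, then rarely detected genes.

    The order is fixed (cells first, then genes): gene detection counts are
    evaluated on the surviving cells only. Raises if no cell survives.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("thresholds must be >= 0")
    X = adata.X
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    keep_cells = detected >= min_genes_per_cell
    if not keep_cells.any():
        raise ValueError("QC filter removed every cell")
    out = adata[keep_cells].copy()
    cells_per_gene = np.asarray((out.X > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene
    out = out[:, keep_genes].copy()
    logger.info(
        "qc_filter removed %d cell(s) and %d gene(s)",
        int((~keep_cells).sum()),
        int((~keep_genes).sum()),
    )
    return out
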