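"""Gene-panel expression profiles and hierarchical clustering.

A panel of genes (e.g. deafness genes plus key developmental genes) is
summarized as a gene x (cell type, stage) matrix of mean normalized
expression, optionally row-Z-scored, and hierarchically clustered along
either axis with correlation distance and average linkage (both
configurable). The cell-type similarity matrix is the pairwise Pearson
correlation of the group profiles.
"""

from __future__ import annotations

import io as _io
import logging

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio.tree import TreeNode

logger = logging.getLogger(__name__)


def profile_matrix(X, genes, cell_types, stages, panel_genes) -> pd.DataFrame:
    """Mean normalized expression of panel genes per (cell type, stage).

    Missing panel genes are excluded and recorded in
    ``result.attrs['missing_genes']``; groups with zero cells simply do
    not appear. Raises on an empty panel or when no panel gene is present.
    """
    panel_genes = list(panel_genes)
    if not panel_genes:
        raise ValueError("empty gene panel")
    Xd = np.asarray(X.todense() if sparse.issparse(X) else X, dtype=float)
    genes = list(genes)
    index = {g: j for j, g in enumerate(genes)}
    present = [g for g in panel_genes if g in index]
    missing = [g for g in panel_genes if g not in index]
    if missing:
        logger.warning("%d panel gene(s) absent from the matrix: %s", len(missing), missing[:10])
    if not present:
        raise ValueError("no panel gene present in the matrix")
    groups = pd.DataFrame({"cell_type": np.asarray(cell_types), "stage": np.asarray(stages)})
    cols = {}
    for (ct, st), idx in groups.groupby(["cell_type", "stage"], sort=True).groups.items():
        cols[(ct, st)] = Xd[np.asarray(idx)][:, [index[g] for g in present]].mean(axis=0)
    out = pd.DataFrame(cols, index=pd.Index(present, name="gene"))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["cell_type", "stage"])
    out.attrs["missing_genes"] = missing
    return out


def zscore_rows(profiles: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores with the population (n-denominator) sd; constant
    rows map to all-zeros and are flagged in
    ``result.attrs['constant_rows']``."""
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 columns to Z-score")
    values = profiles.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd
    constant = sd.ravel() == 0
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (values - mean) / safe_sd
    z[constant] = 0.0
    if constant.any():
        logger.warning("%d constant row(s) mapped to zeros", int(constant.sum()))
    out = pd.DataFrame(z, index=profiles.index, columns=profiles.columns)
    out.attrs["constant_rows"] = profiles.index[constant].tolist()
    return out


def hcluster(matrix: pd.DataFrame, axis: str = "rows",
             metric: str = "correlation", method: str = "average"):
    """Hierarchical clustering of rows or columns.

    Returns ``(linkage, leaf_order, labels)``. Undefined correlation
    distances (constant items) are set to the maximal distance 1 with a
    warning. A single item yields a degenerate (empty) linkage.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    values = matrix.to_numpy(dtype=float) if axis == "rows" else matrix.to_numpy(dtype=float).T
    labels = list(matrix.index if axis == "rows" else matrix.columns)
    if len(labels) < 1:
        raise ValueError("nothing to cluster")
    if len(labels) == 1:
        return np.empty((0, 4)), np.array([0]), labels
    d = pdist(values, metric=metric)
    if np.isnan(d).any():
        logger.warning("undefined %s distance(s) set to 1", metric)
        d = np.nan_to_num(d, nan=1.0)
    Z = hierarchy.linkage(d, method=method)
    return Z, hierarchy.leaves_list(Z), labels


def celltype_similarity(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of pairwise Pearson correlations between group
    profiles (columns), with an exact unit diagonal; undefined
    correlations (constant profiles) become 0 with a warning."""
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    sim = profiles.corr(method="pearson")
    if sim.isna().to_numpy().any():
        logger.warning("undefined correlation(s) (constant profile) set to 0")
        sim = sim.fillna(0.0)
    np.fill_diagonal(sim.to_numpy(), 1.0)
    values = (sim.to_numpy() + sim.to_numpy().T) / 2.0
    np.fill_diagonal(values, 1.0)
    return pd.DataFrame(values, index=sim.index, columns=sim.columns)


def cut_tree(Z: np.ndarray, k: int, labels) -> pd.Series:
    """Cut a linkage tree into exactly ``k`` clusters (nested cuts)."""
    n = len(labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    if n == 1:
        ids = np.array([0])
    else:
        ids = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    return pd.Series(ids, index=pd.Index(labels, name="gene"), name="cluster")


def to_newick(Z: np.ndarray, labels) -> str:
    """Serialize a linkage tree as a Newick string."""
    if len(labels) == 1:
        return f"{labels[0]};\n"
    tree = TreeNode.from_linkage_matrix(Z, list(map(str, labels)))
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue()
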