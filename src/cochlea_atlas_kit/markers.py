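"""One-vs-rest marker ranking and bubble-plot statistics.

Each gene is tested per group with a two-sided Wilcoxon rank-sum test
(exact null when both group sizes are <= 10, normal approximation with
tie correction otherwise); p values are Benjamini-Hochberg adjusted per
group across genes. The effect size is the log2 fold-change of de-logged
group means (expm1 of the mean log-normalized value) with a pseudocount.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse

from .stats import benjamini_hochberg, exact_rank_sum_p, rank_sum_vectorized

logger = logging.getLogger(__name__)

LOG2FC_PSEUDOCOUNT = 1e-9
EXACT_MAX_GROUP = 10
MIN_CELLS_PER_GROUP = 3


def _dense(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def _log2fc(mean_in: np.ndarray, mean_out: np.ndarray) -> np.ndarray:
    a = np.expm1(mean_in) + LOG2FC_PSEUDOCOUNT
    b = np.expm1(mean_out) + LOG2FC_PSEUDOCOUNT
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2(a / b)


def rank_markers(X, genes, labels, min_cells: int = MIN_CELLS_PER_GROUP) -> pd.DataFrame:
    """Rank genes per group, one group against all the rest.

    Parameters
    ----------
    X
        Normalized (cells x genes) matrix.
    genes
        Gene names, length X.shape[1].
    labels
        Per-cell group labels.

    Returns
    -------
    DataFrame with columns ``gene, group, log2fc, stat, p, q, pct_in,
    pct_out, rank``; within each group rows are ordered by (q ascending,
    log2fc descending). Groups with fewer than ``min_cells`` cells are
    skipped with a warning.
    """
    Xd = _dense(X)
    genes = np.asarray(genes)
    labels = np.asarray(labels)
    if Xd.shape[1] != len(genes):
        raise ValueError("genes length does not match matrix width")
    uniq = pd.unique(labels)
    usable = [g for g in uniq if (labels == g).sum() >= min_cells]
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with enough cells")
    for g in uniq:
        if g not in usable:
            logger.warning("group %r has < %d cells; skipped", g, min_cells)

    nonzero = Xd > 0
    frames = []
    for g in usable:
        mask = labels == g
        n1, n2 = int(mask.sum()), int((~mask).sum())
        W, _, p = rank_sum_vectorized(Xd, mask)
        if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
            p = np.array(
                [exact_rank_sum_p(Xd[mask, j], Xd[~mask, j]) for j in range(Xd.shape[1])]
            )
        mean_in = Xd[mask].mean(axis=0)
        mean_out = Xd[~mask].mean(axis=0)
        df = pd.DataFrame(
            {
                "gene": genes,
                "group": g,
                "log2fc": _log2fc(mean_in, mean_out),
                "stat": W,
                "p": p,
                "q": benjamini_hochberg(p),
                "pct_in": nonzero[mask].mean(axis=0),
                "pct_out": nonzero[~mask].mean(axis=0),
            }
        )
        # enriched genes first (a "marker" is over-expressed in its group),
        # then by q ascending and log2fc descending
        df = (
            df.assign(_depleted=df["log2fc"] <= 0)
            .sort_values(
                ["_depleted", "q", "log2fc"],
                ascending=[True, True, False],
                kind="stable",
            )
            .drop(columns="_depleted")
            .reset_index(drop=True)
        )
        df["rank"] = np.arange(1, len(df) + 1)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def top_markers(results: pd.DataFrame, n: int = 1) -> pd.DataFrame:
    """The ``n`` best-ranked genes of each group."""
    return results[results["rank"] <= n].reset_index(drop=True)


def bubble_stats(X, genes, labels, query_genes) -> pd.DataFrame:
    """Bubble-plot statistics: per (gene, group), the fraction of cells
    expressing the gene (count > 0) and the mean normalized expression
    over all cells of the group (zeros included)."""
    Xd = _dense(X)
    genes = list(genes)
    labels = np.asarray(labels)
    index = {g: j for j, g in enumerate(genes)}
    missing = [g for g in query_genes if g not in index]
    if missing:
        raise ValueError(f"unknown gene(s): {missing}")
    rows = []
    for g in pd.unique(labels):
        mask = labels == g
        sub = Xd[mask]
        for gene in query_genes:
            col = sub[:, index[gene]]
            rows.append((gene, g, float((col > 0).mean()), float(col.mean())))
    return pd.DataFrame(rows, columns=["gene", "label", "pct_expressing", "mean_normalized"])
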