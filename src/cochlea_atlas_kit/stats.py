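"""Shared rank-based statistics used across the analysis modules."""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_vectorized(X: np.ndarray, in_group: np.ndarray):
    """Two-sided Wilcoxon rank-sum test of group vs rest, per column.

    Normal approximation with tie correction (no continuity correction).

    Parameters
    ----------
    X
        Dense (n_samples, n_features) value matrix.
    in_group
        Boolean mask of length n_samples.

    Returns
    -------
    W, z, p : arrays of length n_features
        ``W`` is the in-group rank sum on midranks.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(X, axis=0)
    W = ranks[in_group].sum(axis=0)
    mean_W = n1 * (n + 1) / 2.0
    # per-column tie term sum(t^3 - t)
    tie = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie[j] = float(np.sum(counts**3 - counts))
    var_W = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (W - mean_W) / np.sqrt(var_W)
    z = np.where(var_W > 0, z, 0.0)
    p = np.clip(2.0 * sps.norm.sf(np.abs(z)), 0.0, 1.0)
    return W, z, p


def exact_rank_sum_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all assignments of the
    pooled midranks to the first group. Suitable for small groups
    (n1 + n2 choose n1 assignments are enumerated)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    W_obs = ranks[:n1].sum()
    mean_W = n1 * (n1 + n2 + 1) / 2.0
    dev = abs(W_obs - mean_W)
    total = 0
    hits = 0
    for idx in combinations(range(n1 + n2), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mean_W) >= dev - 1e-12:
            hits += 1
    return hits / total
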