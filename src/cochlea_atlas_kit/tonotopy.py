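"""Anchor-gene pseudo-spatial binning and tonotopic gradient screening.

Tympanic border cells (TBCs) lack spatial coordinates in droplet data, but
the anchor gene Emilin2 has a known base-high expression gradient along
the cochlea. Ranking TBCs by anchor expression and splitting them into
four equal-sized quartile bins therefore yields a pseudo-spatial ordering:
Q1 (strongest anchor expression) = base, Q2 = middle-base, Q3 =
middle-apex, Q4 (weakest) = apex.

Each gene is then screened for a tonotopic gradient across the bins with a
tie-corrected Kruskal-Wallis test, Benjamini-Hochberg adjustment across
screened genes, the Dunn-Holland-Wolfe nonparametric multiple-comparison
test on joint mean ranks for the pairwise post-hoc decisions, and a strict
base/apex fold-change filter (> 1.3 in either direction by default). A
gene is called base-high when q < alpha, the Q1-vs-Q4 post-hoc comparison
is significant, the fold-change passes, and the base mean exceeds the apex
mean; apex-high is the mirror image; anything else is direction "none".
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .simulate import ANCHOR_GENE
from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 4
DEFAULT_ALPHA = 0.05
DEFAULT_FC_THRESHOLD = 1.3
FC_EPS = 1e-9
REGION_ALIASES_4 = ("base", "middle-base", "middle-apex", "apex")


def assign_bins(anchor_values, barcodes=None, n_bins: int = DEFAULT_N_BINS,
                anchor: str = ANCHOR_GENE) -> pd.DataFrame:
    """Quartile pseudo-spatial binning by anchor expression.

    Cells are sorted by anchor expression descending (ties broken by input
    order, stable) and split into ``n_bins`` contiguous groups whose sizes
    differ by at most one, larger groups first; Q1 holds the cells with
    the strongest anchor expression and maps to the base.
    """
    values = np.asarray(anchor_values, dtype=float)
    n = len(values)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} cells, got {n}")
    if np.all(values == values[0]):
        logger.warning("all anchor values identical; bin ordering is arbitrary")
    order = np.argsort(-values, kind="stable")
    base_size, rem = divmod(n, n_bins)
    sizes = [base_size + 1] * rem + [base_size] * (n_bins - rem)
    bins = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes, start=1):
        bins[order[start:start + size]] = b
        start += size
    if n_bins == 4:
        region = [REGION_ALIASES_4[b - 1] for b in bins]
    else:
        region = [f"bin{b}" for b in bins]
    index = pd.Index(barcodes, name="barcode") if barcodes is not None else pd.RangeIndex(n)
    return pd.DataFrame(
        {
            "bin": [f"Q{b}" for b in bins],
            "region": region,
            "anchor": anchor,
            "anchor_value": values,
        },
        index=index,
    )


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square tail p (df = k-1).

    All-identical inputs degenerate to (H, p) = (0, 1).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) == 0:
        raise ValueError("empty input")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if np.all(values == values[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def dunn_mc(values, labels, alpha: float = DEFAULT_ALPHA,
            p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn-Holland-Wolfe pairwise comparisons on joint mean ranks.

    For groups i, j with joint midranks,

        z_ij = (rbar_i - rbar_j) / sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_i + 1/n_j))

    where ``T = sum(t^3 - t)`` over tie groups; two-sided normal p values
    are adjusted over the k(k-1)/2 pairs (Bonferroni by default, "holm"
    and "none" are available).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if any((labels == g).sum() == 0 for g in uniq):
        raise ValueError("empty group")
    N = len(values)
    ranks = sps.rankdata(values)
    mean_rank = {g: ranks[labels == g].mean() for g in uniq}
    n = {g: int((labels == g).sum()) for g in uniq}
    _, counts = np.unique(values, return_counts=True)
    tie = float(np.sum(counts**3 - counts))
    var_base = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
    rows = []
    for a, b in combinations(uniq, 2):
        se2 = var_base * (1.0 / n[a] + 1.0 / n[b])
        if se2 <= 0:
            z = 0.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / np.sqrt(se2)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        rows.append((a, b, z, p))
    df = pd.DataFrame(rows, columns=["group1", "group2", "z", "p"])
    m = len(df)
    if p_adjust == "bonferroni":
        df["p_adj"] = np.minimum(1.0, df["p"] * m)
    elif p_adjust == "holm":
        order = np.argsort(df["p"].to_numpy(), kind="stable")
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        df["p_adj"] = adj
    elif p_adjust == "none":
        df["p_adj"] = df["p"]
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    df["significant"] = df["p_adj"] < alpha
    return df


def fold_change(bin_means: dict, threshold: float = DEFAULT_FC_THRESHOLD,
                eps: float = FC_EPS) -> tuple[float, bool]:
    """Base/apex fold-change on de-logged bin means, with the symmetric
    'or vice versa' rule and strict exclusion at the boundary.

    ``bin_means`` maps bin labels to de-logged means; the first and last
    (sorted) bins are base and apex.
    """
    keys = sorted(bin_means)
    base, apex = float(bin_means[keys[0]]), float(bin_means[keys[-1]])
    fc = (base + eps) / (apex + eps)
    passes = max(fc, 1.0 / fc) > threshold
    return fc, passes


def classify_direction(
    q: float,
    extreme_pair_significant: bool,
    fc: float,
    base_mean: float,
    apex_mean: float,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> str:
    """Direction call for one gene (``base_high`` / ``apex_high`` / ``none``)."""
    if q < alpha and extreme_pair_significant and max(fc, 1.0 / fc) > fc_threshold:
        if base_mean > apex_mean:
            return "base_high"
        if apex_mean > base_mean:
            return "apex_high"
    return "none"


class TonotopyScreen(BaseEstimator):
    """Screen every sufficiently expressed gene for a tonotopic gradient.

    Fitted attributes: ``bins_`` (per-cell quartile table) and
    ``results_`` (per-gene statistics, sorted by q then |log2 fc|).
    """

    def __init__(
        self,
        anchor: str = ANCHOR_GENE,
        n_bins: int = DEFAULT_N_BINS,
        alpha: float = DEFAULT_ALPHA,
        fc_threshold: float = DEFAULT_FC_THRESHOLD,
        min_frac: float = 0.1,
    ):
        self.anchor = anchor
        self.n_bins = n_bins
        self.alpha = alpha
        self.fc_threshold = fc_threshold
        self.min_frac = min_frac

    def fit(self, X, genes, barcodes=None):
        Xd = np.asarray(X.todense() if sparse.issparse(X) else X, dtype=float)
        genes = list(genes)
        if self.anchor not in genes:
            raise ValueError(f"anchor gene {self.anchor!r} absent from the matrix")
        anchor_col = genes.index(self.anchor)
        self.bins_ = assign_bins(
            Xd[:, anchor_col], barcodes=barcodes, n_bins=self.n_bins, anchor=self.anchor
        )
        bin_labels = self.bins_["bin"].to_numpy()
        bin_ids = sorted(set(bin_labels))
        first, last = bin_ids[0], bin_ids[-1]

        expressed_frac = (Xd > 0).mean(axis=0)
        screened = [
            j for j, g in enumerate(genes)
            if expressed_frac[j] >= self.min_frac or g == self.anchor
        ]
        rows = []
        for j in screened:
            v = Xd[:, j]
            H, p = kruskal_wallis(v, bin_labels)
            posthoc = dunn_mc(v, bin_labels, alpha=self.alpha)
            pair = posthoc[
                ((posthoc["group1"] == first) & (posthoc["group2"] == last))
                | ((posthoc["group1"] == last) & (posthoc["group2"] == first))
            ]
            extreme_sig = bool(pair["significant"].iloc[0])
            means = {b: float(np.expm1(v[bin_labels == b].mean())) for b in bin_ids}
            fc, _ = fold_change(means, threshold=self.fc_threshold)
            rows.append(
                {
                    "gene": genes[j],
                    "is_anchor": genes[j] == self.anchor,
                    "H": H,
                    "p": p,
                    "fc": fc,
                    "log2fc": np.log2(fc),
                    "extreme_pair_significant": extreme_sig,
                    **{f"mean_{b}": means[b] for b in bin_ids},
                }
            )
        res = pd.DataFrame(rows)
        res["q"] = benjamini_hochberg(res["p"].to_numpy())
        res["direction"] = [
            classify_direction(
                r["q"], r["extreme_pair_significant"], r["fc"],
                r[f"mean_{first}"], r[f"mean_{last}"],
                alpha=self.alpha, fc_threshold=self.fc_threshold,
            )
            for _, r in res.iterrows()
        ]
        self.results_ = (
            res.assign(_absfc=res["log2fc"].abs())
            .sort_values(["q", "_absfc"], ascending=[True, False], kind="stable")
            .drop(columns="_absfc")
            .reset_index(drop=True)
        )
        return self


def screen(
    X,
    genes,
    anchor: str = ANCHOR_GENE,
    n_bins: int = DEFAULT_N_BINS,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    min_frac: float = 0.1,
    barcodes=None,
) -> pd.DataFrame:
    """Thin wrapper over :class:`TonotopyScreen`; returns ``results_``."""
    est = TonotopyScreen(
        anchor=anchor, n_bins=n_bins, alpha=alpha,
        fc_threshold=fc_threshold, min_frac=min_frac,
    ).fit(X, genes, barcodes=barcodes)
    return est.results_


def over_representation(selected, gene_sets: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``selected`` genes
    in each user-supplied gene set, BH-adjusted across sets.

    Set genes outside the universe are dropped with a warning; an empty
    selection yields an empty table.
    """
    universe = set(universe)
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    if not selected:
        return pd.DataFrame(columns=["set", "n_set", "overlap", "p", "q"])
    M, N = len(universe), len(selected)
    rows = []
    for name, members in gene_sets.items():
        members = set(members)
        outside = members - universe
        if outside:
            logger.warning("set %r: %d gene(s) outside universe dropped", name, len(outside))
            members &= universe
        K = len(members)
        overlap = len(members & selected)
        p = float(sps.hypergeom.sf(overlap - 1, M, K, N)) if K else 1.0
        rows.append((name, K, overlap, p))
    df = pd.DataFrame(rows, columns=["set", "n_set", "overlap", "p"])
    df["q"] = benjamini_hochberg(df["p"].to_numpy())
    return df
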