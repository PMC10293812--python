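"""Marker-score cell-type assignment and the fibrocyte subtype split.

Assignment is cluster-level, matching the cluster-then-name workflow of
atlas building: for every cluster, each registry type receives a score
equal to the mean (over the type's marker genes) of the cluster's mean
expression scaled per gene to [0, 1] across clusters. A cluster is
assigned to the argmax type only when the best score beats the runner-up
by at least ``min_margin``; otherwise every cell of the cluster is labeled
``"nonassigned"``.

Fibrocytes are further split into their five spiral-ligament subtypes by
sub-clustering and reading each sub-cluster's high/low profile over the
Slc12a2 / Gjb2 / Car2 marker triplet through a configurable
8-combination -> 5-subtype mapping table.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .registry import CellTypeSpec

logger = logging.getLogger(__name__)

NONASSIGNED = "nonassigned"
DEFAULT_MIN_MARGIN = 0.1
FIBROCYTE_TRIPLET = ("Slc12a2", "Gjb2", "Car2")
FIBROCYTE_UNRESOLVED = "fibrocyte-unresolved"


def _dense(X):
    return np.asarray(X.todense() if sparse.issparse(X) else X, dtype=float)


class MarkerScoreAssigner(BaseEstimator):
    """Score clusters against a cell-type registry and assign labels.

    Fitted attributes
    -----------------
    cluster_scores_ : DataFrame (clusters x types) of marker scores.
    cluster_assignment_ : DataFrame per cluster with ``cell_type``,
        ``ensemble``, ``score`` and ``margin``.
    """

    def __init__(self, registry: list[CellTypeSpec], min_margin: float = DEFAULT_MIN_MARGIN):
        self.registry = registry
        self.min_margin = min_margin

    def fit(self, X, clusters, genes):
        if not self.registry:
            raise ValueError("registry is empty")
        Xd = _dense(X)
        genes = list(genes)
        clusters = np.asarray(clusters)
        gene_index = {g: j for j, g in enumerate(genes)}
        cluster_ids = pd.unique(clusters)
        means = np.vstack([Xd[clusters == c].mean(axis=0) for c in cluster_ids])
        lo, hi = means.min(axis=0), means.max(axis=0)
        span = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(span > 0, (means - lo) / np.where(span > 0, span, 1.0), 0.0)

        scores = {}
        ensembles = {}
        for spec in self.registry:
            cols = [gene_index[g] for g in spec.marker_genes() if g in gene_index]
            absent = [g for g in spec.marker_genes() if g not in gene_index]
            if absent:
                logger.warning("%s: marker(s) %s absent from matrix", spec.name, absent)
            scores[spec.name] = scaled[:, cols].mean(axis=1) if cols else np.full(len(cluster_ids), np.nan)
            ensembles[spec.name] = spec.ensemble
        score_df = pd.DataFrame(scores, index=pd.Index(cluster_ids, name="cluster"))

        rows = []
        for c in cluster_ids:
            s = score_df.loc[c].dropna()
            if s.empty:
                rows.append((c, NONASSIGNED, None, np.nan, np.nan))
                continue
            ranked = s.sort_values(ascending=False, kind="stable")
            best, best_score = ranked.index[0], float(ranked.iloc[0])
            second = float(ranked.iloc[1]) if len(ranked) > 1 else -np.inf
            margin = best_score - second
            if margin >= self.min_margin:
                rows.append((c, best, ensembles[best], best_score, margin))
            else:
                rows.append((c, NONASSIGNED, None, best_score, margin))
        self.cluster_scores_ = score_df
        self.cluster_assignment_ = pd.DataFrame(
            rows, columns=["cluster", "cell_type", "ensemble", "score", "margin"]
        ).set_index("cluster")
        return self

    def predict(self, clusters) -> np.ndarray:
        return self.cluster_assignment_["cell_type"].loc[np.asarray(clusters)].to_numpy()

    def annotation(self, clusters, barcodes=None) -> pd.DataFrame:
        """Per-cell annotation table: cluster, assigned type (or
        ``nonassigned``), ensemble, score and margin."""
        clusters = np.asarray(clusters)
        out = self.cluster_assignment_.loc[clusters].reset_index()
        if barcodes is not None:
            out.index = pd.Index(barcodes, name="barcode")
        return out


def score_and_assign(
    X, genes, clusters, registry, min_margin: float = DEFAULT_MIN_MARGIN, barcodes=None
) -> pd.DataFrame:
    """Thin wrapper over :class:`MarkerScoreAssigner`."""
    est = MarkerScoreAssigner(registry, min_margin=min_margin).fit(X, clusters, genes)
    return est.annotation(clusters, barcodes=barcodes)


def default_fibrocyte_map() -> dict[str, str]:
    """The bundled (editable) 8-combination -> 5-subtype mapping. Keys are
    H/L strings over (Slc12a2, Gjb2, Car2) in that order."""
    with resources.files("cochlea_atlas_kit.data").joinpath("fibrocyte_map.yaml").open() as fh:
        return yaml.safe_load(fh)


def subtype_fibrocytes(
    X,
    genes,
    fibrocyte_mask,
    marker_triplet: tuple[str, str, str] = FIBROCYTE_TRIPLET,
    mapping: dict[str, str] | None = None,
    n_subclusters: int = 5,
    min_cells: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Label fibrocytes with one of five subtypes.

    Sub-clusters the fibrocyte cells (KMeans on the full normalized
    profile), calls each sub-cluster high/low on the three triplet markers
    (scaled across sub-clusters, high above 0.5), and maps the combination
    through ``mapping``; unmapped combinations become
    ``"fibrocyte-unresolved"``.
    """
    Xd = _dense(X)
    genes = list(genes)
    fibrocyte_mask = np.asarray(fibrocyte_mask, dtype=bool)
    n_fib = int(fibrocyte_mask.sum())
    if n_fib < n_subclusters * min_cells:
        raise ValueError(
            f"need at least {n_subclusters * min_cells} fibrocytes, got {n_fib}"
        )
    missing = [g for g in marker_triplet if g not in genes]
    if missing:
        raise ValueError(f"marker triplet gene(s) absent: {missing}")
    if mapping is None:
        mapping = default_fibrocyte_map()

    sub = Xd[fibrocyte_mask]
    km = KMeans(n_clusters=n_subclusters, n_init=10, random_state=seed)
    labels = km.fit_predict(sub)
    found = np.unique(labels)
    if len(found) < n_subclusters:
        logger.warning(
            "only %d fibrocyte sub-cluster(s) found (%d requested); labels partial",
            len(found), n_subclusters,
        )

    cols = [genes.index(g) for g in marker_triplet]
    means = np.vstack([sub[labels == c][:, cols].mean(axis=0) for c in found])
    lo, hi = means.min(axis=0), means.max(axis=0)
    span = hi - lo
    scaled = np.where(span > 0, (means - lo) / np.where(span > 0, span, 1.0), 0.0)
    high = scaled > 0.5

    names = {}
    for i, c in enumerate(found):
        key = "".join("H" if h else "L" for h in high[i])
        name = mapping.get(key)
        if name is None:
            logger.warning("fibrocyte combination %s not in mapping; unresolved", key)
            name = FIBROCYTE_UNRESOLVED
        names[c] = name
    if len(set(names.values())) < len(found):
        logger.warning("fibrocyte sub-clusters share subtype labels")
    return pd.Series([names[c] for c in labels], name="fibrocyte_subtype")
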