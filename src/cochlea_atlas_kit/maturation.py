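"""Per-cell-type stage contrasts (P8 vs P20 by default).

For one cell type, every gene is tested between two maturation stages
with a two-sided Wilcoxon rank-sum test; effect size is the log2
fold-change of de-logged stage means (stage_b over stage_a) with a
pseudocount, and p values are BH-adjusted within the contrast, yielding
volcano-plot coordinates (log2FC, -log10 q).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse

from .markers import _log2fc
from .stats import benjamini_hochberg, rank_sum_vectorized

logger = logging.getLogger(__name__)

MIN_CELLS_PER_SIDE = 3


def stage_contrast(
    X,
    genes,
    cell_types,
    stages,
    cell_type: str,
    stage_a: str = "P8",
    stage_b: str = "P20",
    min_cells: int = MIN_CELLS_PER_SIDE,
) -> pd.DataFrame:
    """Volcano-plot table for one cell type between two stages.

    Raises if either stage is absent for the cell type, naming the stage.
    """
    Xd = np.asarray(X.todense() if sparse.issparse(X) else X, dtype=float)
    genes = np.asarray(genes)
    cell_types = np.asarray(cell_types)
    stages = np.asarray(stages)
    type_mask = cell_types == cell_type
    if not type_mask.any():
        raise ValueError(f"no cells of type {cell_type!r}")
    for stage in (stage_a, stage_b):
        if not (type_mask & (stages == stage)).any():
            raise ValueError(f"stage {stage!r} missing for cell type {cell_type!r}")
    mask_a = type_mask & (stages == stage_a)
    mask_b = type_mask & (stages == stage_b)
    if mask_a.sum() < min_cells or mask_b.sum() < min_cells:
        raise ValueError(
            f"{cell_type!r}: fewer than {min_cells} cells on one side "
            f"({int(mask_a.sum())} at {stage_a}, {int(mask_b.sum())} at {stage_b})"
        )
    sub = Xd[mask_a | mask_b]
    in_b = np.concatenate(
        [np.zeros(int(mask_a.sum()), bool), np.ones(int(mask_b.sum()), bool)]
    )
    # rows of sub follow the original cell order; rebuild in_b accordingly
    order_mask = (mask_a | mask_b)
    in_b = mask_b[order_mask]
    W, _, p = rank_sum_vectorized(sub, in_b)
    mean_a = sub[~in_b].mean(axis=0)
    mean_b = sub[in_b].mean(axis=0)
    q = benjamini_hochberg(p)
    with np.errstate(divide="ignore"):
        neg_log10_q = -np.log10(np.maximum(q, np.finfo(float).tiny))
    return pd.DataFrame(
        {
            "gene": genes,
            "cell_type": cell_type,
            "log2fc": _log2fc(mean_b, mean_a),
            "stat": W,
            "p": p,
            "q": q,
            "neg_log10_q": neg_log10_q,
        }
    )


def stage_contrast_all(
    X, genes, cell_types, stages,
    stage_a: str = "P8", stage_b: str = "P20",
    min_cells: int = MIN_CELLS_PER_SIDE,
) -> pd.DataFrame:
    """Stage contrast for every cell type with enough cells at both
    stages; underpowered or single-stage types are skipped with a log
    message."""
    frames = []
    for ct in pd.unique(np.asarray(cell_types)):
        try:
            frames.append(
                stage_contrast(
                    X, genes, cell_types, stages, ct,
                    stage_a=stage_a, stage_b=stage_b, min_cells=min_cells,
                )
            )
        except ValueError as exc:
            logger.info("skipping %r: %s", ct, exc)
    if not frames:
        return pd.DataFrame(
            columns=["gene", "cell_type", "log2fc", "stat", "p", "q", "neg_log10_q"]
        )
    return pd.concat(frames, ignore_index=True)
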