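"""Readers and writers for the on-disk artifacts.

Count matrices use the 10x-style MatrixMarket triplet dialect: a
``matrix.mtx`` in integer coordinate format (genes x cells, 1-based
indices), a headerless two-column ``features.tsv`` (gene id, gene name)
and a one-column ``barcodes.tsv``. Per-cell metadata, gene panels and
result tables are UTF-8 TSV with a header; result tables carry a
provenance line prefixed with ``#``.

Internally everything is 0-based; cells are rows of an AnnData, genes its
columns, matching the single-cell ecosystem convention (the on-disk MTX is
transposed, genes x cells, matching the 10x convention). Gene identity is
matched case-sensitively on the name column.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from .registry import STAGES, TECHNOLOGIES

logger = logging.getLogger(__name__)

_VALID_STAGES = set(STAGES) | {"unknown"}
_VALID_TECH = set(TECHNOLOGIES) | {"unknown"}
_META_COLS = ("stage", "technology", "cluster", "cell_type")


def _read_mtx(path: Path) -> sparse.csr_matrix:
    """Parse an integer coordinate MatrixMarket file, strictly."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("%%MatrixMarket"):
            raise ValueError(f"{path}: not a MatrixMarket file")
        fields = header.split()
        if len(fields) < 4 or fields[1] != "matrix" or fields[2] != "coordinate":
            raise ValueError(f"{path}: expected 'matrix coordinate' format")
        if fields[3] != "integer":
            raise ValueError(f"{path}: expected integer field, got {fields[3]!r}")
        line = fh.readline()
        while line.startswith("%"):
            line = fh.readline()
        try:
            n_rows, n_cols, nnz = (int(x) for x in line.split())
        except Exception as exc:
            raise ValueError(f"{path}: malformed size line {line!r}") from exc
        if nnz == 0:
            data = pd.DataFrame(columns=["i", "j", "x"], dtype=np.int64)
        else:
            data = pd.read_csv(
                fh, sep=r"\s+", header=None, names=["i", "j", "x"], dtype=np.int64
            )
    if len(data) != nnz:
        raise ValueError(
            f"{path}: header declares {nnz} entries but {len(data)} were found"
        )
    if len(data):
        if data["i"].min() < 1 or data["i"].max() > n_rows or \
           data["j"].min() < 1 or data["j"].max() > n_cols:
            raise ValueError(f"{path}: triplet index outside declared extent")
        if (data["x"] < 0).any():
            raise ValueError(f"{path}: negative count")
        dup = data.duplicated(subset=["i", "j"])
        if dup.any():
            raise ValueError(
                f"{path}: duplicate (gene, cell) entries at data rows "
                f"{(dup[dup].index + 1).tolist()[:5]}"
            )
    mat = sparse.coo_matrix(
        (data["x"].to_numpy(), (data["i"].to_numpy() - 1, data["j"].to_numpy() - 1)),
        shape=(n_rows, n_cols),
    )
    return mat.tocsr()


def read_counts(
    mtx_path, features_path, barcodes_path, meta_path=None
) -> ad.AnnData:
    """Load a 10x-style triplet (plus optional metadata TSV) into AnnData.

    Raises on dimension mismatch, duplicate gene names or barcodes,
    duplicate matrix entries, and unknown stage/technology values. When no
    metadata file is given, stage and technology default to ``"unknown"``.
    """
    mtx_path, features_path, barcodes_path = map(Path, (mtx_path, features_path, barcodes_path))
    mat = _read_mtx(mtx_path)  # genes x cells

    feats = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    if feats.shape[1] == 1:
        feats[1] = feats[0]
    gene_ids, gene_names = feats[0].tolist(), feats[1].tolist()
    if len(gene_names) != mat.shape[0]:
        raise ValueError(
            f"features file has {len(gene_names)} genes, matrix declares {mat.shape[0]}"
        )
    if len(set(gene_names)) != len(gene_names):
        raise ValueError("duplicate gene name in features file")

    try:
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)[0].tolist()
    except pd.errors.EmptyDataError:
        barcodes = []
    if len(barcodes) != mat.shape[1]:
        raise ValueError(
            f"barcodes file has {len(barcodes)} barcodes, matrix declares {mat.shape[1]}"
        )
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcode in barcodes file")

    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str, comment="#")
        if "barcode" not in meta.columns:
            raise ValueError("metadata file lacks a 'barcode' column")
        meta = meta.set_index("barcode")
        if meta.index.duplicated().any():
            raise ValueError("duplicate barcode in metadata file")
        bad = set(meta.get("stage", pd.Series(dtype=str)).dropna()) - _VALID_STAGES
        if bad:
            raise ValueError(f"unknown stage value(s): {sorted(bad)}")
        bad = set(meta.get("technology", pd.Series(dtype=str)).dropna()) - _VALID_TECH
        if bad:
            raise ValueError(f"unknown technology value(s): {sorted(bad)}")
        for col in _META_COLS:
            if col in meta.columns:
                obs[col] = meta[col].reindex(obs.index)
    for col, default in (("stage", "unknown"), ("technology", "unknown")):
        if col not in obs.columns:
            obs[col] = default
        else:
            obs[col] = obs[col].fillna(default)

    var = pd.DataFrame({"gene_id": gene_ids}, index=pd.Index(gene_names, name="gene"))
    return ad.AnnData(X=mat.T.tocsr().astype(np.int32), obs=obs, var=var)


def write_counts(adata: ad.AnnData, out_dir) -> dict[str, Path]:
    """Write a count AnnData as matrix.mtx + features.tsv + barcodes.tsv
    (+ meta.tsv). Output is deterministic and round-trips through
    :func:`read_counts` exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = sparse.coo_matrix(adata.X.T)  # genes x cells on disk
    if X.data.size and (np.mod(X.data, 1) != 0).any():
        raise ValueError("count matrix contains non-integer values")
    if X.data.size and (X.data < 0).any():
        raise ValueError("count matrix contains negative values")
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
        "meta": out_dir / "meta.tsv",
    }
    # written directly (not via scipy.io.mmwrite) so the header is always
    # 'integer general' — mmwrite auto-detects symmetry and chooses the
    # field from the dtype, both of which break the fixed 10x dialect
    order = np.lexsort((X.row, X.col))  # column-major, the 10x convention
    with open(paths["matrix"], "wt", encoding="utf-8") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{X.shape[0]} {X.shape[1]} {X.nnz}\n")
        for k in order:
            fh.write(f"{X.row[k] + 1} {X.col[k] + 1} {int(X.data[k])}\n")
    gene_ids = (
        adata.var["gene_id"]
        if "gene_id" in adata.var.columns
        else pd.Series(adata.var_names, index=adata.var_names)
    )
    pd.DataFrame({"gene_id": gene_ids.to_numpy(), "gene_name": adata.var_names}).to_csv(
        paths["features"], sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    meta_cols = [c for c in _META_COLS if c in adata.obs.columns]
    meta = adata.obs[meta_cols].copy()
    meta.insert(0, "barcode", adata.obs_names)
    meta.to_csv(paths["meta"], sep="\t", index=False)
    return paths


def read_gene_panels(path) -> pd.DataFrame:
    """Read a gene-panel TSV with columns ``panel``, ``gene`` and an
    optional ``weight``; (panel, gene) pairs must be unique."""
    df = pd.read_csv(path, sep="\t", dtype={"panel": str, "gene": str}, comment="#")
    missing = {"panel", "gene"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df["panel"].isna() | df["gene"].isna()
    if bad.any():
        raise ValueError(
            f"{path}: malformed row(s) at line(s) {(df.index[bad] + 2).tolist()}"
        )
    dup = df.duplicated(subset=["panel", "gene"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicated (panel, gene) row(s) at line(s) "
            f"{(df.index[dup] + 2).tolist()}"
        )
    if "weight" in df.columns:
        df["weight"] = df["weight"].astype(float)
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> Path:
    """Write a result table as TSV with an optional '#'-prefixed
    provenance header line (tool version, seed, parameters)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt", encoding="utf-8") as fh:
        if provenance:
            items = " ".join(f"{k}={v}" for k, v in provenance.items())
            fh.write(f"# {items}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (skips '#' lines)."""
    return pd.read_csv(path, sep="\t", comment="#")
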