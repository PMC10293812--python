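"""End-to-end orchestration: one config, deterministic seeding, manifest.

A :class:`PipelineConfig` names either on-disk inputs (10x triplet +
metadata) or a simulation block, plus the stages to run. Every stage's
randomness derives from the global seed through fixed per-stage offsets,
so adding or removing a stage never perturbs another stage's draws, and
re-running the same config reproduces identical result tables
(checksummed in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as aio
from .assign import score_and_assign
from .cluster import cluster_cells
from .maturation import stage_contrast_all
from .markers import bubble_stats, rank_markers, top_markers
from .patterns import (
    celltype_similarity,
    cut_tree,
    hcluster,
    profile_matrix,
    to_newick,
    zscore_rows,
)
from .preprocess import DEFAULT_TARGET_DEPTH, normalize, qc_filter
from .registry import default_registry
from .simulate import ANCHOR_GENE, SimConfig, simulate_counts
from .study import synthetic_deafness_panel
from .tonotopy import over_representation, screen

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "annotate", "tonotopy", "contrast", "patterns", "enrich")

# fixed per-stage seed offsets (see module docstring)
_SEED_OFFSETS = {"simulate": 11, "annotate": 23, "tonotopy": 37, "patterns": 53}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "qc", "annotate")
    inputs: dict | None = None        # {mtx, features, barcodes, meta?}
    simulation: dict | None = None    # SimConfig kwargs (n_cells keys "stage:tech")
    target_depth: float = DEFAULT_TARGET_DEPTH
    min_genes_per_cell: int = 1
    min_cells_per_gene: int = 1
    resolution_or_k: float | int = 2.0
    min_margin: float = 0.1
    anchor: str = ANCHOR_GENE
    tbc_type: str = "TBC"
    n_bins: int = 4
    fc_threshold: float = 1.3
    alpha: float = 0.05
    min_frac: float = 0.1
    contrast_stages: tuple[str, str] = ("P8", "P20")
    panel_path: str | None = None
    gene_sets_path: str | None = None
    k_gene_clusters: int = 20

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError("exactly one of inputs/simulation must be configured")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.simulation is not None and "simulate" not in self.stages:
            raise ValueError("a simulation block requires the 'simulate' stage")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("stages", "contrast_stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _parse_n_cells(block: dict) -> dict:
    out = {}
    for key, n in block.items():
        if isinstance(key, tuple):
            out[key] = int(n)
        else:
            stage, tech = str(key).split(":")
            out[(stage, tech)] = int(n)
    return out


def run_all(config: PipelineConfig) -> dict:
    """Run the configured stages in order; return the output manifest
    (relative path -> sha256), which is also written to manifest.json."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    prov = {"tool": "cochlea-atlas-kit", "version": __version__, "seed": config.seed}

    def record(path: Path):
        manifest[str(path.relative_to(out_dir))] = _sha256(path)

    def write(df: pd.DataFrame, name: str, **params):
        path = aio.write_table(df, out_dir / name, provenance={**prov, **params})
        record(path)

    # config echo (without out_dir, so identical runs in different
    # directories produce identical checksums)
    echo = out_dir / "config.yaml"
    echo_dict = {k: v for k, v in config.__dict__.items() if k != "out_dir"}
    echo.write_text(yaml.safe_dump({**echo_dict, "version": __version__}))
    record(echo)

    adata = None
    truth = None
    annotation = None
    registry = default_registry()
    stage = "setup"
    try:
        if config.inputs is not None:
            stage = "load"
            adata = aio.read_counts(
                config.inputs["mtx"], config.inputs["features"],
                config.inputs["barcodes"], config.inputs.get("meta"),
            )
        if "simulate" in config.stages and config.simulation is not None:
            stage = "simulate"
            sim_kwargs = dict(config.simulation)
            sim_kwargs["n_cells"] = _parse_n_cells(sim_kwargs["n_cells"])
            sim_kwargs.setdefault("seed", config.seed + _SEED_OFFSETS["simulate"])
            adata, truth = simulate_counts(SimConfig(**sim_kwargs), registry)
            for p in aio.write_counts(adata, out_dir / "counts").values():
                record(p)
            write(truth.reset_index(), "truth.tsv")
        if adata is None:
            raise ValueError("no input data")

        if "qc" in config.stages:
            stage = "qc"
            adata = qc_filter(adata, config.min_genes_per_cell, config.min_cells_per_gene)

        norm = normalize(adata, config.target_depth)
        genes = list(norm.var_names)

        if "annotate" in config.stages:
            stage = "annotate"
            clusters = cluster_cells(
                norm.X, resolution_or_k=config.resolution_or_k,
                seed=config.seed + _SEED_OFFSETS["annotate"],
            )
            annotation = score_and_assign(
                norm.X, genes, clusters, registry,
                min_margin=config.min_margin, barcodes=norm.obs_names,
            )
            annotation["stage"] = norm.obs["stage"].to_numpy()
            annotation["technology"] = norm.obs["technology"].to_numpy()
            write(annotation.reset_index(), "annotation.tsv")
            marker_table = rank_markers(norm.X, genes, clusters)
            write(marker_table, "markers.tsv")
            best = top_markers(marker_table)["gene"].unique().tolist()
            write(bubble_stats(norm.X, genes, annotation["cell_type"], best), "bubble.tsv")

        if "tonotopy" in config.stages:
            stage = "tonotopy"
            if annotation is None:
                raise ValueError("tonotopy requires the annotate stage")
            tbc = (annotation["cell_type"] == config.tbc_type).to_numpy()
            sub = norm[tbc]
            results = screen(
                sub.X, genes, anchor=config.anchor, n_bins=config.n_bins,
                alpha=config.alpha, fc_threshold=config.fc_threshold,
                min_frac=config.min_frac, barcodes=sub.obs_names,
            )
            write(results, "tonotopy.tsv", anchor=config.anchor)
            from .tonotopy import assign_bins
            anchor_col = genes.index(config.anchor)
            Xd = sub.X
            anchor_vals = np.asarray(
                Xd[:, anchor_col].todense() if hasattr(Xd[:, anchor_col], "todense")
                else Xd[:, anchor_col]
            ).ravel()
            bins = assign_bins(anchor_vals, barcodes=sub.obs_names,
                               n_bins=config.n_bins, anchor=config.anchor)
            write(bins.reset_index(), "tonotopy_bins.tsv", anchor=config.anchor)

        if "contrast" in config.stages:
            stage = "contrast"
            if annotation is None:
                raise ValueError("contrast requires the annotate stage")
            a, b = config.contrast_stages
            volcano = stage_contrast_all(
                norm.X, genes, annotation["cell_type"].to_numpy(),
                norm.obs["stage"].to_numpy(), stage_a=a, stage_b=b,
            )
            write(volcano, "contrast.tsv", stage_a=a, stage_b=b)

        if "patterns" in config.stages:
            stage = "patterns"
            if annotation is None:
                raise ValueError("patterns requires the annotate stage")
            if config.panel_path:
                panel = aio.read_gene_panels(config.panel_path)
            else:
                panel = synthetic_deafness_panel()
            panel_genes = [g for g in panel["gene"] if g in set(genes)]
            profiles = profile_matrix(
                norm.X, genes, annotation["cell_type"].to_numpy(),
                norm.obs["stage"].to_numpy(), panel_genes,
            )
            zs = zscore_rows(profiles) if profiles.shape[1] > 1 else profiles
            flat = profiles.copy()
            flat.columns = [f"{ct}|{st}" for ct, st in profiles.columns]
            write(flat.reset_index(), "panel_profiles.tsv")
            zflat = zs.copy()
            zflat.columns = flat.columns
            write(zflat.reset_index(), "panel_zscores.tsv")
            if profiles.shape[0] > 1:
                Z, _, labels = hcluster(zs, axis="rows")
                k = min(config.k_gene_clusters, len(labels))
                write(cut_tree(Z, k, labels).reset_index(), "gene_clusters.tsv", k=k)
                tree_path = out_dir / "gene_tree.nwk"
                tree_path.write_text(to_newick(Z, labels))
                record(tree_path)
            if profiles.shape[1] > 1:
                sim = celltype_similarity(profiles)
                sim.columns = [f"{ct}|{st}" for ct, st in sim.columns]
                sim.index = sim.columns
                write(sim.reset_index(names="group"), "celltype_similarity.tsv")

        if "enrich" in config.stages:
            stage = "enrich"
            if config.gene_sets_path is None:
                raise ValueError("enrich requires gene_sets_path")
            sets_df = aio.read_gene_panels(config.gene_sets_path)
            gene_sets = {
                name: grp["gene"].tolist() for name, grp in sets_df.groupby("panel")
            }
            tono = aio.read_table(out_dir / "tonotopy.tsv")
            selected = tono.loc[tono["direction"] != "none", "gene"]
            universe = tono["gene"]
            write(
                over_representation(selected, gene_sets, universe),
                "enrichment.tsv",
            )
    except Exception as exc:  # abort with stage name + partial manifest
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(stage, exc, manifest) from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
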