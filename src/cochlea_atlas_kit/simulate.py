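"""Synthetic cochlear count-data generator.

Counts follow the standard single-cell model: for cell ``c`` and gene ``g``,

    count ~ NegativeBinomial(mean = s_c * mu_g * m_{g, type(c)} * G_g(p_c),
                             dispersion phi_g)

thinned by Bernoulli dropout with a fixed keep probability, where

* ``s_c`` is a per-cell log-normal library-size factor (mean 1),
* ``mu_g`` is the gene's baseline mean,
* ``m_{g,t}`` is the registry marker multiplier (1 for non-markers),
* ``G_g(p)`` encodes a tonotopic gradient for tympanic border cells (TBCs):
  each TBC receives a latent base-to-apex position ``p ~ Uniform(0, 1)``
  (p=0 base, p=1 apex), and a base-high gradient gene with base/apex fold
  ratio ``r`` has ``G(p) = r**(-p)`` (apex-high: ``r**(p - 1)``) — a
  log-linear profile, i.e. constant fold change per unit position.

The negative binomial is parameterized by mean ``mu`` and dispersion
``phi`` with variance ``mu + phi * mu**2``, sampled as a gamma-Poisson
mixture. All randomness flows from a single integer seed, so identical
configurations yield byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .registry import (
    STAGES,
    TECHNOLOGIES,
    CellTypeSpec,
    effective_proportions,
    validate_registry,
)

logger = logging.getLogger(__name__)

#: Name of the tympanic border cell population, the only one carrying a
#: latent tonotopic position.
TBC_TYPE = "TBC"

#: Anchor gene whose base-high gradient is used for pseudo-spatial ordering.
ANCHOR_GENE = "Emilin2"


@dataclass(frozen=True)
class GradientSpec:
    """A planted tonotopic gradient: ``fold_base_apex`` is the base/apex
    mean ratio ``r > 1``; direction says which end carries the larger mean."""

    gene: str
    fold_base_apex: float
    direction: str  # "base_high" | "apex_high"

    def __post_init__(self):
        if self.fold_base_apex <= 1.0:
            raise ValueError(f"{self.gene}: fold_base_apex must be > 1")
        if self.direction not in ("base_high", "apex_high"):
            raise ValueError(f"{self.gene}: direction must be base_high or apex_high")


@dataclass(frozen=True)
class StageEffect:
    """Multiplicative expression shift for one gene at one stage,
    optionally restricted to one cell type (None = all types)."""

    gene: str
    stage: str
    fold: float
    cell_type: str | None = None


#: Gradients planted by default, mirroring the known base-high gradients of
#: the basilar-membrane matrix genes and two opposite-direction genes.
DEFAULT_GRADIENTS = (
    GradientSpec(ANCHOR_GENE, 2.0, "base_high"),
    GradientSpec("Rarres1", 2.0, "base_high"),
    GradientSpec("Notum", 2.0, "base_high"),
    GradientSpec("Sptssb", 2.0, "apex_high"),
    GradientSpec("Tnfaip6", 2.0, "apex_high"),
)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    ``n_cells`` maps ``(stage, technology)`` to a cell count. Gene baseline
    means are drawn log-normally around ``baseline_mean`` with log-sd
    ``gene_mean_sdlog`` (set to 0 for identical means). ``dropout_keep`` is
    the per-molecule keep probability in [0, 1]; 0 yields an all-zero
    matrix. ``library_sdlog`` is the log-scale sd of the per-cell library
    factor. ``type_variation_sdlog`` controls the between-type divergence
    of background (non-marker) genes.
    """

    n_cells: dict[tuple[str, str], int]
    n_genes: int = 300
    baseline_mean: float = 1.0
    gene_mean_sdlog: float = 0.5
    dispersion: float = 0.5
    dropout_keep: float = 0.8
    library_sdlog: float = 0.3
    type_variation_sdlog: float = 0.8
    dispersion_overrides: tuple[tuple[str, float], ...] = ()
    gradients: tuple[GradientSpec, ...] = DEFAULT_GRADIENTS
    stage_effects: tuple[StageEffect, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if not self.n_cells:
            raise ValueError("n_cells is empty")
        for (stage, tech), n in self.n_cells.items():
            if tech not in TECHNOLOGIES:
                raise ValueError(
                    f"unknown technology {tech!r}; expected one of {TECHNOLOGIES}"
                )
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
            if n <= 0:
                raise ValueError(f"n_cells for {(stage, tech)} must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if any(phi <= 0 for _, phi in self.dispersion_overrides):
            raise ValueError("per-gene dispersion must be > 0")
        if not 0.0 <= self.dropout_keep <= 1.0:
            raise ValueError("dropout_keep must lie in [0, 1]")
        if self.library_sdlog < 0:
            raise ValueError("library_sdlog must be >= 0")
        if self.gene_mean_sdlog < 0:
            raise ValueError("gene_mean_sdlog must be >= 0")
        if self.type_variation_sdlog < 0:
            raise ValueError("type_variation_sdlog must be >= 0")
        genes = [g.gene for g in self.gradients]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene in gradient specs")


def _allocate(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``n`` cells to populations.

    Deterministic, and every population with a nonzero proportion of at
    least 1/(2n) receives its rounded share; zero-proportion populations
    receive no cells.
    """
    names = list(proportions)
    fracs = np.array([proportions[k] for k in names], dtype=float)
    raw = fracs * n
    base = np.floor(raw).astype(int)
    remainder = n - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:remainder]:
        base[i] += 1
    # never allocate to impossible populations
    base[fracs == 0] = 0
    short = n - int(base.sum())
    if short > 0:  # redistribute anything removed above
        for i in order:
            if fracs[i] > 0:
                base[i] += short
                break
    return dict(zip(names, base.tolist()))


def simulate_counts(
    config: SimConfig, registry: list[CellTypeSpec]
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate a count matrix plus its ground-truth table.

    Returns
    -------
    adata
        AnnData with sparse integer counts (cells x genes), ``obs`` columns
        ``stage`` and ``technology``, and ``var`` columns ``gene_id``,
        ``baseline_mean`` and ``dispersion``.
    truth
        One row per cell: ``true_type``, ``stage``, ``technology`` and the
        latent ``position`` (NaN for every non-TBC cell).
    """
    config.validate()
    validate_registry(registry)
    rng = np.random.default_rng(config.seed)

    # Gene universe: registry markers, gradient genes, stage-effect genes,
    # padded with synthetic null genes up to n_genes.
    genes: list[str] = []
    seen = set()
    for spec in registry:
        for g in spec.marker_genes():
            if g not in seen:
                genes.append(g)
                seen.add(g)
    for grad in config.gradients:
        if grad.gene not in seen:
            genes.append(grad.gene)
            seen.add(grad.gene)
    for eff in config.stage_effects:
        if eff.gene not in seen:
            genes.append(eff.gene)
            seen.add(eff.gene)
    if config.n_genes < len(genes):
        raise ValueError(
            f"n_genes={config.n_genes} smaller than the {len(genes)} named genes"
        )
    n_named = len(genes)
    pad_counter = 0
    while len(genes) < config.n_genes:
        name = f"synth-gene-{pad_counter:04d}"
        pad_counter += 1
        if name not in seen:
            genes.append(name)
    gene_index = {g: j for j, g in enumerate(genes)}
    n_genes = len(genes)

    if config.gene_mean_sdlog > 0:
        mu = rng.lognormal(np.log(config.baseline_mean), config.gene_mean_sdlog, n_genes)
    else:
        mu = np.full(n_genes, config.baseline_mean, dtype=float)
    phi = np.full(n_genes, config.dispersion, dtype=float)
    for g, val in config.dispersion_overrides:
        if g not in gene_index:
            raise ValueError(f"dispersion override for unknown gene {g!r}")
        phi[gene_index[g]] = val

    # Marker multiplier table per type. On top of the named markers,
    # background (unnamed) genes receive per-type log-normal multipliers,
    # emulating the broad transcriptomic divergence between real cell
    # types; named genes keep flat cross-type profiles except in their
    # own population.
    n_background = n_genes - n_named
    if config.type_variation_sdlog > 0 and n_background > 0:
        sd = config.type_variation_sdlog
        background_var = rng.lognormal(0.0, sd, (len(registry), n_background))
        background_var /= np.exp(sd**2 / 2.0)  # mean-one multipliers
    else:
        background_var = np.ones((len(registry), n_background))
    type_mult = {}
    for t_idx, spec in enumerate(registry):
        m = np.ones(n_genes)
        for g, fold in spec.markers:
            m[gene_index[g]] *= fold
        m[n_named:] = background_var[t_idx]
        type_mult[spec.name] = m

    blocks = []
    obs_rows = []
    cell_counter = 0
    for (stage, tech) in sorted(config.n_cells):
        n = config.n_cells[(stage, tech)]
        props = effective_proportions(registry, tech)
        alloc = _allocate(n, props)
        types = np.concatenate(
            [np.full(alloc[s.name], s.name, dtype=object) for s in registry]
        )
        n_block = len(types)
        position = np.full(n_block, np.nan)
        is_tbc = types == TBC_TYPE
        position[is_tbc] = rng.uniform(0.0, 1.0, int(is_tbc.sum()))

        s_lib = np.exp(
            rng.normal(-config.library_sdlog**2 / 2.0, config.library_sdlog, n_block)
        )

        mean = np.tile(mu, (n_block, 1))
        for t, m in type_mult.items():
            rows = types == t
            if rows.any():
                mean[rows] *= m
        for grad in config.gradients:
            j = gene_index[grad.gene]
            r = grad.fold_base_apex
            p = position[is_tbc]
            if grad.direction == "base_high":
                mean[is_tbc, j] *= r ** (-p)
            else:
                mean[is_tbc, j] *= r ** (p - 1.0)
        for eff in config.stage_effects:
            if eff.stage != stage:
                continue
            j = gene_index[eff.gene]
            rows = np.ones(n_block, bool) if eff.cell_type is None else types == eff.cell_type
            mean[rows, j] *= eff.fold
        mean *= s_lib[:, None]

        lam = rng.gamma(1.0 / phi[None, :], mean * phi[None, :])
        counts = rng.poisson(lam)
        if config.dropout_keep < 1.0:
            # binomial thinning: each molecule kept independently, so a
            # thinned NB stays NB with mean scaled by the keep probability
            counts = rng.binomial(counts, config.dropout_keep)

        blocks.append(sparse.csr_matrix(counts.astype(np.int32)))
        for i in range(n_block):
            obs_rows.append(
                (
                    f"cell{cell_counter + i:06d}-{stage}-{tech}",
                    stage,
                    tech,
                    types[i],
                    position[i],
                    s_lib[i],
                )
            )
        cell_counter += n_block

    X = sparse.vstack(blocks, format="csr")
    obs = pd.DataFrame(
        obs_rows,
        columns=["barcode", "stage", "technology", "true_type", "position", "library_factor"],
    ).set_index("barcode")
    var = pd.DataFrame(
        {"gene_id": [f"SIM{j:05d}" for j in range(n_genes)],
         "baseline_mean": mu, "dispersion": phi},
        index=pd.Index(genes, name="gene"),
    )
    adata = ad.AnnData(X=X, obs=obs[["stage", "technology"]].copy(), var=var)
    adata.uns["simulation"] = {
        "seed": config.seed,
        "dropout_keep": config.dropout_keep,
        "library_sdlog": config.library_sdlog,
    }
    truth = obs[["true_type", "stage", "technology", "position"]].copy()
    return adata, truth


def simulate_tbc_gradient(
    n_cells: int,
    gradient_specs: tuple[GradientSpec, ...] = (),
    n_null_genes: int = 50,
    seed: int = 0,
    anchor_fold: float = 16.0,
    anchor_level: float = 16.0,
    anchor_dispersion: float = 0.1,
    baseline_mean: float = 12.0,
    dispersion: float = 0.5,
    dropout_keep: float = 0.8,
    library_sdlog: float = 0.3,
    dispersion_overrides: tuple[tuple[str, float], ...] = (),
) -> tuple[ad.AnnData, pd.DataFrame]:
    """TBC-only fixture for the tonotopy screen.

    The matrix contains the anchor gene (Emilin2), the requested gradient
    genes, and ``n_null_genes`` exchangeable non-gradient genes (identical
    baseline means). The anchor is expressed at ``anchor_level`` times
    baseline — it is a strong marker of this population — and carries a
    conspicuous base-high gradient with base/apex ratio ``anchor_fold``;
    both must be large enough for anchor-based ordering to approximate the
    latent position, which is what makes the screen's pseudo-spatial
    binning informative.
    """
    if n_cells < 8:
        raise ValueError("n_cells must be >= 8")
    named = [ANCHOR_GENE] + [g.gene for g in gradient_specs]
    if len(set(named)) != len(named):
        raise ValueError("duplicate gene in gradient specs (the anchor is implicit)")
    registry = [
        CellTypeSpec(
            name=TBC_TYPE,
            ensemble="surrounding",
            markers=((ANCHOR_GENE, anchor_level),),
            proportion=1.0,
        )
    ]
    config = SimConfig(
        n_cells={("P8", "cell"): n_cells},
        n_genes=1 + len(gradient_specs) + n_null_genes,
        baseline_mean=baseline_mean,
        gene_mean_sdlog=0.0,
        dispersion=dispersion,
        dropout_keep=dropout_keep,
        library_sdlog=library_sdlog,
        type_variation_sdlog=0.0,  # null genes must stay exchangeable
        dispersion_overrides=((ANCHOR_GENE, anchor_dispersion),) + tuple(dispersion_overrides),
        gradients=(GradientSpec(ANCHOR_GENE, anchor_fold, "base_high"),)
        + tuple(gradient_specs),
        seed=seed,
    )
    return simulate_counts(config, registry)
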