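"""Curated registry of mouse cochlear cell types and their marker genes.

The registry drives both the synthetic-data generator (which populations to
plant, with which marker genes up-regulated) and marker-score cell-type
assignment. It covers the 37 populations of the postnatal cochlea: lateral
wall (stria vascularis layers, spindle/root cells, fibrocytes, vasculature),
the neurosensory epithelium (hair cells and supporting-cell groups), the
spiral ganglion (neurons and glia), surrounding structures (bone lineage,
Reissner's membrane, scala vestibuli border cells, tympanic border cells),
and circulating blood cells.

Capture biases encode the known technology differences: outer hair cells
are lost during single-cell dissociation (captured only as nuclei), the
basal stria layer is nearly absent from scRNAseq, and intermediate stria
cells are over-represented there, whereas snRNAseq yields more balanced
population sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

ENSEMBLES = ("lateral_wall", "neurosensory", "ganglion", "surrounding", "circulating")
TECHNOLOGIES = ("cell", "nucleus")
STAGES = ("E16.5", "P0", "P1", "P8", "P12", "P20")

#: Default fold multiplier applied to a marker gene over baseline expression.
DEFAULT_MARKER_FOLD = 8.0


@dataclass(frozen=True)
class CellTypeSpec:
    """One cell-type population: its markers and sampling behaviour.

    Parameters
    ----------
    name
        Unique population label (e.g. ``"OHC"``, ``"fibrocyte"``).
    ensemble
        One of :data:`ENSEMBLES`.
    markers
        Tuple of ``(gene, fold)`` pairs; ``fold`` is the mean multiplier
        over baseline applied in simulation (>= 1).
    proportion
        Fraction of cells in [0, 1] before technology bias.
    capture_bias
        Per-technology multiplier (>= 0) on ``proportion``; 0 means the
        population is never captured by that technology.
    """

    name: str
    ensemble: str
    markers: tuple[tuple[str, float], ...]
    proportion: float
    capture_bias: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType({"cell": 1.0, "nucleus": 1.0})
    )

    def marker_genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.markers)


def _spec(name, ensemble, genes, proportion, bias_cell=1.0, bias_nucleus=1.0,
          fold=DEFAULT_MARKER_FOLD):
    return CellTypeSpec(
        name=name,
        ensemble=ensemble,
        markers=tuple((g, fold) for g in genes),
        proportion=proportion,
        capture_bias=MappingProxyType({"cell": bias_cell, "nucleus": bias_nucleus}),
    )


def default_registry() -> list[CellTypeSpec]:
    """Return the bundled 37-population cochlear registry.

    Marker sets are chosen so that no population's marker set is a subset
    of another's, which guarantees that marker-score assignment can
    discriminate every pair of populations (e.g. root vs spindle cells
    share Slc26a4 but differ in Epyc vs Anxa1).
    """
    p = 1.0 / 37.0
    lw, ns, gg, su, ci = ENSEMBLES
    specs = [
        # --- lateral wall ---------------------------------------------------
        _spec("marginal_stria", lw, ("Kcne1", "Bsnd"), p),
        _spec("intermediate_stria", lw, ("Tyr", "Dct", "Slc45a2"), p, bias_cell=3.0),
        _spec("basal_stria", lw, ("Atp6v0a4", "Cldn11"), p, bias_cell=0.05),
        _spec("spindle_cells", lw, ("Slc26a4", "Anxa1"), p),
        _spec("root_cells", lw, ("Slc26a4", "Epyc"), p),
        _spec("fibrocyte", lw, ("Otos", "Col9a2"), p),
        _spec("endothelial", lw, ("Esam", "Pecam1"), p),
        _spec("pericyte", lw, ("Rgs5", "Kcnj8"), p),
        _spec("smooth_muscle", lw, ("Tagln", "Acta2"), p),
        # --- neurosensory epithelium ----------------------------------------
        _spec("IHC", ns, ("Slc17a8", "Otof"), p),
        _spec("OHC", ns, ("Slc26a5", "Ikzf2"), p, bias_cell=0.0),
        _spec("SC_otog", ns, ("Otog", "Otogl", "Tectb"), p),
        _spec("interdental", ns, ("Otoa", "Ush1c"), p),
        _spec("pillar", ns, ("Lgr6", "Ednrb", "Prdm12"), p),
        _spec("deiters", ns, ("Ceacam16", "Fabp3"), p),
        _spec("SC_smpx_epyc", ns, ("Smpx", "Epyc"), p),
        _spec("SC_epyc", ns, ("Epyc", "Aqp4"), p),
        # --- spiral ganglion -------------------------------------------------
        _spec("neuron_type_I", gg, ("Nefh", "Snap25"), p, bias_nucleus=1.5),
        _spec("neuron_type_II", gg, ("Prph", "Snap25"), p, bias_nucleus=1.5),
        _spec("satellite_glia", gg, ("Mog", "Mag", "Mobp"), p),
        _spec("glial_precursor", gg, ("Olig1", "Olig2"), p),
        _spec("schwann", gg, ("Mpz", "Prx"), p),
        # --- surrounding structures ------------------------------------------
        _spec("preosteoblast", su, ("Dlx5", "Runx2"), p),
        _spec("osteoblast", su, ("Bglap", "Ifitm5", "Ibsp"), p),
        _spec("osteocyte", su, ("Phex", "Dmp1"), p),
        _spec("SS1", su, ("Osr2", "Chrdl1"), p),
        _spec("SS2", su, ("Bmp6", "Col1a1", "Slc7a11"), p),
        _spec("reissner_membrane", su, ("Slc26a7", "Slc4a11"), p),
        _spec("SVB", su, ("Fxyd2", "Kcnk2"), p),
        _spec("TBC", su, ("Emilin2", "Rarres1", "Notum"), p),
        # --- circulating cells ------------------------------------------------
        _spec("macrophage", ci, ("C1qa", "Cd68"), p),
        _spec("t_cell", ci, ("Cd3e", "Cd3d"), p),
        _spec("b_cell", ci, ("Cd79a", "Ms4a1"), p),
        _spec("nk_cell", ci, ("Nkg7", "Klrb1c"), p),
        _spec("neutrophil", ci, ("S100a8", "S100a9"), p),
        _spec("erythrocyte", ci, ("Hba-a1", "Alas2"), p),
        _spec("dendritic", ci, ("Cd209a", "Flt3"), p),
    ]
    validate_registry(specs)
    return specs


def validate_registry(registry: list[CellTypeSpec]) -> None:
    """Check registry invariants; raise ``ValueError`` on violation."""
    if not registry:
        raise ValueError("registry is empty")
    names = [s.name for s in registry]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cell-type names in registry")
    for s in registry:
        if not s.markers:
            raise ValueError(f"{s.name}: marker list is empty")
        if any(fold < 1.0 for _, fold in s.markers):
            raise ValueError(f"{s.name}: marker fold multipliers must be >= 1")
        if not 0.0 <= s.proportion <= 1.0:
            raise ValueError(f"{s.name}: proportion outside [0, 1]")
        if s.ensemble not in ENSEMBLES:
            raise ValueError(f"{s.name}: unknown ensemble {s.ensemble!r}")
        for tech, b in s.capture_bias.items():
            if tech not in TECHNOLOGIES:
                raise ValueError(f"{s.name}: unknown technology {tech!r}")
            if b < 0:
                raise ValueError(f"{s.name}: capture bias must be >= 0")
    for tech in TECHNOLOGIES:
        if sum(s.proportion * s.capture_bias.get(tech, 1.0) for s in registry) <= 0:
            raise ValueError(f"no population is capturable by technology {tech!r}")


def effective_proportions(registry: list[CellTypeSpec], technology: str) -> dict[str, float]:
    """Bias-adjusted, renormalized population proportions for one technology."""
    if technology not in TECHNOLOGIES:
        raise ValueError(f"unknown technology {technology!r}; expected one of {TECHNOLOGIES}")
    raw = {s.name: s.proportion * s.capture_bias.get(technology, 1.0) for s in registry}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}
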