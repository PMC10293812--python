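"""Study-design constants of the mouse cochlear atlas and a synthetic
gene-panel builder.

The atlas profiled three postnatal stages by scRNAseq (P8: before hearing
onset, P12: hearing onset, P20: near-mature) plus P8 snRNAseq, and
analyzed a combined panel of detected genes involved in isolated deafness
together with key genes for cochlear development and function.
"""

from __future__ import annotations

import pandas as pd

#: scRNAseq cells recovered per stage.
CELLS_PER_STAGE = {"P8": 22_827, "P12": 26_169, "P20": 39_010}

#: Cells in the merged three-stage scRNAseq dataset.
COMBINED_CELLS = 88_006

#: P8 snRNAseq nuclei.
NUCLEI_P8 = 28_822

#: Cell types in the atlas.
N_CELL_TYPES = 37

#: Spiral-ligament fibrocyte subtypes.
N_FIBROCYTE_SUBTYPES = 5

#: Detected genes involved in isolated deafness / key cochlear genes.
N_DEAFNESS_GENES = 120
N_KEY_GENES = 75
N_PANEL_GENES = N_DEAFNESS_GENES + N_KEY_GENES

#: Approximate number of gene clusters formed by the combined panel.
N_GENE_CLUSTERS = 20

#: Pseudo-spatial bins along the tonotopic axis (quartiles, base to apex).
N_TONOTOPIC_BINS = 4

#: Base/apex fold-change threshold (strict) for gradient genes.
FC_THRESHOLD = 1.3

#: Anchor gene for pseudo-spatial ordering of tympanic border cells.
ANCHOR_GENE = "Emilin2"


def combined_cell_total() -> int:
    """Merged three-stage scRNAseq cell count, from the per-stage counts."""
    return sum(CELLS_PER_STAGE.values())


# A seed list of real murine deafness / cochlear genes used to make the
# synthetic panel biologically plausible; padding gene names are clearly
# synthetic.
_DEAFNESS_SEED = (
    "Gjb2 Gjb6 Myo7a Myo15a Myo6 Myo3a Tmc1 Tmie Lhfpl5 Pcdh15 Cdh23 Ush1c "
    "Ush1g Ush2a Adgrv1 Whrn Otof Slc26a4 Slc26a5 Tecta Tectb Otog Otogl "
    "Otoa Coch Pou3f4 Pou4f3 Eya4 Kcnq1 Kcnq4 Kcne1 Tmprss3 Espn Triobp "
    "Actg1 Ceacam16 Col11a2 Marveld2 Cldn14 Strc Loxhd1 Ptprq Tprn Grxcr1 "
    "Lrtomt Smpx Wfs1 Esrrb Ildr1 Bsnd"
).split()

_KEY_SEED = (
    "Atoh1 Sox2 Pou4f3 Gata3 Six1 Eya1 Fgfr3 Fgf8 Fgf20 Bmp4 Jag1 Notch1 "
    "Hes5 Hey2 Emx2 Tbx1 Lmx1a Pax2 Otx2 Gli3 Shh Wnt5a Isl1 Neurod1 Insm1 "
    "Ikzf2 Sox10 Emilin2 Notum Rarres1"
).split()


def synthetic_deafness_panel(
    n_deafness: int = N_DEAFNESS_GENES, n_key: int = N_KEY_GENES
) -> pd.DataFrame:
    """Build a synthetic stand-in for the deafness/key-gene panel.

    Real murine deafness and cochlear-development gene symbols seed each
    panel; the remainder are clearly synthetic placeholder names. Returns
    a DataFrame with columns ``panel`` and ``gene`` (unique pairs),
    suitable for :func:`cochlea_atlas_kit.io.write_table`.
    """
    def build(seed, n, prefix):
        names = list(dict.fromkeys(seed))[:n]
        names += [f"{prefix}{i:03d}" for i in range(1, n - len(names) + 1)]
        return names

    deaf = build(_DEAFNESS_SEED, n_deafness, "synth-deafness-")
    key = [g for g in build(_KEY_SEED, n_key, "synth-key-") if g not in set(deaf)]
    key += [f"synth-key-x{i:03d}" for i in range(1, n_key - len(key) + 1)]
    return pd.DataFrame(
        {
            "panel": ["deafness"] * n_deafness + ["key"] * n_key,
            "gene": deaf + key,
        }
    )
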