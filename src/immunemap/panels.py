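"""Default gene panels and gene-set collections for immune scoring.

The feature matrix needs three configurable gene resources: a 31-gene panel
of immune-regulation / antigen-presentation genes, 28 immune-cell-type marker
sets, and 217 immune-signalling pathway sets. The cell-type roster follows
the 28-population pan-cancer immunome convention (activated/memory T-cell
subsets, NK subsets, DC subsets, MDSC, Treg, ...). Marker content here is a
documented placeholder: a core of well-established human markers per cell
type, padded with synthetic genes so set sizes are realistic. All three
resources can be replaced by user GMT/YAML files of the same shapes.

Synthetic filler genes are named ``IMGENE<k>``; they are deterministic, so
every process sees the same universe.
"""

from __future__ import annotations

import numpy as np

from .types import GeneSetCollection

# ---------------------------------------------------------------------------
# 31 immune regulation / antigen presentation genes (checkpoints,
# costimulation, MHC machinery)
IMMUNE_GENES_31: tuple[str, ...] = (
    "PDCD1", "CD274", "PDCD1LG2", "CTLA4", "ICOS", "IDO1", "TIGIT", "LAG3",
    "HAVCR2", "BTLA", "CD27", "CD28", "CD40", "CD40LG", "CD80", "CD86",
    "TNFRSF9", "TNFRSF4", "TNFRSF18", "CD276", "CD48", "TAP1", "TAP2", "B2M",
    "HLA-A", "HLA-B", "HLA-C", "HLA-DRA", "HLA-DPB1", "HLA-DQA1", "CIITA",
)

# POPLAR-style prognostic panel: effector T-cell chemotaxis plus
# IFN-gamma-associated cytotoxicity
POPLAR_GENES: tuple[str, ...] = (
    "CD8A", "CXCL9", "CXCL10", "IFNG", "GZMA", "GZMB", "EOMES", "TBX21",
)

CYTOLYTIC_GENES: tuple[str, ...] = ("GZMA", "PRF1")

# the 12 anti-tumor and 8 pro-tumor populations used in the
# infiltration-balance correlation
ANTI_TUMOR_CELLS: tuple[str, ...] = (
    "ActCD4", "ActCD8", "TcmCD4", "TcmCD8", "TemCD4", "TemCD8",
    "Th1", "Th17", "ActDC", "CD56briNK", "NK", "NKT",
)
PRO_TUMOR_CELLS: tuple[str, ...] = (
    "Treg", "Th2", "CD56dimNK", "imDC", "TAM", "MDSC", "Neutrophil", "pDC",
)

# core human markers for each of the 28 populations; padded with synthetic
# genes to 12 members each
_CELL_CORE_MARKERS: dict[str, list[str]] = {
    "ActCD4": ["CD4", "IL2RA", "CD69", "TNFRSF4"],
    "ActCD8": ["CD8A", "CD8B", "GZMB", "PRF1", "IFNG", "KLRG1"],
    "TcmCD4": ["CD4", "CCR7", "SELL", "IL7R"],
    "TcmCD8": ["CD8A", "CCR7", "SELL", "IL7R"],
    "TemCD4": ["CD4", "GZMA", "KLRG1", "CCL5"],
    "TemCD8": ["CD8A", "GZMA", "GZMK", "EOMES"],
    "Th1": ["TBX21", "IFNG", "CXCR3", "IL12RB2", "STAT4"],
    "Th2": ["GATA3", "IL4", "IL5", "CCR4"],
    "Th17": ["RORC", "IL17A", "IL23R", "CCR6"],
    "Tfh": ["CXCR5", "BCL6", "ICOS", "IL21"],
    "Treg": ["FOXP3", "IL2RA", "CTLA4", "IKZF2"],
    "Tgd": ["TRDC", "TRGC1", "KLRC1"],
    "NKT": ["CD3E", "KLRB1", "ZBTB16", "GZMB"],
    "NK": ["NCR1", "KLRD1", "NKG7", "GNLY", "PRF1"],
    "CD56briNK": ["NCAM1", "XCL1", "XCL2", "KLRC1"],
    "CD56dimNK": ["FCGR3A", "KIR2DL1", "KIR2DL3", "S1PR5"],
    "ActB": ["CD19", "MS4A1", "CD69", "CD86"],
    "ImmB": ["CD19", "MS4A1", "CD38", "MME"],
    "MemB": ["CD19", "MS4A1", "CD27", "TNFRSF13B"],
    "ActDC": ["CD83", "CCR7", "LAMP3", "CD86", "CXCL9", "CXCL10"],
    "imDC": ["CD1C", "CD1A", "ITGAX", "F13A1"],
    "pDC": ["LILRA4", "CLEC4C", "IL3RA", "IRF7"],
    "TAM": ["CD68", "CD163", "MRC1", "MSR1", "CSF1R"],
    "Monocyte": ["CD14", "FCN1", "S100A8", "S100A9"],
    "MDSC": ["ITGAM", "ARG1", "S100A8", "IL4R", "NOS2"],
    "Neutrophil": ["FCGR3B", "CSF3R", "CXCR2", "FUT4"],
    "Mast": ["TPSAB1", "TPSB2", "CPA3", "MS4A2"],
    "Eosinophil": ["SIGLEC8", "CCR3", "IL5RA", "PRG2"],
}

CELL_TYPES_28: tuple[str, ...] = tuple(_CELL_CORE_MARKERS)

# genes whose expression the simulator elevates in latently hot loci:
# effector/checkpoint program plus the markers of effector cell populations
_HOT_EXTRA: tuple[str, ...] = (
    "PRF1", "PDCD1", "CD274", "CTLA4", "IDO1", "LAG3", "TIGIT", "GZMK",
    "NKG7", "GNLY", "CCL5", "CXCR3", "STAT1", "STAT4",
)
_HOT_EFFECTOR_SETS: tuple[str, ...] = (
    "ActCD8", "ActCD4", "TemCD8", "TemCD4", "Th1", "NK", "NKT", "CD56briNK", "ActDC",
)

N_PATHWAYS = 217
_CELL_SET_SIZE = 12
_PATHWAY_MIN, _PATHWAY_MAX = 10, 25
_N_FILLER = 2500
_PANEL_SEED = 20240917  # fixed: panels must be identical across processes


def _filler_genes(n: int = _N_FILLER) -> list[str]:
    return [f"IMGENE{k:04d}" for k in range(n)]


def hot_program_genes() -> list[str]:
    """Genes planted as elevated in immunologically hot loci."""
    genes: list[str] = list(POPLAR_GENES) + list(_HOT_EXTRA)
    for cell in _HOT_EFFECTOR_SETS:
        genes.extend(_CELL_CORE_MARKERS[cell])
    seen: set[str] = set()
    ordered = [g for g in genes if not (g in seen or seen.add(g))]
    return ordered


def suppressive_program_genes() -> list[str]:
    """Markers of pro-tumor suppressive populations (Treg, MDSC, TAM, ...)
    that the simulator co-elevates in hot loci as infiltration feedback."""
    hot = set(hot_program_genes())
    genes: list[str] = []
    seen: set[str] = set()
    for cell in PRO_TUMOR_CELLS:
        for g in _CELL_CORE_MARKERS[cell]:
            if g not in hot and g not in seen:
                seen.add(g)
                genes.append(g)
    return genes


def cell_marker_genes() -> list[str]:
    """Union of all 28 cell-type set members (core markers plus filler)."""
    seen: set[str] = set()
    genes: list[str] = []
    for members in default_cell_type_sets().sets.values():
        for g in members:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    return genes


def default_cell_type_sets() -> GeneSetCollection:
    """28 immune-cell marker sets (core markers + deterministic filler)."""
    rng = np.random.default_rng(_PANEL_SEED)
    filler = _filler_genes()
    sets: dict[str, list[str]] = {}
    for name, core in _CELL_CORE_MARKERS.items():
        pad = rng.choice(filler, size=_CELL_SET_SIZE - len(core), replace=False)
        sets[name] = list(core) + [str(g) for g in pad]
    return GeneSetCollection(sets)


def default_pathway_sets() -> GeneSetCollection:
    """217 immune-signalling pathway sets (placeholder content).

    Roughly a quarter of the sets carry hot-program genes, reflecting that
    the pathway panel is immune-centred; the rest are background sets drawn
    from the filler universe.
    """
    rng = np.random.default_rng(_PANEL_SEED + 1)
    filler = _filler_genes()
    hot = hot_program_genes()
    sets: dict[str, list[str]] = {}
    for k in range(N_PATHWAYS):
        size = int(rng.integers(_PATHWAY_MIN, _PATHWAY_MAX + 1))
        name = f"PATHWAY_{k + 1:03d}"
        if k % 4 == 0:  # immune-effector-linked pathway
            n_hot = int(rng.integers(3, 7))
            members = [str(g) for g in rng.choice(hot, size=n_hot, replace=False)]
            members += [str(g) for g in rng.choice(filler, size=size - n_hot, replace=False)]
        else:
            members = [str(g) for g in rng.choice(filler, size=size, replace=False)]
        sets[name] = members
    return GeneSetCollection(sets)


def default_immune_gene_panel() -> list[str]:
    return list(IMMUNE_GENES_31)


def gene_universe() -> list[str]:
    """All gene symbols the default panels and simulator know about."""
    genes: list[str] = []
    seen: set[str] = set()
    for source in (
        list(IMMUNE_GENES_31),
        list(POPLAR_GENES),
        list(CYTOLYTIC_GENES),
        hot_program_genes(),
        [g for s in default_cell_type_sets().sets.values() for g in s],
        [g for s in default_pathway_sets().sets.values() for g in s],
        _filler_genes(),
    ):
        for g in source:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    return genes


def write_default_collections(outdir) -> dict[str, str]:
    """Materialize the editable default panels as GMT/YAML files."""
    import os

    from .io import write_gene_panel, write_gmt

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "immune_genes": os.path.join(outdir, "immune_genes_31.yaml"),
        "pathways": os.path.join(outdir, "pathways_217.gmt"),
        "cell_types": os.path.join(outdir, "cell_types_28.gmt"),
    }
    write_gene_panel(default_immune_gene_panel(), paths["immune_genes"])
    write_gmt(default_pathway_sets(), paths["pathways"])
    write_gmt(default_cell_type_sets(), paths["cell_types"])
    return paths
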