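"""The 96-gene single-cell RT-qPCR panel and the marker sets used for classification.

The panel covers neuronal identity, cortical layer identity, neurotransmitter
phenotype, synaptic function, glial genes, housekeepers and negative-control
genes normally expressed only in kidney or liver. Marker sets are the canonical
ones used to call phenotype and laminar identity from detection patterns:

* neuron: any of MAP2 / NCAM1 / TUBB3 detected
* deep layer: BCL11B (CTIP2), TBR1
* upper layer: CUX1, POU3F2 (BRN2), SATB2
* GABAergic: GAD1 (in a cell already called a neuron)
* glutamatergic: SLC17A7 (VGLUT1)
* glia: GFAP, OLIG2
"""

from __future__ import annotations

from dataclasses import dataclass, field

HOUSEKEEPERS = ("GAPDH", "ACTB")
NEURON_MARKERS = ("MAP2", "NCAM1", "TUBB3")
DEEP_MARKERS = ("BCL11B", "TBR1")
UPPER_MARKERS = ("CUX1", "POU3F2", "SATB2")
GABA_MARKER = "GAD1"
GLUT_MARKER = "SLC17A7"
GLIA_MARKERS = ("GFAP", "OLIG2")

#: Full 96-gene assay panel (housekeepers, identity/layer markers, receptors,
#: channels, synaptic genes, development/regional genes, glial genes and
#: kidney/liver negative controls).
PANEL_GENES: tuple[str, ...] = (
    # housekeepers
    "GAPDH", "ACTB",
    # neuronal identity
    "MAP2", "NCAM1", "TUBB3",
    # deep layer markers
    "BCL11B", "TBR1",
    # upper layer markers
    "CUX1", "POU3F2", "SATB2",
    # neurotransmitter phenotype
    "GAD1", "SLC17A7", "SLC17A6", "SLC32A1",
    # glial genes
    "GFAP", "OLIG2", "S100B", "AQP4", "PDGFRA", "SLC1A3",
    # glutamate receptors
    "GRIA1", "GRIA2", "GRIA3", "GRIN1", "GRIN2A", "GRIN2B", "GRM5", "GRIK2",
    # GABA receptors
    "GABRA1", "GABRB2", "GABBR1",
    # ion channels
    "SCN1A", "SCN2A", "KCNQ2", "KCNQ3", "CACNA1A", "CACNA1C",
    # synaptic structure and release
    "SYN1", "SYN2", "SYP", "SYT1", "SNAP25", "STX1A", "VAMP2",
    "DLG4", "HOMER1", "SHANK3", "GPHN", "NLGN1", "NRXN1", "ANK2",
    # cortical / regional identity and neural development
    "FEZF2", "NEUROD6", "ADAMTS3", "FOXP2", "TLE4", "FOXG1", "EMX2",
    "PAX6", "EOMES", "RELN", "NEUROD2", "NEUROG2", "ASCL1", "DLX1",
    "DLX2", "LHX2", "OTX1", "SOX2", "NES", "VIM", "PTPRZ1",
    # interneuron subtype markers
    "CALB1", "CALB2", "PVALB", "SST", "VIP", "NPY",
    # neuronal cytoskeleton and maturation
    "DCX", "ROBO2", "MAP1B", "CDK5R1", "NEFL", "NEFM", "RBFOX3", "ENO2",
    # activity and plasticity
    "BDNF", "NTRK2", "CAMK2A", "ARC", "EGR1", "FOS",
    # negative controls (kidney / liver restricted)
    "ALB", "CYP3A4", "UMOD", "SLC34A1",
)

assert len(PANEL_GENES) == 96, "assay panel must contain exactly 96 genes"
assert len(set(PANEL_GENES)) == 96, "panel gene symbols must be unique"


@dataclass(frozen=True)
class MarkerPanel:
    """Marker gene sets driving phenotype and cortical-layer calls.

    The defaults are the canonical sets; individual sets may be overridden
    (e.g. to drop a marker excluded for poor inter-chip reliability) but must
    stay disjoint and within the assay panel.
    """

    neuron_markers: frozenset[str] = frozenset(NEURON_MARKERS)
    deep_markers: frozenset[str] = frozenset(DEEP_MARKERS)
    upper_markers: frozenset[str] = frozenset(UPPER_MARKERS)
    gaba_marker: str = GABA_MARKER
    glut_marker: str = GLUT_MARKER
    glia_markers: frozenset[str] = frozenset(GLIA_MARKERS)
    housekeepers: frozenset[str] = frozenset(HOUSEKEEPERS)

    def __post_init__(self) -> None:
        groups = [
            set(self.neuron_markers),
            set(self.deep_markers),
            set(self.upper_markers),
            {self.gaba_marker},
            {self.glut_marker},
            set(self.glia_markers),
            set(self.housekeepers),
        ]
        n_union = len(set().union(*groups))
        if n_union != sum(len(g) for g in groups):
            raise ValueError("marker sets must be pairwise disjoint")

    @property
    def all_markers(self) -> frozenset[str]:
        return frozenset(
            set(self.neuron_markers)
            | set(self.deep_markers)
            | set(self.upper_markers)
            | {self.gaba_marker, self.glut_marker}
            | set(self.glia_markers)
            | set(self.housekeepers)
        )

    def missing_from(self, genes) -> list[str]:
        """Markers absent from an iterable of gene ids, sorted."""
        return sorted(self.all_markers - set(genes))
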