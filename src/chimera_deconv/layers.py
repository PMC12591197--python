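"""Gene-level layer analysis.

Pools allele counts over each gene's diagnostic sites, computes the
donor-O allele frequency f_O per gene, normalizes it into an "L1-normalized
expression percentage" (f_O divided by the tissue-level L1 fraction, capped
at 100%), classifies genes as L1-specific, L2/L3-specific, shared or
unclassified, and infers the chimera's layer arrangement from declared
marker genes (e.g. PDF1 with known L1-specific expression, prosystemin/SYS
with known L2/L3-specific expression).

The percentage normalization is deliberately isolated in
:func:`pct_expression_L1`: a gene expressed only in L1 has f_O equal to the
tissue's L1 transcript fraction, so dividing by that fraction rescales full
L1 specificity to 100%.  Genes whose f_O exceeds the tissue fraction (L1
expression above the tissue-average rate) are capped at 100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from intervaltree import IntervalTree

from .errors import ConfigurationError, EstimationError
from .origin import BOTH, C_ONLY, O_ONLY, UNINFORMATIVE, AlleleCounts, OriginCall
from .vcf_io import GeneInterval

__all__ = [
    "GeneLayerStats",
    "MarkerDeclaration",
    "ChimeraStructure",
    "L1_SPECIFIC",
    "L2L3_SPECIFIC",
    "SHARED",
    "UNCLASSIFIED",
    "LAYER_CLASSES",
    "PERICLINAL",
    "INCONSISTENT",
    "UNDETERMINED",
    "assign_sites_to_genes",
    "pool_gene_counts",
    "pct_expression_L1",
    "classify_gene_layer",
    "annotate_gene_layers",
    "infer_structure",
]

logger = logging.getLogger(__name__)

L1_SPECIFIC = "L1_SPECIFIC"
L2L3_SPECIFIC = "L2L3_SPECIFIC"
SHARED = "SHARED"
UNCLASSIFIED = "UNCLASSIFIED"
LAYER_CLASSES = (L1_SPECIFIC, L2L3_SPECIFIC, SHARED, UNCLASSIFIED)

PERICLINAL = "PERICLINAL"
INCONSISTENT = "INCONSISTENT"
UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class GeneLayerStats:
    """Pooled allele evidence and layer assignment for one gene."""

    gene_id: str
    n_sites: int
    n_O: int
    n_C: int
    f_O: float | None = None
    pct_L1: float | None = None
    layer_class: str = UNCLASSIFIED


@dataclass(frozen=True)
class MarkerDeclaration:
    """A gene whose layer specificity is known a priori (declared, never
    inferred from the data at hand)."""

    gene_id: str
    known_layer: str  # "L1" or "L2L3"

    def __post_init__(self):
        if self.known_layer not in ("L1", "L2L3"):
            raise ConfigurationError(
                f"{self.gene_id}: known_layer must be L1 or L2L3, "
                f"got {self.known_layer!r}")


@dataclass(frozen=True)
class ChimeraStructure:
    """Layer arrangement inferred from marker-gene origin calls."""

    arrangement: str  # PERICLINAL, INCONSISTENT or UNDETERMINED
    l1_donor: str | None  # "O" or "C" when periclinal
    l2l3_donor: str | None
    evidence: dict  # gene_id -> origin category


def assign_sites_to_genes(
    counts: list[AlleleCounts],
    intervals: list[GeneInterval],
) -> dict[tuple[str, int], str]:
    """Map each site (chrom, 1-based pos) to the unique gene containing it.

    Sites overlapping more than one gene are excluded (ambiguous
    attribution) and logged; sites in no gene are simply absent from the
    map.  They all still count toward tissue-level composition.
    """
    if not intervals:
        raise ConfigurationError("empty gene interval list")
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end,
                                                        iv.gene_id)
    gene_map: dict[tuple[str, int], str] = {}
    n_ambiguous = 0
    for c in counts:
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        hits = tree[c.pos - 1]  # VCF pos P overlaps [start, end) iff start <= P-1 < end
        if len(hits) == 1:
            gene_map[(c.chrom, c.pos)] = next(iter(hits)).data
        elif len(hits) > 1:
            n_ambiguous += 1
    if n_ambiguous:
        logger.info("assign_sites_to_genes: excluded %d multi-gene sites",
                    n_ambiguous)
    return gene_map


def pool_gene_counts(
    counts: list[AlleleCounts],
    gene_map: dict[tuple[str, int], str],
) -> list[GeneLayerStats]:
    """Sum donor-allele reads over each gene's diagnostic sites.

    Genes with zero informative reads get f_O missing and stay
    UNCLASSIFIED.  Output is sorted by gene_id.
    """
    if not gene_map:
        raise ConfigurationError("empty site-to-gene map")
    acc: dict[str, list[int]] = {}
    for c in counts:
        gene = gene_map.get((c.chrom, c.pos))
        if gene is None:
            continue
        rec = acc.setdefault(gene, [0, 0, 0])
        rec[0] += c.n_O
        rec[1] += c.n_C
        rec[2] += 1
    out = []
    for gene_id in sorted(acc):
        n_o, n_c, n_sites = acc[gene_id]
        f_o = n_o / (n_o + n_c) if n_o + n_c > 0 else None
        out.append(GeneLayerStats(gene_id=gene_id, n_sites=n_sites,
                                  n_O=n_o, n_C=n_c, f_O=f_o))
    return out


def pct_expression_L1(stats: GeneLayerStats, tissue_L1_fraction: float) -> float:
    """L1-normalized expression percentage: min(f_O / L1 fraction, 1) x 100.

    ``tissue_L1_fraction`` is the tissue-level L1 (donor-O) transcript
    fraction p_O from the composition stage.
    """
    if not (0.0 < tissue_L1_fraction <= 1.0):
        raise EstimationError(
            f"tissue_L1_fraction = {tissue_L1_fraction} outside (0, 1]")
    if stats.f_O is None:
        raise EstimationError(f"gene {stats.gene_id}: f_O undefined")
    return min(stats.f_O / tissue_L1_fraction, 1.0) * 100.0


def classify_gene_layer(stats: GeneLayerStats, min_reads: int = 20,
                        hi: float = 0.95, lo: float = 0.05) -> str:
    """Layer class from the gene's pooled donor-O allele frequency."""
    if hi <= lo:
        raise ConfigurationError(f"hi ({hi}) must exceed lo ({lo})")
    if stats.n_O + stats.n_C < min_reads or stats.f_O is None:
        return UNCLASSIFIED
    if stats.f_O >= hi:
        return L1_SPECIFIC
    if stats.f_O <= lo:
        return L2L3_SPECIFIC
    return SHARED


def annotate_gene_layers(
    stats: list[GeneLayerStats],
    tissue_L1_fraction: float,
    min_reads: int = 20,
    hi: float = 0.95,
    lo: float = 0.05,
) -> list[GeneLayerStats]:
    """Fill pct_L1 and layer_class on pooled gene stats."""
    out = []
    for s in stats:
        cls = classify_gene_layer(s, min_reads=min_reads, hi=hi, lo=lo)
        pct = (pct_expression_L1(s, tissue_L1_fraction)
               if s.f_O is not None else None)
        out.append(replace(s, pct_L1=pct, layer_class=cls))
    return out


def infer_structure(
    marker_calls: list[tuple[MarkerDeclaration, OriginCall]],
) -> ChimeraStructure:
    """Infer the chimera's layer arrangement from marker-gene origin calls.

    PERICLINAL requires every L1 marker to resolve to one donor and every
    L2/L3 marker to the other; any UNINFORMATIVE marker yields
    UNDETERMINED; any other configuration (including a marker called BOTH)
    is INCONSISTENT.
    """
    l1 = [(m, c) for m, c in marker_calls if m.known_layer == "L1"]
    l23 = [(m, c) for m, c in marker_calls if m.known_layer == "L2L3"]
    if not l1 or not l23:
        raise ConfigurationError(
            "structure inference needs >= 1 marker of each layer "
            f"(got {len(l1)} L1, {len(l23)} L2/L3)")
    evidence = {m.gene_id: c.category for m, c in marker_calls}
    cats_l1 = {c.category for _, c in l1}
    cats_l23 = {c.category for _, c in l23}
    if UNINFORMATIVE in cats_l1 | cats_l23:
        return ChimeraStructure(UNDETERMINED, None, None, evidence)
    if cats_l1 == {O_ONLY} and cats_l23 == {C_ONLY}:
        return ChimeraStructure(PERICLINAL, "O", "C", evidence)
    if cats_l1 == {C_ONLY} and cats_l23 == {O_ONLY}:
        return ChimeraStructure(PERICLINAL, "C", "O", evidence)
    return ChimeraStructure(INCONSISTENT, None, None, evidence)
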