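"""Donor-diagnostic SNP discovery.

A diagnostic site is a position where the two chimera donors are confidently
homozygous for *different* alleles, so that any sequencing read covering the
site identifies its donor of origin.  Homozygosity is taken from the
genotype call, never re-derived from allele depths; sites with a missing
genotype in either donor are excluded.  Sites present in only one donor's
call set are excluded by default (a per-donor VCF of unknown completeness
does not license "absent means homozygous reference"); the alternative
convention is available via ``absent_means_homref``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ConfigurationError
from .vcf_io import VariantSite

__all__ = [
    "DiagnosticSite",
    "DiagnosticFilters",
    "find_diagnostic_sites",
    "swap_donors",
]

_SNP_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class DiagnosticSite:
    """A homozygous-divergent site: ``allele_O`` tags donor O, ``allele_C``
    donor C.  (chrom, pos) is unique within a set."""

    chrom: str
    pos: int
    allele_O: str
    allele_C: str
    qual_O: float | None = None
    qual_C: float | None = None
    depth_O: int | None = None
    depth_C: int | None = None

    def __post_init__(self):
        if not self.allele_O or not self.allele_C:
            raise ConfigurationError(f"{self.chrom}:{self.pos}: empty allele")
        if self.allele_O == self.allele_C:
            raise ConfigurationError(
                f"{self.chrom}:{self.pos}: alleles identical ({self.allele_O})"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class DiagnosticFilters:
    """Confidence filters applied to each donor call independently.

    Defaults (depth >= 10 reads, QUAL >= 30, biallelic SNPs only) are this
    package's choices, exposed in configuration.
    """

    min_depth: int = 10
    min_qual: float = 30.0
    require_biallelic: bool = True
    snps_only: bool = True
    absent_means_homref: bool = False

    def __post_init__(self):
        if self.min_depth < 1:
            raise ConfigurationError("min_depth must be >= 1")
        if self.min_qual < 0:
            raise ConfigurationError("min_qual must be >= 0")


def _passes(site: VariantSite, f: DiagnosticFilters) -> bool:
    if f.require_biallelic and len(site.alts) > 1:
        return False
    if site.qual is None or site.qual < f.min_qual:
        return False
    d = site.depth
    if d is None or d < f.min_depth:
        return False
    return True


def _is_snp_allele(a: str) -> bool:
    return len(a) == 1 and a.upper() in _SNP_BASES


def _index(sites: list[VariantSite], label: str) -> dict[tuple[str, int], VariantSite]:
    idx: dict[tuple[str, int], VariantSite] = {}
    for s in sites:
        key = (s.chrom, s.pos)
        if key in idx:
            raise ConfigurationError(f"{label}: duplicate record at {s.chrom}:{s.pos}")
        idx[key] = s
    return idx


def find_diagnostic_sites(
    donor_O: list[VariantSite],
    donor_C: list[VariantSite],
    filters: DiagnosticFilters = DiagnosticFilters(),
) -> list[DiagnosticSite]:
    """Identify homozygous-divergent sites between the two donor call sets.

    Returns sites sorted by (chrom, pos).  Raises
    :class:`ConfigurationError` when the two call sets share no chromosome
    names (a likely reference mismatch).
    """
    idx_o = _index(donor_O, "donor_O")
    idx_c = _index(donor_C, "donor_C")
    chroms_o = {c for c, _ in idx_o}
    chroms_c = {c for c, _ in idx_c}
    if chroms_o and chroms_c and not (chroms_o & chroms_c):
        raise ConfigurationError(
            "donor VCFs share no chromosome names: "
            f"{sorted(chroms_o)[:3]} vs {sorted(chroms_c)[:3]}"
        )
    out: list[DiagnosticSite] = []
    keys = set(idx_o) & set(idx_c)
    for key in sorted(keys):
        ds = _diagnostic_from_pair(idx_o[key], idx_c[key], filters)
        if ds is not None:
            out.append(ds)
    if filters.absent_means_homref:
        for key in sorted((set(idx_o) ^ set(idx_c))):
            present, o_side = (idx_o, True) if key in idx_o else (idx_c, False)
            ds = _diagnostic_vs_homref(present[key], o_side, filters)
            if ds is not None:
                out.append(ds)
        out.sort(key=lambda d: d.key)
    return out


def _diagnostic_from_pair(
    so: VariantSite, sc: VariantSite, f: DiagnosticFilters
) -> DiagnosticSite | None:
    a_o = so.homozygous_allele()
    a_c = sc.homozygous_allele()
    if a_o is None or a_c is None:
        return None
    a_o, a_c = a_o.upper(), a_c.upper()
    if a_o == a_c:
        return None
    if f.snps_only and not (_is_snp_allele(a_o) and _is_snp_allele(a_c)):
        return None
    if not (_passes(so, f) and _passes(sc, f)):
        return None
    return DiagnosticSite(
        chrom=so.chrom, pos=so.pos, allele_O=a_o, allele_C=a_c,
        qual_O=so.qual, qual_C=sc.qual, depth_O=so.depth, depth_C=sc.depth,
    )


def _diagnostic_vs_homref(
    present: VariantSite, present_is_O: bool, f: DiagnosticFilters
) -> DiagnosticSite | None:
    """Under absent_means_homref, a site called in one donor only is paired
    with an assumed hom-ref call in the other donor; the assumed side is
    exempt from depth/qual filters because no call was attempted."""
    a = present.homozygous_allele()
    if a is None:
        return None
    a = a.upper()
    ref = present.ref.upper()
    if a == ref:
        return None
    if f.snps_only and not (_is_snp_allele(a) and _is_snp_allele(ref)):
        return None
    if not _passes(present, f):
        return None
    if present_is_O:
        return DiagnosticSite(chrom=present.chrom, pos=present.pos,
                              allele_O=a, allele_C=ref,
                              qual_O=present.qual, depth_O=present.depth)
    return DiagnosticSite(chrom=present.chrom, pos=present.pos,
                          allele_O=ref, allele_C=a,
                          qual_C=present.qual, depth_C=present.depth)


def swap_donors(sites: list[DiagnosticSite]) -> list[DiagnosticSite]:
    """Exchange the donor roles at every site.  Involution: applying twice
    returns the input."""
    return [
        replace(s, allele_O=s.allele_C, allele_C=s.allele_O,
                qual_O=s.qual_C, qual_C=s.qual_O,
                depth_O=s.depth_C, depth_C=s.depth_O)
        for s in sites
    ]
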