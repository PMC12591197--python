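"""Per-site donor-of-origin classification in chimera tissue.

At every diagnostic site the chimera's allelic depths are partitioned into
reads carrying the donor-O allele (``n_O``), the donor-C allele (``n_C``)
and anything else (``n_other``).  A site is then labelled O_ONLY, C_ONLY,
BOTH or UNINFORMATIVE; an allele counts as *present* only when it clears
both an absolute read floor and a relative fraction floor, which keeps the
call stable across the depth range real tissues produce.  Reads in
``n_other`` never contribute to the donor-allele fraction f_O; sites where
they dominate are voided as likely mismapping artifacts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .diagnostics import DiagnosticSite
from .errors import ConfigurationError
from .vcf_io import VariantSite

__all__ = [
    "AlleleCounts",
    "OriginCall",
    "OriginThresholds",
    "O_ONLY",
    "C_ONLY",
    "BOTH",
    "UNINFORMATIVE",
    "CATEGORIES",
    "count_alleles",
    "classify_site",
    "classify_counts",
    "tabulate_origins",
]

logger = logging.getLogger(__name__)

O_ONLY = "O_ONLY"
C_ONLY = "C_ONLY"
BOTH = "BOTH"
UNINFORMATIVE = "UNINFORMATIVE"
CATEGORIES = (O_ONLY, C_ONLY, BOTH, UNINFORMATIVE)


@dataclass(frozen=True)
class AlleleCounts:
    """Read counts at one diagnostic site in one chimera sample.

    ``covered`` is False for diagnostic sites absent from the chimera call
    set; they are retained with all-zero counts so that category counts are
    conserved and the expressed fraction of diagnostic sites is reportable.
    """

    chrom: str
    pos: int
    sample_id: str
    n_O: int
    n_C: int
    n_other: int = 0
    covered: bool = True

    def __post_init__(self):
        if min(self.n_O, self.n_C, self.n_other) < 0:
            raise ConfigurationError(f"{self.chrom}:{self.pos}: negative count")

    @property
    def n(self) -> int:
        """Informative depth: donor-allele reads only."""
        return self.n_O + self.n_C

    @property
    def f_O(self) -> float | None:
        """Donor-O allele fraction among informative reads."""
        return self.n_O / self.n if self.n > 0 else None


@dataclass(frozen=True)
class OriginCall:
    chrom: str
    pos: int
    category: str
    n_O: int
    n_C: int
    f_O: float | None

    @property
    def informative(self) -> bool:
        return self.category != UNINFORMATIVE


@dataclass(frozen=True)
class OriginThresholds:
    """Calling thresholds; all are this package's choices, surfaced in
    configuration.

    An allele is *present* iff its reads >= ``min_allele_reads`` AND its
    fraction of informative reads >= ``min_allele_frac``.
    """

    min_total: int = 10
    min_allele_reads: int = 3
    min_allele_frac: float = 0.05
    max_other_frac: float = 0.2

    def __post_init__(self):
        if self.min_total < 1:
            raise ConfigurationError("min_total must be >= 1")
        if not (0 <= self.min_allele_frac < 0.5):
            raise ConfigurationError("min_allele_frac must be in [0, 0.5)")


def count_alleles(
    chimera: list[VariantSite],
    sites: list[DiagnosticSite],
    sample: str,
) -> list[AlleleCounts]:
    """Map the chimera's allelic depths onto donor alleles at each
    diagnostic site.

    Allele strings are compared uppercased.  Depths of alleles matching
    neither donor allele are summed into ``n_other``.  Diagnostic sites not
    present in the chimera call set are emitted with zero counts and
    ``covered=False``.
    """
    idx: dict[tuple[str, int], VariantSite] = {}
    for rec in chimera:
        if rec.sample != sample:
            raise ConfigurationError(
                f"chimera record at {rec.chrom}:{rec.pos} is for sample "
                f"{rec.sample!r}, expected {sample!r}"
            )
        idx[(rec.chrom, rec.pos)] = rec
    out: list[AlleleCounts] = []
    n_uncovered = 0
    for ds in sites:
        rec = idx.get(ds.key)
        if rec is None or rec.allele_depths is None:
            out.append(AlleleCounts(ds.chrom, ds.pos, sample, 0, 0, 0,
                                    covered=False))
            n_uncovered += 1
            continue
        n_o = n_c = n_other = 0
        for allele, depth in zip(rec.alleles, rec.allele_depths):
            a = allele.upper()
            if a == ds.allele_O:
                n_o += depth
            elif a == ds.allele_C:
                n_c += depth
            else:
                n_other += depth
        out.append(AlleleCounts(ds.chrom, ds.pos, sample, n_o, n_c, n_other))
    if n_uncovered:
        logger.info("count_alleles: %d/%d diagnostic sites uncovered in %s",
                    n_uncovered, len(sites), sample)
    return out


def classify_site(counts: AlleleCounts,
                  t: OriginThresholds = OriginThresholds()) -> OriginCall:
    """Classify one site's donor of origin from its allele counts."""
    n = counts.n
    total = n + counts.n_other
    category = UNINFORMATIVE
    if n >= t.min_total and (total == 0 or counts.n_other / total <= t.max_other_frac):
        o_present = (counts.n_O >= t.min_allele_reads
                     and counts.n_O / n >= t.min_allele_frac)
        c_present = (counts.n_C >= t.min_allele_reads
                     and counts.n_C / n >= t.min_allele_frac)
        if o_present and c_present:
            category = BOTH
        elif o_present:
            category = O_ONLY
        elif c_present:
            category = C_ONLY
    return OriginCall(chrom=counts.chrom, pos=counts.pos, category=category,
                      n_O=counts.n_O, n_C=counts.n_C, f_O=counts.f_O)


def classify_counts(counts: list[AlleleCounts],
                    t: OriginThresholds = OriginThresholds()) -> list[OriginCall]:
    return [classify_site(c, t) for c in counts]


def tabulate_origins(calls: list[OriginCall]) -> dict[str, int]:
    """Category counts; always contains every category and sums to the
    input length."""
    counter = Counter(call.category for call in calls)
    unknown = set(counter) - set(CATEGORIES)
    if unknown:
        raise ConfigurationError(f"unknown categories {sorted(unknown)}")
    return {cat: counter.get(cat, 0) for cat in CATEGORIES}
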