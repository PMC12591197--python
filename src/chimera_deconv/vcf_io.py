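"""Reading and writing the standard formats the pipeline touches.

VCF (via pysam), BED4+ gene intervals, and the tab-separated tables used to
exchange every tabular domain type between pipeline stages.  Coordinates are
kept native to each format: VCF positions are 1-based, BED intervals are
0-based half-open, and a VCF site at position P overlaps a BED interval
[start, end) iff start <= P - 1 < end.
"""

from __future__ import annotations

import dataclasses
import math
import types
import typing
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

from .errors import ConfigurationError, VcfParseError

__all__ = [
    "VariantSite",
    "GeneInterval",
    "read_vcf",
    "read_gene_bed",
    "write_table",
    "read_table",
]

# how total_depth relates to the allelic depths of a record
DIALECT_AD_SUM = "ad_sum"        # DP equals the sum of AD (or DP absent)
DIALECT_DP_EXTRA = "dp_extra"    # DP > sum(AD): the caller counts filtered reads
DIALECT_NO_AD = "no_ad"          # no usable per-allele depths; record flagged


@dataclass(frozen=True)
class VariantSite:
    """One VCF data line restricted to a single sample.

    ``genotype`` is an ordered pair of allele indices, or ``None`` when the
    call is missing (``./.``).  ``allele_depths`` has one entry per allele
    (ref first) when the producer wrote a usable AD field, else ``None`` and
    ``depth_dialect`` is set to ``"no_ad"``.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    sample: str
    genotype: tuple[int, int] | None
    allele_depths: tuple[int, ...] | None
    total_depth: int | None
    depth_dialect: str = DIALECT_AD_SUM

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def depth(self) -> int | None:
        """Informative depth: sum of allelic depths when present, else DP."""
        if self.allele_depths is not None:
            return int(sum(self.allele_depths))
        return self.total_depth

    def is_homozygous(self) -> bool:
        g = self.genotype
        return g is not None and g[0] == g[1]

    def homozygous_allele(self) -> str | None:
        """The allele string carried homozygously, or None."""
        if not self.is_homozygous():
            return None
        return self.alleles[self.genotype[0]]


@dataclass(frozen=True)
class GeneInterval:
    """A gene locus in BED convention (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "."  # carried but ignored by all computations

    def __post_init__(self):
        if self.start >= self.end:
            raise VcfParseError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise VcfParseError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def contains_vcf_pos(self, pos: int) -> bool:
        return self.start <= pos - 1 < self.end


def _clean_ad(raw, n_alleles: int) -> tuple[int, ...] | None:
    if raw is None:
        return None
    vals = tuple(raw) if isinstance(raw, (tuple, list)) else (raw,)
    if all(v is None for v in vals):
        return None
    if len(vals) != n_alleles:
        return None  # malformed AD: flag rather than guess
    return tuple(0 if v is None else int(v) for v in vals)


def read_vcf(path: str | Path, sample: str) -> list[VariantSite]:
    """Read one sample's records from a VCF 4.x file, in file order.

    Records are never silently dropped: sites with a missing genotype keep
    ``genotype=None`` and sites without usable allelic depths carry
    ``allele_depths=None`` with ``depth_dialect="no_ad"``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"VCF not found: {path}")
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc
    with vcf:
        if sample not in vcf.header.samples:
            raise ConfigurationError(
                f"sample {sample!r} not in header of {path} "
                f"(samples: {list(vcf.header.samples)})"
            )
        out: list[VariantSite] = []
        for i, rec in enumerate(vcf.fetch(), start=1):
            try:
                out.append(_site_from_record(rec, sample))
            except VcfParseError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise VcfParseError(f"{path}: record {i}: {exc}") from exc
    return out


def _site_from_record(rec, sample: str) -> VariantSite:
    alts = tuple(a for a in (rec.alts or ()) if a is not None)
    n_alleles = 1 + len(alts)
    if rec.pos < 1:
        raise VcfParseError(f"{rec.chrom}: position {rec.pos} < 1")
    fmt = rec.samples[sample]
    gt = fmt.get("GT")
    genotype: tuple[int, int] | None
    if gt is None or any(g is None for g in gt) or len(gt) != 2:
        genotype = None
    else:
        genotype = (int(gt[0]), int(gt[1]))
        if any(g >= n_alleles for g in genotype):
            raise VcfParseError(
                f"{rec.chrom}:{rec.pos}: genotype index out of range "
                f"({genotype} with {n_alleles} alleles)"
            )
    ad = _clean_ad(fmt.get("AD"), n_alleles)
    dp = fmt.get("DP")
    dp = int(dp) if dp is not None else None
    if ad is None:
        dialect = DIALECT_NO_AD
    elif dp is not None and dp > sum(ad):
        dialect = DIALECT_DP_EXTRA
    else:
        dialect = DIALECT_AD_SUM
    qual = float(rec.qual) if rec.qual is not None else None
    return VariantSite(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alts=alts,
        qual=qual,
        sample=sample,
        genotype=genotype,
        allele_depths=ad,
        total_depth=dp,
        depth_dialect=dialect,
    )


def read_gene_bed(path: str | Path) -> list[GeneInterval]:
    """Read a BED4+ file of gene intervals, in file order.

    Requires chrom, start, end, name; a fifth column is ignored and a sixth,
    when present, is taken as strand.  Duplicate gene names are an error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"BED not found: {path}")
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        dtype=str,
        skip_blank_lines=True,
    )
    if df.shape[1] < 4:
        raise VcfParseError(f"{path}: BED needs >= 4 columns, got {df.shape[1]}")
    # track/browser lines are not tab-delimited into 4 columns and would
    # already have failed; guard anyway
    df = df[~df[0].str.startswith(("track", "browser"))]
    out: list[GeneInterval] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        chrom, start, end, name = row[0], int(row[1]), int(row[2]), str(row[3])
        strand = str(row[5]) if len(row) > 5 and not _is_na(row[5]) else "."
        if name in seen:
            raise VcfParseError(f"{path}: duplicate gene_id {name!r}")
        seen.add(name)
        out.append(GeneInterval(gene_id=name, chrom=chrom, start=start, end=end,
                                strand=strand))
    return out


# ---------------------------------------------------------------------------
# Generic TSV round-tripping for tabular domain types
# ---------------------------------------------------------------------------

def _is_na(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _caster(tp):
    """Build a string->value caster from a dataclass field annotation."""
    origin = typing.get_origin(tp)
    if origin in (typing.Union, types.UnionType):
        inner = [a for a in typing.get_args(tp) if a is not type(None)]
        cast_inner = _caster(inner[0])
        return lambda v: None if _is_na(v) else cast_inner(v)
    if tp is int:
        return lambda v: int(v)
    if tp is float:
        return lambda v: float(v)
    if tp is bool:
        return lambda v: str(v).strip().lower() in ("true", "1")
    return lambda v: str(v)


def write_table(records: typing.Sequence, path: str | Path,
                cls: type | None = None) -> None:
    """Write homogeneous dataclass records as a TSV with one header row.

    Missing values are written as ``NA``.  An empty list needs an explicit
    ``cls`` to produce the header.  Round-trips losslessly through
    :func:`read_table`.
    """
    if not records and cls is None:
        raise ConfigurationError("empty record list needs cls= for the header")
    cls = cls or type(records[0])
    if not dataclasses.is_dataclass(cls):
        raise ConfigurationError(f"{cls} is not a dataclass type")
    if any(type(r) is not cls for r in records):
        raise ConfigurationError("records are not homogeneous")
    names = [f.name for f in dataclasses.fields(cls)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(names) + "\n")
        for rec in records:
            vals = []
            for name in names:
                v = getattr(rec, name)
                vals.append("NA" if _is_na(v) else str(v))
            fh.write("\t".join(vals) + "\n")


def read_table(path: str | Path, cls: type) -> list:
    """Read a TSV written by :func:`write_table` back into dataclasses."""
    if not dataclasses.is_dataclass(cls):
        raise ConfigurationError(f"{cls} is not a dataclass type")
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                     keep_default_na=False)
    hints = typing.get_type_hints(cls)
    fields = dataclasses.fields(cls)
    missing = [f.name for f in fields if f.name not in df.columns]
    if missing:
        raise VcfParseError(f"{path}: missing columns {missing}")
    casters = {f.name: _caster(hints[f.name]) for f in fields}
    out = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for f in fields:
            v = getattr(row, f.name)
            kwargs[f.name] = None if _is_na(v) else casters[f.name](v)
        out.append(cls(**kwargs))
    return out
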