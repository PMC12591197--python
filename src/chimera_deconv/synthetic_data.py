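"""Synthetic chimeric allele-specific expression datasets with known truth.

The generator emulates the data-generating situation of a periclinal graft
chimera sequenced together with its two donors: two homozygous-divergent
donor genotype sets, and a chimera tissue whose informative transcript pool
is a mixture of an L1 contribution (donor O) at proportion ``p_L1`` and an
L2/L3 contribution (donor C) at proportion ``1 - p_L1``.  Genes are either
shared (expressed from all layers, expected donor-O allele fraction
f_O = p_L1), L1-specific (f_O = 1) or L2/L3-specific (f_O = 0).  Expression
level enters only through per-site sequencing depth; base-level allele
miscalls flip a read's apparent donor with probability ``epsilon``.

For each diagnostic site with depth n drawn from the depth model, the
number of reads truly originating from L1 is Binomial(n, f_g); each L1 read
is then observed as the donor-C allele with probability epsilon and vice
versa, so the observed donor-O count is marginally
Binomial(n, f_g (1 - eps) + (1 - f_g) eps).  Both pre-error and post-error
counts are recorded in the emitted truth.

Decoy sites, where the donors share a genotype, are interleaved so that the
diagnostic-site filter is exercised rather than assumed.  Two marker genes
(PDF1, declared L1; SYS, declared L2/L3) are always emitted unless
disabled.  All outputs are reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .diagnostics import DiagnosticFilters, DiagnosticSite, find_diagnostic_sites
from .errors import ConfigurationError
from .layers import MarkerDeclaration
from .origin import AlleleCounts, count_alleles
from .vcf_io import GeneInterval, read_vcf, write_table

__all__ = [
    "SimulationConfig",
    "SiteTruth",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_counts",
    "simulate_dataset",
    "truth_check",
]

_BASES = np.array(list("ACGT"))

GENE_SPAN = 5_000     # bp of simulated gene body
GENE_PITCH = 10_000   # bp between gene starts (genes never overlap)

L1_SPECIFIC_GENE = "l1_specific"
L2L3_SPECIFIC_GENE = "l2l3_specific"
SHARED_GENE = "shared"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated chimera tissue.

    Defaults describe a flavedo-like tissue: roughly 1,000 diagnostic
    sites, mean depth 50, miscall rate 0.005, and an L1 transcript
    contribution of about one fifth.
    """

    seed: int = 0
    n_genes: int = 334
    sites_per_gene: int | tuple[int, int] = 3  # fixed k, or uniform [a, b]
    p_L1: float = 0.2019
    frac_l1_specific: float = 0.0
    frac_l2l3_specific: float = 0.0
    depth_model: str = "poisson"  # "poisson" or "nbinom"
    depth_mean: float = 50.0
    depth_dispersion: float = 5.0  # nbinom size r; ignored for poisson
    epsilon: float = 0.005
    n_decoy_sites: int = 100
    donor_depth_mean: float = 50.0
    include_markers: bool = True
    marker_sites: int = 5
    chrom: str = "chr1"
    sample_O: str = "OOO"
    sample_C: str = "CCC"
    sample_chimera: str = "OCC"

    def __post_init__(self):
        if not (0.0 <= self.p_L1 <= 1.0):
            raise ConfigurationError("p_L1 must be in [0, 1]")
        if not (0.0 <= self.epsilon < 0.5):
            raise ConfigurationError("epsilon must be in [0, 0.5)")
        if self.frac_l1_specific < 0 or self.frac_l2l3_specific < 0 or \
                self.frac_l1_specific + self.frac_l2l3_specific > 1.0:
            raise ConfigurationError(
                "layer-specific gene fractions must be >= 0 and sum to <= 1")
        if self.depth_model not in ("poisson", "nbinom"):
            raise ConfigurationError(f"unknown depth model {self.depth_model!r}")
        if self.depth_mean <= 0 or (self.depth_model == "nbinom"
                                    and self.depth_dispersion <= 0):
            raise ConfigurationError("depth parameters must be positive")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        k = self.sites_per_gene
        if isinstance(k, int):
            ok = k >= 1
        else:
            ok = len(k) == 2 and 1 <= k[0] <= k[1]
        if not ok:
            raise ConfigurationError(f"bad sites_per_gene spec {k!r}")


@dataclass(frozen=True)
class SiteTruth:
    """Ground truth for one diagnostic site."""

    chrom: str
    pos: int
    gene_id: str
    allele_O: str
    allele_C: str
    depth: int          # informative depth n written to the chimera VCF
    n_from_L1: int      # reads truly originating from the L1 layer (pre-error)
    n_O_obs: int        # post-error observed donor-O reads
    n_C_obs: int
    expected_f_O: float


@dataclass
class SimulationTruth:
    p_L1: float
    epsilon: float
    gene_classes: dict[str, str]
    sites: list[SiteTruth]
    decoy_keys: list[tuple[str, int]] = field(default_factory=list)
    markers: list[MarkerDeclaration] = field(default_factory=list)

    @property
    def site_by_key(self) -> dict[tuple[str, int], SiteTruth]:
        return {(s.chrom, s.pos): s for s in self.sites}


@dataclass(frozen=True)
class SimulatedDataset:
    """File paths of one simulated dataset plus its ground truth."""

    donor_O_vcf: Path
    donor_C_vcf: Path
    chimera_vcf: Path
    genes_bed: Path
    markers_tsv: Path
    truth: SimulationTruth


def _draw_depths(rng: np.random.Generator, cfg: SimulationConfig,
                 size: int) -> np.ndarray:
    if cfg.depth_model == "poisson":
        return rng.poisson(cfg.depth_mean, size=size)
    r = cfg.depth_dispersion
    return rng.negative_binomial(r, r / (r + cfg.depth_mean), size=size)


def _gene_layout(rng: np.random.Generator, cfg: SimulationConfig):
    """Gene intervals, per-gene classes and per-gene site positions."""
    gene_ids = [f"g{i + 1:04d}" for i in range(cfg.n_genes)]
    classes = {}
    n_l1 = int(round(cfg.frac_l1_specific * cfg.n_genes))
    n_l23 = int(round(cfg.frac_l2l3_specific * cfg.n_genes))
    order = rng.permutation(cfg.n_genes)
    for rank, gi in enumerate(order):
        if rank < n_l1:
            classes[gene_ids[gi]] = L1_SPECIFIC_GENE
        elif rank < n_l1 + n_l23:
            classes[gene_ids[gi]] = L2L3_SPECIFIC_GENE
        else:
            classes[gene_ids[gi]] = SHARED_GENE
    if cfg.include_markers:
        gene_ids += ["PDF1", "SYS"]
        classes["PDF1"] = L1_SPECIFIC_GENE
        classes["SYS"] = L2L3_SPECIFIC_GENE
    intervals = []
    site_pos: dict[str, np.ndarray] = {}
    for i, gid in enumerate(gene_ids):
        start = i * GENE_PITCH
        intervals.append(GeneInterval(gene_id=gid, chrom=cfg.chrom,
                                      start=start, end=start + GENE_SPAN))
        if gid in ("PDF1", "SYS"):
            k = cfg.marker_sites
        elif isinstance(cfg.sites_per_gene, int):
            k = cfg.sites_per_gene
        else:
            k = int(rng.integers(cfg.sites_per_gene[0],
                                 cfg.sites_per_gene[1] + 1))
        offs = rng.choice(GENE_SPAN, size=k, replace=False)
        site_pos[gid] = np.sort(offs) + start + 1  # 1-based VCF positions
    return gene_ids, classes, intervals, site_pos


def simulate_counts(cfg: SimulationConfig):
    """Fast in-memory path: diagnostic sites, chimera allele counts and
    truth, without writing any files.

    Returns (sites, counts, intervals, truth); ``counts`` are exactly what
    :func:`chimera_deconv.origin.count_alleles` would recover from the
    files written by :func:`simulate_dataset` with the same config.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids, classes, intervals, site_pos = _gene_layout(rng, cfg)

    sites: list[DiagnosticSite] = []
    counts: list[AlleleCounts] = []
    site_truths: list[SiteTruth] = []
    eps = cfg.epsilon
    for gid in gene_ids:
        f_g = {L1_SPECIFIC_GENE: 1.0, L2L3_SPECIFIC_GENE: 0.0,
               SHARED_GENE: cfg.p_L1}[classes[gid]]
        q_o = f_g * (1.0 - eps) + (1.0 - f_g) * eps
        positions = site_pos[gid]
        depths = _draw_depths(rng, cfg, positions.size)
        for pos, n in zip(positions, depths):
            n = int(n)
            b_o, b_c = rng.choice(4, size=2, replace=False)
            allele_o, allele_c = str(_BASES[b_o]), str(_BASES[b_c])
            k_l1 = int(rng.binomial(n, f_g))
            n_o_obs = int(rng.binomial(k_l1, 1.0 - eps)
                          + rng.binomial(n - k_l1, eps))
            sites.append(DiagnosticSite(
                chrom=cfg.chrom, pos=int(pos),
                allele_O=allele_o, allele_C=allele_c,
                qual_O=60.0, qual_C=60.0,
                depth_O=_donor_depth(rng, cfg),
                depth_C=_donor_depth(rng, cfg)))
            counts.append(AlleleCounts(
                chrom=cfg.chrom, pos=int(pos), sample_id=cfg.sample_chimera,
                n_O=n_o_obs, n_C=n - n_o_obs))
            site_truths.append(SiteTruth(
                chrom=cfg.chrom, pos=int(pos), gene_id=gid,
                allele_O=allele_o, allele_C=allele_c, depth=n,
                n_from_L1=k_l1, n_O_obs=n_o_obs, n_C_obs=n - n_o_obs,
                expected_f_O=q_o))
    decoy_keys = _decoy_positions(rng, cfg, site_pos)
    markers = [MarkerDeclaration("PDF1", "L1"), MarkerDeclaration("SYS", "L2L3")] \
        if cfg.include_markers else []
    truth = SimulationTruth(p_L1=cfg.p_L1, epsilon=eps, gene_classes=classes,
                            sites=site_truths, decoy_keys=decoy_keys,
                            markers=markers)
    return sites, counts, intervals, truth


def _donor_depth(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    # donor call sets emulate already-quality-filtered genotypes: depth is
    # floored at 10 so every planted site survives default filters
    return max(int(rng.poisson(cfg.donor_depth_mean)), 10)


def _decoy_positions(rng, cfg, site_pos) -> list[tuple[str, int]]:
    used = {int(p) for arr in site_pos.values() for p in arr}
    span = (len(site_pos) + 1) * GENE_PITCH
    out: list[tuple[str, int]] = []
    while len(out) < cfg.n_decoy_sites:
        p = int(rng.integers(1, span))
        if p not in used:
            used.add(p)
            out.append((cfg.chrom, p))
    return out


# ---------------------------------------------------------------------------
# VCF / BED / TSV emission
# ---------------------------------------------------------------------------

def _vcf_header(cfg: SimulationConfig, sample: str, contig_len: int) -> str:
    return (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={cfg.chrom},length={contig_len}>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Allelic depths for the ref and alt alleles">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + sample + "\n"
    )


def _vcf_line(chrom, pos, ref, alt, qual, gt, ad) -> str:
    dp = sum(ad)
    ad_s = ",".join(str(x) for x in ad)
    return (f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual:g}\t.\t.\t"
            f"GT:AD:DP\t{gt}:{ad_s}:{dp}\n")


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path) -> SimulatedDataset:
    """Write a complete simulated dataset (two donor VCFs, a chimera VCF, a
    gene BED and a marker TSV) and return the paths plus ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites, counts, intervals, truth = simulate_counts(cfg)
    # decoy genotype shared by both donors: drawn from an independent stream
    # keyed off the main seed so file emission stays byte-reproducible
    rng = np.random.default_rng((cfg.seed, 0xDEC0))
    truth_by_key = truth.site_by_key
    contig_len = (len(intervals) + 1) * GENE_PITCH

    records: dict[tuple[str, int], dict] = {}
    for ds, ac in zip(sites, counts):
        st = truth_by_key[ds.key]
        # REF/ALT orientation: donor-O allele is REF or ALT at random
        o_is_ref = bool(rng.integers(2))
        ref, alt = (ds.allele_O, ds.allele_C) if o_is_ref \
            else (ds.allele_C, ds.allele_O)
        gt_o, gt_c = ("0/0", "1/1") if o_is_ref else ("1/1", "0/0")
        ad_chimera = (st.n_O_obs, st.n_C_obs) if o_is_ref \
            else (st.n_C_obs, st.n_O_obs)
        records[ds.key] = dict(
            ref=ref, alt=alt, qual_o=ds.qual_O, qual_c=ds.qual_C,
            gt_o=gt_o, gt_c=gt_c,
            ad_o=(ds.depth_O, 0) if o_is_ref else (0, ds.depth_O),
            ad_c=(0, ds.depth_C) if o_is_ref else (ds.depth_C, 0),
            gt_x="0/1", ad_x=ad_chimera,
        )
    for key in truth.decoy_keys:
        kind = int(rng.integers(3))  # 0 hom-ref, 1 hom-alt, 2 shared het
        ref, alt = (str(b) for b in _BASES[rng.choice(4, 2, replace=False)])
        d_o, d_c, d_x = (_donor_depth(rng, cfg), _donor_depth(rng, cfg),
                         int(_draw_depths(rng, cfg, 1)[0]))
        if kind == 0:
            gt, ad_o, ad_c, ad_x = "0/0", (d_o, 0), (d_c, 0), (d_x, 0)
        elif kind == 1:
            gt, ad_o, ad_c, ad_x = "1/1", (0, d_o), (0, d_c), (0, d_x)
        else:
            gt = "0/1"
            half = int(rng.binomial(d_x, 0.5))
            ad_o = (d_o // 2, d_o - d_o // 2)
            ad_c = (d_c // 2, d_c - d_c // 2)
            ad_x = (half, d_x - half)
        records[key] = dict(ref=ref, alt=alt, qual_o=60.0, qual_c=60.0,
                            gt_o=gt, gt_c=gt, ad_o=ad_o, ad_c=ad_c,
                            gt_x=gt, ad_x=ad_x)

    paths = {
        "donor_O_vcf": outdir / "donor_O.vcf",
        "donor_C_vcf": outdir / "donor_C.vcf",
        "chimera_vcf": outdir / "chimera.vcf",
        "genes_bed": outdir / "genes.bed",
        "markers_tsv": outdir / "markers.tsv",
    }
    keys = sorted(records)
    for path_key, sample, gt_field, ad_field, qual_field in (
            ("donor_O_vcf", cfg.sample_O, "gt_o", "ad_o", "qual_o"),
            ("donor_C_vcf", cfg.sample_C, "gt_c", "ad_c", "qual_c"),
            ("chimera_vcf", cfg.sample_chimera, "gt_x", "ad_x", None)):
        with open(paths[path_key], "w", encoding="utf-8", newline="\n") as fh:
            fh.write(_vcf_header(cfg, sample, contig_len))
            for key in keys:
                r = records[key]
                qual = r[qual_field] if qual_field else 60.0
                fh.write(_vcf_line(key[0], key[1], r["ref"], r["alt"], qual,
                                   r[gt_field], r[ad_field]))
    with open(paths["genes_bed"], "w", encoding="utf-8", newline="\n") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene_id}\t0\t"
                     f"{iv.strand if iv.strand != '.' else '+'}\n")
    if truth.markers:
        write_table(truth.markers, paths["markers_tsv"], cls=MarkerDeclaration)
    else:
        write_table([], paths["markers_tsv"], cls=MarkerDeclaration)
    return SimulatedDataset(truth=truth, **paths)


# ---------------------------------------------------------------------------
# Self-check
# ---------------------------------------------------------------------------

@dataclass
class TruthReport:
    n_sites_checked: int
    mismatches: list[str]

    @property
    def ok(self) -> bool:
        return not self.mismatches


def truth_check(dataset: SimulatedDataset,
                cfg: SimulationConfig) -> TruthReport:
    """Re-derive per-site counts from the emitted files and compare with
    the recorded truth; also assert that no decoy site is diagnostic."""
    donor_o = read_vcf(dataset.donor_O_vcf, cfg.sample_O)
    donor_c = read_vcf(dataset.donor_C_vcf, cfg.sample_C)
    chimera = read_vcf(dataset.chimera_vcf, cfg.sample_chimera)
    diag = find_diagnostic_sites(donor_o, donor_c, DiagnosticFilters())
    truth = dataset.truth
    truth_keys = set(truth.site_by_key)
    mism: list[str] = []
    diag_keys = {d.key for d in diag}
    for key in sorted(truth_keys - diag_keys):
        mism.append(f"{key[0]}:{key[1]}: planted site not recovered as diagnostic")
    for key in sorted(diag_keys - truth_keys):
        mism.append(f"{key[0]}:{key[1]}: spurious diagnostic site")
    for key in sorted(set(truth.decoy_keys) & diag_keys):
        mism.append(f"{key[0]}:{key[1]}: decoy site called diagnostic")
    counts = count_alleles(chimera, diag, cfg.sample_chimera)
    by_key = truth.site_by_key
    for ac in counts:
        st = by_key.get((ac.chrom, ac.pos))
        if st is None:
            continue
        if (ac.n_O, ac.n_C) != (st.n_O_obs, st.n_C_obs):
            mism.append(f"{ac.chrom}:{ac.pos}: counts ({ac.n_O},{ac.n_C}) "
                        f"!= truth ({st.n_O_obs},{st.n_C_obs})")
    return TruthReport(n_sites_checked=len(counts), mismatches=mism)
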