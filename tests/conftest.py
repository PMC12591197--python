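import textwrap

import pytest
from hypothesis import HealthCheck, settings

from chimera_deconv import SimulationConfig, simulate_counts, simulate_dataset

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_vcf(path, sample, rows, contig="chr1", contig_len=10_000_000):
    """Write a minimal single-sample VCF.

    ``rows``: (chrom, pos, ref, alt, qual, gt, ad) tuples; ``ad`` is a
    comma-joined string or None to omit the AD field; ``qual`` may be ".".
    """
    header = textwrap.dedent(f"""\
        ##fileformat=VCFv4.2
        ##contig=<ID={contig},length={contig_len}>
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
        ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
        """)
    lines = [header]
    for chrom, pos, ref, alt, qual, gt, ad in rows:
        if ad is None:
            fmt, val = "GT", gt
        else:
            dp = sum(int(x) for x in str(ad).split(","))
            fmt, val = "GT:AD:DP", f"{gt}:{ad}:{dp}"
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t.\t{fmt}\t{val}\n")
    path.write_text("".join(lines), encoding="utf-8")
    return path


@pytest.fixture
def vcf_factory(tmp_path):
    def _make(name, sample, rows, **kw):
        return make_vcf(tmp_path / name, sample, rows, **kw)

    return _make


@pytest.fixture(scope="session")
def sim_cfg():
    """A small but structured tissue: layer-specific genes, decoys, markers."""
    return SimulationConfig(seed=11, n_genes=100, sites_per_gene=3,
                            p_L1=0.2019, frac_l1_specific=0.1,
                            frac_l2l3_specific=0.1, n_decoy_sites=50)


@pytest.fixture(scope="session")
def sim_mem(sim_cfg):
    """(sites, counts, intervals, truth) from the in-memory simulator."""
    return simulate_counts(sim_cfg)


@pytest.fixture(scope="session")
def sim_files(sim_cfg, tmp_path_factory):
    """The same tissue written out as VCF/BED/TSV files."""
    outdir = tmp_path_factory.mktemp("simdata")
    return simulate_dataset(sim_cfg, outdir)
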