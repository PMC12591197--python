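# Methods

## Data model and coordinate conventions

The pipeline consumes per-sample VCF 4.x call sets (read with pysam) and a
BED4+ gene interval file. VCF positions are 1-based; BED intervals are
0-based half-open; a VCF site at position P overlaps an interval
`[start, end)` iff `start <= P − 1 < end`. That is the only coordinate
conversion in the package and it is stated once, in `vcf_io`. Strand is
carried but ignored: allele identity in a VCF is already strand-resolved.

Per-allele read depths are taken from the `AD` FORMAT field. When `DP`
exceeds `sum(AD)` the producer counts filtered reads; the dialect is
recorded per record. Records without a usable `AD` are kept and flagged
(`no_ad`), never silently dropped: at every stage, records out plus
records flagged equals records in, and the run manifest makes those counts
auditable.

## Diagnostic sites

A site is donor-diagnostic when both donors are **homozygous for
different alleles** and both calls pass confidence filters. Homozygosity
is read from the genotype field, not re-derived from allele depths,
because the caller's genotype is the published unit of evidence. Only the
homozygous-divergent rule makes chimera allele counts donor-interpretable:
at such a site every informative read identifies its donor.

Default filters (package choices, all configurable): per-donor depth
>= 10 reads, site QUAL >= 30, biallelic records only, SNPs only (indel
alleles excluded). Sites present in only one donor's call set are
excluded by default — a per-donor call set of unknown completeness does
not justify "absent means homozygous reference" — but that convention is
available via `absent_means_homref`, in which case the assumed hom-ref
side is exempt from depth/qual filters (no call was attempted).

Raising any threshold can only remove sites (monotonicity), and swapping
the two donor inputs yields the same site set with the allele roles
exchanged (an involution); both properties are tested.

## Origin classification

At each diagnostic site the chimera's allelic depths are partitioned by
string match into `n_O`, `n_C` and `n_other`. An allele is *present* iff
its reads >= 3 **and** its fraction of informative reads >= 5%. The
absolute floor protects low-depth sites from noise; the relative floor
protects high-depth sites, where a fixed read count is easily reached by
miscalls alone. A site is UNINFORMATIVE when informative depth
`n = n_O + n_C` < 10 or when `n_other` exceeds 20% of all reads (treated
as a mismapping artifact — `n_other` never enters `f_O`). Otherwise the
category is O_ONLY, C_ONLY or BOTH according to which alleles are present.
Zero-coverage diagnostic sites are retained as UNINFORMATIVE so category
counts are conserved and the expressed fraction of diagnostic sites is
reportable.

## Composition estimators

`p_C` is the donor-C (L2/L3) fraction of the informative transcript pool;
`p_O = 1 − p_C`.

- **site_share** (pipeline default): `p_C = (#C_ONLY + Σ_BOTH (1 − f_O)) /
  #informative`. BOTH sites contribute fractionally through `1 − f_O`
  rather than a flat 1/2, so deeply covered shared sites inform the
  estimate. This is the count-of-SNPs reading of a donor percentage.
- **read_fraction**: `p_C = Σ n_C / Σ n`, the pooled donor-C allele
  frequency — the read-weighted reading.
- **binomial_mle**: `n_C,i ~ Binomial(n_i, q(p))` with
  `q(p) = p(1 − ε) + (1 − p)ε`. Because `q` is common to all sites the
  likelihood depends on the counts only through `Σ n_C` and `Σ n`. Default
  `ε = 0.005`, a typical short-read substitution error rate;
  configurable.

All three are reported side by side so the choice between site-counting
and read-weighting is auditable rather than implicit. The two simple
estimators carry a miscall bias of `ε(1 − 2p)`; the MLE removes it.

**Optimizer.** The MLE is located by a 1,001-point grid over `p ∈ [0, 1]`
followed by golden-section refinement of the bracketing interval down to a
bracket width of 1e-9 (comfortably below the 1e-6 contract), with an
explicit endpoint check for boundary optima. The likelihood is unimodal in
`p` (monotone reparametrization of a binomial likelihood in `q`), so the
derivative-free search is exact to tolerance and fully deterministic. At
`ε = 0` the closed form `Σ n_C / Σ n` is returned directly, never through
the optimizer, so the zero-error limit is exact.

**Uncertainty.** Percentile bootstrap over sites (default B = 1000,
level 0.95), treating sites as the independent units. Degenerate
resamples with zero informative reads are redrawn and the redraw count
logged. A single seeded NumPy generator drives resampling; the seed is
echoed in every output that depends on it. An `exhaustive` mode
enumerates all ordered resamples for tiny inputs, which gives the tests a
closed enumeration oracle.

## Gene-level layer analysis

Sites are assigned to genes by interval overlap; sites overlapping more
than one gene are excluded from pooling (ambiguous attribution, logged)
but still count toward tissue-level composition. Per gene, pooled counts
give `f_O`; genes with zero informative reads stay UNCLASSIFIED.

- **L1-normalized percentage**: `pct_L1 = min(f_O / p_O, 1) × 100`, where
  `p_O` is the tissue-level L1 fraction from the composition stage. A gene
  expressed only in L1 has `f_O ≈ p_O`, so the ratio rescales full L1
  specificity to 100%; genes whose L1 allele frequency exceeds the tissue
  fraction are capped at 100%. This normalization is a reconstruction from
  the quantity's verbal definition and is deliberately isolated in one
  function.
- **Layer class**: UNCLASSIFIED below 20 pooled reads; L1_SPECIFIC at
  `f_O >= 0.95`; L2L3_SPECIFIC at `f_O <= 0.05`; else SHARED. The 0.95/0.05
  pair mirrors the site-level presence logic at gene scale and makes the
  classification exactly symmetric under donor relabelling.
- **Structure inference**: marker genes with declared layer specificity
  (e.g. PDF1 for L1, prosystemin/SYS for L2/L3) are classified from their
  pooled counts. PERICLINAL requires all L1 markers to resolve to one
  donor and all L2/L3 markers to the other; any UNINFORMATIVE marker
  yields UNDETERMINED; any other configuration (including a marker called
  BOTH) is INCONSISTENT.

## Synthetic data

The simulator emulates the two-donor chimera design: homozygous-divergent
donors at every diagnostic site, a chimera transcript pool mixing L1
(donor O) at proportion `p_L1` with L2/L3 (donor C), genes that are
shared, L1-specific or L2/L3-specific, per-site depth from a Poisson
(default) or negative-binomial model, and symmetric allele miscalls at
rate `ε`. For a site in gene *g* with depth `n`, reads truly from L1 are
`Binomial(n, f_g)` with `f_g ∈ {1, 0, p_L1}` by gene class; each read then
reports the wrong donor's allele with probability `ε`. Pre-error and
post-error counts are both recorded in the emitted truth, and
`truth_check` re-derives counts from the emitted files to prove
self-consistency.

Default conditions describe a flavedo-like tissue: ~1,000 diagnostic
sites (334 genes x 3 sites, plus two 5-site marker genes), mean depth 50,
`ε = 0.005`, `p_L1 = 0.2019`, 100 decoy sites at which the donors share a
genotype (so the diagnostic filter is exercised, not assumed). Donor call
depths are floored at 10 reads, emulating donor call sets that were
already quality-filtered upstream. Marker genes carry 5 sites because
markers in this design are well-expressed genes; pooling across sites is
what makes the presence thresholds (3 reads, 5%) robust to miscall
bursts.

What the simulator does **not** model: read-level alignment and mapping
bias toward the reference allele, isoform structure, correlated errors,
overdispersion between sites of the same gene beyond the depth model, and
expression differences between layers within a gene class. Passing tests
therefore demonstrate the statistical machinery under the stated error
model, not robustness to alignment artifacts in real tissue — the
mapping-bias limitation in particular is inherited by any real analysis
and is listed under Non-goals in `origin`.

## Problem sizes and numerical choices

The verification suite runs at desk scale, chosen to pin each property
with comfortable margins: mixture recovery uses 100 replicates per tissue
at 1,000 sites (the estimator's standard error there is ~0.002, ten times
tighter than the ±0.02 acceptance band); bootstrap calibration uses 200
replicates at B = 500 and 300 sites; oracle agreement uses 50 random
count sets against a 10⁶-point grid. Ties in the coarse grid resolve to
the lowest index (numpy argmax); quantiles use numpy's default linear
interpolation; golden-section bracket width 1e-9. Exact donor-swap
symmetry is asserted on integer counts and category tallies; estimator
symmetry is asserted to 1e-12 (closed forms) and 1e-6 (optimizer paths),
reflecting the optimizer's own tolerance.

## Known limitations

- Two donors only; the design cannot separate L2 from L3 (both derive
  from the same donor), so the unit of inference is L1 vs L2/L3.
- The donor percentage of a real tissue depends on upstream alignment and
  calling choices; this package quantifies everything downstream of the
  VCFs.
- `site_share` and `read_fraction` are biased by `ε(1 − 2p)`; use the MLE
  when the miscall rate matters.
- The L1-normalized percentage divides by an estimated `p_O`; its error
  propagates multiplicatively and is not given an interval.
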