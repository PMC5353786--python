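# Methods

`dremap` reimplements a differential regulatory-element (dRE) analysis for
reduced-representation bisulfite sequencing (RRBS) data: two sample classes
(a cancer cohort and a control cohort) are compared at the level of local
methylation state, and the resulting element classes are interrogated with
expression, GWAS, genetic-association and transcription-factor binding site
(TFBS) statistics. This note documents the models, the parameters that
matter, the synthetic data the tests run on, and the numerical choices made
where the design was open.

## Class consensus profile

Per sample, RRBS yields total reads `r_ik` and methylated reads `mr_ik`
per CpG site `k`. Sites with fewer than `min_reads = 5` aligned reads are
dropped per sample before anything else. The class consensus weights each
sample by the reciprocal of its total aligned read count, `w_i = 1/total_i`:

    R(k)  = Σ_i w_i · r_ik / Σ_i w_i        (same with mr_ik for MR(k))
    meth(k) = MR(k) / R(k)

The normalizer Σ w_i runs over the samples that still carry site `k` after
the coverage filter. This per-site convention avoids deflating `R(k)` at
sites missing from some libraries; the alternative (all samples in the
class) was rejected because it would make `R(k)` depend on how many
libraries happened to cover the site at all. Two invariants pin the
definition down: with equal totals the consensus is the arithmetic mean,
and scaling every total by a common factor leaves `R(k)` unchanged.

Strand handling: + and − strand measurements of one CpG dinucleotide are
distinct sites by default; `collapse_strands` merges them (minus-strand
site mapped to `pos − 1`, reads summed) for callers who want
dinucleotide-level counts.

## Segmentation

Hypomethylated regions are maximal runs of consecutive assayed CpGs with
`meth < meth_cutoff` (default 0.5), at least `n_cpg_cutoff = 3` CpGs long,
broken wherever consecutive CpGs are more than `max_gap_bp = 500` apart.
Hypermethylated regions use `meth ≥ 0.5`; a site exactly at the cutoff is
hyper. A region spans its first CpG to its last CpG + 2 (half-open,
covering the dinucleotide).

The gap rule is this package's own: RRBS coverage is sparse, and ungapped
runs would span arbitrarily long assay deserts. 500 bp reflects the scale
over which methylation state is locally coherent; it is exposed as a
parameter. No HMM or FDR machinery sits behind the rule — the run-based
definition is the entire model, which makes the brute-force run enumeration
in the tests an exact oracle.

## Element classification

Case and control hypomethylated maps are contrasted with a 1 bp minimum
overlap (any overlap is evidence of the same element):

- case-only region → **gained** dRE (active only in cancer),
- control-only → **lost** dRE,
- overlapping case/control regions → one **shared** element (sRE) whose
  coordinates are the union of the overlapping chain,
- intersections of the two hypermethylated maps → **hiMR** (inactive in
  both classes), with the ≥3-CpG requirement re-checked on the intersection
  against both consensus profiles.

Classification is exactly antisymmetric: swapping the class arguments swaps
gained with lost and fixes shared and hiMR. Genomic categories are assigned
with precedence promoter > exonic > intronic > intergenic; the promoter
window is TSS −1,000/+500 bp, strand-aware, both bounds exposed.

## Gene linkage and expression coupling

Every region is assigned to the single gene with the nearest TSS (distance
0 if the TSS lies inside the region, ties broken by gene id). Genes with
average expression < 0.1 in either class are excluded as unreliable; fold
change is the plain ratio of class means (ratio scale, not log — the
ranking only needs an order). The top `p%` up- or down-regulated genes form
the gene set `G`; enrichment of dREs `R` near `G` against the sRE baseline
`S` is

    enrichment = fract(R, G) / fract(S, G)

with denominators restricted to regions linked to expression-measured
genes, and a one-sided binomial tail (`n_R` trials, success probability
`fract(S, G)`). Both tails are always reported with the direction flagged.
When `fract(S, G) = 0` the enrichment is reported as infinite with the
exact zero-null p (0 unless the observed count is 0); the synthetic fixture
reaches this regime easily because its expression signal is strong and its
shared-element count modest.

## Spatial statistics

Distances are edge-to-edge (overlap = 0), never across chromosomes. The
null for any distance statistic keeps region coordinates fixed and shuffles
the class labels (class sizes preserved, 1,000 permutations by default);
the observed distribution is compared against the pooled permutation
distances with a one-sided Mann–Whitney test — "shorter than background"
for within-class clustering — and the per-permutation distributions are
also averaged on a fixed quantile grid for plotting. Lost-element clusters
are the subset with a within-class neighbor closer than 10 kb, chained by
single linkage at that gap.

## GWAS enrichment

Catalog tag SNPs are expanded to all panel SNPs with `r² > 0.8` within
500 kb, where `r²` is the squared allelic correlation over phased
haplotypes; a partner qualifies if the criterion holds in at least one
supplied panel. Traits are agglomerated by case-insensitive keyword rules
with precedence CLL > lymphoma > cancer > irrelevant (lymphoma explicitly
excludes CLL matches); the rules ship as editable regex lists because no
keyword list can reproduce manual curation exactly. The irrelevant category
is the baseline.

The enrichment statistic is the count of trait SNPs inside a region class;
its p-value is the label-shuffle exceedance probability with the add-one
correction, `p = (1 + #{perm ≥ obs}) / (n_perm + 1)` (the raw fraction is
also reported). Density is reported per 1,000 panel SNPs inside the class;
panel SNPs — not trait-annotated SNPs — form the denominator, since the
trait annotation is exactly what is being tested. SNP-in-region membership
is half-open: a SNP at `end` is outside.

## SNP association

A SNP monomorphic in the pooled reads is *non-assayed* below 10 overlapping
reads and *non-mutated* at 10 or more. For polymorphic SNPs, each allele
`k` is scored by the strict upper-tail binomial probability

    Pr(X > n_k,c),  X ~ Binomial(n_c, p_k,n)

with `n_k,c` the case occurrence count, `n_c` the case total, and `p_k,n`
the pooled control frequency (no pseudocount). The same form scores each
diploid genotype state against control genotype frequencies. The minimum
over all tails is compared with `alpha = 0.05`; the allele with the largest
positive case-minus-control frequency excess is the cancer-associated
allele and is treated downstream as the mutant (MU) allele.

Two properties of this test deserve flagging. First, a category unobserved
in controls has `p = 0`, making any case observation "infinitely"
significant; such calls carry a `zero_control_support` flag so callers can
require minimum control depth. Second, the test treats the control
frequency estimate as known. When the control class is as shallow as the
case class, the estimate's sampling noise inflates the tail — at equal
planted frequencies and 40-read depth on both sides, roughly a third of
SNPs can be flagged, versus well under 20% when controls are deep. This is
a property of the method as specified, not a defect of the implementation;
no multiple-testing correction is applied by default (a Benjamini–Hochberg
helper is provided, off by default).

## Haplotype association

For an associated SNP `m` and a GWAS tag `m_tag`, panel chromosomes are
cross-tabulated by carriage of the cancer-associated allele (`1|m`) and the
risk allele (`1|m_tag`), with all non-focal alleles pooled into the "2"
strata. The odds ratio is `D11·D22 / (D12·D21)` (infinite when only the
denominator vanishes, undefined when both products are zero), and
significance comes from Fisher's exact test, two-sided by the
point-probability rule, with one-sided variants available. All panel
chromosomes are pooled.

## TFBS scanning and gain/loss statistics

A motif is a column-stochastic position weight matrix; log-odds scores use
a 0.01-per-cell pseudocount against a uniform background unless one is
supplied. A window is a hit when its score's tail probability under the
background model is at most `p_threshold = 1e-4`. The score distribution is
computed exactly by dynamic-programming convolution on a discretized grid
(1/1,000 of the score range), so thresholds are deterministic and the
exhaustive per-window rescoring oracle in the tests is exact. Both strands
are scanned; a minus-strand hit reports the same forward window.

Matched controls for density enrichment are rejection-sampled genome
windows of identical length with GC and repeat fractions within ±0.05 of
the region's (budgeted; a shortfall is returned with a warning).

For each associated SNP the cancer-enriched allele is the mutant. Per motif
`t`, hits are counted only in the `2w−1` window overlapping the substituted
base, aggregated over the class's SNPs:

    Fract(lost|t)   = N(t|WT, not MU) / N(t|WT)
    Fract(gained|t) = N(t|MU, not WT) / N(t|MU)

Significance is the strict upper-tail binomial with trial count `N(t|WT)`
(lost) or `N(t|MU)` (gained) and success probability `p_t`, the same
fraction measured at `N = 30` background positions per SNP — positions in
the host region carrying the WT base, each given the same pseudo-
substitution, pooled across SNPs. Reporting thresholds mirror the study:
loss enrichment > 1.5 at p < 0.05; gain at p < 0.01.

## Synthetic data

The generator emulates the study conditions: 32 case and 10 control
methylation profiles; per-CpG coverage Poisson(30) truncated at ≥1 (the
simplest model that exercises the <5-read filter; the real per-site
coverage law is unknown); methylated reads binomial at 0.05
(hypomethylated) or 0.9 (methylated) by planted region class; 2,000
background CpGs at 0.9. Planted regions default to 20 gained, 20 lost, 10
shared and 10 hiMR of 10 CpGs each (≈360 bp), laid out round-robin over
two 1 Mb chromosomes. SNP read counts are per-sample binomial draws at the
class allele frequency (keeping pooled counts binomial, matching the
association model) with genotype states from Hardy–Weinberg draws;
associated SNPs are planted at 0.8 vs 0.2, nulls at 0.5/0.5, plus
monomorphic SNPs under and over the 10-read rule. The haplotype panel
(1,000 haplotypes) builds LD partners by copy-with-replacement: an entry is
kept with probability √r²_target, else redrawn at the tag frequency, which
hits the target r² in expectation; a pair at 600 kb exercises the distance
rule. The catalog spans all four trait categories with some sub-5-SNP
traits; CLL-trait SNPs are planted inside gained elements. Motifs are
planted as exact consensus sites with one destroying and one creating
substitution each.

What the generator does *not* emulate, and hence what green tests do not
show about real data: biological between-sample heterogeneity
(overdispersion beyond binomial), bisulfite conversion error, alignment
bias, copy-number variation, realistic LD block structure, and motif
redundancy. The last matters for the TFBS statistics: synthetic motifs are
maximally informative (consensus probability 0.9, width 7–8), so *any*
in-site substitution destroys the hit and the background fraction `p_t`
saturates at 1 (or is undefined when no background position touches a
site). The Eq.-level significance machinery is therefore validated in unit
tests with controlled counts rather than on the end-to-end fixture.
Motif widths 7–8 are chosen so that a planted single-base substitution
genuinely flips hits at the 1e-4 threshold; for wider high-information
motifs a single mismatch stays below threshold, which is true of real
scanners too.

## Numerical and tie conventions

- `meth = 0.5` is hypermethylated (hypo predicate is strict `<`).
- Nearest-TSS and top-percentile ties break by lexicographic gene id; the
  percentile count is `ceil(n · p/100)`, at least 1.
- Region/SNP intervals are 0-based half-open everywhere.
- Permutation p-values use the add-one correction and can never be 0.
- The binomial tails are strict (`X > k`), matching the association
  definition; `k = n` gives exactly 0.
- All randomness flows through numpy Generators seeded from one integer;
  generator sub-streams are derived per stage, so every artifact is
  byte-reproducible from (configuration, seed).

## Problem sizes in the shipped checks

The test-suite and the acceptance script run at deliberately desk-sized
conditions chosen to keep the checks sharp: the default synthetic cohort
(42 samples × ~2.6k CpGs), 500 random profiles for the segmentation
oracle, 100 exact-oracle triples up to n = 10,000, all 2×2 tables with
total ≤ 40 for Fisher enumeration, and 100–200 simulated traits × 200
permutations for null calibration. The study's genome-scale counts (tens
of thousands of regions, hundreds of thousands of catalog SNPs) depend on
the original resources and are not reproduction targets of the run-based
reimplementation.
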