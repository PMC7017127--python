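# Methods

This note documents the models, estimators and design decisions behind
`lglwgs`, in the order the pipeline runs them.

## Synthetic paired-genome generator

The generator emulates the statistical structure the analysis assumes, not
sequencing itself: no reads, alignments or mapping qualities are produced
(those steps sit upstream of this package in a real study).

**Genome.** Each of `n_chromosomes` chromosomes (default 4 × 1 Mb) is
partitioned into equal windows, one per entry of `gc_profile` (default 16
windows), and bases are drawn i.i.d. with P(G or C) equal to the window's
target. The profile is rotated by 5 positions per chromosome so each GC
level occurs at several loci; without that rotation GC would be perfectly
confounded with the fixed copy-number segments and no GC correction could
be identified. Realised window GC tracks its target to within ±0.01 at
these window sizes (tests assert ±0.03).

**Coverage.** Bins of `bin_size` (default 10 kb) mappable bases are cut
from the reference. The normal sample draws
`count ~ Poisson(mu · f(gc))` per bin and the tumor
`count ~ Poisson(mu · (c/2) · f(gc))`, with `mu = mean_fragments_per_bin`
(default 100), `c` the true tumor copy number, and the bias
`f(gc) = exp(a·(gc−0.5) + b·(gc−0.5)²)` (defaults a=2, b=0). The
log-linear/quadratic family is the simplest smooth bias a nonparametric
LOWESS must recover without being told the functional form. The planted
truth is one deletion (c=1, 40 bins), one gain (c=3, 40 bins) and one
amplification (c=4, 60 bins) over a diploid baseline — every segment well
above the 30-bin floor the recovery checks assume. Expected tumor/normal
ratio is c/2 independent of GC because the bias multiplies both samples.

**Variants.** 170 sites by default: 100 germline (~half heterozygous at
allele fraction 0.5/0.5, half homozygous at 1/1), 50 somatic (0.5 tumor,
0 normal) and 20 shared low-frequency artifacts with a common allele
fraction drawn U(0.05, 0.15) in both samples — contamination-like sites
that sit clearly inside the "low frequency in both" class the labelling
rule removes; an artifact drawn at the 0.25 decision boundary would be
indistinguishable from a subclonal somatic event at depth 30 and would not
represent that class. Per sample, depth is Poisson(`site_depth_mean`,
default 30) and alt reads Binomial(depth, af·(1−ε) + (1−af)·ε) with
`base_error_rate` ε (default 0.01), so errors both seed alt reads on
reference alleles and erode true alleles. ε is a free simulation
parameter, not an estimate of any instrument's error rate.

Genotype likelihoods use the standard diploid read model
`log10 L(g) = Σ_reads log10 P(base | g, ε)` with
P(ref | hom-ref) = 1−ε, P(· | het) = ½, P(alt | hom-alt) = 1−ε, giving
e.g. GL(hom-ref) = 10·log10(0.99) ≈ −0.0436 for ten clean reference
reads. Site QUAL is the Phred-scaled flat-prior probability that *both*
samples are hom-ref: `−10·Σ_s (GL_s(hom-ref) − log10 Σ_g 10^GL_s(g))`.
Sites where either sample draws zero depth are dropped and logged.
Records are written as VCF 4.2 with FORMAT GL:AD:DP (or PL, Phred-rounded
and min-normalized, for dialect coverage).

The generator also emits the externally-produced inputs the gene funnel
consumes — variant→gene impact annotations, a rat→human homolog table
(including renames such as Stag→STAG2 and a few unmapped symbols) and a
two-tier cancer-gene-census table — plus truth tables: per-bin copy
number, per-variant class and allele fractions, and the exact gene set a
correct funnel must report.

All randomness flows through `numpy` Generators derived from one seed via
`SeedSequence` spawn keys (one stream per stage); identical config + seed
reproduces every output byte-for-byte. No global random state is touched.

## Copy-number model

`CopyNumberModel.fit()` composes five operations, all public:

**Binning** (`build_bins`) accumulates exactly `target_mappable` mappable
positions per bin (all positions when no mappability track is given), so
genomic bin widths vary and the last bin per chromosome carries the
remainder; GC fractions are computed over mappable positions only.
Fragments are assigned to bins by midpoint under half-open coordinates
(each fragment counts exactly once; a midpoint on a bin start belongs to
that bin). Coordinates are 0-based half-open internally and in BED output;
VCF interaction is 1-based.

**GC correction** (`fit_gc_curve`, `normalize_coverage`) fits a LOWESS of
raw count on GC (span `smoothing_fraction` = 0.3, three robustifying
iterations) evaluated on a 101-point grid, and divides each bin's count by
the curve at its GC. Bins with no mappable bases or non-positive fitted
expectation get a missing ratio. Degenerate GC support yields a constant
curve at the mean count. `fit()` then applies a **second pass**: the curve
is refitted on the copy-neutral bins only (ratio within ±25% of the
genome-wide median) and ratios are recomputed. This prevents copy-number
segments from distorting the correction at the GC values they happen to
occupy — with a single pass the curve absorbs part of the aneuploidy and
leaves residual GC structure that the segmentation then "discovers".

**Recentering.** Ratios are divided by the median of the copy-neutral
subset, not of all bins: in an aneuploid genome the gained bins outrank
part of the diploid distribution, so the global median sits above the
diploid centre and would deflate every level by several percent — enough
to pull mixture components off the c/2 grid. The assumption, stated
explicitly: the modal coverage level is the baseline ploidy (default 2).

**Segmentation** (`segment_cbs`) runs circular binary segmentation on
log2(ratio + 1e−3): for the current segment, find the arc (i, j]
maximizing the pooled-variance two-sample t statistic between arc and
complement (interior arcs cover the circular wrap because the statistic is
symmetric under complementation); accept the split when the permutation
p-value of the max statistic is below `alpha` (default 0.01, default 1000
permutations, p = (1+exceedances)/(1+B)); recurse on the pieces. Every
resulting piece must have at least `min_width` (default 2) bins.
Permutations stop early as soon as enough exceedances have accumulated to
guarantee p ≥ alpha, which makes null series cheap without changing any
decision. Afterwards adjacent segments whose log2 means differ by less
than `prune_delta` (default 0.05 — well under the smallest true
copy-state contrast, log2(1.5) ≈ 0.58) are merged. Zero-variance series
produce t = 0 (no split) when means agree; ties in the arc scan break to
the lexicographically first (i, j). Missing bins are dropped before
segmentation with index bookkeeping and reported as unassigned, never
imputed. The pseudocount bounds log2(0) for homozygous-deletion bins.

A false split costs little here: the affected bins still receive the
correct copy state from the mixture stage, so the alpha-level false-split
rate (verified ≤ 2·alpha on pure-noise series) is the relevant budget.

**Genotyping** (`genotype_segments`) fits 1-D Gaussian mixtures to the
segment mean ratios, each mean replicated `n_bins` times (exact integer
length-weighting), for k = 1 .. max_copy+1 components (EM, k-means++
init, 5 restarts), selecting k by BIC. Two guards keep the mixture on the
copy-state grid: `reg_covar = 1e−3` floors component variance at the
within-state scale (states are 0.5 apart on the ratio scale), so BIC does
not shatter one state into near-degenerate components; and segments
shorter than `min_fit_bins = 5` do not inform the fit — a 2–3-bin
segment's level is dominated by noise and would otherwise spawn an
off-grid component — though they are still genotyped under the fitted
model. Each component maps to the integer state c minimizing
|mean − c/2| (clipped to [0, max_copy], default 6); components mapping to
the same state are merged by summing posteriors; each segment takes its
maximum-posterior state with that posterior. Non-convergent EM falls back
to the best restart with a warning. Multiplying all raw counts by a
constant leaves boundaries and states unchanged (the curve scales with the
counts).

## Somatic labelling

Filters run in a fixed order and the first violated rule is reported:
no coverage in either sample; best alt support across samples
< `min_alt_reads` (2); best allele fraction across samples < `min_af`
(0.1); site quality not strictly greater than `min_site_qual` (5).
The across-samples maximum is used for the support rules (a somatic
variant has, by definition, no support in the normal).

For a passing site, flat-prior posteriors come from the GL triple
(computed relative to the maximum for numerical stability; posteriors sum
to 1 within 1e−9). The two evidence scores are Phred-scaled and capped at
200 to avoid infinities when posteriors saturate. Decision order:

1. **Shared low frequency** — tumor AF < `low_af_cutoff` (0.25) *and* the
   normal has ≥ 1 alt read at AF < `low_af_cutoff`. Applied before the
   evidence rule: a contamination-like shared variant is removed even when
   its evidence scores would pass.
2. **Somatic** — both evidence scores ≥ `min_evidence_phred` (10).
3. **Germline** — the normal's non-reference evidence ≥ the same
   threshold.
4. **Reference** otherwise.

Evidence thresholds are applied to normalized posteriors rather than raw
likelihoods, making the decision invariant to the arbitrary GL scale (PL
input, normalized or not, labels identically). The threshold value 10
(posterior error ≤ 0.1) and the 0.25 cutoff are exposed configuration;
records with missing likelihoods are labelled `failed_site_filter`
(`no_likelihood`). Multi-allelic records must be split upstream; the
reader rejects them explicitly.

## Gene prioritization

Somatic calls join one impact annotation per (variant, gene); pairs with
QUAL strictly > `min_impact_qual` (20) and impact in {HIGH, MODERATE}
pass (unannotated variants are tallied, unknown impact strings are an
error naming the row). Homolog mapping is a join against a user-supplied
table (source symbols must be unique; renames counted case-insensitively);
census membership is a join against a user-supplied two-tier table.
Canonical-transcript resolution is delegated to the annotation input. The
report (one row per census gene with ≥ 1 passing variant, sorted by
symbol) carries tier, the variant rollup, and validation flags rendered
"unknown" unless a validation table is supplied.

## Pipeline and evaluation

`run_pipeline` chains simulate → cnvmap → somatic-label → gene-report →
evaluate, writing a manifest with the config hash and seed; a rerun with
the same config is byte-identical (asserted in tests). Evaluation scores
per-bin copy-state accuracy, the truth-class × label confusion matrix,
somatic sensitivity, the fraction of each non-somatic class labelled
somatic, and whether the report equals the planted gene set exactly.
Coordinate mismatches between artifacts and truth are hard errors.

## Problem sizes and what the checks show

The shipped checks run the default 400-bin genome and 170-site VCF, a
2000-bin diploid genome for GC flattening, 100 planted-step series (10–50
bins, interior change-points, step U(0.5, 1.5) against noise σ = 0.1) for
the change-point oracle comparison, and 800 pure-noise series (100 bins,
σ = 0.1) for the null false-split rate; the whole suite completes in well
under a minute of compute. These sizes make sampling noise small relative
to the tolerances checked (e.g. mixture components within 0.05 of c/2)
while keeping runs fast; at state c=4 that tolerance is ~2.5% of the
level, comparable to the combined count/curve/recentering noise, so a
marginal excursion on an unlucky seed is possible and expected.

Passing these checks shows the estimators are correct under the generative
model they assume — Poisson counts, smooth multiplicative GC bias, clonal
integer copy numbers, i.i.d. read errors, biallelic sites. Real data add
mappability artifacts, overdispersion, subclonality, multi-allelic and
indel sites, and correlated errors, none of which the generator emulates;
performance numbers here are upper bounds, not forecasts, for real
genomes.

## Known limitations

- No allele-fraction/BAF refinement of the CNV map; copy states are
  integer and clonal by construction.
- The labeller trusts the caller's GL model; it does not re-genotype from
  reads.
- The permutation CBS is O(n² · B) per split test; chromosome arms of
  ~10⁴ bins are fine, but much longer series would want the O(n) max-t
  recursions of the published algorithm.
- Gene prioritization is a pair of table joins; it inherits whatever
  incompleteness the supplied homolog and census tables have.
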