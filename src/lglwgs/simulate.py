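"""Synthetic paired tumor/normal genome generator.

Emulates the data a read-depth CNV + somatic-labelling analysis consumes:
a small multi-chromosome reference with heterogeneous GC, per-bin fragment
counts for a diploid normal and an aneuploid tumor with GC-dependent
coverage bias, and a paired VCF of germline / somatic / shared-artifact
variants with genotype likelihoods computed under a diploid error model.
Truth tables are emitted alongside every artifact so downstream calls can
be scored exactly.

All randomness flows through `numpy.random.Generator` streams derived from
the single configured seed; identical config + seed yields byte-identical
output files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from . import vcfio

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: default tumor copy-number truth: (chrom, start_bp, end_bp, copy_number)
DEFAULT_CNV_TRUTH = (
    ("chr1", 300_000, 700_000, 1),
    ("chr2", 300_000, 700_000, 3),
    ("chr3", 200_000, 800_000, 4),
)

#: default piecewise-constant GC targets; one equal-width window per value.
#: The profile is rotated per chromosome (see :func:`simulate_genome`) so
#: that each GC level occurs mostly outside any one CNV segment and the
#: robust LOWESS can separate GC bias from copy number.
DEFAULT_GC_PROFILE = (
    0.30, 0.50, 0.40, 0.60, 0.35, 0.55, 0.45, 0.65,
    0.50, 0.30, 0.60, 0.40, 0.70, 0.50, 0.35, 0.55,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic tumor/normal dataset.

    The defaults define a 4 x 1 Mb genome (400 bins of 10 kb) whose tumor
    carries one deletion (c=1), one gain (c=3) and one amplification (c=4)
    over a diploid baseline, sequenced to ~100 fragments/bin with a
    log-linear GC bias of slope ``a=2``, plus 170 variant sites (100
    germline, 50 somatic, 20 shared low-frequency artifacts) at mean depth
    30 and base error rate 1%.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length_bp: int = 1_000_000
    gc_profile: tuple = DEFAULT_GC_PROFILE
    mean_fragments_per_bin: float = 100.0
    gc_bias_coefficients: tuple = (2.0, 0.0)
    cnv_truth: tuple = DEFAULT_CNV_TRUTH
    n_germline_variants: int = 100
    n_somatic_variants: int = 50
    n_artifact_variants: int = 20
    site_depth_mean: float = 30.0
    base_error_rate: float = 0.01
    bin_size: int = 10_000
    tumor_sample: str = "RNK16"
    normal_sample: str = "F344"

    def __post_init__(self):
        for g in self.gc_profile:
            if not (0.0 < g < 1.0):
                raise ConfigurationError(f"gc_profile value {g} outside (0, 1)")
        if not (0.0 < self.base_error_rate <= 0.1):
            raise ConfigurationError(
                f"base_error_rate {self.base_error_rate} outside (0, 0.1]"
            )
        if self.mean_fragments_per_bin <= 0 or self.site_depth_mean <= 0:
            raise ConfigurationError("rate parameters must be positive")
        by_chrom: dict[str, list] = {}
        for chrom, start, end, cn in self.cnv_truth:
            if not (0 <= cn <= 6):
                raise ConfigurationError(f"copy number {cn} outside 0..6")
            if not (0 <= start < end):
                raise ConfigurationError(f"bad CNV interval {start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ConfigurationError(
                        f"overlapping cnv_truth segments on {chrom}"
                    )

    @property
    def chrom_names(self) -> list:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def rng(self, stream: int) -> np.random.Generator:
        """Named substream of the global seed (one per generation stage)."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )

    def to_flat_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in sorted(asdict(self).items()):
                fh.write(f"{key}={value!r}\n")


@dataclass
class TruthSet:
    """Ground truth for scoring: per-bin copy numbers, per-variant classes
    and allele fractions, and the gene set the prioritization funnel should
    report."""

    bins: pd.DataFrame          # chrom, start, end, true_copy
    variants: pd.DataFrame      # chrom, pos, ref, alt, truth_class, af_*, gene, impact, annotated, qual
    expected_report_genes: tuple  # rat symbols the gene funnel must report

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        _write_tsv(self.bins, outdir / "truth_bins.tsv")
        _write_tsv(self.variants, outdir / "truth_variants.tsv")
        pd.DataFrame({"gene_symbol": list(self.expected_report_genes)}).pipe(
            _write_tsv, outdir / "truth_report_genes.tsv"
        )

    @classmethod
    def read(cls, outdir) -> "TruthSet":
        outdir = Path(outdir)
        genes = pd.read_csv(outdir / "truth_report_genes.tsv", sep="\t")
        return cls(
            bins=pd.read_csv(outdir / "truth_bins.tsv", sep="\t"),
            variants=pd.read_csv(outdir / "truth_variants.tsv", sep="\t"),
            expected_report_genes=tuple(genes["gene_symbol"].tolist()),
        )


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimulationConfig, fasta_path=None):
    """Draw a random genome whose GC composition tracks ``gc_profile``.

    Each chromosome is partitioned into ``len(gc_profile)`` equal windows;
    bases are drawn i.i.d. within a window with P(G or C) equal to the
    window's target.  On chromosome k the profile is rotated by 5*k
    positions, so every GC level appears on several chromosomes and is not
    tied to any one locus.  Returns ``(sequences, windows)`` where
    ``sequences`` maps chromosome name to string and ``windows`` records
    the target and realised GC per window.  If ``fasta_path`` is given the
    genome is also written as FASTA (wrapped at 70 columns).
    """
    rng = config.rng(0)
    sequences: dict[str, str] = {}
    rows = []
    n_windows = len(config.gc_profile)
    for ci, chrom in enumerate(config.chrom_names):
        length = config.chrom_length_bp
        edges = np.linspace(0, length, n_windows + 1).astype(int)
        parts = []
        for w in range(n_windows):
            target = config.gc_profile[(w + 5 * ci) % n_windows]
            size = edges[w + 1] - edges[w]
            p_at = (1.0 - target) / 2.0
            p_gc = target / 2.0
            idx = rng.choice(4, size=size, p=[p_at, p_gc, p_gc, p_at])
            seq = _BASES[idx]
            observed = float(np.mean((idx == 1) | (idx == 2)))
            parts.append(seq)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(edges[w]),
                    "end": int(edges[w + 1]),
                    "target_gc": target,
                    "observed_gc": observed,
                }
            )
        sequences[chrom] = b"".join(p.tobytes() for p in parts).decode("ascii")
    windows = pd.DataFrame(rows)
    if fasta_path is not None:
        write_fasta(sequences, fasta_path)
    return sequences, windows


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# coverage


def gc_bias_factor(gc, coefficients):
    """Multiplicative coverage bias f(gc) = exp(a*(gc-0.5) + b*(gc-0.5)^2)."""
    a, b = coefficients
    d = np.asarray(gc, dtype=float) - 0.5
    return np.exp(a * d + b * d * d)


def true_copy_per_bin(config: SimulationConfig, bins: pd.DataFrame) -> np.ndarray:
    """Tumor copy number of each bin (by bin midpoint; diploid elsewhere)."""
    copy = np.full(len(bins), 2, dtype=int)
    mid = ((bins["start"] + bins["end"]) // 2).to_numpy()
    for chrom, start, end, cn in config.cnv_truth:
        mask = (bins["chrom"] == chrom).to_numpy() & (mid >= start) & (mid < end)
        copy[mask] = cn
    return copy


def simulate_coverage(config: SimulationConfig, sequences: dict, tsv_path=None):
    """Per-bin fragment counts for normal and tumor.

    Bins of ``bin_size`` mappable bases are cut from the reference; the
    normal sample draws Poisson(mu * f(gc)) fragments per bin and the tumor
    Poisson(mu * (c/2) * f(gc)) with ``c`` the true tumor copy number, so
    the tumor/normal ratio is c/2 independent of GC.  Returns a DataFrame
    with columns chrom, start, end, mappable_bases, gc, count_normal,
    count_tumor, true_copy; the TSV written to ``tsv_path`` omits the truth
    column (it belongs to the truth tables).
    """
    from .coverage import build_bins

    rng = config.rng(1)
    bins = build_bins(sequences, target_mappable=config.bin_size)
    copy = true_copy_per_bin(config, bins)
    f = gc_bias_factor(bins["gc"].to_numpy(), config.gc_bias_coefficients)
    mappable_frac = bins["mappable_bases"].to_numpy() / config.bin_size
    mu = config.mean_fragments_per_bin * f * mappable_frac
    bins = bins.copy()
    empty = bins["mappable_bases"].to_numpy() == 0
    count_normal = rng.poisson(mu).astype(float)
    count_tumor = rng.poisson(mu * (copy / 2.0)).astype(float)
    count_normal[empty] = np.nan
    count_tumor[empty] = np.nan
    bins["count_normal"] = count_normal
    bins["count_tumor"] = count_tumor
    bins["true_copy"] = copy
    if tsv_path is not None:
        _write_tsv(bins.drop(columns=["true_copy"]), tsv_path)
    return bins


# ---------------------------------------------------------------------------
# variants + genes

_CLASS_GERMLINE_HET = "germline_het"
_CLASS_GERMLINE_HOM = "germline_hom"
_CLASS_SOMATIC = "somatic"
_CLASS_ARTIFACT = "artifact_shared_lowfreq"

#: rat genes planted with HIGH/MODERATE somatic variants -> must be reported
PLANTED_SOMATIC_CGC = ("Jak1", "Ddr2", "Fat1", "Ncor2", "Stag")
#: CGC genes receiving only germline / low-impact variants -> must NOT appear
CONTROL_CGC = ("Brd3", "Nono", "Thrap3")
TIER2_CGC = ("Ezh2", "Gpc3")
FILLER_GENES = (
    "Abca4", "Bcan", "Cdh23", "Dnah5", "Emb", "Fbn1", "Gria2",
    "Hspa4", "Ins2", "Klf4", "Lama1", "Myo7a", "Nrxn1", "Pclo",
)
#: rat -> human homolog map; Stag and Ins2 change name, Nrxn1/Pclo unmapped.
HOMOLOG_MAP = {
    "Jak1": "JAK1", "Ddr2": "DDR2", "Fat1": "FAT1", "Ncor2": "NCOR2",
    "Stag": "STAG2", "Brd3": "BRD3", "Nono": "NONO", "Thrap3": "THRAP3",
    "Ezh2": "EZH2", "Gpc3": "GPC3",
    "Abca4": "ABCA4", "Bcan": "BCAN", "Cdh23": "CDH23", "Dnah5": "DNAH5",
    "Emb": "EMB", "Fbn1": "FBN1", "Gria2": "GRIA2", "Hspa4": "HSPA4",
    "Ins2": "INS", "Klf4": "KLF4", "Lama1": "LAMA1", "Myo7a": "MYO7A",
}
CGC_TIERS = {
    "JAK1": 1, "DDR2": 1, "FAT1": 1, "NCOR2": 1, "STAG2": 1,
    "BRD3": 1, "NONO": 1, "THRAP3": 1, "EZH2": 2, "GPC3": 2,
}

_IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")


def _log10_gl(ref_reads: int, alt_reads: int, eps: float):
    """Diploid genotype log10-likelihoods (hom-ref, het, hom-alt).

    log10 L(g) = sum over reads of log10 P(base | g, eps) with
    P(ref | hom-ref) = 1 - eps, P(alt | hom-ref) = eps, P(. | het) = 1/2.
    """
    dp = ref_reads + alt_reads
    l_rr = ref_reads * math.log10(1 - eps) + alt_reads * math.log10(eps)
    l_ra = dp * math.log10(0.5)
    l_aa = alt_reads * math.log10(1 - eps) + ref_reads * math.log10(eps)
    return (l_rr, l_ra, l_aa)


def _log10sumexp(values):
    m = max(values)
    return m + math.log10(sum(10.0 ** (v - m) for v in values))


def site_qual(gls_per_sample, ndigits: int = 2) -> float:
    """Phred-scaled probability that the site is non-reference in at least
    one sample, under a flat genotype prior: QUAL = -10 * sum_s
    (GL_s(hom-ref) - log10 sum_g 10^GL_s(g))."""
    q = 0.0
    for gl in gls_per_sample:
        q += gl[0] - _log10sumexp(gl)
    return round(-10.0 * q, ndigits)


def _assign_genes_impacts(classes, rng):
    """Gene symbol + impact per variant, planting the CGC funnel truth.

    The first somatic variants are spread 3-per-gene over
    ``PLANTED_SOMATIC_CGC`` with HIGH/MODERATE impacts; control CGC genes
    receive germline variants (some HIGH impact, so only the somatic label
    keeps them out of the report); everything else draws filler genes and
    random impacts.
    """
    genes = []
    impacts = []
    pool = list(FILLER_GENES) + list(TIER2_CGC)
    somatic_seen = 0
    germline_seen = 0
    n_planted = 3 * len(PLANTED_SOMATIC_CGC)
    for cls in classes:
        if cls == _CLASS_SOMATIC and somatic_seen < n_planted:
            genes.append(PLANTED_SOMATIC_CGC[somatic_seen % len(PLANTED_SOMATIC_CGC)])
            impacts.append("HIGH" if somatic_seen % 2 == 0 else "MODERATE")
            somatic_seen += 1
        elif cls in (_CLASS_GERMLINE_HET, _CLASS_GERMLINE_HOM) and germline_seen < len(CONTROL_CGC) * 2:
            genes.append(CONTROL_CGC[germline_seen % len(CONTROL_CGC)])
            impacts.append("HIGH" if germline_seen % 2 == 0 else "MODERATE")
            germline_seen += 1
        else:
            genes.append(pool[int(rng.integers(len(pool)))])
            impacts.append(_IMPACTS[int(rng.integers(len(_IMPACTS)))])
    return genes, impacts


def simulate_variants(config: SimulationConfig, sequences: dict, vcf_path=None,
                      gl_format: str = "GL"):
    """Paired-sample variant records with genotype likelihoods.

    Truth classes and their allele fractions (tumor, normal):
    germline_het (0.5, 0.5); germline_hom (1, 1); somatic (0.5, 0);
    artifact_shared_lowfreq (u, u) with u ~ U(0.08, 0.20).  Per sample,
    depth ~ Poisson(site_depth_mean) and alt reads ~ Binomial(depth, p)
    with p = af*(1-eps) + (1-af)*eps, so sequencing error both seeds alt
    reads on reference alleles and erodes true alt alleles.  GLs follow the
    diploid model of :func:`_log10_gl`; QUAL follows :func:`site_qual`.
    Sites where either sample draws zero depth are dropped and logged.

    Returns the variants DataFrame (also the truth table); writes a VCF 4.2
    with FORMAT GL:AD:DP (or PL:AD:DP when ``gl_format='PL'``).
    """
    rng = config.rng(2)
    eps = config.base_error_rate
    n_g, n_s, n_a = (
        config.n_germline_variants,
        config.n_somatic_variants,
        config.n_artifact_variants,
    )
    n_het = (n_g + 1) // 2
    classes = (
        [_CLASS_GERMLINE_HET] * n_het
        + [_CLASS_GERMLINE_HOM] * (n_g - n_het)
        + [_CLASS_SOMATIC] * n_s
        + [_CLASS_ARTIFACT] * n_a
    )
    n = len(classes)

    # unique positions across the genome
    chroms = config.chrom_names
    taken = set()
    sites = []
    while len(sites) < n:
        c = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, config.chrom_length_bp + 1))
        if (c, pos) in taken:
            continue
        taken.add((c, pos))
        sites.append((c, pos))

    genes, impacts = _assign_genes_impacts(classes, rng)

    rows = []
    n_dropped = 0
    for (chrom, pos), cls, gene, impact in zip(sites, classes, genes, impacts):
        ref = sequences[chrom][pos - 1]
        alt_choices = [b for b in "ACGT" if b != ref]
        alt = alt_choices[int(rng.integers(3))]
        if cls == _CLASS_GERMLINE_HET:
            af_t, af_n = 0.5, 0.5
        elif cls == _CLASS_GERMLINE_HOM:
            af_t, af_n = 1.0, 1.0
        elif cls == _CLASS_SOMATIC:
            af_t, af_n = 0.5, 0.0
        else:
            # shared artifacts sit clearly below the low-frequency cutoff
            # in both samples (contamination-like allele fractions ~5-15%)
            u = float(rng.uniform(0.05, 0.15))
            af_t, af_n = u, u
        per_sample = {}
        dropped = False
        for name, af in ((config.tumor_sample, af_t), (config.normal_sample, af_n)):
            dp = int(rng.poisson(config.site_depth_mean))
            if dp == 0:
                dropped = True
                break
            p_alt = af * (1 - eps) + (1 - af) * eps
            alt_reads = int(rng.binomial(dp, p_alt))
            per_sample[name] = (dp - alt_reads, alt_reads)
        if dropped:
            n_dropped += 1
            log.warning("dropping zero-depth site %s:%d", chrom, pos)
            continue
        gl_t = _log10_gl(*per_sample[config.tumor_sample], eps)
        gl_n = _log10_gl(*per_sample[config.normal_sample], eps)
        qual = site_qual([gl_t, gl_n])
        ad_t = per_sample[config.tumor_sample]
        ad_n = per_sample[config.normal_sample]
        rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "truth_class": cls, "af_tumor": af_t, "af_normal": af_n,
                "gene": gene, "impact": impact, "annotated": True,
                "qual": qual,
                "ad_ref_tumor": ad_t[0], "ad_alt_tumor": ad_t[1],
                "ad_ref_normal": ad_n[0], "ad_alt_normal": ad_n[1],
                "gl_tumor": gl_t, "gl_normal": gl_n,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    # a few germline filler sites lack annotation rows (exercises the
    # unannotated tally downstream)
    mask = (df["truth_class"] == _CLASS_GERMLINE_HET) & ~df["gene"].isin(
        PLANTED_SOMATIC_CGC + CONTROL_CGC
    )
    df.loc[df.index[mask][:3], "annotated"] = False

    if n_dropped:
        log.info("dropped %d zero-depth sites", n_dropped)
    if vcf_path is not None:
        vcfio.write_paired_vcf(
            df,
            vcf_path,
            contigs={c: config.chrom_length_bp for c in chroms},
            tumor=config.tumor_sample,
            normal=config.normal_sample,
            gl_format=gl_format,
        )
    return df


def annotation_tables(variants: pd.DataFrame):
    """Impact-annotation, homolog and cancer-gene-census tables for the
    simulated variants (the externally-produced inputs of the gene funnel)."""
    ann = variants.loc[
        variants["annotated"],
        ["chrom", "pos", "ref", "alt", "gene", "impact"],
    ].rename(columns={"gene": "gene_symbol"})
    homologs = pd.DataFrame(
        sorted(HOMOLOG_MAP.items()), columns=["source_symbol", "target_symbol"]
    )
    cgc = pd.DataFrame(
        sorted(CGC_TIERS.items()), columns=["human_symbol", "tier"]
    )
    return ann.reset_index(drop=True), homologs, cgc


def expected_report_genes(variants: pd.DataFrame, min_impact_qual: float = 20.0):
    """Rat symbols the funnel must report: CGC genes carrying at least one
    annotated truth-somatic variant of HIGH/MODERATE impact with
    QUAL > min_impact_qual."""
    keep = variants[
        (variants["truth_class"] == _CLASS_SOMATIC)
        & variants["annotated"]
        & variants["impact"].isin(["HIGH", "MODERATE"])
        & (variants["qual"] > min_impact_qual)
    ]
    out = []
    for gene in keep["gene"].unique():
        human = HOMOLOG_MAP.get(gene)
        if human is not None and human in CGC_TIERS:
            out.append(gene)
    return tuple(sorted(out))


@dataclass
class SyntheticDataset:
    """One fully materialised synthetic run (in memory + optional files)."""

    config: SimulationConfig
    sequences: dict
    gc_windows: pd.DataFrame
    coverage: pd.DataFrame
    variants: pd.DataFrame
    annotations: pd.DataFrame
    homologs: pd.DataFrame
    cgc: pd.DataFrame
    truth: TruthSet


def simulate_dataset(config: SimulationConfig, outdir=None,
                     gl_format: str = "GL") -> SyntheticDataset:
    """Generate genome, coverage, variants, annotation tables and truth.

    When ``outdir`` is given, writes reference.fa, bins.tsv, variants.vcf,
    annotations.tsv, homologs.tsv, cgc.tsv, config.txt and the truth tables
    there, all byte-deterministic in config + seed.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "reference.fa" if outdir else None
    sequences, windows = simulate_genome(config, fasta_path=fasta)
    coverage = simulate_coverage(
        config, sequences, tsv_path=(outdir / "bins.tsv" if outdir else None)
    )
    variants = simulate_variants(
        config, sequences,
        vcf_path=(outdir / "variants.vcf" if outdir else None),
        gl_format=gl_format,
    )
    ann, homologs, cgc = annotation_tables(variants)
    truth = TruthSet(
        bins=coverage[["chrom", "start", "end", "true_copy"]].copy(),
        variants=variants.drop(columns=["gl_tumor", "gl_normal"]),
        expected_report_genes=expected_report_genes(variants),
    )
    if outdir is not None:
        _write_tsv(ann, outdir / "annotations.tsv")
        _write_tsv(homologs, outdir / "homologs.tsv")
        _write_tsv(cgc, outdir / "cgc.tsv")
        config.to_flat_file(outdir / "config.txt")
        truth.write(outdir)
    return SyntheticDataset(
        config=config, sequences=sequences, gc_windows=windows,
        coverage=coverage, variants=variants, annotations=ann,
        homologs=homologs, cgc=cgc, truth=truth,
    )
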