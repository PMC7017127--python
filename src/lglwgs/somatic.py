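"""Paired tumor/normal somatic labelling from genotype likelihoods.

A site is called somatic when the tumor's evidence of being non-reference
and the normal's evidence of being homozygous reference are both strong:
under a flat genotype prior, per-sample posteriors are computed from the
log10 genotype likelihoods and Phred-scaled into two scores (SpeedSeq-style
SSC), each required to clear ``min_evidence_phred``.  Before that evidence
rule, low-frequency variants shared by both samples (contamination-like
artifacts) are removed.  Site-level support filters (allele fraction,
supporting reads, site quality) run first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from . import vcfio
from .errors import ConfigurationError, VcfFormatError

log = logging.getLogger(__name__)

PHRED_CAP = 200.0

LABELS = ("somatic", "germline", "reference", "shared_low_frequency",
          "failed_site_filter")


@dataclass(frozen=True)
class SampleCall:
    """One sample's evidence at a site: log10 GL triple (hom-ref, het,
    hom-alt) or None, allele depths (ref, alt), and total depth."""

    gl: Optional[tuple]
    ad: tuple
    dp: int

    @property
    def alt_depth(self) -> int:
        return int(self.ad[1])

    @property
    def allele_fraction(self) -> float:
        return self.ad[1] / self.dp if self.dp > 0 else 0.0


@dataclass(frozen=True)
class VariantSite:
    """One biallelic VCF record with per-sample likelihoods and depths."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    tumor: SampleCall
    normal: SampleCall


@dataclass(frozen=True)
class SomaticThresholds:
    """Filter and evidence thresholds.

    min_af / min_alt_reads / min_site_qual are the site-support filters
    (allele fraction >= 0.1 in at least one sample, >= 2 supporting reads,
    site quality strictly > 5); min_evidence_phred is the Phred floor both
    somatic evidence scores must reach; low_af_cutoff defines "low
    frequency" for the shared-artifact removal; min_impact_qual is the
    stricter site quality used downstream by the gene-level filter.
    """

    min_evidence_phred: float = 10.0
    low_af_cutoff: float = 0.25
    min_af: float = 0.1
    min_alt_reads: int = 2
    min_site_qual: float = 5.0
    min_impact_qual: float = 20.0

    def __post_init__(self):
        vals = (self.min_evidence_phred, self.low_af_cutoff, self.min_af,
                self.min_alt_reads, self.min_site_qual, self.min_impact_qual)
        if any(v < 0 for v in vals):
            raise ConfigurationError("thresholds must be non-negative")
        if not self.low_af_cutoff < 0.5:
            raise ConfigurationError("low_af_cutoff must be below 0.5")


@dataclass(frozen=True)
class SomaticCall:
    site: VariantSite
    label: str
    tumor_nonref_phred: float
    normal_ref_phred: float
    reason: Optional[str] = None


def site_filter(site: VariantSite, thresholds: SomaticThresholds = SomaticThresholds()):
    """Site-support filter: pass iff some sample has allele fraction >=
    min_af, the best alt support is >= min_alt_reads, and QUAL is strictly
    greater than min_site_qual.  Returns (True, None) or (False, reason
    naming the first violated rule); both rules on read support are
    evaluated across samples (maximum)."""
    if site.tumor.dp == 0 and site.normal.dp == 0:
        return False, "no_coverage"
    max_alt = max(site.tumor.alt_depth, site.normal.alt_depth)
    if max_alt < thresholds.min_alt_reads:
        return False, "min_alt_reads"
    max_af = max(site.tumor.allele_fraction, site.normal.allele_fraction)
    if max_af < thresholds.min_af:
        return False, "min_af"
    if not site.qual > thresholds.min_site_qual:
        return False, "min_site_qual"
    return True, None


def genotype_posteriors(gl) -> np.ndarray:
    """Flat-prior genotype posteriors from a log10 GL triple.

    posteriors ∝ 10^GL, normalized to sum to one; computed relative to the
    maximum for numerical stability.  Raises ValueError if no GL is finite.
    """
    gl = np.asarray(gl, dtype=float)
    if not np.any(np.isfinite(gl)):
        raise ValueError("all genotype likelihoods are -inf")
    m = np.max(gl[np.isfinite(gl)])
    w = np.where(np.isfinite(gl), np.power(10.0, gl - m), 0.0)
    return w / w.sum()


def _phred(p_error: float) -> float:
    """-10 log10(p), capped at PHRED_CAP to avoid infinities."""
    if p_error <= 0:
        return PHRED_CAP
    return min(-10.0 * np.log10(p_error), PHRED_CAP)


def label_somatic(site: VariantSite,
                  thresholds: SomaticThresholds = SomaticThresholds()) -> SomaticCall:
    """Label one site that already passed the site filter.

    tumor_nonref_phred Phred-scales 1 - max(P(het), P(hom-alt)) in the
    tumor; normal_ref_phred Phred-scales 1 - P(hom-ref) in the normal.
    A shared low-frequency variant (tumor AF < low_af_cutoff, normal has
    >= 1 alt read at AF < low_af_cutoff) is removed before the evidence
    rule; then somatic iff both scores >= min_evidence_phred; else germline
    when the normal's non-reference evidence clears the threshold; else
    reference.
    """
    if site.tumor.gl is None or site.normal.gl is None:
        return SomaticCall(site, "failed_site_filter", 0.0, 0.0,
                           reason="no_likelihood")
    try:
        post_t = genotype_posteriors(site.tumor.gl)
        post_n = genotype_posteriors(site.normal.gl)
    except ValueError:
        return SomaticCall(site, "failed_site_filter", 0.0, 0.0,
                           reason="no_likelihood")
    tumor_nonref = _phred(1.0 - max(post_t[1], post_t[2]))
    normal_ref = _phred(1.0 - post_n[0])
    normal_nonref = _phred(1.0 - max(post_n[1], post_n[2]))

    af_t = site.tumor.allele_fraction
    af_n = site.normal.allele_fraction
    if (af_t < thresholds.low_af_cutoff and site.normal.alt_depth >= 1
            and af_n < thresholds.low_af_cutoff):
        label = "shared_low_frequency"
    elif (tumor_nonref >= thresholds.min_evidence_phred
          and normal_ref >= thresholds.min_evidence_phred):
        label = "somatic"
    elif normal_nonref >= thresholds.min_evidence_phred:
        label = "germline"
    else:
        label = "reference"
    return SomaticCall(site, label, tumor_nonref, normal_ref)


class SomaticLabeller:
    """Configured tumor/normal labeller over a VCF stream."""

    def __init__(self, thresholds: SomaticThresholds = SomaticThresholds()):
        self.thresholds = thresholds

    def label_site(self, site: VariantSite) -> SomaticCall:
        ok, reason = site_filter(site, self.thresholds)
        if not ok:
            return SomaticCall(site, "failed_site_filter", 0.0, 0.0, reason=reason)
        return label_somatic(site, self.thresholds)

    def run(self, vcf_in, tumor: str, normal: str, vcf_out=None,
            summary_tsv=None):
        """Label every record of a paired VCF.

        Returns ``(calls_df, counts)`` where ``calls_df`` has one row per
        record (chrom, pos, ref, alt, qual, label, scores, AFs) and
        ``counts`` maps label -> number of records.  When ``vcf_out`` is
        given, records are rewritten with INFO fields LABEL, SSC (tumor
        non-reference Phred), NRP (normal reference Phred) and the SOMATIC
        flag.  A VCF without GL or PL raises VcfFormatError up front.
        """
        calls = list(self.iter_calls(vcf_in, tumor, normal, vcf_out=vcf_out))
        rows = [
            {
                "chrom": c.site.chrom, "pos": c.site.pos,
                "ref": c.site.ref, "alt": c.site.alt, "qual": c.site.qual,
                "label": c.label, "reason": c.reason or "",
                "tumor_nonref_phred": c.tumor_nonref_phred,
                "normal_ref_phred": c.normal_ref_phred,
                "af_tumor": c.site.tumor.allele_fraction,
                "af_normal": c.site.normal.allele_fraction,
            }
            for c in calls
        ]
        columns = ["chrom", "pos", "ref", "alt", "qual", "label", "reason",
                   "tumor_nonref_phred", "normal_ref_phred",
                   "af_tumor", "af_normal"]
        df = pd.DataFrame(rows, columns=columns)
        counts = {label: int((df["label"] == label).sum()) for label in LABELS}
        if summary_tsv is not None:
            pd.DataFrame(
                {"label": list(counts), "n": list(counts.values())}
            ).to_csv(summary_tsv, sep="\t", index=False, lineterminator="\n")
        return df, counts

    def iter_calls(self, vcf_in, tumor: str, normal: str, vcf_out=None):
        out = None
        if vcf_out is not None:
            with pysam.VariantFile(str(vcf_in)) as src:
                hdr = src.header.copy()
            for line in (
                '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic event">',
                '##INFO=<ID=SSC,Number=1,Type=Float,Description="Phred-scaled tumor non-reference posterior">',
                '##INFO=<ID=NRP,Number=1,Type=Float,Description="Phred-scaled normal reference posterior">',
                '##INFO=<ID=LABEL,Number=1,Type=String,Description="Somatic classification label">',
            ):
                hdr.add_line(line)
            out = pysam.VariantFile(str(vcf_out), "w", header=hdr)
            src = pysam.VariantFile(str(vcf_in))
        try:
            if out is None:
                for site in vcfio.read_paired_sites(vcf_in, tumor, normal):
                    yield self.label_site(site)
            else:
                sites = vcfio.read_paired_sites(vcf_in, tumor, normal)
                for rec, site in zip(src, sites):
                    call = self.label_site(site)
                    new = rec.copy()
                    new.translate(out.header)
                    label = call.label
                    if call.reason:
                        label = f"{label}:{call.reason}"
                    new.info["LABEL"] = label
                    new.info["SSC"] = round(call.tumor_nonref_phred, 2)
                    new.info["NRP"] = round(call.normal_ref_phred, 2)
                    if call.label == "somatic":
                        new.info["SOMATIC"] = True
                    out.write(new)
                    yield call
        finally:
            if out is not None:
                out.close()
                src.close()


def run_labelling(vcf_in, thresholds: SomaticThresholds = SomaticThresholds(),
                  tumor_sample_name: str = "RNK16",
                  normal_sample_name: str = "F344",
                  vcf_out=None, summary_tsv=None):
    """Functional entry point; see :meth:`SomaticLabeller.run`."""
    return SomaticLabeller(thresholds).run(
        vcf_in, tumor_sample_name, normal_sample_name,
        vcf_out=vcf_out, summary_tsv=summary_tsv,
    )
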