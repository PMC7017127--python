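"""Thin pysam-based VCF 4.2 read/write layer for paired tumor/normal records.

Records carry per-sample genotype likelihoods either as log10 GL
(FORMAT/GL, Number=G, ordered hom-ref, het, hom-alt) or as Phred-scaled
integer PL; PL is converted back with GL = -PL/10 (the usual integer
rounding of PL is accepted).
"""

from __future__ import annotations

from typing import Iterator, Optional

import pysam

from .errors import VcfFormatError


def _make_header(contigs: dict, samples, gl_format: str) -> pysam.VariantHeader:
    hdr = pysam.VariantHeader()
    for name, length in contigs.items():
        hdr.contigs.add(name, length=length)
    hdr.formats.add("GT", "1", "String", "Genotype")
    if gl_format == "GL":
        hdr.formats.add("GL", "G", "Float",
                        "log10 genotype likelihoods (hom-ref, het, hom-alt)")
    elif gl_format == "PL":
        hdr.formats.add("PL", "G", "Integer",
                        "Phred-scaled genotype likelihoods, normalized to min 0")
    else:
        raise ValueError(f"gl_format must be GL or PL, got {gl_format!r}")
    hdr.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    hdr.formats.add("DP", "1", "Integer", "Read depth")
    for s in samples:
        hdr.add_sample(s)
    return hdr


def gl_to_pl(gl) -> tuple:
    """Phred-scale a log10 GL triple, normalized so the best genotype is 0."""
    m = max(gl)
    return tuple(int(round(-10.0 * (g - m))) for g in gl)


def pl_to_gl(pl) -> tuple:
    """Inverse of :func:`gl_to_pl` up to the normalizing constant (which all
    downstream posterior computations are invariant to)."""
    return tuple(-float(p) / 10.0 for p in pl)


def write_paired_vcf(df, path, contigs: dict, tumor: str, normal: str,
                     gl_format: str = "GL") -> None:
    """Write the simulator's variant table as a two-sample VCF.

    Expects columns chrom, pos, ref, alt, qual, ad_ref_tumor, ad_alt_tumor,
    ad_ref_normal, ad_alt_normal, gl_tumor, gl_normal.
    """
    hdr = _make_header(contigs, [tumor, normal], gl_format)
    with pysam.VariantFile(str(path), "w", header=hdr) as out:
        for row in df.itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom,
                start=row.pos - 1,
                alleles=(row.ref, row.alt),
                qual=float(row.qual),
            )
            for sample, gl, ad in (
                (tumor, row.gl_tumor, (row.ad_ref_tumor, row.ad_alt_tumor)),
                (normal, row.gl_normal, (row.ad_ref_normal, row.ad_alt_normal)),
            ):
                call = rec.samples[sample]
                call["GT"] = (None, None)  # likelihood-only records
                if gl_format == "GL":
                    call["GL"] = tuple(float(g) for g in gl)
                else:
                    call["PL"] = gl_to_pl(gl)
                call["AD"] = (int(ad[0]), int(ad[1]))
                call["DP"] = int(ad[0]) + int(ad[1])
            out.write(rec)


def _sample_call(rec, sample: str, has_gl: bool):
    from .somatic import SampleCall

    call = rec.samples[sample]
    gl: Optional[tuple]
    if has_gl:
        raw = call.get("GL")
        gl = tuple(float(g) for g in raw) if raw is not None and None not in raw else None
    else:
        raw = call.get("PL")
        gl = pl_to_gl(raw) if raw is not None and None not in raw else None
    ad = call.get("AD")
    if ad is None or None in ad:
        ad = (0, 0)
    dp = call.get("DP")
    if dp is None:
        dp = int(ad[0]) + int(ad[1])
    return SampleCall(gl=gl, ad=(int(ad[0]), int(ad[1])), dp=int(dp))


def read_paired_sites(path, tumor: str, normal: str) -> Iterator:
    """Yield :class:`~lglwgs.somatic.VariantSite` for each biallelic record.

    Raises :class:`VcfFormatError` if the header declares neither GL nor PL,
    or if a requested sample is missing.
    """
    from .somatic import VariantSite

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in (tumor, normal):
            if s not in samples:
                raise VcfFormatError(f"sample {s!r} not in VCF header {samples}")
        fmts = set(vcf.header.formats.keys())
        if "GL" in fmts:
            has_gl = True
        elif "PL" in fmts:
            has_gl = False
        else:
            raise VcfFormatError("VCF declares neither GL nor PL in FORMAT")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise VcfFormatError(
                    f"record {rec.contig}:{rec.pos} is not biallelic; "
                    "split multi-allelic records upstream"
                )
            yield VariantSite(
                chrom=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alts[0],
                qual=float(rec.qual) if rec.qual is not None else 0.0,
                tumor=_sample_call(rec, tumor, has_gl),
                normal=_sample_call(rec, normal, has_gl),
            )
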