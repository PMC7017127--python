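"""Site filters, genotype posteriors and somatic labelling."""

import math

import numpy as np
import pandas as pd
import pytest

from lglwgs import vcfio
from lglwgs.errors import VcfFormatError
from lglwgs.somatic import (
    SampleCall,
    VariantSite,
    SomaticThresholds,
    SomaticLabeller,
    site_filter,
    genotype_posteriors,
    label_somatic,
    run_labelling,
)
from lglwgs.simulate import SimulationConfig, simulate_dataset, _log10_gl

from _oracles import label_site_oracle, decimal_posteriors

THR = SomaticThresholds()


def make_site(ad_t, ad_n, qual=40.0, gl_t=None, gl_n=None, eps=0.01):
    if gl_t is None:
        gl_t = _log10_gl(ad_t[0], ad_t[1], eps)
    if gl_n is None:
        gl_n = _log10_gl(ad_n[0], ad_n[1], eps)
    return VariantSite(
        chrom="chr1", pos=100, ref="A", alt="T", qual=qual,
        tumor=SampleCall(gl=gl_t, ad=ad_t, dp=sum(ad_t)),
        normal=SampleCall(gl=gl_n, ad=ad_n, dp=sum(ad_n)),
    )


class TestSiteFilter:
    def test_passing_site(self):
        ok, reason = site_filter(make_site((20, 10), (30, 0)), THR)
        assert ok and reason is None

    def test_single_supporting_read_fails(self):
        ok, reason = site_filter(make_site((29, 1), (30, 0)), THR)
        assert not ok and reason == "min_alt_reads"

    def test_low_allele_fraction_fails(self):
        ok, reason = site_filter(make_site((98, 2), (100, 0)), THR)
        assert not ok and reason == "min_af"

    def test_qual_exactly_five_fails_strict_boundary(self):
        ok, reason = site_filter(make_site((20, 10), (30, 0), qual=5.0), THR)
        assert not ok and reason == "min_site_qual"

    def test_af_exactly_point_one_passes(self):
        ok, _ = site_filter(make_site((27, 3), (30, 0)), THR)
        assert ok

    def test_no_coverage(self):
        site = make_site((0, 0), (0, 0), gl_t=(0, 0, 0), gl_n=(0, 0, 0))
        ok, reason = site_filter(site, THR)
        assert not ok and reason == "no_coverage"


class TestPosteriors:
    def test_flat_likelihoods_give_uniform(self):
        assert np.allclose(genotype_posteriors((0.0, 0.0, 0.0)), 1 / 3)

    def test_hand_normalized_example(self):
        post = genotype_posteriors((0.0, -1.0, -1.0))
        assert np.allclose(post, [10 / 12, 1 / 12, 1 / 12])
        assert post.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dominant_het(self):
        post = genotype_posteriors((-300.0, 0.0, -300.0))
        assert post[1] > 1 - 1e-9

    def test_agrees_with_decimal_oracle(self):
        gl = (-4.32, -0.87, -12.5)
        ours = genotype_posteriors(gl)
        exact = [float(p) for p in decimal_posteriors(gl)]
        assert np.allclose(ours, exact, atol=1e-12)

    def test_all_minus_inf_rejected(self):
        with pytest.raises(ValueError):
            genotype_posteriors((-np.inf, -np.inf, -np.inf))


class TestLabelSomatic:
    def test_clear_somatic_call(self):
        site = make_site((15, 15), (30, 0),
                         gl_t=(-20.0, 0.0, -20.0), gl_n=(0.0, -20.0, -20.0))
        call = label_somatic(site, THR)
        assert call.label == "somatic"
        assert call.tumor_nonref_phred >= 10
        assert call.normal_ref_phred >= 10

    def test_shared_low_frequency_removed_before_evidence(self):
        site = make_site((27, 3), (28, 2))
        call = label_somatic(site, THR)
        assert call.label == "shared_low_frequency"

    def test_both_reference(self):
        site = make_site((30, 0), (30, 0),
                         gl_t=(0.0, -20.0, -20.0), gl_n=(0.0, -20.0, -20.0))
        assert label_somatic(site, THR).label == "reference"

    def test_germline_het(self):
        site = make_site((15, 15), (16, 14))
        assert label_somatic(site, THR).label == "germline"

    def test_missing_likelihood(self):
        site = VariantSite("chr1", 1, "A", "T", 50.0,
                           SampleCall(None, (10, 10), 20),
                           SampleCall((0.0, -5.0, -9.0), (20, 0), 20))
        call = label_somatic(site, THR)
        assert call.label == "failed_site_filter"
        assert call.reason == "no_likelihood"

    def test_phred_capped_at_200(self):
        site = make_site((0, 60), (60, 0))
        call = label_somatic(site, THR)
        assert call.tumor_nonref_phred <= 200.0
        assert call.normal_ref_phred <= 200.0

    def test_evidence_threshold_monotonicity(self):
        """Raising the evidence floor never increases the somatic count."""
        rng = np.random.default_rng(0)
        sites = []
        for _ in range(120):
            dp_t, dp_n = rng.poisson(30, 2) + 1
            alt_t = int(rng.integers(0, dp_t + 1))
            alt_n = int(rng.integers(0, dp_n + 1))
            sites.append(make_site((dp_t - alt_t, alt_t), (dp_n - alt_n, alt_n)))
        prev = None
        for phred in (0.0, 5.0, 10.0, 20.0, 50.0, 150.0):
            thr = SomaticThresholds(min_evidence_phred=phred)
            n = sum(SomaticLabeller(thr).label_site(s).label == "somatic"
                    for s in sites)
            if prev is not None:
                assert n <= prev
            prev = n


class TestOracleEquivalence:
    def test_labels_match_arbitrary_precision_oracle(self):
        """Twenty constructed records spanning every label class agree with
        the decimal brute-force reimplementation."""
        cases = [
            ((15, 15), (30, 0), 200.0),   # somatic
            ((15, 15), (15, 15), 200.0),  # germline het
            ((0, 30), (0, 30), 400.0),    # germline hom
            ((30, 0), (30, 0), 0.1),      # reference-ish, fails qual
            ((27, 3), (28, 2), 60.0),     # shared low frequency
            ((29, 1), (30, 0), 60.0),     # one supporting read
            ((98, 2), (100, 0), 60.0),    # low AF
            ((20, 10), (29, 1), 80.0),    # somatic w/ one normal error read? af rules
            ((25, 5), (26, 4), 50.0),     # low AF both, shared
            ((10, 20), (30, 0), 150.0),   # strong somatic
            ((22, 8), (30, 0), 90.0),
            ((28, 2), (30, 0), 30.0),
            ((15, 15), (28, 2), 120.0),
            ((0, 25), (25, 0), 300.0),
            ((24, 6), (24, 6), 70.0),
            ((30, 0), (15, 15), 100.0),   # tumor ref, normal het
            ((16, 14), (17, 13), 90.0),
            ((26, 4), (30, 0), 40.0),
            ((5, 5), (10, 0), 5.0),       # boundary qual exactly 5
            ((12, 18), (29, 1), 140.0),
        ]
        labeller = SomaticLabeller(THR)
        for ad_t, ad_n, qual in cases:
            site = make_site(ad_t, ad_n, qual=qual)
            ours = labeller.label_site(site).label
            assert ours == label_site_oracle(site, THR), (ad_t, ad_n, qual)


@pytest.fixture(scope="module")
def labelled(default_dataset, tmp_path_factory):
    ds, outdir = default_dataset
    out = tmp_path_factory.mktemp("labelled")
    calls, counts = run_labelling(
        outdir / "variants.vcf", THR,
        tumor_sample_name="RNK16", normal_sample_name="F344",
        vcf_out=out / "labelled.vcf", summary_tsv=out / "summary.tsv",
    )
    return ds, calls, counts, out


class TestRunLabelling:
    def test_every_record_gets_one_label(self, labelled):
        ds, calls, counts, _ = labelled
        assert len(calls) == len(ds.variants)
        assert sum(counts.values()) == len(calls)

    def test_somatic_performance_on_truth(self, labelled):
        ds, calls, _, _ = labelled
        j = ds.truth.variants.merge(
            calls[["chrom", "pos", "ref", "alt", "label"]],
            on=["chrom", "pos", "ref", "alt"],
        )
        som = j[j["truth_class"] == "somatic"]
        germ = j[j["truth_class"].str.startswith("germline")]
        art = j[j["truth_class"] == "artifact_shared_lowfreq"]
        assert (som["label"] == "somatic").mean() >= 0.95
        assert (germ["label"] == "somatic").mean() <= 0.01
        assert (art["label"] == "somatic").mean() <= 0.05

    def test_labelled_vcf_round_trip(self, labelled):
        import pysam

        ds, calls, _, out = labelled
        with pysam.VariantFile(str(out / "labelled.vcf")) as vcf:
            labels = [rec.info["LABEL"].split(":")[0] for rec in vcf]
        assert labels == calls["label"].tolist()

    def test_summary_tsv(self, labelled):
        _, _, counts, out = labelled
        summary = pd.read_csv(out / "summary.tsv", sep="\t")
        assert dict(zip(summary["label"], summary["n"])) == counts

    def test_pl_encoding_gives_same_labels(self, tmp_path):
        cfg = SimulationConfig(seed=4, n_chromosomes=2,
                               chrom_length_bp=200_000,
                               n_germline_variants=20,
                               n_somatic_variants=10, n_artifact_variants=5)
        simulate_dataset(cfg, outdir=tmp_path / "gl", gl_format="GL")
        simulate_dataset(cfg, outdir=tmp_path / "pl", gl_format="PL")
        calls_gl, _ = run_labelling(tmp_path / "gl" / "variants.vcf", THR)
        calls_pl, _ = run_labelling(tmp_path / "pl" / "variants.vcf", THR)
        assert calls_gl["label"].tolist() == calls_pl["label"].tolist()

    def test_empty_vcf(self, tmp_path):
        vcfio.write_paired_vcf(
            pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "qual",
                                  "ad_ref_tumor", "ad_alt_tumor",
                                  "ad_ref_normal", "ad_alt_normal",
                                  "gl_tumor", "gl_normal"]),
            tmp_path / "empty.vcf", contigs={"chr1": 1000},
            tumor="RNK16", normal="F344",
        )
        calls, counts = run_labelling(tmp_path / "empty.vcf", THR)
        assert len(calls) == 0
        assert sum(counts.values()) == 0

    def test_vcf_without_likelihoods_is_format_error(self, tmp_path):
        path = tmp_path / "nogl.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tRNK16\tF344\n"
            "chr1\t100\t.\tA\tT\t50\t.\t.\tDP\t30\t30\n"
        )
        with pytest.raises(VcfFormatError):
            run_labelling(path, THR)

    def test_missing_sample_name_is_format_error(self, default_dataset):
        _, outdir = default_dataset
        with pytest.raises(VcfFormatError):
            run_labelling(outdir / "variants.vcf", THR,
                          tumor_sample_name="NOT_A_SAMPLE")
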