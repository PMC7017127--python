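"""Synthetic-data generator: GC targeting, coverage model, variant model,
determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lglwgs.errors import ConfigurationError
from lglwgs.simulate import (
    SimulationConfig,
    simulate_genome,
    simulate_coverage,
    simulate_variants,
    simulate_dataset,
    gc_bias_factor,
    site_qual,
    _log10_gl,
)

from _oracles import diploid_gl_oracle


def _gc(seq):
    return sum(b in "GCgc" for b in seq) / len(seq)


class TestGenome:
    def test_constant_gc_target(self):
        cfg = SimulationConfig(n_chromosomes=1, gc_profile=(0.5,),
                               chrom_length_bp=1_000_000)
        seqs, _ = simulate_genome(cfg)
        assert 0.47 <= _gc(seqs["chr1"]) <= 0.53

    def test_two_window_targets(self):
        cfg = SimulationConfig(n_chromosomes=1, gc_profile=(0.3, 0.7),
                               chrom_length_bp=200_000)
        seqs, windows = simulate_genome(cfg)
        seq = seqs["chr1"]
        assert abs(_gc(seq[:100_000]) - 0.3) <= 0.03
        assert abs(_gc(seq[100_000:]) - 0.7) <= 0.03
        assert np.allclose(windows["observed_gc"], windows["target_gc"],
                           atol=0.03)

    def test_same_seed_identical_fasta(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_chromosomes=2,
                               chrom_length_bp=100_000)
        simulate_genome(cfg, fasta_path=tmp_path / "a.fa")
        simulate_genome(cfg, fasta_path=tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    @pytest.mark.parametrize("bad", [
        dict(gc_profile=(0.5, 1.2)),
        dict(gc_profile=(0.0,)),
        dict(base_error_rate=0.0),
        dict(base_error_rate=0.2),
        dict(cnv_truth=(("chr1", 0, 100, 2), ("chr1", 50, 200, 3))),
        dict(cnv_truth=(("chr1", 0, 100, 9),)),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**bad)


class TestCoverage:
    def test_unbiased_diploid_mean(self):
        cfg = SimulationConfig(seed=3, n_chromosomes=1,
                               chrom_length_bp=1_000_000,
                               gc_bias_coefficients=(0.0, 0.0), cnv_truth=())
        seqs, _ = simulate_genome(cfg)
        cov = simulate_coverage(cfg, seqs)
        mu = cfg.mean_fragments_per_bin
        se = math.sqrt(mu / len(cov))
        for col in ("count_normal", "count_tumor"):
            assert abs(cov[col].mean() - mu) < 3 * se

    def test_cn4_segment_doubles_coverage(self):
        truth = (("chr1", 0, 1_000_000, 4),)
        cfg = SimulationConfig(seed=4, n_chromosomes=2,
                               chrom_length_bp=1_000_000,
                               gc_bias_coefficients=(0.0, 0.0),
                               cnv_truth=truth)
        seqs, _ = simulate_genome(cfg)
        cov = simulate_coverage(cfg, seqs)
        amp = cov[cov["true_copy"] == 4]["count_tumor"]
        dip = cov[cov["true_copy"] == 2]["count_tumor"]
        assert len(amp) >= 100
        assert amp.mean() / dip.mean() == pytest.approx(2.0, rel=0.05)

    def test_gc_bias_induces_count_correlation(self):
        cfg = SimulationConfig(seed=5, n_chromosomes=2,
                               chrom_length_bp=1_000_000,
                               gc_bias_coefficients=(2.0, 0.0), cnv_truth=())
        seqs, _ = simulate_genome(cfg)
        cov = simulate_coverage(cfg, seqs)
        rho = stats.spearmanr(cov["gc"], cov["count_normal"]).statistic
        assert rho > 0.5

    def test_tumor_normal_ratio_tracks_copy_number(self, default_dataset):
        """Expected tumor/normal count ratio is c/2 regardless of GC."""
        ds, _ = default_dataset
        cov = ds.coverage
        for c in (1, 2, 3, 4):
            seg = cov[cov["true_copy"] == c]
            ratio = seg["count_tumor"].sum() / seg["count_normal"].sum()
            assert ratio == pytest.approx(c / 2, rel=0.05)


class TestVariants:
    def test_gl_closed_form_reference_reads(self):
        gl = _log10_gl(10, 0, 0.01)
        assert gl[0] == pytest.approx(10 * math.log10(0.99), abs=1e-12)
        assert gl == pytest.approx(diploid_gl_oracle(10, 0, 0.01), abs=1e-12)

    def test_hom_alt_dominates_at_depth30(self):
        gl = _log10_gl(0, 30, 0.01)
        assert np.argmax(gl) == 2

    def test_somatic_normal_best_genotype_is_homref(self):
        # tumor 15/30 alt, normal 0/30 alt, eps=0.01
        gl_t = _log10_gl(15, 15, 0.01)
        gl_n = _log10_gl(30, 0, 0.01)
        assert np.argmax(gl_t) == 1
        assert np.argmax(gl_n) == 0

    def test_qual_is_phred_of_all_reference(self):
        strong = site_qual([_log10_gl(0, 30, 0.01), _log10_gl(15, 15, 0.01)])
        weak = site_qual([_log10_gl(30, 0, 0.01), _log10_gl(30, 0, 0.01)])
        assert strong > 100
        assert weak < 1

    def test_truth_partition_and_counts(self, default_dataset):
        ds, _ = default_dataset
        counts = ds.variants["truth_class"].value_counts()
        assert counts["somatic"] == 50
        assert counts["artifact_shared_lowfreq"] == 20
        assert counts["germline_het"] + counts["germline_hom"] == 100
        assert len(ds.variants) == 170
        # one class per emitted record
        assert ds.variants["truth_class"].notna().all()
        assert not ds.variants.duplicated(["chrom", "pos"]).any()

    def test_truth_genotype_attains_max_gl(self, default_dataset):
        """At depth ~30 and eps=0.01 the truth genotype should be the ML
        genotype essentially always (target: at least 99% of samples)."""
        ds, _ = default_dataset
        expected_idx = {"germline_het": 1, "germline_hom": 2}
        hits = total = 0
        for row in ds.variants.itertuples(index=False):
            for sample, gl in (("tumor", row.gl_tumor), ("normal", row.gl_normal)):
                if row.truth_class == "somatic":
                    want = 1 if sample == "tumor" else 0
                elif row.truth_class in expected_idx:
                    want = expected_idx[row.truth_class]
                else:
                    continue
                total += 1
                hits += int(np.argmax(gl) == want)
        assert total >= 300
        assert hits / total >= 0.99

    def test_zero_depth_sites_dropped(self):
        cfg = SimulationConfig(seed=9, site_depth_mean=1.0,
                               n_germline_variants=40,
                               n_somatic_variants=0, n_artifact_variants=0)
        seqs, _ = simulate_genome(cfg)
        df = simulate_variants(cfg, seqs)
        assert len(df) < 40          # Poisson(1) draws zeros
        assert (df[["ad_ref_tumor", "ad_alt_tumor"]].sum(axis=1) > 0).all()

    def test_artifact_allele_fractions_low_in_both(self, default_dataset):
        ds, _ = default_dataset
        art = ds.variants[ds.variants["truth_class"] == "artifact_shared_lowfreq"]
        assert (art["af_tumor"] < 0.25).all()
        assert (art["af_normal"] < 0.25).all()


class TestDeterminism:
    def test_dataset_bytes_reproducible(self, tmp_path):
        cfg = SimulationConfig(seed=11, n_chromosomes=2,
                               chrom_length_bp=200_000,
                               n_germline_variants=20,
                               n_somatic_variants=10, n_artifact_variants=5)
        simulate_dataset(cfg, outdir=tmp_path / "a")
        simulate_dataset(cfg, outdir=tmp_path / "b")
        for name in ("reference.fa", "bins.tsv", "variants.vcf",
                     "truth_variants.tsv", "annotations.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name
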