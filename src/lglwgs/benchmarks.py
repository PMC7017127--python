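"""Benchmark scenarios that exercise the pipeline against known truth.

Each function generates its inputs from scratch (seeded), runs the package
and returns measured quantities.  These back both the acceptance checks in
the test suite and `scripts/acceptance.py`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import stats

from .simulate import SimulationConfig, simulate_dataset, simulate_genome, simulate_coverage
from .coverage import (
    CopyNumberModel,
    first_split,
    fit_gc_curve,
    normalize_coverage,
    segment_cbs,
)
from .somatic import SomaticLabeller, SomaticThresholds
from .pipeline import RunConfig, run_pipeline


def _exhaustive_two_segment_boundary(x, min_width=2):
    """Independent change-point oracle: single boundary maximizing the
    prefix/suffix two-sample t statistic."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    best_t, best_k = -1.0, None
    for k in range(min_width, n - min_width + 1):
        a, b = x[:k], x[k:]
        m1, m2 = a.mean(), b.mean()
        sp2 = (((a - m1) ** 2).sum() + ((b - m2) ** 2).sum()) / max(n - 2, 1)
        diff = abs(m1 - m2)
        t = diff / np.sqrt(sp2 * (1 / len(a) + 1 / len(b))) if sp2 > 0 else (
            0.0 if diff < 1e-12 else 1e12)
        if t > best_t:
            best_t, best_k = t, k
    return best_k


def cbs_oracle_match(seed: int, n_series: int = 100) -> dict:
    """Planted one-step series: fraction of accepted top-level splits whose
    boundary equals the exhaustive two-segment scan."""
    rng = np.random.default_rng(seed)
    matched = accepted = 0
    for rep in range(n_series):
        n = int(rng.integers(10, 51))
        # interior steps: a 1-2 bin edge segment is legitimately below the
        # permutation test's resolution and would make the check vacuous
        k = int(rng.integers(max(2, n // 4), 3 * n // 4 + 1))
        delta = float(rng.uniform(0.5, 1.5))
        x = np.concatenate([np.zeros(k), np.full(n - k, delta)])
        x = x + rng.normal(0, 0.1, n)
        bounds, _ = first_split(x, seed=int(rng.integers(2 ** 31 - 1)))
        if bounds:
            accepted += 1
            matched += (list(bounds) == [_exhaustive_two_segment_boundary(x)])
    return {"n_series": n_series, "n_accepted": accepted,
            "match_rate": matched / accepted if accepted else float("nan")}


def cbs_null_rate(seed: int, n_series: int = 800, n_bins: int = 100,
                  sigma: float = 0.1, alpha: float = 0.01) -> dict:
    """Pure-noise series: fraction of runs reporting more than one segment
    (should stay at or below 2*alpha)."""
    rng = np.random.default_rng(seed)
    multi = 0
    for _ in range(n_series):
        x = 1.0 + rng.normal(0, sigma, n_bins)
        segs = segment_cbs(x, alpha=alpha,
                           seed=int(rng.integers(2 ** 31 - 1)))
        multi += len(segs) > 1
    return {"n_series": n_series, "multi_rate": multi / n_series,
            "bound": 2 * alpha}


def gc_flattening(seed: int, n_bins: int = 2000) -> dict:
    """Biased (a=2) diploid genome: |Spearman rho| between GC and the
    normalized ratio, before and after correction."""
    chrom_len = (n_bins // 2) * 10_000
    cfg = SimulationConfig(seed=seed, n_chromosomes=2,
                           chrom_length_bp=chrom_len, cnv_truth=())
    seqs, _ = simulate_genome(cfg)
    cov = simulate_coverage(cfg, seqs)
    curve = fit_gc_curve(cov, sample="tumor")
    bins = normalize_coverage(cov, curve, "tumor")
    rho_raw = stats.spearmanr(bins["gc"], bins["count_tumor"]).statistic
    rho = stats.spearmanr(bins["gc"], bins["ratio_tumor"]).statistic
    return {"n_bins": len(bins), "rho_raw": float(rho_raw),
            "rho_corrected_abs": float(abs(rho))}


def copy_state_recovery(seed: int) -> dict:
    """Default synthetic genome: per-bin copy-state accuracy and worst
    distance of a mixture component mean from its c/2 grid point."""
    ds = simulate_dataset(SimulationConfig(seed=seed))
    res = CopyNumberModel(ds.coverage, sample="tumor").fit(seed=seed)
    truth = ds.coverage["true_copy"].to_numpy()
    acc = float(np.mean(res.bin_states == truth))
    err = float(max(abs(m - s / 2) for m, s in
                    zip(res.cnv_map.component_means,
                        res.cnv_map.component_states)))
    return {"n_bins": len(truth), "accuracy": acc,
            "component_max_abs_error": err,
            "n_segments": len(res.segments)}


def somatic_performance(seed: int, workdir) -> dict:
    """Default 170-site paired VCF: somatic sensitivity and the fraction of
    each non-somatic truth class labelled somatic."""
    workdir = Path(workdir)
    ds = simulate_dataset(SimulationConfig(seed=seed), outdir=workdir)
    calls, _ = SomaticLabeller(SomaticThresholds()).run(
        workdir / "variants.vcf", tumor="RNK16", normal="F344")
    j = ds.truth.variants.merge(
        calls[["chrom", "pos", "ref", "alt", "label"]],
        on=["chrom", "pos", "ref", "alt"])
    som = j[j["truth_class"] == "somatic"]
    germ = j[j["truth_class"].str.startswith("germline")]
    art = j[j["truth_class"] == "artifact_shared_lowfreq"]
    return {
        "n_sites": len(j),
        "sensitivity": float((som["label"] == "somatic").mean()),
        "germline_somatic_rate": float((germ["label"] == "somatic").mean()),
        "artifact_somatic_rate": float((art["label"] == "somatic").mean()),
    }


def full_pipeline(seed: int, workdir) -> dict:
    """Full synthetic run twice with one seed: gene-report exact match
    against planted truth and byte-identity of the rerun."""
    import json

    workdir = Path(workdir)
    results = []
    for tag in ("a", "b"):
        cfg = RunConfig(outdir=str(workdir / tag), seed=seed,
                        log_level="WARNING")
        results.append(run_pipeline(cfg))
    manifest = json.loads(results[0].manifest_path.read_text())
    identical = all(
        (workdir / "a" / name).read_bytes() == (workdir / "b" / name).read_bytes()
        for name in manifest["artifacts"]
    )
    ev = results[0].evaluation
    return {
        "n_variants": len(results[0].calls),
        "gene_report_exact_match": bool(ev.gene_report_exact_match),
        "copy_state_accuracy": ev.copy_state_accuracy,
        "somatic_sensitivity": ev.somatic_sensitivity,
        "rerun_identical": bool(identical),
        "reported_genes": list(ev.reported_genes),
    }
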