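"""End-to-end orchestration: simulate -> CNV map -> somatic labelling ->
gene report -> evaluation against truth, with a manifest for reproducible
reruns.  One global seed deterministically derives every stage's substream,
so a rerun with the same config is byte-identical."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InputError
from .simulate import SimulationConfig, SyntheticDataset, simulate_dataset
from .coverage import CopyNumberModel
from .somatic import SomaticThresholds, SomaticLabeller
from .genes import prioritize_genes

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration of one pipeline run (defaults mirror the module
    defaults)."""

    outdir: str = "lglwgs_run"
    seed: int = 0
    log_level: str = "INFO"
    # synthetic data
    n_chromosomes: int = 4
    chrom_length_bp: int = 1_000_000
    mean_fragments_per_bin: float = 100.0
    gc_bias_a: float = 2.0
    gc_bias_b: float = 0.0
    n_germline_variants: int = 100
    n_somatic_variants: int = 50
    n_artifact_variants: int = 20
    site_depth_mean: float = 30.0
    base_error_rate: float = 0.01
    # CNV stage
    bin_size: int = 10_000
    smoothing_fraction: float = 0.3
    cbs_alpha: float = 0.01
    cbs_permutations: int = 1000
    cbs_min_width: int = 2
    max_copy: int = 6
    # somatic stage
    min_evidence_phred: float = 10.0
    low_af_cutoff: float = 0.25
    min_af: float = 0.1
    min_alt_reads: int = 2
    min_site_qual: float = 5.0
    # gene stage
    min_impact_qual: float = 20.0
    # evaluation
    with_truth: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            seed=self.seed,
            n_chromosomes=self.n_chromosomes,
            chrom_length_bp=self.chrom_length_bp,
            mean_fragments_per_bin=self.mean_fragments_per_bin,
            gc_bias_coefficients=(self.gc_bias_a, self.gc_bias_b),
            n_germline_variants=self.n_germline_variants,
            n_somatic_variants=self.n_somatic_variants,
            n_artifact_variants=self.n_artifact_variants,
            site_depth_mean=self.site_depth_mean,
            base_error_rate=self.base_error_rate,
            bin_size=self.bin_size,
        )

    def thresholds(self) -> SomaticThresholds:
        return SomaticThresholds(
            min_evidence_phred=self.min_evidence_phred,
            low_af_cutoff=self.low_af_cutoff,
            min_af=self.min_af,
            min_alt_reads=self.min_alt_reads,
            min_site_qual=self.min_site_qual,
            min_impact_qual=self.min_impact_qual,
        )

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class EvaluationSummary:
    """Truth-scored run: per-bin copy-state accuracy, somatic
    sensitivity/specificity, truth-class x label confusion matrix, and
    whether the gene report matched the planted gene set exactly."""

    copy_state_accuracy: float
    somatic_sensitivity: float
    somatic_mislabel_by_class: dict
    confusion: pd.DataFrame
    gene_report_exact_match: bool
    reported_genes: tuple
    expected_genes: tuple

    def to_dict(self) -> dict:
        return {
            "copy_state_accuracy": self.copy_state_accuracy,
            "somatic_sensitivity": self.somatic_sensitivity,
            "somatic_mislabel_by_class": self.somatic_mislabel_by_class,
            "confusion": {
                cls: {k: int(v) for k, v in row.items()}
                for cls, row in self.confusion.to_dict(orient="index").items()
            },
            "gene_report_exact_match": self.gene_report_exact_match,
            "reported_genes": list(self.reported_genes),
            "expected_genes": list(self.expected_genes),
        }


def evaluate_against_truth(bin_states, truth_bins: pd.DataFrame,
                           calls: pd.DataFrame, truth_variants: pd.DataFrame,
                           reported_genes, expected_genes) -> EvaluationSummary:
    """Score called copy states, somatic labels and the gene report.

    ``bin_states`` must align 1:1 with ``truth_bins`` rows; a mismatch in
    length is a hard coordinate error.  Variant calls and truth are joined
    on (chrom, pos, ref, alt).
    """
    states = np.asarray(bin_states)
    if len(states) != len(truth_bins):
        raise InputError(
            f"bin coordinate mismatch: {len(states)} called vs "
            f"{len(truth_bins)} truth bins"
        )
    copy_acc = float(np.mean(states == truth_bins["true_copy"].to_numpy()))

    key = ["chrom", "pos", "ref", "alt"]
    joined = truth_variants.merge(
        calls[key + ["label"]], on=key, how="left", validate="one_to_one"
    )
    if joined["label"].isna().any():
        raise InputError("variant coordinate mismatch between calls and truth")
    confusion = pd.crosstab(joined["truth_class"], joined["label"])
    somatic_truth = joined[joined["truth_class"] == "somatic"]
    sensitivity = (
        float((somatic_truth["label"] == "somatic").mean())
        if len(somatic_truth) else float("nan")
    )
    mislabel = {}
    for cls, grp in joined.groupby("truth_class"):
        if cls != "somatic":
            mislabel[cls] = float((grp["label"] == "somatic").mean())

    reported = tuple(sorted(reported_genes))
    expected = tuple(sorted(expected_genes))
    return EvaluationSummary(
        copy_state_accuracy=copy_acc,
        somatic_sensitivity=sensitivity,
        somatic_mislabel_by_class=mislabel,
        confusion=confusion,
        gene_report_exact_match=(reported == expected),
        reported_genes=reported,
        expected_genes=expected,
    )


@dataclass
class PipelineResult:
    config: RunConfig
    outdir: Path
    dataset: SyntheticDataset
    cnv_results: object
    calls: pd.DataFrame
    label_counts: dict
    gene_result: object
    evaluation: EvaluationSummary = None

    @property
    def manifest_path(self) -> Path:
        return self.outdir / "manifest.json"


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full synthetic run and write all artifacts + manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = []

    def _stage(name):
        log.info("stage: %s", name)

    try:
        _stage("simulate")
        sim_cfg = config.simulation_config()
        dataset = simulate_dataset(sim_cfg, outdir=outdir)
        artifacts += ["reference.fa", "bins.tsv", "variants.vcf",
                      "annotations.tsv", "homologs.tsv", "cgc.tsv",
                      "config.txt", "truth_bins.tsv", "truth_variants.tsv",
                      "truth_report_genes.tsv"]

        _stage("cnvmap")
        model = CopyNumberModel(dataset.coverage, sample="tumor")
        cnv = model.fit(
            smoothing_fraction=config.smoothing_fraction,
            alpha=config.cbs_alpha,
            n_permutations=config.cbs_permutations,
            min_width=config.cbs_min_width,
            max_copy=config.max_copy,
            seed=config.seed,
        )
        cnv.to_bed(outdir / "cnv_map.bed")
        cnv.to_tsv(outdir / "cnv_segments.tsv")
        cnv.gc_diagnostic().to_csv(outdir / "gc_diagnostic.tsv", sep="\t",
                                   index=False, float_format="%.6g",
                                   lineterminator="\n")
        artifacts += ["cnv_map.bed", "cnv_segments.tsv", "gc_diagnostic.tsv"]

        _stage("somatic-label")
        labeller = SomaticLabeller(config.thresholds())
        calls, counts = labeller.run(
            outdir / "variants.vcf",
            tumor=sim_cfg.tumor_sample, normal=sim_cfg.normal_sample,
            vcf_out=outdir / "labelled.vcf",
            summary_tsv=outdir / "label_summary.tsv",
        )
        artifacts += ["labelled.vcf", "label_summary.tsv"]
        for label, n in sorted(counts.items()):
            log.info("  %-22s %d", label, n)

        _stage("gene-report")
        gene_result = prioritize_genes(
            calls, dataset.annotations, dataset.homologs, dataset.cgc,
            min_qual=config.min_impact_qual,
            report_path=outdir / "gene_report.tsv",
        )
        artifacts += ["gene_report.tsv"]

        evaluation = None
        if config.with_truth:
            _stage("evaluate")
            evaluation = evaluate_against_truth(
                cnv.bin_states, dataset.truth.bins, calls,
                dataset.truth.variants,
                gene_result.report["gene_symbol"].tolist(),
                dataset.truth.expected_report_genes,
            )
            with open(outdir / "evaluation.json", "w") as fh:
                json.dump(evaluation.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
            artifacts += ["evaluation.json"]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "artifacts": sorted(artifacts),
        "label_counts": counts,
        "funnel_counts": gene_result.counts,
    }
    if evaluation is not None:
        manifest["evaluation"] = {
            "copy_state_accuracy": evaluation.copy_state_accuracy,
            "somatic_sensitivity": evaluation.somatic_sensitivity,
            "gene_report_exact_match": evaluation.gene_report_exact_match,
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(config, outdir, dataset, cnv, calls, counts,
                          gene_result, evaluation)
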