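"""Cancer-gene prioritization funnel.

Somatic-labelled variants are filtered on site quality and SnpEff-style
impact class (HIGH/MODERATE), their genes mapped to human symbols through a
user-supplied homolog table, intersected with a Cancer Gene Census table,
and rolled up into a per-gene report (gene, tier, passing variants,
validation flags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import InputError

log = logging.getLogger(__name__)

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
DAMAGING_IMPACTS = ("HIGH", "MODERATE")

REPORT_COLUMNS = [
    "gene_symbol", "human_symbol", "tier", "n_passing_variants", "variants",
    "wgs_detected", "validated_cell_line", "validated_primary",
]

_KEY = ["chrom", "pos", "ref", "alt"]


def filter_impact(calls: pd.DataFrame, annotations: pd.DataFrame,
                  min_qual: float = 20.0):
    """Join somatic calls to (variant, gene, impact) annotations and keep
    pairs with site QUAL strictly greater than ``min_qual`` and impact in
    {HIGH, MODERATE}.

    ``calls`` needs columns chrom, pos, ref, alt, qual (and, if present, a
    ``label`` column from which only ``somatic`` rows are used);
    ``annotations`` needs chrom, pos, ref, alt, gene_symbol, impact.
    Returns ``(pairs, n_unannotated)`` where ``pairs`` has one row per
    passing (variant, gene).  An impact outside the closed vocabulary is an
    input error naming the row.
    """
    bad = ~annotations["impact"].isin(IMPACT_CLASSES)
    if bad.any():
        row = annotations[bad].iloc[0]
        raise InputError(
            f"unknown impact {row['impact']!r} for "
            f"{row['chrom']}:{row['pos']} {row['ref']}>{row['alt']}"
        )
    if "label" in calls.columns:
        calls = calls[calls["label"] == "somatic"]
    calls = calls[_KEY + ["qual"]].copy()  # avoid column collisions on merge
    merged = calls.merge(annotations[_KEY + ["gene_symbol", "impact"]],
                         on=_KEY, how="left")
    n_unannotated = int(merged["gene_symbol"].isna().sum())
    if n_unannotated:
        log.info("%d somatic variants had no annotation", n_unannotated)
    merged = merged.dropna(subset=["gene_symbol"])
    passing = merged[(merged["qual"] > min_qual)
                     & merged["impact"].isin(DAMAGING_IMPACTS)]
    return passing.reset_index(drop=True), n_unannotated


@dataclass
class HomologMapping:
    mapped: pd.DataFrame       # source_symbol, target_symbol
    unmapped: tuple            # source symbols without a table row / target
    renamed_count: int         # pairs whose names differ (case-insensitive)


def map_homologs(gene_symbols, homolog_table: pd.DataFrame) -> HomologMapping:
    """Map each source (rat) symbol to at most one human symbol.

    Reports mapped pairs, symbols without a mapping, and how many mapped
    pairs changed name (case-insensitive comparison).  Duplicate source
    symbols in the table are an input error.
    """
    if homolog_table["source_symbol"].duplicated().any():
        dup = homolog_table.loc[
            homolog_table["source_symbol"].duplicated(), "source_symbol"
        ].iloc[0]
        raise InputError(f"duplicate source symbol {dup!r} in homolog table")
    lut = dict(zip(homolog_table["source_symbol"],
                   homolog_table["target_symbol"]))
    mapped_rows, unmapped = [], []
    for sym in sorted(set(gene_symbols)):
        target = lut.get(sym)
        if target is None or (isinstance(target, float) and pd.isna(target)):
            unmapped.append(sym)
        else:
            mapped_rows.append({"source_symbol": sym, "target_symbol": target})
    mapped = pd.DataFrame(mapped_rows, columns=["source_symbol", "target_symbol"])
    renamed = int(sum(
        r["source_symbol"].lower() != r["target_symbol"].lower()
        for r in mapped_rows
    ))
    return HomologMapping(mapped, tuple(unmapped), renamed)


def intersect_cgc(mapping: HomologMapping, cgc_table: pd.DataFrame,
                  passing_pairs: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly the mapped genes present in the Cancer Gene Census and
    roll up their passing variants.

    Returns the gene report (one row per CGC gene with >= 1 passing
    variant, sorted by symbol): gene_symbol, human_symbol, tier,
    n_passing_variants, variants (comma-joined chrom:pos:ref>alt).
    """
    if cgc_table["human_symbol"].duplicated().any():
        raise InputError("duplicate human symbol in CGC table")
    tiers = dict(zip(cgc_table["human_symbol"], cgc_table["tier"]))
    rows = []
    for r in mapping.mapped.itertuples(index=False):
        tier = tiers.get(r.target_symbol)
        if tier is None:
            continue
        hits = passing_pairs[passing_pairs["gene_symbol"] == r.source_symbol]
        if len(hits) == 0:
            continue
        variants = ",".join(
            f"{h.chrom}:{h.pos}:{h.ref}>{h.alt}"
            for h in hits.sort_values(["chrom", "pos"]).itertuples(index=False)
        )
        rows.append({
            "gene_symbol": r.source_symbol,
            "human_symbol": r.target_symbol,
            "tier": int(tier),
            "n_passing_variants": len(hits),
            "variants": variants,
        })
    report = pd.DataFrame(
        rows, columns=["gene_symbol", "human_symbol", "tier",
                       "n_passing_variants", "variants"]
    ).sort_values("gene_symbol").reset_index(drop=True)
    return report


def render_report(report: pd.DataFrame, path=None,
                  validation: pd.DataFrame = None) -> pd.DataFrame:
    """Finalise the report table (Table-1 shape) and optionally write TSV.

    Adds wgs_detected (always "yes": every reported gene carries a passing
    WGS variant) and validation flag columns, populated from an optional
    validation table (gene_symbol, validated_cell_line, validated_primary)
    or rendered "unknown".
    """
    out = report.copy()
    out["wgs_detected"] = "yes"
    if validation is not None:
        v = validation.set_index("gene_symbol")
        out["validated_cell_line"] = [
            str(v["validated_cell_line"].get(g, "unknown")) for g in out["gene_symbol"]
        ]
        out["validated_primary"] = [
            str(v["validated_primary"].get(g, "unknown")) for g in out["gene_symbol"]
        ]
    else:
        out["validated_cell_line"] = "unknown"
        out["validated_primary"] = "unknown"
    out = out[REPORT_COLUMNS]
    if path is not None:
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return out


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"variants": str})


@dataclass
class GeneFunnelResult:
    report: pd.DataFrame
    pairs: pd.DataFrame
    mapping: HomologMapping
    counts: dict


def prioritize_genes(calls: pd.DataFrame, annotations: pd.DataFrame,
                     homolog_table: pd.DataFrame, cgc_table: pd.DataFrame,
                     min_qual: float = 20.0, validation: pd.DataFrame = None,
                     report_path=None) -> GeneFunnelResult:
    """Run the whole funnel: impact/quality filter -> homolog mapping ->
    CGC intersection -> rendered report.  ``counts`` records the funnel
    stage sizes (somatic variants, passing pairs, genes, mapped, renamed,
    CGC genes)."""
    pairs, n_unann = filter_impact(calls, annotations, min_qual=min_qual)
    genes = pairs["gene_symbol"].unique().tolist()
    mapping = map_homologs(genes, homolog_table)
    report = intersect_cgc(mapping, cgc_table, pairs)
    rendered = render_report(report, path=report_path, validation=validation)
    n_somatic = int((calls["label"] == "somatic").sum()) if "label" in calls.columns else len(calls)
    counts = {
        "somatic_variants": n_somatic,
        "unannotated": n_unann,
        "passing_pairs": int(len(pairs)),
        "genes_with_passing_variants": len(genes),
        "mapped_genes": int(len(mapping.mapped)),
        "unmapped_genes": len(mapping.unmapped),
        "renamed_genes": mapping.renamed_count,
        "cgc_genes": int(len(report)),
    }
    return GeneFunnelResult(rendered, pairs, mapping, counts)
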