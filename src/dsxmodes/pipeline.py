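"""End-to-end orchestration: regions -> expression -> contrasts -> modes -> enrichment.

``analyze`` runs the whole cascade in memory and returns a
:class:`PipelineResult`; ``write_reports`` serialises every stage to TSV
plus a human-readable markdown summary and a run log with stage counts (the
per-strain tally of regions and genes surviving each cascade stage).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as dio
from .contrasts import ContrastModel, ContrastResults, DEFAULT_FDR_LEVELS
from .enrichment import (
    EnrichmentResult,
    GeneAnnotation,
    chromosome_arm_scan,
    go_enrichment,
    occupancy_scan,
    results_frame,
)
from .expression import CountMatrix, ExpressionMatrix, SampleMeta, detect, ln_normalize
from .modes import (
    MODES,
    NO_BIAS,
    UNASSIGNED,
    aggregate_to_genes,
    classify_regions,
    consistent_across_strains,
    stage_counts,
)
from .regions import AnalysisRegion, region_summary


@dataclass
class PipelineResult:
    """All artefacts of one end-to-end run."""

    regions: list[AnalysisRegion]
    expr: ExpressionMatrix
    results: ContrastResults
    calls: pd.DataFrame
    gene_summary: pd.DataFrame
    stage_table: pd.DataFrame
    consistent_genes: pd.DataFrame
    occupancy: list[EnrichmentResult]
    arm_scan: list[EnrichmentResult]
    go: list[EnrichmentResult]
    effect_summary: pd.DataFrame
    log: dict = field(default_factory=dict)


def mode_effect_summary(results: ContrastResults, calls: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SEM of contrast estimates per (strain, mode, contrast).

    Covers the wild-type sex contrast and the two null contrasts, over the
    regions classified into each mode. SEM is NaN for single-member modes
    (reported, not dropped).
    """
    rows = []
    contrasts = ("WTF_vs_WTM", "WTF_vs_NULLXX", "WTM_vs_NULLXY")
    assigned = calls[(calls["dsx_regulated"]) & (calls["mode"] != UNASSIGNED)]
    for (strain, mode), grp in assigned.groupby(["strain_context", "mode"], sort=True):
        rids = set(grp["region_id"])
        for name in contrasts:
            sub = results.select(name, strain)
            est = sub.loc[sub.index.isin(rids), "estimate"]
            if est.empty:
                continue
            sem = float(est.std(ddof=1) / np.sqrt(len(est))) if len(est) > 1 else float("nan")
            rows.append(
                {
                    "strain_context": strain,
                    "mode": mode,
                    "contrast": name,
                    "n_regions": len(est),
                    "mean_estimate": float(est.mean()),
                    "sem": sem,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["strain_context", "mode", "contrast", "n_regions", "mean_estimate", "sem"],
    )


def analyze(
    regions: Sequence[AnalysisRegion],
    counts: CountMatrix,
    meta: Sequence[SampleMeta],
    annotations: Mapping[str, GeneAnnotation] | None = None,
    read_length: int = 100,
    fdr_levels: Sequence[float] = DEFAULT_FDR_LEVELS,
    call_level: float = 0.05,
    consistency_level: float = 0.10,
) -> PipelineResult:
    """Run the full analysis cascade in memory.

    Stages: drop inter-gene-excluded regions, apply the detection filter,
    ln(RPKM)-normalise, fit per-region contrasts with one pooled BH
    adjustment, classify DSX regulatory modes at ``call_level``, aggregate
    to genes, call cross-strain consistency at ``consistency_level``, and —
    when annotations are supplied — run the occupancy, chromosome-arm and
    GO enrichment scans over the detected-gene universe.
    """
    log: dict = {"region_summary": region_summary(list(regions))}

    included = [r for r in regions if not r.excluded]
    kept_ids = [r.region_id for r in included if r.region_id in counts.counts.index]
    counts_kept = CountMatrix(
        counts=counts.counts.loc[kept_ids],
        region_lengths=counts.region_lengths.loc[kept_ids],
    )
    mask = detect(counts_kept, read_length)
    log["regions_detected"] = int(mask.sum())
    if not mask.any():
        raise ValueError("no regions detected: every region has a zero count somewhere")
    expr = ln_normalize(counts_kept, meta, mask)

    region_genes = {r.region_id: r.gene_id for r in regions}
    results = ContrastModel(expr, region_genes=region_genes).fit(fdr_levels=fdr_levels)
    calls = classify_regions(results, level=call_level)
    gene_summary = aggregate_to_genes(calls)
    stage_table = stage_counts(calls)
    log["stage_counts"] = stage_table.to_dict(orient="records")
    # stage-count conservation: each stage is a subset of the previous one
    for row in stage_table.itertuples():
        assert row.regions_sex_biased >= row.regions_dsx_regulated >= row.regions_mode_assigned
    consistent = consistent_across_strains(results, level=consistency_level)

    occupancy: list[EnrichmentResult] = []
    arm: list[EnrichmentResult] = []
    go: list[EnrichmentResult] = []
    if annotations:
        detected_genes = {region_genes[r] for r in expr.detected.index}
        universe = sorted(detected_genes & set(annotations))
        log["universe_size"] = len(universe)
        strains = sorted(calls["strain_context"].unique())
        biased_sets, regulated_sets, mode_sets = {}, {}, {}
        for strain in strains:
            sub = calls[calls["strain_context"] == strain]
            biased = set(sub.loc[sub["sex_bias"] != NO_BIAS, "gene_id"]) & set(universe)
            regulated = set(sub.loc[sub["dsx_regulated"], "gene_id"]) & set(universe)
            if biased:
                biased_sets[f"{strain}_sex_biased"] = biased
            if regulated:
                regulated_sets[f"{strain}_dsx_regulated"] = regulated
            for mode in MODES:
                genes = set(sub.loc[sub["mode"] == mode, "gene_id"]) & set(universe)
                if genes:
                    mode_sets[(strain, mode)] = genes
        if regulated_sets:
            occupancy = occupancy_scan(regulated_sets, annotations, universe)
        for name, genes in {**biased_sets, **regulated_sets}.items():
            arm.extend(chromosome_arm_scan(genes, annotations, universe, set_name=name))
        if mode_sets:
            go = go_enrichment(mode_sets, annotations, universe)

    effect_summary = mode_effect_summary(results, calls)
    return PipelineResult(
        regions=list(regions),
        expr=expr,
        results=results,
        calls=calls,
        gene_summary=gene_summary,
        stage_table=stage_table,
        consistent_genes=consistent,
        occupancy=occupancy,
        arm_scan=arm,
        go=go,
        effect_summary=effect_summary,
        log=log,
    )


def write_reports(result: PipelineResult, outdir: str | os.PathLike) -> None:
    """Serialise every stage: TSV tables, a markdown summary, a JSON run log."""
    os.makedirs(outdir, exist_ok=True)
    out = lambda name: os.path.join(outdir, name)  # noqa: E731

    dio.write_regions(result.regions, out("regions.tsv"))
    with open(out("expression_lnrpkm.tsv"), "w") as fh:
        fh.write("# ln(RPKM) per (region, sample); NaN = region not detected\n")
        result.expr.values.to_csv(fh, sep="\t", index_label="region_id")
    with open(out("contrasts.tsv"), "w") as fh:
        fh.write("# per-region contrasts on ln(RPKM); q = BH over all tests pooled\n")
        result.results.table.to_csv(fh, sep="\t", index=False)
    result.calls.to_csv(out("mode_calls.tsv"), sep="\t", index=False)
    result.gene_summary.to_csv(out("gene_modes.tsv"), sep="\t", index=False)
    result.stage_table.to_csv(out("stage_counts.tsv"), sep="\t", index=False)
    result.consistent_genes.to_csv(out("consistent_genes.tsv"), sep="\t", index=False)
    results_frame(result.occupancy).to_csv(out("enrichment_occupancy.tsv"), sep="\t", index=False)
    results_frame(result.arm_scan).to_csv(out("enrichment_arms.tsv"), sep="\t", index=False)
    results_frame(result.go).to_csv(out("enrichment_go.tsv"), sep="\t", index=False)
    result.effect_summary.to_csv(out("mode_effect_summary.tsv"), sep="\t", index=False)
    with open(out("run_log.json"), "w") as fh:
        json.dump(result.log, fh, indent=2, default=str)

    with open(out("summary.md"), "w") as fh:
        fh.write("# Pipeline run summary\n\n")
        rs = result.log["region_summary"]
        fh.write(
            f"- regions built: {rs['regions_built']} "
            f"(single {rs['regions_single']}, overlap {rs['regions_overlap']}); "
            f"excluded for inter-gene overlap: {rs['regions_excluded']} "
            f"({rs['excluded_bases']} bases)\n"
        )
        fh.write(f"- regions detected in all samples: {result.log['regions_detected']}\n")
        if "universe_size" in result.log:
            fh.write(f"- enrichment universe: {result.log['universe_size']} genes\n")
        fh.write("\n## Cascade stage counts (FDR level per column noted in mode_calls.tsv)\n\n")
        fh.write(result.stage_table.to_string(index=False))
        fh.write("\n\n## Contrast summary\n\n```\n")
        fh.write(result.results.summary())
        fh.write("\n```\n")
        if not result.consistent_genes.empty:
            fh.write("\n## Genes consistent across strains\n\n")
            fh.write(result.consistent_genes.to_string(index=False))
            fh.write("\n")


@dataclass
class RunConfig:
    """File-based configuration for a full run (the CLI surface)."""

    gff: str | None = None
    regions: str | None = None
    counts: str = ""
    meta: str = ""
    annotations: str | None = None
    go: str | None = None
    outdir: str = "dsxmodes_out"
    read_length: int = 100
    fdr_levels: tuple[float, ...] = DEFAULT_FDR_LEVELS
    call_level: float = 0.05
    consistency_level: float = 0.10

    def __post_init__(self) -> None:
        for level in (*self.fdr_levels, self.call_level, self.consistency_level):
            if not 0 < level < 1:
                raise ValueError(f"FDR level {level} outside (0, 1)")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load inputs per ``config``, run :func:`analyze`, write all reports."""
    from .regions import build_regions, mark_inter_gene_exclusions

    if config.regions:
        regions = dio.read_regions(config.regions)
    elif config.gff:
        models = dio.read_gene_models(config.gff)
        regions = mark_inter_gene_exclusions(build_regions(models), models)
    else:
        raise ValueError("either a region table or a GFF file is required")
    counts = dio.read_counts(config.counts)
    meta = dio.read_meta(config.meta)
    annotations = (
        dio.read_annotations(config.annotations, config.go)
        if config.annotations
        else None
    )
    result = analyze(
        regions,
        counts,
        meta,
        annotations,
        read_length=config.read_length,
        fdr_levels=config.fdr_levels,
        call_level=config.call_level,
        consistency_level=config.consistency_level,
    )
    write_reports(result, config.outdir)
    return result
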