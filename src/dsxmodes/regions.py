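"""Flatten multi-isoform gene models into disjoint exonic analysis regions.

Isoforms of one gene frequently disagree about exon boundaries. Measuring
expression per annotated exon would then count some genomic bases several
times and attribute reads ambiguously between isoforms. Instead, each gene's
exons are flattened into disjoint *analysis regions*: an exon whose genomic
footprint is identical in every isoform that contains it (and touches no
differing exon) becomes a ``single`` region, while any set of exons that
overlap one another — transitively, across isoforms — is merged into one
``overlap`` region spanning the entire connected run of overlap.

Regions that share bases with the exonic footprint of a *different* gene are
ambiguous with respect to gene assignment and are flagged excluded
(``inter_gene_overlap``); the whole region is dropped from analysis, not just
the shared bases.

All coordinates are 0-based half-open internally. GFF input (1-based
inclusive) is converted on read; see :mod:`dsxmodes.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

SINGLE = "single"
OVERLAP = "overlap"
NO_EXCLUSION = "none"
INTER_GENE_OVERLAP = "inter_gene_overlap"


class GeneModelError(ValueError):
    """A gene model violates a structural invariant."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: a set of transcripts, each a list of exon intervals.

    Exon intervals are 0-based half-open ``(start, end)`` tuples in genomic
    coordinates. All exons of a gene must share one chromosome arm and
    strand.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[tuple[str, tuple[tuple[int, int], ...]], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        for tid, exons in self.transcripts:
            for start, end in exons:
                if start >= end:
                    raise GeneModelError(
                        f"gene {self.gene_id}, transcript {tid}: malformed exon "
                        f"interval [{start}, {end}) (start >= end)"
                    )

    @property
    def all_exons(self) -> list[tuple[int, int]]:
        return [iv for _, exons in self.transcripts for iv in exons]


@dataclass(frozen=True)
class AnalysisRegion:
    """A disjoint exonic interval within one gene; the unit of testing."""

    region_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    region_class: str  # SINGLE or OVERLAP
    excluded: bool = False
    exclusion_reason: str = NO_EXCLUSION

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.region_id}: empty interval")

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_models(models: Sequence[GeneModel]) -> None:
    seen: dict[str, str] = {}
    for m in models:
        if m.gene_id in seen:
            raise GeneModelError(f"duplicate gene_id {m.gene_id}")
        seen[m.gene_id] = m.chrom


def build_regions(models: Iterable[GeneModel]) -> list[AnalysisRegion]:
    """Flatten every gene's isoform exons into disjoint analysis regions.

    Within each gene, exon footprints identical across isoforms are
    deduplicated; footprints that share at least one base are merged
    transitively, and each connected component becomes one region spanning
    ``[min start, max end)``. A component holding exactly one distinct
    footprint is classed ``single``; anything merged is ``overlap``.
    Adjacent-but-not-overlapping exons stay separate regions.
    """
    models = list(models)
    _check_models(models)
    regions: list[AnalysisRegion] = []
    for m in models:
        footprints = sorted(set(m.all_exons))
        if not footprints:
            continue
        # Sweep: strict overlap (start < run_end) merges; touching does not.
        run_start, run_end = footprints[0]
        run_count = 1
        runs: list[tuple[int, int, int]] = []
        for start, end in footprints[1:]:
            if start < run_end:
                run_end = max(run_end, end)
                run_count += 1
            else:
                runs.append((run_start, run_end, run_count))
                run_start, run_end, run_count = start, end, 1
        runs.append((run_start, run_end, run_count))
        for start, end, count in runs:
            regions.append(
                AnalysisRegion(
                    region_id=f"{m.gene_id}:{start}-{end}",
                    gene_id=m.gene_id,
                    chrom=m.chrom,
                    start=start,
                    end=end,
                    region_class=SINGLE if count == 1 else OVERLAP,
                )
            )
    return regions


def mark_inter_gene_exclusions(
    regions: Iterable[AnalysisRegion], models: Iterable[GeneModel]
) -> list[AnalysisRegion]:
    """Flag regions that share bases with another gene's exonic footprint.

    Overlap is tested on genomic footprints; strand is ignored, so
    opposite-strand genes still exclude each other. Intervals are not
    altered — the flagged region is returned whole.
    """
    trees: dict[str, IntervalTree] = {}
    for m in models:
        tree = trees.setdefault(m.chrom, IntervalTree())
        for start, end in m.all_exons:
            tree.addi(start, end, m.gene_id)
    out: list[AnalysisRegion] = []
    for r in regions:
        tree = trees.get(r.chrom)
        hit = tree is not None and any(
            iv.data != r.gene_id for iv in tree.overlap(r.start, r.end)
        )
        if hit:
            out.append(replace(r, excluded=True, exclusion_reason=INTER_GENE_OVERLAP))
        else:
            out.append(replace(r, excluded=False, exclusion_reason=NO_EXCLUSION))
    return out


def region_summary(regions: Sequence[AnalysisRegion]) -> dict[str, int]:
    """Counts for the run log: regions built, merged (overlap class), excluded."""
    return {
        "regions_built": len(regions),
        "regions_single": sum(r.region_class == SINGLE for r in regions),
        "regions_overlap": sum(r.region_class == OVERLAP for r in regions),
        "regions_excluded": sum(r.excluded for r in regions),
        "excluded_bases": sum(r.length for r in regions if r.excluded),
    }
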