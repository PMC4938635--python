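"""Readers and writers for the pipeline's file formats.

Gene models travel as GFF3 (gene -> mRNA -> exon; 1-based inclusive
coordinates, converted to the package's internal 0-based half-open
convention on read). Everything else is TSV with ``#``-prefixed header
comments naming units and conventions: region tables (BED-like, 0-based
half-open), count matrices with a length column, sample metadata, gene
annotations, and GO term maps.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .enrichment import GeneAnnotation, ONTOLOGIES
from .expression import CountMatrix, SampleMeta
from .regions import AnalysisRegion, GeneModel


def read_gene_models(gff_path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GFF3 file into gene models (0-based half-open exons)."""
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            exons = []
            for e in db.children(t, featuretype="exon", order_by="start"):
                if e.seqid != g.seqid:
                    raise ValueError(
                        f"gene {g.id}: exon of transcript {t.id} on {e.seqid}, "
                        f"gene on {g.seqid}"
                    )
                exons.append((e.start - 1, e.end))
            transcripts.append((t.id, tuple(exons)))
        models.append(GeneModel(g.id, g.seqid, g.strand, tuple(transcripts)))
    return models


def write_gene_models(models: Iterable[GeneModel], gff_path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (converting back to 1-based inclusive)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.all_exons
            g_start = min(s for s, _ in span) + 1
            g_end = max(e for _, e in span)
            fh.write(
                f"{m.chrom}\tdsxmodes\tgene\t{g_start}\t{g_end}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            for tid, exons in m.transcripts:
                t_start = min(s for s, _ in exons) + 1
                t_end = max(e for _, e in exons)
                fh.write(
                    f"{m.chrom}\tdsxmodes\tmRNA\t{t_start}\t{t_end}\t.\t{m.strand}\t.\tID={tid};Parent={m.gene_id}\n"
                )
                for i, (s, e) in enumerate(sorted(exons), 1):
                    fh.write(
                        f"{m.chrom}\tdsxmodes\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                        f"ID={tid}.e{i};Parent={tid}\n"
                    )


def write_regions(regions: Sequence[AnalysisRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# exonic analysis regions; coordinates 0-based half-open\n")
        fh.write("chrom\tstart\tend\tregion_id\tgene_id\tregion_class\texcluded\texclusion_reason\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.gene_id}\t"
                f"{r.region_class}\t{int(r.excluded)}\t{r.exclusion_reason}\n"
            )


def read_regions(path: str | os.PathLike) -> list[AnalysisRegion]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        AnalysisRegion(
            region_id=row.region_id, gene_id=row.gene_id, chrom=row.chrom,
            start=int(row.start), end=int(row.end), region_class=row.region_class,
            excluded=bool(row.excluded), exclusion_reason=row.exclusion_reason,
        )
        for row in df.itertuples()
    ]


def write_counts(counts: CountMatrix, path: str | os.PathLike) -> None:
    df = counts.counts.copy()
    df.insert(0, "length", counts.region_lengths)
    with open(path, "w") as fh:
        fh.write("# read counts per (region, sample); length in nucleotides\n")
        df.to_csv(fh, sep="\t", index_label="region_id")


def read_counts(path: str | os.PathLike) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="region_id")
    lengths = df.pop("length")
    return CountMatrix(counts=df.astype(int), region_lengths=lengths)


def write_meta(meta: Sequence[SampleMeta], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# sample metadata; total_mapped_reads counts all mapped reads\n")
        fh.write("sample_id\tstrain_context\tgenotype_group\treplicate\ttotal_mapped_reads\n")
        for m in meta:
            fh.write(
                f"{m.sample_id}\t{m.strain_context}\t{m.genotype_group}\t"
                f"{m.replicate}\t{m.total_mapped_reads}\n"
            )


def read_meta(path: str | os.PathLike) -> tuple[SampleMeta, ...]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return tuple(
        SampleMeta(
            sample_id=row.sample_id, strain_context=row.strain_context,
            genotype_group=row.genotype_group, replicate=int(row.replicate),
            total_mapped_reads=int(row.total_mapped_reads),
        )
        for row in df.itertuples()
    )


def write_annotations(
    annotations: Mapping[str, GeneAnnotation],
    path: str | os.PathLike,
    go_path: str | os.PathLike | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("# gene annotations: chromosome arm and binary DSX occupancy flags\n")
        fh.write("gene_id\tchrom_arm\toccupancy_A\toccupancy_B\n")
        for gid in sorted(annotations):
            a = annotations[gid]
            fh.write(f"{gid}\t{a.chrom_arm}\t{int(a.occupancy_A)}\t{int(a.occupancy_B)}\n")
    if go_path is not None:
        with open(go_path, "w") as fh:
            fh.write("# GO term assignments; one row per (gene, ontology, term)\n")
            fh.write("gene_id\tontology\tterm\n")
            for gid in sorted(annotations):
                for ont in ONTOLOGIES:
                    for term in sorted(annotations[gid].go_terms.get(ont, ())):
                        fh.write(f"{gid}\t{ont}\t{term}\n")


def read_annotations(
    path: str | os.PathLike, go_path: str | os.PathLike | None = None
) -> dict[str, GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#")
    go: dict[str, dict[str, set]] = {}
    if go_path is not None:
        go_df = pd.read_csv(go_path, sep="\t", comment="#")
        for row in go_df.itertuples():
            go.setdefault(row.gene_id, {}).setdefault(row.ontology, set()).add(row.term)
    out = {}
    for row in df.itertuples():
        terms = {
            ont: frozenset(go.get(row.gene_id, {}).get(ont, set()))
            for ont in ONTOLOGIES
        }
        out[row.gene_id] = GeneAnnotation(
            gene_id=row.gene_id, chrom_arm=str(row.chrom_arm),
            occupancy_A=bool(row.occupancy_A), occupancy_B=bool(row.occupancy_B),
            go_terms=terms,
        )
    return out


def write_gene_sets(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_sets(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
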