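"""Count assembly, detection filtering, and ln(RPKM) normalisation.

Expression is measured per analysis region as reads per kilobase of region
per million mapped reads (RPKM) and analysed on the natural-log scale. A
region is *detected* only if its average per-nucleotide coverage is greater
than zero in every sample; with count data and a fixed read length that is
exactly a count-positivity test, which is what is implemented. Undetected
regions keep their rows (mask ``False``) but carry no ln(RPKM) values, so a
log of zero can never be attempted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

WT_STRAINS = ("CantonS", "Berlin")
SHARED_MUTANT = "shared_mutant"
WT_GROUPS = ("WT_F", "WT_M")
MUTANT_GROUPS = ("DSXD_PM", "NULL_XX", "NULL_XY")
GENOTYPE_GROUPS = WT_GROUPS + MUTANT_GROUPS


@dataclass(frozen=True)
class SampleMeta:
    """One library: strain context, genotype group, replicate, library size.

    Wild-type samples belong to a wild-type strain (Canton-S or Berlin);
    the *dsx* mutant genotypes exist once, in their own backgrounds, and are
    shared between both strain contexts (``shared_mutant``).
    """

    sample_id: str
    strain_context: str
    genotype_group: str
    replicate: int
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.genotype_group not in GENOTYPE_GROUPS:
            raise ValueError(f"unknown genotype group {self.genotype_group!r}")
        if self.genotype_group in WT_GROUPS:
            if self.strain_context not in WT_STRAINS:
                raise ValueError(
                    f"sample {self.sample_id}: wild-type group "
                    f"{self.genotype_group} needs a wild-type strain context"
                )
        elif self.strain_context != SHARED_MUTANT:
            raise ValueError(
                f"sample {self.sample_id}: mutant group {self.genotype_group} "
                f"must carry strain_context={SHARED_MUTANT!r}"
            )
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id}: replicate must be >= 1")
        if self.total_mapped_reads <= 0:
            raise ValueError(f"sample {self.sample_id}: total_mapped_reads must be > 0")

    @property
    def cell(self) -> str:
        """Design cell label: wild-type cells are strain-specific, mutant cells shared."""
        if self.genotype_group in WT_GROUPS:
            return f"{self.strain_context}:{self.genotype_group}"
        return self.genotype_group


def check_meta(meta: Sequence[SampleMeta]) -> None:
    keys = [(m.strain_context, m.genotype_group, m.replicate) for m in meta]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (strain_context, genotype_group, replicate)")
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id")


@dataclass
class CountMatrix:
    """Read counts per (region, sample) plus region lengths in nucleotides."""

    counts: pd.DataFrame  # regions x samples, nonnegative integers
    region_lengths: pd.Series  # nucleotides, indexed like counts rows

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.region_lengths.index):
            raise ValueError("counts and region_lengths indexed differently")
        if (self.region_lengths <= 0).any():
            bad = self.region_lengths.index[self.region_lengths <= 0][0]
            raise ValueError(f"region {bad}: nonpositive length")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")


@dataclass
class ExpressionMatrix:
    """ln(RPKM) values; rows where ``detection_mask`` is False are all-NaN."""

    values: pd.DataFrame  # regions x samples, ln(RPKM); NaN where undetected
    detection_mask: pd.Series  # bool per region
    region_lengths: pd.Series
    meta: tuple[SampleMeta, ...]

    @property
    def detected(self) -> pd.DataFrame:
        return self.values.loc[self.detection_mask]


def detect(counts: CountMatrix, read_length: int) -> pd.Series:
    """Detection mask: average per-nucleotide coverage > 0 in every sample.

    Coverage is taken as ``count * read_length / region_length``; because the
    threshold is strictly zero this is equivalent to requiring a positive
    count in every sample. Nothing is dropped — a boolean mask is returned.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    return (counts.counts > 0).all(axis=1)


def rpkm(count, region_length, total_mapped):
    """Reads per kilobase of region per million mapped reads.

    ``count / (region_length/1e3) / (total_mapped/1e6)``. Accepts scalars or
    arrays; doubling count and total_mapped together leaves the value fixed.
    """
    region_length = np.asarray(region_length, dtype=float)
    total_mapped = np.asarray(total_mapped, dtype=float)
    if (region_length <= 0).any():
        raise ValueError("region_length must be positive")
    if (total_mapped <= 0).any():
        raise ValueError("total_mapped must be positive")
    return np.asarray(count, dtype=float) / (region_length / 1e3) / (total_mapped / 1e6)


def ln_normalize(
    counts: CountMatrix, meta: Iterable[SampleMeta], mask: pd.Series
) -> ExpressionMatrix:
    """ln(RPKM) for every detected region/sample; undetected rows carry no values.

    Raises if the mask admits a zero count (the detection filter was
    bypassed): ln(0) is never silently produced.
    """
    meta = tuple(meta)
    check_meta(meta)
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in counts.counts.columns if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    totals = np.array([by_id[s].total_mapped_reads for s in counts.counts.columns], float)

    mask = mask.reindex(counts.counts.index)
    kept = counts.counts.loc[mask].to_numpy(dtype=float)
    if (kept <= 0).any():
        raise ValueError("detection mask admits a nonpositive count; ln(RPKM) undefined")
    lengths = counts.region_lengths.loc[mask].to_numpy(dtype=float)
    vals = np.log(rpkm(kept, lengths[:, None], totals[None, :]))

    values = pd.DataFrame(
        np.nan, index=counts.counts.index, columns=counts.counts.columns, dtype=float
    )
    values.loc[mask] = vals
    return ExpressionMatrix(
        values=values,
        detection_mask=mask,
        region_lengths=counts.region_lengths,
        meta=meta,
    )
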