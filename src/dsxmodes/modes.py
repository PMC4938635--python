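"""Classification of regions into the seven DSX regulatory modes.

The cascade runs per region and per wild-type strain context, at one FDR
level throughout:

1. *Sex bias* — the wild-type female vs male contrast must be significant;
   the sign of the estimate gives the direction (positive = female-biased).
2. *dsx regulation* — the wild-type female vs *dsx^D* pseudo-male contrast
   must also be significant AND biased in the same direction. Pseudo males
   are chromosomally XX but produce only DSX^M, so a gene under DSX control
   should shift towards the male program in them.
3. *Mode* — the two wild-type vs *dsx*-null contrasts decide how DSX acts.
   A significantly lower null (positive wild-type-minus-null estimate) means
   DSX activates in that sex; a significantly higher null means it
   represses. Significance in one sex only gives a sex-specific
   activator/repressor; in both sexes with the same sign, an activator or
   repressor in both; with opposite signs, the opposing mode (the Yolk
   protein paradigm: DSX^F activates while DSX^M represses). A region that
   passes step 2 but reaches significance in neither null comparison stays
   ``unassigned`` — a regulated candidate whose mode the data cannot
   resolve; it is reported but not counted among mode-classified regions.

Gene-level aggregation keeps every distinct (direction, mode) pair carried
by a gene's regions: multi-isoform genes can legitimately be regulated by
more than one mode, and direction conflicts are preserved, not voted away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contrasts import ContrastResults

FEMALE = "female"
MALE = "male"
NO_BIAS = "none"

F_ACT = "F_specific_activator"
F_REP = "F_specific_repressor"
M_ACT = "M_specific_activator"
M_REP = "M_specific_repressor"
BOTH_ACT = "activator_both"
BOTH_REP = "repressor_both"
OPPOSING = "opposing"
UNASSIGNED = "unassigned"

MODES = (F_ACT, F_REP, M_ACT, M_REP, BOTH_ACT, BOTH_REP, OPPOSING)


@dataclass(frozen=True)
class ModeCall:
    """Cascade outcome for one region in one wild-type strain context."""

    region_id: str
    gene_id: str
    strain_context: str
    sex_bias: str  # female / male / none
    dsx_regulated: bool
    mode: str  # one of MODES or UNASSIGNED
    fdr_level_used: float

    def __post_init__(self) -> None:
        if self.mode in MODES and not self.dsx_regulated:
            raise ValueError("a mode implies dsx regulation")
        if self.dsx_regulated and self.sex_bias == NO_BIAS:
            raise ValueError("dsx regulation implies sex bias")


def call_sex_bias(estimate: float, q_value: float, level: float) -> str:
    """Direction of wild-type sex bias, or ``none``.

    A zero estimate is directionless and yields ``none`` even when
    significant (tie rule).
    """
    if q_value < level and estimate > 0:
        return FEMALE
    if q_value < level and estimate < 0:
        return MALE
    return NO_BIAS


def call_dsx_regulated(
    bias: str, estimate_dsxd: float, q_dsxd: float, level: float
) -> bool:
    """Step 2: the pseudo-male contrast must be significant and concordant.

    Concordance means the sign of the wild-type-female minus pseudo-male
    estimate matches the wild-type bias: female bias needs a positive
    estimate (pseudo males look male, i.e. lower), male bias a negative one.
    """
    if bias == NO_BIAS:
        raise ValueError("call_dsx_regulated requires a sex-biased region")
    if not q_dsxd < level:
        return False
    if bias == FEMALE:
        return estimate_dsxd > 0
    return estimate_dsxd < 0


def classify_mode(
    estimate_f: float,
    q_f: float,
    estimate_m: float,
    q_m: float,
    level: float,
) -> str:
    """Step 3: mode from the two wild-type vs *dsx*-null contrasts.

    A positive estimate (wild type above null) marks DSX as an activator in
    that sex, a negative one as a repressor. An estimate of exactly zero is
    treated as not significant regardless of its q-value.
    """
    sig_f = q_f < level and estimate_f != 0
    sig_m = q_m < level and estimate_m != 0
    act_f = estimate_f > 0
    act_m = estimate_m > 0
    if sig_f and not sig_m:
        return F_ACT if act_f else F_REP
    if sig_m and not sig_f:
        return M_ACT if act_m else M_REP
    if sig_f and sig_m:
        if act_f and act_m:
            return BOTH_ACT
        if not act_f and not act_m:
            return BOTH_REP
        return OPPOSING
    return UNASSIGNED


def classify_regions(
    results: ContrastResults, level: float = 0.05
) -> pd.DataFrame:
    """Run the full cascade for every detected region in every strain context.

    Returns one row per (region, strain) with columns ``sex_bias``,
    ``dsx_regulated``, ``mode`` and ``fdr_level_used``. Regions failing step
    1 carry bias ``none``; regions failing step 2 carry ``dsx_regulated``
    False and mode ``unassigned``.
    """
    if not results.adjusted:
        raise ValueError("results must be FDR-adjusted before classification")
    strains = sorted(results.table["strain_context"].unique())
    rows = []
    for strain in strains:
        wt = results.select("WTF_vs_WTM", strain)
        dsxd = results.select("WTF_vs_DSXD", strain)
        null_f = results.select("WTF_vs_NULLXX", strain)
        null_m = results.select("WTM_vs_NULLXY", strain)
        for rid in wt.index:
            bias = call_sex_bias(wt.at[rid, "estimate"], wt.at[rid, "q_value"], level)
            regulated = False
            mode = UNASSIGNED
            if bias != NO_BIAS:
                regulated = call_dsx_regulated(
                    bias, dsxd.at[rid, "estimate"], dsxd.at[rid, "q_value"], level
                )
            if regulated:
                mode = classify_mode(
                    null_f.at[rid, "estimate"],
                    null_f.at[rid, "q_value"],
                    null_m.at[rid, "estimate"],
                    null_m.at[rid, "q_value"],
                    level,
                )
            rows.append(
                {
                    "region_id": rid,
                    "gene_id": wt.at[rid, "gene_id"],
                    "strain_context": strain,
                    "sex_bias": bias,
                    "dsx_regulated": regulated,
                    "mode": mode,
                    "fdr_level_used": level,
                }
            )
    return pd.DataFrame(rows)


def aggregate_to_genes(calls: pd.DataFrame) -> pd.DataFrame:
    """Gene-level summaries: a gene carries every distinct (bias, mode) pair.

    A gene is sex-biased / regulated in a strain iff at least one of its
    regions is; genes with both female- and male-biased regions appear in
    both direction tallies.
    """
    rows = []
    for (gene, strain), grp in calls.groupby(["gene_id", "strain_context"], sort=True):
        biased = grp[grp["sex_bias"] != NO_BIAS]
        regulated = grp[grp["dsx_regulated"]]
        assigned = regulated[regulated["mode"] != UNASSIGNED]
        pairs = sorted(set(zip(assigned["sex_bias"], assigned["mode"])))
        rows.append(
            {
                "gene_id": gene,
                "strain_context": strain,
                "sex_biased": not biased.empty,
                "bias_directions": sorted(set(biased["sex_bias"])),
                "dsx_regulated": not regulated.empty,
                "mode_pairs": pairs,
            }
        )
    return pd.DataFrame(rows)


def stage_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Region- and gene-level tallies per cascade stage, strain and direction.

    Stages: ``sex_biased`` (wild-type comparison), ``dsx_regulated``
    (concordant pseudo-male comparison), ``mode_assigned`` (significant in
    at least one null comparison).
    """
    rows = []
    for strain, grp in calls.groupby("strain_context", sort=True):
        for direction in (MALE, FEMALE):
            d = grp[grp["sex_bias"] == direction]
            reg = d[d["dsx_regulated"]]
            assigned = reg[reg["mode"] != UNASSIGNED]
            rows.append(
                {
                    "strain_context": strain,
                    "direction": direction,
                    "regions_sex_biased": len(d),
                    "regions_dsx_regulated": len(reg),
                    "regions_mode_assigned": len(assigned),
                    "genes_sex_biased": d["gene_id"].nunique(),
                    "genes_dsx_regulated": reg["gene_id"].nunique(),
                    "genes_mode_assigned": assigned["gene_id"].nunique(),
                }
            )
    return pd.DataFrame(rows)


def consistent_across_strains(
    results: ContrastResults, level: float = 0.10
) -> pd.DataFrame:
    """Genes carrying the same (bias, mode) pair in both wild-type strains.

    The whole cascade is re-run at ``level`` (default 0.10) in each strain;
    a gene qualifies if at least one (direction, mode) pair — mode
    assigned — is shared between the two strain contexts.
    """
    calls = classify_regions(results, level=level)
    strains = sorted(calls["strain_context"].unique())
    if len(strains) < 2:
        raise ValueError("cross-strain consistency needs two strain contexts")
    summaries = aggregate_to_genes(calls)
    per_strain: dict[str, dict[str, set]] = {}
    for strain in strains:
        sub = summaries[summaries["strain_context"] == strain]
        per_strain[strain] = {
            r.gene_id: set(r.mode_pairs) for r in sub.itertuples() if r.mode_pairs
        }
    first, *rest = strains
    rows = []
    for gene, pairs in sorted(per_strain[first].items()):
        shared = set(pairs)
        for s in rest:
            shared &= per_strain[s].get(gene, set())
        if shared:
            rows.append(
                {
                    "gene_id": gene,
                    "shared_pairs": sorted(shared),
                    "fdr_level_used": level,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "shared_pairs", "fdr_level_used"])
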