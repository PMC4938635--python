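"""Fisher's-exact enrichment of gene sets against binary annotations.

Three annotation families are tested: DSX DNA occupancy (two prior binding
studies, consumed as boolean gene flags), chromosome-arm membership (X, 2L,
2R, 3L, 3R, 4), and GO terms. Every test is a two-sided Fisher's exact test
on the 2x2 table {in set x annotated} over a stated gene universe, since
both enrichment and depletion are of interest. Reported per test: observed
count, expected count |set|*|annotated|/|universe|, fold = observed/expected,
and the exact p (sum of hypergeometric probabilities no larger than that of
the observed table).

Arm-scan results carry unadjusted p-values with a not-significant convention
at 0.05; GO tests are BH-adjusted per ontology, pooling both strains and all
modes into one adjustment. Expected counts are rounded to integers and folds
to two decimals only for display; machine output keeps full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CHROM_ARMS = ("X", "2L", "2R", "3L", "3R", "4")
ONTOLOGIES = ("BP", "MF", "CC")


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene annotation: arm, two occupancy flags, GO terms per ontology."""

    gene_id: str
    chrom_arm: str
    occupancy_A: bool  # adult-female occupancy study
    occupancy_B: bool  # cell-line / fat-body / ovary occupancy study
    go_terms: Mapping[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chrom_arm not in CHROM_ARMS:
            raise ValueError(f"gene {self.gene_id}: unknown arm {self.chrom_arm!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """One Fisher test: observed/expected/fold and two-sided exact p."""

    set_name: str
    annotation_name: str
    observed: int
    expected: float
    fold: float
    p_value: float
    set_size: int
    annotated_size: int
    universe_size: int
    q_value: float | None = None  # filled for GO tests only

    def as_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "annotation_name": self.annotation_name,
            "observed": self.observed,
            "expected": self.expected,
            "fold": self.fold,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "set_size": self.set_size,
            "annotated_size": self.annotated_size,
            "universe_size": self.universe_size,
        }

    @property
    def display_expected(self) -> int:
        return int(round(self.expected))

    @property
    def display_fold(self) -> float:
        return round(self.fold, 2)


def fold_enrichment(observed: float, expected: float) -> float:
    """Fold = observed / expected; the identity fold * expected = observed holds exactly."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return observed / expected


def fisher_enrichment(
    gene_set: Iterable[str],
    annotated: Iterable[str],
    universe: Iterable[str],
    set_name: str = "set",
    annotation_name: str = "annotation",
) -> EnrichmentResult:
    """Two-sided Fisher's exact test of a gene set against a binary annotation.

    The universe defines the margins; the set must be contained in it and
    the annotation is restricted to it.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    if not gene_set <= universe:
        raise ValueError("gene set not contained in universe")
    annotated = set(annotated) & universe
    n = len(universe)
    k = len(gene_set)
    m = len(annotated)
    obs = len(gene_set & annotated)
    expected = k * m / n
    table = [[obs, k - obs], [m - obs, n - k - (m - obs)]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        set_name=set_name,
        annotation_name=annotation_name,
        observed=obs,
        expected=expected,
        fold=fold_enrichment(obs, expected) if expected > 0 else float("nan"),
        p_value=float(p),
        set_size=k,
        annotated_size=m,
        universe_size=n,
    )


def occupancy_scan(
    gene_sets: Mapping[str, Iterable[str]],
    annotations: Mapping[str, GeneAnnotation],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Test each gene set against both occupancy studies over the universe."""
    universe = set(universe)
    results = []
    for flag, label in (("occupancy_A", "occupancy_A"), ("occupancy_B", "occupancy_B")):
        annotated = [g for g in universe if getattr(annotations[g], flag)]
        for set_name, genes in gene_sets.items():
            results.append(
                fisher_enrichment(genes, annotated, universe, set_name, label)
            )
    return results


def chromosome_arm_scan(
    gene_set: Iterable[str],
    annotations: Mapping[str, GeneAnnotation],
    universe: Iterable[str],
    set_name: str = "set",
) -> list[EnrichmentResult]:
    """One arm-vs-rest Fisher test per chromosome arm present in the universe.

    Arms absent from the universe are omitted (a warning is carried by the
    caller's log); p-values are unadjusted, with N.S. read at 0.05 in the
    display layer.
    """
    universe = set(universe)
    results = []
    for arm in CHROM_ARMS:
        on_arm = [g for g in universe if annotations[g].chrom_arm == arm]
        if not on_arm:
            continue
        results.append(
            fisher_enrichment(gene_set, on_arm, universe, set_name, f"arm_{arm}")
        )
    return results


def go_enrichment(
    mode_gene_sets: Mapping[tuple[str, str], Iterable[str]],
    annotations: Mapping[str, GeneAnnotation],
    universe: Iterable[str],
    ontologies: Sequence[str] = ONTOLOGIES,
) -> list[EnrichmentResult]:
    """GO-term enrichment per (strain, mode) set, BH-adjusted per ontology.

    ``mode_gene_sets`` maps (strain_context, mode) -> genes. The universe is
    first restricted to GO-annotated genes (per ontology); terms annotating
    no universe gene are skipped. All strains and modes are pooled into a
    single BH adjustment within each ontology.
    """
    universe = set(universe)
    out: list[EnrichmentResult] = []
    for ont in ontologies:
        ont_universe = {
            g for g in universe if annotations[g].go_terms.get(ont)
        }
        if not ont_universe:
            continue
        terms = sorted({t for g in ont_universe for t in annotations[g].go_terms[ont]})
        batch: list[EnrichmentResult] = []
        for (strain, mode), genes in sorted(mode_gene_sets.items()):
            genes = set(genes) & ont_universe
            if not genes:
                continue
            for term in terms:
                annotated = [g for g in ont_universe if term in annotations[g].go_terms[ont]]
                batch.append(
                    fisher_enrichment(
                        genes,
                        annotated,
                        ont_universe,
                        set_name=f"{strain}:{mode}",
                        annotation_name=f"{ont}:{term}",
                    )
                )
        if batch:
            q = multipletests([r.p_value for r in batch], method="fdr_bh")[1]
            batch = [_with_q(r, float(qi)) for r, qi in zip(batch, q)]
        out.extend(batch)
    return out


def _with_q(r: EnrichmentResult, q: float) -> EnrichmentResult:
    return EnrichmentResult(
        set_name=r.set_name,
        annotation_name=r.annotation_name,
        observed=r.observed,
        expected=r.expected,
        fold=r.fold,
        p_value=r.p_value,
        set_size=r.set_size,
        annotated_size=r.annotated_size,
        universe_size=r.universe_size,
        q_value=q,
    )


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results with both machine-precision and display columns."""
    df = pd.DataFrame([r.as_dict() for r in results])
    if not df.empty:
        df["display_expected"] = df["expected"].round().astype(int)
        df["display_fold"] = df["fold"].round(2)
        df["ns_at_0.05"] = df["p_value"] >= 0.05
    return df
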