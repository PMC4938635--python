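"""Synthetic data with planted truth for the full analysis pipeline.

The generator emulates the head RNA-seq design the pipeline targets: two
wild-type strains (Canton-S, Berlin) each sampled in both sexes, one
*dsx^D* pseudo-male genotype (XX, DSX^M only) and two *dsx*-null genotypes
(XX and XY), three biological replicates per condition — 21 libraries, each
a pool of a few hundred heads with its own total mapped-read count.

Expression is lognormal: each region gets a baseline ln(RPKM) drawn once,
and each design cell a generating mean shifted from that baseline according
to the region's planted DSX regulatory mode (effect size ``delta`` on the
ln scale). The *dsx*-null cells always sit at baseline (no DSX, no
regulation); the pseudo-male cell follows the male-program mean. Sample
values add Normal(0, ``sigma``) noise on the ln scale and are converted to
reads by inverting RPKM against the library size, rounding to integers —
the discreteness of real counts without a separate count-noise model.
Strain-specific regulation is planted by restricting the wild-type effect
to one strain; the shared mutant cells keep their mode-defined means.

What this does not emulate: overdispersed count noise, GC/length biases,
isoform-level read assignment ambiguity, or correlated replicates. Planted
DSX occupancy is enriched among regulated genes; a GO term is planted into
one mode's gene set; chromosome arms are drawn from configurable
proportions (arm 4 small, as in the fly genome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CountMatrix, SampleMeta
from .enrichment import CHROM_ARMS, GeneAnnotation
from .modes import (
    BOTH_ACT,
    BOTH_REP,
    F_ACT,
    F_REP,
    M_ACT,
    M_REP,
    MODES,
    OPPOSING,
)
from .regions import AnalysisRegion, GeneModel, build_regions, mark_inter_gene_exclusions

NO_MODE = "none"
WT_STRAIN_NAMES = ("CantonS", "Berlin")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; the defaults are the study conditions.

    ``delta`` is the DSX effect on the ln(RPKM) scale, ``sigma`` the
    residual ln-scale SD between biological replicates. ``exons_per_gene``
    switches to simple single-isoform genes with exactly that many exons
    (predictable region count, used by the large calibration runs); left
    ``None``, genes get 1-3 isoforms with boundary-shifted or dropped exons
    so that single- and overlap-class regions both occur.
    """

    seed: int = 0
    n_genes: int = 200
    exons_per_gene: int | None = None
    max_isoforms: int = 3
    max_exons: int = 5
    exon_length_range: tuple[int, int] = (200, 1000)
    intron_length_range: tuple[int, int] = (300, 800)
    boundary_shift_range: tuple[int, int] = (20, 100)
    inter_gene_overlap_frac: float = 0.02
    arm_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "X": 0.17, "2L": 0.18, "2R": 0.19, "3L": 0.19, "3R": 0.21, "4": 0.06,
        }
    )
    n_replicates: int = 3
    read_length: int = 100
    library_size_range: tuple[int, int] = (10_000_000, 20_000_000)
    baseline_mean: float = 4.0
    baseline_sd: float = 0.75
    mode_probs: Mapping[str, float] = field(
        default_factory=lambda: {NO_MODE: 0.65, **{m: 0.05 for m in MODES}}
    )
    delta: float = 2.0
    sigma: float = 0.25
    strain_specific_frac: float = 0.3
    occupancy_A_rate: float = 0.05
    occupancy_B_rate: float = 0.25
    occupancy_boost: float = 3.0
    n_go_terms: Mapping[str, int] = field(
        default_factory=lambda: {"BP": 20, "MF": 10, "CC": 10}
    )
    go_term_rate: float = 0.10
    go_plant_boost: float = 5.0
    go_planted_mode: str = F_ACT

    def __post_init__(self) -> None:
        total = sum(self.mode_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.mode_probs.values()):
            raise ValueError("negative mode probability")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if abs(sum(self.arm_probs.values()) - 1.0) > 1e-9:
            raise ValueError("arm probabilities must sum to 1")


@dataclass
class SimulationResult:
    """Everything the pipeline consumes, plus the planted truth."""

    models: list[GeneModel]
    regions: list[AnalysisRegion]
    counts: CountMatrix
    meta: tuple[SampleMeta, ...]
    annotations: dict[str, GeneAnnotation]
    truth: pd.DataFrame  # per region: mode, per-strain effect, baseline, bias
    config: SimulationConfig | None = None


def cell_means(
    mode: str, baseline: float, delta: float, strain_effects: Sequence[str]
) -> dict[str, float]:
    """Generating ln(RPKM) mean per design cell for one region.

    The null cells are always at baseline (no DSX present); the pseudo-male
    cell tracks the male-program mean. Wild-type cells of a strain not in
    ``strain_effects`` collapse to baseline (no regulation in that
    background). The "both sexes" modes use the full effect in females and
    half of it in males, giving the sex-specific extent that separates them
    from a flat shift.
    """
    b, d = baseline, delta
    wt = {  # (WT_F shift, WT_M shift) under an active effect
        NO_MODE: (0.0, 0.0),
        F_ACT: (+d, 0.0),
        F_REP: (-d, 0.0),
        M_ACT: (0.0, +d),
        M_REP: (0.0, -d),
        BOTH_ACT: (+d, +d / 2),
        BOTH_REP: (-d, -d / 2),
        OPPOSING: (+d, -d),
    }[mode]
    means = {}
    for strain in WT_STRAIN_NAMES:
        active = strain in strain_effects and mode != NO_MODE
        means[f"{strain}:WT_F"] = b + (wt[0] if active else 0.0)
        means[f"{strain}:WT_M"] = b + (wt[1] if active else 0.0)
    means["NULL_XX"] = b
    means["NULL_XY"] = b
    means["DSXD_PM"] = b + (wt[1] if mode != NO_MODE else 0.0)  # male program
    return means


def default_design(
    rng: np.random.Generator,
    n_replicates: int = 3,
    library_size_range: tuple[int, int] = (10_000_000, 20_000_000),
) -> tuple[SampleMeta, ...]:
    """The 21-library design: 2 strains x 2 sexes + 3 mutant genotypes, n=3."""
    lo, hi = library_size_range
    meta = []
    conditions = [
        *[(s, g) for s in WT_STRAIN_NAMES for g in ("WT_F", "WT_M")],
        *[("shared_mutant", g) for g in ("DSXD_PM", "NULL_XX", "NULL_XY")],
    ]
    for strain, group in conditions:
        for rep in range(1, n_replicates + 1):
            meta.append(
                SampleMeta(
                    sample_id=f"{strain}_{group}_r{rep}",
                    strain_context=strain,
                    genotype_group=group,
                    replicate=rep,
                    total_mapped_reads=int(rng.integers(lo, hi + 1)),
                )
            )
    return tuple(meta)


def _random_gene_models(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    models: list[GeneModel] = []
    cursors = {arm: 10_000 for arm in cfg.arm_probs}
    arms = list(cfg.arm_probs)
    probs = np.array([cfg.arm_probs[a] for a in arms])
    gene_arms = rng.choice(len(arms), size=cfg.n_genes, p=probs)
    for i in range(cfg.n_genes):
        gid = f"g{i:05d}"
        arm = arms[gene_arms[i]]
        start = cursors[arm] + int(rng.integers(2_000, 6_000))
        if cfg.exons_per_gene is not None:
            n_exons, n_iso = cfg.exons_per_gene, 1
        else:
            n_exons = int(rng.integers(1, cfg.max_exons + 1))
            n_iso = int(rng.integers(1, cfg.max_isoforms + 1))
        base = []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(*cfg.exon_length_range))
            base.append((pos, pos + length))
            pos = pos + length + int(rng.integers(*cfg.intron_length_range))
        transcripts = [(f"{gid}.t1", tuple(base))]
        for t in range(2, n_iso + 1):
            exons = []
            for s, e in base:
                u = rng.random()
                if u < 0.2 and len(base) > 1:
                    continue  # exon dropped in this isoform
                if u < 0.5:
                    shift = int(rng.integers(*cfg.boundary_shift_range))
                    if rng.random() < 0.5:
                        s = max(s - shift, 0)
                    else:
                        e = e + shift
                exons.append((s, e))
            if not exons:
                exons = [base[0]]
            transcripts.append((f"{gid}.t{t}", tuple(exons)))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(gid, f"chr{arm}", strand, tuple(transcripts)))
        cursors[arm] = max(e for _, ex in transcripts for _, e in ex)
    # Inter-gene ambiguity: plant a small gene overlapping another's first exon.
    n_overlap = int(round(cfg.inter_gene_overlap_frac * cfg.n_genes))
    for j in range(n_overlap):
        host = models[int(rng.integers(0, cfg.n_genes))]
        s, e = host.all_exons[0]
        mid = (s + e) // 2
        gid = f"gov{j:03d}"
        models.append(
            GeneModel(
                gid, host.chrom, "+",
                ((f"{gid}.t1", ((mid, mid + 400),)),),
            )
        )
    return models


def _emit_counts(
    regions: Sequence[AnalysisRegion],
    truth: pd.DataFrame,
    meta: Sequence[SampleMeta],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> CountMatrix:
    """Counts from planted cell means: inverse-RPKM with integer rounding."""
    index = [r.region_id for r in regions]
    lengths = pd.Series([r.length for r in regions], index=index, name="length")
    truth = truth.set_index("region_id").loc[index]
    cols = {}
    for m in meta:
        mu = np.array(
            [
                cell_means(
                    truth.at[rid, "mode"],
                    truth.at[rid, "baseline"],
                    cfg.delta,
                    truth.at[rid, "strain_effects"],
                )[m.cell]
                for rid in index
            ]
        )
        value = mu + rng.normal(0.0, cfg.sigma, size=len(index))
        reads = np.rint(
            np.exp(value) * (lengths.to_numpy() / 1e3) * (m.total_mapped_reads / 1e6)
        )
        cols[m.sample_id] = np.maximum(reads, 0).astype(np.int64)
    counts = pd.DataFrame(cols, index=index)
    return CountMatrix(counts=counts, region_lengths=lengths)


def _plant_annotations(
    models: Sequence[GeneModel],
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, GeneAnnotation]:
    regulated_genes = set(truth.loc[truth["mode"] != NO_MODE, "gene_id"])
    planted_genes = set(
        truth.loc[truth["mode"] == cfg.go_planted_mode, "gene_id"]
    )
    annotations = {}
    for m in models:
        arm = m.chrom.removeprefix("chr")
        boost = cfg.occupancy_boost if m.gene_id in regulated_genes else 1.0
        occ_a = rng.random() < min(1.0, cfg.occupancy_A_rate * boost)
        occ_b = rng.random() < min(1.0, cfg.occupancy_B_rate * boost)
        go: dict[str, frozenset] = {}
        for ont, n_terms in cfg.n_go_terms.items():
            terms = set()
            for t in range(n_terms):
                rate = cfg.go_term_rate
                if ont == "BP" and t == 0 and m.gene_id in planted_genes:
                    rate = min(1.0, rate * cfg.go_plant_boost)
                if rng.random() < rate:
                    terms.add(f"{ont}{t:03d}")
            go[ont] = frozenset(terms)
        annotations[m.gene_id] = GeneAnnotation(
            gene_id=m.gene_id,
            chrom_arm=arm,
            occupancy_A=occ_a,
            occupancy_B=occ_b,
            go_terms=go,
        )
    return annotations


def _truth_frame(
    regions: Sequence[AnalysisRegion],
    modes: Mapping[str, str],
    strain_effects: Mapping[str, tuple[str, ...]],
    baselines: Mapping[str, float],
    delta: float,
) -> pd.DataFrame:
    rows = []
    for r in regions:
        mode = modes[r.region_id]
        eff = strain_effects[r.region_id]
        means = cell_means(mode, baselines[r.region_id], delta, eff)
        row = {
            "region_id": r.region_id,
            "gene_id": r.gene_id,
            "mode": mode,
            "strain_effects": eff,
            "baseline": baselines[r.region_id],
            "excluded": r.excluded,
        }
        for strain in WT_STRAIN_NAMES:
            diff = means[f"{strain}:WT_F"] - means[f"{strain}:WT_M"]
            row[f"sex_bias_{strain}"] = (
                "female" if diff > 0 else "male" if diff < 0 else "none"
            )
        rows.append(row)
    return pd.DataFrame(rows)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate gene models, counts, annotations and truth from one seed.

    The seed fully determines the output: the same config yields
    byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    models = _random_gene_models(config, rng)
    regions = mark_inter_gene_exclusions(build_regions(models), models)

    mode_names = list(config.mode_probs)
    mode_p = np.array([config.mode_probs[m] for m in mode_names])
    modes: dict[str, str] = {}
    strain_effects: dict[str, tuple[str, ...]] = {}
    baselines: dict[str, float] = {}
    for r in regions:
        if r.excluded:
            mode = NO_MODE
        else:
            mode = mode_names[int(rng.choice(len(mode_names), p=mode_p))]
        modes[r.region_id] = mode
        if mode != NO_MODE and rng.random() < config.strain_specific_frac:
            eff = (WT_STRAIN_NAMES[int(rng.integers(0, 2))],)
        else:
            eff = WT_STRAIN_NAMES
        strain_effects[r.region_id] = eff if mode != NO_MODE else ()
        baselines[r.region_id] = float(
            rng.normal(config.baseline_mean, config.baseline_sd)
        )

    truth = _truth_frame(regions, modes, strain_effects, baselines, config.delta)
    meta = default_design(rng, config.n_replicates, config.library_size_range)
    counts = _emit_counts(regions, truth, meta, config, rng)
    annotations = _plant_annotations(models, truth, config, rng)
    return SimulationResult(
        models=models,
        regions=regions,
        counts=counts,
        meta=meta,
        annotations=annotations,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Worked fixture: a hand-built miniature exercising every pipeline feature.

_FIXTURE_SEED = 797979


def make_worked_fixture(delta: float = 3.0, sigma: float = 0.1) -> SimulationResult:
    """Deterministic 18-gene miniature with one exemplar gene per mode.

    Contains: one gene per DSX mode (the opposing exemplar is a Yolk-protein
    -like, strongly female-biased gene), a two-isoform gene whose two
    regions carry different modes, a pair of genes with overlapping exons
    (their shared regions are excluded but each keeps a clean one), and
    eight unregulated genes. The eight regulated genes include all four
    residents of arm 4, planting an arm-4 enrichment among regulated genes.
    Effects are large (``delta`` = 3 ln units) and noise small so the
    cascade recovers every planted mode.
    """

    offsets = iter(range(10_000, 500_000, 10_000))

    def gene(gid, arm, exons_by_iso, offset=None):
        off = next(offsets) if offset is None else offset
        return GeneModel(
            gid, f"chr{arm}", "+",
            tuple(
                (f"{gid}.t{i+1}", tuple((s + off, e + off) for s, e in exons))
                for i, exons in enumerate(exons_by_iso)
            ),
        )

    two_exon = [[(1000, 1600), (2400, 3000)]]
    one_exon = [[(1000, 1800)]]
    models = [
        gene("gFact", "4", one_exon),
        gene("gFrep", "4", two_exon),
        gene("gMact", "X", one_exon),
        gene("gMrep", "2L", two_exon),
        gene("gBact", "2R", one_exon),
        gene("gBrep", "3L", one_exon),
        gene("gYp", "4", one_exon),  # opposing: DSX^F activates, DSX^M represses
        # Two isoforms; exon 1 identical (single region), exon 2
        # boundary-shifted (overlap region). Regions carry different modes.
        gene("gMulti", "4", [[(1000, 1500), (2400, 3000)], [(1000, 1500), (2300, 3100)]]),
        # Inter-gene overlap pair: first exons overlap (excluded), second
        # exons are private, so both genes stay in the analysis universe.
        gene("gOvA", "3R", [[(1000, 1700), (2600, 3200)]], offset=900_000),
        gene("gOvB", "3R", [[(1400, 2000), (4000, 4600)]], offset=900_000),
    ]
    for i in range(8):
        arm = ["X", "2L", "2R", "3L", "3R", "X", "2L", "2R"][i]
        models.append(gene(f"gNull{i}", arm, [[(1000, 1800)]]))

    regions = mark_inter_gene_exclusions(build_regions(models), models)
    gene_modes = {
        "gFact": F_ACT, "gFrep": F_REP, "gMact": M_ACT, "gMrep": M_REP,
        "gBact": BOTH_ACT, "gBrep": BOTH_REP, "gYp": OPPOSING,
    }
    modes, effects, baselines = {}, {}, {}
    for r in regions:
        if r.excluded:
            mode = NO_MODE
        elif r.gene_id == "gMulti":
            # single-class first region activator-in-females; overlap-class
            # second region male-specific repressor
            mode = F_ACT if r.region_class == "single" else M_REP
        else:
            mode = gene_modes.get(r.gene_id, NO_MODE)
        modes[r.region_id] = mode
        effects[r.region_id] = WT_STRAIN_NAMES if mode != NO_MODE else ()
        baselines[r.region_id] = 4.0

    cfg = SimulationConfig(seed=_FIXTURE_SEED, delta=delta, sigma=sigma)
    rng = np.random.default_rng(_FIXTURE_SEED)
    truth = _truth_frame(regions, modes, effects, baselines, delta)
    meta = default_design(rng, cfg.n_replicates, cfg.library_size_range)
    counts = _emit_counts(regions, truth, meta, cfg, rng)

    regulated = {g for g, m in gene_modes.items()} | {"gMulti"}
    annotations = {}
    for m in models:
        gid = m.gene_id
        annotations[gid] = GeneAnnotation(
            gene_id=gid,
            chrom_arm=m.chrom.removeprefix("chr"),
            occupancy_A=gid in {"gFact", "gYp", "gMrep", "gMulti"},
            occupancy_B=gid in regulated or gid == "gNull0",
            go_terms={
                "BP": frozenset(
                    {"BP000"} if gid in {"gFact", "gMulti", "gYp", "gFrep"} else set()
                ),
                "MF": frozenset(),
                "CC": frozenset(),
            },
        )
    return SimulationResult(
        models=models,
        regions=regions,
        counts=counts,
        meta=meta,
        annotations=annotations,
        truth=truth,
        config=cfg,
    )
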