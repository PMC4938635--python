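# Methods

## Analysis unit: exonic regions

Expression is measured per *exonic analysis region*, not per gene, so that
isoform-specific sex differences are visible. Within a gene, exon
footprints identical across isoforms are deduplicated; any two footprints
sharing at least one base are linked, and each connected component of this
overlap graph becomes one region spanning its full extent. A component of
one footprint is classed `single`, anything merged `overlap`. Adjacent but
non-overlapping exons remain separate regions. Consequences worth knowing:
the union of a gene's regions equals the union of its exonic bases, regions
are pairwise disjoint, and chains of staggered exons collapse into a single
long region (by construction — the entire region of overlap is the unit).

Regions overlapping the exonic footprint of a *different* gene are
ambiguous and are excluded whole, rather than trimming just the shared
bases: partial regions would have a different length and coverage
support than the annotation implies, and the simpler rule is reproducible.
Overlap is tested on genomic footprints regardless of strand, since reads
from unstranded libraries cannot be attributed to a strand either. Excluded
base counts go to the run log.

Coordinates are 0-based half-open internally; GFF3 input (1-based
inclusive) is converted on read and all output headers state the
convention.

## Expression and detection

RPKM = count / (region length / 10^3) / (total mapped reads / 10^6), with
total mapped reads taken from sample metadata (the count matrix covers only
exonic regions, so recomputing totals from it would be biased). Analysis
operates on ln(RPKM). A region is *detected* only if its average
per-nucleotide coverage (count × read length / region length) exceeds zero
in every sample; with a strictly-positive threshold this is equivalent to
requiring a positive count everywhere, which is what is implemented — no
per-base read positions are needed. Undetected regions keep their rows but
carry no values, and the normaliser refuses to take a log if the mask was
bypassed, so ln(0) is structurally impossible. A gene is considered
detected when at least one of its regions is.

## The contrast model

Per region, a one-way fixed-effects layout over the design cells present —
in the full design Canton-S ♀/♂, Berlin ♀/♂, *dsx^D* pseudo male, null XX,
null XY (7 cells × 3 replicates = 21 libraries). The residual variance is
pooled across all cells (df = N − number of cells = 14 in the full design):
all libraries come from a single shared experiment, and pooling maximises
df at n = 3 per cell. The mutant cells exist once and are shared between
the two strain contexts; the strain label on a contrast refers only to its
wild-type side. Each contrast is a difference of two cell means with
SE = √(s²(1/n_A + 1/n_B)) and a two-sided t test. Whether one joint model
or separate per-comparison fits is preferable is genuinely open; the joint
fit is this package's documented choice, and a cross-check against an
ordinary least-squares cell-means fit (statsmodels) is part of the test
suite. Degenerate cases: identical cells give estimate 0 and p = 1; zero
residual variance with a nonzero difference gives p = 0; zero residual df
is rejected outright.

Benjamini–Hochberg q-values are computed once over the pooled set of all
contrasts × all detected regions — deliberately conservative relative to
per-contrast adjustment, and matching how the three strict cut-offs
(q < 0.05 / 0.10 / 0.20) are used downstream. Ties are handled by the
standard step-up rule; boundaries are strict (q = 0.05 is not significant
at 0.05).

## Mode cascade

Stage 1 — sex bias: wild-type ♀−♂ contrast significant; sign gives the
direction (an estimate of exactly 0 is directionless, hence no bias).
Stage 2 — *dsx* regulation: the ♀−pseudo-male contrast must be significant
*and* sign-concordant with the bias (a pseudo male produces only DSX^M, so
a DSX-driven female-biased gene should drop toward the male program).
Stage 3 — mode: significance and sign of the two wild-type−null contrasts;
positive = activator (expression falls without DSX), negative = repressor;
one sex only → sex-specific mode; both with equal signs → activator/
repressor in both; both with opposite signs → opposing. Regions passing
stage 2 but significant in neither null comparison are reported as
`unassigned` candidates rather than dropped, so stage-wise tallies are
reproducible. All stages use the same FDR level; cross-strain consistency
re-runs the entire cascade at 0.10 in both strains and requires an
identical (direction, mode) pair — applying the level to every stage is a
documented choice where the alternative (only the null comparisons) is
equally defensible.

Gene aggregation keeps every distinct (direction, mode) pair across a
gene's regions: multi-isoform genes can genuinely carry two modes, and a
gene with a female-biased region and a male-biased region is counted in
both direction tallies. No vote resolves conflicts.

## Enrichment

Every test is two-sided Fisher's exact (enrichment or depletion) on
{in set × annotated} over an explicit gene universe — in real analyses the
occupancy-constrained detected-gene universe supplied at run time, in
synthetic runs the simulated universe. Expected = |set|·|annotated|/|universe|;
fold = observed/expected, so fold × expected = observed exactly before
display rounding (expected shown as nearest integer, fold to 2 decimals).
Chromosome-arm scans test each arm against the rest and report unadjusted p
with a not-significant convention at 0.05; GO tests are BH-adjusted per
ontology with both strains and all mode sets pooled, after restricting the
universe to GO-annotated genes. The asymmetry (no multiplicity adjustment
for the arm scans) mirrors how such scans are conventionally reported and
is deliberate.

## Synthetic data

The generator emulates the target design: 2 wild-type strains × 2 sexes,
pseudo males, null XX/XY, 3 replicates, library sizes 10–20 M mapped reads.
Per region a baseline ln(RPKM) is drawn (Normal, mean 4.0, SD 0.75 —
comfortably detected at these library sizes); each design cell's mean is
baseline shifted per the planted mode with effect δ (default 2.0 ln units)
— null cells always at baseline, pseudo males at the male-program mean, and
the "both sexes" modes use δ in females and δ/2 in males so extent differs
by sex. Replicate values add Normal(0, σ = 0.25) noise on the ln scale and
are converted to integer counts by inverting RPKM (lognormal emission
rather than negative binomial, because the pipeline's statistics operate on
ln(RPKM); count rounding supplies discreteness, and an NB emitter is a
possible extension). Strain-specific regulation zeroes the wild-type effect
in the unaffected strain while shared mutant cells keep mode-defined means.
35 % of regions carry a mode (5 % each) — far above real prevalence, chosen
so that every mode has enough members for calibration at desk scale; DSX
occupancy is planted at 3× rate among regulated genes; one GO term is
planted into one mode's gene set.

Passing tests on these data show the pipeline recovers what it assumes —
lognormal noise, independent replicates, exact region annotation. They do
not show robustness to overdispersion, mapping ambiguity, correlated
replicates, or annotation error, none of which are modelled.

Calibration sizes used by the tests and the acceptance script: mode
recovery on 2,000-region experiments (500 four-exon single-isoform genes)
across 10–20 seeds, type-I control on 5,000-region global-null experiments
across 5–10 seeds. Observed behaviour: ≈97 % of planted (region, strain)
modes recovered at FDR < 0.05; essentially no sex-bias calls under the
global null (pooled BH across 16,000 tests is strongly conservative when
nothing is true).

The 18-gene worked fixture is hand-built: one exemplar gene per mode
(opposing exemplified by a Yolk-protein-like strongly female-biased gene),
a two-isoform gene whose `single` and `overlap` regions carry different
modes, an overlapping gene pair whose shared regions are excluded while
each keeps one analysable region, and all four arm-4 residents regulated,
planting an arm-4 enrichment (observed 4, expected 2, fold 2.25). Effects
are δ = 3, σ = 0.1, so recovery is certain and the fixture serves as an
end-to-end regression anchor.

## Known limitations

* The linear-model form (joint 7-cell fit, pooled variance, df) is a
  defensible reconstruction, not a uniquely determined choice; estimates
  are identical under per-comparison fits, p-values differ slightly with
  the df.
* No moderated variance estimators and no covariates; at n = 3 per cell a
  shrinkage estimator would add power but changes the testing framework.
* Exclusion of whole regions at inter-gene overlaps discards some
  unambiguous bases.
* Enrichment consumes occupancy as binary flags; no distance-to-gene or
  binding-strength information.
* The mode classification is threshold-sensitive by construction: a region
  whose null contrasts straddle the significance boundary can change mode
  with the FDR level, which is why the level used is recorded on every
  call.
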