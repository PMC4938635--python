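"""Fisher enrichment: exact-p oracle, fold identities, arm and GO scans."""

import numpy as np
import pytest
from scipy import stats

from dsxmodes import (
    GeneAnnotation,
    chromosome_arm_scan,
    fisher_enrichment,
    fold_enrichment,
    go_enrichment,
)
from dsxmodes.enrichment import occupancy_scan, results_frame


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration.

    Sums P(table) over all tables with the observed margins whose
    probability does not exceed (up to rounding) that of the observed one.
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def sets_from_table(a, b, c, d):
    """Universe, gene set and annotation realising a 2x2 table."""
    universe = [f"g{i}" for i in range(a + b + c + d)]
    gene_set = universe[: a + b]
    annotated = universe[:a] + universe[a + b: a + b + c]
    return gene_set, annotated, universe


def make_annotations(arms=None, occ_a=(), occ_b=(), go=None, n=20):
    out = {}
    for i in range(n):
        g = f"g{i}"
        out[g] = GeneAnnotation(
            gene_id=g,
            chrom_arm=(arms or {}).get(g, "2L"),
            occupancy_A=g in occ_a,
            occupancy_B=g in occ_b,
            go_terms=(go or {}).get(g, {}),
        )
    return out


class TestFisherEnrichment:
    def test_expected_and_fold_arithmetic(self):
        # |universe| 100, |set| 10, |annotated| 10, observed 5
        universe = [f"g{i}" for i in range(100)]
        gene_set = universe[:10]
        annotated = universe[:5] + universe[50:55]
        r = fisher_enrichment(gene_set, annotated, universe)
        assert r.observed == 5 and r.expected == pytest.approx(1.0)
        assert r.fold == pytest.approx(5.0)

    def test_printed_style_rounding(self):
        # observed 62 against expected 30 prints as fold 2.07
        assert round(fold_enrichment(62, 30), 2) == 2.07

    def test_specific_table_matches_enumeration(self):
        gene_set, annotated, universe = sets_from_table(3, 7, 2, 88)
        r = fisher_enrichment(gene_set, annotated, universe)
        assert r.p_value == pytest.approx(fisher_oracle(3, 7, 2, 88), rel=1e-9)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 25, size=4)
            if a + b == 0 or a + b + c + d == 0:
                continue
            gene_set, annotated, universe = sets_from_table(a, b, c, d)
            r = fisher_enrichment(gene_set, annotated, universe)
            assert r.p_value == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)

    def test_fold_times_expected_is_observed(self):
        rng = np.random.default_rng(19)
        for _ in range(30):
            a, b, c, d = rng.integers(1, 40, size=4)
            gene_set, annotated, universe = sets_from_table(a, b, c, d)
            r = fisher_enrichment(gene_set, annotated, universe)
            assert r.fold * r.expected == pytest.approx(r.observed, rel=1e-12)

    def test_complement_symmetry(self):
        """Testing against the complement annotation keeps p, inverts fold."""
        gene_set, annotated, universe = sets_from_table(8, 12, 30, 50)
        complement = sorted(set(universe) - set(annotated))
        r1 = fisher_enrichment(gene_set, annotated, universe)
        r2 = fisher_enrichment(gene_set, complement, universe)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)
        assert r1.observed + r2.observed == len(gene_set)
        # folds sit on opposite sides of 1 (or both at 1)
        assert (r1.fold - 1) * (r2.fold - 1) <= 0

    def test_depletion_detected(self):
        universe = [f"g{i}" for i in range(200)]
        annotated = universe[:100]
        avoiding = universe[100:140]  # set constructed to miss the annotation
        r = fisher_enrichment(avoiding, annotated, universe)
        assert r.fold < 1 and r.p_value < 0.05

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment([], ["g1"], ["g1"])
        with pytest.raises(ValueError):
            fisher_enrichment(["g1"], ["g1"], [])
        with pytest.raises(ValueError, match="universe"):
            fisher_enrichment(["absent"], ["g1"], ["g1"])


class TestChromosomeArmScan:
    def test_set_equal_to_arm_matches_closed_form(self):
        arms = {f"g{i}": ("X" if i < 6 else "3R") for i in range(20)}
        ann = make_annotations(arms=arms)
        x_genes = [g for g, a in arms.items() if a == "X"]
        results = {r.annotation_name: r for r in
                   chromosome_arm_scan(x_genes, ann, list(arms))}
        rx = results["arm_X"]
        assert rx.observed == len(x_genes)
        assert rx.fold == pytest.approx(len(arms) / len(x_genes))

    def test_uniform_set_folds_near_one(self):
        rng = np.random.default_rng(29)
        arms = {f"g{i}": ["X", "2L", "2R", "3L", "3R", "4"][i % 6] for i in range(600)}
        ann = make_annotations(arms=arms, n=600)
        universe = list(arms)
        gene_set = list(rng.choice(universe, size=200, replace=False))
        for r in chromosome_arm_scan(gene_set, ann, universe):
            assert 0.6 < r.fold < 1.5  # sampling error only
            assert r.p_value > 0.001

    def test_absent_arm_omitted(self):
        arms = {f"g{i}": "2L" for i in range(10)}
        ann = make_annotations(arms=arms, n=10)
        results = chromosome_arm_scan(["g0", "g1"], ann, list(arms))
        assert {r.annotation_name for r in results} == {"arm_2L"}


class TestGoEnrichment:
    def test_bookkeeping_pools_strains_and_modes_per_ontology(self):
        go = {
            f"g{i}": {"BP": frozenset({f"BP{i % 3}"}), "MF": frozenset({"MF0"})}
            for i in range(20)
        }
        ann = make_annotations(go=go)
        sets = {
            ("CantonS", "F_specific_activator"): [f"g{i}" for i in range(5)],
            ("Berlin", "opposing"): [f"g{i}" for i in range(5, 12)],
        }
        results = go_enrichment(sets, ann, list(ann))
        bp = [r for r in results if r.annotation_name.startswith("BP")]
        mf = [r for r in results if r.annotation_name.startswith("MF")]
        assert len(bp) == 2 * 3 and len(mf) == 2 * 1
        assert all(r.q_value is not None for r in results)

    def test_universal_term_is_null(self):
        go = {f"g{i}": {"BP": frozenset({"BPall"})} for i in range(20)}
        ann = make_annotations(go=go)
        (r,) = [
            r for r in go_enrichment({("CantonS", "opposing"): ["g0", "g1"]},
                                     ann, list(ann))
            if r.annotation_name == "BP:BPall"
        ]
        assert r.fold == pytest.approx(1.0) and r.p_value == pytest.approx(1.0)

    def test_planted_term_recovered(self):
        """A 5x-enriched term in one mode set reaches q < 0.05."""
        rng = np.random.default_rng(41)
        n = 400
        target = {f"g{i}" for i in range(60)}
        go = {}
        for i in range(n):
            g = f"g{i}"
            terms = {f"BP{t}" for t in range(1, 10) if rng.random() < 0.1}
            rate = 0.5 if g in target else 0.1
            if rng.random() < rate:
                terms.add("BP0")
            if not terms:
                terms.add("BP9")
            go[g] = {"BP": frozenset(terms)}
        ann = make_annotations(go=go, n=n)
        results = go_enrichment({("CantonS", "F_specific_activator"): sorted(target)},
                                ann, list(ann))
        planted = [r for r in results if r.annotation_name == "BP:BP0"][0]
        assert planted.fold > 2 and planted.q_value < 0.05

    def test_occupancy_scan_labels(self):
        ann = make_annotations(occ_a={"g0", "g1"}, occ_b={"g0", "g5"})
        results = occupancy_scan({"setA": ["g0", "g1", "g2"]}, ann, list(ann))
        frame = results_frame(results)
        assert set(frame["annotation_name"]) == {"occupancy_A", "occupancy_B"}
        row = frame.set_index("annotation_name").loc["occupancy_A"]
        assert row["observed"] == 2
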