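"""DSX regulatory-mode cascade: bias, regulation, mode, gene aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dsxmodes import (
    aggregate_to_genes,
    call_dsx_regulated,
    call_sex_bias,
    classify_mode,
    classify_regions,
    consistent_across_strains,
    stage_counts,
)
from dsxmodes.contrasts import ContrastResults
from dsxmodes.modes import (
    BOTH_ACT,
    BOTH_REP,
    F_ACT,
    F_REP,
    M_ACT,
    M_REP,
    MODES,
    OPPOSING,
    UNASSIGNED,
)

SIG = 0.01  # q below the 0.05 level
NS = 0.5  # q above every level


def make_results(rows):
    """Synthetic adjusted ContrastResults from (region, gene, strain, contrast,
    estimate, q) tuples."""
    return ContrastResults(
        pd.DataFrame(
            rows,
            columns=["region_id", "gene_id", "strain_context", "contrast",
                     "estimate", "q_value"],
        ).assign(p_value=lambda d: d["q_value"] / 2)
    )


def region_rows(rid, gene, strain, wt, dsxd, nf, nm):
    """Rows for one region: (estimate, q) per contrast."""
    return [
        (rid, gene, strain, "WTF_vs_WTM", *wt),
        (rid, gene, strain, "WTF_vs_DSXD", *dsxd),
        (rid, gene, strain, "WTF_vs_NULLXX", *nf),
        (rid, gene, strain, "WTM_vs_NULLXY", *nm),
    ]


class TestCallSexBias:
    @pytest.mark.parametrize(
        "estimate,q,expected",
        [(0.8, 0.04, "female"), (-0.8, 0.04, "male"), (0.8, 0.06, "none"),
         (0.0, 0.01, "none")],
    )
    def test_direction_and_threshold(self, estimate, q, expected):
        assert call_sex_bias(estimate, q, level=0.05) == expected


class TestCallDsxRegulated:
    @pytest.mark.parametrize(
        "bias,estimate,q,expected",
        [
            ("female", 1.1, 0.01, True),
            ("female", -1.1, 0.01, False),  # significant but wrong direction
            ("male", -0.5, 0.2, False),  # right direction, not significant
            ("male", -0.5, 0.01, True),
        ],
    )
    def test_concordance(self, bias, estimate, q, expected):
        assert call_dsx_regulated(bias, estimate, q, level=0.05) is expected

    def test_requires_bias(self):
        with pytest.raises(ValueError):
            call_dsx_regulated("none", 1.0, 0.01, 0.05)


MODE_TRUTH = {
    # (sigF, sigM, actF, actM) -> mode; sig=False rows collapse by design
    (True, False, True, True): F_ACT,
    (True, False, True, False): F_ACT,
    (True, False, False, True): F_REP,
    (True, False, False, False): F_REP,
    (False, True, True, True): M_ACT,
    (False, True, False, True): M_ACT,
    (False, True, True, False): M_REP,
    (False, True, False, False): M_REP,
    (True, True, True, True): BOTH_ACT,
    (True, True, False, False): BOTH_REP,
    (True, True, True, False): OPPOSING,
    (True, True, False, True): OPPOSING,
    (False, False, True, True): UNASSIGNED,
    (False, False, True, False): UNASSIGNED,
    (False, False, False, True): UNASSIGNED,
    (False, False, False, False): UNASSIGNED,
}


class TestClassifyMode:
    def test_all_sixteen_configurations(self):
        """Every (sigF, sigM, signF, signM) combination maps to one label."""
        for sig_f, sig_m, act_f, act_m in itertools.product([True, False], repeat=4):
            est_f = 1.0 if act_f else -1.0
            est_m = 1.0 if act_m else -1.0
            got = classify_mode(est_f, SIG if sig_f else NS, est_m,
                                SIG if sig_m else NS, level=0.05)
            assert got == MODE_TRUTH[(sig_f, sig_m, act_f, act_m)]
            assert got in (*MODES, UNASSIGNED)

    def test_zero_estimate_treated_as_not_significant(self):
        assert classify_mode(0.0, SIG, -1.0, SIG, 0.05) == M_REP
        assert classify_mode(0.0, SIG, 0.0, SIG, 0.05) == UNASSIGNED

    def test_table2_exemplar_patterns(self):
        # female-biased gene, null-female significant and positive only
        assert classify_mode(1.2, SIG, 0.3, NS, 0.05) == F_ACT
        # Yolk-protein pattern: activated in females, repressed in males
        assert classify_mode(2.0, SIG, -2.0, SIG, 0.05) == OPPOSING
        # female-biased, significant negative male-null contrast only
        assert classify_mode(0.2, NS, -1.5, SIG, 0.05) == M_REP


class TestClassifyRegions:
    def test_cascade_stages(self):
        rows = (
            # passes everything: opposing
            region_rows("r1", "gA", "CantonS", (2.0, SIG), (2.0, SIG), (1.0, SIG), (-1.0, SIG))
            # sex-biased but dsxD discordant: not regulated
            + region_rows("r2", "gB", "CantonS", (2.0, SIG), (-2.0, SIG), (1.0, SIG), (1.0, SIG))
            # regulated but neither null significant: unassigned candidate
            + region_rows("r3", "gC", "CantonS", (-1.0, SIG), (-1.0, SIG), (0.5, NS), (0.5, NS))
            # not sex-biased at all
            + region_rows("r4", "gD", "CantonS", (0.5, NS), (2.0, SIG), (1.0, SIG), (1.0, SIG))
        )
        calls = classify_regions(make_results(rows), level=0.05).set_index("region_id")
        assert calls.at["r1", "mode"] == OPPOSING and calls.at["r1", "dsx_regulated"]
        assert not calls.at["r2", "dsx_regulated"]
        assert calls.at["r3", "dsx_regulated"] and calls.at["r3", "mode"] == UNASSIGNED
        assert calls.at["r4", "sex_bias"] == "none"
        counts = stage_counts(calls.reset_index())
        female = counts[counts["direction"] == "female"].iloc[0]
        assert female["regions_sex_biased"] == 2  # r1, r2
        assert female["regions_dsx_regulated"] == 1  # r1
        assert female["regions_mode_assigned"] == 1

    def test_raising_level_never_shrinks_regulated_set(self):
        rng = np.random.default_rng(31)
        rows = []
        for i in range(80):
            rows += region_rows(
                f"r{i}", f"g{i}", "CantonS",
                (rng.normal(), rng.random()), (rng.normal(), rng.random()),
                (rng.normal(), rng.random()), (rng.normal(), rng.random()),
            )
        res = make_results(rows)
        regulated = {}
        for level in (0.05, 0.10, 0.20):
            calls = classify_regions(res, level=level)
            regulated[level] = set(calls.loc[calls["dsx_regulated"], "region_id"])
        assert regulated[0.05] <= regulated[0.10] <= regulated[0.20]

    def test_opposing_calls_have_opposite_null_signs(self):
        rng = np.random.default_rng(37)
        rows = []
        for i in range(120):
            rows += region_rows(
                f"r{i}", f"g{i}", "CantonS",
                (rng.normal(), rng.random() / 2), (rng.normal(), rng.random() / 2),
                (rng.normal(), rng.random() / 2), (rng.normal(), rng.random() / 2),
            )
        res = make_results(rows)
        calls = classify_regions(res, level=0.10)
        opposing = calls.loc[calls["mode"] == OPPOSING, "region_id"]
        nf = res.select("WTF_vs_NULLXX", "CantonS")
        nm = res.select("WTM_vs_NULLXY", "CantonS")
        for rid in opposing:
            assert nf.at[rid, "estimate"] * nm.at[rid, "estimate"] < 0


class TestGeneAggregation:
    def _calls(self, rows):
        return pd.DataFrame(
            rows,
            columns=["region_id", "gene_id", "strain_context", "sex_bias",
                     "dsx_regulated", "mode", "fdr_level_used"],
        )

    def test_duplicate_modes_collapse(self):
        calls = self._calls([
            ("r1", "g", "CantonS", "female", True, F_ACT, 0.05),
            ("r2", "g", "CantonS", "female", True, F_ACT, 0.05),
        ])
        out = aggregate_to_genes(calls)
        assert len(out) == 1 and out.iloc[0]["mode_pairs"] == [("female", F_ACT)]

    def test_gene_counted_in_both_directions(self):
        calls = self._calls([
            ("r1", "g", "CantonS", "female", True, F_ACT, 0.05),
            ("r2", "g", "CantonS", "male", True, F_REP, 0.05),
        ])
        out = aggregate_to_genes(calls).iloc[0]
        assert set(out["bias_directions"]) == {"female", "male"}
        assert set(out["mode_pairs"]) == {("female", F_ACT), ("male", F_REP)}

    def test_multi_mode_gene_keeps_both_modes(self):
        # a gene regulated by opposing effects through one region and
        # male-specific repression through another keeps both modes
        calls = self._calls([
            ("r1", "g", "CantonS", "female", True, OPPOSING, 0.05),
            ("r2", "g", "CantonS", "female", True, M_REP, 0.05),
        ])
        out = aggregate_to_genes(calls).iloc[0]
        assert set(out["mode_pairs"]) == {("female", OPPOSING), ("female", M_REP)}


class TestCrossStrainConsistency:
    def _two_strain_results(self, ber_mode_rows):
        rows = region_rows("r1", "gA", "CantonS", (2.0, SIG), (2.0, SIG), (1.0, SIG), (0.1, NS))
        rows += ber_mode_rows
        return make_results(rows)

    def test_same_pair_in_both_strains_included(self):
        res = self._two_strain_results(
            region_rows("r1", "gA", "Berlin", (2.0, SIG), (2.0, SIG), (1.0, SIG), (0.1, NS))
        )
        out = consistent_across_strains(res, level=0.10)
        assert list(out["gene_id"]) == ["gA"]
        assert out.iloc[0]["shared_pairs"] == [("female", F_ACT)]

    def test_single_strain_regulation_excluded(self):
        res = self._two_strain_results(
            region_rows("r1", "gA", "Berlin", (0.1, NS), (2.0, SIG), (1.0, SIG), (0.1, NS))
        )
        assert consistent_across_strains(res, level=0.10).empty

    def test_differing_modes_excluded(self):
        res = self._two_strain_results(
            region_rows("r1", "gA", "Berlin", (2.0, SIG), (2.0, SIG), (0.1, NS), (-1.0, SIG))
        )
        assert consistent_across_strains(res, level=0.10).empty
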