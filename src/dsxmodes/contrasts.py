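"""Per-region fixed-effects contrasts on ln(RPKM), with pooled-FDR adjustment.

The model is a per-region one-way fixed-effects layout with one cell per
(strain x genotype) combination present in the design — seven cells in the
full head design: Canton-S female/male, Berlin female/male, *dsx^D* pseudo
male, and the XX and XY *dsx*-null genotypes. All libraries were produced in
one experiment, so the residual variance is pooled across every cell and the
error degrees of freedom are ``n_samples - n_cells``.

Four contrasts are computed per wild-type strain, each a difference of two
cell means: wild-type female vs male (positive = female-biased), wild-type
female vs *dsx^D* pseudo male, and each wild-type sex vs its same-chromosome
*dsx* null. The mutant cells exist once and are shared between the two
strain contexts. P-values are two-sided t tests on the pooled variance;
Benjamini–Hochberg q-values are computed over ALL contrasts and ALL regions
together, and significance is read off at strict cut-offs (q < level).

``ContrastModel`` / ``ContrastResults`` follow the statsmodels convention:
build the model from data, ``fit()`` returns a results object carrying
estimates, standard errors, p, q and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, SampleMeta, check_meta

CONTRAST_NAMES = ("WTF_vs_WTM", "WTF_vs_DSXD", "WTF_vs_NULLXX", "WTM_vs_NULLXY")
DEFAULT_FDR_LEVELS = (0.05, 0.10, 0.20)

#: (group_A cell template, group_B cell template); {wt} is the strain context.
_CONTRAST_CELLS = {
    "WTF_vs_WTM": ("{wt}:WT_F", "{wt}:WT_M"),
    "WTF_vs_DSXD": ("{wt}:WT_F", "DSXD_PM"),
    "WTF_vs_NULLXX": ("{wt}:WT_F", "NULL_XX"),
    "WTM_vs_NULLXY": ("{wt}:WT_M", "NULL_XY"),
}


@dataclass(frozen=True)
class ContrastSpec:
    """One named cell-mean difference in one wild-type strain context.

    ``estimate = mean(group_A) - mean(group_B)``; group_A is always the
    wild-type side, so a positive WTF_vs_WTM estimate means female-biased.
    """

    name: str
    strain_context: str

    def __post_init__(self) -> None:
        if self.name not in CONTRAST_NAMES:
            raise ValueError(f"unknown contrast {self.name!r}")
        if self.strain_context not in ("CantonS", "Berlin"):
            raise ValueError(f"strain_context must be a wild-type strain, got {self.strain_context!r}")

    @property
    def cells(self) -> tuple[str, str]:
        a, b = _CONTRAST_CELLS[self.name]
        return a.format(wt=self.strain_context), b.format(wt=self.strain_context)

    @property
    def label(self) -> str:
        return f"{self.strain_context}:{self.name}"


def default_contrasts(strains: Sequence[str] = ("CantonS", "Berlin")) -> list[ContrastSpec]:
    """The four contrasts for each wild-type strain (eight in the full design)."""
    return [ContrastSpec(n, s) for s in strains for n in CONTRAST_NAMES]


class ContrastModel:
    """Per-region one-way group-means model over the design cells.

    Parameters
    ----------
    expr
        ln(RPKM) matrix with detection mask; only detected regions are fit.
    region_genes
        Optional mapping region_id -> gene_id, attached to the results.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        region_genes: Mapping[str, str] | None = None,
    ) -> None:
        check_meta(expr.meta)
        self.expr = expr
        self.region_genes = dict(region_genes) if region_genes else {}
        self.cells = pd.Series(
            [m.cell for m in expr.meta], index=[m.sample_id for m in expr.meta]
        )

    def fit(
        self,
        specs: Iterable[ContrastSpec] | None = None,
        adjust: bool = True,
        fdr_levels: Sequence[float] = DEFAULT_FDR_LEVELS,
    ) -> "ContrastResults":
        specs = list(specs) if specs is not None else default_contrasts(
            sorted({m.strain_context for m in self.expr.meta if m.strain_context != "shared_mutant"})
        )
        y = self.expr.detected
        if y.empty:
            raise ValueError("no regions detected; nothing to fit")
        cells = self.cells.reindex(y.columns)
        if cells.isna().any():
            raise ValueError("expression columns without sample metadata")
        cell_names = sorted(cells.unique())
        missing = sorted(
            {c for s in specs for c in s.cells} - set(cell_names)
        )
        if missing:
            raise ValueError(f"contrasts name absent design cells: {missing}")

        n = np.asarray(y, dtype=float)
        groups = {c: np.flatnonzero(cells.to_numpy() == c) for c in cell_names}
        n_samples = n.shape[1]
        df_resid = n_samples - len(cell_names)
        if df_resid <= 0:
            raise ValueError(
                f"zero residual degrees of freedom ({n_samples} samples, "
                f"{len(cell_names)} cells)"
            )
        means = {c: n[:, idx].mean(axis=1) for c, idx in groups.items()}
        sse = np.zeros(n.shape[0])
        for c, idx in groups.items():
            sse += ((n[:, idx] - means[c][:, None]) ** 2).sum(axis=1)
        s2 = sse / df_resid

        frames = []
        for spec in specs:
            a, b = spec.cells
            est = means[a] - means[b]
            se = np.sqrt(s2 * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(est == 0.0, 0.0, est / se)
            p = 2.0 * stats.t.sf(np.abs(t), df_resid)
            p = np.where(np.isinf(t), 0.0, p)
            frames.append(
                pd.DataFrame(
                    {
                        "region_id": y.index,
                        "gene_id": [self.region_genes.get(r, r) for r in y.index],
                        "contrast": spec.name,
                        "strain_context": spec.strain_context,
                        "estimate": est,
                        "se": se,
                        "t": t,
                        "df": df_resid,
                        "p_value": p,
                    }
                )
            )
        table = pd.concat(frames, ignore_index=True)
        table["direction"] = np.sign(table["estimate"]).astype(int)
        res = ContrastResults(table, fdr_levels=tuple(fdr_levels))
        return fdr_adjust(res) if adjust else res


@dataclass
class ContrastResults:
    """Long-format contrast results; one row per (region, contrast, strain).

    ``q_value`` is present after :func:`fdr_adjust` (the default ``fit()``
    path applies it, pooling every contrast and region into one adjustment).
    """

    table: pd.DataFrame
    fdr_levels: tuple[float, ...] = DEFAULT_FDR_LEVELS

    @property
    def adjusted(self) -> bool:
        return "q_value" in self.table.columns

    def select(self, contrast: str, strain_context: str) -> pd.DataFrame:
        t = self.table
        out = t[(t["contrast"] == contrast) & (t["strain_context"] == strain_context)]
        return out.set_index("region_id")

    def summary(self) -> str:
        lines = ["Per-region group-means contrasts on ln(RPKM)", ""]
        n_regions = self.table["region_id"].nunique()
        lines.append(f"regions tested: {n_regions}; tests pooled for FDR: {len(self.table)}")
        if self.adjusted:
            header = f"{'contrast':<32}" + "".join(f"q<{l:<8}" for l in self.fdr_levels)
            lines += ["", header, "-" * len(header)]
            for (strain, name), grp in self.table.groupby(["strain_context", "contrast"], sort=True):
                counts = "".join(
                    f"{(grp['q_value'] < l).sum():<10}" for l in self.fdr_levels
                )
                lines.append(f"{strain + ':' + name:<32}{counts}")
        return "\n".join(lines)


def fdr_adjust(results: ContrastResults) -> ContrastResults:
    """Benjamini–Hochberg step-up over the pooled set of all tests.

    Input ordering is preserved; q-values satisfy q >= p and q in [0, 1].
    """
    p = results.table["p_value"].to_numpy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values outside [0, 1]")
    table = results.table.copy()
    if len(p):
        table["q_value"] = multipletests(p, method="fdr_bh")[1]
    else:
        table["q_value"] = np.array([], dtype=float)
    for level in results.fdr_levels:
        table[f"sig_{level:g}"] = table["q_value"] < level
    return ContrastResults(table, fdr_levels=results.fdr_levels)


def significance_flags(
    results: ContrastResults, levels: Sequence[float] = DEFAULT_FDR_LEVELS
) -> pd.DataFrame:
    """Strict-inequality significance flags, one boolean column per level."""
    if not results.adjusted:
        raise ValueError("results not FDR-adjusted")
    return pd.DataFrame(
        {f"sig_{l:g}": results.table["q_value"] < l for l in levels},
        index=results.table.index,
    )


def fit_and_contrast(
    expr: ExpressionMatrix,
    meta: Iterable[SampleMeta] | None = None,
    specs: Iterable[ContrastSpec] | None = None,
    region_genes: Mapping[str, str] | None = None,
) -> ContrastResults:
    """Functional wrapper: build the model, fit, and BH-adjust in one call.

    ``meta`` is accepted for symmetry but the expression matrix already
    carries its metadata; if given, it must match.
    """
    if meta is not None and tuple(meta) != tuple(expr.meta):
        raise ValueError("meta does not match expression matrix metadata")
    return ContrastModel(expr, region_genes=region_genes).fit(specs=specs)
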