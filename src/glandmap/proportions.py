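"""Per-patient cell-type proportions and group tests with BH correction.

Cell annotations are cross-tabulated per patient and row-normalized to
proportions; each cell type is then compared between two clinical groups
with a two-sided two-sample t-test (Welch by default) and the p-values are
Benjamini-Hochberg adjusted across all tested types, flagging q < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["proportion_table", "ProportionTest", "ProportionTestResults"]


def proportion_table(
    cells: pd.DataFrame, patient_col: str = "patient", type_col: str = "cell_type"
) -> pd.DataFrame:
    """Patient x cell-type proportion table (rows sum to 1).

    Types absent in a patient get 0.  Cells with missing patient or type are
    dropped with a warning.
    """
    sub = cells[[patient_col, type_col]]
    bad = sub.isna().any(axis=1)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} cell(s) with missing patient/type dropped")
        sub = sub[~bad]
    counts = pd.crosstab(sub[patient_col], sub[type_col])
    return counts.div(counts.sum(axis=1), axis=0)


@dataclass
class ProportionTestResults:
    """Per-type group means, fold change, t/p/q and significance flags."""

    table: pd.DataFrame  # index: cell type
    group_pair: tuple[str, str]
    alpha: float = 0.05
    welch: bool = True

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def summary(self) -> str:
        g1, g2 = self.group_pair
        lines = [
            "Cell-type proportion comparison",
            f"  groups: {g1!r} (n={self.table.attrs.get('n1', '?')}) vs "
            f"{g2!r} (n={self.table.attrs.get('n2', '?')})",
            f"  test: {'Welch' if self.welch else 'pooled-variance'} two-sided t, "
            f"BH-adjusted, q < {self.alpha:g}",
            f"  significant types: {[str(t) for t in self.significant] or 'none'}",
        ]
        show = self.table.sort_values("q_value").head(10)
        for t, r in show.iterrows():
            lines.append(
                f"    {t}: mean_{g1}={r['mean_1']:.4f} mean_{g2}={r['mean_2']:.4f} "
                f"fc={r['fold_change']:.3g} t={r['t_stat']:+.3f} "
                f"p={r['p_value']:.4g} q={r['q_value']:.4g}"
            )
        return "\n".join(lines)


class ProportionTest:
    """Two-group comparison of per-patient cell-type proportions.

    Parameters
    ----------
    table : patient x type proportion table (rows sum to 1 within 1e-9).
    groups : patient -> group label mapping (Series indexed like the table).
    group_pair : the two labels to compare; fold change is mean(g1)/mean(g2).
    welch : use the unequal-variance t-test (default); False for pooled.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        groups: pd.Series,
        group_pair: tuple[str, str],
        welch: bool = True,
    ):
        sums = table.sum(axis=1).to_numpy()
        if len(table) and np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("each patient row must sum to 1")
        self.table = table
        self.groups = pd.Series(groups).reindex(table.index)
        self.group_pair = tuple(group_pair)
        self.welch = welch
        for g in self.group_pair:
            if (self.groups == g).sum() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 patients")

    def fit(self, alpha: float = 0.05) -> ProportionTestResults:
        g1, g2 = self.group_pair
        A = self.table[self.groups == g1]
        B = self.table[self.groups == g2]
        rows = []
        for t in self.table.columns:
            a, b = A[t].to_numpy(), B[t].to_numpy()
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                warnings.warn(f"type {t!r}: zero variance in both groups, p set to 1")
                tstat, p = 0.0, 1.0
            else:
                tstat, p = stats.ttest_ind(a, b, equal_var=not self.welch)
            m1, m2 = a.mean(), b.mean()
            fc = m1 / m2 if m2 > 0 else np.inf if m1 > 0 else np.nan
            rows.append(
                {"cell_type": t, "mean_1": m1, "mean_2": m2, "fold_change": fc,
                 "t_stat": float(tstat), "p_value": float(p)}
            )
        res = pd.DataFrame(rows).set_index("cell_type")
        _, q, _, _ = multipletests(res["p_value"], method="fdr_bh")
        res["q_value"] = q
        res["significant"] = res["q_value"] < alpha
        res.attrs["n1"], res.attrs["n2"] = len(A), len(B)
        return ProportionTestResults(
            table=res, group_pair=self.group_pair, alpha=alpha, welch=self.welch
        )
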