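"""Cohort x subtype composition tables and group-comparison statistics.

The central artifact is the cohort composition cross-tab: absolute cell
counts per subtype and cohort with percent-of-cohort-column values rounded
half-away-from-zero to two decimals, in the fixed lineage-grouped subtype
order.  Per-subject subtype fractions feed one-way ANOVA with Tukey HSD
(cell-frequency comparisons) and Kruskal-Wallis tests (functional assay
cohort medians).  The packaged reference cross-tab of the published sepsis
cohorts ships as ``data/table2_counts.csv``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import LINEAGE_OF, TABLE2_SUBTYPES

__all__ = [
    "CompositionTable",
    "crosstab",
    "subject_proportions",
    "anova_tukey",
    "kruskal_wallis",
    "division_index",
    "load_reference_crosstab",
    "SUBTYPE_ORDER",
]

SUBTYPE_ORDER = [s for subs in TABLE2_SUBTYPES.values() for s in subs]
COHORT_ORDER = ["HS", "D4", "RAP", "CCI"]


def _round2(x: float) -> float:
    """Round half away from zero at 2 decimals (matches the printed table)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CompositionTable:
    counts: pd.DataFrame  # subtype x cohort absolute counts
    percents: pd.DataFrame  # subtype x cohort percent of cohort column, 2 dp
    column_totals: pd.Series
    grand_total: int

    def to_csv(self, path) -> None:
        out = self.counts.astype(str) + " (" + self.percents.map(lambda v: f"{v:.2f}") + ")"
        out.loc["Total"] = [
            f"{int(self.column_totals[c])} (100.00)" for c in self.counts.columns
        ]
        out.to_csv(path)


def crosstab(meta: pd.DataFrame, label_col: str = "consensus",
             cohort_col: str = "cohort", subtype_order=None,
             cohort_order=None) -> CompositionTable:
    """Cohort x subtype cross-tab with exact counts and 2-dp percents.

    Percents are ``100 * count / column_total`` rounded half away from zero;
    an empty cohort column makes percents undefined and raises.
    """
    counts = pd.crosstab(meta[label_col], meta[cohort_col], dropna=False)
    sub_order = [s for s in (subtype_order or SUBTYPE_ORDER) if s in counts.index]
    sub_order += [s for s in counts.index if s not in sub_order]
    coh_order = [c for c in (cohort_order or COHORT_ORDER) if c in counts.columns]
    coh_order += [c for c in counts.columns if c not in coh_order]
    counts = counts.reindex(index=sub_order, columns=coh_order, fill_value=0)
    col_tot = counts.sum(axis=0)
    if (col_tot == 0).any():
        empty = list(col_tot.index[col_tot == 0])
        raise ValueError(f"empty cohort column(s): {empty}; percents undefined")
    percents = counts.div(col_tot, axis=1) * 100.0
    percents = percents.map(_round2)
    return CompositionTable(
        counts=counts,
        percents=percents,
        column_totals=col_tot,
        grand_total=int(counts.to_numpy().sum()),
    )


def load_reference_crosstab() -> pd.DataFrame:
    """The packaged published cohort composition counts (lineage, subtype,
    and absolute counts per cohort column)."""
    with (resources.files("lymphtraj") / "data" / "table2_counts.csv").open() as fh:
        return pd.read_csv(fh)


def reference_crosstab_as_meta() -> pd.DataFrame:
    """Expand the packaged reference counts to one row per cell (for feeding
    the same code paths as real annotations)."""
    ref = load_reference_crosstab()
    rows = []
    for _, r in ref.iterrows():
        for cohort in COHORT_ORDER:
            rows.extend([(r["subtype"], cohort)] * int(r[cohort]))
    return pd.DataFrame(rows, columns=["consensus", "cohort"])


def subject_proportions(meta: pd.DataFrame, label_col: str = "consensus",
                        subject_col: str = "donor") -> pd.DataFrame:
    """Per-subject fraction of each subtype among that subject's cells.

    Rows are subjects (with their cohort); columns subtypes; each row sums
    to 1.  Subjects with zero cells are excluded with a warning.
    """
    counts = pd.crosstab(meta[subject_col], meta[label_col])
    row_tot = counts.sum(axis=1)
    empty = row_tot == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} subjects with zero cells excluded")
        counts = counts.loc[~empty]
        row_tot = row_tot[~empty]
    frac = counts.div(row_tot, axis=0)
    cohorts = meta.groupby(subject_col)["cohort"].first() if "cohort" in meta else None
    if cohorts is not None:
        frac.insert(0, "cohort", cohorts.reindex(frac.index))
    return frac


def anova_tukey(values, groups) -> dict:
    """One-way ANOVA plus all-pairs Tukey HSD on one subtype's fractions.

    Returns ``{"F", "p", "tukey": {(a, b): p_adj}, "flag"}``; degenerate
    data (zero residual variance) reports NA with a flag.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = [g for g in pd.unique(groups)]
    samples = [values[groups == g] for g in uniq]
    if len(uniq) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >=2 groups with >=2 subjects each")
    resid_var = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if resid_var == 0:
        if all(abs(s.mean() - samples[0].mean()) < 1e-300 for s in samples):
            return {"F": 0.0, "p": 1.0, "tukey": {}, "flag": "degenerate"}
        return {"F": np.nan, "p": np.nan, "tukey": {}, "flag": "zero residual variance"}
    F, p = stats.f_oneway(*samples)
    tk = stats.tukey_hsd(*samples)
    tukey = {}
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            tukey[(uniq[i], uniq[j])] = float(tk.pvalue[i, j])
    return {"F": float(F), "p": float(p), "tukey": tukey, "flag": None}


def composition_anova(fractions: pd.DataFrame) -> pd.DataFrame:
    """anova_tukey over every subtype column of a subject_proportions frame."""
    rows = []
    groups = fractions["cohort"].to_numpy()
    for subtype in [c for c in fractions.columns if c != "cohort"]:
        res = anova_tukey(fractions[subtype].to_numpy(), groups)
        row = {"subtype": subtype, "F": res["F"], "p": res["p"], "flag": res["flag"]}
        for pair, padj in res["tukey"].items():
            row[f"tukey_{pair[0]}_vs_{pair[1]}"] = padj
        rows.append(row)
    return pd.DataFrame(rows)


def kruskal_wallis(values, groups) -> dict:
    """Kruskal-Wallis H with tie correction, chi-square reference (g-1 df)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    samples = [values[groups == g] for g in uniq]
    if len(uniq) < 2 or len(values) < 2:
        raise ValueError("need >=2 groups and >=2 observations")
    if np.ptp(values) == 0:
        return {"H": np.nan, "p": np.nan, "flag": "all values identical"}
    H, p = stats.kruskal(*samples)
    return {"H": float(H), "p": float(p), "flag": None}


def division_index(total_divisions: float, starting_cells: float) -> float:
    """Total divisions divided by the number of cells at culture start."""
    if starting_cells <= 0:
        raise ValueError("starting_cells must be > 0")
    if total_divisions < 0:
        raise ValueError("total_divisions must be >= 0")
    return float(total_divisions) / float(starting_cells)
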