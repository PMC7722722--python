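"""Cell-type / cluster composition tables and paired tumor-vs-adjacent tests.

Fractions are computed per (patient, tissue) sample against a declared
denominator: all cells of the sample, the CD45+ subset, or the cell's
parent lineage.  The paired test contrasts each unit's per-patient tumor
and adjacent fractions (two-tailed paired t by default, signed-rank
selectable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ImmscapeError

DENOMINATORS = ("all_cells", "cd45_cells", "parent_lineage")

__all__ = ["FractionTable", "fraction_table", "paired_tissue_test"]


@dataclass
class FractionTable:
    """Tidy per-sample unit fractions with the denominator recorded."""

    table: pd.DataFrame  # columns: patient_id, tissue, unit, n, denominator_n, fraction
    unit_column: str
    denominator: str


def fraction_table(
    annotations: pd.DataFrame,
    unit_column: str = "cell_type",
    denominator: str = "all_cells",
) -> FractionTable:
    """Per-sample fractions of each unit (cell type or cluster).

    ``annotations`` is the per-cell metadata frame (one row per cell) with
    ``patient_id`` and ``tissue`` columns.  For ``cd45_cells`` a boolean
    ``is_cd45`` column restricts the denominator; for ``parent_lineage`` a
    ``lineage`` column defines each cell's parent compartment and fractions
    are taken within (patient, tissue, lineage).
    """
    if denominator not in DENOMINATORS:
        raise ImmscapeError(f"unknown denominator '{denominator}'; expected {DENOMINATORS}")
    if unit_column not in annotations.columns:
        raise ImmscapeError(f"annotations lack unit column '{unit_column}'")
    df = annotations.copy()
    group_cols = ["patient_id", "tissue"]
    if denominator == "cd45_cells":
        if "is_cd45" not in df.columns:
            raise ImmscapeError("denominator 'cd45_cells' needs an 'is_cd45' column")
        df = df[df["is_cd45"].astype(bool)]
    elif denominator == "parent_lineage":
        if "lineage" not in df.columns:
            raise ImmscapeError("denominator 'parent_lineage' needs a 'lineage' column")
        group_cols = ["patient_id", "tissue", "lineage"]
    counts = (
        df.groupby(group_cols + [unit_column], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = df.groupby(group_cols, observed=True).size().rename("denominator_n")
    counts = counts.join(totals, on=group_cols)
    counts["fraction"] = counts["n"] / counts["denominator_n"]
    counts = counts.rename(columns={unit_column: "unit"})
    return FractionTable(table=counts, unit_column=unit_column, denominator=denominator)


def paired_tissue_test(
    ft: FractionTable,
    unit: str,
    method: str = "t",
) -> tuple[float, float, str]:
    """Two-tailed paired test of a unit's tumor vs adjacent fractions.

    Patients missing either tissue are dropped with a warning; fewer than
    two complete pairs is an error.  ``method`` is ``"t"`` (paired Student's
    t) or ``"wilcoxon"`` (signed-rank).  Returns ``(statistic, p_value,
    direction)`` with direction in {tumor-enriched, adjacent-enriched,
    none}.  A sample where the unit is absent contributes fraction 0.
    """
    df = ft.table[ft.table["unit"] == unit]
    if not len(df):
        raise ImmscapeError(f"unit '{unit}' not present in fraction table")
    wide = df.pivot_table(
        index="patient_id", columns="tissue", values="fraction", aggfunc="mean"
    )
    for tissue in ("tumor", "adjacent"):
        if tissue not in wide.columns:
            wide[tissue] = np.nan
    # a patient with the sample but no cells of this unit has fraction 0
    sampled = ft.table.groupby(["patient_id", "tissue"], observed=True).size().unstack()
    for tissue in ("tumor", "adjacent"):
        if tissue in sampled.columns:
            present = sampled[tissue].dropna().index
            wide.loc[wide.index.isin(present) & wide[tissue].isna(), tissue] = 0.0
    incomplete = wide[["tumor", "adjacent"]].isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"{int(incomplete.sum())} unpaired patient(s) dropped: "
            f"{wide.index[incomplete].tolist()}"
        )
        wide = wide[~incomplete]
    if len(wide) < 2:
        raise ImmscapeError("insufficient pairs: need >= 2 patients with both tissues")
    diff = (wide["tumor"] - wide["adjacent"]).to_numpy()
    if np.allclose(diff, 0):
        stat, p = 0.0, 1.0
    elif method == "t":
        res = sps.ttest_rel(wide["tumor"], wide["adjacent"])
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "wilcoxon":
        res = sps.wilcoxon(diff, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ImmscapeError(f"unknown method '{method}'")
    mean_diff = diff.mean()
    if mean_diff > 0:
        direction = "tumor-enriched"
    elif mean_diff < 0:
        direction = "adjacent-enriched"
    else:
        direction = "none"
    return stat, p, direction
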