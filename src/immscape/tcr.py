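"""Paired alpha/beta TCR clonotype assignment and clonality analytics.

A cell's dominant chain per locus is its highest-UMI productive contig.
Cells with an in-frame dominant TRA *and* TRB get a clonotype key; two cells
belong to the same clonotype only if both the alpha and the beta sequence
match (CDR3 nucleotide identity by default), scoped within a patient.
Downstream analytics: chain-recovery accounting, clone-size spectrum,
clonal-expansion bins, and cross-cluster clonotype sharing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import ImmscapeError

REQUIRED_CONTIG_COLUMNS = (
    "barcode", "chain", "cdr3_nt", "productive", "full_length", "umis",
)

__all__ = [
    "ClonotypeTable",
    "SharingMatrix",
    "ChainRecovery",
    "parse_contigs",
    "assign_clonotypes",
    "chain_recovery_stats",
    "clonal_expansion_profile",
    "shared_clonotype_matrix",
    "clone_size_spectrum",
]


def _parse_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    return col.astype(str).str.strip().str.lower().isin(("true", "t", "1"))


def parse_contigs(
    source: Union[str, Path, pd.DataFrame],
) -> tuple[pd.DataFrame, dict]:
    """Parse a filtered-contig CSV (Cell Ranger VDJ dialect).

    Keeps rows that are productive, full-length, and on a TRA/TRB chain;
    everything else is dropped and tallied.  Returns ``(contigs, tallies)``.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    missing = [c for c in REQUIRED_CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise ImmscapeError(f"contig table lacks required column(s): {missing}")
    df["productive"] = _parse_bool(df["productive"])
    df["full_length"] = _parse_bool(df["full_length"])
    df["umis"] = pd.to_numeric(df["umis"])
    n_in = len(df)
    bad_chain = ~df["chain"].isin(("TRA", "TRB"))
    not_prod = ~df["productive"] & ~bad_chain
    not_full = ~df["full_length"] & df["productive"] & ~bad_chain
    keep = df["productive"] & df["full_length"] & ~bad_chain
    tallies = {
        "n_in": n_in,
        "n_kept": int(keep.sum()),
        "n_dropped_chain": int(bad_chain.sum()),
        "n_dropped_not_productive": int(not_prod.sum()),
        "n_dropped_not_full_length": int(not_full.sum()),
    }
    return df[keep].reset_index(drop=True), tallies


@dataclass
class ClonotypeTable:
    """Cell -> dominant paired clonotype mapping plus per-clonotype roster.

    ``clonotypes`` has one row per clonotype: id, patient_id, cdr3 of both
    chains, and size (member-cell count).  ``cell_assignments`` maps each
    paired cell to its clonotype id; cells missing either dominant chain are
    absent.  ``diagnostics`` records cells that carried extra productive
    contigs beyond the dominant one per locus.
    """

    cell_assignments: pd.Series
    clonotypes: pd.DataFrame
    key_level: str = "nt"
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.clonotypes):
            if (self.clonotypes["size"] < 1).any():
                raise ImmscapeError("clonotype with size < 1")
            per_patient = self.clonotypes.groupby("clonotype_id")["patient_id"].nunique()
            if (per_patient > 1).any():
                raise ImmscapeError("clonotype key spans patients")

    @property
    def n_assigned_cells(self) -> int:
        return len(self.cell_assignments)

    def sizes(self) -> pd.Series:
        return self.clonotypes.set_index("clonotype_id")["size"]

    def size_of_cell(self) -> pd.Series:
        """Clone size of each assigned cell."""
        return self.cell_assignments.map(self.sizes())


def _dominant_per_chain(contigs: pd.DataFrame) -> pd.DataFrame:
    """One contig per (barcode, chain): highest UMI, ties to the smallest cdr3_nt."""
    ordered = contigs.sort_values(
        ["barcode", "chain", "umis", "cdr3_nt"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(["barcode", "chain"], keep="first")


def assign_clonotypes(
    contigs: pd.DataFrame,
    cell_universe: Sequence[str],
    patient_of: Optional[pd.Series] = None,
    key_level: str = "nt",
    include_vj: bool = False,
    on_unknown_barcode: str = "warn",
) -> ClonotypeTable:
    """Assign paired alpha/beta clonotypes to cells.

    Parameters
    ----------
    contigs
        Parsed contig table (see :func:`parse_contigs`); must carry a
        ``patient_id`` column unless ``patient_of`` maps barcodes to patients.
    cell_universe
        Annotated T-cell barcodes; contigs outside it are dropped with a
        warning (``on_unknown_barcode="error"`` raises instead).
    key_level
        ``"nt"`` (default) keys clonotypes on CDR3 nucleotide sequences,
        ``"aa"`` on amino-acid sequences; ``include_vj`` adds V/J gene
        segments to the key.
    """
    if key_level not in ("nt", "aa"):
        raise ImmscapeError(f"unknown key_level '{key_level}'")
    universe = pd.Index(cell_universe)
    df = contigs.copy()
    if patient_of is not None:
        df["patient_id"] = df["barcode"].map(patient_of)
    if "patient_id" not in df.columns or df["patient_id"].isna().any():
        raise ImmscapeError("contigs lack patient_id; supply patient_of")
    unknown = ~df["barcode"].isin(universe)
    if unknown.any():
        msg = f"{int(unknown.sum())} contig(s) with barcode outside the cell universe"
        if on_unknown_barcode == "error":
            raise ImmscapeError(msg)
        warnings.warn(msg + "; dropped")
        df = df[~unknown]
    seq_col = "cdr3_nt" if key_level == "nt" else "cdr3"
    if seq_col not in df.columns:
        raise ImmscapeError(f"contigs lack '{seq_col}' column for key_level={key_level}")
    dom = _dominant_per_chain(df)
    extras = df.merge(
        dom[["barcode", "chain", "cdr3_nt"]],
        on=["barcode", "chain", "cdr3_nt"],
        how="left",
        indicator=True,
    )
    diagnostics = (
        extras[extras["_merge"] == "left_only"]
        .drop(columns="_merge")
        .reset_index(drop=True)
    )
    parts = [dom[dom["chain"] == ch].set_index("barcode") for ch in ("TRA", "TRB")]
    paired = parts[0].join(parts[1], how="inner", lsuffix="_a", rsuffix="_b")
    if not len(paired):
        return ClonotypeTable(
            cell_assignments=pd.Series(dtype=object),
            clonotypes=pd.DataFrame(
                columns=["clonotype_id", "patient_id", "alpha", "beta", "size"]
            ),
            key_level=key_level,
            diagnostics=diagnostics,
        )
    alpha = paired[f"{seq_col}_a"].astype(str)
    beta = paired[f"{seq_col}_b"].astype(str)
    if include_vj:
        alpha = alpha + "/" + paired["v_gene_a"] + "/" + paired["j_gene_a"]
        beta = beta + "/" + paired["v_gene_b"] + "/" + paired["j_gene_b"]
    key = paired["patient_id_a"].astype(str) + ":" + alpha + "|" + beta
    groups = pd.DataFrame(
        {"key": key, "patient_id": paired["patient_id_a"], "alpha": alpha, "beta": beta}
    )
    table = (
        groups.groupby(["key", "patient_id", "alpha", "beta"], sort=True)
        .size()
        .reset_index(name="size")
        .rename(columns={"key": "clonotype_id"})
    )
    return ClonotypeTable(
        cell_assignments=key.rename("clonotype_id"),
        clonotypes=table,
        key_level=key_level,
        diagnostics=diagnostics,
    )


@dataclass
class ChainRecovery:
    """Fractions of universe cells with a productive dominant TRA / TRB / both."""

    n_cells: int
    n_alpha: int
    n_beta: int
    n_paired: int

    @property
    def frac_alpha(self) -> float:
        return self.n_alpha / self.n_cells

    @property
    def frac_beta(self) -> float:
        return self.n_beta / self.n_cells

    @property
    def frac_paired(self) -> float:
        return self.n_paired / self.n_cells

    def percentages(self) -> tuple[float, float, float]:
        """(alpha, beta, paired) recovery as percentages rounded to 2 decimals."""
        return (
            round(100 * self.frac_alpha, 2),
            round(100 * self.frac_beta, 2),
            round(100 * self.frac_paired, 2),
        )


def chain_recovery_stats(
    contigs: pd.DataFrame, cell_universe: Sequence[str]
) -> ChainRecovery:
    """Per-chain and paired recovery over a T-cell universe."""
    universe = pd.Index(cell_universe)
    if not len(universe):
        raise ImmscapeError("empty cell universe")
    df = contigs[contigs["barcode"].isin(universe)]
    has_alpha = set(df.loc[df["chain"] == "TRA", "barcode"])
    has_beta = set(df.loc[df["chain"] == "TRB", "barcode"])
    return ChainRecovery(
        n_cells=len(universe),
        n_alpha=len(has_alpha),
        n_beta=len(has_beta),
        n_paired=len(has_alpha & has_beta),
    )


def clonal_expansion_profile(
    table: ClonotypeTable, group_labels: pd.Series
) -> pd.DataFrame:
    """Cell fractions per group in clonotype-size bins {1, 2, >=3}.

    A cell is *clonal* when its clonotype is carried by at least two cells;
    ``clonal_fraction`` is the share of assigned cells in a group with clone
    size >= 2.  ``group_labels`` must cover every assigned cell (indexed by
    barcode); groups with no assigned cells raise.
    """
    sizes = table.size_of_cell()
    labels = group_labels.reindex(sizes.index)
    if labels.isna().any():
        raise ImmscapeError("group labels missing for some assigned cells")
    rows = []
    for group, s in sizes.groupby(labels):
        n = len(s)
        if n == 0:
            raise ImmscapeError(f"empty group '{group}'")
        rows.append(
            {
                "group": group,
                "n_cells": n,
                "frac_unique": float((s == 1).sum() / n),
                "frac_double": float((s == 2).sum() / n),
                "frac_expanded": float((s >= 3).sum() / n),
                "clonal_fraction": float((s >= 2).sum() / n),
            }
        )
    return pd.DataFrame(rows).set_index("group")


@dataclass
class SharingMatrix:
    """Shared-clonotype counts and (asymmetric) percentages between clusters.

    ``counts`` is symmetric with the per-cluster clonotype count on the
    diagonal; ``percentages[i, j]`` divides the shared count by cluster i's
    clonotype count (the focal-cluster convention), so it is not symmetric.
    """

    clusters: tuple
    counts: pd.DataFrame
    percentages: pd.DataFrame


def shared_clonotype_matrix(
    table: ClonotypeTable, cluster_labels: pd.Series
) -> SharingMatrix:
    """Clonotype sharing between clusters.

    A clonotype is *present* in a cluster when at least one member cell
    carries that cluster label; counts are presence-set intersections.
    """
    labels = cluster_labels.reindex(table.cell_assignments.index)
    if labels.isna().any():
        raise ImmscapeError("cluster labels missing for some assigned cells")
    presence: dict[str, set] = {}
    for cluster, cells in table.cell_assignments.groupby(labels):
        presence[cluster] = set(cells)
    clusters = tuple(sorted(presence))
    n = len(clusters)
    counts = np.zeros((n, n), dtype=int)
    for i, ci in enumerate(clusters):
        for j, cj in enumerate(clusters):
            counts[i, j] = len(presence[ci] & presence[cj])
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.diag(counts).astype(float)[:, None]
        pct = np.where(denom > 0, 100.0 * counts / denom, 0.0)
    counts_df = pd.DataFrame(counts, index=clusters, columns=clusters)
    pct_df = pd.DataFrame(np.round(pct, 2), index=clusters, columns=clusters)
    return SharingMatrix(clusters=clusters, counts=counts_df, percentages=pct_df)


def clone_size_spectrum(table: ClonotypeTable) -> pd.Series:
    """Histogram of clone sizes: size -> number of clonotypes of that size."""
    if not len(table.clonotypes):
        raise ImmscapeError("empty clonotype table")
    spectrum = table.clonotypes["size"].value_counts().sort_index()
    spectrum.index.name = "clone_size"
    return spectrum.rename("n_clonotypes")
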