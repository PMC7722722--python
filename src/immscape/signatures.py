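"""Gene-signature scoring and correlation-anchored signature derivation.

A signature score for a cell is the mean, over the signature genes present
in the matrix, of the gene's per-gene z-scored ``log2(count + 1)`` value.
Cluster-level scores are means of member-cell scores and can be re-z-scored
across clusters for dot-plot style output.

Signatures can also be derived from the data itself: given an anchor gene
(e.g. FGFBP2 for cytotoxicity, LAG3 for exhaustion, FOXP3 for Treg), the
top-k genes by Pearson correlation with the anchor across a cell subset
form the signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ImmscapeError, NormalizedMatrix, zscore_by_gene

NAIVE_MARKERS = ("CCR7", "TCF7", "LEF1", "SELL")

__all__ = [
    "GeneSignature",
    "SignatureScores",
    "NAIVE_MARKERS",
    "read_gmt",
    "write_gmt",
    "score_signature",
    "naive_score",
    "derive_correlation_signature",
    "proliferation_score",
    "pairwise_gene_correlation",
    "load_cell_cycle_signatures",
]


@dataclass
class GeneSignature:
    """Named ordered gene list with optional derivation provenance."""

    name: str
    genes: tuple
    provenance: str = "published"
    correlations: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        # deduplicate preserving order; scoring must be invariant to dupes
        self.genes = tuple(dict.fromkeys(self.genes))
        if not self.genes:
            raise ImmscapeError(f"signature '{self.name}' has no genes")
        if self.correlations is not None:
            self.correlations = np.asarray(self.correlations, dtype=float)
            if len(self.correlations) != len(self.genes):
                raise ImmscapeError("correlations length does not match genes")
            if np.any(np.diff(self.correlations) > 1e-12):
                raise ImmscapeError("correlations must be sorted non-increasing")


@dataclass
class SignatureScores:
    """Per-cell or per-cluster signature scores."""

    signature: str
    level: str  # "cell" | "cluster"
    scores: pd.Series
    normalization: str = "raw_mean_z"
    missing_genes: tuple = ()


def read_gmt(path) -> list[GeneSignature]:
    """Read GMT (name <tab> description <tab> genes...) signature lists."""
    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ImmscapeError(f"malformed GMT line: {line[:60]!r}")
        sigs.append(GeneSignature(name=parts[0], genes=tuple(g for g in parts[2:] if g)))
    if not sigs:
        raise ImmscapeError("empty GMT file")
    return sigs


def write_gmt(signatures: Sequence[GeneSignature], path, description: str = "") -> None:
    lines = [
        "\t".join([s.name, description or s.provenance, *s.genes]) for s in signatures
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _ensure_z(norm: NormalizedMatrix) -> NormalizedMatrix:
    if norm.scale == "zscore_log2p1":
        return norm
    return zscore_by_gene(norm)


def score_signature(
    norm: NormalizedMatrix,
    sig: GeneSignature,
    cluster_labels: Optional[Sequence] = None,
    level: str = "cell",
    re_zscore: bool = False,
) -> SignatureScores:
    """Score a signature per cell, optionally aggregated per cluster.

    Genes absent from the matrix are dropped with a warning and recorded in
    ``missing_genes``; if none of the signature genes are present an error
    is raised.  With ``re_zscore`` the cluster-level means are z-scored
    across clusters (dot-plot convention).
    """
    z = _ensure_z(norm)
    present = [g for g in sig.genes if g in z.gene_ids]
    missing = tuple(g for g in sig.genes if g not in z.gene_ids)
    if not present:
        raise ImmscapeError(f"no gene of signature '{sig.name}' present in matrix")
    if missing:
        warnings.warn(
            f"signature '{sig.name}': {len(missing)} gene(s) absent and dropped"
        )
    rows = z.gene_ids.get_indexer(present)
    cell_scores = pd.Series(
        np.asarray(z.values)[rows].mean(axis=0), index=z.cell_barcodes, name=sig.name
    )
    if level == "cell":
        return SignatureScores(sig.name, "cell", cell_scores, "raw_mean_z", missing)
    if level != "cluster":
        raise ImmscapeError(f"unknown level '{level}'")
    if cluster_labels is None:
        raise ImmscapeError("cluster_labels required for cluster-level scores")
    labels = pd.Series(np.asarray(cluster_labels), index=z.cell_barcodes)
    cluster_scores = cell_scores.groupby(labels).mean()
    note = "raw_mean_z"
    if re_zscore:
        sd = cluster_scores.std(ddof=0)
        mean = cluster_scores.mean()
        cluster_scores = (
            (cluster_scores - mean) / sd if sd > 0 else cluster_scores * 0.0
        )
        note = "re_zscored_across_clusters"
    return SignatureScores(sig.name, "cluster", cluster_scores, note, missing)


def naive_score(
    norm: NormalizedMatrix,
    cluster_labels: Optional[Sequence] = None,
    level: str = "cluster",
    re_zscore: bool = False,
) -> SignatureScores:
    """Naive T-cell score: mean z-scored expression of CCR7, TCF7, LEF1, SELL."""
    sig = GeneSignature("naive", NAIVE_MARKERS, provenance="fixed_naive")
    return score_signature(norm, sig, cluster_labels, level=level, re_zscore=re_zscore)


def derive_correlation_signature(
    norm: NormalizedMatrix,
    anchor: str,
    k: int = 50,
    subset: Optional[Sequence] = None,
) -> GeneSignature:
    """Top-k genes by Pearson correlation with an anchor gene.

    Correlation is computed on ``log2(count + 1)`` values across the chosen
    cell subset (Pearson is invariant to the per-gene affine rescaling a
    z-score applies, so either scale ranks identically).  The anchor is
    excluded from its own signature; genes constant over the subset are
    ineligible; ties are broken lexicographically by gene symbol.
    """
    if anchor not in norm.gene_ids:
        raise ImmscapeError(f"anchor gene '{anchor}' not in matrix")
    if subset is None:
        cols = np.arange(norm.values.shape[1])
    else:
        subset = np.asarray(subset)
        if subset.dtype == bool:
            cols = np.flatnonzero(subset)
        else:
            cols = norm.cell_barcodes.get_indexer(pd.Index(subset))
            if (cols < 0).any():
                raise ImmscapeError("subset barcode not found in matrix")
    if len(cols) < 3:
        raise ImmscapeError("subset must contain at least 3 cells")
    dense = norm.values[:, cols]
    dense = np.asarray(dense.todense()) if hasattr(dense, "todense") else np.asarray(dense)
    a = dense[norm.gene_ids.get_loc(anchor)]
    if np.std(a) == 0:
        raise ImmscapeError(f"undefined correlation: anchor '{anchor}' constant on subset")
    centered = dense - dense.mean(axis=1, keepdims=True)
    sds = centered.std(axis=1)
    ac = a - a.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = centered @ ac / (len(a) * sds * ac.std())
    eligible = (sds > 0) & (norm.gene_ids != anchor)
    if k > int(eligible.sum()):
        raise ImmscapeError(
            f"k = {k} exceeds the {int(eligible.sum())} eligible genes"
        )
    table = pd.DataFrame({"gene": norm.gene_ids, "r": r})[eligible]
    table = table.sort_values(["r", "gene"], ascending=[False, True], kind="mergesort")
    top = table.head(k)
    return GeneSignature(
        name=f"{anchor}_top{k}",
        genes=tuple(top["gene"]),
        provenance=f"anchor_derived(anchor={anchor}, k={k}, n_cells={len(cols)})",
        correlations=top["r"].to_numpy(),
    )


def proliferation_score(
    norm: NormalizedMatrix,
    g1s: GeneSignature,
    g2m: GeneSignature,
    cluster_labels: Optional[Sequence] = None,
    level: str = "cluster",
    re_zscore: bool = False,
) -> SignatureScores:
    """Proliferation score: per cell, the larger of the G1/S and G2/M scores.

    A cell in either cell-cycle phase is proliferating, hence the max rule.
    """
    z = _ensure_z(norm)
    s1 = score_signature(z, g1s, level="cell").scores
    s2 = score_signature(z, g2m, level="cell").scores
    cell_scores = pd.Series(
        np.maximum(s1.to_numpy(), s2.to_numpy()), index=s1.index, name="proliferation"
    )
    if level == "cell":
        return SignatureScores("proliferation", "cell", cell_scores)
    if cluster_labels is None:
        raise ImmscapeError("cluster_labels required for cluster-level scores")
    labels = pd.Series(np.asarray(cluster_labels), index=cell_scores.index)
    cluster_scores = cell_scores.groupby(labels).mean()
    note = "raw_mean_z"
    if re_zscore:
        sd = cluster_scores.std(ddof=0)
        cluster_scores = (
            (cluster_scores - cluster_scores.mean()) / sd
            if sd > 0
            else cluster_scores * 0.0
        )
        note = "re_zscored_across_clusters"
    return SignatureScores("proliferation", "cluster", cluster_scores, note)


def pairwise_gene_correlation(
    norm: NormalizedMatrix,
    gene_a: str,
    gene_b: str,
    subset: Optional[Sequence] = None,
) -> tuple[float, float]:
    """Pearson r between two genes on log2p1 values, with a two-sided p.

    The p-value is the standard t-distribution test with n - 2 degrees of
    freedom (as computed by :func:`scipy.stats.pearsonr`).
    """
    for g in (gene_a, gene_b):
        if g not in norm.gene_ids:
            raise ImmscapeError(f"gene '{g}' not in matrix")
    if subset is None:
        mask = np.ones(norm.values.shape[1], dtype=bool)
    else:
        subset = np.asarray(subset)
        if subset.dtype == bool:
            mask = subset
        else:
            mask = np.zeros(norm.values.shape[1], dtype=bool)
            idx = norm.cell_barcodes.get_indexer(subset)
            if (idx < 0).any():
                raise ImmscapeError("subset barcode not found in matrix")
            mask[idx] = True
    if mask.sum() < 3:
        raise ImmscapeError("subset must contain at least 3 cells")
    x = norm.gene_values(gene_a)[mask]
    y = norm.gene_values(gene_b)[mask]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ImmscapeError("constant gene on subset: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def load_cell_cycle_signatures() -> tuple[GeneSignature, GeneSignature]:
    """The bundled G1/S and G2/M cell-cycle phase gene lists (editable GMT)."""
    path = Path(__file__).parent / "data" / "cell_cycle.gmt"
    sigs = {s.name: s for s in read_gmt(path)}
    return sigs["G1S"], sigs["G2M"]
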