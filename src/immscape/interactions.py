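"""Per-sample ligand-receptor interaction scoring and cohort-level calls.

The interaction score of a ligand-receptor pair between a sender and a
receiver cell type, within one sample, is the product of the ligand's
average ``log2(count + 1)`` expression over the sender-type cells and the
receptor's average over the receiver-type cells.  An interaction is called
when the per-patient scores within a tissue are significantly greater than
zero by an exact one-sided Wilcoxon signed-rank test (p < alpha, default
0.05).  No multiple-testing correction is applied to the call itself; a
Benjamini-Hochberg column is emitted alongside for users who want one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import ImmscapeError, NormalizedMatrix
from .stats import wilcoxon_greater_than_zero

__all__ = [
    "LigandReceptorPair",
    "InteractionResult",
    "load_lr_pairs",
    "lr_score",
    "call_interactions",
    "interaction_screen",
]


@dataclass(frozen=True)
class LigandReceptorPair:
    ligand: str
    receptor: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ImmscapeError("ligand and receptor must be nonempty")

    @property
    def self_pair(self) -> bool:
        return self.ligand == self.receptor


@dataclass
class InteractionResult:
    pair: LigandReceptorPair
    sender_type: str
    receiver_type: str
    tissue: str
    per_sample_scores: pd.Series  # indexed by patient_id; absent samples omitted
    p_value: float
    significant: bool
    mean_score: float
    note: str = ""


def load_lr_pairs(
    source: Union[str, Path, pd.DataFrame],
) -> list[LigandReceptorPair]:
    """Load and deduplicate a two-column (ligand, receptor) pair catalogue."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("ligand", "receptor"):
        if needed not in cols:
            raise ImmscapeError(f"pair table lacks a '{needed}' column")
    if not len(df):
        raise ImmscapeError("empty ligand-receptor table")
    source_col = cols.get("source_tag") or cols.get("source")
    pairs: list[LigandReceptorPair] = []
    seen = set()
    for _, row in df.iterrows():
        lig = str(row[cols["ligand"]]).strip()
        rec = str(row[cols["receptor"]]).strip()
        if not lig or lig == "nan" or not rec or rec == "nan":
            raise ImmscapeError("blank ligand or receptor in pair table")
        if (lig, rec) in seen:
            continue
        seen.add((lig, rec))
        tag = str(row[source_col]) if source_col else ""
        pairs.append(LigandReceptorPair(lig, rec, tag))
    return pairs


def _sample_type_means(
    norm: NormalizedMatrix, genes: Sequence[str]
) -> pd.DataFrame:
    """Mean expression of each gene per (patient, tissue, cell_type).

    One pass over the matrix; the screen reuses the result for every pair.
    """
    if norm.cell_meta is None:
        raise ImmscapeError("annotated matrix required (patient_id / tissue / cell_type)")
    rows = norm.gene_ids.get_indexer(pd.Index(genes))
    if (rows < 0).any():
        missing = [g for g, r in zip(genes, rows) if r < 0]
        raise ImmscapeError(f"gene(s) not in matrix: {missing[:5]}")
    vals = norm.values[rows]
    vals = np.asarray(vals.todense()) if hasattr(vals, "todense") else np.asarray(vals)
    frame = pd.DataFrame(vals.T, index=norm.cell_barcodes, columns=list(genes))
    meta = norm.cell_meta.loc[norm.cell_barcodes]
    frame["patient_id"] = meta["patient_id"].to_numpy()
    frame["tissue"] = meta["tissue"].to_numpy()
    frame["cell_type"] = meta["cell_type"].to_numpy()
    return frame.groupby(["patient_id", "tissue", "cell_type"], observed=True).mean()


def lr_score(
    norm: NormalizedMatrix,
    pair: LigandReceptorPair,
    sender_type: str,
    receiver_type: str,
    patient_id: str,
    tissue: str,
) -> Optional[float]:
    """Interaction score for one sample; ``None`` when a cell type is absent.

    score = mean(ligand | sender cells) * mean(receptor | receiver cells),
    means taken over all cells of the type in the sample on the log2p1
    scale.  A missing cell type makes the score undefined (recorded as
    absent, never as 0).
    """
    if norm.scale != "log2p1":
        raise ImmscapeError("lr_score expects log2p1-scale values")
    means = _sample_type_means(norm, [pair.ligand, pair.receptor])
    try:
        lig = means.loc[(patient_id, tissue, sender_type), pair.ligand]
        rec = means.loc[(patient_id, tissue, receiver_type), pair.receptor]
    except KeyError:
        return None
    return float(lig * rec)


def call_interactions(
    per_sample_scores: Union[pd.Series, Sequence[float]],
    pair: Optional[LigandReceptorPair] = None,
    sender_type: str = "",
    receiver_type: str = "",
    tissue: str = "",
    alpha: float = 0.05,
) -> InteractionResult:
    """Cohort-level significance call on per-patient interaction scores.

    Exact one-sided (greater-than-zero) Wilcoxon signed-rank; zero scores
    are dropped before ranking, and an all-zero vector yields p = 1.
    """
    scores = pd.Series(per_sample_scores, dtype=float)
    if scores.empty:
        raise ImmscapeError("no per-sample scores")
    p, significant = wilcoxon_greater_than_zero(scores.to_numpy(), alpha=alpha)
    return InteractionResult(
        pair=pair or LigandReceptorPair("?", "?"),
        sender_type=sender_type,
        receiver_type=receiver_type,
        tissue=tissue,
        per_sample_scores=scores,
        p_value=p,
        significant=significant,
        mean_score=float(scores.mean()),
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (extra column, not used for calls)."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def interaction_screen(
    norm: NormalizedMatrix,
    pairs: Sequence[LigandReceptorPair],
    type_pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    tissues: Sequence[str] = ("tumor", "adjacent"),
    min_samples: int = 2,
) -> pd.DataFrame:
    """Score and call every (pair, sender, receiver, tissue) combination.

    Patients whose sample lacks either cell type are excluded from that
    test rather than scored zero.  Combinations with fewer than
    ``min_samples`` scoreable patients are flagged ``insufficient samples``
    and not called.  The output is a tidy frame sortable by ``mean_score``,
    with the number of tests and a BH-adjusted p column for optional user
    correction (the ``significant`` flag itself is uncorrected).
    """
    if norm.cell_meta is None:
        raise ImmscapeError("annotated matrix required")
    genes = sorted({g for p in pairs for g in (p.ligand, p.receptor)})
    present = [g for g in genes if g in norm.gene_ids]
    means = _sample_type_means(norm, present)
    patients = sorted(norm.cell_meta["patient_id"].unique())
    records = []
    for pair in pairs:
        gene_missing = pair.ligand not in norm.gene_ids or pair.receptor not in norm.gene_ids
        for sender, receiver in type_pairs:
            for tissue in tissues:
                if gene_missing:
                    records.append(
                        dict(ligand=pair.ligand, receptor=pair.receptor,
                             sender_type=sender, receiver_type=receiver,
                             tissue=tissue, n_samples=0, mean_score=np.nan,
                             p_value=np.nan, significant=False,
                             note="gene missing"))
                    continue
                scores = {}
                for patient in patients:
                    try:
                        lig = means.loc[(patient, tissue, sender), pair.ligand]
                        rec = means.loc[(patient, tissue, receiver), pair.receptor]
                    except KeyError:
                        continue
                    scores[patient] = float(lig * rec)
                if len(scores) < min_samples:
                    records.append(
                        dict(ligand=pair.ligand, receptor=pair.receptor,
                             sender_type=sender, receiver_type=receiver,
                             tissue=tissue, n_samples=len(scores),
                             mean_score=(np.mean(list(scores.values()))
                                         if scores else np.nan),
                             p_value=np.nan, significant=False,
                             note="insufficient samples"))
                    continue
                vec = np.array(list(scores.values()))
                p, sig = wilcoxon_greater_than_zero(vec, alpha=alpha)
                records.append(
                    dict(ligand=pair.ligand, receptor=pair.receptor,
                         sender_type=sender, receiver_type=receiver,
                         tissue=tissue, n_samples=len(vec),
                         mean_score=float(vec.mean()), p_value=p,
                         significant=sig, note=""))
    out = pd.DataFrame.from_records(records)
    tested = out["p_value"].notna()
    out["n_tests"] = int(tested.sum())
    out["p_adj_bh"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj_bh"] = _bh_adjust(out.loc[tested, "p_value"].to_numpy())
    return out.sort_values("mean_score", ascending=False).reset_index(drop=True)
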