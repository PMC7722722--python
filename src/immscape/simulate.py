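"""Seeded synthetic cohort generator: paired tumor/adjacent samples from a
multi-patient design, with planted cell-type markers, planted ligand-receptor
co-expression and planted clonal TCR structure.

The generator emulates the study design every downstream stage expects —
seven patients, each contributing one tumor and one matched adjacent-tissue
sample of sorted immune cells — and records the planted structure in a truth
record so recovery can be tested.

Counts are negative-binomial with a shared dispersion.  Two expression
regimes are used: ordinary "program" genes (cell-type markers, signature
genes, filler genes) at a moderate baseline mean, and sparse "signaling"
transcripts (the ligand/receptor catalogue) at a much lower baseline, so
that a per-sample, per-cell-type mean of a signaling gene is frequently
exactly zero — the empirical behaviour of cytokine and receptor transcripts
in droplet data, and the regime in which a greater-than-zero significance
call is meaningful at all.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .core import ExpressionMatrix, write_counts_mtx

__all__ = [
    "CellTypeSpec",
    "PlantedInteraction",
    "CloneLaw",
    "ChainDropout",
    "SimulationConfig",
    "SyntheticDataset",
    "default_config",
    "simulate_expression",
    "simulate_tcr",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    tumor_fraction: float
    adjacent_fraction: float
    markers: tuple = ()  # (gene, fold_up) pairs, fold_up >= 1
    is_t_cell: bool = False
    lineage: str = "other"


@dataclass(frozen=True)
class PlantedInteraction:
    ligand: str
    receptor: str
    sender_type: str
    receiver_type: str
    fold_up: float = 4.0
    tissue: str = "tumor"  # tumor | adjacent | both


@dataclass(frozen=True)
class CloneLaw:
    """Clone-size law: singleton with ``p_singleton``, else 1 + Geometric."""

    p_singleton: float = 0.6
    geometric_p: float = 0.5


@dataclass(frozen=True)
class ChainDropout:
    p_alpha_missing: float = 0.25
    p_beta_missing: float = 0.15


_MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP6",
    "MT-CO3", "MT-ND3", "MT-ND4", "MT-ND5", "MT-CYB",
)


def _default_cell_types() -> tuple:
    f = 8.0  # marker fold-change over baseline
    return (
        CellTypeSpec("CD4_naive", 0.10, 0.16,
                     tuple((g, f) for g in ("CCR7", "TCF7", "LEF1", "SELL", "IL7R")),
                     is_t_cell=True, lineage="T"),
        CellTypeSpec("CD4_T", 0.12, 0.14,
                     tuple((g, f) for g in ("CD40LG", "ANXA1", "IL2")),
                     is_t_cell=True, lineage="T"),
        CellTypeSpec("Treg", 0.16, 0.08,
                     tuple((g, f) for g in ("FOXP3", "IL2RA", "IKZF2", "TNFRSF9")),
                     is_t_cell=True, lineage="T"),
        CellTypeSpec("CD8_T", 0.14, 0.20,
                     tuple((g, f) for g in
                           ("FGFBP2", "GZMB", "GZMH", "NKG7", "GNLY", "PRF1", "KLRG1")),
                     is_t_cell=True, lineage="T"),
        CellTypeSpec("CD8_Tex", 0.18, 0.08,
                     tuple((g, f) for g in
                           ("LAG3", "PDCD1", "TIGIT", "HAVCR2", "CTLA4", "ENTPD1",
                            "TOX", "EOMES", "CXCL13", "GZMK", "IFNG", "CD38")),
                     is_t_cell=True, lineage="T"),
        CellTypeSpec("Macrophage", 0.18, 0.14,
                     tuple((g, f) for g in
                           ("CD68", "CD163", "CSF1R", "C1QA", "APOE", "LYZ")),
                     lineage="Myeloid"),
        CellTypeSpec("NK", 0.06, 0.10,
                     tuple((g, f) for g in ("KLRD1", "KLRC1", "NCR3", "XCL1")),
                     lineage="NK"),
        CellTypeSpec("B", 0.06, 0.10,
                     tuple((g, f) for g in ("CD79A", "MS4A1", "CD19")),
                     lineage="B"),
    )


def _default_planted_lr() -> tuple:
    # Macrophage <-> Treg crosstalk planted in tumor tissue only
    return (
        PlantedInteraction("IL1B", "IL1R2", "Macrophage", "Treg", 4.0, "tumor"),
        PlantedInteraction("HLA-A", "LILRB1", "Treg", "Macrophage", 4.0, "tumor"),
    )


def _default_signaling_genes() -> tuple:
    planted = ("IL1B", "IL1R2", "HLA-A", "LILRB1")
    nulls = tuple(f"LIGAND{i:02d}" for i in range(1, 21)) + tuple(
        f"RECEPTOR{i:02d}" for i in range(1, 21)
    )
    return planted + nulls


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic cohort.

    ``baseline_mean`` is the negative-binomial mean per gene per cell for
    ordinary genes; ``lr_baseline_mean`` is the (much lower) baseline for
    the genes listed in ``signaling_genes``.  ``dispersion`` is the NB size
    parameter shared by all genes.  Cluster labels in the output equal the
    cell-type names (the generator plants type-level structure only).
    """

    seed: int = 0
    n_patients: int = 7
    cells_per_sample: int = 2000
    n_genes: int = 200
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    lr_baseline_mean: float = 0.0025
    mito_mean_multiplier: float = 1.0
    cell_types: tuple = field(default_factory=_default_cell_types)
    planted_lr: tuple = field(default_factory=_default_planted_lr)
    signaling_genes: tuple = field(default_factory=_default_signaling_genes)
    clone_law: CloneLaw = field(default_factory=CloneLaw)
    chain_dropout: ChainDropout = field(default_factory=ChainDropout)
    secondary_tra_fraction: float = 0.05

    def __post_init__(self) -> None:
        for tiss, attr in (("tumor", "tumor_fraction"), ("adjacent", "adjacent_fraction")):
            total = sum(getattr(ct, attr) for ct in self.cell_types)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{tiss} cell-type fractions sum to {total}, not 1")
        for p in (
            self.clone_law.p_singleton,
            self.clone_law.geometric_p,
            self.chain_dropout.p_alpha_missing,
            self.chain_dropout.p_beta_missing,
            self.secondary_tra_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for ct in self.cell_types:
            for gene, fold in ct.markers:
                if fold < 1.0:
                    raise ValueError(f"marker fold_up {fold} for {gene} must be >= 1")
        for lr in self.planted_lr:
            if lr.fold_up < 1.0:
                raise ValueError("planted L-R fold_up must be >= 1")
            if lr.tissue not in ("tumor", "adjacent", "both"):
                raise ValueError(f"unknown planted tissue '{lr.tissue}'")
        n_named = len(self.gene_panel())
        if self.n_genes < n_named:
            raise ValueError(
                f"n_genes = {self.n_genes} too small for the {n_named} named genes"
            )

    # -- gene panel ---------------------------------------------------------
    def named_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for ct in self.cell_types:
            for gene, _ in ct.markers:
                seen.setdefault(gene, None)
        for lr in self.planted_lr:
            seen.setdefault(lr.ligand, None)
            seen.setdefault(lr.receptor, None)
        for g in self.signaling_genes:
            seen.setdefault(g, None)
        for g in _MITO_GENES:
            seen.setdefault(g, None)
        return list(seen)

    def gene_panel(self) -> list[str]:
        genes = self.named_genes()
        i = 1
        while len(genes) < self.n_genes:
            name = f"GENE{i:04d}"
            if name not in genes:
                genes.append(name)
            i += 1
        return genes

    # -- (de)serialization --------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["cell_types"] = tuple(
            CellTypeSpec(
                name=ct["name"],
                tumor_fraction=ct["tumor_fraction"],
                adjacent_fraction=ct["adjacent_fraction"],
                markers=tuple((g, f) for g, f in ct.get("markers", ())),
                is_t_cell=ct.get("is_t_cell", False),
                lineage=ct.get("lineage", "other"),
            )
            for ct in raw["cell_types"]
        )
        raw["planted_lr"] = tuple(PlantedInteraction(**lr) for lr in raw["planted_lr"])
        raw["signaling_genes"] = tuple(raw["signaling_genes"])
        raw["clone_law"] = CloneLaw(**raw["clone_law"])
        raw["chain_dropout"] = ChainDropout(**raw["chain_dropout"])
        return cls(**raw)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study conditions with a chosen seed."""
    return SimulationConfig(seed=seed, **overrides)


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix
    contigs: pd.DataFrame
    truth: dict
    config: SimulationConfig


# ---------------------------------------------------------------------------
# expression


def _mean_vector(config: SimulationConfig, genes: list[str], cell_type: str,
                 tissue: str) -> np.ndarray:
    """Per-gene NB mean for a cell of the given type and tissue."""
    signaling = set(config.signaling_genes) | {
        g for lr in config.planted_lr for g in (lr.ligand, lr.receptor)
    }
    base = np.full(len(genes), config.baseline_mean)
    idx = {g: i for i, g in enumerate(genes)}
    for g in signaling:
        base[idx[g]] = config.lr_baseline_mean
    for g in _MITO_GENES:
        base[idx[g]] = config.baseline_mean * config.mito_mean_multiplier
    ct = next(c for c in config.cell_types if c.name == cell_type)
    for gene, fold in ct.markers:
        if gene not in idx:
            raise ValueError(f"marker gene {gene} not among simulated genes")
        base[idx[gene]] *= fold
    for lr in config.planted_lr:
        if lr.tissue not in (tissue, "both"):
            continue
        if cell_type == lr.sender_type:
            base[idx[lr.ligand]] *= lr.fold_up
        if cell_type == lr.receiver_type:
            base[idx[lr.receptor]] *= lr.fold_up
    return base


def simulate_expression(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> ExpressionMatrix:
    """Draw the full cohort count matrix with annotations.

    Deterministic given the config seed: same seed, byte-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = config.gene_panel()
    r = config.dispersion
    blocks, barcodes, meta_rows = [], [], []
    type_names = [ct.name for ct in config.cell_types]
    ct_by_name = {ct.name: ct for ct in config.cell_types}
    mean_cache: dict[tuple[str, str], np.ndarray] = {}
    for p in range(1, config.n_patients + 1):
        patient = f"P{p}"
        for tissue, attr in (("tumor", "tumor_fraction"), ("adjacent", "adjacent_fraction")):
            fracs = np.array([getattr(ct, attr) for ct in config.cell_types])
            counts_per_type = rng.multinomial(config.cells_per_sample, fracs)
            cell_idx = 0
            for tname, n_cells in zip(type_names, counts_per_type):
                if n_cells == 0:
                    continue
                key = (tname, tissue)
                if key not in mean_cache:
                    mean_cache[key] = _mean_vector(config, genes, tname, tissue)
                mu = mean_cache[key]
                prob = r / (r + mu)
                block = rng.negative_binomial(
                    r, prob[:, None], size=(len(genes), n_cells)
                )
                blocks.append(sp.csr_matrix(block))
                ct = ct_by_name[tname]
                for _ in range(n_cells):
                    bc = f"{patient}-{tissue[0].upper()}-{cell_idx:05d}"
                    barcodes.append(bc)
                    meta_rows.append(
                        (bc, patient, tissue, tname, tname, True, ct.lineage, ct.is_t_cell)
                    )
                    cell_idx += 1
    counts = sp.hstack(blocks, format="csr")
    meta = pd.DataFrame(
        meta_rows,
        columns=["barcode", "patient_id", "tissue", "cell_type", "cluster",
                 "is_cd45", "lineage", "is_t_cell"],
    ).set_index("barcode")
    return ExpressionMatrix(
        counts=counts,
        gene_ids=pd.Index(genes),
        cell_barcodes=pd.Index(barcodes),
        cell_meta=meta,
    )


# ---------------------------------------------------------------------------
# TCR contigs

# 16 sense codons (distinct amino acids) used to spell CDR3 sequences; a
# two-codon patient prefix makes cross-patient clonotype collisions
# impossible by construction.
_CODONS = (
    ("TGT", "C"), ("GCT", "A"), ("GGT", "G"), ("ACT", "T"),
    ("TTT", "F"), ("AGA", "R"), ("GAA", "E"), ("TCA", "S"),
    ("GAT", "D"), ("CAT", "H"), ("AAA", "K"), ("CTG", "L"),
    ("ATG", "M"), ("AAT", "N"), ("CCT", "P"), ("GTT", "V"),
)


def _random_cdr3(rng: np.random.Generator, patient_index: int) -> tuple[str, str]:
    """Random CDR3 (nt, aa) with a deterministic per-patient codon prefix."""
    prefix = [_CODONS[patient_index // 16], _CODONS[patient_index % 16]]
    n_body = int(rng.integers(9, 14))  # total length 33-45 nt
    body = [_CODONS[int(i)] for i in rng.integers(0, len(_CODONS), n_body)]
    codons = prefix + body
    return "".join(c for c, _ in codons), "".join(a for _, a in codons)


def simulate_tcr(
    config: SimulationConfig,
    t_cell_barcodes: Sequence[str],
    patient_ids: Sequence[str],
    cluster_labels: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict]:
    """Plant clonal structure on T cells and emit a contig table.

    Clonotypes are drawn per patient (never shared across patients).  Each
    cell emits one TRA and one TRB contig subject to independent chain
    dropout; a configurable fraction of cells receives a second, lower-UMI
    TRA contig to exercise dominant-chain selection downstream.

    Returns ``(contigs, truth)`` where ``truth`` maps each cell to its
    planted clonotype key and records planted clone sizes.
    """
    barcodes = list(t_cell_barcodes)
    if not barcodes:
        raise ValueError("empty T-cell barcode list")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    patients = pd.Series(list(patient_ids), index=barcodes)
    law, drop = config.clone_law, config.chain_dropout
    rows = []
    cell_to_key: dict[str, str] = {}
    clone_sizes: dict[str, int] = {}
    patient_order = list(dict.fromkeys(patients))
    for p_idx, patient in enumerate(patient_order):
        cells = [b for b in barcodes if patients[b] == patient]
        perm = rng.permutation(len(cells))
        cells = [cells[i] for i in perm]
        pos = 0
        clone_i = 0
        while pos < len(cells):
            if rng.random() < law.p_singleton:
                size = 1
            else:
                size = 1 + int(rng.geometric(law.geometric_p))
            size = min(size, len(cells) - pos)
            alpha_nt, alpha_aa = _random_cdr3(rng, p_idx)
            beta_nt, beta_aa = _random_cdr3(rng, p_idx)
            key = f"{patient}:{alpha_nt}|{beta_nt}"
            clone_sizes[key] = size
            members = cells[pos : pos + size]
            pos += size
            clone_i += 1
            for bc in members:
                cell_to_key[bc] = key
                if rng.random() >= drop.p_alpha_missing:
                    umis = int(rng.integers(3, 30))
                    rows.append((bc, "TRA", alpha_aa, alpha_nt,
                                 f"TRAV{1 + clone_i % 20}", f"TRAJ{1 + clone_i % 30}",
                                 True, True, umis, patient))
                    if rng.random() < config.secondary_tra_fraction:
                        sec_nt, sec_aa = _random_cdr3(rng, p_idx)
                        rows.append((bc, "TRA", sec_aa, sec_nt,
                                     f"TRAV{2 + clone_i % 20}", f"TRAJ{2 + clone_i % 30}",
                                     True, True, int(rng.integers(1, max(umis, 2))),
                                     patient))
                if rng.random() >= drop.p_beta_missing:
                    rows.append((bc, "TRB", beta_aa, beta_nt,
                                 f"TRBV{1 + clone_i % 20}", f"TRBJ{1 + clone_i % 12}",
                                 True, True, int(rng.integers(3, 30)), patient))
    contigs = pd.DataFrame(
        rows,
        columns=["barcode", "chain", "cdr3", "cdr3_nt", "v_gene", "j_gene",
                 "productive", "full_length", "umis", "patient_id"],
    )
    truth = {"cell_to_clonotype": cell_to_key, "clone_sizes": clone_sizes}
    return contigs, truth


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimulationConfig) -> SyntheticDataset:
    """Assemble the full synthetic cohort: expression, contigs, truth record."""
    rng = np.random.default_rng(config.seed)
    matrix = simulate_expression(config, rng=rng)
    meta = matrix.cell_meta
    t_mask = meta["is_t_cell"].astype(bool)
    t_barcodes = meta.index[t_mask]
    contigs, tcr_truth = simulate_tcr(
        config,
        t_cell_barcodes=t_barcodes,
        patient_ids=meta.loc[t_barcodes, "patient_id"],
        cluster_labels=meta.loc[t_barcodes, "cluster"],
        rng=rng,
    )
    truth = {
        "markers": {
            ct.name: [[g, f] for g, f in ct.markers] for ct in config.cell_types
        },
        "planted_lr": [asdict(lr) for lr in config.planted_lr],
        "tcr": tcr_truth,
        "composition": {
            "tumor": {ct.name: ct.tumor_fraction for ct in config.cell_types},
            "adjacent": {ct.name: ct.adjacent_fraction for ct in config.cell_types},
        },
    }
    return SyntheticDataset(matrix=matrix, contigs=contigs, truth=truth, config=config)


def write_cohort(dataset: SyntheticDataset, outdir) -> dict:
    """Write the cohort in the formats the readers consume.

    MatrixMarket trio for counts, CSV for annotations and contigs, YAML for
    the config, JSON for the truth record.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_counts_mtx(dataset.matrix, outdir)
    ann_path = outdir / "annotations.csv"
    dataset.matrix.cell_meta.reset_index().to_csv(ann_path, index=False)
    contig_path = outdir / "contigs.csv"
    dataset.contigs.to_csv(contig_path, index=False)
    cfg_path = outdir / "config.yaml"
    dataset.config.to_yaml(cfg_path)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(dataset.truth))
    paths.update(
        annotations=ann_path, contigs=contig_path, config=cfg_path, truth=truth_path
    )
    return paths
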