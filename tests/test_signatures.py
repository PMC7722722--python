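"""Signature scoring, anchored derivation, proliferation, gene correlation."""

import numpy as np
import pandas as pd
import pytest

import immscape as im
from immscape.core import ImmscapeError
from immscape.simulate import CellTypeSpec

from conftest import make_matrix


def _norm(counts, genes=None):
    return im.normalize_log2(make_matrix(counts, genes=genes))


def test_single_gene_signature_equals_that_genes_zscore(rng):
    counts = rng.integers(0, 9, size=(6, 20))
    norm = _norm(counts)
    z = im.zscore_by_gene(norm)
    sig = im.GeneSignature("solo", ("G2",))
    scored = im.score_signature(norm, sig)
    assert np.allclose(scored.scores.to_numpy(), z.dense()[2])


def test_all_constant_signature_genes_score_zero():
    norm = _norm(np.full((3, 5), 4))
    scored = im.score_signature(norm, im.GeneSignature("flat", ("G0", "G1")))
    assert np.allclose(scored.scores, 0.0)


def test_three_gene_four_cell_hand_oracle():
    # z-values and row means computed by explicit per-gene arithmetic
    counts = [[0, 1, 3, 7], [2, 2, 2, 2], [1, 0, 4, 2]]
    scored = im.score_signature(_norm(counts), im.GeneSignature("s", ("G0", "G1", "G2")))
    expected = [-0.5362159147, -0.6306338534, 0.579005416, 0.587844352]
    assert np.allclose(scored.scores.to_numpy(), expected, atol=1e-9)


def test_score_invariant_to_gene_order_and_duplicates(rng):
    counts = rng.integers(0, 6, size=(8, 15))
    norm = _norm(counts)
    a = im.score_signature(norm, im.GeneSignature("a", ("G1", "G4", "G6")))
    b = im.score_signature(norm, im.GeneSignature("b", ("G6", "G1", "G4", "G1")))
    assert np.allclose(a.scores, b.scores)


def test_missing_genes_dropped_with_warning_all_missing_errors(rng):
    norm = _norm(rng.integers(0, 6, size=(4, 10)))
    with pytest.warns(UserWarning, match="absent"):
        scored = im.score_signature(norm, im.GeneSignature("m", ("G1", "NOPE")))
    assert scored.missing_genes == ("NOPE",)
    with pytest.raises(ImmscapeError, match="no gene"):
        im.score_signature(norm, im.GeneSignature("m", ("NOPE", "NADA")))


def test_cluster_level_re_zscore_has_zero_mean_unit_sd(rng):
    counts = rng.integers(0, 6, size=(6, 40))
    labels = np.repeat(["c1", "c2", "c3", "c4"], 10)
    scored = im.score_signature(
        _norm(counts), im.GeneSignature("s", ("G0", "G1")),
        cluster_labels=labels, level="cluster", re_zscore=True,
    )
    assert abs(scored.scores.mean()) < 1e-8
    assert abs(scored.scores.std(ddof=0) - 1.0) < 1e-6


# ---------------------------------------------------------------------------
# naive score


def test_naive_score_requires_at_least_one_marker(rng):
    norm = _norm(rng.integers(0, 6, size=(3, 8)))
    with pytest.raises(ImmscapeError):
        im.naive_score(norm, cluster_labels=["a"] * 8)


def test_naive_cluster_ranks_first_on_planted_cohort(small_cohort):
    norm = im.normalize_log2(small_cohort.matrix)
    meta = small_cohort.matrix.cell_meta
    t_mask = np.asarray(meta["is_t_cell"].astype(bool))
    z = im.zscore_by_gene(norm, within=t_mask)
    scored = im.naive_score(z, cluster_labels=meta.loc[t_mask, "cluster"])
    assert scored.scores.idxmax() == "CD4_naive"


def test_identical_expression_across_clusters_scores_equal():
    block = np.arange(12).reshape(4, 3) % 5
    counts = np.hstack([block, block])  # two clusters, same cells
    labels = ["c1"] * 3 + ["c2"] * 3
    scored = im.naive_score(
        _norm(counts, genes=["CCR7", "TCF7", "LEF1", "SELL"]), cluster_labels=labels
    )
    assert scored.scores["c1"] == pytest.approx(scored.scores["c2"], abs=1e-12)


# ---------------------------------------------------------------------------
# anchored derivation


def test_duplicated_anchor_profile_ranks_first(rng):
    counts = rng.integers(0, 7, size=(30, 50))
    counts[5] = counts[0]  # G5 duplicates the anchor G0
    sig = im.derive_correlation_signature(_norm(counts), "G0", k=10)
    assert sig.genes[0] == "G5"
    assert sig.correlations[0] == pytest.approx(1.0)
    assert "G0" not in sig.genes


def test_constant_anchor_errors():
    counts = np.ones((4, 10), dtype=int)
    counts[1:] = np.arange(10) % 3
    with pytest.raises(ImmscapeError, match="constant"):
        im.derive_correlation_signature(_norm(counts), "G0", k=2)


def test_k_larger_than_eligible_errors(rng):
    norm = _norm(rng.integers(0, 5, size=(6, 20)))
    with pytest.raises(ImmscapeError, match="eligible"):
        im.derive_correlation_signature(norm, "G0", k=6)


def test_k_equal_all_eligible_returns_permutation(rng):
    counts = rng.integers(1, 9, size=(10, 30))  # all genes vary w.h.p.
    norm = _norm(counts)
    sig = im.derive_correlation_signature(norm, "G0", k=9)
    assert sorted(sig.genes) == [f"G{i}" for i in range(1, 10)]
    assert np.all(np.diff(sig.correlations) <= 1e-12)


def test_planted_correlated_genes_recovered_in_top_k():
    hits = 0
    for rep in range(100):
        rng = np.random.default_rng(900 + rep)
        n_cells = 200
        latent = rng.normal(size=n_cells)
        anchor = latent + 0.1 * rng.normal(size=n_cells)
        planted = latent + 0.45 * rng.normal(size=(10, n_cells))  # r ~ 0.9
        noise = rng.normal(size=(150, n_cells))
        values = np.vstack([anchor, planted, noise])
        values = np.round(np.exp(values)).astype(int)  # positive counts
        genes = ["ANCHOR"] + [f"PL{i}" for i in range(10)] + [f"N{i}" for i in range(150)]
        sig = im.derive_correlation_signature(_norm(values, genes=genes), "ANCHOR", k=50)
        if all(f"PL{i}" in sig.genes for i in range(10)):
            hits += 1
    assert hits >= 95


# ---------------------------------------------------------------------------
# proliferation


def test_proliferation_is_max_of_phase_scores(rng):
    counts = rng.integers(0, 8, size=(6, 12))
    norm = _norm(counts)
    g1s = im.GeneSignature("G1S", ("G0", "G1"))
    g2m = im.GeneSignature("G2M", ("G2", "G3"))
    s1 = im.score_signature(norm, g1s).scores
    s2 = im.score_signature(norm, g2m).scores
    prolif = im.proliferation_score(norm, g1s, g2m, level="cell")
    assert np.allclose(prolif.scores, np.maximum(s1, s2))


def test_planted_cycling_cluster_ranks_first():
    g1s, g2m = im.load_cell_cycle_signatures()
    cycle_markers = tuple((g, 6.0) for g in (g1s.genes[:8] + g2m.genes[:8]))
    cfg = im.SimulationConfig(
        seed=21, n_patients=2, cells_per_sample=400, n_genes=150,
        cell_types=(
            CellTypeSpec("Cycling", 0.3, 0.3, cycle_markers),
            CellTypeSpec("Quiet", 0.4, 0.4, ()),
            CellTypeSpec("Other", 0.3, 0.3, ()),
        ),
        planted_lr=(), signaling_genes=(),
    )
    m = im.simulate_expression(cfg)
    scored = im.proliferation_score(
        im.normalize_log2(m), g1s, g2m, cluster_labels=m.cell_meta["cluster"]
    )
    assert scored.scores.idxmax() == "Cycling"


# ---------------------------------------------------------------------------
# pairwise correlation


def test_gene_self_correlation_is_one(rng):
    norm = _norm(rng.integers(0, 9, size=(3, 25)))
    r, p = im.pairwise_gene_correlation(norm, "G1", "G1")
    assert r == pytest.approx(1.0)


def test_pairwise_correlation_matches_hand_computation():
    # Pearson on log2(count+1) of (1,2,3,4) vs (2,4,5,9), p from t with 2 df
    norm = _norm([[1, 2, 3, 4], [2, 4, 5, 9]])
    r, p = im.pairwise_gene_correlation(norm, "G0", "G1")
    assert r == pytest.approx(0.9793918644689605, abs=1e-12)
    assert p == pytest.approx(0.020608135531039448, rel=1e-9)


def test_negated_profile_gives_minus_one():
    # values and their reflection around a constant: r = -1
    norm = _norm([[0, 1, 3], [3, 1, 0]])
    r, _ = im.pairwise_gene_correlation(norm, "G0", "G1")
    assert r == pytest.approx(-1.0)


def test_constant_gene_correlation_errors():
    norm = _norm([[1, 1, 1], [0, 1, 2]])
    with pytest.raises(ImmscapeError, match="constant"):
        im.pairwise_gene_correlation(norm, "G0", "G1")


def test_gmt_round_trip(tmp_path):
    sigs = [im.GeneSignature("a", ("X", "Y")), im.GeneSignature("b", ("Z",))]
    im.write_gmt(sigs, tmp_path / "s.gmt")
    back = im.read_gmt(tmp_path / "s.gmt")
    assert [(s.name, s.genes) for s in back] == [("a", ("X", "Y")), ("b", ("Z",))]
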