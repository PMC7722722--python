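"""Clonotype assignment and clonality analytics, with brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import immscape as im
from immscape.core import ImmscapeError
from immscape.simulate import ChainDropout


def _contig(barcode, chain, cdr3_nt, umis=5, patient="P1", productive=True,
            full_length=True):
    return dict(barcode=barcode, chain=chain, cdr3=cdr3_nt[: len(cdr3_nt) // 3],
                cdr3_nt=cdr3_nt, v_gene="TRAV1", j_gene="TRAJ1",
                productive=productive, full_length=full_length, umis=umis,
                patient_id=patient)


def brute_force_clonotypes(contigs: pd.DataFrame, universe):
    """Independent per-cell reference: explicit dominant-chain selection then
    group-by on (patient, alpha, beta)."""
    assignments = {}
    for bc in universe:
        rows = contigs[contigs["barcode"] == bc]
        dom = {}
        for chain in ("TRA", "TRB"):
            sub = rows[rows["chain"] == chain]
            if not len(sub):
                continue
            best = None
            for _, r in sub.iterrows():
                key = (-r["umis"], r["cdr3_nt"])
                if best is None or key < best[0]:
                    best = (key, r)
            dom[chain] = best[1]
        if "TRA" in dom and "TRB" in dom:
            assignments[bc] = (
                dom["TRA"]["patient_id"], dom["TRA"]["cdr3_nt"], dom["TRB"]["cdr3_nt"]
            )
    sizes = {}
    for key in assignments.values():
        sizes[key] = sizes.get(key, 0) + 1
    return assignments, sizes


# ---------------------------------------------------------------------------
# parsing


def test_parse_drops_non_tcr_nonproductive_partial_rows():
    rows = [
        _contig("c1", "TRA", "TGTGCT"),
        _contig("c1", "TRB", "TGTGGT"),
        _contig("c2", "IGH", "TGTACT"),                       # wrong chain
        _contig("c2", "TRA", "TGTTTT", productive=False),     # not productive
        _contig("c3", "TRB", "TGTAGA", full_length=False),    # partial
        _contig("c3", "TRA", "TGTGAA"),
        _contig("c4", "TRA", "TGTTCA"),
        _contig("c4", "TRB", "TGTGAT"),
        _contig("c5", "TRB", "TGTCAT"),
        _contig("c5", "TRA", "TGTAAA"),
    ]
    contigs, tallies = im.parse_contigs(pd.DataFrame(rows))
    assert len(contigs) == 7
    assert tallies["n_dropped_chain"] == 1
    assert tallies["n_dropped_not_productive"] == 1
    assert tallies["n_dropped_not_full_length"] == 1


def test_parse_accepts_string_booleans(tmp_path):
    df = pd.DataFrame([_contig("c1", "TRA", "TGT")])
    df["productive"] = "True"
    df["full_length"] = "true"
    path = tmp_path / "contigs.csv"
    df.to_csv(path, index=False)
    contigs, _ = im.parse_contigs(path)
    assert len(contigs) == 1 and bool(contigs["productive"].iloc[0])


def test_parse_missing_column_errors():
    with pytest.raises(ImmscapeError, match="required column"):
        im.parse_contigs(pd.DataFrame({"barcode": ["c1"]}))


# ---------------------------------------------------------------------------
# clonotype assignment


def test_beta_only_cell_gets_no_clonotype():
    contigs = pd.DataFrame([_contig("c1", "TRB", "TGTGCT")])
    table = im.assign_clonotypes(contigs, ["c1"])
    assert table.n_assigned_cells == 0


def test_shared_alpha_beta_pair_forms_size_two_clonotype():
    contigs = pd.DataFrame([
        _contig("c1", "TRA", "TGTGCT"), _contig("c1", "TRB", "TGTGGT"),
        _contig("c2", "TRA", "TGTGCT"), _contig("c2", "TRB", "TGTGGT"),
    ])
    table = im.assign_clonotypes(contigs, ["c1", "c2"])
    assert len(table.clonotypes) == 1
    assert table.clonotypes["size"].iloc[0] == 2


def test_six_cell_hand_enumeration():
    """One multi-TRA cell (umis 7 vs 2), two cells sharing a pair, one
    alpha-only cell: 4 clonotypes of sizes (2,1,1,1), one unassigned."""
    contigs = pd.DataFrame([
        # c1: two TRAs, dominant = umis 7
        _contig("c1", "TRA", "TGTAAA", umis=7), _contig("c1", "TRA", "TGTCCC", umis=2),
        _contig("c1", "TRB", "TGTGGG", umis=5),
        # c2, c3 share the same pair
        _contig("c2", "TRA", "TGTTTT"), _contig("c2", "TRB", "TGTAGA"),
        _contig("c3", "TRA", "TGTTTT"), _contig("c3", "TRB", "TGTAGA"),
        # c4 alpha-only -> unassigned
        _contig("c4", "TRA", "TGTGAA"),
        # c5, c6 distinct pairs
        _contig("c5", "TRA", "TGTCAT"), _contig("c5", "TRB", "TGTGAT"),
        _contig("c6", "TRA", "TGTAAT"), _contig("c6", "TRB", "TGTCTG"),
    ])
    universe = [f"c{i}" for i in range(1, 7)]
    table = im.assign_clonotypes(contigs, universe)
    assert len(table.clonotypes) == 4
    assert sorted(table.clonotypes["size"]) == [1, 1, 1, 2]
    assert table.n_assigned_cells == 5
    assert "c4" not in table.cell_assignments.index
    # dominant alpha of c1 is the 7-UMI contig
    c1_key = table.cell_assignments["c1"]
    assert "TGTAAA" in c1_key and "TGTCCC" not in c1_key
    assert len(table.diagnostics) == 1  # the losing TRA of c1


def test_umi_tie_breaks_to_lexicographically_smallest():
    contigs = pd.DataFrame([
        _contig("c1", "TRA", "TGTZZZ", umis=5), _contig("c1", "TRA", "TGTAAA", umis=5),
        _contig("c1", "TRB", "TGTGGG", umis=5),
    ])
    table = im.assign_clonotypes(contigs, ["c1"])
    assert "TGTAAA" in table.cell_assignments["c1"]


def _random_contig_table(rng, n_cells):
    rows = []
    universe = []
    pool = [f"TGT{''.join(rng.choice(list('ACGT'), 9))}" for _ in range(max(4, n_cells // 4))]
    for i in range(n_cells):
        patient = f"P{1 + i % 3}"
        bc = f"{patient}-c{i}"
        universe.append(bc)
        if rng.random() < 0.1:
            continue  # no contigs at all
        if rng.random() > 0.2:  # TRA present
            n_tra = 1 + (rng.random() < 0.25) + (rng.random() < 0.1)
            for _ in range(n_tra):
                rows.append(_contig(bc, "TRA", str(rng.choice(pool)),
                                    umis=int(rng.integers(1, 6)), patient=patient))
        if rng.random() > 0.15:  # TRB present
            rows.append(_contig(bc, "TRB", str(rng.choice(pool)),
                                umis=int(rng.integers(1, 6)), patient=patient))
    return pd.DataFrame(rows) if rows else pd.DataFrame([_contig("x", "TRA", "TGT")]), universe


@pytest.mark.parametrize("seed", range(12))
def test_assignment_agrees_with_bruteforce(seed):
    rng = np.random.default_rng(5000 + seed)
    contigs, universe = _random_contig_table(rng, int(rng.integers(20, 200)))
    contigs = contigs[contigs["barcode"].isin(universe)]
    table = im.assign_clonotypes(contigs, universe)
    ref_assign, ref_sizes = brute_force_clonotypes(contigs, universe)
    assert table.n_assigned_cells == len(ref_assign)
    ours = {
        bc: key for bc, key in table.cell_assignments.items()
    }
    for bc, (patient, a, b) in ref_assign.items():
        assert ours[bc] == f"{patient}:{a}|{b}"
    assert sorted(table.clonotypes["size"]) == sorted(ref_sizes.values())


def test_aa_level_keys_merge_synonymous_nt():
    contigs = pd.DataFrame([
        dict(_contig("c1", "TRA", "TGTAAA"), cdr3="CK"),
        dict(_contig("c1", "TRB", "TGTGGG"), cdr3="CG"),
        dict(_contig("c2", "TRA", "TGCAAG"), cdr3="CK"),  # different nt, same aa
        dict(_contig("c2", "TRB", "TGTGGA"), cdr3="CG"),
    ])
    nt = im.assign_clonotypes(contigs, ["c1", "c2"], key_level="nt")
    aa = im.assign_clonotypes(contigs, ["c1", "c2"], key_level="aa")
    assert len(nt.clonotypes) == 2
    assert len(aa.clonotypes) == 1


def test_unknown_barcode_warns_and_drops_or_errors():
    contigs = pd.DataFrame([_contig("cX", "TRA", "TGT")])
    with pytest.warns(UserWarning, match="outside"):
        table = im.assign_clonotypes(contigs, ["c1"])
    assert table.n_assigned_cells == 0
    with pytest.raises(ImmscapeError, match="outside"):
        im.assign_clonotypes(contigs, ["c1"], on_unknown_barcode="error")


# ---------------------------------------------------------------------------
# chain recovery


def test_chain_recovery_percentages_from_published_accounting():
    """38,134 cells; 26,920 with alpha, 31,440 with beta, 26,672 with both
    -> 70.59% / 82.45% / 69.94%."""
    n, n_a, n_b, n_both = 38134, 26920, 31440, 26672
    rows = []
    for i in range(n):
        bc = f"c{i}"
        has_a = i < n_a
        has_b = (i < n_both) or (n_a <= i < n_a + (n_b - n_both))
        if has_a:
            rows.append(_contig(bc, "TRA", "TGTAAA"))
        if has_b:
            rows.append(_contig(bc, "TRB", "TGTGGG"))
    contigs = pd.DataFrame(rows)
    rec = im.chain_recovery_stats(contigs, [f"c{i}" for i in range(n)])
    assert rec.percentages() == (70.59, 82.45, 69.94)


def test_chain_recovery_empty_universe_errors():
    with pytest.raises(ImmscapeError, match="empty"):
        im.chain_recovery_stats(pd.DataFrame([_contig("c", "TRA", "T")]), [])


# ---------------------------------------------------------------------------
# expansion, sharing, spectrum


def _table_from_pairs(pairs):
    """pairs: list of (barcode, alpha, beta)."""
    rows = []
    for bc, a, b in pairs:
        rows.append(_contig(bc, "TRA", a))
        rows.append(_contig(bc, "TRB", b))
    return im.assign_clonotypes(pd.DataFrame(rows), [p[0] for p in pairs])


def test_all_singletons_bins():
    table = _table_from_pairs([(f"c{i}", f"A{i}", f"B{i}") for i in range(5)])
    labels = pd.Series("g", index=[f"c{i}" for i in range(5)])
    prof = im.clonal_expansion_profile(table, labels)
    assert prof.loc["g", ["frac_unique", "frac_double", "frac_expanded"]].tolist() \
        == [1.0, 0.0, 0.0]


def test_clonal_fraction_single_expanded_clone():
    pairs = [(f"c{i}", "A", "B") for i in range(4)]  # size-4 clone
    pairs += [(f"d{i}", f"A{i}", f"B{i}") for i in range(6)]  # singletons
    table = _table_from_pairs(pairs)
    labels = pd.Series("g", index=[p[0] for p in pairs])
    prof = im.clonal_expansion_profile(table, labels)
    assert prof.loc["g", "clonal_fraction"] == pytest.approx(0.4)


def test_expansion_bins_match_simulator_truth():
    cfg = im.default_config(seed=31, cells_per_sample=200,
                            chain_dropout=ChainDropout(0.0, 0.0),
                            secondary_tra_fraction=0.0)
    ds = im.simulate_cohort(cfg)
    contigs, _ = im.parse_contigs(ds.contigs)
    meta = ds.matrix.cell_meta
    universe = meta.index[meta["is_t_cell"].astype(bool)]
    table = im.assign_clonotypes(contigs, universe)
    truth_sizes = ds.truth["tcr"]["clone_sizes"]
    assert sorted(table.clonotypes["size"]) == sorted(truth_sizes.values())
    spectrum = im.clone_size_spectrum(table)
    truth_spectrum = pd.Series(list(truth_sizes.values())).value_counts().sort_index()
    assert spectrum.tolist() == truth_spectrum.tolist()


def test_sharing_disjoint_clusters_zero_overlap():
    pairs = [("c1", "A1", "B1"), ("c2", "A2", "B2")]
    table = _table_from_pairs(pairs)
    labels = pd.Series(["x", "y"], index=["c1", "c2"])
    sh = im.shared_clonotype_matrix(table, labels)
    assert sh.counts.loc["x", "y"] == 0
    assert sh.percentages.loc["x", "x"] == 100.0


def test_sharing_three_cluster_hand_example():
    """Presence sets A:{1,2,3}, B:{2,3}, C:{3,4} -> counts(A,B)=2,
    pct(A->B)=66.67, pct(B->A)=100."""
    pairs, labels = [], {}
    # clonotype k spans the clusters listed
    spec = {1: ["A"], 2: ["A", "B"], 3: ["A", "B", "C"], 4: ["C"]}
    i = 0
    for k, clusters in spec.items():
        for cl in clusters:
            bc = f"c{i}"; i += 1
            pairs.append((bc, f"ALPHA{k}", f"BETA{k}"))
            labels[bc] = cl
    table = _table_from_pairs(pairs)
    sh = im.shared_clonotype_matrix(table, pd.Series(labels))
    assert sh.counts.loc["A", "B"] == 2
    assert sh.counts.loc["B", "A"] == 2
    assert sh.percentages.loc["A", "B"] == pytest.approx(66.67)
    assert sh.percentages.loc["B", "A"] == pytest.approx(100.0)
    assert (sh.counts.to_numpy() == sh.counts.to_numpy().T).all()


def test_spectrum_shapes_and_conservation():
    table = _table_from_pairs(
        [("c1", "A", "B"), ("c2", "A", "B"), ("c3", "A2", "B2"),
         ("c4", "A3", "B3"), ("c5", "A3", "B3"), ("c6", "A3", "B3"),
         ("c7", "A3", "B3")]
    )
    spectrum = im.clone_size_spectrum(table)
    assert dict(spectrum) == {1: 1, 2: 1, 4: 1}
    assert sum(s * c for s, c in spectrum.items()) == table.n_assigned_cells
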