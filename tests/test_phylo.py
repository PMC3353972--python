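"""Gap filtering, concatenation, rooting, NJ and Dollo reconstruction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from riboscan import phylo
from riboscan.census import PhyleticMatrix
from riboscan.profiles import SeedAlignment
from riboscan.phylo import (
    DolloReconstruction, concatenate, dollo_reconstruct, edge_ids,
    filter_gap_columns, gainloss_report, midpoint_root, nj_tree, read_tree,
    replay_reconstruction,
)


# ---------------------------------------------------------------------------
# gap filtering & concatenation

def test_gap_filter_strict_boundary():
    # column 0: 2 of 4 gaps (fraction 0.5) -> dropped under strict <
    aln = SeedAlignment("f", [
        ("a", "-AA"), ("b", "-AA"), ("c", "AAA"), ("d", "AAA"),
    ])
    filtered, kept = filter_gap_columns(aln)
    assert list(kept) == [1, 2]
    assert filtered.length == 2


def test_gap_filter_identity_on_gapless():
    aln = SeedAlignment("f", [("a", "ACD"), ("b", "ACD")])
    filtered, kept = filter_gap_columns(aln)
    assert filtered.members == aln.members
    assert list(kept) == [0, 1, 2]


def test_gap_filter_hand_enumerated():
    # 10 columns, 5 members; gap counts 0,1,2,3,4,5,2,0,3,1 -> keep <2.5
    rows = [
        "AAAAA-AA-A",
        "AA-A---A-A",
        "A--A-A-AAA",
        "AAA---AA-A",
        "AAAA--AAAA",
    ]
    aln = SeedAlignment("f", [(f"m{i}", r) for i, r in enumerate(rows)])
    gap_counts = [sum(r[c] == "-" for r in rows) for c in range(10)]
    want = [c for c in range(10) if gap_counts[c] / 5 < 0.5]
    _, kept = filter_gap_columns(aln)
    assert list(kept) == want


def test_gap_filter_all_dropped_is_error():
    aln = SeedAlignment("f", [("a", "A-"), ("b", "-A")])
    with pytest.raises(ValueError, match="no columns survive"):
        filter_gap_columns(aln)


def _aln(fam, width, taxa):
    return SeedAlignment(fam, [(t, "A" * width) for t in taxa])


def test_concatenate_width_additivity_and_gap_blocks():
    alns = {"f1": _aln("f1", 30, ["t1", "t2", "t3"]),
            "f2": _aln("f2", 50, ["t1", "t3"])}
    sup = concatenate(alns, ["t1", "t2", "t3"])
    assert sup.length == 80
    row_t2 = dict(sup.members)["t2"]
    assert row_t2 == "A" * 30 + "-" * 50


def test_concatenate_family_order_permutation():
    alns = {"f1": _aln("f1", 3, ["t1", "t2"]),
            "f2": SeedAlignment("f2", [("t1", "CC"), ("t2", "DD")])}
    s1 = concatenate(alns, ["t1", "t2"], family_order=["f1", "f2"])
    s2 = concatenate(alns, ["t1", "t2"], family_order=["f2", "f1"])
    for t in ("t1", "t2"):
        assert sorted(dict(s1.members)[t]) == sorted(dict(s2.members)[t])
    assert s1.length == s2.length


def test_concatenate_taxon_absent_everywhere_is_error():
    alns = {"f1": _aln("f1", 5, ["t1", "t2"])}
    with pytest.raises(ValueError, match="absent from every family"):
        concatenate(alns, ["t1", "t2", "t3"])


def test_filter_then_concatenate_additivity_and_idempotence():
    rng = np.random.default_rng(0)
    alns = {}
    taxa = ["t1", "t2", "t3", "t4"]
    for fam in ("f1", "f2", "f3"):
        rows = []
        for t in taxa:
            chars = rng.choice(list("ACDE-"), size=20, p=[0.2, 0.2, 0.2, 0.2, 0.2])
            rows.append((t, "".join(chars)))
        # ensure no all-gap member
        rows = [(t, ("A" + s[1:]) if set(s) == {"-"} else s) for t, s in rows]
        alns[fam] = SeedAlignment(fam, rows)
    filtered = {f: filter_gap_columns(a)[0] for f, a in alns.items()}
    sup = concatenate(filtered, taxa)
    assert sup.length == sum(a.length for a in filtered.values())
    for f, a in filtered.items():
        again, kept = filter_gap_columns(a)
        assert again.members == a.members
        assert len(kept) == a.length


# ---------------------------------------------------------------------------
# rooting and NJ

def _root_depths(tree):
    return {l.taxon.label: l.distance_from_root()
            for l in tree.leaf_node_iter()}


def test_midpoint_root_balanced_tree():
    tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
    rooted = midpoint_root(tree)
    depths = _root_depths(rooted)
    assert all(abs(d - 2.0) < 1e-9 for d in depths.values())


def test_midpoint_root_caterpillar_long_terminal():
    # diameter path ends on E's 10-unit pendant edge; midpoint sits on it
    tree = read_tree("((((A:1,B:1):1,C:1):1,D:1):1,E:10);")
    rooted = midpoint_root(tree)
    depths = _root_depths(rooted)
    diameter = 10 + 1 + 1 + 1 + 1  # E to A/B
    assert depths["E"] == pytest.approx(diameter / 2)
    assert max(depths.values()) == pytest.approx(diameter / 2)


def test_midpoint_root_idempotent():
    tree = read_tree("((((A:1,B:2):1,C:1):2,D:1):1,E:7);")
    once = midpoint_root(tree)
    twice = midpoint_root(once)
    d1, d2 = _root_depths(once), _root_depths(twice)
    assert set(d1) == set(d2)
    for k in d1:
        assert d1[k] == pytest.approx(d2[k])


def test_midpoint_root_requires_lengths():
    tree = read_tree("((A,B),(C,D));")
    with pytest.raises(ValueError, match="branch lengths"):
        midpoint_root(tree)


def test_nj_recovers_additive_four_taxon_metric():
    # tree ((a:2,b:3):1,c:4,d:5) gives an additive metric
    d = pd.DataFrame(
        [[0, 5, 7, 8],
         [5, 0, 8, 9],
         [7, 8, 0, 9],
         [8, 9, 9, 0]],
        index=list("abcd"), columns=list("abcd"), dtype=float,
    )
    tree = nj_tree(d)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for x, y in itertools.combinations("abcd", 2):
        assert pdm.distance(taxa[x], taxa[y]) == pytest.approx(d.loc[x, y])


def test_nj_label_permutation_invariance():
    rng = np.random.default_rng(4)
    base = rng.uniform(1, 10, size=(5, 5))
    d = (base + base.T) / 2
    np.fill_diagonal(d, 0)
    taxa = list("abcde")
    df1 = pd.DataFrame(d, index=taxa, columns=taxa)
    perm = ["c", "a", "e", "b", "d"]
    df2 = df1.loc[perm, perm]
    t1, t2 = nj_tree(df1), nj_tree(df2)
    d1 = t1.phylogenetic_distance_matrix()
    d2 = t2.phylogenetic_distance_matrix()
    tax1 = {t.label: t for t in t1.taxon_namespace}
    tax2 = {t.label: t for t in t2.taxon_namespace}
    for x, y in itertools.combinations(taxa, 2):
        assert d1.distance(tax1[x], tax1[y]) == pytest.approx(
            d2.distance(tax2[x], tax2[y])
        )


def test_nj_needs_three_taxa():
    d = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(d)


# ---------------------------------------------------------------------------
# Dollo

def test_dollo_all_present_gains_at_root():
    tree = read_tree("((A,B),(C,D));")
    rec = dollo_reconstruct(tree, {l: 1 for l in "ABCD"})
    assert rec.gain_edge == "root"
    assert rec.n_losses == 0


def test_dollo_single_leaf_gain_on_pendant_edge():
    tree = read_tree("((A,B),(C,D));")
    rec = dollo_reconstruct(tree, {"A": 0, "B": 0, "C": 1, "D": 0})
    assert rec.gain_edge == "C"
    assert rec.n_losses == 0


def test_dollo_six_leaf_two_losses():
    tree = read_tree("(((A,B),(C,D)),(E,F));")
    presence = {"A": 1, "B": 1, "C": 0, "D": 0, "E": 1, "F": 0}
    rec = dollo_reconstruct(tree, presence)
    assert rec.gain_edge == "root"
    assert rec.loss_edges == {"C|2", "F"}
    assert rec.n_losses == 2
    assert replay_reconstruction(tree, rec) == presence


def test_dollo_all_absent_is_error():
    tree = read_tree("((A,B),(C,D));")
    with pytest.raises(ValueError, match="absent everywhere"):
        dollo_reconstruct(tree, {l: 0 for l in "ABCD"})


def test_dollo_polytomy_support():
    tree = read_tree("((A,B,C),(D,E),F);")
    presence = {"A": 1, "B": 0, "C": 1, "D": 0, "E": 0, "F": 1}
    rec = dollo_reconstruct(tree, presence)
    assert rec.gain_edge == "root"
    assert rec.loss_edges == {"B", "D|2"}
    assert replay_reconstruction(tree, rec) == presence


def test_dollo_replay_consistency_random_patterns():
    tree = read_tree("(((A,B),(C,D)),((E,F),(G,H)));")
    leaves = list("ABCDEFGH")
    rng = np.random.default_rng(0)
    for _ in range(100):
        bits = rng.integers(0, 2, size=8)
        if bits.sum() == 0:
            continue
        presence = dict(zip(leaves, map(int, bits)))
        rec = dollo_reconstruct(tree, presence)
        assert replay_reconstruction(tree, rec) == presence
        # no loss edge is ancestral to another within the gained subtree
        ids = edge_ids(tree)
        for e1, e2 in itertools.permutations(rec.loss_edges, 2):
            n1, n2 = ids[e1], ids[e2]
            assert n2 not in [x for x in n1.preorder_iter() if x is not n1]


def test_gainloss_report_conservation():
    tree = read_tree("((A,B),(C,D));")
    counts = pd.DataFrame(
        {"F1": [1, 1, 1, 1], "F2": [1, 1, 0, 0], "F3": [0, 1, 0, 0]},
        index=list("ABCD"),
    )
    per_family, per_branch = gainloss_report(tree, PhyleticMatrix(counts))
    assert per_family.set_index("family_id")["ancestral"].to_dict() == {
        "F1": True, "F2": False, "F3": False,
    }
    # F2 is confined to the (A,B) clade: gained at its stem, no losses
    assert per_family.set_index("family_id").loc["F2", "gain_edge"] == "A|2"
    assert per_branch["n_lost"].sum() == per_family["n_losses"].sum()
    assert per_branch["n_gained"].sum() == len(counts.columns)
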