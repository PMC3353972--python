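"""Concatenated alignments, tree handling and Dollo gain/loss mapping.

Dollo parsimony models a complex character (here: possession of an
r-protein family) that is gained at most once on the tree and subsequently
lost any number of times.  For a rooted species tree and a presence/absence
pattern over the leaves, the most parsimonious scenario places the single
gain on the edge above the last common ancestor of all present leaves and a
loss on the edge above every maximal all-absent subtree inside the gained
clade; this minimises the loss count.  Trees may contain polytomies.

Edges are identified by their child node: a pendant edge by the leaf label,
an internal edge by "<smallest leaf label below>|<number of leaves below>",
which is unique within a tree; the virtual edge above the root is "root".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .census import PhyleticMatrix
from .profiles import SeedAlignment

__all__ = [
    "DolloReconstruction",
    "read_tree",
    "write_tree",
    "filter_gap_columns",
    "concatenate",
    "midpoint_root",
    "dollo_reconstruct",
    "replay_reconstruction",
    "gainloss_report",
    "nj_tree",
    "edge_ids",
]


@dataclass
class DolloReconstruction:
    """Single-gain, minimal-loss history of one family on a rooted tree."""

    family_id: str
    gain_edge: str            # edge id, or "root"
    loss_edges: frozenset[str]

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


# ---------------------------------------------------------------------------
# Trees

def read_tree(source: str | Path, schema: str = "newick") -> dendropy.Tree:
    """Read a tree from a file path or a literal newick string."""
    text = None
    p = Path(str(source))
    if p.exists():
        text = p.read_text()
    else:
        text = str(source)
    return dendropy.Tree.get(
        data=text, schema=schema, rooting="default-rooted",
        preserve_underscores=True,
    )


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", unquoted_underscores=True)
    )


def _leaf_stats(tree: dendropy.Tree) -> dict:
    """Per node: (min leaf label, n leaves, n present slots unused)."""
    stats = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            stats[node] = (label, 1)
        else:
            kids = [stats[c] for c in node.child_nodes()]
            stats[node] = (min(k[0] for k in kids), sum(k[1] for k in kids))
    return stats


def edge_ids(tree: dendropy.Tree) -> dict:
    """Map edge id string -> child node, for every edge below the root."""
    stats = _leaf_stats(tree)
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        label, n = stats[node]
        out[label if n == 1 else f"{label}|{n}"] = node
    return out


def _edge_id(node, stats) -> str:
    label, n = stats[node]
    return label if n == 1 else f"{label}|{n}"


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Requires strictly positive branch lengths; returns a new tree.  Ties on
    the diameter break on the lexicographically smallest leaf-label pair, so
    the result is deterministic.
    """
    t = tree.clone(depth=1)
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            raise ValueError("midpoint rooting requires positive branch lengths")

    def label(leaf):
        return leaf.taxon.label if leaf.taxon else leaf.label

    def path_to_root(leaf):
        path = [(leaf, 0.0)]
        node, dist = leaf, 0.0
        while node.parent_node is not None:
            dist += node.edge.length
            node = node.parent_node
            path.append((node, dist))
        return path

    leaves = sorted(t.leaf_node_iter(), key=label)
    paths = {label(l): path_to_root(l) for l in leaves}

    best = None  # (diameter, label_u, label_v, joint path u -> v)
    for i, u in enumerate(leaves):
        pu = paths[label(u)]
        anc_u = {id(n): d for n, d in pu}
        for v in leaves[i + 1:]:
            pv = paths[label(v)]
            mrca_d = None
            for n, dv in pv:
                if id(n) in anc_u:
                    mrca_d = (anc_u[id(n)], dv, n)
                    break
            du, dv, mrca = mrca_d
            diam = du + dv
            key = (-diam, label(u), label(v))
            if best is None or key < best[0]:
                up = [(n, d) for n, d in pu if d <= du]
                down = [(n, diam - d) for n, d in pv if d < dv][::-1]
                best = (key, diam, up + down)
    _, diameter, path = best
    half = diameter / 2.0
    for k, (node, d) in enumerate(path):
        if abs(d - half) < 1e-12:
            if node is not t.seed_node:
                t.reroot_at_node(node, update_bipartitions=True)
            return t
        if d > half:
            prev_node, prev_d = path[k - 1]
            child = node if node.parent_node is prev_node else prev_node
            into = half - prev_d  # distance from prev_node into the edge
            elen = child.edge.length
            if child is node:
                tail_part, head_part = into, elen - into
            else:
                tail_part, head_part = elen - into, into
            t.reroot_at_edge(
                child.edge, length1=tail_part, length2=head_part,
                update_bipartitions=True,
            )
            return t
    raise AssertionError("midpoint not found on diameter path")


def nj_tree(distances: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix (DataFrame).

    Wraps scikit-bio's NJ; the result is unrooted (trifurcating root node).
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    d = distances.to_numpy(dtype=float)
    taxa = [str(t) for t in distances.index]
    if len(taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if list(distances.index) != list(distances.columns):
        raise ValueError("distance matrix rows and columns must match")
    if not np.isfinite(d).all() or not np.allclose(d, d.T) or np.diag(d).any():
        raise ValueError("distance matrix must be finite, symmetric, zero-diagonal")
    import io

    buf = io.StringIO()
    nj(DistanceMatrix(d, taxa)).write(buf)
    newick = buf.getvalue()
    return dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-unrooted",
        preserve_underscores=True,
    )


# ---------------------------------------------------------------------------
# Alignment concatenation

def filter_gap_columns(
    aln: SeedAlignment, max_gap_fraction: float = 0.5
) -> tuple[SeedAlignment, np.ndarray]:
    """Keep columns whose gap fraction is strictly below the threshold.

    Returns the filtered alignment and the kept original column indices.
    """
    n = len(aln.members)
    kept = []
    for c in range(aln.length):
        gaps = sum(1 for _, s in aln.members if s[c] == "-")
        if gaps / n < max_gap_fraction:
            kept.append(c)
    if not kept:
        raise ValueError(f"{aln.family_id}: no columns survive the gap filter")
    members = [(t, "".join(s[c] for c in kept)) for t, s in aln.members]
    return (
        SeedAlignment(
            family_id=aln.family_id,
            members=members,
            domain_class=aln.domain_class,
            rare_family=aln.rare_family,
        ),
        np.array(kept, dtype=np.int64),
    )


def concatenate(
    alignments: dict[str, SeedAlignment],
    taxa: list[str],
    family_order: list[str] | None = None,
) -> SeedAlignment:
    """Concatenate per-family alignments into one supermatrix row per taxon.

    Each family alignment must have at most one row per taxon (primary calls
    only).  Taxa missing a family receive an all-gap block of that family's
    width.  A taxon absent from every family is an error.
    """
    order = family_order if family_order is not None else sorted(alignments)
    rows = {t: [] for t in taxa}
    coverage = {t: 0 for t in taxa}
    for fam in order:
        aln = alignments[fam]
        width = aln.length
        by_taxon = {}
        for t, s in aln.members:
            if t in by_taxon:
                raise ValueError(f"{fam}: duplicate row for taxon {t}")
            by_taxon[t] = s
        for t in taxa:
            if t in by_taxon:
                rows[t].append(by_taxon[t])
                coverage[t] += 1
            else:
                rows[t].append("-" * width)
    empty = [t for t in taxa if coverage[t] == 0]
    if empty:
        raise ValueError(f"taxa absent from every family: {empty}")
    return SeedAlignment(
        family_id="concatenation",
        members=[(t, "".join(rows[t])) for t in taxa],
    )


# ---------------------------------------------------------------------------
# Dollo parsimony

def dollo_reconstruct(
    tree: dendropy.Tree, presence: dict[str, int], family_id: str = ""
) -> DolloReconstruction:
    """Most parsimonious single-gain/multiple-loss history of one family.

    ``presence`` maps every leaf label to 0/1.  The gain is placed on the
    edge above the LCA of the present leaves ("root" when that is the root);
    losses are the edges above the maximal all-absent subtrees within the
    gained clade.
    """
    stats = _leaf_stats(tree)
    leaves = [stats[l][0] for l in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in presence]
    if missing:
        raise ValueError(f"presence undefined for leaves {missing}")

    n_present: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            n_present[node] = int(bool(presence[stats[node][0]]))
        else:
            n_present[node] = sum(n_present[c] for c in node.child_nodes())
    total = n_present[tree.seed_node]
    if total == 0:
        raise ValueError(f"family {family_id or '?'} absent everywhere")

    # LCA of present leaves: descend while a single child holds them all
    lca = tree.seed_node
    while True:
        carrier = [c for c in lca.child_nodes() if n_present[c] == total]
        if len(carrier) == 1 and n_present[lca] == total:
            lca = carrier[0]
        else:
            break
    gain_edge = "root" if lca is tree.seed_node else _edge_id(lca, stats)

    losses = []
    stack = [lca]
    while stack:
        node = stack.pop()
        for child in node.child_nodes():
            if n_present[child] == 0:
                losses.append(_edge_id(child, stats))
            else:
                stack.append(child)
    return DolloReconstruction(
        family_id=family_id,
        gain_edge=gain_edge,
        loss_edges=frozenset(losses),
    )


def replay_reconstruction(
    tree: dendropy.Tree, rec: DolloReconstruction
) -> dict[str, int]:
    """Leaf pattern implied by a (gain, losses) scenario, for verification."""
    stats = _leaf_stats(tree)
    ids = edge_ids(tree)
    gain_node = tree.seed_node if rec.gain_edge == "root" else ids[rec.gain_edge]
    state: dict = {}
    out: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            s = 1 if gain_node is tree.seed_node else 0
        else:
            s = state[node.parent_node]
            if node is gain_node:
                s = 1
            if _edge_id(node, stats) in rec.loss_edges:
                s = 0
        state[node] = s
        if node.is_leaf():
            out[stats[node][0]] = s
    return out


def gainloss_report(
    tree: dendropy.Tree, matrix: PhyleticMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-family gain/loss table and per-branch event table.

    The matrix is binarized (presence <=> count >= 1); its genomes must
    match the tree's leaves.  A family is *ancestral* when its gain maps to
    the root.
    """
    leaves = sorted(
        (l.taxon.label if l.taxon else l.label) for l in tree.leaf_node_iter()
    )
    if sorted(matrix.genomes) != leaves:
        raise ValueError("matrix genomes do not match tree leaves")
    binary = matrix.binarized()
    fam_rows = []
    branch_gain: dict[str, list[str]] = {}
    branch_loss: dict[str, list[str]] = {}
    for fam in matrix.families:
        rec = dollo_reconstruct(tree, binary[fam].to_dict(), family_id=fam)
        fam_rows.append({
            "family_id": fam,
            "gain_edge": rec.gain_edge,
            "loss_edges": ",".join(sorted(rec.loss_edges)),
            "n_losses": rec.n_losses,
            "ancestral": rec.gain_edge == "root",
        })
        branch_gain.setdefault(rec.gain_edge, []).append(fam)
        for e in rec.loss_edges:
            branch_loss.setdefault(e, []).append(fam)
    edges = ["root"] + sorted(edge_ids(tree))
    branch_rows = [{
        "edge_id": e,
        "n_gained": len(branch_gain.get(e, [])),
        "n_lost": len(branch_loss.get(e, [])),
        "gained_families": ",".join(sorted(branch_gain.get(e, []))),
        "lost_families": ",".join(sorted(branch_loss.get(e, []))),
    } for e in edges]
    return pd.DataFrame(fam_rows), pd.DataFrame(branch_rows)
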