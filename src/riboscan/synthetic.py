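"""Synthetic data with known ground truth for every pipeline stage.

Three generators: protein families (a consensus plus diverged members,
giving a seed alignment whose true alignment is known by construction),
genomes with planted r-protein genes (back-translated, optionally
frameshifted, embedded in random intergenic sequence), and gain/loss
histories simulated on a rooted tree under a Dollo regime (at most one gain
per family, losses as a Poisson process on descendant edges).

Everything is deterministic given (seed, parameters), and every generator
emits machine-readable truth alongside the data.  Gene placement is uniform
(no operon structure) and back-translation uses uniform synonymous codons;
both are adequate because the search pipeline operates on amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import _align
from .genomes import Genome, Replicon, reverse_complement
from .profiles import BLOSUM62_BACKGROUND, SeedAlignment, blosum62_conditional
from Bio.Data import CodonTable

__all__ = [
    "TruthSet",
    "make_family",
    "plant_genome",
    "simulate_gainloss",
    "random_tree",
]

AA_ORDER = _align.AA_ORDER
_NT = "ACGT"


@dataclass
class TruthSet:
    """Planted-gene table (one row per planted gene) plus optional tree truth.

    Columns: genome_id, family_id, replicon_id, strand, nt_start, nt_end
    (0-based half-open, forward strand, including start and stop codons),
    divergence, rank_truth, frameshifted, protein.
    """

    planted_genes: pd.DataFrame
    tree_truth: tuple[dendropy.Tree, pd.DataFrame] | None = None


def _mutate(
    protein_idx: np.ndarray, divergence: float, rng: np.random.Generator,
    cond: np.ndarray,
) -> np.ndarray:
    """Substitute residues at expected ``divergence`` substitutions/site.

    A site mutates with probability 1 - exp(-d); the replacement is drawn
    from BLOSUM62 conditional probabilities given the current residue,
    excluding the identity.
    """
    out = protein_idx.copy()
    if divergence <= 0:
        return out
    p_sub = 1.0 - np.exp(-divergence)
    for i in np.flatnonzero(rng.random(out.size) < p_sub):
        b = out[i]
        probs = cond[b].copy()
        probs[b] = 0.0
        probs /= probs.sum()
        out[i] = rng.choice(20, p=probs)
    return out


def _idx_to_aa(idx: np.ndarray) -> str:
    return "".join(AA_ORDER[i] for i in idx)


def make_family(
    seed: int,
    n_members: int = 8,
    length: int = 120,
    divergence: float = 0.3,
    indel_rate: float = 0.01,
) -> tuple[SeedAlignment, str]:
    """Generate one family: a consensus protein and diverged, aligned members.

    Members are i.i.d. mutants of the consensus at the stated expected
    substitutions/site; single-residue indels occur at ``indel_rate``/site
    (half deletions, half insertions), so the induced alignment is exact by
    construction.  At divergence 0 members are exact copies.  Deterministic
    given ``seed``.
    """
    if n_members < 2:
        raise ValueError("need at least 2 members")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xFA31,)))
    cond = blosum62_conditional()
    consensus_idx = rng.choice(20, size=length, p=BLOSUM62_BACKGROUND)
    consensus = _idx_to_aa(consensus_idx)
    member_idx = [
        _mutate(consensus_idx, divergence, rng, cond) for _ in range(n_members)
    ]
    deletions = np.zeros((n_members, length), dtype=bool)
    insertions: list[tuple[int, int, int]] = []  # (site, member, residue)
    if divergence > 0 and indel_rate > 0:
        for m in range(n_members):
            r = rng.random(length)
            deletions[m] = r < indel_rate / 2.0
            for i in np.flatnonzero(r > 1.0 - indel_rate / 2.0):
                insertions.append((int(i), m, int(rng.choice(20, p=BLOSUM62_BACKGROUND))))
    # assemble aligned strings: base columns, plus one private column per insertion
    ins_by_site: dict[int, list[tuple[int, int]]] = {}
    for site, m, res in insertions:
        ins_by_site.setdefault(site, []).append((m, res))
    rows = [[] for _ in range(n_members)]
    for c in range(length):
        for m in range(n_members):
            rows[m].append("-" if deletions[m, c] else AA_ORDER[member_idx[m][c]])
        for m_ins, res in sorted(ins_by_site.get(c, [])):
            for m in range(n_members):
                rows[m].append(AA_ORDER[res] if m == m_ins else "-")
    members = [(f"member_{m:02d}", "".join(rows[m])) for m in range(n_members)]
    aln = SeedAlignment(family_id=f"fam{seed:04d}", members=members)
    return aln, consensus


def _back_translate(
    protein: str, rng: np.random.Generator, code_table: int
) -> str:
    """Uniform synonymous-codon back-translation, plus start and stop codons."""
    table = CodonTable.unambiguous_dna_by_id[code_table]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    codons = ["ATG"]
    for aa in protein:
        options = sorted(by_aa[aa])
        codons.append(options[rng.integers(len(options))])
    stops = sorted(table.stop_codons)
    codons.append(stops[rng.integers(len(stops))])
    return "".join(codons)


def plant_genome(
    seed: int,
    families: list[tuple[str, str, int, float]],
    frameshift_fraction: float = 0.0,
    intergenic_model: np.ndarray | None = None,
    genome_length: int = 100_000,
    n_replicons: int = 1,
    code_table: int = 11,
    genome_id: str | None = None,
    replicon_quota: list[int] | None = None,
) -> tuple[Genome, TruthSet]:
    """Plant diverged copies of family proteins into a random genome.

    ``families`` rows are (family_id, consensus_protein, n_copies,
    divergence).  Each copy is a substitution mutant of the consensus,
    back-translated with uniform synonymous codons, wrapped in ATG...stop,
    and placed uniformly without overlap on a random strand; with
    probability ``frameshift_fraction`` a single +-1 nt indel is injected
    near the gene's midpoint and recorded.  Intergenic sequence is i.i.d.
    from ``intergenic_model`` (default uniform).  Deterministic given seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x6E0E,)))
    cond = blosum62_conditional()
    gid = genome_id if genome_id is not None else f"synth{seed:04d}"
    model = (
        np.full(4, 0.25) if intergenic_model is None
        else np.asarray(intergenic_model, dtype=float)
    )
    model = model / model.sum()

    cassettes = []  # (family_id, divergence, protein, nt, frameshifted)
    for family_id, consensus, n_copies, divergence in families:
        cons_idx = np.array([AA_ORDER.index(a) for a in consensus])
        for _ in range(n_copies):
            prot_idx = _mutate(cons_idx, divergence, rng, cond)
            protein = _idx_to_aa(prot_idx)
            nt = _back_translate(protein, rng, code_table)
            frameshifted = bool(rng.random() < frameshift_fraction)
            if frameshifted:
                third = len(nt) // 3
                pos = int(rng.integers(third, 2 * third))
                if rng.random() < 0.5:
                    nt = nt[:pos] + _NT[rng.integers(4)] + nt[pos:]
                else:
                    nt = nt[:pos] + nt[pos + 1:]
            cassettes.append((family_id, divergence, protein, nt, frameshifted))

    n_genes = len(cassettes)
    if replicon_quota is not None:
        if sum(replicon_quota) != n_genes or len(replicon_quota) != n_replicons:
            raise ValueError("replicon_quota inconsistent with gene count")
        assignment = np.repeat(np.arange(n_replicons), replicon_quota)
    else:
        assignment = rng.integers(0, n_replicons, size=n_genes)
    order = rng.permutation(n_genes)

    rep_len = genome_length // n_replicons
    replicons = []
    truth_rows = []
    for r in range(n_replicons):
        idx = [k for k in order if assignment[k] == r]
        genes = [cassettes[k] for k in idx]
        total_gene_nt = sum(len(g[3]) for g in genes)
        slack = rep_len - total_gene_nt
        if slack < 10 * (len(genes) + 1):
            raise ValueError(
                f"infeasible packing: {total_gene_nt} nt of genes in a "
                f"{rep_len} nt replicon"
            )
        # intergenic gap lengths: multinomial split of the slack
        gaps = rng.multinomial(slack - 10 * (len(genes) + 1),
                               np.full(len(genes) + 1, 1.0 / (len(genes) + 1))) + 10
        rep_id = f"{gid}_rep{r}"
        parts = []
        pos = 0
        for g, gap in zip(genes, gaps[:-1]):
            parts.append("".join(rng.choice(list(_NT), size=gap, p=model)))
            pos += gap
            family_id, divergence, protein, nt, frameshifted = g
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(nt if strand == "+" else reverse_complement(nt))
            truth_rows.append({
                "genome_id": gid,
                "family_id": family_id,
                "replicon_id": rep_id,
                "strand": strand,
                "nt_start": pos,
                "nt_end": pos + len(nt),
                "divergence": divergence,
                "frameshifted": frameshifted,
                "protein": protein,
            })
            pos += len(nt)
        parts.append("".join(rng.choice(list(_NT), size=int(gaps[-1]), p=model)))
        replicons.append(Replicon(replicon_id=rep_id, sequence="".join(parts)))

    truth = pd.DataFrame(truth_rows, columns=[
        "genome_id", "family_id", "replicon_id", "strand", "nt_start",
        "nt_end", "divergence", "frameshifted", "protein",
    ])
    # expected rank: copies of a family ordered by divergence (ties: position)
    truth["rank_truth"] = (
        truth.sort_values(["divergence", "replicon_id", "nt_start"])
        .groupby("family_id").cumcount() + 1
    )
    genome = Genome(
        genome_id=gid, taxon_label=gid, replicons=replicons,
        code_table=code_table,
    )
    return genome, TruthSet(planted_genes=truth)


def random_tree(
    seed: int, n_leaves: int, mean_branch: float = 0.1
) -> dendropy.Tree:
    """Random rooted binary tree with exponential branch lengths."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x72EE,)))

    def nwk(labels):
        if len(labels) == 1:
            return labels[0], rng.exponential(mean_branch)
        k = int(rng.integers(1, len(labels)))
        left, llen = nwk(labels[:k])
        right, rlen = nwk(labels[k:])
        return f"({left}:{llen:.6f},{right}:{rlen:.6f})", rng.exponential(mean_branch)

    labels = [f"t{i:03d}" for i in range(n_leaves)]
    perm = [labels[i] for i in rng.permutation(n_leaves)]
    topo, _ = nwk(perm)
    return dendropy.Tree.get(
        data=topo + ";", schema="newick", rooting="default-rooted",
        preserve_underscores=True,
    )


def simulate_gainloss(
    seed: int,
    tree: dendropy.Tree,
    n_families: int,
    p_ancestral: float = 0.5,
    gain_rate: float = 1.0,
    loss_rate: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate single-gain / Poisson-loss histories on a rooted tree.

    Each family is ancestral (gained at the root) with probability
    ``p_ancestral``, otherwise gains once on an edge sampled proportional to
    branch length.  Loss events arrive as a Poisson process with rate
    ``loss_rate`` per unit branch length on every edge below the gain
    (including edges already below another loss, so nested events are
    possible and the true event count can exceed the parsimony minimum).
    Returns (presence matrix genomes x families, event table with one row
    per family: gain_edge, loss_edges with multiplicity, n_true_losses).
    """
    from .phylo import _leaf_stats, _edge_id

    if loss_rate < 0 or gain_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x6A15,)))
    stats = _leaf_stats(tree)
    nodes = list(tree.preorder_node_iter())
    non_root = [n for n in nodes if n is not tree.seed_node]
    lengths = np.array([
        (n.edge.length if n.edge.length is not None else 1.0) for n in non_root
    ], dtype=float)
    weights = gain_rate * lengths
    if weights.sum() == 0:
        weights = np.ones_like(weights)
    weights = weights / weights.sum()

    leaf_labels = [stats[l][0] for l in tree.leaf_node_iter()]
    presence = {}
    event_rows = []
    for f in range(n_families):
        fam = f"fam{f:05d}"
        if rng.random() < p_ancestral:
            gain_node = tree.seed_node
            gain_edge = "root"
        else:
            gain_node = non_root[int(rng.choice(len(non_root), p=weights))]
            gain_edge = _edge_id(gain_node, stats)
        # descendant edges of the gain node
        loss_edges = []
        state = {gain_node: 1}
        pattern = {}
        for node in tree.preorder_node_iter():
            if node is gain_node:
                pass
            elif node.parent_node in state:
                s = state[node.parent_node]
                elen = node.edge.length if node.edge.length is not None else 1.0
                k = int(rng.poisson(loss_rate * elen))
                if k > 0:
                    loss_edges.extend([_edge_id(node, stats)] * k)
                    s = 0
                state[node] = s
            else:
                continue
            if node.is_leaf():
                pattern[stats[node][0]] = state.get(node, 1 if node is gain_node else 0)
        full = {l: pattern.get(l, 0) for l in leaf_labels}
        presence[fam] = full
        event_rows.append({
            "family_id": fam,
            "gain_edge": gain_edge,
            "loss_edges": ",".join(loss_edges),
            "n_true_losses": len(loss_edges),
        })
    matrix = pd.DataFrame(presence, index=leaf_labels).astype(int)
    return matrix, pd.DataFrame(event_rows)
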