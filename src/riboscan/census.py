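"""Copy-number census of r-protein families across genomes.

Turns per-genome calls into the phyletic copy-number matrix (genomes x
families), ubiquity and paralog reports, the distribution of r-protein genes
over genome partitions, and the geometric-mean paralogy index computed on a
deduplicated set of representative genomes (one genus representative with
the largest genome, genomes with fewer than 500 protein-coding genes
excluded).

Percent identity between paralogs is a global alignment under BLOSUM62 with
gap open 11 / extend 1 and free terminal gaps; the denominator is the
shorter sequence's length, which keeps fragment paralogs comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _align
from .genomes import Genome
from .search import RProteinCall

__all__ = [
    "PhyleticMatrix",
    "ParalogRecord",
    "build_matrix",
    "ubiquity_report",
    "pairwise_identity",
    "classify_paralogs",
    "partition_report",
    "select_representatives",
    "paralogy_index",
    "read_phyletic_tsv",
    "write_phyletic_tsv",
    "read_phyletic_xlsx",
]


@dataclass
class PhyleticMatrix:
    """Genomes x families copy-number table."""

    counts: pd.DataFrame  # index = genome_ids, columns = family_ids, int

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate genome or family labels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative copy numbers")
        self.counts = self.counts.astype(int)

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    def binarized(self) -> pd.DataFrame:
        """Presence/absence view: presence <=> copy number >= 1."""
        return (self.counts >= 1).astype(int)


@dataclass
class ParalogRecord:
    genome_id: str
    family_id: str
    rank: int
    identity_to_primary: float
    identity_class: str  # {near_identical, intermediate, diverged}


def build_matrix(
    calls: list[RProteinCall],
    genome_ids: list[str],
    family_ids: list[str],
) -> PhyleticMatrix:
    """Count calls of every rank per (genome, family); absent cells are 0."""
    counts = pd.DataFrame(0, index=list(genome_ids), columns=list(family_ids))
    for c in calls:
        if c.genome_id not in counts.index:
            raise ValueError(f"call references unknown genome {c.genome_id}")
        if c.family_id not in counts.columns:
            raise ValueError(f"call references unknown family {c.family_id}")
        counts.loc[c.genome_id, c.family_id] += 1
    return PhyleticMatrix(counts)


def ubiquity_report(m: PhyleticMatrix) -> pd.DataFrame:
    """Per family: genomes present/missing and strict ubiquity."""
    present = (m.counts >= 1).sum(axis=0)
    n = len(m.genomes)
    return pd.DataFrame({
        "n_present": present,
        "n_missing": n - present,
        "strictly_ubiquitous": present == n,
    })


_SUB_EXT = None


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned residues, over the shorter length.

    Global alignment, BLOSUM62, gap open 11 / extend 1, terminal gaps free.
    Among co-optimal alignments the one with the most identities is scored,
    so the result is symmetric and deterministic.
    """
    global _SUB_EXT
    if not a or not b:
        raise ValueError("empty sequence")
    if _SUB_EXT is None:
        from .profiles import blosum62_matrix

        _SUB_EXT = _align.extend_substitution(blosum62_matrix())
    ea = _align.encode_protein(a)
    eb = _align.encode_protein(b)
    _, matches = _align.global_align_identity(_SUB_EXT, ea, eb, 11, 1)
    return int(matches) / min(len(a), len(b))


def classify_paralogs(
    calls: list[RProteinCall],
    near_identical: float = 0.97,
    diverged: float = 0.50,
) -> tuple[list[ParalogRecord], dict[str, int]]:
    """Classify every rank >= 2 call by identity to its primary.

    Strict inequalities, as conventionally printed: > 0.97 near-identical,
    < 0.50 diverged, the rest intermediate.
    """
    records = []
    summary = {"near_identical": 0, "intermediate": 0, "diverged": 0}
    for c in calls:
        if c.rank < 2:
            continue
        if c.identity_to_primary is None:
            raise ValueError(
                f"{c.genome_id}/{c.family_id} rank {c.rank}: missing identity"
            )
        ident = c.identity_to_primary
        if ident > near_identical:
            cls = "near_identical"
        elif ident < diverged:
            cls = "diverged"
        else:
            cls = "intermediate"
        summary[cls] += 1
        records.append(ParalogRecord(
            genome_id=c.genome_id,
            family_id=c.family_id,
            rank=c.rank,
            identity_to_primary=ident,
            identity_class=cls,
        ))
    return records, summary


def partition_report(
    calls: list[RProteinCall], genome: Genome
) -> tuple[pd.DataFrame, bool]:
    """Distinct families called per replicon, plus the multi-partition flag.

    A family with copies on several replicons counts once on each.
    ``multi_partition`` is true when two or more replicons carry calls.
    """
    per_replicon = {r.replicon_id: set() for r in genome.replicons}
    for c in calls:
        if c.genome_id != genome.genome_id:
            continue
        per_replicon[c.replicon_id].add(c.family_id)
    df = pd.DataFrame({
        "replicon_id": [r.replicon_id for r in genome.replicons],
        "role": [r.role for r in genome.replicons],
        "n_families": [len(per_replicon[r.replicon_id]) for r in genome.replicons],
    })
    multi = int((df["n_families"] >= 1).sum()) >= 2
    return df, multi


def select_representatives(
    metadata: pd.DataFrame,
    min_protein_coding: int = 500,
    genus_aliases: dict[str, str] | None = None,
    force_include: list[str] | None = None,
) -> list[str]:
    """One representative genome per genus, the one with the largest genome.

    ``metadata`` columns: genome_id, genus, n_protein_coding, genome_length.
    Genomes with fewer than ``min_protein_coding`` protein-coding genes are
    dropped first.  ``genus_aliases`` merges genera (e.g. Shigella ->
    Escherichia); ``force_include`` adds named genomes regardless of the
    per-genus rule.  Ties on size break on the lexicographically first
    genome_id.
    """
    required = {"genome_id", "genus", "n_protein_coding", "genome_length"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    bad = metadata["genus"].isna() | (metadata["genus"].astype(str).str.strip() == "")
    if bad.any():
        raise ValueError(
            "genomes without genus: "
            + ", ".join(metadata.loc[bad, "genome_id"].astype(str))
        )
    df = metadata.copy()
    aliases = genus_aliases or {}
    df["genus"] = df["genus"].map(lambda g: aliases.get(g, g))
    df = df[df["n_protein_coding"] >= min_protein_coding]
    df = df.sort_values(
        ["genus", "genome_length", "genome_id"],
        ascending=[True, False, True],
    )
    reps = df.groupby("genus", sort=True).head(1)["genome_id"].tolist()
    for gid in force_include or []:
        if gid not in reps:
            reps.append(gid)
    return sorted(reps)


def paralogy_index(
    m: PhyleticMatrix, representatives: list[str] | None = None
) -> float:
    """Geometric mean copy number over all occupied (genome, family) cells.

    Zero cells are excluded: an absent gene is no evidence about paralogy.
    Restricting to representative genomes removes sequencing-sampling bias.
    """
    counts = m.counts
    if representatives is not None:
        counts = counts.loc[[g for g in m.genomes if g in set(representatives)]]
    vals = counts.to_numpy().ravel()
    vals = vals[vals >= 1]
    if vals.size == 0:
        raise ValueError("phyletic matrix has no occupied cells")
    return float(np.exp(np.mean(np.log(vals))))


# ---------------------------------------------------------------------------
# IO

def write_phyletic_tsv(m: PhyleticMatrix, path: str | Path) -> None:
    m.counts.to_csv(path, sep="\t", index_label="genome_id")


def read_phyletic_tsv(path: str | Path) -> PhyleticMatrix:
    return PhyleticMatrix(pd.read_csv(path, sep="\t", index_col="genome_id"))


def read_phyletic_xlsx(
    path: str | Path, sheet: int | str = 0, index_col: int = 0
) -> PhyleticMatrix:
    """Ingest a published phyletic copy-number table from an XLS/XLSX sheet."""
    df = pd.read_excel(path, sheet_name=sheet, index_col=index_col)
    df = df.apply(pd.to_numeric, errors="coerce").fillna(0).astype(int)
    return PhyleticMatrix(df)
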