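"""Genome input, six-frame conceptual translation and ORF extraction.

A genome is a set of replicons (chromosomes and plasmids).  Each replicon is
translated in all six frames under its genome's NCBI genetic-code table, and
open reading frames are extracted as the span from the *first start codon* to
the first in-frame stop codon of each stop-delimited segment, keeping frames
of at least 16 codons by default.  This deliberately over-calls relative to a
gene predictor: the downstream profile search, not the ORF caller, decides
what is a ribosomal protein, so short and unannotated genes are not lost.

Coordinates are 0-based half-open on the forward strand throughout the
library; report writers convert to 1-based inclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "Genome",
    "Replicon",
    "Orf",
    "read_genome",
    "translate_frame",
    "extract_orfs",
    "reverse_complement",
    "write_orfs_fasta",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_NT_ALPHABET = frozenset(_IUPAC)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)

_NT_INDEX = np.full(128, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _NT_INDEX[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Replicon:
    """One genome partition: a chromosome, secondary chromosome or plasmid."""

    replicon_id: str
    sequence: str
    topology: str = "linear"  # {linear, circular}
    role: str = "unknown"     # {chromosome, plasmid, unknown}

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"replicon {self.replicon_id}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _NT_ALPHABET
        if bad:
            raise ValueError(
                f"replicon {self.replicon_id}: non-nucleotide characters "
                f"{sorted(bad)}"
            )


@dataclass
class Genome:
    """A taxon's replicon set plus its genetic-code table."""

    genome_id: str
    taxon_label: str
    replicons: list[Replicon]
    code_table: int = 11

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValueError(f"genome {self.genome_id}: no replicons")
        ids = [r.replicon_id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValueError(f"genome {self.genome_id}: duplicate replicon ids")
        _get_table(self.code_table)

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(replicon_id)


@dataclass(frozen=True)
class Orf:
    """One open reading frame, coordinates on the forward replicon strand.

    ``frame`` is the 0..2 offset on the ORF's own strand (for '-' the frame
    is counted on the reverse complement).  ``nt_start``/``nt_end`` are
    0-based half-open forward-strand coordinates excluding the stop codon.
    """

    orf_id: str
    genome_id: str
    replicon_id: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    aa_sequence: str
    started_at_start_codon: bool = True

    def __post_init__(self) -> None:
        if (self.nt_end - self.nt_start) % 3 != 0:
            raise ValueError(f"{self.orf_id}: length not divisible by 3")
        if len(self.aa_sequence) != (self.nt_end - self.nt_start) // 3:
            raise ValueError(f"{self.orf_id}: aa length inconsistent with span")


def _get_table(code_table: int) -> CodonTable.CodonTable:
    try:
        return CodonTable.unambiguous_dna_by_id[code_table]
    except KeyError:
        supported = sorted(CodonTable.unambiguous_dna_by_id)
        raise ValueError(
            f"unsupported genetic-code table {code_table}; "
            f"supported NCBI tables: {supported}"
        ) from None


class _TableData:
    """Precomputed lookup arrays for one genetic-code table."""

    def __init__(self, code_table: int) -> None:
        table = _get_table(code_table)
        self.aa_lut = np.full(64, ord("X"), dtype=np.uint8)
        self.start_lut = np.zeros(64, dtype=bool)
        for codon, aa in table.forward_table.items():
            self.aa_lut[_codon_index(codon)] = ord(aa)
        for codon in table.stop_codons:
            self.aa_lut[_codon_index(codon)] = ord("*")
        for codon in table.start_codons:
            self.start_lut[_codon_index(codon)] = True
        self.forward = dict(table.forward_table)
        for codon in table.stop_codons:
            self.forward[codon] = "*"


def _codon_index(codon: str) -> int:
    a, b, c = (int(_NT_INDEX[ord(x)]) for x in codon)
    return 16 * a + 4 * b + c


_TABLE_CACHE: dict[int, _TableData] = {}


def _table_data(code_table: int) -> _TableData:
    if code_table not in _TABLE_CACHE:
        _TABLE_CACHE[code_table] = _TableData(code_table)
    return _TABLE_CACHE[code_table]


def _translate_ambiguous_codon(codon: str, data: _TableData) -> str:
    """Resolve an ambiguity-containing codon: unique residue or 'X'."""
    try:
        expansions = [_IUPAC[b] for b in codon]
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in codon {codon!r}")
    residues = {data.forward["".join(c)] for c in itertools.product(*expansions)}
    return residues.pop() if len(residues) == 1 else "X"


def _frame_arrays(seq: str, frame: int, data: _TableData):
    """Codon-wise translation of one frame of an (already oriented) strand.

    Returns (aa uint8 array, is_start bool array, ambiguous positions list).
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[frame:]
    n_codons = raw.size // 3
    raw = raw[: n_codons * 3]
    idx = _NT_INDEX[raw].reshape(n_codons, 3)
    ambiguous = idx.max(axis=1) >= 4
    codon_idx = idx[:, 0] * 16 + idx[:, 1] * 4 + idx[:, 2]
    codon_idx[ambiguous] = 0
    aa = data.aa_lut[codon_idx]
    is_start = data.start_lut[codon_idx]
    if ambiguous.any():
        s = seq[frame:]
        for p in np.flatnonzero(ambiguous):
            codon = s[3 * p: 3 * p + 3]
            aa[p] = ord(_translate_ambiguous_codon(codon, data))
        is_start[ambiguous] = False  # an ambiguous codon is never a start
    return aa, is_start


def translate_frame(sequence: str, strand: str, frame: int, code_table: int) -> str:
    """Conceptually translate one frame; '*' marks stops, 'X' unresolved codons.

    For strand '-', the reverse complement is translated.  The trailing
    partial codon is dropped.  A codon containing ambiguity codes is
    translated to the unique residue all its resolutions share, else 'X'.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0..2, got {frame!r}")
    data = _table_data(code_table)
    seq = sequence.upper()
    if strand == "-":
        seq = reverse_complement(seq)
    aa, _ = _frame_arrays(seq, frame, data)
    return aa.tobytes().decode("ascii")


def extract_orfs(genome: Genome, min_len: int = 16) -> list[Orf]:
    """Extract all six-frame ORFs of at least ``min_len`` amino acids.

    Each stop-delimited segment contributes at most one ORF, running from its
    first start codon (start-codon set of the genome's code table) to the
    segment's stop codon; the stop is excluded from sequence and coordinates.
    Segments without a start codon, or not terminated by a stop, yield
    nothing.  Circular replicons are treated as linear (no origin-spanning
    ORFs).  The first codon is rendered as 'M' regardless of which start
    codon it is.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    data = _table_data(genome.code_table)
    orfs: list[Orf] = []
    for rep in genome.replicons:
        fwd = rep.sequence
        L = len(fwd)
        rev = reverse_complement(fwd)
        for strand, seq in (("+", fwd), ("-", rev)):
            for frame in range(3):
                aa, is_start = _frame_arrays(seq, frame, data)
                stops = np.flatnonzero(aa == ord("*"))
                if stops.size == 0:
                    continue
                start_pos = np.flatnonzero(is_start)
                seg_begin = 0
                for stop in stops:
                    # first start codon within [seg_begin, stop)
                    k = np.searchsorted(start_pos, seg_begin)
                    if k < start_pos.size and start_pos[k] < stop:
                        first = int(start_pos[k])
                        if stop - first >= min_len:
                            aa_seq = "M" + aa[first + 1: stop].tobytes().decode("ascii")
                            s_local = frame + 3 * first
                            e_local = frame + 3 * int(stop)
                            if strand == "+":
                                nt_start, nt_end = s_local, e_local
                            else:
                                nt_start, nt_end = L - e_local, L - s_local
                            orf_id = (
                                f"{genome.genome_id}|{rep.replicon_id}|{strand}"
                                f"|{frame}|{nt_start}|{nt_end}"
                            )
                            orfs.append(
                                Orf(
                                    orf_id=orf_id,
                                    genome_id=genome.genome_id,
                                    replicon_id=rep.replicon_id,
                                    strand=strand,
                                    frame=frame,
                                    nt_start=int(nt_start),
                                    nt_end=int(nt_end),
                                    aa_sequence=aa_seq,
                                )
                            )
                    seg_begin = int(stop) + 1
    return orfs


def read_genome(
    path: str | Path,
    code_table: int = 11,
    genome_id: str | None = None,
    taxon_label: str | None = None,
    roles: dict[str, str] | None = None,
) -> Genome:
    """Read one genome from a multi-FASTA file (one record per replicon).

    Record ids become replicon ids, in file order; sequences are uppercased.
    An empty file or a record with non-nucleotide characters is an error.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    gid = genome_id if genome_id is not None else path.stem
    replicons = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - _NT_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} has non-nucleotide characters "
                f"{sorted(bad)}"
            )
        role = (roles or {}).get(rec.id, "unknown")
        replicons.append(Replicon(replicon_id=rec.id, sequence=seq, role=role))
    return Genome(
        genome_id=gid,
        taxon_label=taxon_label if taxon_label is not None else gid,
        replicons=replicons,
        code_table=code_table,
    )


def read_genome_metadata(path: str | Path) -> dict[str, dict]:
    """Read the per-genome metadata TSV.

    Columns: genome_id, taxon_label, code_table; optional genus,
    n_protein_coding, genome_length for representative selection.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "taxon_label", "code_table"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        entry = {
            "taxon_label": row["taxon_label"],
            "code_table": int(row["code_table"]),
        }
        for opt in ("genus", "n_protein_coding", "genome_length"):
            if opt in df.columns and not pd.isna(row[opt]):
                entry[opt] = row[opt] if opt == "genus" else int(row[opt])
        out[row["genome_id"]] = entry
    return out


def write_orfs_fasta(orfs: list[Orf], path: str | Path) -> None:
    """Write ORF amino-acid sequences; headers encode the genomic locus."""
    with open(path, "w") as fh:
        for orf in orfs:
            fh.write(f">{orf.orf_id}\n{orf.aa_sequence}\n")
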