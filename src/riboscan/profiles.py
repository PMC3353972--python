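"""Family profiles: seed alignments, PSSM construction and E-value statistics.

A ribosomal-protein family is described by a curated seed alignment.  The
alignment is turned into a position-specific scoring matrix (PSSM) of
integer half-bit log-odds scores using Henikoff position-based sequence
weights and BLOSUM62-derived pseudocounts, and the PSSM's score statistics
are calibrated empirically: random sequences drawn from the background
composition are aligned locally against the profile and a Gumbel law is
fitted to the resulting maximal scores, giving the Karlin-Altschul
parameters (lambda, K) used to convert raw scores into E-values

    E(S) = K * m * n * exp(-lambda * S)

with m the profile length and n the searched database size in residues.
Because gapped local alignment has no closed-form score statistics, the
empirical fit is the honest option, and the classic E-value thresholds
(1, 1e-4, 1e-2) are operating points of this engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from zlib import crc32 as _zlib_crc32

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from . import _align

__all__ = [
    "SeedAlignment",
    "Pssm",
    "sequence_weights",
    "build_pssm",
    "calibrate",
    "evalue",
    "bit_score",
    "read_seed_alignment",
    "read_family_metadata",
    "save_profiles",
    "load_profiles",
    "BLOSUM62_BACKGROUND",
    "blosum62_matrix",
    "blosum62_conditional",
]

AA_ORDER = _align.AA_ORDER
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
_EULER_GAMMA = 0.5772156649015329


def _crc32(text: str) -> int:
    return _zlib_crc32(text.encode("utf-8"))

# Standard BLOSUM62 amino-acid background frequencies (order = AA_ORDER),
# normalised to sum to 1.
_BG = np.array([
    0.074, 0.052, 0.045, 0.054, 0.025, 0.034, 0.054, 0.074, 0.026, 0.068,
    0.099, 0.058, 0.025, 0.047, 0.039, 0.057, 0.051, 0.013, 0.032, 0.073,
])
BLOSUM62_BACKGROUND = _BG / _BG.sum()


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as an int (20, 20) array in AA_ORDER (half-bit scores)."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20), dtype=np.int32)
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            out[i, j] = int(m[a, b])
    return out


def blosum62_conditional() -> np.ndarray:
    """Conditional substitution probabilities P(a | b) implied by BLOSUM62.

    The joint target frequencies are reconstructed from the half-bit scores,
    q_ab proportional to p_a * p_b * 2**(s_ab / 2) (q is symmetric), then
    conditioned: ``cond[b, a] = P(a | b)``; each row sums to 1.
    """
    s = blosum62_matrix().astype(float)
    p = BLOSUM62_BACKGROUND
    q = np.outer(p, p) * np.exp2(s / 2.0)
    q /= q.sum()
    return q / q.sum(axis=1, keepdims=True)


_conditional = blosum62_conditional


@dataclass
class SeedAlignment:
    """A curated, pre-aligned seed set for one r-protein family."""

    family_id: str
    members: list[tuple[str, str]]  # (taxon label, aligned sequence with '-')
    domain_class: str = "universal"  # {bacterial, archaeal, universal, lineage-specific}
    rare_family: bool = False  # absent from >20% of the species set

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"{self.family_id}: need >= 2 members")
        lengths = {len(s) for _, s in self.members}
        if len(lengths) != 1:
            raise ValueError(f"{self.family_id}: unequal aligned lengths")
        self.members = [(t, s.upper()) for t, s in self.members]
        for t, s in self.members:
            if not s.replace("-", ""):
                raise ValueError(f"{self.family_id}: member {t} is all gaps")

    @property
    def length(self) -> int:
        return len(self.members[0][1])

    @property
    def sequences(self) -> list[str]:
        """Ungapped member sequences."""
        return [s.replace("-", "") for _, s in self.members]


@dataclass
class Pssm:
    """A calibrated position-specific scoring matrix (half-bit log odds)."""

    family_id: str
    scores: np.ndarray  # (L, 20) int32
    background: np.ndarray  # (20,) frequencies summing to 1
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float | None = None
    K: float | None = None
    kept_columns: np.ndarray | None = None  # indices into the seed alignment
    rare_family: bool = False

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])

    @property
    def calibrated(self) -> bool:
        return self.lambda_ is not None and self.K is not None


def sequence_weights(aln: SeedAlignment) -> np.ndarray:
    """Henikoff position-based weights, normalised to sum to 1.

    In each column a member holding residue x receives 1 / (r * s) where r
    is the number of distinct residues in the column and s the count of x;
    gapped members receive nothing from that column.
    """
    n = len(aln.members)
    w = np.zeros(n)
    cols = np.array([list(s) for _, s in aln.members])
    for c in range(aln.length):
        col = cols[:, c]
        residues = col[col != "-"]
        if residues.size == 0:
            continue
        uniq, counts = np.unique(residues, return_counts=True)
        r = len(uniq)
        count_of = dict(zip(uniq, counts))
        for i in range(n):
            if col[i] != "-":
                w[i] += 1.0 / (r * count_of[col[i]])
    if w.sum() == 0:
        w[:] = 1.0
    return w / w.sum()


def build_pssm(
    aln: SeedAlignment,
    pseudocount_weight: float = 10.0,
    background: np.ndarray | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> Pssm:
    """Build a half-bit PSSM from a seed alignment.

    Columns gapped in more than half of the members are dropped.  Per kept
    column, observed residue frequencies come from Henikoff-weighted counts;
    they are blended with BLOSUM62-implied pseudocount frequencies
    g_a = sum_b f_b P(a|b) as q = (alpha*f + beta*g) / (alpha + beta), where
    alpha is the column's effective observation count (distinct residues
    minus one) and beta = ``pseudocount_weight``.  Scores are
    round(2 * log2(q / background)).
    """
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    bg = BLOSUM62_BACKGROUND if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    weights = sequence_weights(aln)
    cond = _conditional()
    n = len(aln.members)
    kept = []
    rows = []
    for c in range(aln.length):
        col = [s[c] for _, s in aln.members]
        gap_fraction = col.count("-") / n
        if gap_fraction > 0.5:
            continue
        f = np.zeros(20)
        for i, ch in enumerate(col):
            if ch == "-":
                continue
            idx = _AA_INDEX.get(ch)
            if idx is None:  # X or ambiguity in the seed: ignore
                continue
            f[idx] += weights[i]
        if f.sum() == 0:
            continue
        f /= f.sum()
        alpha = max(np.count_nonzero(f) - 1, 0)
        g = f @ cond  # g[a] = sum_b f[b] P(a|b)
        q = (alpha * f + pseudocount_weight * g) / (alpha + pseudocount_weight)
        rows.append(np.round(2.0 * np.log2(q / bg)).astype(np.int32))
        kept.append(c)
    if not rows:
        raise ValueError(f"{aln.family_id}: seed alignment too gappy")
    return Pssm(
        family_id=aln.family_id,
        scores=np.vstack(rows),
        background=bg,
        gap_open=gap_open,
        gap_extend=gap_extend,
        kept_columns=np.array(kept, dtype=np.int64),
        rare_family=aln.rare_family,
    )


def calibrate(
    pssm: Pssm,
    decoy_count: int = 500,
    decoy_length: int = 200,
    seed: int = 0,
) -> Pssm:
    """Fit Gumbel (lambda, K) by scoring random background sequences.

    ``decoy_count`` i.i.d. sequences of ``decoy_length`` residues are drawn
    from the profile's background and aligned locally against the profile.
    Method-of-moments on the maximal scores: lambda = pi / (sigma * sqrt 6)
    and the Gumbel location mu = mean - gamma / lambda, with
    K = exp(lambda * mu) / (m * n).  Deterministic given the seed.
    """
    if decoy_count < 200:
        raise ValueError("decoy_count must be >= 200 for a stable fit")
    # salt the stream with the family id so equal seeds never reuse the
    # stream that generated other data (or another family's decoys)
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(0xCA11B, _crc32(pssm.family_id)))
    )
    ext = _align.extend_scores(pssm.scores)
    draws = rng.choice(20, size=(decoy_count, decoy_length), p=pssm.background)
    cat = draws.astype(np.int8).ravel()
    offsets = np.arange(decoy_count + 1, dtype=np.int64) * decoy_length
    scores = _align.sw_score_many(ext, cat, offsets, pssm.gap_open, pssm.gap_extend)
    scores = np.asarray(scores, dtype=float)
    sigma = scores.std()
    if sigma == 0:
        raise ValueError(f"{pssm.family_id}: degenerate decoy score variance")
    lam = math.pi / (sigma * math.sqrt(6.0))
    mu = scores.mean() - _EULER_GAMMA / lam
    K = math.exp(lam * mu) / (pssm.length * decoy_length)
    pssm.lambda_ = lam
    pssm.K = K
    return pssm


def evalue(pssm: Pssm, score: float, database_size: int) -> float:
    """Karlin-Altschul E-value of a raw score in a database of n residues."""
    if not pssm.calibrated:
        raise ValueError(f"{pssm.family_id}: PSSM is not calibrated")
    return pssm.K * pssm.length * database_size * math.exp(-pssm.lambda_ * score)


def bit_score(pssm: Pssm, score: float) -> float:
    """Normalised bit score (lambda*S - ln K) / ln 2."""
    if not pssm.calibrated:
        raise ValueError(f"{pssm.family_id}: PSSM is not calibrated")
    return (pssm.lambda_ * score - math.log(pssm.K)) / math.log(2.0)


# ---------------------------------------------------------------------------
# IO

def read_seed_alignment(
    path: str | Path,
    family_id: str | None = None,
    domain_class: str = "universal",
    rare_family: bool = False,
) -> SeedAlignment:
    """Read one family's aligned FASTA."""
    path = Path(path)
    members = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return SeedAlignment(
        family_id=family_id if family_id is not None else path.stem,
        members=members,
        domain_class=domain_class,
        rare_family=rare_family,
    )


def read_family_metadata(path: str | Path) -> dict[str, dict]:
    """Read the family metadata TSV (family_id, domain_class, rare_family)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "domain_class", "rare_family"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[row["family_id"]] = {
            "domain_class": row["domain_class"],
            "rare_family": str(row["rare_family"]).strip().lower()
            in {"1", "true", "yes"},
        }
    return out


def save_profiles(profiles: list[Pssm], path: str | Path) -> None:
    """Serialise calibrated profiles to JSON-lines."""
    with open(path, "w") as fh:
        for p in profiles:
            fh.write(json.dumps({
                "family_id": p.family_id,
                "scores": p.scores.tolist(),
                "background": p.background.tolist(),
                "gap_open": p.gap_open,
                "gap_extend": p.gap_extend,
                "lambda": p.lambda_,
                "K": p.K,
                "kept_columns": None if p.kept_columns is None else p.kept_columns.tolist(),
                "rare_family": p.rare_family,
            }) + "\n")


def load_profiles(path: str | Path) -> list[Pssm]:
    """Load profiles saved by :func:`save_profiles`."""
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(Pssm(
                family_id=d["family_id"],
                scores=np.asarray(d["scores"], dtype=np.int32),
                background=np.asarray(d["background"], dtype=float),
                gap_open=d["gap_open"],
                gap_extend=d["gap_extend"],
                lambda_=d["lambda"],
                K=d["K"],
                kept_columns=None if d["kept_columns"] is None
                else np.asarray(d["kept_columns"], dtype=np.int64),
                rare_family=d["rare_family"],
            ))
    return out
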