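"""Low-level local-alignment kernels shared by profile search and calibration.

Smith-Waterman dynamic programming with affine gaps, in integer half-bit
scores, compiled with numba.  A gap of length k costs ``gap_open +
k * gap_extend`` (BLAST convention), so the first gapped position costs
``gap_open + gap_extend``.

Sequences are encoded as integer arrays over the 20-letter amino-acid
alphabet in BLOSUM62 order; any other symbol (X, ambiguity codes, ...) is
encoded as :data:`UNKNOWN_INDEX` and scored via an extra matrix column/row
carrying a flat mildly negative score.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Amino acids in BLOSUM62 row order; index i encodes AA_ORDER[i].
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
#: Code assigned to any residue outside AA_ORDER (X, B, Z, U, ...).
UNKNOWN_INDEX = 20
#: Half-bit score used for aligning anything against an unknown residue.
UNKNOWN_SCORE = -1

_AA_TO_INDEX = np.full(128, UNKNOWN_INDEX, dtype=np.int8)
for _i, _a in enumerate(AA_ORDER):
    _AA_TO_INDEX[ord(_a)] = _i
    _AA_TO_INDEX[ord(_a.lower())] = _i


def encode_protein(seq: str) -> np.ndarray:
    """Encode an amino-acid string as int8 indices (unknowns -> 20)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _AA_TO_INDEX[np.minimum(raw, 127)].astype(np.int8)


def extend_scores(scores: np.ndarray, unknown_score: int = UNKNOWN_SCORE) -> np.ndarray:
    """Append the unknown-residue column to an (L, 20) score matrix."""
    ext = np.full((scores.shape[0], 21), unknown_score, dtype=np.int32)
    ext[:, :20] = scores
    return ext


def extend_substitution(sub: np.ndarray, unknown_score: int = UNKNOWN_SCORE) -> np.ndarray:
    """Append unknown-residue row+column to a (20, 20) substitution matrix."""
    ext = np.full((21, 21), unknown_score, dtype=np.int32)
    ext[:20, :20] = sub
    return ext


@njit(cache=True)
def sw_score(scores, seq, gap_open, gap_extend):  # pragma: no cover - numba
    """Best local alignment score of ``seq`` against profile ``scores``.

    ``scores`` is (L, 21) int32, ``seq`` int8 indices.  Returns int32 >= 0.
    """
    L = scores.shape[0]
    n = seq.shape[0]
    NEG = -(10**7)
    open_cost = gap_open + gap_extend
    m_prev = np.zeros(L + 1, dtype=np.int64)
    x_prev = np.full(L + 1, NEG, dtype=np.int64)
    y_prev = np.full(L + 1, NEG, dtype=np.int64)
    m_cur = np.zeros(L + 1, dtype=np.int64)
    x_cur = np.full(L + 1, NEG, dtype=np.int64)
    y_cur = np.full(L + 1, NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        ai = seq[i - 1]
        m_cur[0] = 0
        x_cur[0] = NEG
        y_cur[0] = NEG
        for j in range(1, L + 1):
            diag = m_prev[j - 1]
            if x_prev[j - 1] > diag:
                diag = x_prev[j - 1]
            if y_prev[j - 1] > diag:
                diag = y_prev[j - 1]
            if diag < 0:
                diag = 0
            m = diag + scores[j - 1, ai]
            if m < 0:
                m = 0
            # gap in the sequence: consume profile column j
            xo = m_cur[j - 1] - open_cost
            xe = x_cur[j - 1] - gap_extend
            x = xo if xo > xe else xe
            # gap in the profile: consume sequence residue i
            yo = m_prev[j] - open_cost
            ye = y_prev[j] - gap_extend
            y = yo if yo > ye else ye
            m_cur[j] = m
            x_cur[j] = x
            y_cur[j] = y
            if m > best:
                best = m
        m_prev, m_cur = m_cur, m_prev
        x_prev, x_cur = x_cur, x_prev
        y_prev, y_cur = y_cur, y_prev
    return best


@njit(cache=True)
def sw_score_many(scores, seq_cat, offsets, gap_open, gap_extend):  # pragma: no cover
    """Best local score of each concatenated sequence against the profile.

    ``offsets`` has length n_seqs + 1; sequence k is
    ``seq_cat[offsets[k]:offsets[k + 1]]``.
    """
    out = np.zeros(offsets.shape[0] - 1, dtype=np.int64)
    for k in range(offsets.shape[0] - 1):
        out[k] = sw_score(scores, seq_cat[offsets[k]:offsets[k + 1]], gap_open, gap_extend)
    return out


@njit(cache=True)
def sw_best_end(scores, seq, gap_open, gap_extend, take_last):  # pragma: no cover
    """Best score and its (sequence, profile) end cell, 1-based inclusive.

    With ``take_last`` false the first maximal cell in row-major scan order
    (sequence outer, profile inner) is reported, otherwise the last.
    Returns (best, end_i, end_j); (0, 0, 0) when no positive alignment exists.
    """
    L = scores.shape[0]
    n = seq.shape[0]
    NEG = -(10**7)
    open_cost = gap_open + gap_extend
    m_prev = np.zeros(L + 1, dtype=np.int64)
    x_prev = np.full(L + 1, NEG, dtype=np.int64)
    y_prev = np.full(L + 1, NEG, dtype=np.int64)
    m_cur = np.zeros(L + 1, dtype=np.int64)
    x_cur = np.full(L + 1, NEG, dtype=np.int64)
    y_cur = np.full(L + 1, NEG, dtype=np.int64)
    best = 0
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        ai = seq[i - 1]
        m_cur[0] = 0
        x_cur[0] = NEG
        y_cur[0] = NEG
        for j in range(1, L + 1):
            diag = m_prev[j - 1]
            if x_prev[j - 1] > diag:
                diag = x_prev[j - 1]
            if y_prev[j - 1] > diag:
                diag = y_prev[j - 1]
            if diag < 0:
                diag = 0
            m = diag + scores[j - 1, ai]
            if m < 0:
                m = 0
            xo = m_cur[j - 1] - open_cost
            xe = x_cur[j - 1] - gap_extend
            x = xo if xo > xe else xe
            yo = m_prev[j] - open_cost
            ye = y_prev[j] - gap_extend
            y = yo if yo > ye else ye
            m_cur[j] = m
            x_cur[j] = x
            y_cur[j] = y
            if m > best or (take_last and m == best and m > 0):
                best = m
                best_i = i
                best_j = j
        m_prev, m_cur = m_cur, m_prev
        x_prev, x_cur = x_cur, x_prev
        y_prev, y_cur = y_cur, y_prev
    return best, best_i, best_j


def sw_locate(scores: np.ndarray, seq: np.ndarray, gap_open: int, gap_extend: int):
    """Best local score plus one optimal span on sequence and profile.

    Returns ``(score, (seq_first, seq_last), (col_first, col_last))`` with
    0-based inclusive spans, or ``(0, None, None)`` when the best score is 0.
    The reported span ends at the first maximal cell in row-major order and
    starts at the earliest sequence position achieving that score (found by
    aligning the reversed prefix), which makes the output deterministic.
    """
    best, ei, ej = sw_best_end(scores, seq, gap_open, gap_extend, False)
    if best <= 0:
        return 0, None, None
    rev_scores = np.ascontiguousarray(scores[:ej][::-1])
    rev_seq = np.ascontiguousarray(seq[:ei][::-1])
    rbest, ri, rj = sw_best_end(rev_scores, rev_seq, gap_open, gap_extend, True)
    # rbest == best by construction; reversed end cell maps to the start.
    si = ei - ri  # 0-based first sequence index
    sj = ej - rj  # 0-based first profile column
    return int(best), (si, ei - 1), (sj, ej - 1)


@njit(cache=True)
def ungapped_score_many(prof_t, seq_cat, offsets):  # pragma: no cover - numba
    """Best *ungapped* local segment score of each sequence vs the profile.

    ``prof_t`` is the transposed (21, L) profile.  This is a lower bound on
    the gapped Smith-Waterman score, computed ~6x faster, and is used as a
    conservative prescan: a gapped alignment of score S built from k+1
    ungapped segments pays at least (gap_open + gap_extend) per gap, so its
    best segment scores at least (S + k*(gap_open+gap_extend)) / (k+1).
    """
    L = prof_t.shape[1]
    out = np.zeros(offsets.shape[0] - 1, dtype=np.int64)
    prev = np.zeros(L + 1, dtype=np.int32)
    cur = np.zeros(L + 1, dtype=np.int32)
    for k in range(offsets.shape[0] - 1):
        seq = seq_cat[offsets[k]:offsets[k + 1]]
        n = seq.shape[0]
        best = 0
        prev[:] = 0
        cur[:] = 0
        for i in range(n):
            row = prof_t[seq[i]]
            for j in range(1, L + 1):
                v = prev[j - 1] + row[j - 1]
                if v < 0:
                    v = 0
                cur[j] = v
                if v > best:
                    best = v
            prev, cur = cur, prev
        out[k] = best
    return out


@njit(cache=True)
def sw_pair_score(sub, a, b, gap_open, gap_extend):  # pragma: no cover - numba
    """Best local score between two encoded sequences under matrix ``sub``."""
    n = a.shape[0]
    L = b.shape[0]
    NEG = -(10**7)
    open_cost = gap_open + gap_extend
    m_prev = np.zeros(L + 1, dtype=np.int64)
    x_prev = np.full(L + 1, NEG, dtype=np.int64)
    y_prev = np.full(L + 1, NEG, dtype=np.int64)
    m_cur = np.zeros(L + 1, dtype=np.int64)
    x_cur = np.full(L + 1, NEG, dtype=np.int64)
    y_cur = np.full(L + 1, NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        m_cur[0] = 0
        x_cur[0] = NEG
        y_cur[0] = NEG
        for j in range(1, L + 1):
            diag = m_prev[j - 1]
            if x_prev[j - 1] > diag:
                diag = x_prev[j - 1]
            if y_prev[j - 1] > diag:
                diag = y_prev[j - 1]
            if diag < 0:
                diag = 0
            m = diag + sub[ai, b[j - 1]]
            if m < 0:
                m = 0
            xo = m_cur[j - 1] - open_cost
            xe = x_cur[j - 1] - gap_extend
            x = xo if xo > xe else xe
            yo = m_prev[j] - open_cost
            ye = y_prev[j] - gap_extend
            y = yo if yo > ye else ye
            m_cur[j] = m
            x_cur[j] = x
            y_cur[j] = y
            if m > best:
                best = m
        m_prev, m_cur = m_cur, m_prev
        x_prev, x_cur = x_cur, x_prev
        y_prev, y_cur = y_cur, y_prev
    return best


@njit(cache=True)
def sw_pair_best_of(sub, a, b_cat, b_offsets, gap_open, gap_extend):  # pragma: no cover
    """Best local score of ``a`` against any of the concatenated sequences."""
    best = 0
    for k in range(b_offsets.shape[0] - 1):
        s = sw_pair_score(sub, a, b_cat[b_offsets[k]:b_offsets[k + 1]], gap_open, gap_extend)
        if s > best:
            best = s
    return best


@njit(cache=True)
def global_align_identity(sub, a, b, gap_open, gap_extend):  # pragma: no cover
    """Global alignment with free terminal gaps; returns (score, matches).

    Among all score-optimal alignments the one with the most identical
    aligned pairs is reported, which makes the match count symmetric and
    deterministic.  Implemented by maximising score*SHIFT + matches in one
    lexicographic DP (matches < SHIFT always).
    """
    n = a.shape[0]
    m = b.shape[0]
    SHIFT = np.int64(1) << np.int64(20)
    NEG = np.int64(-(10**15))
    oc = np.int64(gap_open + gap_extend) * SHIFT
    ge = np.int64(gap_extend) * SHIFT
    # rows over j (sequence b); iterate i over a
    M_prev = np.full(m + 1, NEG, dtype=np.int64)
    X_prev = np.full(m + 1, NEG, dtype=np.int64)  # gap in a, consumes b
    Y_prev = np.full(m + 1, NEG, dtype=np.int64)  # gap in b, consumes a
    M_cur = np.full(m + 1, NEG, dtype=np.int64)
    X_cur = np.full(m + 1, NEG, dtype=np.int64)
    Y_cur = np.full(m + 1, NEG, dtype=np.int64)
    M_prev[0] = 0
    for j in range(1, m + 1):
        X_prev[j] = 0  # leading gap in a is terminal: free
    for i in range(1, n + 1):
        ai = a[i - 1]
        M_cur[0] = NEG
        X_cur[0] = NEG
        Y_cur[0] = 0  # leading gap in b is free
        for j in range(1, m + 1):
            diag = M_prev[j - 1]
            if X_prev[j - 1] > diag:
                diag = X_prev[j - 1]
            if Y_prev[j - 1] > diag:
                diag = Y_prev[j - 1]
            sc = np.int64(sub[ai, b[j - 1]]) * SHIFT
            if ai == b[j - 1]:
                sc += 1
            M_cur[j] = diag + sc if diag > NEG else NEG
            # gap in a (consume b[j-1]); free when a is exhausted (i == n)
            o = np.int64(0) if i == n else oc
            e = np.int64(0) if i == n else ge
            xo = M_cur[j - 1] - o
            xe = X_cur[j - 1] - e
            X_cur[j] = xo if xo > xe else xe
            # gap in b (consume a[i-1]); free when b is exhausted (j == m)
            o = np.int64(0) if j == m else oc
            e = np.int64(0) if j == m else ge
            yo = M_prev[j] - o
            ye = Y_prev[j] - e
            Y_cur[j] = yo if yo > ye else ye
        M_prev, M_cur = M_cur, M_prev
        X_prev, X_cur = X_cur, X_prev
        Y_prev, Y_cur = Y_cur, Y_prev
    best = M_prev[m]
    if X_prev[m] > best:
        best = X_prev[m]
    if Y_prev[m] > best:
        best = Y_prev[m]
    matches = best & (SHIFT - 1)
    score = best >> np.int64(20)
    return score, matches


def pack_sequences(seqs) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate encoded sequences; returns (cat, offsets) for *_many kernels."""
    offsets = np.zeros(len(seqs) + 1, dtype=np.int64)
    for i, s in enumerate(seqs):
        offsets[i + 1] = offsets[i] + len(s)
    cat = np.empty(int(offsets[-1]), dtype=np.int8)
    for i, s in enumerate(seqs):
        cat[offsets[i]:offsets[i + 1]] = s
    return cat, offsets
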