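"""Profile search over ORF sets: forward scan, reciprocal validation,
frameshift merging and per-genome r-protein calls.

The detection logic mirrors a two-step homology search.  Forward: every ORF
is aligned locally against every calibrated family PSSM and hits with
E <= 1 are pooled.  Reverse: each hit region is aligned back against its own
family's ungapped seed sequences (BLOSUM62, same gap penalties, empirically
calibrated statistics) and kept only if the best reverse E-value passes
1e-4, relaxed to 1e-2 for families known to be absent from a large fraction
of species.  Candidate genes disrupted by a sequencing or genuine frameshift
appear as two same-family hits in different frames covering complementary
parts of the profile; these are merged into a single call flagged
``frameshift`` rather than edited.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _align
from .genomes import Genome, Orf
from .profiles import Pssm, blosum62_matrix, evalue as profile_evalue, bit_score

__all__ = [
    "Hit",
    "RProteinCall",
    "ReverseValidator",
    "align_pssm",
    "scan_genome",
    "reciprocal_filter",
    "detect_frameshifts",
    "call_rproteins",
    "crosscheck_annotations",
    "calls_to_frame",
    "read_annotation_gff",
]

_EULER_GAMMA = 0.5772156649015329


@dataclass
class Hit:
    """One forward profile-vs-ORF local alignment passing the E cutoff."""

    family_id: str
    orf_id: str
    raw_score: int
    bit_score: float
    evalue: float
    orf_span: tuple[int, int]      # 0-based inclusive residue interval
    profile_span: tuple[int, int]  # 0-based inclusive column interval
    reciprocal_evalue: float | None = None


@dataclass
class MergedCall:
    """Two frameshift-complementary hits merged into one candidate gene."""

    family_id: str
    hits: tuple[Hit, Hit]  # ordered by profile span


@dataclass
class RProteinCall:
    """One called r-protein gene copy in one genome."""

    genome_id: str
    family_id: str
    rank: int                       # 1 = primary
    orf_ids: list[str]              # two entries iff frameshift-merged
    evalue: float
    reciprocal_evalue: float | None
    frameshift: bool
    identity_to_primary: float | None  # None for rank 1
    replicon_id: str
    strand: str
    nt_start: int                   # 0-based half-open, forward strand
    nt_end: int
    aa_sequence: str


def align_pssm(
    pssm: Pssm, sequence: str
) -> tuple[int, tuple[int, int] | None, tuple[int, int] | None]:
    """Optimal local alignment of one sequence against a profile.

    Returns (raw_score, sequence_span, profile_span); spans are 0-based
    inclusive, or None when no positive-scoring alignment exists.  Ties are
    resolved deterministically (earliest endpoint in scan order, maximal
    extension back to the earliest start).
    """
    if not sequence:
        raise ValueError("empty sequence")
    ext = _align.extend_scores(pssm.scores)
    enc = _align.encode_protein(sequence)
    return _align.sw_locate(ext, enc, pssm.gap_open, pssm.gap_extend)


def _hit_region(hit: Hit, orf: Orf) -> tuple[int, int]:
    """Forward-strand genomic interval (0-based half-open) of a hit region."""
    a, b = hit.orf_span
    if orf.strand == "+":
        return orf.nt_start + 3 * a, orf.nt_start + 3 * (b + 1)
    return orf.nt_end - 3 * (b + 1), orf.nt_end - 3 * a


def scan_genome(
    profiles: list[Pssm],
    orfs: list[Orf],
    forward_E: float = 1.0,
    prescan_margin: int | None = 20,
) -> list[Hit]:
    """Scan all ORFs with all profiles; keep hits with E <= ``forward_E``.

    The database size n is the total residue count of the ORF set.  Hits are
    sorted by (family_id, evalue, orf_id).

    ``prescan_margin`` enables a fast ungapped prescan: full affine DP is
    run only for ORFs whose best ungapped segment scores within ``margin``
    half-bits of the score needed to reach ``forward_E``.  Since a gapped
    alignment with one gap outscores its best segment by less than the
    segment score minus the gap cost, a margin of 20 prunes essentially no
    genuine hits while skipping >90% of the database; pass None to disable.
    """
    if not orfs or forward_E <= 0:
        return []
    for p in profiles:
        if not p.calibrated:
            raise ValueError(f"profile {p.family_id} is not calibrated")
    encoded = [_align.encode_protein(o.aa_sequence) for o in orfs]
    cat, offsets = _align.pack_sequences(encoded)
    n_db = int(offsets[-1])
    hits: list[Hit] = []
    for p in profiles:
        ext = _align.extend_scores(p.scores)
        if prescan_margin is not None:
            # smallest integer score with E <= forward_E
            s_cut = math.ceil(
                (math.log(p.K * p.length * n_db) - math.log(forward_E))
                / p.lambda_
            )
            prof_t = np.ascontiguousarray(ext.T)
            ung = _align.ungapped_score_many(prof_t, cat, offsets)
            cand = np.flatnonzero(ung >= max(s_cut - prescan_margin, 1))
            if cand.size == 0:
                continue
            sub_off = np.zeros(cand.size + 1, dtype=np.int64)
            lengths = offsets[cand + 1] - offsets[cand]
            sub_off[1:] = np.cumsum(lengths)
            sub_cat = np.concatenate(
                [cat[offsets[k]:offsets[k + 1]] for k in cand]
            )
            sub_raw = _align.sw_score_many(
                ext, sub_cat, sub_off, p.gap_open, p.gap_extend
            )
            raw = np.zeros(len(orfs), dtype=np.int64)
            raw[cand] = sub_raw
        else:
            raw = _align.sw_score_many(ext, cat, offsets, p.gap_open, p.gap_extend)
        for k in np.flatnonzero(raw > 0):
            score = int(raw[k])
            E = profile_evalue(p, score, n_db)
            if E <= forward_E:
                s, orf_span, profile_span = _align.sw_locate(
                    ext, encoded[k], p.gap_open, p.gap_extend
                )
                hits.append(Hit(
                    family_id=p.family_id,
                    orf_id=orfs[k].orf_id,
                    raw_score=score,
                    bit_score=bit_score(p, score),
                    evalue=E,
                    orf_span=orf_span,
                    profile_span=profile_span,
                ))
    hits.sort(key=lambda h: (h.family_id, h.evalue, h.orf_id))
    return hits


class ReverseValidator:
    """Pairwise-alignment engine for reverse validation against seed sets.

    For each family the ungapped seed members form the reverse database.
    Score statistics are calibrated once per family exactly like profile
    calibration: random background sequences are scored (best local BLOSUM62
    alignment over all members) and a Gumbel law is fitted by moments.
    """

    def __init__(
        self,
        seeds: dict[str, list[str]],
        gap_open: int = 11,
        gap_extend: int = 1,
        decoy_count: int = 300,
        decoy_length: int = 200,
        seed: int = 0,
        background: np.ndarray | None = None,
    ) -> None:
        from .profiles import BLOSUM62_BACKGROUND

        if not seeds:
            raise ValueError("no seed sets supplied")
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.sub = _align.extend_substitution(blosum62_matrix())
        self.background = (
            BLOSUM62_BACKGROUND if background is None else np.asarray(background)
        )
        self._db: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._params: dict[str, tuple[float, float, int]] = {}
        # salted stream: equal integer seeds elsewhere never share decoys
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x5EED,)))
        for fam in sorted(seeds):
            members = seeds[fam]
            if not members:
                raise ValueError(f"family {fam}: empty seed set")
            enc = [_align.encode_protein(s) for s in members]
            cat, off = _align.pack_sequences(enc)
            self._db[fam] = (cat, off)
            n_db = int(off[-1])
            draws = rng.choice(
                20, size=(decoy_count, decoy_length), p=self.background
            ).astype(np.int8)
            maxima = np.array([
                _align.sw_pair_best_of(self.sub, d, cat, off, gap_open, gap_extend)
                for d in draws
            ], dtype=float)
            sigma = maxima.std()
            if sigma == 0:
                raise ValueError(f"family {fam}: degenerate reverse calibration")
            lam = math.pi / (sigma * math.sqrt(6.0))
            mu = maxima.mean() - _EULER_GAMMA / lam
            K = math.exp(lam * mu) / (decoy_length * n_db)
            self._params[fam] = (lam, K, n_db)

    def families(self) -> list[str]:
        return sorted(self._db)

    def best_evalue(self, family_id: str, query: str) -> float:
        """Best reverse E-value of ``query`` against the family's seeds."""
        if family_id not in self._db:
            raise ValueError(f"family {family_id}: no seed set")
        cat, off = self._db[family_id]
        lam, K, n_db = self._params[family_id]
        q = _align.encode_protein(query)
        s = _align.sw_pair_best_of(self.sub, q, cat, off, self.gap_open, self.gap_extend)
        return K * max(len(query), 1) * n_db * math.exp(-lam * float(s))


def reciprocal_filter(
    hits: list[Hit],
    seeds: dict[str, list[str]],
    orfs: list[Orf],
    strict_E: float = 1e-4,
    relaxed_E: float = 1e-2,
    rare_families: frozenset[str] | set[str] = frozenset(),
    validator: ReverseValidator | None = None,
) -> list[Hit]:
    """Keep hits whose region aligns back to their own family's seeds.

    The cutoff is ``strict_E`` (1e-4), or ``relaxed_E`` (1e-2) for families
    flagged rare (absent from >20% of species).  Surviving hits carry their
    best reverse E-value in ``reciprocal_evalue``.
    """
    by_id = {o.orf_id: o for o in orfs}
    v = validator if validator is not None else ReverseValidator(seeds)
    out = []
    for h in hits:
        if h.family_id not in seeds:
            raise ValueError(f"hit family {h.family_id}: no seed set")
        orf = by_id[h.orf_id]
        region = orf.aa_sequence[h.orf_span[0]: h.orf_span[1] + 1]
        E = v.best_evalue(h.family_id, region)
        cutoff = relaxed_E if h.family_id in rare_families else strict_E
        if E <= cutoff:
            out.append(Hit(**{**h.__dict__, "reciprocal_evalue": E}))
    return out


def detect_frameshifts(
    hits: list[Hit],
    orfs: list[Orf],
    profile_lengths: dict[str, int],
    max_gap_nt: int = 60,
    max_overlap_cols: int = 10,
    min_joint_coverage: float = 0.8,
) -> tuple[list[MergedCall], list[Hit]]:
    """Merge frameshift-split genes; returns (merged calls, remaining hits).

    Two validated hits to the same family, on one replicon and strand but in
    different frames, whose profile spans overlap by at most
    ``max_overlap_cols`` columns, jointly cover at least
    ``min_joint_coverage`` of the profile, and whose genomic regions are at
    most ``max_gap_nt`` apart in profile-consistent order, are merged.
    Constituent hits are consumed.
    """
    by_id = {o.orf_id: o for o in orfs}
    groups: dict[tuple, list[Hit]] = {}
    for h in hits:
        orf = by_id[h.orf_id]
        groups.setdefault((h.family_id, orf.replicon_id, orf.strand), []).append(h)

    merged: list[MergedCall] = []
    consumed: set[int] = set()
    for key in sorted(groups):
        fam = key[0]
        L = profile_lengths[fam]
        group = sorted(groups[key], key=lambda h: (h.evalue, h.orf_id))
        candidates = []
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                if by_id[a.orf_id].frame == by_id[b.orf_id].frame:
                    continue
                # order the pair by profile span
                first, second = (a, b) if a.profile_span[0] <= b.profile_span[0] else (b, a)
                overlap = first.profile_span[1] - second.profile_span[0] + 1
                if overlap > max_overlap_cols:
                    continue
                cov_cols = (first.profile_span[1] - first.profile_span[0] + 1) + (
                    second.profile_span[1] - second.profile_span[0] + 1
                ) - max(overlap, 0)
                if cov_cols / L < min_joint_coverage:
                    continue
                ga = _hit_region(first, by_id[first.orf_id])
                gb = _hit_region(second, by_id[second.orf_id])
                strand = by_id[first.orf_id].strand
                # the profile-first piece must come first in gene orientation
                up, down = (ga, gb) if strand == "+" else (gb, ga)
                gap = down[0] - up[1]
                if gap > max_gap_nt or down[0] < up[0]:
                    continue
                candidates.append((min(a.evalue, b.evalue), id(a), id(b), first, second))
        candidates.sort(key=lambda t: t[0])
        for _, ia, ib, first, second in candidates:
            if ia in consumed or ib in consumed:
                continue
            consumed.add(ia)
            consumed.add(ib)
            merged.append(MergedCall(family_id=fam, hits=(first, second)))
    remaining = [h for h in hits if id(h) not in consumed]
    return merged, remaining


@dataclass
class _Locus:
    family_id: str
    replicon_id: str
    strand: str
    nt_start: int
    nt_end: int
    evalue: float
    reciprocal_evalue: float | None
    frameshift: bool
    orf_ids: list[str]
    aa_sequence: str


def _loci(
    hits: list[Hit], merged: list[MergedCall], orfs: list[Orf]
) -> list[_Locus]:
    by_id = {o.orf_id: o for o in orfs}
    loci = []
    for h in hits:
        orf = by_id[h.orf_id]
        g = _hit_region(h, orf)
        loci.append(_Locus(
            family_id=h.family_id,
            replicon_id=orf.replicon_id,
            strand=orf.strand,
            nt_start=g[0],
            nt_end=g[1],
            evalue=h.evalue,
            reciprocal_evalue=h.reciprocal_evalue,
            frameshift=False,
            orf_ids=[h.orf_id],
            aa_sequence=orf.aa_sequence[h.orf_span[0]: h.orf_span[1] + 1],
        ))
    for mc in merged:
        first, second = mc.hits
        o1, o2 = by_id[first.orf_id], by_id[second.orf_id]
        g1, g2 = _hit_region(first, o1), _hit_region(second, o2)
        aa = (
            o1.aa_sequence[first.orf_span[0]: first.orf_span[1] + 1]
            + o2.aa_sequence[second.orf_span[0]: second.orf_span[1] + 1]
        )
        rec = [h.reciprocal_evalue for h in mc.hits if h.reciprocal_evalue is not None]
        loci.append(_Locus(
            family_id=mc.family_id,
            replicon_id=o1.replicon_id,
            strand=o1.strand,
            nt_start=min(g1[0], g2[0]),
            nt_end=max(g1[1], g2[1]),
            evalue=min(first.evalue, second.evalue),
            reciprocal_evalue=min(rec) if rec else None,
            frameshift=True,
            orf_ids=[first.orf_id, second.orf_id],
            aa_sequence=aa,
        ))
    return loci


def call_rproteins(
    hits: list[Hit],
    merged: list[MergedCall],
    genome: Genome,
    orfs: list[Orf],
    min_locus_overlap: float = 0.5,
) -> list[RProteinCall]:
    """Deduplicate loci and rank copies per family into final calls.

    Two same-family loci on one replicon count as one locus when their
    genomic intervals share at least ``min_locus_overlap`` of the shorter
    interval (the better E-value wins); this removes ORFs nested across
    frames.  Distinct loci are ranked by ascending forward E-value (rank 1 =
    primary); ties break by replicon order then coordinate.  Ranks >= 2 get
    their global identity to the primary.
    """
    from .census import pairwise_identity

    replicon_order = {r.replicon_id: i for i, r in enumerate(genome.replicons)}
    loci = _loci(hits, merged, orfs)
    calls: list[RProteinCall] = []
    for fam in sorted({l.family_id for l in loci}):
        fam_loci = [l for l in loci if l.family_id == fam]
        fam_loci.sort(key=lambda l: (l.evalue, replicon_order[l.replicon_id], l.nt_start))
        kept: list[_Locus] = []
        for l in fam_loci:
            dup = False
            for k in kept:
                if k.replicon_id != l.replicon_id:
                    continue
                ov = min(k.nt_end, l.nt_end) - max(k.nt_start, l.nt_start)
                shorter = min(k.nt_end - k.nt_start, l.nt_end - l.nt_start)
                if shorter > 0 and ov / shorter >= min_locus_overlap:
                    dup = True
                    break
            if not dup:
                kept.append(l)
        primary = kept[0] if kept else None
        for rank, l in enumerate(kept, start=1):
            ident = None
            if rank >= 2:
                ident = pairwise_identity(l.aa_sequence, primary.aa_sequence)
            calls.append(RProteinCall(
                genome_id=genome.genome_id,
                family_id=fam,
                rank=rank,
                orf_ids=list(l.orf_ids),
                evalue=l.evalue,
                reciprocal_evalue=l.reciprocal_evalue,
                frameshift=l.frameshift,
                identity_to_primary=ident,
                replicon_id=l.replicon_id,
                strand=l.strand,
                nt_start=l.nt_start,
                nt_end=l.nt_end,
                aa_sequence=l.aa_sequence,
            ))
    return calls


# ---------------------------------------------------------------------------
# Annotation cross-check

def default_family_synonyms(family_id: str) -> list[str]:
    """Token synonyms for a family name, e.g. L25p -> ['l25p', 'l25']."""
    syn = [family_id.lower()]
    if len(family_id) > 2 and family_id[-1] in "pe" and family_id[-2].isdigit():
        syn.append(family_id[:-1].lower())
    return syn


def crosscheck_annotations(
    calls: list[RProteinCall],
    annotation: pd.DataFrame,
    synonyms: dict[str, list[str]] | None = None,
) -> list[str]:
    """Classify each call as consistent / unannotated / misannotated.

    ``annotation`` rows carry replicon_id, strand, start, end (1-based
    inclusive) and product.  A call overlapping no annotated CDS on its
    strand by at least half of its own length is *unannotated*; one whose
    overlapping CDS products never token-match the family's name/synonyms is
    *misannotated*; otherwise *consistent*.
    """
    required = ["replicon_id", "strand", "start", "end", "product"]
    missing = [c for c in required if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation table missing columns {missing}")
    rows = []
    for idx, row in annotation.iterrows():
        try:
            rows.append((
                str(row["replicon_id"]), str(row["strand"]),
                int(row["start"]), int(row["end"]),
                str(row["product"]),
            ))
            if rows[-1][1] not in "+-" or rows[-1][2] > rows[-1][3]:
                raise ValueError
        except (TypeError, ValueError):
            raise ValueError(f"malformed annotation row {idx}") from None

    statuses = []
    for call in calls:
        c_start, c_end = call.nt_start + 1, call.nt_end  # 1-based inclusive
        c_len = c_end - c_start + 1
        fam_tokens = set(
            (synonyms or {}).get(call.family_id)
            or default_family_synonyms(call.family_id)
        )
        overlapping = []
        for rep, strand, a, b, product in rows:
            if rep != call.replicon_id or strand != call.strand:
                continue
            ov = min(b, c_end) - max(a, c_start) + 1
            if ov >= 0.5 * c_len:
                overlapping.append(product)
        if not overlapping:
            statuses.append("unannotated")
            continue
        consistent = False
        for product in overlapping:
            tokens = set(re.split(r"[^a-z0-9]+", product.lower())) - {""}
            if tokens & fam_tokens:
                consistent = True
                break
        statuses.append("consistent" if consistent else "misannotated")
    return statuses


def read_annotation_gff(path) -> pd.DataFrame:
    """Read CDS features from a GFF3 file into the annotation table format."""
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GFF row {lineno}")
            seqid, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "CDS":
                continue
            product = ""
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    if k.strip().lower() in ("product", "name"):
                        product = v.strip()
                        break
            recs.append({
                "replicon_id": seqid,
                "strand": strand,
                "start": int(start),
                "end": int(end),
                "product": product,
            })
    return pd.DataFrame(recs, columns=["replicon_id", "strand", "start", "end", "product"])


def calls_to_frame(calls: list[RProteinCall]) -> pd.DataFrame:
    """Calls as a table with 1-based inclusive coordinates for reports."""
    rows = []
    for c in calls:
        rows.append({
            "genome_id": c.genome_id,
            "family_id": c.family_id,
            "rank": c.rank,
            "replicon_id": c.replicon_id,
            "strand": c.strand,
            "start": c.nt_start + 1,
            "end": c.nt_end,
            "evalue": c.evalue,
            "reciprocal_evalue": c.reciprocal_evalue,
            "frameshift": c.frameshift,
            "identity_to_primary": c.identity_to_primary,
            "orf_ids": ",".join(c.orf_ids),
        })
    cols = ["genome_id", "family_id", "rank", "replicon_id", "strand", "start",
            "end", "evalue", "reciprocal_evalue", "frameshift",
            "identity_to_primary", "orf_ids"]
    return pd.DataFrame(rows, columns=cols)
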