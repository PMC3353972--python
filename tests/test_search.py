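"""Forward scan, reciprocal validation, frameshift merging and calling."""

import numpy as np
import pandas as pd
import pytest

from riboscan import genomes, profiles, search, synthetic
from riboscan.genomes import Genome, Replicon, extract_orfs
from riboscan.search import (
    ReverseValidator, call_rproteins, calls_to_frame, crosscheck_annotations,
    detect_frameshifts, read_annotation_gff, reciprocal_filter, scan_genome,
)
from riboscan.synthetic import _back_translate


def _pssms(small_families):
    return [p for _, _, p in small_families]


def test_align_pssm_self_and_background():
    """Self-alignment spans the whole profile; background queries floor at 0."""
    peptide = "MKWVRTACDEFGHILNPQSY"
    aln = profiles.SeedAlignment("self", [(f"m{i}", peptide) for i in range(4)])
    pssm = profiles.build_pssm(aln, pseudocount_weight=0.001)
    score, seq_span, prof_span = search.align_pssm(pssm, peptide)
    assert seq_span == (0, len(peptide) - 1)
    assert prof_span == (0, pssm.length - 1)
    rng = np.random.default_rng(0)
    for _ in range(5):
        q = "".join(rng.choice(list(profiles.AA_ORDER), size=40))
        s, _, _ = search.align_pssm(pssm, q)
        assert s >= 0


def test_scan_planted_copy_ranks_first(small_families, planted):
    """A planted family member is that family's best-E hit."""
    genome, truth, orfs = planted
    hits = scan_genome(_pssms(small_families), orfs, forward_E=1.0)
    for _, row in truth.planted_genes.iterrows():
        fam_hits = [h for h in hits if h.family_id == row.family_id]
        assert fam_hits, f"no hits for {row.family_id}"
        best = min(fam_hits, key=lambda h: h.evalue)
        orf = next(o for o in orfs if o.orf_id == best.orf_id)
        assert orf.replicon_id == row.replicon_id
        region = search._hit_region(best, orf)
        assert min(region[1], row.nt_end) - max(region[0], row.nt_start) > 0


def test_scan_zero_threshold_empty(small_families, planted):
    _, _, orfs = planted
    assert scan_genome(_pssms(small_families), orfs, forward_E=0.0) == []


def test_scan_threshold_monotonicity(small_families, planted):
    _, _, orfs = planted
    loose = scan_genome(_pssms(small_families), orfs, forward_E=1.0)
    tight = scan_genome(_pssms(small_families), orfs, forward_E=1e-3)
    loose_keys = {(h.family_id, h.orf_id) for h in loose}
    tight_keys = {(h.family_id, h.orf_id) for h in tight}
    assert tight_keys <= loose_keys


def test_scan_prescan_matches_full_dp(small_families, planted):
    _, _, orfs = planted
    fast = scan_genome(_pssms(small_families), orfs, forward_E=1.0)
    full = scan_genome(_pssms(small_families), orfs, forward_E=1.0,
                       prescan_margin=None)
    assert [(h.family_id, h.orf_id, h.raw_score) for h in fast] == \
           [(h.family_id, h.orf_id, h.raw_score) for h in full]


def test_reciprocal_keeps_planted_drops_nothing_true(
    small_families, planted, seed_sets, reverse_validator
):
    genome, truth, orfs = planted
    hits = scan_genome(_pssms(small_families), orfs, forward_E=1.0)
    kept = reciprocal_filter(hits, seed_sets, orfs, validator=reverse_validator)
    kept_keys = {(h.family_id, h.orf_id) for h in kept}
    assert kept_keys <= {(h.family_id, h.orf_id) for h in hits}
    # every planted gene still has a validated hit with a tiny reverse E
    for _, row in truth.planted_genes.iterrows():
        fam_kept = [h for h in kept if h.family_id == row.family_id]
        assert fam_kept
        assert min(h.reciprocal_evalue for h in fam_kept) < 1e-10


def test_reciprocal_threshold_semantics():
    """E = 5e-3 is dropped for common families, kept for rare ones."""

    class FixedValidator:
        def best_evalue(self, family_id, query):
            return 5e-3

    hit = search.Hit("famX", "o1", 50, 30.0, 0.5, (0, 9), (0, 9))
    orf = genomes.Orf("o1", "g", "r", "+", 0, 0, 33, "M" + "A" * 10)
    common = reciprocal_filter(
        [hit], {"famX": ["MAAAA"]}, [orf], validator=FixedValidator()
    )
    rare = reciprocal_filter(
        [hit], {"famX": ["MAAAA"]}, [orf], rare_families={"famX"},
        validator=FixedValidator(),
    )
    assert common == []
    assert len(rare) == 1 and rare[0].reciprocal_evalue == 5e-3


def test_reciprocal_requires_seeds(planted, small_families, reverse_validator):
    _, _, orfs = planted
    hits = scan_genome(_pssms(small_families), orfs, forward_E=1.0)
    if hits:
        with pytest.raises(ValueError, match="no seed set"):
            reciprocal_filter(hits, {}, orfs, validator=reverse_validator)


def _frameshift_setup(insertion=True):
    """Genome with one exact family copy split by a +-1 indel at codon 50."""
    rng = np.random.default_rng(42)
    aln, cons = synthetic.make_family(500, n_members=6, length=100,
                                      divergence=0.15)
    prot = cons[:52] + "M" + cons[53:]  # ORF restart right after the break
    pssm = profiles.build_pssm(aln)
    profiles.calibrate(pssm, decoy_count=300, decoy_length=150, seed=9)
    nt = _back_translate(prot, np.random.default_rng(1), 11)
    pos = 3 * 50
    nt = nt[:pos] + "A" + nt[pos:] if insertion else nt[:pos] + nt[pos + 1:]
    flank1 = "".join(rng.choice(list("ACGT"), size=300))
    flank2 = "".join(rng.choice(list("ACGT"), size=300))
    g = Genome("t", "t", [Replicon("r1", flank1 + nt + flank2)])
    orfs = extract_orfs(g)
    seeds = {aln.family_id: aln.sequences}
    hits = scan_genome([pssm], orfs, forward_E=1.0)
    hits = reciprocal_filter(
        hits, seeds, orfs, validator=ReverseValidator(seeds, seed=3)
    )
    return g, orfs, hits, pssm


def test_frameshift_split_gene_merges_to_one_call():
    g, orfs, hits, pssm = _frameshift_setup(insertion=True)
    merged, remaining = detect_frameshifts(hits, orfs, {pssm.family_id: pssm.length})
    assert len(merged) == 1
    calls = call_rproteins(remaining, merged, g, orfs)
    assert [(c.rank, c.frameshift, len(c.orf_ids)) for c in calls] == [(1, True, 2)]


def test_frameshift_same_frame_never_merged():
    g, orfs, hits, pssm = _frameshift_setup()
    same_frame = [h for h in hits]
    by_id = {o.orf_id: o for o in orfs}
    # restrict to pairs in one frame by filtering the hit list
    frames = {by_id[h.orf_id].frame for h in same_frame}
    if len(frames) > 1:
        keep = frames.pop()
        same_frame = [h for h in same_frame if by_id[h.orf_id].frame == keep]
    merged, _ = detect_frameshifts(same_frame, orfs, {pssm.family_id: pssm.length})
    assert merged == []


def test_frameshift_distant_hits_not_merged():
    """Two complete copies far apart stay separate calls."""
    rng = np.random.default_rng(7)
    aln, cons = synthetic.make_family(501, n_members=6, length=90,
                                      divergence=0.15)
    pssm = profiles.build_pssm(aln)
    profiles.calibrate(pssm, decoy_count=300, decoy_length=150, seed=9)
    nt = _back_translate(cons, np.random.default_rng(2), 11)
    spacer = "".join(rng.choice(list("ACGT"), size=10_000))
    seq = ("".join(rng.choice(list("ACGT"), size=200)) + nt + spacer + nt
           + "".join(rng.choice(list("ACGT"), size=200)))
    g = Genome("t", "t", [Replicon("r1", seq)])
    orfs = extract_orfs(g)
    seeds = {aln.family_id: aln.sequences}
    hits = scan_genome([pssm], orfs, forward_E=1.0)
    hits = reciprocal_filter(hits, seeds, orfs,
                             validator=ReverseValidator(seeds, seed=4))
    merged, remaining = detect_frameshifts(hits, orfs, {pssm.family_id: pssm.length})
    assert merged == []
    calls = call_rproteins(remaining, merged, g, orfs)
    fam_calls = [c for c in calls if c.family_id == aln.family_id]
    assert [c.rank for c in fam_calls] == [1, 2]
    assert fam_calls[1].identity_to_primary == pytest.approx(1.0)


def test_call_ranking_follows_divergence(small_families, seed_sets,
                                         reverse_validator):
    """Copies at 0 / 0.2 / 0.6 divergence rank by E; identities match truth."""
    aln, consensus, pssm = small_families[0]
    fams = [(aln.family_id, consensus, 1, 0.0),
            (aln.family_id, consensus, 1, 0.2),
            (aln.family_id, consensus, 1, 0.6)]
    genome, truth = synthetic.plant_genome(19, fams, genome_length=30_000)
    orfs = extract_orfs(genome)
    hits = scan_genome([pssm], orfs, forward_E=1.0)
    hits = reciprocal_filter(hits, seed_sets, orfs, validator=reverse_validator)
    merged, remaining = detect_frameshifts(hits, orfs, {pssm.family_id: pssm.length})
    calls = call_rproteins(remaining, merged, genome, orfs)
    fam = [c for c in calls if c.family_id == aln.family_id]
    assert len(fam) == 3
    assert [c.rank for c in fam] == [1, 2, 3]
    # ranks must follow ascending E-value
    assert fam[0].evalue <= fam[1].evalue <= fam[2].evalue
    # rank >= 2 identity matches an independent global identity of the
    # planted proteins (the generator knows the truth)
    from riboscan.census import pairwise_identity

    t = truth.planted_genes
    by_call = {}
    for c in fam:
        row = t[(t.nt_start <= c.nt_start) & (t.nt_end >= c.nt_start)].iloc[0]
        by_call[c.rank] = (c, row)
    prot_primary = by_call[1][1].protein
    for rank in (2, 3):
        c, row = by_call[rank]
        expected = pairwise_identity("M" + row.protein, "M" + prot_primary)
        assert c.identity_to_primary == pytest.approx(expected, abs=0.02)


def test_pipeline_determinism(small_families, seed_sets, planted):
    genome, _, orfs = planted
    tables = []
    for _ in range(2):
        validator = ReverseValidator(seed_sets, decoy_count=300, seed=5)
        hits = scan_genome(_pssms(small_families), orfs, forward_E=1.0)
        hits = reciprocal_filter(hits, seed_sets, orfs, validator=validator)
        merged, remaining = detect_frameshifts(
            hits, orfs, {p.family_id: p.length for _, _, p in small_families}
        )
        calls = call_rproteins(remaining, merged, genome, orfs)
        tables.append(calls_to_frame(calls).to_csv(sep="\t", index=False))
    assert tables[0] == tables[1]


# ---------------------------------------------------------------------------
# annotation cross-check

def _one_call(family_id="L25p", start=100, end=400):
    return search.RProteinCall(
        genome_id="g", family_id=family_id, rank=1, orf_ids=["o"],
        evalue=1e-30, reciprocal_evalue=1e-20, frameshift=False,
        identity_to_primary=None, replicon_id="chr", strand="+",
        nt_start=start, nt_end=end, aa_sequence="M" * 100,
    )


def test_crosscheck_consistent_unannotated_misannotated():
    ann = pd.DataFrame([
        {"replicon_id": "chr", "strand": "+", "start": 101, "end": 400,
         "product": "50S ribosomal protein L25"},
        {"replicon_id": "chr", "strand": "+", "start": 5001, "end": 5400,
         "product": "hypothetical protein"},
    ])
    calls = [
        _one_call("L25p", 100, 400),    # matches the L25 CDS
        _one_call("S31e", 9000, 9300),  # nothing there
        _one_call("L31p", 5000, 5400),  # inside the hypothetical CDS
    ]
    assert crosscheck_annotations(calls, ann) == [
        "consistent", "unannotated", "misannotated",
    ]


def test_crosscheck_rejects_malformed_rows():
    ann = pd.DataFrame([
        {"replicon_id": "chr", "strand": "+", "start": "oops", "end": 10,
         "product": "x"},
    ])
    with pytest.raises(ValueError, match="row 0"):
        crosscheck_annotations([_one_call()], ann)


def test_gff_reader(tmp_path):
    gff = tmp_path / "ann.gff"
    gff.write_text(
        "##gff-version 3\n"
        "chr\trefseq\tCDS\t101\t400\t.\t+\t0\tID=c1;product=50S ribosomal protein L25\n"
        "chr\trefseq\tgene\t101\t400\t.\t+\t.\tID=g1\n"
    )
    df = read_annotation_gff(gff)
    assert len(df) == 1
    assert df.iloc[0]["product"] == "50S ribosomal protein L25"
    statuses = crosscheck_annotations([_one_call("L25p", 100, 400)], df)
    assert statuses == ["consistent"]
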