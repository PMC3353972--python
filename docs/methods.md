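# Methods

This note documents the models, statistics and design choices behind
`riboscan`, in the order the pipeline runs them.

## ORF extraction (`riboscan.genomes`)

Each replicon is translated in six frames under its genome's NCBI
genetic-code table (tables 11, 4 and any other table Biopython provides).
A frame is segmented at stop codons; within each stop-delimited segment one
ORF is emitted, running from the segment's *first* start codon to the stop,
provided it is at least `min_len = 16` amino acids. The start-codon set is
taken from the code table (for table 11: ATG, GTG, TTG plus the minor
starts), the first codon is rendered as Met, later start codons translate
to their table residue. Segments without a start codon, or not terminated
by a stop, emit nothing — the search layer's frameshift handling, not a
stop-to-stop fallback, compensates for disrupted genes. Codons containing
IUPAC ambiguity codes translate to the unique residue shared by all their
resolutions, else to `X`; an ambiguous codon is never accepted as a start.

Circular replicons are treated as linear, so an ORF spanning the origin is
split; this is a known limitation, relevant only for the rare gene that
straddles the chosen origin.

Coordinates are 0-based half-open on the forward strand inside the library;
all report writers emit 1-based inclusive coordinates.

## Profiles and score statistics (`riboscan.profiles`)

A family is described by a curated seed alignment. Construction of the
PSSM:

* **Sequence weights** are Henikoff position-based: in each column a member
  carrying residue *x* receives `1/(r·s)` (r = distinct residues in the
  column, s = count of *x*); gapped members receive nothing; weights are
  normalised to sum to 1. This de-biases redundant seed sets — duplicating
  a member redistributes, not inflates, its influence, and `build_pssm` is
  invariant to member order.
* **Columns** gapped in more than half of the members are dropped from the
  model (mirroring the 50% rule used for concatenation, below).
* **Pseudocounts** are substitution-matrix based. Observed weighted
  frequencies `f` are blended with `g_a = Σ_b f_b·P(a|b)` as
  `q = (α·f + β·g)/(α+β)`, with α the column's effective observation count
  (distinct residues − 1) and β = 10 by default. The conditional
  probabilities `P(a|b)` are reconstructed from the BLOSUM62 half-bit
  scores via `q_ab ∝ p_a·p_b·2^(s_ab/2)` with the standard BLOSUM62
  background `p`; the matrix's original count data are not distributed with
  the score matrix, and the reconstruction is exact up to the integer
  rounding of the published scores.
* **Scores** are integer half-bits, `round(2·log2(q/p_a))`, so the DP runs
  in integers; gap penalties default to open 11 / extend 1 (a length-k gap
  costs 11 + k).

**E-values.** Gapped local alignment has no analytic score distribution, so
each profile is calibrated empirically: `decoy_count ≥ 200` i.i.d. random
sequences drawn from the background composition are aligned against the
profile, and a Gumbel law is fitted to the maximal scores by the method of
moments (λ = π/(σ√6); location μ = mean − γ/λ; K = e^(λμ)/(m·n₀) with m
the profile length and n₀ the decoy length). E-values then follow the
Karlin–Altschul form `E = K·m·n·e^(−λS)` for a database of n residues.
The calibration is deterministic given its seed, and its stream is salted
with the family id so that equal integer seeds passed to different
components never share random streams. The classic thresholds (1, 10⁻⁴,
10⁻²) are operating points of *this* engine: absolute E-values are not
comparable to any particular BLAST build. An acceptance test verifies the
calibration is honest — on fresh background decoys the number of hits with
E ≤ x stays within 3·√x of x for x ∈ {1, 5, 10}.

## Search (`riboscan.search`)

`scan_genome` aligns every ORF against every calibrated profile
(Smith–Waterman, affine gaps, numba-compiled) and keeps hits with
E ≤ 1, where n is the total residue count of the genome's ORF set. For
speed a prescan computes each ORF's best *ungapped* segment score (a lower
bound of the gapped score, ~6× cheaper) and the full DP runs only for ORFs
within 20 half-bits of the score needed to reach the E cutoff; a gapped
alignment with one gap outscores its best segment by less than a segment
score minus the gap cost, so the margin is conservative, and a unit test
asserts prescan and full DP produce identical hit lists.

`reciprocal_filter` realigns each hit region against its own family's
ungapped seed sequences (pairwise local, BLOSUM62, same gap penalties),
with per-family Gumbel statistics calibrated the same way; hits survive at
reverse E ≤ 10⁻⁴, or ≤ 10⁻² for families flagged `rare_family` in the
metadata (absent from > 20% of species). The rare flag is static input, not
recomputed mid-run, avoiding circularity.

`detect_frameshifts` merges two validated same-family hits on one replicon
and strand but in *different* frames when their profile spans overlap by at
most 10 columns, jointly cover ≥ 80% of the profile, and their genomic
regions are ≤ 60 nt apart in profile-consistent order. These operating
points are configuration, chosen once: the 60-nt gap absorbs the
unalignable residues around a break, the coverage floor keeps chance
same-family pairs out. A split gene whose minor fragment is too short or
too diverged to pass validation is still detected through its major piece
and both pieces remain visible in the forward candidate pool; the merged
call records both ORF ids and never edits the sequence.

`call_rproteins` collapses same-family hits whose genomic intervals share
≥ 50% of the shorter interval (nested ORFs across frames), ranks distinct
loci by ascending forward E-value — rank 1 is the primary copy, "most
similar to the profile" — and annotates ranks ≥ 2 with their global
identity to the primary. Identical inputs and seeds give byte-identical
call tables.

`crosscheck_annotations` compares calls with an annotation table (GFF3 or
TSV): a call overlapping no same-strand CDS by at least half its length is
*unannotated*; one whose overlapping CDS products never token-match the
family name/synonyms is *misannotated*; otherwise *consistent*.

## Census (`riboscan.census`)

The phyletic matrix counts calls of every rank per (genome, family).
Paralog identity classes use strict inequalities as conventionally printed:
\> 0.97 near-identical, < 0.50 diverged. `pairwise_identity` is a global
alignment (BLOSUM62, open 11 / extend 1, terminal gaps free) with the
*shorter* sequence as denominator, robust to fragment paralogs. Because
many co-optimal global alignments can exist, the DP maximises
(score, identities) lexicographically, making the fraction symmetric and
deterministic; an off-the-shelf aligner that returns an arbitrary
co-optimal alignment does not guarantee either.

Representative-genome selection drops genomes with < 500 protein-coding
genes and keeps the largest genome per genus (ties: lexicographically first
id), with configurable genus aliasing (e.g. merging *Shigella* into
*Escherichia*) and forced inclusions for model organisms. The paralogy
index is the geometric mean of copy numbers over occupied cells only:
log 0 is undefined, and an absent gene carries no paralogy information.

## Trees and Dollo parsimony (`riboscan.phylo`)

Alignment columns with a gap fraction ≥ 0.5 are removed (strict `< 0.5` to
keep); concatenation joins per-family blocks in a fixed family order, with
all-gap blocks for missing taxa, so the total width is exactly the sum of
filtered family widths.

Midpoint rooting places the root halfway along the longest leaf-to-leaf
path, with ties broken by the lexicographically smallest leaf-label pair;
it is implemented directly (the bundled tree library mis-handles the case
where the midpoint falls exactly on an internal node) and is idempotent.
Externally rooted trees are accepted verbatim, and a neighbor-joining
fallback (via scikit-bio) builds a tree from a distance matrix when no
externally inferred tree is available — tree *inference* is otherwise out
of scope.

Dollo parsimony assumes a complex character is gained at most once. For a
presence/absence pattern the gain is placed on the edge above the LCA of
the present leaves ("root" when that is the root) and losses on the edges
above the maximal all-absent subtrees inside the gained clade. This is the
minimum-loss scenario; the test suite proves it exhaustively for every
rooted tree shape with ≤ 8 leaves — 80,528 (shape, pattern) instances
including all multifurcations — against a brute-force search over
single-gain, arbitrary-loss scenarios. Copy numbers are binarized
(presence ⇔ count ≥ 1) before mapping; paralogs do not affect gain/loss
inference. Edges are identified by their child node ("smallest leaf
label | clade size", unique within a tree), so reports are stable across
serialisations.

## Synthetic data (`riboscan.synthetic`)

The generators emulate the study conditions and emit machine-readable
truth:

* `make_family` draws a consensus from the BLOSUM62 background and derives
  members by per-site substitution (probability `1 − e^(−d)` at divergence
  d, replacements from BLOSUM62 conditionals excluding the identity) plus
  single-residue indels at 0.01/site, so the induced alignment is exact by
  construction. At divergence 0 members are exact copies.
* `plant_genome` back-translates planted proteins with uniform synonymous
  codons (the pipeline works on amino acids, so codon usage is
  irrelevant), wraps them in a start and stop codon, places them uniformly
  without overlap on random strands and replicons, injects a single ±1 nt
  indel near the midpoint with probability `frameshift_fraction`, and
  fills the rest i.i.d. from the intergenic model.
* `simulate_gainloss` gains each family at the root with probability
  `p_ancestral`, else once on an edge sampled proportional to branch
  length, and drops losses as a Poisson process on all edges below the
  gain. Events on already-lost lineages are recorded too, so the true
  event count can exceed the parsimony minimum — which is exactly what the
  minimality tests need.

What the synthetic data does *not* model: operon structure and gene order,
codon usage, GC skew, compositional heterogeneity along the genome, and
sequencing error beyond the single injected indel. Passing the recovery
tests therefore demonstrates the pipeline's detection logic under
realistic divergence, not robustness to every artefact of real assemblies.

## Problem sizes and numerical choices

* Recovery benchmark: 50 genomes × 1 Mb, 30 families (length 90–180 aa,
  true divergence uniform on 0.05–0.4 expected substitutions/site), 10%
  frameshifted copies — the regime where r-protein divergence actually
  lives; sensitivity is measured as same-family calls covering ≥ 50% of a
  planted gene.
* Profile calibration: 300–500 decoys of length 150–200 per family.
* Scores are exact integers; the only stochastic elements are the
  calibrations and generators, all seeded. Gumbel moment fitting can sit a
  hair above or below the nominal tail mass; the 3·√x tolerance covers
  both the fit and Poisson counting noise.
* Degenerate inputs raise: empty FASTA, non-nucleotide characters, all-gap
  alignments, uncalibrated profiles, all-absent phyletic patterns,
  distance matrices that are not symmetric/finite/zero-diagonal.

## Known limitations

* No origin-spanning ORFs on circular replicons.
* Frameshift merging is limited to two pieces; a gene broken by two or
  more indels in distinct frames is reported as separate candidate copies.
* The reverse-validation E-value scales calibration constants from a fixed
  decoy length to the query length; for very short hit regions (< ~25 aa)
  the approximation is coarse, which is one reason minor fragments of
  split genes can fall below the strict cutoff.
* Identity classes depend on the stated alignment recipe; other
  denominators (alignment length, longer sequence) shift borderline cases.
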