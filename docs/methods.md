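# Methods

This note records the model, the defaults and the genuinely open design
choices behind `multiguide`, and what the synthetic-data experiments do
and do not demonstrate.

## Target-site model

A site is protospacer + PAM.  The only sequence constraints imposed are
the ones CRISPR/Cas systems are known to impose: the PAM pattern (any
IUPAC string, either side of the protospacer) and optionally the
5′-most protospacer dinucleotide (`NN` none, `GN` U6-driven, `GG`
T7-driven synthesis).  Compiled matchers hold a per-position
allowed-base set for the whole site in forward orientation plus the
complement-reversed mirror, so both genomic strands are tested against
forward-strand text directly.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `target_length` | 20 nt | protospacer length (17–20 typical for type II) |
| `pam`, `pam_side` | `NGG`, 3′ | PAM pattern and side |
| `five_prime_dinucleotide` | `NN` | expression-method constraint |
| `allow_seed_mismatch` | off | tolerate one mismatch in the seed when matching the consensus |
| `seed_region_length` | 8 nt | PAM-distal seed; validated only for type II systems |

The seed is anchored PAM-distal regardless of PAM side: protospacer
positions 1–8 for a 3′ PAM, the last 8 for a 5′ PAM.  For systems other
than SpCas9 the single-seed-mismatch tolerance is an extrapolation and
the option should be left off.

**Degenerate symbols.** Input sequences are uppercased; ambiguity codes
other than `N` are rejected at ingest.  In a window, `N` satisfies only
fully unconstrained positions.  In consensus matching, `-` never
matches; an `X` (rows disagree) never matches a constrained position,
matches an unconstrained PAM position outright (each sequence still
shows the PAM a valid base there), and at an unconstrained protospacer
position counts as the single permitted seed mismatch.  The distinction
matters: a protospacer disagreement is a real guide:target mismatch for
some of the sequences, a PAM-`N` disagreement is not.  Whether a
consensus `X` should be allowed to match at `N` PAM positions was an
open interpretation; we allow it, on the argument above.

## Search

Single-sequence enumeration is vectorized (per-position boolean tables
over an integer-encoded sequence); all exact hits on both strands are
reported, overlapping hits included, sorted by (start, strand).
Coordinates are 0-based half-open internally; TSV reports print 1-based
inclusive, BED stays 0-based half-open.  The seed-mismatch option plays
no role here — a concrete window either conforms or not.

Nickase pairing (geometry not fixed by the biology of the search
itself, so chosen as standard double-nicking practice): only (+,−)
pairs in PAM-out orientation, nick positions 3 bp PAM-proximal, nick
separation within a configurable window defaulting to [0, 31] bp.

## Alignment and consensus

The consensus is strict unanimity — a base only where all rows agree,
`-` on any gap, `X` otherwise.  No majority rule is offered: one
disagreeing sequence already breaks a guide:target match, which is the
question being asked.

Alignments can be imported (aligned FASTA or Clustal, so output of any
external aligner is usable) or computed internally: optimal pairwise
global alignment under affine gap scoring, extended to k > 2 sequences
by center-star merging (center = maximal summed pairwise identity;
"once a gap, always a gap").

**Scoring defaults** are match +2, mismatch −2, gap open −5, gap
extension −0.2 per additional position.  The unusual choice is the
cheap extension, and it is deliberate.  The sequences this tool aligns
are block-structured: exactly shared exons separated by private exons
or indels.  With extension penalties of conventional magnitude the
optimal global alignment of such sequences is a *mosaic* — unrelated
blocks aligned against each other at the ~0.6 apparent identity that
adaptive gapping achieves between random sequences — because spanning a
whole private exon with one long gap costs more than chasing chance
matches inside it.  A mosaic destroys column unanimity and with it
every common site.  Cheap extension makes whole-block gaps affordable;
mismatch −2 still keeps isolated substitution runs (up to ~5) aligned
gaplessly, so diverged-but-colinear paralog pairs produce gapless
alignments.  The scores are exposed (`AlignScores`) for users whose
inputs look different.  Tie-breaking among co-optimal alignments
follows the underlying aligner's deterministic first choice.

## Common and unique sites

Common-site search slides the matcher over the consensus and its
reverse complement (`X` is its own complement).  Hits are mapped
through per-row column→coordinate maps into one concrete site per
sequence; under strict unanimity a matched window can contain no gap
column, so the per-row windows are always contiguous and the mapped
sites always round-trip against their source sequences (asserted
before any report is written).

Uniqueness compares protospacers only — PAM-degenerate positions make
PAM comparison uninformative — scanning 5′→3′ with early termination
once more than 2 mismatches accumulate.  Unique ⇔ distance ≥ 3 from
every site of every other sequence, the contrapositive of the early
stop.  Duplicate occurrences within the owner sequence do not
disqualify (uniqueness is absence from the *other* sequences, the
isoform-specificity semantics).  A single specification (one
protospacer length) applies per run, so compared protospacers always
have equal length.  For reported unique sites the exact minimum
cross-sequence distance is recomputed without the cap.

Exon filtering retains exactly the sites whose half-open interval lies
inside one exon interval — flush boundaries retained, junction
straddlers removed — in merged-exon gene-local coordinates for the
genes workflow and transcript coordinates for the isoforms workflow.

## Annotation

GC% is over the protospacer.  Tm uses RNA:DNA hybrid nearest-neighbor
parameters (Sugimoto et al. 1995; bundled as a TSV, indexed by the
guide-strand dinucleotide), Tm = 1000·ΔH/(ΔS + R·ln(C/4)) − 273.15 with
R = 1.987 cal/(mol·K) and strand concentration C = 50 nM; the Na⁺
condition (50 mM) is documented but no salt correction is applied
beyond the parameter set itself, matching the baseline nearest-neighbor
formulation.  The test suite cross-checks this against an independent
nearest-neighbor implementation to 0.01 °C.

The activity score applies only to the 20-nt/3′-3-nt-PAM layout and
needs the full 30-nt context (4 nt 5′ + 20 + PAM + 3 nt 3′); sites too
close to a sequence edge get no score rather than a fabricated one.
The model is logistic: intercept + position-specific mononucleotide and
dinucleotide indicator weights + `gc_low`/`gc_high` terms weighting
max(0, 10−GC) and max(0, GC−10) over the protospacer GC count.  The
published coefficients of the model this structure follows are not
printed in an obtainable form, so the bundled table
(`data/activity_model_synthetic.tsv`) is an explicitly synthetic
stand-in: correct feature structure, placeholder weights.  Scores from
it are self-consistent and well-behaved (strictly inside (0,1),
monotone in the intercept) but are not the published model's numbers;
drop in a published table by path for those.  Reported effective
guides have scored as low as 0.1–0.2 under the original model, so no
hard score filter is applied anywhere.

## Synthetic data

Two generator families stand in for a genome annotation database.

`make_ohnolog_fixture` emulates a duplicated gene pair: one ancestral
exonic sequence (default 1000 nt in 3 exons on a synthetic contig; the
second copy is assembled on the − strand to exercise strand handling),
copies diverged by uniform point substitutions (default 10%), with
planted sites — identical common sites at shared coordinates, optional
common sites differing at one seed position (recoverable only in
mismatch mode), and unique-site pairs mutated to protospacer distance
≥ 3.  `make_isoform_fixture` emulates alternative splicing:
constitutive exons shared by all transcripts carrying one planted
common site, plus one private exon per transcript carrying its planted
isoform-specific site.

Everything outside planted windows is scrubbed free of
spec-conforming sites (iterative disruption of PAM matches, applied at
identical coordinates with identical bases in all copies so the scrub
itself can create neither common nor unique sites; planted site texts
are sampled to contain no internal PAM occurrence so every spurious
match stays disruptable).  Consequently the recorded truth is exact:
zero false common sites are possible in 0-mismatch mode and every
unique site is planted.  Generators are deterministic per seed.

What fixtures do **not** emulate: clustered (non-uniform) conservation,
real codon structure and GC heterogeneity, natural site density inside
the planted fixtures (the scrub removes it), indel divergence between
gene copies, and real splice-site sequence.  Passing the planted-truth
experiments therefore demonstrates the correctness of the search,
consensus, mapping and comparison machinery — not field performance on
genome annotations.  For density-style summary numbers the separate
`make_diverged_pair` generator leaves the background untouched; on
uniform random backgrounds the conserved/mismatch and strand splits it
yields are necessarily near-symmetric, unlike annotation-derived data
where conservation clustering and strand-biased G runs skew them.

## Problem sizes and verification

The test suite checks each operation against an independently coded
oracle: site enumeration vs naive sliding-window membership on 1,000
random sequences (100–500 nt) plus strand-mirror symmetry on 500;
consensus rules exhaustively over every possible 2–4-row column;
common sites vs per-sequence enumeration with coordinate agreement on
gapless families; uniqueness vs all-pairs full-Hamming brute force on
200 random 3×300-nt fixtures; planted-truth recovery on 50 seeded
fixtures; exon filtering exhaustively over every site start on toy
gene models; Tm vs an independent summation to 0.01 °C and the score
vs a manual feature sum to 1e−9; and byte-identical CLI reports across
repeated runs.  `scripts/acceptance.py` uses 40 screen pairs of
1200 nt and 20 fixtures per family — sizes chosen so the whole
recomputation stays interactive while keeping the per-quantity
sampling error a few percent.

## Known limitations

- Center-star alignment is a heuristic; with many weakly similar
  sequences the consensus can lose common sites a better MSA would
  keep.  Importing a ClustalW2/MAFFT alignment is supported for exactly
  this case (the consensus logic is alignment-agnostic).
- Off-target screening is out of scope by design; exported TSVs are
  meant to be handed to dedicated genome-wide scanners.
- The uniqueness criterion is a fixed Hamming threshold on equal-length
  protospacers; it does not model position-dependent mismatch
  sensitivity or bulges.
- Trans-spliced or mixed-strand gene annotations are rejected rather
  than guessed at.
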