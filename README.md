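# multiguide

CRISPR sgRNA target-site search in sets of **similar** DNA sequences:
paralogous (e.g. duplicated) genes, transcript isoforms of one gene, or
any collection of related sequences.  Beyond the usual per-sequence
enumeration, `multiguide` answers the two questions such sets raise:

- **Which sites are common to all sequences?**  One guide that cuts
  every member — e.g. knocking out both copies of a duplicated gene
  pair with a single sgRNA.
- **Which sites are unique to exactly one sequence?**  A guide that
  discriminates — e.g. mutating one transcript isoform while sparing
  the others.

It is a library plus a `multiguide` command-line tool, aimed at
researchers designing guides for organisms with many duplicated genes
(teleost fish being the classic case) or for isoform-specific
perturbations.

## The method

A target site is a protospacer of length *L* (default 20 nt) flanked by
a PAM given as an IUPAC pattern on a chosen side — `N20-NGG` for
SpCas9 by default, but `NNAGAAW` (StCas9), `NNNNGATT` (NmCas9), 5′ PAMs
and other lengths are all expressible.  The 5′-most dinucleotide can be
constrained to `GG` (T7 transcription) or `GN` (U6 promoter).

**Simple search.** The compiled per-position matcher slides over every
window of each sequence and its reverse complement; all exact hits are
reported, including overlapping ones.  Opposite-strand hits in PAM-out
orientation whose predicted nicks (3 bp PAM-proximal) fall 0–31 bp
apart are additionally paired for double-nicking designs.

**Common sites.** The sequences are aligned (internal affine-gap
aligner with center-star merging, or any imported aligned-FASTA/Clustal
alignment) and reduced to a consensus over `{A,C,G,T,-,X}`: a base
where all rows agree, `-` where any row has a gap, `X` where rows
disagree.  The matcher then runs over the consensus in both
orientations.  `-` never matches; an `X` is tolerated at most once, and
only at an unconstrained position inside the PAM-distal 8-nt seed
region when mismatches are allowed (a single seed mismatch does not
abolish guide binding).  Each consensus hit is mapped back to one
per-sequence site via the alignment coordinate maps.

**Unique sites.** All PAM-containing sites of all sequences (both
strands) are compared exhaustively by protospacer Hamming distance,
scanning 5′→3′ and stopping early once the count exceeds 2.  A site is
unique iff it is ≥ 3 mismatches away from every site of every *other*
sequence.

**Gene models.** For genes and transcripts, search spaces are built by
merging exons (union of genomic intervals, strand-aware) or
concatenating transcript exons; candidate sites must then lie
completely within a single exon, so the matched sequence actually
exists in the genome rather than spanning a splice junction.  Gene
models load from GFF3 + genome FASTA or a small JSON format.

**Per-site annotation.** GC%, the RNA:DNA hybrid melting temperature by
nearest-neighbor thermodynamics (Sugimoto et al. 1995 parameter set;
`Tm = ΔH/(ΔS + R ln(C/4)) − 273.15`, C = 50 nM), and a 0–1 activity
score from a logistic model over the 30-nt context (4 nt 5′ flank +
protospacer + PAM + 3 nt 3′ flank) with position-specific nucleotide,
dinucleotide and GC-count features.  The bundled coefficient table is a
synthetic stand-in with the published model's feature structure; a
published table can be supplied by path.

## Worked example

Find common and unique guides in a pair of diverged gene copies
(`paralogs.fasta`, two ~300-nt sequences at ~8% divergence), allowing a
single seed mismatch:

```bash
multiguide multi paralogs.fasta --allow-mismatch --out out
```

`out/common_sites.tsv` (excerpt; 1-based inclusive coordinates):

```
common_id  consensus_start  consensus_end  strand  mismatch_column  sequence_id  start  end  protospacer            pam  gc_percent  tm     score
common_1   30               52             -                        copy_a       30     52   TAACAGATGCATCGAATACT   TGG  35.00       59.28  0.8686
common_1   30               52             -                        copy_b       30     52   TAACAGATGCATCGAATACT   TGG  35.00       59.28  0.8898
common_2   137              159            +       137              copy_a       137    159  GACCTACCTTAATATCTCCG   AGG  45.00       57.27  0.9272
common_2   137              159            +       137              copy_b       137    159  AACCTACCTTAATATCTCCG   AGG  40.00       56.29  0.9252
```

`common_1` is fully conserved: one guide (`TAACAGATGCATCGAATACT`, −
strand) cuts both copies.  `common_2` carries one disagreement at
consensus column 137 — protospacer position 1, inside the seed — so a
guide against either copy still targets both under the one-seed-
mismatch rule.  Per-row columns give each site's GC%, predicted
guide:target Tm in °C, and activity score.

`out/unique_sites.tsv` lists sites found in only one copy with their
minimum cross-copy distance:

```
site_id   owner_sequence_id  strand  start  end  protospacer            pam  min_cross_distance
unique_1  copy_a             -       53     75   CTGTAGTGAGGAGCACCTCT   GGG  11
```

`out/alignment_view.txt` shows the alignment with common sites
bracketed (`>`/`<` by strand) above the consensus:

```
                                        <<<<<<<<<<<<<<<<<<<<<<<
copy_a     ATGCCTAGAAGTGTGTGATCGCATTGCTGCCAAGTATTCGATGCATCTGTTACCCAGAGG
copy_b     ATGCCTAGAAGTGAGTGATCGCATCGCTGCCAAGTATTCGATGCATCTGTTACGCAGAGG
consensus  ATGCCTAGAAGTGXGTGATCGCATXGCTGCCAAGTATTCGATGCATCTGTTACXCAGAGG
```

Other subcommands: `multiguide simple` (per-sequence sites, optional
`--nickase` pairs, BED export), `multiguide genes` (merged-exon gene
sequences from `--gff`/`--genome` or `--fixture` JSON, with exon
filtering), `multiguide isoforms` (transcripts of one gene), and
`multiguide fixtures` (synthetic ground-truth data, below).

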