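"""Gene/transcript/exon models and synthetic test fixtures.

Gene sequences are assembled by sequential merging of all exons of a
gene (union of overlapping genomic intervals, concatenated in
transcription order, reverse-complemented for − strand genes), which is
the search space for the similar-genes workflow.  Transcript sequences
are exon concatenations in transcript order and carry their exon
boundary offsets so sites can be required to lie within single exons.

The fixture generators replace an annotation database for testing: they
build pairs of diverged gene duplicates ("ohnolog" pairs, echoing
post-genome-duplication paralogs) and single genes with alternative
transcript isoforms, with *planted* common and unique target sites whose
coordinates are recorded as ground truth.  Outside the planted windows
the fixtures are scrubbed free of specification-conforming sites, so
recovery of the truth is exact by construction: no false common sites
can exist in 0-mismatch mode, and every unique site is planted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .search import SequenceRecord, find_sites, reverse_complement
from .targetspec import ALL_BASES, SiteMatcher, TargetSpec, build_matcher, parse_iupac

__all__ = [
    "Exon",
    "GeneModel",
    "CoordinateMap",
    "PlantedSite",
    "CommonTruth",
    "FixtureTruth",
    "build_gene_sequence",
    "transcript_sequence",
    "make_ohnolog_fixture",
    "make_diverged_pair",
    "make_isoform_fixture",
    "read_gene_models_gff3",
    "write_gene_models_gff3",
    "gene_models_to_json",
    "gene_models_from_json",
]

_BASES = "ACGT"


class _Retry(Exception):
    """Internal: restart fixture construction with fresh random draws."""


@dataclass
class Exon:
    exon_id: str
    genomic_start: int
    genomic_end: int
    strand: str
    gene_local_start: Optional[int] = None
    gene_local_end: Optional[int] = None

    def __post_init__(self):
        if self.genomic_end <= self.genomic_start:
            raise ValueError(
                f"exon {self.exon_id}: end ({self.genomic_end}) must exceed "
                f"start ({self.genomic_start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"exon {self.exon_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start


class CoordinateMap:
    """Bijection between gene-local positions and genomic exonic positions."""

    def __init__(self, genomic_positions: np.ndarray):
        self._to_genomic = genomic_positions
        self._to_local = {int(g): i for i, g in enumerate(genomic_positions)}

    def __len__(self) -> int:
        return len(self._to_genomic)

    def to_genomic(self, gene_local: int) -> int:
        if not 0 <= gene_local < len(self._to_genomic):
            raise IndexError(f"gene-local position {gene_local} out of range")
        return int(self._to_genomic[gene_local])

    def to_gene_local(self, genomic: int) -> int:
        try:
            return self._to_local[int(genomic)]
        except KeyError:
            raise ValueError(f"genomic position {genomic} is not exonic") from None


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def build_gene_sequence(
    exons: list[Exon], genome: str
) -> tuple[str, CoordinateMap]:
    """Merge exons into the gene sequence plus its coordinate map.

    Overlapping/adjacent genomic intervals are unioned, sorted by
    genomic coordinate and concatenated; − strand genes are read in
    genomic-descending order on the reverse complement.  The map is a
    bijection between gene-local positions and exonic genomic positions.
    """
    if not exons:
        raise ValueError("no exons")
    strands = {e.strand for e in exons}
    if len(strands) > 1:
        raise ValueError(f"exons on mixed strands: {sorted(strands)}")
    (strand,) = strands
    blocks = _merge_intervals([(e.genomic_start, e.genomic_end) for e in exons])
    if blocks[-1][1] > len(genome):
        raise ValueError("exon coordinates exceed genome length")
    concat = "".join(genome[a:b] for a, b in blocks)
    positions = np.concatenate([np.arange(a, b) for a, b in blocks])
    if strand == "-":
        concat = reverse_complement(concat)
        positions = positions[::-1]
    return concat, CoordinateMap(positions)


@dataclass
class GeneModel:
    """A gene with ordered exons, transcripts, and its merged sequence."""

    gene_id: str
    symbol: str
    species: str
    exons: list[Exon]
    transcripts: dict[str, list[str]]
    genome: str
    contig_id: str = ""

    def __post_init__(self):
        if not self.contig_id:
            self.contig_id = f"{self.gene_id}_contig"
        ids = [e.exon_id for e in self.exons]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate exon ids in gene {self.gene_id}")
        self._by_id = {e.exon_id: e for e in self.exons}
        for tid, exon_ids in self.transcripts.items():
            missing = [x for x in exon_ids if x not in self._by_id]
            if missing:
                raise ValueError(
                    f"transcript {tid} refers to unknown exons {missing}"
                )
        self.gene_sequence, self.coord_map = build_gene_sequence(self.exons, self.genome)
        for e in self.exons:
            if e.strand == "+":
                e.gene_local_start = self.coord_map.to_gene_local(e.genomic_start)
                e.gene_local_end = self.coord_map.to_gene_local(e.genomic_end - 1) + 1
            else:
                e.gene_local_start = self.coord_map.to_gene_local(e.genomic_end - 1)
                e.gene_local_end = self.coord_map.to_gene_local(e.genomic_start) + 1

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    def gene_local_exon_intervals(self) -> list[tuple[int, int]]:
        """Merged exon blocks as half-open gene-local intervals, in order."""
        blocks = _merge_intervals(
            [(e.genomic_start, e.genomic_end) for e in self.exons]
        )
        lengths = [b - a for a, b in blocks]
        if self.strand == "-":
            lengths = lengths[::-1]
        out, pos = [], 0
        for ln in lengths:
            out.append((pos, pos + ln))
            pos += ln
        return out

    def exon_sequence(self, exon_id: str) -> str:
        e = self._by_id[exon_id]
        s = self.genome[e.genomic_start : e.genomic_end]
        return reverse_complement(s) if e.strand == "-" else s

    def transcript_sequence(self, transcript_id: str) -> tuple[str, list[int]]:
        """Transcript sequence and exon boundary offsets [0, l1, l1+l2, ...]."""
        if transcript_id not in self.transcripts:
            raise KeyError(
                f"unknown transcript {transcript_id!r} of gene {self.gene_id}"
            )
        parts = [self.exon_sequence(x) for x in self.transcripts[transcript_id]]
        boundaries = [0]
        for p in parts:
            boundaries.append(boundaries[-1] + len(p))
        return "".join(parts), boundaries


def transcript_sequence(gene: GeneModel, transcript_id: str) -> tuple[str, list[int]]:
    return gene.transcript_sequence(transcript_id)


# ---------------------------------------------------------------------------
# planted-site fixtures


@dataclass(frozen=True)
class PlantedSite:
    start: int
    end: int
    strand: str
    protospacer: str


@dataclass(frozen=True)
class CommonTruth:
    """A common site planted in every sequence of the fixture.

    ``kind`` is "conserved" (identical in all sequences) or
    "seed_mismatch" (one all-base seed position differs between the
    copies; recoverable only when mismatches are allowed).
    """

    kind: str
    per_sequence: dict[str, PlantedSite]


@dataclass(frozen=True)
class FixtureTruth:
    common: list[CommonTruth]
    unique: dict[str, list[PlantedSite]]
    params: dict


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _pam_occurrences(text: str, spec: TargetSpec) -> list[tuple[int, str]]:
    """Offsets where the PAM pattern alone occurs, either orientation."""
    fwd = parse_iupac(spec.pam)
    rev = [frozenset({"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in s) for s in reversed(fwd)]
    hits = []
    for sets, strand in ((fwd, "+"), (rev, "-")):
        k = len(sets)
        for o in range(len(text) - k + 1):
            if all(text[o + j] in sets[j] for j in range(k)):
                hits.append((o, strand))
    return hits


def _random_site_text(
    rng: np.random.Generator, spec: TargetSpec, max_tries: int = 500
) -> str:
    """A concrete spec-conforming site whose only PAM occurrence is intended.

    Restricting the site text to a single internal PAM occurrence keeps
    every spurious match around a planted site disruptable without
    touching the planted window itself.
    """
    dinuc_sets = parse_iupac(spec.five_prime_dinucleotide)
    pam_sets = parse_iupac(spec.pam)
    for _ in range(max_tries):
        proto = [
            sorted(dinuc_sets[i])[rng.integers(0, len(dinuc_sets[i]))]
            for i in range(2)
        ] + [_BASES[i] for i in rng.integers(0, 4, spec.target_length - 2)]
        pam = [sorted(s)[rng.integers(0, len(s))] for s in pam_sets]
        if spec.pam_side == "three_prime":
            text = "".join(proto) + "".join(pam)
            intended = (spec.target_length, "+")
        else:
            text = "".join(pam) + "".join(proto)
            intended = (0, "+")
        if _pam_occurrences(text, spec) == [intended]:
            return text
    raise _Retry("could not sample a clean planted site text")


def _split_text(text: str, spec: TargetSpec) -> tuple[str, str]:
    if spec.pam_side == "three_prime":
        return text[: spec.target_length], text[spec.target_length :]
    return text[spec.pam_length :], text[: spec.pam_length]


def _mutate_protospacer(
    rng: np.random.Generator, text: str, spec: TargetSpec, n_changes: int
) -> str:
    """Change ``n_changes`` unconstrained protospacer positions of a site text."""
    matcher = build_matcher(spec)
    candidates = [
        i
        for i in range(len(text))
        if matcher.forward[i] == ALL_BASES and i not in matcher.pam_positions
    ]
    if len(candidates) < n_changes:
        raise ValueError("not enough unconstrained protospacer positions to mutate")
    chosen = rng.choice(len(candidates), size=n_changes, replace=False)
    out = list(text)
    for c in chosen:
        i = candidates[int(c)]
        out[i] = rng.permutation([b for b in _BASES if b != out[i]])[0]
    return "".join(out)


def _spurious_hits(seq: str, spec: TargetSpec, matcher, planted: set) -> list:
    rec = SequenceRecord("tmp", seq)
    return [
        s
        for s in find_sites(rec, spec, matcher)
        if (s.start, s.end, s.strand) not in planted
    ]


def _scrub(
    seqs: list[list[str]],
    spec: TargetSpec,
    matcher: SiteMatcher,
    frozen: set[int],
    planted: set,
    rng: np.random.Generator,
    max_sweeps: int = 200,
) -> None:
    """Remove all non-planted sites from parallel same-length sequences.

    Mutations are applied at identical coordinates with identical bases
    in every sequence of the list, so scrubbing never introduces
    sequence-specific (unique) or shared (common) sites of its own.
    """
    for _ in range(max_sweeps):
        dirty = False
        for seq in seqs:
            text = "".join(seq)
            touched: set[int] = set()
            for hit in _spurious_hits(text, spec, matcher, planted):
                if any(p in touched for p in range(hit.start, hit.end)):
                    continue  # re-scan next sweep, a mutation already landed here
                allowed = matcher.forward if hit.strand == "+" else matcher.reverse
                candidates = [
                    hit.start + i
                    for i in range(matcher.site_length)
                    if allowed[i] != ALL_BASES and (hit.start + i) not in frozen
                ]
                if not candidates:
                    raise _Retry("spurious site locked inside planted windows")
                p = int(candidates[rng.integers(0, len(candidates))])
                disallowed = sorted(ALL_BASES - allowed[p - hit.start])
                base = disallowed[rng.integers(0, len(disallowed))]
                for s in seqs:
                    s[p] = base
                touched.add(p)
                dirty = True
        if not dirty:
            return
    raise _Retry("scrub did not converge")


def _place_windows(
    rng: np.random.Generator,
    exon_intervals: list[tuple[int, int]],
    n_windows: int,
    site_len: int,
    margin: int = 10,
    separation: int = 2,
    max_tries: int = 400,
) -> list[int]:
    """Non-overlapping window starts, each fully inside one exon."""
    eligible = [
        (a + margin, b - margin - site_len)
        for a, b in exon_intervals
        if b - a >= site_len + 2 * margin
    ]
    if not eligible:
        raise ValueError("no exon long enough for a planted site; use a longer length")
    for _ in range(max_tries):
        starts: list[int] = []
        for _ in range(n_windows):
            lo, hi = eligible[rng.integers(0, len(eligible))]
            s = int(rng.integers(lo, hi + 1))
            if all(abs(s - t) >= site_len + separation for t in starts):
                starts.append(s)
        if len(starts) == n_windows:
            return sorted(starts)
    raise ValueError(
        "planted sites cannot be placed without overlap; use a longer length"
    )


def _embed(seq: list[str], start: int, text: str, strand: str) -> None:
    content = text if strand == "+" else reverse_complement(text)
    seq[start : start + len(text)] = list(content)


def _check_cross_distances(
    groups: dict[str, list[str]], minimum: int = 3, exempt: set = frozenset()
) -> None:
    """All planted protospacers across different owners must differ >=minimum."""
    owners = list(groups)
    for i, a in enumerate(owners):
        for b in owners[i + 1 :]:
            for ia, pa in enumerate(groups[a]):
                for ib, pb in enumerate(groups[b]):
                    if (a, ia, b, ib) in exempt:
                        continue
                    d = sum(x != y for x, y in zip(pa, pb))
                    if d < minimum:
                        raise _Retry("planted protospacers collide across sequences")


def _exon_layout(
    rng: np.random.Generator, total: int, n_exons: int, min_len: int
) -> list[int]:
    """Split ``total`` into n_exons parts each >= min_len."""
    if total < n_exons * min_len:
        raise ValueError("length too small for the requested exon count")
    extra = total - n_exons * min_len
    cuts = np.sort(rng.integers(0, extra + 1, n_exons - 1))
    parts = np.diff(np.concatenate([[0], cuts, [extra]]))
    return [min_len + int(p) for p in parts]


def _assemble_gene(
    gene_id: str,
    symbol: str,
    species: str,
    gene_local_seq: str,
    exon_lengths: list[int],
    strand: str,
    rng: np.random.Generator,
    intron_range: tuple[int, int] = (40, 80),
) -> GeneModel:
    """Build a GeneModel on a fresh contig from a gene-local sequence."""
    pieces = []
    pos = 0
    for ln in exon_lengths:
        pieces.append(gene_local_seq[pos : pos + ln])
        pos += ln
    introns = [
        _random_seq(rng, int(rng.integers(*intron_range)))
        for _ in range(len(pieces) - 1)
    ]
    exons: list[Exon] = []
    contig_parts: list[str] = []
    gpos = 0
    genomic_pieces = pieces if strand == "+" else [reverse_complement(p) for p in reversed(pieces)]
    n = len(pieces)
    for k, piece in enumerate(genomic_pieces):
        contig_parts.append(piece)
        start, end = gpos, gpos + len(piece)
        # exon ids follow transcription order
        order = k if strand == "+" else n - 1 - k
        exons.append(
            Exon(f"{gene_id}_e{order + 1}", start, end, strand)
        )
        gpos = end
        if k < n - 1:
            contig_parts.append(introns[k])
            gpos += len(introns[k])
    exons.sort(key=lambda e: int(e.exon_id.rsplit("e", 1)[1]))
    transcripts = {f"{gene_id}_t1": [e.exon_id for e in exons]}
    return GeneModel(
        gene_id=gene_id,
        symbol=symbol,
        species=species,
        exons=exons,
        transcripts=transcripts,
        genome="".join(contig_parts),
    )


def make_diverged_pair(
    seed: int, length: int = 1200, divergence: float = 0.1
) -> tuple[SequenceRecord, SequenceRecord]:
    """A pair of sequences diverged by random substitutions, no planting.

    Unlike the planted fixtures the background is untouched, so the pair
    carries a natural density of specification-conforming sites — the
    realistic regime for screening duplicated genes for shared guides.
    """
    rng = np.random.default_rng(seed)
    anc = _random_seq(rng, length)
    other = list(anc)
    for i in range(length):
        if rng.random() < divergence:
            other[i] = _BASES[(("ACGT".index(other[i])) + 1 + int(rng.integers(0, 3))) % 4]
    return SequenceRecord("copy_a", anc), SequenceRecord("copy_b", "".join(other))


def make_ohnolog_fixture(
    seed: int,
    length: int = 1000,
    divergence: float = 0.1,
    n_common: int = 3,
    n_unique_each: int = 2,
    spec: Optional[TargetSpec] = None,
    n_exons: int = 3,
    n_common_mismatch: int = 0,
    species: str = "synthetic",
) -> tuple[tuple[GeneModel, GeneModel], FixtureTruth]:
    """A pair of diverged gene duplicates with planted target sites.

    ``length`` is the exonic (gene-local) length of each copy.  Two gene
    models are derived from one ancestral exonic sequence by point
    substitutions at rate ``divergence`` (planted windows spared);
    ``n_common`` identical sites are planted at shared coordinates in
    both copies, ``n_common_mismatch`` planted common sites differ at
    one seed position between the copies, and each of ``n_unique_each``
    window slots receives two variants at protospacer Hamming distance
    >=3, one per copy, so each copy owns that many unique sites.  The
    background is scrubbed free of any other specification-conforming
    site.  Deterministic for a given seed.
    """
    if not 0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")
    if length <= 0 or n_common < 0 or n_unique_each < 0:
        raise ValueError("parameters must be non-negative and length positive")
    spec = spec or TargetSpec()
    matcher = build_matcher(spec)
    site_len = matcher.site_length
    n_windows = n_common + n_common_mismatch + n_unique_each
    rng = np.random.default_rng(seed)
    last_err: Optional[Exception] = None
    for _attempt in range(30):
        try:
            exon_lengths = _exon_layout(rng, length, n_exons, min_len=site_len + 10)
            bounds = []
            pos = 0
            for ln in exon_lengths:
                bounds.append((pos, pos + ln))
                pos += ln
            anc = list(_random_seq(rng, length))
            _scrub([anc], spec, matcher, frozen=set(), planted=set(), rng=rng)
            starts = _place_windows(rng, bounds, n_windows, site_len)
            order = rng.permutation(n_windows)
            slots = [starts[int(i)] for i in order]
            common_slots = slots[:n_common]
            mm_slots = slots[n_common : n_common + n_common_mismatch]
            unique_slots = slots[n_common + n_common_mismatch :]

            g1, g2 = list(anc), list(anc)
            frozen: set[int] = set()
            planted: set[tuple[int, int, str]] = set()
            common_truth: list[CommonTruth] = []
            unique_truth: dict[str, list[PlantedSite]] = {"gene_a": [], "gene_b": []}
            proto_groups: dict[str, list[str]] = {"gene_a": [], "gene_b": []}
            exempt: set = set()

            def register(start: int, strand: str) -> None:
                frozen.update(range(start, start + site_len))
                planted.add((start, start + site_len, strand))

            for s in common_slots:
                text = _random_site_text(rng, spec)
                strand = "+" if rng.random() < 0.5 else "-"
                _embed(g1, s, text, strand)
                _embed(g2, s, text, strand)
                register(s, strand)
                proto = _split_text(text, spec)[0]
                ps = PlantedSite(s, s + site_len, strand, proto)
                common_truth.append(
                    CommonTruth("conserved", {"gene_a": ps, "gene_b": ps})
                )
                ia, ib = len(proto_groups["gene_a"]), len(proto_groups["gene_b"])
                exempt.add(("gene_a", ia, "gene_b", ib))
                proto_groups["gene_a"].append(proto)
                proto_groups["gene_b"].append(proto)

            seed_fwd = sorted(
                i
                for i in matcher.seed_positions
                if matcher.forward[i] == ALL_BASES
            )
            for s in mm_slots:
                for _try in range(100):
                    text1 = _random_site_text(rng, spec)
                    i = seed_fwd[int(rng.integers(0, len(seed_fwd)))]
                    t2 = list(text1)
                    t2[i] = rng.permutation([b for b in _BASES if b != t2[i]])[0]
                    text2 = "".join(t2)
                    if _pam_occurrences(text2, spec) == _pam_occurrences(text1, spec):
                        break
                else:
                    raise _Retry("seed mutation kept creating PAM occurrences")
                strand = "+" if rng.random() < 0.5 else "-"
                _embed(g1, s, text1, strand)
                _embed(g2, s, text2, strand)
                register(s, strand)
                p1, p2 = _split_text(text1, spec)[0], _split_text(text2, spec)[0]
                common_truth.append(
                    CommonTruth(
                        "seed_mismatch",
                        {
                            "gene_a": PlantedSite(s, s + site_len, strand, p1),
                            "gene_b": PlantedSite(s, s + site_len, strand, p2),
                        },
                    )
                )
                ia, ib = len(proto_groups["gene_a"]), len(proto_groups["gene_b"])
                exempt.add(("gene_a", ia, "gene_b", ib))
                proto_groups["gene_a"].append(p1)
                proto_groups["gene_b"].append(p2)

            for s in unique_slots:
                for _try in range(100):
                    text1 = _random_site_text(rng, spec)
                    n_changes = 3 + int(rng.integers(0, 3))
                    text2 = _mutate_protospacer(rng, text1, spec, n_changes)
                    if _pam_occurrences(text2, spec) == _pam_occurrences(text1, spec):
                        break
                else:
                    raise _Retry("unique-site mutation kept creating PAM occurrences")
                strand = "+" if rng.random() < 0.5 else "-"
                _embed(g1, s, text1, strand)
                _embed(g2, s, text2, strand)
                register(s, strand)
                p1, p2 = _split_text(text1, spec)[0], _split_text(text2, spec)[0]
                unique_truth["gene_a"].append(PlantedSite(s, s + site_len, strand, p1))
                unique_truth["gene_b"].append(PlantedSite(s, s + site_len, strand, p2))
                proto_groups["gene_a"].append(p1)
                proto_groups["gene_b"].append(p2)

            for i in range(length):
                if i not in frozen and rng.random() < divergence:
                    g2[i] = _BASES[("ACGT".index(g2[i]) + 1 + int(rng.integers(0, 3))) % 4]

            _scrub([g1, g2], spec, matcher, frozen, planted, rng)
            _check_cross_distances(proto_groups, exempt=exempt)

            gene_a = _assemble_gene(
                "gene_a", "dupa", species, "".join(g1), exon_lengths, "+", rng
            )
            gene_b = _assemble_gene(
                "gene_b", "dupb", species, "".join(g2), exon_lengths, "-", rng
            )
            truth = FixtureTruth(
                common=common_truth,
                unique=unique_truth,
                params={
                    "seed": seed,
                    "length": length,
                    "divergence": divergence,
                    "n_common": n_common,
                    "n_common_mismatch": n_common_mismatch,
                    "n_unique_each": n_unique_each,
                },
            )
            return (gene_a, gene_b), truth
        except _Retry as exc:
            last_err = exc
            continue
    raise ValueError(
        f"sites cannot be placed cleanly ({last_err}); try a longer length"
    )


def make_isoform_fixture(
    seed: int,
    n_exons: int = 5,
    n_transcripts: int = 3,
    alt_exon_length: int = 120,
    spec: Optional[TargetSpec] = None,
    species: str = "synthetic",
) -> tuple[GeneModel, FixtureTruth]:
    """One gene with alternative transcript isoforms and planted sites.

    Constitutive exons are shared by all transcripts and carry one
    planted common site; each transcript additionally includes one
    private alternative exon with one planted isoform-specific site.
    Truth coordinates are in transcript coordinates per transcript.
    """
    if n_transcripts < 2:
        raise ValueError("need at least 2 transcripts")
    if n_exons < 3:
        raise ValueError("need at least 3 exons")
    if n_exons < n_transcripts + 1:
        raise ValueError(
            "parameter combination leaves no private exon per transcript "
            "(need n_exons >= n_transcripts + 1)"
        )
    spec = spec or TargetSpec()
    matcher = build_matcher(spec)
    site_len = matcher.site_length
    if alt_exon_length < site_len + 20:
        raise ValueError(
            f"alt_exon_length must be at least {site_len + 20} to carry a planted site"
        )
    gene_id = "gene_iso"
    rng = np.random.default_rng(seed)
    last_err: Optional[Exception] = None
    for _attempt in range(30):
        try:
            private_idx = sorted(
                int(i) for i in rng.choice(n_exons, size=n_transcripts, replace=False)
            )
            exon_lengths = [
                alt_exon_length
                if k in private_idx
                else int(rng.integers(max(80, site_len + 10), 150))
                for k in range(n_exons)
            ]
            exon_seqs = [list(_random_seq(rng, ln)) for ln in exon_lengths]
            for es in exon_seqs:
                _scrub([es], spec, matcher, set(), set(), rng)

            # planted sites in exon-local coordinates
            planted_by_exon: dict[int, tuple[int, str, str]] = {}
            protos: dict[str, list[str]] = {}
            constitutive = [k for k in range(n_exons) if k not in private_idx]
            common_exon = constitutive[0]
            text = _random_site_text(rng, spec)
            strand = "+" if rng.random() < 0.5 else "-"
            off = int(rng.integers(10, exon_lengths[common_exon] - site_len - 9))
            _embed(exon_seqs[common_exon], off, text, strand)
            planted_by_exon[common_exon] = (off, strand, text)
            common_proto = _split_text(text, spec)[0]

            tids = [f"{gene_id}_t{i + 1}" for i in range(n_transcripts)]
            for tid, k in zip(tids, private_idx):
                text = _random_site_text(rng, spec)
                strand = "+" if rng.random() < 0.5 else "-"
                off = int(rng.integers(10, exon_lengths[k] - site_len - 9))
                _embed(exon_seqs[k], off, text, strand)
                planted_by_exon[k] = (off, strand, text)
                protos[tid] = [_split_text(text, spec)[0]]
            _check_cross_distances(protos)
            for tid in tids:  # unique sites must also be far from the shared site
                for p in protos[tid]:
                    if sum(x != y for x, y in zip(p, common_proto)) < 3:
                        raise _Retry("planted unique site too close to common site")

            transcripts = {
                tid: [f"{gene_id}_e{k + 1}" for k in sorted(constitutive + [pk])]
                for tid, pk in zip(tids, private_idx)
            }

            # scrub junction-spanning and residual sites at transcript level
            exon_frozen = {
                k: set(range(off, off + site_len))
                for k, (off, _, _) in planted_by_exon.items()
            }
            for _sweep in range(200):
                dirty = False
                for tid in tids:
                    order = [int(x.rsplit("e", 1)[1]) - 1 for x in transcripts[tid]]
                    seq = "".join("".join(exon_seqs[k]) for k in order)
                    offsets = {}
                    pos = 0
                    for k in order:
                        offsets[k] = pos
                        pos += exon_lengths[k]
                    planted_t = set()
                    for k in order:
                        if k in planted_by_exon:
                            off, st, _ = planted_by_exon[k]
                            planted_t.add(
                                (offsets[k] + off, offsets[k] + off + site_len, st)
                            )
                    frozen_t = {
                        offsets[k] + p for k in order for p in exon_frozen.get(k, ())
                    }
                    hits = _spurious_hits(seq, spec, matcher, planted_t)
                    if not hits:
                        continue
                    hit = hits[0]
                    allowed = (
                        matcher.forward if hit.strand == "+" else matcher.reverse
                    )
                    candidates = [
                        hit.start + i
                        for i in range(site_len)
                        if allowed[i] != ALL_BASES and (hit.start + i) not in frozen_t
                    ]
                    if not candidates:
                        raise _Retry("transcript site locked inside planted windows")
                    p = int(candidates[rng.integers(0, len(candidates))])
                    disallowed = sorted(ALL_BASES - allowed[p - hit.start])
                    base = disallowed[rng.integers(0, len(disallowed))]
                    for k in order:  # map back to the owning exon
                        if offsets[k] <= p < offsets[k] + exon_lengths[k]:
                            exon_seqs[k][p - offsets[k]] = base
                            break
                    dirty = True
                    break
                if not dirty:
                    break
            else:
                raise _Retry("transcript scrub did not converge")

            gene_local = "".join("".join(es) for es in exon_seqs)
            gene = _assemble_gene(
                gene_id, "isog", species, gene_local, exon_lengths, "+", rng,
                intron_range=(50, 90),
            )
            gene.transcripts = transcripts  # replace the default all-exon transcript

            common_per_seq = {}
            unique_truth: dict[str, list[PlantedSite]] = {}
            for tid, pk in zip(tids, private_idx):
                order = [int(x.rsplit("e", 1)[1]) - 1 for x in transcripts[tid]]
                offsets = {}
                pos = 0
                for k in order:
                    offsets[k] = pos
                    pos += exon_lengths[k]
                coff, cstr, ctext = planted_by_exon[common_exon]
                common_per_seq[tid] = PlantedSite(
                    offsets[common_exon] + coff,
                    offsets[common_exon] + coff + site_len,
                    cstr,
                    _split_text(ctext, spec)[0],
                )
                uoff, ustr, utext = planted_by_exon[pk]
                unique_truth[tid] = [
                    PlantedSite(
                        offsets[pk] + uoff,
                        offsets[pk] + uoff + site_len,
                        ustr,
                        _split_text(utext, spec)[0],
                    )
                ]
            truth = FixtureTruth(
                common=[CommonTruth("conserved", common_per_seq)],
                unique=unique_truth,
                params={
                    "seed": seed,
                    "n_exons": n_exons,
                    "n_transcripts": n_transcripts,
                    "alt_exon_length": alt_exon_length,
                },
            )
            return gene, truth
        except _Retry as exc:
            last_err = exc
            continue
    raise ValueError(f"isoform fixture construction failed ({last_err})")


# ---------------------------------------------------------------------------
# gene model I/O


def gene_models_to_json(genes: list[GeneModel]) -> dict:
    return {
        "genes": [
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "species": g.species,
                "contig_id": g.contig_id,
                "contig_sequence": g.genome,
                "exons": [
                    {
                        "exon_id": e.exon_id,
                        "start": e.genomic_start,
                        "end": e.genomic_end,
                        "strand": e.strand,
                    }
                    for e in g.exons
                ],
                "transcripts": g.transcripts,
            }
            for g in genes
        ]
    }


def gene_models_from_json(payload: dict) -> list[GeneModel]:
    genes = []
    for g in payload["genes"]:
        genes.append(
            GeneModel(
                gene_id=g["gene_id"],
                symbol=g.get("symbol", g["gene_id"]),
                species=g.get("species", "unknown"),
                exons=[
                    Exon(x["exon_id"], x["start"], x["end"], x["strand"])
                    for x in g["exons"]
                ],
                transcripts={t: list(v) for t, v in g["transcripts"].items()},
                genome=g["contig_sequence"],
                contig_id=g.get("contig_id", ""),
            )
        )
    return genes


def write_gene_models_gff3(
    genes: list[GeneModel], gff_path: str | Path, fasta_path: str | Path
) -> None:
    """Write gene models as GFF3 plus their contigs as FASTA (1-based GFF)."""
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for g in genes:
            lo = min(e.genomic_start for e in g.exons)
            hi = max(e.genomic_end for e in g.exons)
            gff.write(
                f"{g.contig_id}\tmultiguide\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.symbol}\n"
            )
            for tid, exon_ids in sorted(g.transcripts.items()):
                t_exons = [e for e in g.exons if e.exon_id in exon_ids]
                tlo = min(e.genomic_start for e in t_exons)
                thi = max(e.genomic_end for e in t_exons)
                gff.write(
                    f"{g.contig_id}\tmultiguide\tmRNA\t{tlo + 1}\t{thi}\t.\t"
                    f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
                )
                for e in t_exons:
                    gff.write(
                        f"{g.contig_id}\tmultiguide\texon\t{e.genomic_start + 1}\t"
                        f"{e.genomic_end}\t.\t{e.strand}\t.\t"
                        f"ID={tid}:{e.exon_id};Parent={tid}\n"
                    )
    with open(fasta_path, "w") as fa:
        for g in genes:
            fa.write(f">{g.contig_id}\n")
            for i in range(0, len(g.genome), 70):
                fa.write(g.genome[i : i + 70] + "\n")


def read_gene_models_gff3(
    gff_path: str | Path, fasta_path: str | Path, species: str = "unknown"
) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon features) plus genome FASTA."""
    import gffutils
    from Bio import SeqIO

    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene_feat in db.features_of_type("gene"):
        transcripts: dict[str, list[str]] = {}
        exon_map: dict[str, Exon] = {}
        for mrna in db.children(gene_feat, featuretype="mRNA"):
            exon_ids = []
            for ex in db.children(mrna, featuretype="exon", order_by="start"):
                raw_id = ex.id.split(":")[-1]
                if raw_id not in exon_map:
                    exon_map[raw_id] = Exon(
                        raw_id, ex.start - 1, ex.end, ex.strand
                    )
                exon_ids.append(raw_id)
            if gene_feat.strand == "-":
                exon_ids = exon_ids[::-1]  # transcription order
            transcripts[mrna.id] = exon_ids
        exons = sorted(
            exon_map.values(),
            key=lambda e: e.genomic_start if gene_feat.strand == "+" else -e.genomic_end,
        )
        if gene_feat.seqid not in contigs:
            raise ValueError(f"contig {gene_feat.seqid!r} missing from FASTA")
        genes.append(
            GeneModel(
                gene_id=gene_feat.id,
                symbol=gene_feat.attributes.get("Name", [gene_feat.id])[0],
                species=species,
                exons=exons,
                transcripts=transcripts,
                genome=contigs[gene_feat.seqid],
                contig_id=gene_feat.seqid,
            )
        )
    return genes


def truth_to_json(truth: FixtureTruth) -> dict:
    return {
        "common": [
            {
                "kind": c.kind,
                "per_sequence": {
                    sid: {
                        "start": p.start,
                        "end": p.end,
                        "strand": p.strand,
                        "protospacer": p.protospacer,
                    }
                    for sid, p in c.per_sequence.items()
                },
            }
            for c in truth.common
        ],
        "unique": {
            sid: [
                {
                    "start": p.start,
                    "end": p.end,
                    "strand": p.strand,
                    "protospacer": p.protospacer,
                }
                for p in sites
            ]
            for sid, sites in truth.unique.items()
        },
        "params": truth.params,
    }


def truth_from_json(payload: dict) -> FixtureTruth:
    return FixtureTruth(
        common=[
            CommonTruth(
                c["kind"],
                {
                    sid: PlantedSite(p["start"], p["end"], p["strand"], p["protospacer"])
                    for sid, p in c["per_sequence"].items()
                },
            )
            for c in payload["common"]
        ],
        unique={
            sid: [
                PlantedSite(p["start"], p["end"], p["strand"], p["protospacer"])
                for p in sites
            ]
            for sid, sites in payload["unique"].items()
        },
        params=payload.get("params", {}),
    )
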