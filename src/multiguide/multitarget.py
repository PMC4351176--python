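"""Common and unique target sites across sets of similar sequences.

Two complementary screens:

- **Common sites** are found by sliding the site matcher over the
  alignment consensus (and its reverse complement; X complements to X,
  gaps never match).  A hit means every aligned sequence carries a valid
  site at the same aligned position; at most one consensus X is
  tolerated, only in the PAM-distal seed region when mismatches are
  allowed, so a single guide can still bind every sequence.

- **Unique sites** are found by exhaustive comparison: every
  PAM-containing site of every sequence (both strands) is compared with
  every site of every *other* sequence by protospacer Hamming distance,
  scanning 5'->3' and stopping early once more than ``stop_after``
  (default 2) mismatches accumulate.  A site is unique when every
  cross-sequence distance is at least 3 — distant enough that the guide
  does not cut the other sequences.

Sites from gene or transcript searches can additionally be required to
lie completely within one exon, so that the matched sequence exists
contiguously in the genome rather than being an artifact of splicing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genemodel import GeneModel
from .search import SequenceRecord, TargetSite, find_sites, reverse_complement
from .targetspec import MatchKind, TargetSpec, build_matcher, site_matches
from .alignment import MultiAlignment, compute_consensus

__all__ = [
    "CommonSite",
    "UniqueSite",
    "find_common_sites",
    "hamming_compare",
    "find_unique_sites",
    "filter_within_exon",
]


@dataclass
class CommonSite:
    """A site present in every aligned sequence at one consensus window."""

    consensus_start: int
    consensus_end: int
    strand: str
    mismatch_column: Optional[int]
    #: one TargetSite per input sequence, keyed by sequence id in row order
    per_sequence_sites: dict[str, TargetSite]


@dataclass
class UniqueSite:
    """A site of one sequence at protospacer distance >=3 from all others.

    ``min_cross_distance`` is the smallest full Hamming distance to any
    site of any other sequence; ``None`` when the other sequences carry
    no sites at all.
    """

    owner_sequence_id: str
    site: TargetSite
    min_cross_distance: Optional[int]


def find_common_sites(aln: MultiAlignment, spec: TargetSpec) -> list[CommonSite]:
    """Slide the matcher over the alignment consensus, both orientations.

    Windows containing a gap column never match.  A consensus X matches
    an unconstrained PAM position outright, and counts as the single
    permitted seed mismatch at an unconstrained protospacer position
    when ``spec.allow_seed_mismatch`` is set; X never matches a
    constrained position.  Each hit is mapped through the per-row
    column->coordinate maps into one TargetSite per sequence.
    """
    if aln.nrows < 2:
        raise ValueError("common-site search needs an alignment of >=2 sequences")
    matcher = build_matcher(spec)
    slen = matcher.site_length
    consensus = compute_consensus(aln).symbols
    seqs = aln.sequences()
    hits: list[CommonSite] = []
    for orientation in ("+", "-"):
        for c in range(len(consensus) - slen + 1):
            window = consensus[c : c + slen]
            res = site_matches(
                matcher,
                window,
                allow_seed_mismatch=spec.allow_seed_mismatch,
                orientation=orientation,
            )
            if res.kind is MatchKind.NO_MATCH:
                continue
            per_seq: dict[str, TargetSite] = {}
            for rid in aln.ids:
                s0 = aln.column_to_sequence_coord(rid, c)
                s1 = aln.column_to_sequence_coord(rid, c + slen - 1)
                if s0 is None or s1 is None or s1 - s0 != slen - 1:
                    per_seq = {}
                    break  # window split by a row-specific gap
                row_window = seqs[rid][s0 : s1 + 1]
                if orientation == "-":
                    row_window = reverse_complement(row_window)
                if spec.pam_side == "three_prime":
                    proto, pam = row_window[: spec.target_length], row_window[spec.target_length :]
                else:
                    proto, pam = row_window[spec.pam_length :], row_window[: spec.pam_length]
                per_seq[rid] = TargetSite(
                    sequence_id=rid,
                    strand=orientation,
                    start=s0,
                    end=s1 + 1,
                    protospacer=proto,
                    pam_observed=pam,
                    seed_mismatch_position=res.seed_mismatch_position,
                )
            if not per_seq:
                continue
            mismatch_column = (
                c + res.window_position if res.window_position is not None else None
            )
            hits.append(
                CommonSite(
                    consensus_start=c,
                    consensus_end=c + slen,
                    strand=orientation,
                    mismatch_column=mismatch_column,
                    per_sequence_sites=per_seq,
                )
            )
    hits.sort(key=lambda h: (h.consensus_start, h.strand))
    return hits


def hamming_compare(a: str, b: str, stop_after: int = 2) -> tuple[int, bool]:
    """5'->3' mismatch count with early termination.

    Returns ``(distance, stopped_early)`` where the distance is capped
    at ``stop_after + 1``: the scan stops as soon as more than
    ``stop_after`` mismatches have been seen, since the exact value is
    then irrelevant for the uniqueness decision.
    """
    if len(a) != len(b):
        raise ValueError(f"cannot compare protospacers of lengths {len(a)} and {len(b)}")
    dist = 0
    for x, y in zip(a, b):
        if x != y:
            dist += 1
            if dist > stop_after:
                return dist, True
    return dist, False


def find_unique_sites(
    records: list[SequenceRecord],
    spec: TargetSpec,
    stop_after: int = 2,
) -> list[UniqueSite]:
    """Sites unique to exactly one sequence among the inputs.

    Enumerates all PAM-containing sites per sequence (both strands); a
    site is unique iff its protospacer is at Hamming distance
    ``> stop_after`` from every site of every other sequence.  Duplicate
    occurrences within the owner sequence do not disqualify a site
    (uniqueness means absence from the *other* sequences).  Results are
    grouped by owner in input order, then site order.
    """
    if len(records) < 2:
        raise ValueError("unique-site search needs at least 2 sequences")
    matcher = build_matcher(spec)
    all_sites = {rec.id: find_sites(rec, spec, matcher) for rec in records}
    unique: list[UniqueSite] = []
    for rec in records:
        others = [
            s for other in records if other.id != rec.id for s in all_sites[other.id]
        ]
        for site in all_sites[rec.id]:
            is_unique = True
            for t in others:
                dist, _ = hamming_compare(site.protospacer, t.protospacer, stop_after)
                if dist <= stop_after:
                    is_unique = False
                    break
            if not is_unique:
                continue
            min_dist = (
                min(
                    sum(x != y for x, y in zip(site.protospacer, t.protospacer))
                    for t in others
                )
                if others
                else None
            )
            unique.append(
                UniqueSite(
                    owner_sequence_id=rec.id, site=site, min_cross_distance=min_dist
                )
            )
    return unique


def filter_within_exon(
    sites: list[TargetSite],
    gene: GeneModel,
    context: str = "gene",
    transcript_id: Optional[str] = None,
) -> list[TargetSite]:
    """Keep only sites lying completely within one exon.

    ``context='gene'`` interprets site coordinates in the merged-exon
    gene-local system and tests them against the merged exon blocks;
    ``context='transcript'`` interprets them in transcript coordinates
    of ``transcript_id`` (or, when absent, of each site's
    ``sequence_id``).  Surviving sites get an ``exon_index`` annotation
    (0-based position of the containing exon).  Sites straddling an exon
    junction are removed; sites flush with an exon boundary are kept
    (half-open interval containment).
    """
    if context not in ("gene", "transcript"):
        raise ValueError(f"context must be 'gene' or 'transcript', got {context!r}")
    kept: list[TargetSite] = []
    for site in sites:
        if context == "gene":
            intervals = gene.gene_local_exon_intervals()
            seq_len = len(gene.gene_sequence)
        else:
            tid = transcript_id or site.sequence_id
            _, boundaries = gene.transcript_sequence(tid)
            intervals = list(zip(boundaries[:-1], boundaries[1:]))
            seq_len = boundaries[-1]
        if site.start < 0 or site.end > seq_len:
            raise ValueError(
                f"site {site.start}-{site.end} outside sequence bounds [0,{seq_len})"
            )
        for idx, (a, b) in enumerate(intervals):
            if a <= site.start and site.end <= b:
                site.annotations["exon_index"] = idx
                kept.append(site)
                break
    return kept
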