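"""Enumeration of sgRNA target sites on both strands of single sequences.

The search slides the compiled site matcher over every window of the
sequence and its reverse complement, reporting all exact hits including
overlapping ones.  Windows are vectorized over numpy boolean tables, so
enumeration stays fast on kilobase-scale gene sequences; the per-window
:func:`multiguide.targetspec.site_matches` predicate remains the
reference semantics (the two agree by the package's property tests).

Also provides assembly of opposite-strand site pairs for double-nicking
(Cas9 nickase) designs: PAM-out orientation, cut sites 3 bp
PAM-proximal, offset window configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .targetspec import ALL_BASES, SiteMatcher, TargetSpec, build_matcher

__all__ = [
    "SequenceRecord",
    "TargetSite",
    "NickasePair",
    "reverse_complement",
    "find_sites",
    "find_nickase_pairs",
]

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")

# byte code -> base index (A0 C1 G2 T3 N4); 255 marks invalid characters
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid characters for reverse complement: {sorted(bad)}")
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One input DNA sequence, normalized to uppercase {A,C,G,T,N}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside A/C/G/T/N: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TargetSite:
    """One located protospacer+PAM hit.

    ``start``/``end`` are 0-based half-open coordinates of the full site
    (protospacer + PAM) on the forward strand of the source sequence.
    ``protospacer`` and ``pam_observed`` read 5'->3' of the guide, i.e.
    they are taken from the reverse complement of the window for −
    strand sites.
    """

    sequence_id: str
    strand: str
    start: int
    end: int
    protospacer: str
    pam_observed: str
    seed_mismatch_position: Optional[int] = None
    annotations: dict = field(default_factory=dict)

    @property
    def site_length(self) -> int:
        return self.end - self.start

    def guide_window(self, residues: str) -> str:
        """The site window read in guide orientation from the source residues."""
        window = residues[self.start : self.end]
        return reverse_complement(window) if self.strand == "-" else window

    def check_round_trip(self, record: SequenceRecord, pam_side: str = "three_prime"):
        """Verify the site reconstructs from its source sequence exactly."""
        if self.end - self.start != len(self.protospacer) + len(self.pam_observed):
            raise AssertionError("site span does not equal protospacer + PAM length")
        window = self.guide_window(record.residues)
        if pam_side == "three_prime":
            expected = self.protospacer + self.pam_observed
        else:
            expected = self.pam_observed + self.protospacer
        if window != expected:
            raise AssertionError(
                f"site at {self.sequence_id}:{self.start}-{self.end}{self.strand} "
                f"does not round-trip: window {window!r} != {expected!r}"
            )


@dataclass(frozen=True)
class NickasePair:
    """Two opposite-strand sites in PAM-out orientation for double nicking."""

    site_plus: TargetSite
    site_minus: TargetSite
    cut_offset: int


def _allowed_table(allowed: tuple[frozenset, ...]) -> np.ndarray:
    """(site_length, 5) boolean table; column 4 (N) true only for all-base."""
    table = np.zeros((len(allowed), 5), dtype=bool)
    for p, bases in enumerate(allowed):
        for b in bases:
            table[p, "ACGT".index(b)] = True
        table[p, 4] = bases == ALL_BASES
    return table


def _scan(codes: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Start positions where every window position hits its allowed set."""
    slen = table.shape[0]
    n_win = codes.size - slen + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64)
    ok = np.ones(n_win, dtype=bool)
    for p in range(slen):
        ok &= table[p][codes[p : p + n_win]]
    return np.nonzero(ok)[0]


def _split_guide(window: str, spec: TargetSpec) -> tuple[str, str]:
    """(protospacer, pam) from a guide-orientation window."""
    if spec.pam_side == "three_prime":
        return window[: spec.target_length], window[spec.target_length :]
    return window[spec.pam_length :], window[: spec.pam_length]


def find_sites(
    record: SequenceRecord,
    spec: TargetSpec,
    matcher: Optional[SiteMatcher] = None,
) -> list[TargetSite]:
    """All exact target sites on both strands of one sequence.

    Every window of site length is tested on both orientations;
    overlapping hits are all reported.  The seed-mismatch option plays
    no role in single-sequence search (a concrete base either satisfies
    the specification or not).  Returns sites sorted by (start, strand)
    with '+' before '-'.  A sequence shorter than the site length yields
    an empty list.
    """
    if matcher is None:
        matcher = build_matcher(spec)
    codes = np.frombuffer(record.residues.encode("ascii"), dtype=np.uint8)
    codes = _CODE[codes]
    sites: list[TargetSite] = []
    for strand, allowed in (("+", matcher.forward), ("-", matcher.reverse)):
        table = _allowed_table(allowed)
        for start in _scan(codes, table):
            start = int(start)
            end = start + matcher.site_length
            window = record.residues[start:end]
            if strand == "-":
                window = reverse_complement(window)
            proto, pam = _split_guide(window, spec)
            sites.append(
                TargetSite(
                    sequence_id=record.id,
                    strand=strand,
                    start=start,
                    end=end,
                    protospacer=proto,
                    pam_observed=pam,
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))  # '+' < '-' in ASCII
    return sites


def _cut_position(site: TargetSite, pam_side: str) -> int:
    """Forward-strand coordinate of the nick, 3 bp PAM-proximal.

    For the canonical 3' PAM geometry this is the blunt double-strand
    cut position 3 bp 5' of the PAM (between protospacer positions 17/18
    of a 20-mer).
    """
    pam_len = len(site.pam_observed)
    if pam_side == "three_prime":
        if site.strand == "+":
            return site.end - pam_len - 3
        return site.start + pam_len + 3
    if site.strand == "+":
        return site.start + pam_len + 3
    return site.end - pam_len - 3


def find_nickase_pairs(
    sites: list[TargetSite],
    offset_min: int = 0,
    offset_max: int = 31,
    pam_side: str = "three_prime",
) -> list[NickasePair]:
    """All PAM-out (+,−) site pairs with cut-site offset in the window.

    ``offset`` is the separation between the two nicks measured in the
    PAM-out sense (the − site's nick upstream of the + site's nick for a
    3' PAM); pairs whose PAMs face inward are never reported.
    """
    if offset_min > offset_max:
        raise ValueError(f"offset_min ({offset_min}) > offset_max ({offset_max})")
    seq_ids = {s.sequence_id for s in sites}
    if len(seq_ids) > 1:
        raise ValueError(f"sites from multiple sequences: {sorted(seq_ids)}")
    plus = [s for s in sites if s.strand == "+"]
    minus = [s for s in sites if s.strand == "-"]
    pairs = []
    for p in plus:
        cut_p = _cut_position(p, pam_side)
        for m in minus:
            cut_m = _cut_position(m, pam_side)
            if pam_side == "three_prime":
                offset = cut_p - cut_m
            else:
                offset = cut_m - cut_p
            if offset < 0:
                continue  # PAM-in arrangement
            if offset_min <= offset <= offset_max:
                pairs.append(NickasePair(site_plus=p, site_minus=m, cut_offset=offset))
    pairs.sort(key=lambda pr: (pr.site_minus.start, pr.site_plus.start))
    return pairs
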