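"""sgRNA target-site specifications and compiled site matchers.

A target site is a protospacer of fixed length flanked by a PAM
(protospacer adjacent motif) on its 5' or 3' side.  The user-facing
specification captures the few sequence constraints a CRISPR/Cas system
imposes: the PAM pattern (IUPAC alphabet), which side it sits on, the
protospacer length, the 5'-most dinucleotide required by the sgRNA
expression method (NN = unconstrained, GN = U6 promoter, GG = T7
polymerase), and whether a single guide:target mismatch is tolerated in
the PAM-distal seed region.

The compiled :class:`SiteMatcher` holds per-position allowed-base sets
for the full site (protospacer + PAM) in forward orientation together
with the mirrored reverse-complement structure, so windows on either
genomic strand can be tested directly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "IUPAC_CODES",
    "ALL_BASES",
    "TargetSpec",
    "SiteMatcher",
    "MatchKind",
    "MatchResult",
    "parse_iupac",
    "build_matcher",
    "site_matches",
]

#: 15-letter IUPAC DNA alphabet mapped to the set of bases each code allows.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

ALL_BASES = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_DINUCLEOTIDES = ("NN", "GN", "GG")
_PAM_SIDES = ("five_prime", "three_prime")


def parse_iupac(pattern: str) -> list[frozenset[str]]:
    """Expand an IUPAC pattern into per-position allowed-base sets.

    Case-insensitive.  Raises ``ValueError`` naming the offending
    character and its (1-based) position for anything outside the
    15-letter alphabet.
    """
    if not pattern:
        raise ValueError("empty IUPAC pattern")
    sets = []
    for i, ch in enumerate(pattern.upper()):
        try:
            sets.append(frozenset(IUPAC_CODES[ch]))
        except KeyError:
            raise ValueError(
                f"invalid IUPAC character {ch!r} at position {i + 1} of {pattern!r}"
            ) from None
    return sets


@dataclass(frozen=True)
class TargetSpec:
    """User-definable sgRNA target-site pattern.

    Defaults describe the S. pyogenes type II system: a 20-nt
    protospacer with an unconstrained 5' dinucleotide and a 3' NGG PAM.
    ``seed_region_length`` defaults to 8 (PAM-distal); the single-seed
    mismatch allowance is validated only for type II systems and should
    be used with care for other PAM geometries.
    """

    target_length: int = 20
    five_prime_dinucleotide: str = "NN"
    pam: str = "NGG"
    pam_side: str = "three_prime"
    allow_seed_mismatch: bool = False
    seed_region_length: int = 8

    def __post_init__(self):
        object.__setattr__(self, "pam", self.pam.upper())
        object.__setattr__(
            self, "five_prime_dinucleotide", self.five_prime_dinucleotide.upper()
        )
        if self.five_prime_dinucleotide not in _DINUCLEOTIDES:
            raise ValueError(
                f"five_prime_dinucleotide must be one of {_DINUCLEOTIDES}, "
                f"got {self.five_prime_dinucleotide!r}"
            )
        if self.pam_side not in _PAM_SIDES:
            raise ValueError(f"pam_side must be one of {_PAM_SIDES}, got {self.pam_side!r}")
        if self.seed_region_length < 1:
            raise ValueError("seed_region_length must be positive")
        if self.target_length < self.seed_region_length + 2:
            raise ValueError(
                f"target_length ({self.target_length}) must be at least "
                f"seed_region_length + 2 ({self.seed_region_length + 2})"
            )
        parse_iupac(self.pam)  # validates the PAM alphabet

    @property
    def pam_length(self) -> int:
        return len(self.pam)

    @property
    def site_length(self) -> int:
        return self.target_length + self.pam_length


class MatchKind(enum.Enum):
    NO_MATCH = "no_match"
    EXACT = "exact"
    SEED_MISMATCH = "seed_mismatch"


@dataclass(frozen=True)
class MatchResult:
    kind: MatchKind
    #: protospacer position (0-based, 5'->3' of the guide) of the tolerated
    #: seed mismatch, when kind is SEED_MISMATCH.
    seed_mismatch_position: Optional[int] = None
    #: same mismatch as an index into the matched window.
    window_position: Optional[int] = None

    def __bool__(self) -> bool:
        return self.kind is not MatchKind.NO_MATCH


@dataclass(frozen=True)
class SiteMatcher:
    """Compiled per-position matcher for a full target site.

    ``forward`` lists the allowed-base set for every position of the
    site as it reads on the + strand (protospacer then PAM for a 3' PAM,
    PAM then protospacer for a 5' PAM).  ``reverse`` is the
    complement-reversed mirror used to test + strand windows for
    − strand sites.  ``pam_positions`` / ``seed_positions`` are indices
    into the forward layout.
    """

    spec: TargetSpec
    forward: tuple[frozenset[str], ...]
    reverse: tuple[frozenset[str], ...]
    pam_positions: frozenset[int]
    seed_positions: frozenset[int]

    @property
    def site_length(self) -> int:
        return len(self.forward)

    def protospacer_position(self, forward_index: int) -> Optional[int]:
        """Map a forward site index to a protospacer index, or None for PAM."""
        if forward_index in self.pam_positions:
            return None
        if self.spec.pam_side == "three_prime":
            return forward_index
        return forward_index - self.spec.pam_length

    def forward_index(self, window_index: int, orientation: str) -> int:
        """Map an index in a matched window to the forward site layout."""
        if orientation == "+":
            return window_index
        return self.site_length - 1 - window_index


def _complement_set(bases: frozenset[str]) -> frozenset[str]:
    return frozenset(_COMPLEMENT[b] for b in bases)


def build_matcher(spec: TargetSpec) -> SiteMatcher:
    """Compile a :class:`TargetSpec` into a strand-aware :class:`SiteMatcher`."""
    proto = parse_iupac(spec.five_prime_dinucleotide) + [ALL_BASES] * (
        spec.target_length - 2
    )
    pam = parse_iupac(spec.pam)
    if spec.pam_side == "three_prime":
        forward = proto + pam
        pam_positions = frozenset(
            range(spec.target_length, spec.target_length + spec.pam_length)
        )
        # seed = PAM-distal start of the protospacer
        seed = frozenset(range(spec.seed_region_length))
    else:
        forward = pam + proto
        pam_positions = frozenset(range(spec.pam_length))
        # seed = PAM-distal end of the protospacer
        seed = frozenset(
            range(
                spec.pam_length + spec.target_length - spec.seed_region_length,
                spec.pam_length + spec.target_length,
            )
        )
    reverse = tuple(_complement_set(s) for s in reversed(forward))
    return SiteMatcher(
        spec=spec,
        forward=tuple(forward),
        reverse=reverse,
        pam_positions=pam_positions,
        seed_positions=seed,
    )


def site_matches(
    matcher: SiteMatcher,
    window: str,
    allow_seed_mismatch: bool = False,
    orientation: str = "+",
) -> MatchResult:
    """Test one window against the matcher.

    ``window`` reads along the + strand of the source (use
    ``orientation='-'`` to test for a − strand site at the same
    coordinates).  Besides plain {A,C,G,T} the window may contain the
    degenerate/consensus symbols used elsewhere in the package:

    - ``N`` satisfies only fully unconstrained (all-base) positions;
    - ``-`` (alignment gap) never matches;
    - ``X`` (alignment disagreement) never matches a constrained
      position; at an unconstrained PAM position it matches outright
      (every aligned sequence still carries a valid base there); at an
      unconstrained protospacer position it is a real guide:target
      mismatch for some sequence and is tolerated at most once, only in
      the PAM-distal seed region, and only when ``allow_seed_mismatch``
      is set.
    """
    if orientation not in ("+", "-"):
        raise ValueError(f"orientation must be '+' or '-', got {orientation!r}")
    if len(window) != matcher.site_length:
        raise ValueError(
            f"window length {len(window)} does not match site length "
            f"{matcher.site_length}"
        )
    allowed = matcher.forward if orientation == "+" else matcher.reverse
    mismatch_at: Optional[int] = None
    for i, sym in enumerate(window):
        sets = allowed[i]
        if sym in sets:
            continue
        fwd = matcher.forward_index(i, orientation)
        unconstrained = sets == ALL_BASES
        if sym in "ACGT":
            # a concrete base failing a constrained position: never tolerated
            return MatchResult(MatchKind.NO_MATCH)
        if sym == "N":
            if unconstrained:
                continue
            return MatchResult(MatchKind.NO_MATCH)
        if sym == "X":
            if not unconstrained:
                return MatchResult(MatchKind.NO_MATCH)
            if fwd in matcher.pam_positions:
                continue  # per-sequence bases all valid at an N PAM position
            if (
                allow_seed_mismatch
                and mismatch_at is None
                and fwd in matcher.seed_positions
            ):
                mismatch_at = i
                continue
            return MatchResult(MatchKind.NO_MATCH)
        if sym == "-":
            return MatchResult(MatchKind.NO_MATCH)
        raise ValueError(f"invalid window symbol {sym!r} at position {i}")
    if mismatch_at is None:
        return MatchResult(MatchKind.EXACT)
    fwd = matcher.forward_index(mismatch_at, orientation)
    return MatchResult(
        MatchKind.SEED_MISMATCH,
        seed_mismatch_position=matcher.protospacer_position(fwd),
        window_position=mismatch_at,
    )
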