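"""Independent reference implementations used only by the test suite.

Everything here is deliberately written from first principles (plain
loops, no numpy tables, no reuse of the package's matcher machinery) so
it can serve as a second route against which the package is checked.
"""

from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def site_layout(spec) -> list[set]:
    """Per-position allowed sets of the full site, guide orientation."""
    proto = [set(IUPAC[c]) for c in spec.five_prime_dinucleotide] + [
        set("ACGT") for _ in range(spec.target_length - 2)
    ]
    pam = [set(IUPAC[c]) for c in spec.pam]
    return proto + pam if spec.pam_side == "three_prime" else pam + proto


def window_matches(window: str, layout: list[set]) -> bool:
    """Naive per-position membership; N satisfies only all-base positions."""
    for ch, allowed in zip(window, layout):
        if ch == "N":
            if allowed != set("ACGT"):
                return False
        elif ch not in allowed:
            return False
    return True


def naive_find_sites(seq: str, spec) -> set[tuple]:
    """Sliding-window enumeration on the raw and reverse-complemented
    sequence; returns (strand, start, end, protospacer, pam) tuples in
    forward-strand coordinates."""
    layout = site_layout(spec)
    slen = len(layout)
    n = len(seq)
    hits = set()

    def split(window: str) -> tuple[str, str]:
        if spec.pam_side == "three_prime":
            return window[: spec.target_length], window[spec.target_length :]
        return window[spec.pam_length :], window[: spec.pam_length]

    for start in range(n - slen + 1):
        window = seq[start : start + slen]
        if window_matches(window, layout):
            proto, pam = split(window)
            hits.add(("+", start, start + slen, proto, pam))
    rc = revcomp(seq)
    for start_rc in range(n - slen + 1):
        window = rc[start_rc : start_rc + slen]
        if window_matches(window, layout):
            proto, pam = split(window)
            start = n - (start_rc + slen)
            hits.add(("-", start, start + slen, proto, pam))
    return hits


def gotoh_score(a: str, b: str, match=2.0, mismatch=-2.0, gap_open=-5.0,
                gap_extend=-0.2) -> float:
    """Quadratic affine-gap global alignment score.

    Gap of length L costs gap_open + gap_extend*(L-1), matching the
    package's convention.
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    ext = gap_extend
    opn = gap_open
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = opn + ext * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = opn + ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + opn, X[i - 1][j] + ext, Y[i - 1][j] + opn)
            Y[i][j] = max(M[i][j - 1] + opn, Y[i][j - 1] + ext, X[i][j - 1] + opn)
    return max(M[n][m], X[n][m], Y[n][m])


def consensus_column(column: str) -> str:
    if "-" in column:
        return "-"
    if len(set(column)) == 1:
        return column[0]
    return "X"


def naive_common_sites(rows: dict[str, str], spec) -> set[tuple]:
    """Common sites of gapless same-length sequences, 0-mismatch mode.

    A window is common at (strand, start) iff every sequence matches
    the specification there and all sequences agree at every window
    position except fully unconstrained PAM positions (where each
    sequence carries its own valid base).
    """
    layout = site_layout(spec)
    slen = len(layout)
    seqs = list(rows.values())
    n = len(seqs[0])
    assert all(len(s) == n for s in seqs)
    # guide-orientation index -> is an all-base PAM position
    if spec.pam_side == "three_prime":
        pam_idx = set(range(spec.target_length, slen))
    else:
        pam_idx = set(range(spec.pam_length))
    free_pam = {i for i in pam_idx if layout[i] == set("ACGT")}
    hits = set()
    for strand in "+-":
        for start in range(n - slen + 1):
            ok = True
            for s in seqs:
                window = s[start : start + slen]
                if strand == "-":
                    window = revcomp(window)
                if not window_matches(window, layout):
                    ok = False
                    break
            if not ok:
                continue
            for gi in range(slen):
                if gi in free_pam:
                    continue
                # guide index -> forward-strand coordinate
                fc = start + gi if strand == "+" else start + slen - 1 - gi
                chars = {s[fc] for s in seqs}
                if len(chars) != 1:
                    ok = False
                    break
            if ok:
                hits.add((strand, start))
    return hits


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def naive_unique_sites(site_lists: dict[str, list], threshold: int = 3) -> set[tuple]:
    """All-pairs full-Hamming uniqueness, no early stopping.

    ``site_lists`` maps sequence id -> (strand, start, end, proto, pam)
    tuples; returns (owner, strand, start) of unique sites.
    """
    out = set()
    for owner, sites in site_lists.items():
        others = [
            t for oid, lst in site_lists.items() if oid != owner for t in lst
        ]
        for s in sites:
            if all(hamming(s[3], t[3]) >= threshold for t in others):
                out.add((owner, s[0], s[1]))
    return out
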