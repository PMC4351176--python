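"""Readers and report writers.

Coordinates follow each format's convention: the TSV tables use 1-based
inclusive start/end (as a bench scientist reads them), BED uses 0-based
half-open.  Report files start with a ``#``-prefixed header block
carrying the tool version, the target-site specification and a hash of
the run configuration, so exported guide lists remain traceable when
pasted into downstream off-target tools.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from . import __version__
from .alignment import MultiAlignment, compute_consensus
from .multitarget import CommonSite, UniqueSite
from .search import NickasePair, SequenceRecord, TargetSite
from .targetspec import TargetSpec

__all__ = [
    "read_fasta",
    "config_hash",
    "write_sites_tsv",
    "write_sites_bed",
    "write_nickase_tsv",
    "write_common_tsv",
    "write_unique_tsv",
    "alignment_text_view",
]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Multi-record FASTA -> normalized SequenceRecords.

    Sequences are uppercased; residues outside {A,C,G,T,N} (including
    other IUPAC ambiguity codes) are rejected at ingest.
    """
    records = [
        SequenceRecord(rec.id, str(rec.seq), rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sequence ids in {path}: {ids}")
    return records


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header(spec: TargetSpec, config: Optional[dict] = None) -> str:
    lines = [
        f"# multiguide {__version__}",
        f"# spec: length={spec.target_length} dinucleotide={spec.five_prime_dinucleotide} "
        f"pam={spec.pam} pam_side={spec.pam_side} "
        f"allow_seed_mismatch={spec.allow_seed_mismatch} "
        f"seed_region_length={spec.seed_region_length}",
    ]
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    return "\n".join(lines) + "\n"


def _fmt(value, nd=2) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.{nd}f}"
    return str(value)


def _site_fields(site: TargetSite) -> list[str]:
    ann = site.annotations
    return [
        site.sequence_id,
        site.strand,
        str(site.start + 1),  # 1-based inclusive
        str(site.end),
        site.protospacer,
        site.pam_observed,
        _fmt(ann.get("gc_percent")),
        _fmt(ann.get("tm_celsius")),
        _fmt(ann.get("activity_score"), 4),
        _fmt(ann.get("exon_index")),
    ]


_SITE_COLUMNS = [
    "site_id", "sequence_id", "strand", "start", "end",
    "protospacer", "pam", "gc_percent", "tm", "score", "exon",
]


def write_sites_tsv(
    sites: list[TargetSite],
    path: str | Path,
    spec: TargetSpec,
    config: Optional[dict] = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(spec, config))
        fh.write("\t".join(_SITE_COLUMNS) + "\n")
        for i, site in enumerate(sites, 1):
            fh.write("\t".join([f"site_{i}"] + _site_fields(site)) + "\n")


def write_sites_bed(sites: list[TargetSite], path: str | Path) -> None:
    """6-column BED; score column scales activity (0-1) to 0-1000."""
    with open(path, "w") as fh:
        for i, site in enumerate(sites, 1):
            score = site.annotations.get("activity_score")
            bed_score = 0 if score is None else int(round(score * 1000))
            fh.write(
                f"{site.sequence_id}\t{site.start}\t{site.end}\tsite_{i}\t"
                f"{bed_score}\t{site.strand}\n"
            )


def write_nickase_tsv(
    pairs: list[NickasePair],
    path: str | Path,
    spec: TargetSpec,
    config: Optional[dict] = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(spec, config))
        fh.write(
            "pair_id\tsequence_id\tcut_offset\t"
            "plus_start\tplus_end\tplus_protospacer\tplus_pam\t"
            "minus_start\tminus_end\tminus_protospacer\tminus_pam\n"
        )
        for i, pr in enumerate(pairs, 1):
            p, m = pr.site_plus, pr.site_minus
            fh.write(
                f"pair_{i}\t{p.sequence_id}\t{pr.cut_offset}\t"
                f"{p.start + 1}\t{p.end}\t{p.protospacer}\t{p.pam_observed}\t"
                f"{m.start + 1}\t{m.end}\t{m.protospacer}\t{m.pam_observed}\n"
            )


def write_common_tsv(
    commons: list[CommonSite],
    path: str | Path,
    spec: TargetSpec,
    config: Optional[dict] = None,
) -> None:
    """One row per input sequence per common site, keyed by common-site id."""
    with open(path, "w") as fh:
        fh.write(_header(spec, config))
        fh.write(
            "common_id\tconsensus_start\tconsensus_end\tstrand\tmismatch_column\t"
            "sequence_id\tstart\tend\tprotospacer\tpam\tgc_percent\ttm\tscore\texon\n"
        )
        for i, cs in enumerate(commons, 1):
            mm = "" if cs.mismatch_column is None else str(cs.mismatch_column + 1)
            for sid, site in cs.per_sequence_sites.items():
                ann = site.annotations
                fh.write(
                    f"common_{i}\t{cs.consensus_start + 1}\t{cs.consensus_end}\t"
                    f"{cs.strand}\t{mm}\t{sid}\t{site.start + 1}\t{site.end}\t"
                    f"{site.protospacer}\t{site.pam_observed}\t"
                    f"{_fmt(ann.get('gc_percent'))}\t{_fmt(ann.get('tm_celsius'))}\t"
                    f"{_fmt(ann.get('activity_score'), 4)}\t{_fmt(ann.get('exon_index'))}\n"
                )


def write_unique_tsv(
    uniques: list[UniqueSite],
    path: str | Path,
    spec: TargetSpec,
    config: Optional[dict] = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(spec, config))
        fh.write(
            "site_id\towner_sequence_id\tstrand\tstart\tend\tprotospacer\tpam\t"
            "min_cross_distance\tgc_percent\ttm\tscore\texon\n"
        )
        for i, u in enumerate(uniques, 1):
            s = u.site
            ann = s.annotations
            fh.write(
                f"unique_{i}\t{u.owner_sequence_id}\t{s.strand}\t{s.start + 1}\t"
                f"{s.end}\t{s.protospacer}\t{s.pam_observed}\t"
                f"{_fmt(u.min_cross_distance)}\t{_fmt(ann.get('gc_percent'))}\t"
                f"{_fmt(ann.get('tm_celsius'))}\t{_fmt(ann.get('activity_score'), 4)}\t"
                f"{_fmt(ann.get('exon_index'))}\n"
            )


def alignment_text_view(
    aln: MultiAlignment,
    commons: Optional[list[CommonSite]] = None,
    width: int = 60,
) -> str:
    """Plain-text alignment blocks with common sites marked by brackets.

    A marker line above each block carries ``>``/``<`` under consensus
    columns covered by a +/− strand common site (``*`` where sites of
    both strands overlap).
    """
    commons = commons or []
    marks = [" "] * aln.length
    for cs in commons:
        sym = ">" if cs.strand == "+" else "<"
        for c in range(cs.consensus_start, cs.consensus_end):
            marks[c] = "*" if marks[c] not in (" ", sym) else sym
    consensus = compute_consensus(aln).symbols
    name_w = max(len("consensus"), *(len(rid) for rid in aln.ids)) + 2
    out = []
    for block in range(0, aln.length, width):
        hi = min(block + width, aln.length)
        out.append(" " * name_w + "".join(marks[block:hi]))
        for rid, gapped in aln.rows:
            out.append(rid.ljust(name_w) + gapped[block:hi])
        out.append("consensus".ljust(name_w) + consensus[block:hi])
        out.append("")
    return "\n".join(out)
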