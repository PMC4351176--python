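"""Per-site sequence characteristics: GC%, RNA:DNA duplex Tm, activity score.

The melting temperature of the guide RNA : target DNA hybrid is
predicted with nearest-neighbor thermodynamics using the RNA:DNA
dinucleotide parameter set of Sugimoto et al. (1995):

    Tm = 1000 * dH / (dS + R * ln(C/4)) - 273.15

with dH the summed enthalpy (kcal/mol), dS the summed entropy
(cal/(mol*K)) including the initiation term, R = 1.987 cal/(mol*K) and
C the strand concentration (default 50 nM).  Parameters are indexed by
the guide-strand dinucleotide (the protospacer sequence read 5'->3',
T standing in for U).  No additional salt correction is applied beyond
the parameter set itself.

The activity score is a logistic-regression model over the 30-nt site
context (4 nt of 5' flank + 20-nt protospacer + 3-nt PAM + 3 nt of 3'
flank) with position-specific mononucleotide and dinucleotide indicator
features and protospacer GC-count terms, squashed to (0,1).  The model
applies only to 20-nt protospacers with a 3-nt 3' PAM; sites without
the required flanking context get no score rather than a fabricated
one.  Coefficients load from a tab-separated table at runtime, so a
published coefficient set can be dropped in by path; the bundled
default table is a synthetic stand-in (see its header).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .search import SequenceRecord, TargetSite, reverse_complement

__all__ = [
    "ThermoParams",
    "ScoreModel",
    "gc_percent",
    "tm_nearest_neighbor",
    "extract_context30",
    "activity_score",
    "load_thermo_params",
    "load_score_model",
    "annotate_sites",
]

GAS_CONSTANT = 1.987  # cal/(mol*K)

_DINUCS = [a + b for a in "ACGT" for b in "ACGT"]


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbor RNA:DNA hybrid parameters plus run conditions."""

    dh: dict  # kcal/mol per guide-strand dinucleotide
    ds: dict  # cal/(mol*K) per guide-strand dinucleotide
    dh_init: float
    ds_init: float
    strand_conc: float = 50e-9  # M
    na_conc: float = 0.05  # M (documented condition; no correction applied)

    def __post_init__(self):
        missing = [d for d in _DINUCS if d not in self.dh or d not in self.ds]
        if missing:
            raise ValueError(f"missing dinucleotide parameters: {missing}")
        if self.strand_conc <= 0 or self.na_conc <= 0:
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class ScoreModel:
    """Logistic model: intercept + sum of matched feature weights.

    Feature names: ``{N}{pos}`` for a mononucleotide at 1-based 30-mer
    position, ``{NN}{pos}`` for a dinucleotide starting there,
    ``gc_low`` / ``gc_high`` weighting max(0, 10 - GC) / max(0, GC - 10)
    over the protospacer GC count.
    """

    intercept: float
    weights: dict = field(default_factory=dict)


def gc_percent(seq: str) -> float:
    """100 * (#G + #C) / length."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters for GC%: {sorted(bad)}")
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("multiguide").joinpath("data", name)))


def load_thermo_params(path: Optional[str | Path] = None) -> ThermoParams:
    """Load the dinucleotide dH/dS table (tab-separated: name, dH, dS)."""
    path = Path(path) if path else _data_path("rna_dna_nn_sugimoto1995.tsv")
    dh, ds = {}, {}
    dh_init = ds_init = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, h, s = line.split("\t")
        if name == "init":
            dh_init, ds_init = float(h), float(s)
        else:
            dh[name] = float(h)
            ds[name] = float(s)
    if dh_init is None:
        raise ValueError(f"thermo table {path} lacks an 'init' row")
    return ThermoParams(dh=dh, ds=ds, dh_init=dh_init, ds_init=ds_init)


def tm_nearest_neighbor(
    protospacer: str, params: Optional[ThermoParams] = None
) -> float:
    """Nearest-neighbor Tm (deg C) of the guide:target hybrid."""
    if params is None:
        params = load_thermo_params()
    seq = protospacer.upper()
    if len(seq) < 2:
        raise ValueError("need at least 2 nt for nearest-neighbor Tm")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid bases for Tm: {sorted(bad)}")
    dh = params.dh_init
    ds = params.ds_init
    for i in range(len(seq) - 1):
        di = seq[i : i + 2]
        dh += params.dh[di]
        ds += params.ds[di]
    return 1000.0 * dh / (ds + GAS_CONSTANT * math.log(params.strand_conc / 4)) - 273.15


def extract_context30(site: TargetSite, source: SequenceRecord) -> Optional[str]:
    """30-nt scoring context around a 20-nt site with 3-nt 3' PAM.

    Returns 4 nt of 5' flank + protospacer + PAM + 3 nt of 3' flank in
    guide orientation, or ``None`` when the site sits too close to a
    sequence edge for the full context.
    """
    if site.sequence_id != source.id:
        raise ValueError(
            f"site belongs to {site.sequence_id!r}, not {source.id!r}"
        )
    if len(site.protospacer) != 20 or len(site.pam_observed) != 3:
        raise ValueError("scoring context requires a 20-nt protospacer and 3-nt PAM")
    expected = site.protospacer + site.pam_observed
    if site.guide_window(source.residues) != expected:
        raise ValueError("site coordinates do not reproduce its sequence")
    n = len(source.residues)
    if site.strand == "+":
        lo, hi = site.start - 4, site.end + 3
        if lo < 0 or hi > n:
            return None
        return source.residues[lo:hi]
    lo, hi = site.start - 3, site.end + 4
    if lo < 0 or hi > n:
        return None
    return reverse_complement(source.residues[lo:hi])


def load_score_model(path: Optional[str | Path] = None) -> ScoreModel:
    """Load a coefficient table (tab-separated: feature_name, weight)."""
    path = Path(path) if path else _data_path("activity_model_synthetic.tsv")
    intercept = 0.0
    weights = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, w = line.split("\t")
        if name == "intercept":
            intercept = float(w)
        else:
            weights[name] = float(w)
    return ScoreModel(intercept=intercept, weights=weights)


def activity_score(context30: str, model: Optional[ScoreModel] = None) -> float:
    """Predicted sgRNA activity in (0,1) from the 30-nt context."""
    if model is None:
        model = load_score_model()
    seq = context30.upper()
    if len(seq) != 30:
        raise ValueError(f"scoring context must be 30 nt, got {len(seq)}")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid bases in scoring context: {sorted(bad)}")
    total = model.intercept
    w = model.weights
    for i, b in enumerate(seq):
        total += w.get(f"{b}{i + 1}", 0.0)
    for i in range(29):
        total += w.get(f"{seq[i:i + 2]}{i + 1}", 0.0)
    gc = sum(1 for b in seq[4:24] if b in "GC")
    total += w.get("gc_low", 0.0) * max(0, 10 - gc)
    total += w.get("gc_high", 0.0) * max(0, gc - 10)
    return 1.0 / (1.0 + math.exp(-total))


def annotate_sites(
    sites: list[TargetSite],
    record: SequenceRecord,
    thermo: Optional[ThermoParams] = None,
    model: Optional[ScoreModel] = None,
    pam_side: str = "three_prime",
) -> None:
    """Attach gc_percent, tm_celsius and (when applicable) activity_score.

    The activity score is computed only for the layout the model was
    built for (20-nt protospacer, 3-nt 3' PAM, full flanking context).
    """
    thermo = thermo or load_thermo_params()
    model = model or load_score_model()
    scorable = pam_side == "three_prime"
    for site in sites:
        if not set(site.protospacer) <= set("ACGT"):
            continue  # N-containing protospacer: no characteristics
        site.annotations["gc_percent"] = gc_percent(site.protospacer)
        if len(site.protospacer) >= 2:
            site.annotations["tm_celsius"] = tm_nearest_neighbor(
                site.protospacer, thermo
            )
        if scorable and len(site.protospacer) == 20 and len(site.pam_observed) == 3:
            ctx = extract_context30(site, record)
            if ctx is not None and set(ctx) <= set("ACGT"):
                site.annotations["activity_score"] = activity_score(ctx, model)
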