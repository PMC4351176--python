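import numpy as np
import pytest

from multiguide import TargetSpec, SequenceRecord


@pytest.fixture
def spec():
    """Canonical type II specification: N20 + 3' NGG, NN dinucleotide."""
    return TargetSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def at_background():
    """PAM-free background helper: alternating AT carries no NGG/CCN."""

    def make(n: int) -> str:
        return ("AT" * (n // 2 + 1))[:n]

    return make


def plant(seq: str, start: int, text: str, strand: str = "+") -> str:
    """Overwrite seq[start:start+len(text)] with text (revcomp for '-')."""
    from multiguide import reverse_complement

    content = text if strand == "+" else reverse_complement(text)
    return seq[:start] + content + seq[start + len(text) :]


@pytest.fixture
def records_pair(at_background):
    """Two identical 60-nt sequences with one embedded N20+AGG site."""
    site = "TATTATAATTATTAATATAT" + "AGG"
    seq = plant(at_background(60), 20, site)
    return [SequenceRecord("s1", seq), SequenceRecord("s2", seq)], site
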