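import numpy as np
import pytest

from coalabc.sequence_data import LocusAlignment, MultiLocusDataset, SampleRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_alignment(seqs, name="locus", inheritance="autosomal", ids=None):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return LocusAlignment(name, inheritance, dict(zip(ids, seqs)))


@pytest.fixture
def tiny_dataset():
    """Two identical focal populations plus a mitochondrial locus."""
    seqs = {
        "alb1": "ACGTACGTAA",
        "alb2": "ACGTACGTAT",
        "chi1": "ACGTACGTAA",
        "chi2": "ACGTACGTAT",
        "pal1": "ACGTACGTAA",
        "pal2": "ACGTACGTAT",
    }
    samples = [
        SampleRecord("alb1", "albiceps"),
        SampleRecord("alb2", "albiceps"),
        SampleRecord("chi1", "chilensis"),
        SampleRecord("chi2", "chilensis"),
        SampleRecord("pal1", "pallatangae"),
        SampleRecord("pal2", "pallatangae"),
    ]
    nuc = LocusAlignment("nuc1", "autosomal", dict(seqs))
    mt = LocusAlignment("mt1", "mitochondrial", dict(seqs))
    return MultiLocusDataset(samples, [nuc, mt])


def random_alignment(rng, n_rows, length, p_missing=0.0, p_ambig=0.0):
    """Random ACGT alignment with optional missing/ambiguous symbols."""
    bases = np.array(list("ACGT"))
    arr = bases[rng.integers(0, 4, size=(n_rows, length))]
    if p_missing:
        mask = rng.random((n_rows, length)) < p_missing
        arr[mask] = rng.choice(list("N-?"), size=int(mask.sum()))
    if p_ambig:
        mask = rng.random((n_rows, length)) < p_ambig
        arr[mask] = rng.choice(list("RYSWKM"), size=int(mask.sum()))
    return ["".join(row) for row in arr]
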