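"""Shared fixtures: the printed degron peptides and small helpers."""

import numpy as np
import pytest

from spopdegron import SequenceRecord

# The published 17-mer degron peptides with their residue numbering.
# SETD2's printed end coordinate is internally inconsistent in the source
# material (17 residues starting at 363), so the start coordinate governs.
PEPTIDES = {
    "MyD88": ("AEKPLQVAAVDSSVPRT", 125, 134),  # (sequence, first residue, SBC anchor)
    "SRC3": ("NDDDVQKADVSSTGQGV", 91, 100),
    "SETD2": ("DKGSVQAPEISSNSIKD", 363, 372),
    "Caprin1": ("QPEATQVPLVSSTSEGY", 426, 435),
}


@pytest.fixture
def myd88_record():
    seq, first, _ = PEPTIDES["MyD88"]
    return SequenceRecord("MyD88", seq, first_residue_number=first)


@pytest.fixture
def peptide_records():
    return {
        name: SequenceRecord(name, seq, first_residue_number=first)
        for name, (seq, first, _) in PEPTIDES.items()
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
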