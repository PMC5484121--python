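import numpy as np
import pytest

from shiftsieve import NucleusRecord, ShiftTable
from shiftsieve.datasets import load_cereoanhydride


@pytest.fixture(scope="session")
def cereoanhydride():
    """(experimental ShiftTable, CandidateSet) for the bundled dataset."""
    return load_cereoanhydride()


@pytest.fixture
def rng():
    return np.random.default_rng(20170612)


def make_table(labels, exp=None, calc=None, name=""):
    """Small helper to assemble shift tables in tests."""
    n = len(labels)
    exp = exp if exp is not None else [None] * n
    calc = calc if calc is not None else [None] * n
    return ShiftTable(
        [
            NucleusRecord(label=l, exp_shift=e, calc_shift=c)
            for l, e, c in zip(labels, exp, calc)
        ],
        candidate_name=name,
    )
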