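"""Bundled reference data for the cereoanhydride structure problem.

Cereoanhydride is a fungal (Coniothyrium cereale) marine natural product
whose originally assigned seven-membered ring anhydride structure was later
revised to a ring-contracted carboxylic acid.  The bundled table carries the
experimental ¹H/¹³C shifts (methanol solution) alongside Boltzmann-averaged,
linearly scaled DFT shifts for three candidates: the anhydride, the acid, and
the deprotonated acid (carboxylate).  Equivalence groups (methyls) are
already collapsed, and exchangeable protons (OH, CO₂H) are absent, as usual
for experimental shift lists.

Also bundled: literature DFT reaction-energy profiles for the
anhydride → ring-opened intermediate → acid rearrangement, and the
methyl–methine distances relevant to the reported NOE contact.  These numbers
are fixtures — reproducing them requires quantum chemistry, which is outside
this package's scope.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from shiftsieve.discrimination import CandidateSet
from shiftsieve.nmr_io import NucleusRecord, ShiftTable

__all__ = [
    "CEREOANHYDRIDE_SHA256", "CEREOANHYDRIDE_CANDIDATES",
    "REACTION_PROFILES_KCAL", "NOE_DISTANCES_ANGSTROM",
    "load_cereoanhydride",
]

CEREOANHYDRIDE_SHA256 = (
    "448be1da4da43ea9afc740c9bd768e287232db6950ffa3b130e66b0afe7a0867"
)

CEREOANHYDRIDE_CANDIDATES = ("anhydride", "acid", "carboxylate")

#: anhydride → intermediate → acid, kcal/mol relative to the anhydride
REACTION_PROFILES_KCAL: dict[str, list[float]] = {
    "B3LYP/6-31+G(d,p)": [0.0, -2.8, -23.1],
    "SMD(CH3OH)-mPW1PW91/6-311+G(2d,p)": [0.0, -8.5, -25.0],
    "B3LYP-D3/6-31+G(d,p)": [0.0, -1.6, -21.9],
}

#: methyl–methine distance of the diagnostic NOE contact, lowest conformer, Å
NOE_DISTANCES_ANGSTROM: dict[str, float] = {
    "anhydride": 3.29,
    "acid": 2.31,
    "carboxylate": 2.32,
}


def _fixture_text() -> str:
    ref = resources.files("shiftsieve") / "data" / "cereoanhydride_shifts.csv"
    text = ref.read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != CEREOANHYDRIDE_SHA256:
        raise RuntimeError(
            "cereoanhydride fixture checksum mismatch: file was modified"
        )
    return text


def load_cereoanhydride() -> tuple[ShiftTable, CandidateSet]:
    """Load the bundled shift table.

    Returns ``(experimental, candidates)`` where the candidate set holds the
    anhydride, acid and carboxylate computed-shift tables (16 carbons and 8
    proton environments each).
    """
    import io

    df = pd.read_csv(io.StringIO(_fixture_text()))
    exp = ShiftTable(
        [
            NucleusRecord(label=row.label, exp_shift=float(row.exp))
            for row in df.itertuples()
        ],
        candidate_name="cereoanhydride (experimental, CD3OD)",
        solvent="methanol",
    )
    cands = {}
    for name in CEREOANHYDRIDE_CANDIDATES:
        cands[name] = ShiftTable(
            [
                NucleusRecord(label=row.label, calc_shift=float(getattr(row, name)))
                for row in df.itertuples()
            ],
            candidate_name=name,
            solvent="methanol",
        )
    return exp, CandidateSet(cands)
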