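"""Energy-profile plumbing and geometric feasibility checks.

Relative reaction energies (hartree in, kcal/mol out) support the argument
that a rearrangement pathway is downhill; interatomic distances against the
~5 Å NOE visibility cutoff and bond angles support conformational and strain
arguments.  No quantum chemistry happens here — energies and geometries are
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "HARTREE_TO_KCAL", "EnergyProfile", "hartree_to_kcal", "relative_profile",
    "interatomic_distance", "noe_feasible", "bond_angle",
]

HARTREE_TO_KCAL = 627.5094741


def hartree_to_kcal(x: float) -> float:
    """Convert hartree to kcal/mol (× 627.5094741)."""
    return float(np.asarray(x, dtype=float) * HARTREE_TO_KCAL)


@dataclass
class EnergyProfile:
    """Energies of an ordered species sequence, kcal/mol relative to the first."""

    species: list[str]
    energies_kcal: list[float]
    method_label: str = ""

    def __post_init__(self) -> None:
        if len(self.species) != len(self.energies_kcal):
            raise ValueError("species/energies length mismatch")
        if len(self.species) < 2:
            raise ValueError("a profile needs at least two species")
        if self.energies_kcal[0] != 0.0:
            raise ValueError("profile energies must be relative to the first species")

    @property
    def downhill(self) -> bool:
        """True iff every step strictly lowers the energy (ties are not downhill)."""
        e = self.energies_kcal
        return all(b < a for a, b in zip(e, e[1:]))


def relative_profile(
    names: Sequence[str],
    absolute_energies_hartree: Sequence[float],
    method_label: str = "",
) -> EnergyProfile:
    """Build an :class:`EnergyProfile` from absolute energies in hartree."""
    if len(names) != len(absolute_energies_hartree):
        raise ValueError("names/energies length mismatch")
    e = np.asarray(absolute_energies_hartree, dtype=float)
    rel = (e - e[0]) * HARTREE_TO_KCAL
    return EnergyProfile(list(names), [float(x) for x in rel], method_label)


def _coords(geometry) -> np.ndarray:
    """Accept ``(element, x, y, z)`` tuples or an (n, 3) array."""
    arr = np.asarray(geometry, dtype=object)
    if arr.ndim == 2 and arr.shape[1] == 4:
        return np.asarray([row[1:] for row in geometry], dtype=float)
    return np.asarray(geometry, dtype=float).reshape(-1, 3)


def interatomic_distance(geometry, i: int, j: int) -> float:
    """Euclidean distance (Å) between atoms ``i`` and ``j`` (0-based)."""
    xyz = _coords(geometry)
    n = len(xyz)
    for idx in (i, j):
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} out of range for {n} atoms")
    return float(np.linalg.norm(xyz[i] - xyz[j]))


def noe_feasible(distance: float, cutoff: float = 5.0) -> bool:
    """Could an NOE be observed between nuclei this far apart?

    NOE cross-peaks are normally seen only for distances ≤ ~5 Å.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return distance <= cutoff


def bond_angle(geometry, i: int, j: int, k: int) -> float:
    """Angle i–j–k in degrees (vertex at ``j``), in [0, 180]."""
    if len({i, j, k}) != 3:
        raise ValueError("indices must be distinct")
    xyz = _coords(geometry)
    n = len(xyz)
    for idx in (i, j, k):
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} out of range for {n} atoms")
    v1 = xyz[i] - xyz[j]
    v2 = xyz[k] - xyz[j]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length bond vector")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))
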