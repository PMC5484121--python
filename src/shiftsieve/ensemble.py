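"""Boltzmann-weighted conformer ensemble averaging.

Flexible molecules populate several conformers at room temperature, and the
observed chemical shift is the population-weighted average of the conformer
shifts.  Conformers within an energy window of the global minimum (3 kcal/mol
by default) are retained and weighted by w_i ∝ exp(−ΔG_i/RT).  Averaging may
be applied to raw shieldings or to scaled shifts — the two are identical under
an affine scaling — and the pipeline averages scaled shifts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from shiftsieve.nmr_io import ConformerRecord

__all__ = [
    "EnsembleConfig", "filter_window", "boltzmann_weights",
    "weighted_average_maps", "weighted_average_shifts",
    "ensemble_average_shieldings",
]

logger = logging.getLogger(__name__)

#: kcal/(mol·K)
GAS_CONSTANT_KCAL = 1.987204e-3
#: 1 hartree in kcal/mol (CODATA)
_HARTREE_TO_KCAL = 627.5094741


@dataclass
class EnsembleConfig:
    """Energy window (kcal/mol) and temperature (K) for conformer weighting."""

    window_kcal: float = 3.0
    temperature_K: float = 298.15
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if self.window_kcal < 0:
            raise ValueError("window must be non-negative")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        """R·T in kcal/mol."""
        return self.gas_constant * self.temperature_K


def _energies_kcal(conformers: Sequence[ConformerRecord]) -> np.ndarray:
    """Relative conformer energies in kcal/mol; free energies preferred."""
    if all(c.free_energy is not None for c in conformers):
        e = np.array([c.free_energy for c in conformers], dtype=float)
    elif all(c.electronic_energy is not None for c in conformers):
        logger.info("free energies unavailable; using electronic energies")
        e = np.array([c.electronic_energy for c in conformers], dtype=float)
    else:
        missing = [c.conformer_id for c in conformers
                   if c.free_energy is None and c.electronic_energy is None]
        raise ValueError(f"conformers without energies: {missing}")
    return (e - e.min()) * _HARTREE_TO_KCAL


def filter_window(
    conformers: Sequence[ConformerRecord], cfg: EnsembleConfig | None = None
) -> list[ConformerRecord]:
    """Keep conformers within ``cfg.window_kcal`` of the lowest-energy one.

    The minimum-energy conformer is always retained (a zero window keeps all
    conformers tied at the minimum).
    """
    if not conformers:
        raise ValueError("no conformers given")
    cfg = cfg or EnsembleConfig()
    rel = _energies_kcal(conformers)
    return [c for c, dE in zip(conformers, rel) if dE <= cfg.window_kcal]


def boltzmann_weights(
    energies_kcal: Sequence[float], cfg: EnsembleConfig | None = None
) -> np.ndarray:
    """Normalized Boltzmann populations from (relative) energies in kcal/mol.

    w_i = exp(−(G_i − G_min)/RT) / Σ_j exp(−(G_j − G_min)/RT); invariant to
    adding a constant to every energy.
    """
    if len(energies_kcal) == 0:
        raise ValueError("no energies given")
    e = np.asarray(energies_kcal, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite energy")
    cfg = cfg or EnsembleConfig()
    w = np.exp(-(e - e.min()) / cfg.rt)
    return w / w.sum()


def weighted_average_maps(
    maps: Sequence[Mapping], weights: Sequence[float]
) -> dict:
    """Per-key weighted average of aligned mappings (key → value).

    All mappings must share the same key set; the mismatch error lists the
    offending keys per mapping.
    """
    if len(maps) != len(weights):
        raise ValueError("one weight per mapping required")
    if not maps:
        raise ValueError("no mappings given")
    keys = set(maps[0])
    for i, m in enumerate(maps[1:], start=1):
        if set(m) != keys:
            missing = sorted(keys - set(m)) + sorted(set(m) - keys)
            raise ValueError(f"mapping {i} has mismatched keys: {missing}")
    w = np.asarray(weights, dtype=float)
    return {
        k: float(np.dot(w, [m[k] for m in maps])) for k in maps[0]
    }


def weighted_average_shifts(
    conformers: Sequence[ConformerRecord], weights: Sequence[float]
) -> dict[int, float]:
    """Boltzmann-average the per-atom shieldings of aligned conformers."""
    return weighted_average_maps([c.shieldings for c in conformers], weights)


def ensemble_average_shieldings(
    conformers: Sequence[ConformerRecord], cfg: EnsembleConfig | None = None
) -> dict[int, float]:
    """Filter by the energy window, weight, and average in one step."""
    cfg = cfg or EnsembleConfig()
    kept = filter_window(conformers, cfg)
    w = boltzmann_weights(_energies_kcal(kept), cfg)
    return weighted_average_shifts(kept, w)
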