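"""Linear scaling between isotropic shieldings and chemical shifts.

Computed isotropic shieldings σ_iso are converted to chemical shifts through
an affine model σ_iso = slope·δ + intercept, with slope/intercept either
supplied (community reference values fitted for a given functional/basis) or
fitted against reference shifts.  Carbon and proton are always scaled with
separate models.

A second, per-candidate empirical rescaling — regress computed shifts on
experimental shifts and remove the fitted line — is the standard DP4
preprocessing step; it strips systematic (slope/offset) method error so that
only scatter is judged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ScalingModel", "apply_scaling", "invert_scaling",
    "fit_reference_scaling", "rescale_against_experiment",
]


@dataclass
class ScalingModel:
    """σ_iso = slope·δ + intercept for one element (slope is dimensionless,
    intercept in ppm; slope is typically near −1)."""

    slope: float
    intercept: float
    element: str = "C"
    source: str = "user-supplied"
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be non-zero")
        self.element = self.element.capitalize()


def apply_scaling(shielding, model: ScalingModel):
    """Shielding → shift: δ = (intercept − σ_iso)/(−slope).  Accepts scalars
    or arrays."""
    return (model.intercept - np.asarray(shielding, dtype=float)) / (-model.slope)


def invert_scaling(shift, model: ScalingModel):
    """Shift → shielding, the exact inverse of :func:`apply_scaling`."""
    return model.slope * np.asarray(shift, dtype=float) + model.intercept


def fit_reference_scaling(
    shieldings: Sequence[float], reference_shifts: Sequence[float], element: str
) -> ScalingModel:
    """Least-squares fit of σ_iso against reference δ for one element.

    Needs at least two points with distinct reference shifts; two points give
    the exact interpolating line.
    """
    sig = np.asarray(shieldings, dtype=float)
    ref = np.asarray(reference_shifts, dtype=float)
    if sig.shape != ref.shape or sig.size < 2:
        raise ValueError("need >= 2 matched (shielding, shift) points")
    if np.ptp(ref) == 0:
        raise ValueError("degenerate fit: all reference shifts equal")
    res = stats.linregress(ref, sig)
    return ScalingModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        element=element,
        source="fitted",
        r_squared=float(res.rvalue**2),
    )


def rescale_against_experiment(
    calc_shifts: Sequence[float], exp_shifts: Sequence[float]
) -> np.ndarray:
    """Remove the systematic linear trend of computed vs experimental shifts.

    Fits δ_calc = m·δ_exp + b and returns (δ_calc − b)/m.  The operation is
    idempotent and leaves zero-mean residuals uncorrelated with δ_exp.  A
    non-positive slope (anti-correlated candidate) raises a warning but the
    rescaled values are still returned.
    """
    calc = np.asarray(calc_shifts, dtype=float)
    exp = np.asarray(exp_shifts, dtype=float)
    if calc.shape != exp.shape or calc.size < 3:
        raise ValueError("need >= 3 matched (calc, exp) shifts")
    res = stats.linregress(exp, calc)
    m, b = float(res.slope), float(res.intercept)
    if m <= 0:
        warnings.warn(
            f"non-positive rescaling slope {m:.4g}: candidate is "
            "anti-correlated with experiment",
            stacklevel=2,
        )
    return (calc - b) / m
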