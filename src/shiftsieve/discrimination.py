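"""Deviation statistics and DP4 probabilistic ranking of candidate structures.

Given an experimental shift list and a set of candidate structures with
computed shifts, this module answers the structure-elucidation question: which
candidate is the experiment most consistent with?  Two complementary views
are provided:

* **MAD/MAX statistics** — per-nucleus absolute deviations |δ_calc − δ_exp|,
  their mean (MAD) and maximum (MAX), with acceptability flags against the
  community rules of thumb (<5 ppm for ¹³C, <0.3 ppm for ¹H).  Small MADs
  with one glaring outlier are exactly the signature that unmasks a wrong
  (or wrongly protonated) structure.
* **DP4 probabilities** — a Bayesian score treating scaled shift errors as
  draws from a Student t distribution.  Per nucleus the likelihood term is
  1 − T_ν(|e|/σ); per candidate the terms multiply with a uniform prior, and
  normalising over candidates gives the percent likelihood that each is the
  correct match.  Computed shifts are first rescaled per candidate against
  experiment (see :mod:`shiftsieve.scaling`).

The default t parameters (σ_C = 2.306 ppm, ν_C = 11.38; σ_H = 0.185 ppm,
ν_H = 14.18) are the published DP4 values and can be overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from shiftsieve.nmr_io import ShiftTable
from shiftsieve.scaling import rescale_against_experiment

__all__ = [
    "CandidateSet", "DeviationStats", "DP4Params", "DP4Result",
    "DiscriminationReport", "DEFAULT_THRESHOLDS", "round_half_up",
    "deviations", "acceptability_flags", "dp4", "dp4_log_likelihood",
    "build_report",
]

#: acceptability rules of thumb, ppm per element (strict "<" is acceptable)
DEFAULT_THRESHOLDS: dict[str, float] = {"C": 5.0, "H": 0.3}

#: deviations this close under a threshold are flagged borderline
BORDERLINE_MARGIN = 0.02

#: report rounding, decimal places per element
_REPORT_DECIMALS = {"C": 1, "H": 2}

_LIKELIHOOD_FLOOR = 1e-300


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero (0.25 → 0.3 at one decimal), the
    convention used for reported deviations."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CandidateSet:
    """Named candidate structures, each carrying a computed :class:`ShiftTable`."""

    candidates: dict[str, ShiftTable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in self.candidates.items():
            if not any(n.calc_shift is not None for n in table):
                raise ValueError(f"candidate {name!r} has no computed shifts")

    @property
    def names(self) -> list[str]:
        return list(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def __getitem__(self, name: str) -> ShiftTable:
        return self.candidates[name]

    def items(self):
        return self.candidates.items()


@dataclass
class DeviationStats:
    """Per-nucleus absolute deviations and their summary for one element."""

    per_nucleus: dict[str, float]
    element: str
    candidate_name: str = ""

    @property
    def n(self) -> int:
        return len(self.per_nucleus)

    @property
    def mad(self) -> float:
        return float(np.mean(list(self.per_nucleus.values())))

    @property
    def max(self) -> float:
        return float(np.max(list(self.per_nucleus.values())))

    @property
    def max_label(self) -> str:
        return max(self.per_nucleus, key=self.per_nucleus.get)

    def rounded(self) -> dict[str, float]:
        """Deviations rounded to the reporting precision (1 dp ¹³C, 2 dp ¹H)."""
        nd = _REPORT_DECIMALS.get(self.element, 2)
        return {k: round_half_up(v, nd) for k, v in self.per_nucleus.items()}


@dataclass
class DP4Params:
    """Student-t error model per element plus the candidate prior."""

    sigma_C: float = 2.306
    nu_C: float = 11.38
    sigma_H: float = 0.185
    nu_H: float = 14.18
    prior: dict[str, float] | None = None  # None = uniform

    def __post_init__(self) -> None:
        if min(self.sigma_C, self.sigma_H) <= 0:
            raise ValueError("sigmas must be positive")
        if min(self.nu_C, self.nu_H) <= 0:
            raise ValueError("degrees of freedom must be positive")
        if self.prior is not None:
            total = sum(self.prior.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"prior sums to {total}, not 1")

    def for_element(self, element: str) -> tuple[float, float]:
        el = element.capitalize()
        if el == "C":
            return self.sigma_C, self.nu_C
        if el == "H":
            return self.sigma_H, self.nu_H
        raise ValueError(f"no DP4 parameters for element {element!r}")


@dataclass
class DP4Result:
    """Normalized candidate probabilities per nucleus set."""

    p_carbon: dict[str, float] | None = None
    p_proton: dict[str, float] | None = None
    p_combined: dict[str, float] | None = None

    def top(self, mode: str = "both") -> str:
        p = {"C": self.p_carbon, "H": self.p_proton, "both": self.p_combined}[mode]
        if p is None:
            raise ValueError(f"mode {mode!r} was not computed")
        return max(p, key=p.get)


def _paired_shifts(
    calc: ShiftTable, exp: ShiftTable, element: str
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Label-aligned (calc, exp) arrays for one element; orphans are errors."""
    el = element.capitalize()
    calc_lab = [n.label for n in calc if n.element == el and n.calc_shift is not None]
    exp_lab = [n.label for n in exp if n.element == el and n.exp_shift is not None]
    orphans = sorted(set(calc_lab) ^ set(exp_lab))
    if orphans:
        raise ValueError(f"unmatched {el} labels between tables: {orphans}")
    if not exp_lab:
        raise ValueError(f"no {el} nuclei in common")
    c = np.array([calc.get(l).calc_shift for l in exp_lab], dtype=float)
    e = np.array([exp.get(l).exp_shift for l in exp_lab], dtype=float)
    return exp_lab, c, e


def deviations(calc: ShiftTable, exp: ShiftTable, element: str) -> DeviationStats:
    """Per-nucleus |δ_calc − δ_exp| for one element, computed on unrounded
    inputs (equivalence groups must already be collapsed)."""
    labels, c, e = _paired_shifts(calc, exp, element)
    dev = np.abs(c - e)
    return DeviationStats(
        per_nucleus=dict(zip(labels, dev.tolist())),
        element=element.capitalize(),
        candidate_name=calc.candidate_name,
    )


def acceptability_flags(
    stats: DeviationStats, thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS
) -> dict[str, str]:
    """Flag each nucleus ``acceptable`` / ``borderline`` / ``unacceptable``.

    A deviation is unacceptable iff it reaches the element threshold
    (strictly-below passes); acceptable deviations within 0.02 ppm of the
    threshold are flagged borderline.
    """
    thr = thresholds[stats.element]
    if thr <= 0:
        raise ValueError("thresholds must be positive")
    out = {}
    for label, dev in stats.per_nucleus.items():
        if dev >= thr:
            out[label] = "unacceptable"
        elif thr - dev <= BORDERLINE_MARGIN:
            out[label] = "borderline"
        else:
            out[label] = "acceptable"
    return out


def dp4_log_likelihood(
    calc: ShiftTable,
    exp: ShiftTable,
    params: DP4Params,
    element: str,
    rescale: bool = True,
) -> float:
    """Unnormalized DP4 log-likelihood of one candidate for one element.

    Per nucleus: log(1 − T_ν(|e|/σ)), with e the (rescaled) shift error.
    Rescaling needs ≥3 nuclei and is skipped below that, so single-nucleus
    toy problems evaluate the raw errors.  Terms that underflow to zero are
    floored at 1e-300 with a warning.
    """
    _, c, e = _paired_shifts(calc, exp, element)
    if rescale and c.size >= 3:
        c = rescale_against_experiment(c, e)
    sigma, nu = params.for_element(element)
    terms = sps.t.sf(np.abs(c - e) / sigma, df=nu)
    if np.any(terms <= 0):
        warnings.warn(
            f"{calc.candidate_name or 'candidate'}: DP4 likelihood underflow "
            f"for {int(np.sum(terms <= 0))} nuclei; flooring at {_LIKELIHOOD_FLOOR}",
            stacklevel=2,
        )
        terms = np.maximum(terms, _LIKELIHOOD_FLOOR)
    return float(np.sum(np.log(terms)))


def _normalize(log_scores: dict[str, float], prior: dict[str, float] | None) -> dict[str, float]:
    names = list(log_scores)
    ls = np.array([log_scores[n] for n in names], dtype=float)
    if prior is not None:
        ls = ls + np.log([prior[n] for n in names])
    p = np.exp(ls - ls.max())
    p /= p.sum()
    return dict(zip(names, p.tolist()))


def dp4(
    candidates: CandidateSet,
    exp: ShiftTable,
    params: DP4Params | None = None,
    mode: str = "both",
    rescale: bool = True,
) -> DP4Result:
    """DP4 probabilities over a candidate set.

    ``mode`` selects the nucleus sets scored: ``"C"`` (carbon only), ``"H"``
    (proton only) or ``"both"``, which also reports the per-element maps.  In
    combined mode the unnormalized candidate score is the product of its
    carbon and proton likelihoods.
    """
    if len(candidates) < 1:
        raise ValueError("no candidates")
    params = params or DP4Params()
    if mode not in {"C", "H", "both"}:
        raise ValueError(f"unknown mode {mode!r}")

    ll: dict[str, dict[str, float]] = {}
    for el in ("C", "H") if mode == "both" else (mode,):
        ll[el] = {
            name: dp4_log_likelihood(tab, exp, params, el, rescale=rescale)
            for name, tab in candidates.items()
        }

    result = DP4Result()
    if "C" in ll:
        result.p_carbon = _normalize(ll["C"], params.prior)
    if "H" in ll:
        result.p_proton = _normalize(ll["H"], params.prior)
    if mode == "both":
        combined = {n: ll["C"][n] + ll["H"][n] for n in candidates.names}
        result.p_combined = _normalize(combined, params.prior)
    return result


@dataclass
class DiscriminationReport:
    """Everything the structure call rests on: deviations, flags, DP4, verdict."""

    exp_name: str
    candidate_names: list[str]
    stats: dict[str, dict[str, DeviationStats]]  # candidate → element → stats
    flags: dict[str, dict[str, dict[str, str]]]  # candidate → element → label → flag
    dp4_result: DP4Result
    thresholds: dict[str, float]
    verdict: str

    def to_dict(self) -> dict:
        """JSON-serializable summary (deterministic key order)."""
        out: dict = {
            "experiment": self.exp_name,
            "thresholds_ppm": dict(sorted(self.thresholds.items())),
            "candidates": {},
            "dp4": {},
            "verdict": self.verdict,
        }
        for name in self.candidate_names:
            cand: dict = {}
            for el in sorted(self.stats[name]):
                st = self.stats[name][el]
                nd = _REPORT_DECIMALS.get(el, 2)
                cand[el] = {
                    "n": st.n,
                    "mad_ppm": round_half_up(st.mad, nd),
                    "max_ppm": round_half_up(st.max, nd),
                    "max_label": st.max_label,
                    "deviations_ppm": st.rounded(),
                    "flags": self.flags[name][el],
                }
            out["candidates"][name] = cand
        for attr, key in (
            ("p_carbon", "carbon"), ("p_proton", "proton"), ("p_combined", "combined")
        ):
            p = getattr(self.dp4_result, attr)
            if p is not None:
                out["dp4"][key] = {n: round(100 * v, 1) for n, v in p.items()}
        return out

    def to_text(self) -> str:
        lines = [f"Structure discrimination vs {self.exp_name or 'experiment'}", ""]
        for name in self.candidate_names:
            lines.append(f"candidate: {name}")
            for el in sorted(self.stats[name]):
                st = self.stats[name][el]
                nd = _REPORT_DECIMALS.get(el, 2)
                bad = [l for l, f in self.flags[name][el].items() if f == "unacceptable"]
                lines.append(
                    f"  {el}: n={st.n}  MAD={round_half_up(st.mad, nd)}  "
                    f"MAX={round_half_up(st.max, nd)} ({st.max_label})"
                    + (f"  unacceptable: {', '.join(bad)}" if bad else "")
                )
        lines.append("")
        d = self.to_dict()["dp4"]
        for key in ("carbon", "proton", "combined"):
            if key in d:
                probs = "  ".join(f"{n}={v:.1f}%" for n, v in d[key].items())
                lines.append(f"DP4 ({key}): {probs}")
        lines.append("")
        lines.append(f"verdict: {self.verdict}")
        return "\n".join(lines) + "\n"


def build_report(
    candidates: CandidateSet,
    exp: ShiftTable,
    params: DP4Params | None = None,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    mode: str = "both",
) -> DiscriminationReport:
    """Assemble per-candidate deviation statistics, flags and DP4 ranking.

    The verdict names the top candidate of the requested DP4 mode (combined
    by default).  A single candidate trivially receives probability 1.
    """
    params = params or DP4Params()
    stats: dict[str, dict[str, DeviationStats]] = {}
    flags: dict[str, dict[str, dict[str, str]]] = {}
    elements = ("C", "H") if mode == "both" else (mode,)
    for name, tab in candidates.items():
        stats[name] = {}
        flags[name] = {}
        for el in elements:
            st = deviations(tab, exp, el)
            stats[name][el] = st
            flags[name][el] = acceptability_flags(st, thresholds)
    dp4_result = dp4(candidates, exp, params, mode=mode)
    verdict = dp4_result.top(mode)
    return DiscriminationReport(
        exp_name=exp.candidate_name,
        candidate_names=candidates.names,
        stats=stats,
        flags=flags,
        dp4_result=dp4_result,
        thresholds=dict(thresholds),
        verdict=verdict,
    )
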