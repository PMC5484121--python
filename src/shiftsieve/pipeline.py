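"""End-to-end pipeline: shift tables in, discrimination report out.

The pipeline reads the experimental table and one table per candidate,
optionally converts shieldings to shifts (supplied linear models) and
Boltzmann-averages conformer ensembles, collapses equivalence groups, and
emits deviation statistics, DP4 probabilities and a verdict — as a
human-readable text report plus a machine-readable JSON summary whose content
is deterministic for fixed inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from shiftsieve.discrimination import (
    DEFAULT_THRESHOLDS,
    CandidateSet,
    DiscriminationReport,
    DP4Params,
    build_report,
)
from shiftsieve.ensemble import EnsembleConfig
from shiftsieve.nmr_io import (
    ShiftTable,
    TableDialect,
    apply_equivalence_groups,
    read_shift_table,
)
from shiftsieve.scaling import ScalingModel, apply_scaling

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "experimental", "candidates", "mode", "dialect", "equivalence_groups",
    "ensemble", "scaling", "dp4", "thresholds", "output_dir", "log_level",
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown config keys are rejected."""

    experimental: str
    candidates: dict[str, str]
    mode: str = "both"
    dialect: TableDialect = field(default_factory=TableDialect)
    equivalence_groups: dict[str, list[str]] = field(default_factory=dict)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    scaling_models: dict[str, ScalingModel] = field(default_factory=dict)
    dp4_params: DP4Params = field(default_factory=DP4Params)
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    output_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in {"C", "H", "both"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.candidates:
            raise ValueError("no candidates configured")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a YAML/JSON pipeline config file."""
    raw: Mapping[str, Any] = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ValueError(f"config {path} is not a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {
        "experimental": raw["experimental"],
        "candidates": dict(raw["candidates"]),
    }
    for key in ("mode", "output_dir", "log_level", "thresholds", "equivalence_groups"):
        if key in raw:
            kwargs[key] = raw[key]
    if "dialect" in raw:
        kwargs["dialect"] = TableDialect(**raw["dialect"])
    if "ensemble" in raw:
        kwargs["ensemble"] = EnsembleConfig(**raw["ensemble"])
    if "dp4" in raw:
        kwargs["dp4_params"] = DP4Params(**raw["dp4"])
    if "scaling" in raw:
        kwargs["scaling_models"] = {
            el: ScalingModel(element=el, **spec) for el, spec in raw["scaling"].items()
        }
    return PipelineConfig(**kwargs)


def _prepare_candidate(table: ShiftTable, cfg: PipelineConfig) -> ShiftTable:
    """Shielding → shift conversion (when models are supplied) and
    equivalence-group collapsing."""
    if cfg.scaling_models:
        for rec in table:
            if rec.calc_shift is None and rec.shielding is not None:
                model = cfg.scaling_models.get(rec.element)
                if model is not None:
                    rec.calc_shift = float(apply_scaling(rec.shielding, model))
    if cfg.equivalence_groups:
        groups = {
            gid: members
            for gid, members in cfg.equivalence_groups.items()
            if all(m in table.labels for m in members)
        }
        if groups:
            table = apply_equivalence_groups(table, groups)
    return table


def run_pipeline(cfg: PipelineConfig) -> DiscriminationReport:
    """Run read → prepare → discriminate, writing report files if configured.

    Outputs (under ``cfg.output_dir``): ``report.txt``, ``report.json`` and
    one ``deviations_<candidate>.csv`` per candidate.  Reruns on identical
    inputs produce byte-identical JSON (no timestamps).
    """
    logging.basicConfig(level=cfg.log_level)
    exp = read_shift_table(cfg.experimental, cfg.dialect, candidate_name="experimental")
    if not any(n.exp_shift is not None for n in exp):
        raise ValueError(f"{cfg.experimental}: no experimental shift column")
    cands = {}
    for name, path in cfg.candidates.items():
        logger.info("reading candidate %s from %s", name, path)
        tab = read_shift_table(path, cfg.dialect, candidate_name=name)
        cands[name] = _prepare_candidate(tab, cfg)
    report = build_report(
        CandidateSet(cands), exp, cfg.dp4_params, cfg.thresholds, mode=cfg.mode
    )

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(report.to_text())
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        for name in report.candidate_names:
            rows = ["label,element,abs_deviation_ppm,flag"]
            for el in sorted(report.stats[name]):
                st = report.stats[name][el]
                for label, dev in st.rounded().items():
                    flag = report.flags[name][el][label]
                    rows.append(f"\"{label}\",{el},{dev},{flag}")
            safe = name.replace("/", "_").replace(" ", "_")
            (out / f"deviations_{safe}.csv").write_text("\n".join(rows) + "\n")
        logger.info("report written to %s", out)
    return report
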