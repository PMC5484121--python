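"""Readers, writers and record types for shift tables, QM logs and geometries.

Shift tables are CSV/TSV files with a header row; column names are remappable
through :class:`TableDialect` so that differently-labelled spreadsheets (or a
single wide multi-candidate table sliced one candidate at a time) can be read
without editing the file.  Quantum-chemistry text logs are parsed with a
minimal line-oriented grammar (atom index, element symbol, ``Isotropic =``,
value) compatible with common DFT package output.  Exchangeable protons (OH,
CO2H) are conventionally absent from experimental shift lists; rows flagged
exchangeable are dropped on read.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NucleusRecord", "ShiftTable", "ConformerRecord", "TableDialect",
    "element_from_label", "read_shift_table", "write_shift_table",
    "read_qm_log", "read_xyz", "write_xyz", "apply_equivalence_groups",
]

_LABEL_RE = re.compile(r"^([A-Za-z]+)")


def element_from_label(label: str) -> str:
    """Infer the element from the leading alphabetic characters of a label.

    ``"C11" -> "C"``, ``"H17-19" -> "H"``.  Raises ``ValueError`` when the
    label has no alphabetic prefix.
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot infer element from label {label!r}")
    return m.group(1).capitalize()


@dataclass
class NucleusRecord:
    """One nucleus: its label, element, and any combination of shift values.

    At least one of ``exp_shift``, ``calc_shift``, ``shielding`` must be
    present.  The element, if given explicitly, must agree with the element
    inferred from the label prefix.
    """

    label: str
    element: str | None = None
    exp_shift: float | None = None
    calc_shift: float | None = None
    shielding: float | None = None
    equivalence_group: str | None = None

    def __post_init__(self) -> None:
        inferred = element_from_label(self.label)
        if self.element is None:
            self.element = inferred
        elif self.element.capitalize() != inferred:
            raise ValueError(
                f"element {self.element!r} inconsistent with label {self.label!r}"
            )
        else:
            self.element = self.element.capitalize()
        if self.exp_shift is None and self.calc_shift is None and self.shielding is None:
            raise ValueError(f"record {self.label!r} carries no values")


@dataclass
class ShiftTable:
    """An ordered collection of :class:`NucleusRecord` for one candidate."""

    nuclei: list[NucleusRecord] = field(default_factory=list)
    candidate_name: str = ""
    solvent: str = ""

    def __post_init__(self) -> None:
        labels = [n.label for n in self.nuclei]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate labels: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.nuclei)

    def __iter__(self):
        return iter(self.nuclei)

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nuclei]

    def get(self, label: str) -> NucleusRecord:
        for n in self.nuclei:
            if n.label == label:
                return n
        raise KeyError(label)

    def subset(self, element: str) -> "ShiftTable":
        """Records of one element, order preserved."""
        el = element.capitalize()
        return ShiftTable(
            [replace(n) for n in self.nuclei if n.element == el],
            candidate_name=self.candidate_name,
            solvent=self.solvent,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "element": [n.element for n in self.nuclei],
                "exp_shift": [n.exp_shift for n in self.nuclei],
                "calc_shift": [n.calc_shift for n in self.nuclei],
                "shielding": [n.shielding for n in self.nuclei],
                "equivalence_group": [n.equivalence_group for n in self.nuclei],
            }
        )


@dataclass
class ConformerRecord:
    """One conformer: free energy (hartree) and per-atom isotropic shieldings.

    Shieldings are keyed by 1-based atom index as printed in QM logs.  The
    optional geometry is a list of ``(element, x, y, z)`` tuples in Å whose
    length must match the shielding index range when both are present.
    """

    conformer_id: str
    free_energy: float | None = None
    electronic_energy: float | None = None
    shieldings: dict[int, float] = field(default_factory=dict)
    geometry: list[tuple[str, float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.geometry is not None and self.shieldings:
            if len(self.geometry) != len(self.shieldings):
                raise ValueError(
                    f"conformer {self.conformer_id!r}: geometry has "
                    f"{len(self.geometry)} atoms but {len(self.shieldings)} "
                    "shieldings"
                )


@dataclass
class TableDialect:
    """Column-name mapping and separator for shift-table CSV/TSV files."""

    sep: str = ","
    label: str = "label"
    exp: str = "exp_shift"
    calc: str = "calc_shift"
    shielding: str = "shielding"
    group: str = "equivalence_group"
    exchangeable: str = "exchangeable"

    @classmethod
    def for_path(cls, path: str | Path, **kwargs) -> "TableDialect":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        kwargs.setdefault("sep", sep)
        return cls(**kwargs)


def _to_float(cell, row_label: str, column: str) -> float | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    s = str(cell).strip()
    if s == "" or s.lower() in {"nan", "na", "none", "-"}:
        return None
    try:
        return float(s)
    except ValueError:
        raise ValueError(
            f"non-numeric value {s!r} in column {column!r}, row {row_label!r}"
        ) from None


def read_shift_table(
    path: str | Path,
    dialect: TableDialect | None = None,
    candidate_name: str = "",
    solvent: str = "",
) -> ShiftTable:
    """Read a shift table from a delimited text file.

    One :class:`NucleusRecord` per row; the element is inferred from the
    label; empty cells become absent values; rows with a truthy cell in the
    exchangeable column are dropped.  Duplicate labels and non-numeric shift
    cells are hard errors.
    """
    path = Path(path)
    if dialect is None:
        dialect = TableDialect.for_path(path)
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    if dialect.label not in df.columns:
        raise ValueError(f"missing label column {dialect.label!r} in {path}")
    value_cols = [c for c in (dialect.exp, dialect.calc, dialect.shielding)
                  if c in df.columns]
    if not value_cols:
        raise ValueError(f"no shift/shielding column found in {path}")
    if dialect.exchangeable in df.columns:
        keep = ~df[dialect.exchangeable].fillna("").str.strip().str.lower().isin(
            {"1", "true", "yes", "y"}
        )
        df = df[keep]
    if df.empty:
        raise ValueError(f"no records in {path}")

    nuclei = []
    for _, row in df.iterrows():
        label = str(row[dialect.label]).strip()
        nuclei.append(
            NucleusRecord(
                label=label,
                exp_shift=_to_float(row.get(dialect.exp), label, dialect.exp)
                if dialect.exp in df.columns else None,
                calc_shift=_to_float(row.get(dialect.calc), label, dialect.calc)
                if dialect.calc in df.columns else None,
                shielding=_to_float(row.get(dialect.shielding), label, dialect.shielding)
                if dialect.shielding in df.columns else None,
                equivalence_group=(str(row[dialect.group]).strip() or None)
                if dialect.group in df.columns and not pd.isna(row[dialect.group])
                else None,
            )
        )
    return ShiftTable(nuclei, candidate_name=candidate_name, solvent=solvent)


def write_shift_table(
    table: ShiftTable, path: str | Path, dialect: TableDialect | None = None
) -> None:
    """Write a shift table; columns that are empty for every record are omitted."""
    path = Path(path)
    if dialect is None:
        dialect = TableDialect.for_path(path)
    cols: dict[str, list] = {dialect.label: table.labels}
    for attr, name in (
        ("exp_shift", dialect.exp),
        ("calc_shift", dialect.calc),
        ("shielding", dialect.shielding),
        ("equivalence_group", dialect.group),
    ):
        values = [getattr(n, attr) for n in table.nuclei]
        if any(v is not None for v in values):
            cols[name] = values
    pd.DataFrame(cols).to_csv(path, sep=dialect.sep, index=False)


# ---------------------------------------------------------------------------
# QM text logs

# "   11  C    Isotropic =   145.1234   Anisotropy =  ..."
_SHIELDING_RE = re.compile(
    r"^\s*(\d+)\s+([A-Za-z]{1,2})\s+Isotropic\s*=\s*(-?\d+(?:\.\d+)?)"
)
_FREE_ENERGY_RE = re.compile(
    r"Sum of electronic and thermal Free Energies\s*=\s*(-?\d+(?:\.\d+)?)"
)
_SCF_RE = re.compile(r"SCF Done:.*?=\s*(-?\d+(?:\.\d+)?)")


def read_qm_log(path: str | Path, conformer_id: str | None = None) -> ConformerRecord:
    """Parse per-atom isotropic shieldings and energies from a QM text log.

    Shieldings are keyed by the 1-based atom index printed in the log.  When
    the log contains several shielding blocks (e.g. restarted jobs) the last
    block wins and a warning is emitted.  A missing free-energy line yields
    ``free_energy=None`` with a warning.
    """
    path = Path(path)
    blocks: list[dict[int, float]] = []
    current: dict[int, float] = {}
    free_energy = None
    electronic = None
    for line in path.read_text().splitlines():
        m = _SHIELDING_RE.match(line)
        if m:
            idx = int(m.group(1))
            if idx in current:  # index repeats: a new shielding block begins
                blocks.append(current)
                current = {}
            current[idx] = float(m.group(3))
            continue
        m = _FREE_ENERGY_RE.search(line)
        if m:
            free_energy = float(m.group(1))
            continue
        m = _SCF_RE.search(line)
        if m:
            electronic = float(m.group(1))
    if current:
        blocks.append(current)
    if not blocks:
        raise ValueError(f"no isotropic shielding block found in {path}")
    if len(blocks) > 1:
        warnings.warn(
            f"{path}: {len(blocks)} shielding blocks found; using the last",
            stacklevel=2,
        )
    if free_energy is None:
        warnings.warn(f"{path}: no free-energy line found", stacklevel=2)
    return ConformerRecord(
        conformer_id=conformer_id or path.stem,
        free_energy=free_energy,
        electronic_energy=electronic,
        shieldings=blocks[-1],
    )


# ---------------------------------------------------------------------------
# XYZ geometries

def read_xyz(path: str | Path) -> list[tuple[str, float, float, float]]:
    """Read a single-frame XYZ file into ``(element, x, y, z)`` tuples (Å)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guesses masses noisily
        u = mda.Universe(str(path))
    return [
        (str(name), float(x), float(y), float(z))
        for name, (x, y, z) in zip(u.atoms.names, u.atoms.positions)
    ]


def write_xyz(
    geometry: Sequence[tuple[str, float, float, float]],
    path: str | Path,
    comment: str = "",
) -> None:
    lines = [str(len(geometry)), comment.replace("\n", " ")]
    for el, x, y, z in geometry:
        lines.append(f"{el} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Equivalence groups (methyl rotors etc.)

def apply_equivalence_groups(
    table: ShiftTable, groups: Mapping[str, Iterable[str]]
) -> ShiftTable:
    """Collapse chemically equivalent nuclei (fast methyl rotation) to one record.

    Each group becomes a single record, placed at the position of its first
    member, whose ``calc_shift`` (and ``shielding``, if present throughout) is
    the arithmetic mean of the members'.  The experimental shift is the single
    experimental value attached to the group's members; conflicting
    experimental values are an error.  Ungrouped records pass through
    untouched.
    """
    label_to_group: dict[str, str] = {}
    for gid, members in groups.items():
        members = list(members)
        for lab in members:
            if lab not in table.labels:
                raise ValueError(f"group {gid!r} member {lab!r} not in table")
            label_to_group[lab] = gid

    out: list[NucleusRecord] = []
    done: set[str] = set()
    for rec in table.nuclei:
        gid = label_to_group.get(rec.label)
        if gid is None:
            out.append(replace(rec))
            continue
        if gid in done:
            continue
        done.add(gid)
        members = [table.get(lab) for lab in groups[gid]]
        calcs = [m.calc_shift for m in members]
        if any(c is None for c in calcs):
            missing = [m.label for m in members if m.calc_shift is None]
            raise ValueError(f"group {gid!r}: members {missing} lack calc_shift")
        exps = {m.exp_shift for m in members if m.exp_shift is not None}
        if len(exps) > 1:
            raise ValueError(f"group {gid!r}: conflicting experimental shifts {sorted(exps)}")
        shields = [m.shielding for m in members]
        out.append(
            NucleusRecord(
                label=gid,
                exp_shift=exps.pop() if exps else None,
                calc_shift=float(np.mean(calcs)),
                shielding=float(np.mean(shields)) if all(s is not None for s in shields) else None,
                equivalence_group=gid,
            )
        )
    return ShiftTable(out, candidate_name=table.candidate_name, solvent=table.solvent)
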