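"""SIZ/CRG force-field tables: parsing and charge/radius assignment.

The SIZ (radius) and CRG (charge) files follow the DelPhi-community
convention of whitespace-separated columns::

    ! comment
    atom_name  residue_name  value
    atom_name  value              <- no residue: a global default entry

Lookup is case-insensitive after whitespace stripping.  Assignment scans
each atom and, per field (radius and charge independently):

1. exact ``(residue_name, atom_name)`` entry;
2. otherwise the global ``atom_name`` entry;
3. otherwise the defaults radius = 1.0 Å / charge = 0.0 e, and the miss is
   recorded in a :class:`MissingEntryReport` for the user to act on.

Misses are data, not errors: a partially parameterised structure still
converts, and the report says exactly which entries to add.

Four small bundled tables (``amber98``, ``charmm22``, ``opls``, ``parse``)
cover the 20 standard amino acids; they are illustrative subsets curated
for this package, not the published parameter sets, and real work should
load the full published files through the custom SIZ/CRG option.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional, TextIO, Union

from .structure_io import AtomRecord

__all__ = [
    "ForceFieldTable",
    "MissingEntry",
    "MissingEntryReport",
    "ForceFieldParseError",
    "parse_parameter_files",
    "assign_parameters",
    "load_bundled",
    "BUNDLED_FORCE_FIELDS",
]

BUNDLED_FORCE_FIELDS = ("amber98", "charmm22", "opls", "parse")

DEFAULT_RADIUS = 1.0
DEFAULT_CHARGE = 0.0


class ForceFieldParseError(ValueError):
    """Malformed SIZ/CRG line; message carries file kind and line number."""


@dataclass
class ForceFieldTable:
    """(residue, atom) -> radius/charge lookup with global fallbacks."""

    name: str = "custom"
    radius_map: dict[tuple[str, str], float] = field(default_factory=dict)
    charge_map: dict[tuple[str, str], float] = field(default_factory=dict)
    global_radius_map: dict[str, float] = field(default_factory=dict)
    global_charge_map: dict[str, float] = field(default_factory=dict)

    def lookup_radius(self, residue: str, atom: str) -> Optional[float]:
        res, at = _norm(residue), _norm(atom)
        if (res, at) in self.radius_map:
            return self.radius_map[(res, at)]
        return self.global_radius_map.get(at)

    def lookup_charge(self, residue: str, atom: str) -> Optional[float]:
        res, at = _norm(residue), _norm(atom)
        if (res, at) in self.charge_map:
            return self.charge_map[(res, at)]
        return self.global_charge_map.get(at)


@dataclass(frozen=True)
class MissingEntry:
    residue_name: str
    atom_name: str
    missing_field: str   # "radius" or "charge"


@dataclass
class MissingEntryReport:
    """Unique (residue, atom, field) triples that fell back to defaults."""

    entries: list[MissingEntry] = field(default_factory=list)

    def add(self, residue: str, atom: str, which: str) -> None:
        e = MissingEntry(residue, atom, which)
        if e not in self.entries:
            self.entries.append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self) -> str:
        lines = ["residue_name\tatom_name\tmissing_field"]
        lines += [f"{e.residue_name}\t{e.atom_name}\t{e.missing_field}"
                  for e in self.entries]
        return "\n".join(lines) + "\n"


def _norm(s: str) -> str:
    return s.strip().upper()


def _read_lines(source: Union[str, os.PathLike, TextIO]) -> list[str]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    return text.replace("\r\n", "\n").replace("\r", "\n").split("\n")


def _parse_one(source, kind: str) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    keyed: dict[tuple[str, str], float] = {}
    global_map: dict[str, float] = {}
    for lineno, raw in enumerate(_read_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        toks = line.split()
        if len(toks) == 2:
            atom, value_tok = toks[0], toks[1]
            residue = None
        elif len(toks) == 3:
            atom, residue, value_tok = toks
        else:
            raise ForceFieldParseError(
                f"{kind} line {lineno}: expected 2 or 3 columns, got {len(toks)}")
        try:
            value = float(value_tok)
        except ValueError as exc:
            raise ForceFieldParseError(
                f"{kind} line {lineno}: malformed numeric field {value_tok!r}") from exc
        if kind == "SIZ" and value < 0:
            raise ForceFieldParseError(
                f"{kind} line {lineno}: radius must be >= 0, got {value}")
        if residue is None:
            if _norm(atom) in global_map:
                warnings.warn(f"{kind} line {lineno}: duplicate global entry "
                              f"{atom!r}; last one wins")
            global_map[_norm(atom)] = value
        else:
            key = (_norm(residue), _norm(atom))
            if key in keyed:
                warnings.warn(f"{kind} line {lineno}: duplicate entry "
                              f"{residue}/{atom}; last one wins")
            keyed[key] = value
    return keyed, global_map


def parse_parameter_files(siz_source, crg_source, name: str = "custom") -> ForceFieldTable:
    """Parse a SIZ/CRG file pair into a :class:`ForceFieldTable`."""
    radius_map, global_radius = _parse_one(siz_source, "SIZ")
    charge_map, global_charge = _parse_one(crg_source, "CRG")
    return ForceFieldTable(name=name, radius_map=radius_map, charge_map=charge_map,
                           global_radius_map=global_radius,
                           global_charge_map=global_charge)


def load_bundled(name: str) -> ForceFieldTable:
    """Load one of the bundled illustrative parameter subsets by name."""
    if name not in BUNDLED_FORCE_FIELDS:
        raise ValueError(f"unknown bundled force field {name!r}; "
                         f"choose from {BUNDLED_FORCE_FIELDS}")
    pkg = resources.files(__package__) / "data"
    with (pkg / f"{name}.siz").open("r") as siz, (pkg / f"{name}.crg").open("r") as crg:
        return parse_parameter_files(siz, crg, name=name)


def assign_parameters(atoms: Iterable[AtomRecord], ff: ForceFieldTable
                      ) -> tuple[list[AtomRecord], MissingEntryReport]:
    """Assign per-atom radius and charge from a table; see module docstring.

    Returns new records in input order plus the missing-entry report; the
    input list is not modified.
    """
    report = MissingEntryReport()
    out: list[AtomRecord] = []
    for atom in atoms:
        radius = ff.lookup_radius(atom.residue_name, atom.atom_name)
        charge = ff.lookup_charge(atom.residue_name, atom.atom_name)
        if radius is None:
            radius = DEFAULT_RADIUS
            report.add(atom.residue_name, atom.atom_name, "radius")
        if charge is None:
            charge = DEFAULT_CHARGE
            report.add(atom.residue_name, atom.atom_name, "charge")
        out.append(replace(atom, radius=radius, charge=charge))
    return out, report
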