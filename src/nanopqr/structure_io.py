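"""PDB reading and PQR/PQRE writing, with REMARK 400 nano-object blocks.

File dialects
-------------
PDB input is the fixed-column format (``ATOM``/``HETATM`` records); any
other record type is preserved as an opaque passthrough line.  PQR output
is the whitespace-delimited dialect accepted by Poisson-Boltzmann solvers::

    ATOM serial atom_name residue_name [chain] residue_number x y z charge radius

PQRE appends one per-atom dielectric-constant column.  Coordinates are
printed to 3 decimals, charges/radii/epsilons to 4.

Each nano-object embedded in a compiled file is bracketed by a REMARK 400
block that records the generation parameters verbatim, so the object can be
recovered (and its atoms regenerated bit-identically) from the file alone::

    REMARK 400 OBJECT BEGIN <label>
    REMARK 400 <key> <value...>
    ...
    ATOM ...
    REMARK 400 OBJECT END <label>

REMARK 400 is the PDB compound-description remark, so the files stay legal
PDB-family text for viewers that ignore unknown remarks.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

from . import geometry

__all__ = [
    "AtomRecord",
    "ObjectBlock",
    "StructureParseError",
    "read_pdb",
    "write_pqr",
    "parse_object_blocks",
    "format_pqr",
]

#: pseudo-residue codes used for object atoms in output files
RESIDUE_CODES = {"sphere": "SPH", "cylinder": "CYL", "cone": "CON", "box": "BOX"}
_CODE_TO_SHAPE = {v: k for k, v in RESIDUE_CODES.items()}

PSEUDO_ATOM_NAME = "DU"


class StructureParseError(ValueError):
    """Malformed structure file; message carries the offending line number."""


@dataclass(slots=True)
class AtomRecord:
    """One atom or pseudo-atom.

    ``position`` is a 3-tuple in Å; ``charge`` (e), ``radius`` (Å) and
    ``epsilon`` (dielectric constant) are optional and only required by the
    output format that prints them.  ``source`` distinguishes macromolecule
    atoms from generated object pseudo-atoms.
    """

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: tuple[float, float, float]
    charge: Optional[float] = None
    radius: Optional[float] = None
    epsilon: Optional[float] = None
    source: str = "macromolecule"

    def __post_init__(self) -> None:
        if self.serial < 1:
            raise StructureParseError(f"serial must be >= 1, got {self.serial}")
        if self.radius is not None and self.radius < 0:
            raise StructureParseError(
                f"atom {self.serial}: radius must be >= 0, got {self.radius}")
        if self.epsilon is not None and self.epsilon <= 0:
            raise StructureParseError(
                f"atom {self.serial}: epsilon must be > 0, got {self.epsilon}")


@dataclass
class ObjectBlock:
    """A nano-object recovered from a REMARK 400 block."""

    label: str
    shape_type: Optional[str]            # None for unrecognized/opaque blocks
    parameters: dict[str, str] = field(default_factory=dict)
    atoms: list[AtomRecord] = field(default_factory=list)

    def spec(self) -> geometry.ShapeSpec:
        """Rebuild the shape spec from the recorded parameters."""
        return geometry.spec_from_config(self.parameters)

    def lattice(self) -> geometry.LatticeParams:
        p = self.parameters
        return geometry.LatticeParams(
            spacing=float(p["spacing"]),
            atom_radius=float(p.get("atom_radius", 0.0)),
            compensate_radius=p.get("compensate_radius", "false").lower() == "true",
        )


Source = Union[str, os.PathLike, TextIO]


def _open_text(source: Source) -> list[str]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    # tolerate CRLF
    return text.replace("\r\n", "\n").replace("\r", "\n").split("\n")


#: sentinel remark written into every compiled file so readers can pick the
#: whitespace dialect deterministically instead of guessing per line
_DIALECT_SENTINEL = "REMARK 400 FILE FORMAT"


def _is_ws_dialect(lines: list[str]) -> bool:
    return any(ln.startswith(_DIALECT_SENTINEL)
               or ln.startswith("REMARK 400 OBJECT BEGIN") for ln in lines)


def _parse_atom_line(line: str, lineno: int, *, prefer_ws: bool = False) -> AtomRecord:
    """Parse one ATOM/HETATM line.

    Files written by this package carry a dialect sentinel and are parsed
    token-wise (``prefer_ws=True``); everything else is parsed as
    fixed-column PDB first, with a token fallback for hand-made
    whitespace-delimited records.  Occupancy/B-factor columns of PDB input
    are deliberately never reinterpreted as charge/radius.
    """
    if prefer_ws:
        toks = line.split()
        if len(toks) >= 10:
            try:
                return _parse_pqr_tokens(toks, lineno)
            except ValueError:
                pass
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip()
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        return AtomRecord(serial=serial, atom_name=name, residue_name=resname,
                          chain_id=chain, residue_number=resnum,
                          position=(x, y, z))
    except (ValueError, IndexError):
        pass
    if not prefer_ws:
        toks = line.split()
        if len(toks) >= 10:
            try:
                return _parse_pqr_tokens(toks, lineno)
            except ValueError:
                pass
    raise StructureParseError(
        f"line {lineno}: unparseable ATOM/HETATM record "
        f"(neither fixed-column PDB nor whitespace PQR): {line!r}")


def _parse_pqr_tokens(toks: list[str], lineno: int) -> AtomRecord:
    # chain id present iff the 5th token is not an integer
    try:
        int(toks[4])
        chain = ""
        rest = toks[4:]
        name_fields = toks[1:4]
    except ValueError:
        chain = toks[4]
        rest = toks[5:]
        name_fields = toks[1:4]
    try:
        serial = int(name_fields[0])
        resnum = int(rest[0])
        nums = [float(t) for t in rest[1:]]
    except ValueError as exc:
        raise ValueError(str(exc)) from exc
    if len(nums) < 3:
        raise ValueError("too few numeric fields")
    x, y, z = nums[0], nums[1], nums[2]
    charge = nums[3] if len(nums) >= 5 else None
    radius = nums[4] if len(nums) >= 5 else None
    epsilon = nums[5] if len(nums) >= 6 else None
    return AtomRecord(serial=serial, atom_name=name_fields[1],
                      residue_name=name_fields[2], chain_id=chain,
                      residue_number=resnum, position=(x, y, z),
                      charge=charge, radius=radius, epsilon=epsilon)


def read_pdb(source: Source, *, with_passthrough: bool = False):
    """Read ATOM/HETATM records from a PDB/PQR/PQRE file.

    Returns the list of :class:`AtomRecord`; with ``with_passthrough=True``
    returns ``(atoms, other_lines)`` where ``other_lines`` are all
    non-atom records in file order, kept verbatim.
    """
    atoms: list[AtomRecord] = []
    passthrough: list[str] = []
    lines = _open_text(source)
    prefer_ws = _is_ws_dialect(lines)
    for lineno, line in enumerate(lines, start=1):
        rec = line.split(None, 1)[0] if line.strip() else ""
        if rec in ("ATOM", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno, prefer_ws=prefer_ws))
        elif line.strip():
            passthrough.append(line)
    if with_passthrough:
        return atoms, passthrough
    return atoms


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _require(atom: AtomRecord, fmt: str) -> None:
    need = []
    if fmt in ("pqr", "pqre"):
        need += ["charge", "radius"]
    if fmt == "pqre":
        need += ["epsilon"]
    for f in need:
        if getattr(atom, f) is None:
            raise StructureParseError(
                f"atom serial {atom.serial}: missing {f}, required for {fmt} output")


def _atom_line(atom: AtomRecord, fmt: str) -> str:
    x, y, z = atom.position
    if fmt == "pdb":
        name = atom.atom_name if len(atom.atom_name) >= 4 else f" {atom.atom_name}"
        return (f"ATOM  {atom.serial:>5d} {name:<4.4s} {atom.residue_name:<3.3s} "
                f"{atom.chain_id or ' ':1.1s}{atom.residue_number:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}")
    parts = ["ATOM", f"{atom.serial:>6d}", f"{atom.atom_name:<4s}",
             f"{atom.residue_name:<4s}"]
    if atom.chain_id:
        parts.append(f"{atom.chain_id:<1s}")
    parts += [f"{atom.residue_number:>5d}", f"{x:11.3f}", f"{y:11.3f}", f"{z:11.3f}",
              f"{atom.charge:9.4f}", f"{atom.radius:8.4f}"]
    if fmt == "pqre":
        parts.append(f"{atom.epsilon:8.4f}")
    return " ".join(parts)


def _object_remarks(obj) -> list[str]:
    """REMARK 400 header lines for one nano-object (duck-typed)."""
    lines = [f"REMARK 400 OBJECT BEGIN {obj.label}"]
    params = dict(geometry.spec_to_config(obj.spec))
    lat = obj.lattice
    params["spacing"] = repr(float(lat.spacing))
    params["atom_radius"] = repr(float(lat.atom_radius))
    params["compensate_radius"] = "true" if lat.compensate_radius else "false"
    extra = getattr(obj, "metadata", None)
    if extra:
        params.update({k: str(v) for k, v in extra.items()})
    eps = getattr(obj, "epsilon", None)
    if eps is not None:
        params["epsilon"] = repr(float(eps))
    for key, value in params.items():
        lines.append(f"REMARK 400 {key} {value}")
    return lines


def format_pqr(atoms: Sequence[AtomRecord], objects: Iterable = (),
               fmt: str = "pqr", *, renumber: bool = True) -> str:
    """Render macromolecule atoms plus nano-objects to one text blob.

    Macromolecule atoms come first, then each object under its REMARK 400
    block, in insertion order.  Serials are renumbered strictly increasing
    unless ``renumber=False``.
    """
    if fmt not in ("pdb", "pqr", "pqre"):
        raise ValueError(f"unknown format: {fmt!r}")
    out: list[str] = []
    if fmt in ("pqr", "pqre"):
        out.append(f"{_DIALECT_SENTINEL} {fmt} WHITESPACE")
    serial = 0

    def emit(atom: AtomRecord) -> None:
        nonlocal serial
        serial += 1
        _require(atom, fmt)
        rec = atom if not renumber else _with_serial(atom, serial)
        out.append(_atom_line(rec, fmt))

    for atom in atoms:
        emit(atom)
    for obj in objects:
        out.extend(_object_remarks(obj))
        for atom in obj.atoms:
            emit(atom)
        out.append(f"REMARK 400 OBJECT END {obj.label}")
    out.append("END")
    return "\n".join(out) + "\n"


def _with_serial(atom: AtomRecord, serial: int) -> AtomRecord:
    if atom.serial == serial:
        return atom
    return AtomRecord(serial=serial, atom_name=atom.atom_name,
                      residue_name=atom.residue_name, chain_id=atom.chain_id,
                      residue_number=atom.residue_number, position=atom.position,
                      charge=atom.charge, radius=atom.radius,
                      epsilon=atom.epsilon, source=atom.source)


def write_pqr(atoms: Sequence[AtomRecord], objects: Iterable,
              destination: Union[str, os.PathLike, TextIO],
              fmt: str = "pqr") -> None:
    """Write a compiled file; see :func:`format_pqr` for layout rules."""
    text = format_pqr(atoms, objects, fmt)
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# object-block parsing
# ---------------------------------------------------------------------------

def parse_object_blocks(source: Source) -> tuple[list[AtomRecord], list[ObjectBlock]]:
    """Split a compiled file into macromolecule atoms and object blocks.

    Atoms between ``REMARK 400 OBJECT BEGIN`` and its matching ``END``
    belong to that object; everything else is macromolecule.  A block whose
    recorded shape type is not recognized is kept as an opaque
    :class:`ObjectBlock` (``shape_type=None``) with a warning.
    """
    mac: list[AtomRecord] = []
    blocks: list[ObjectBlock] = []
    current: Optional[ObjectBlock] = None
    lines = _open_text(source)
    prefer_ws = _is_ws_dialect(lines)
    for lineno, line in enumerate(lines, start=1):
        rec = line.split(None, 1)[0] if line.strip() else ""
        if line.startswith("REMARK 400 OBJECT BEGIN"):
            if current is not None:
                raise StructureParseError(
                    f"line {lineno}: nested OBJECT BEGIN (missing END for "
                    f"{current.label!r})")
            label = line[len("REMARK 400 OBJECT BEGIN"):].strip()
            current = ObjectBlock(label=label, shape_type=None)
        elif line.startswith("REMARK 400 OBJECT END"):
            if current is None:
                raise StructureParseError(f"line {lineno}: OBJECT END without BEGIN")
            shape = current.parameters.get("shape")
            if shape in RESIDUE_CODES:
                current.shape_type = shape
            else:
                warnings.warn(
                    f"object {current.label!r}: unknown shape type {shape!r}; "
                    "kept as opaque block")
                current.shape_type = None
                current.parameters = {}
            blocks.append(current)
            current = None
        elif line.startswith("REMARK 400 ") and current is not None:
            body = line[len("REMARK 400 "):].strip()
            if body:
                key, _, value = body.partition(" ")
                current.parameters[key] = value.strip()
        elif rec in ("ATOM", "HETATM"):
            atom = _parse_atom_line(line, lineno, prefer_ws=prefer_ws)
            if current is not None:
                atom.source = "object"
                current.atoms.append(atom)
            else:
                mac.append(atom)
        # all other lines are opaque passthrough
    if current is not None:
        raise StructureParseError(
            f"OBJECT BEGIN {current.label!r} without matching OBJECT END")
    return mac, blocks
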