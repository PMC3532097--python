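"""Charging pseudo-atom objects by density or explicit total charge.

Two density modes exist, mirroring how nano-object charge is usually
specified: a *volumetric* density (e/ų) multiplied by the analytic volume,
or a *surface* density (e/Ų) multiplied by the analytic area.  The product
is the total charge carried by the object; it is then split equally over
the receiving atoms (all atoms for volumetric charging, the surface-layer
atoms for surface charging), so the per-atom charge is ``q_total / n``.
This keeps the total exactly at the density-times-measure value regardless
of lattice resolution, which is the bookkeeping a continuum solver expects.

Surface-layer classification uses the 6-face-neighbour rule on the
generation lattice: an atom is *surface* when at least one neighbouring
lattice site (one spacing away along a lattice axis) falls outside the
(possibly radius-compensated) solid, boundary included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np

from . import geometry

if TYPE_CHECKING:  # pragma: no cover
    from .assembly import NanoObject

__all__ = [
    "ChargeMode",
    "ChargeAssignment",
    "ChargingError",
    "total_object_charge",
    "distribute_charge",
    "distribute_total_charge",
    "classify_surface_atoms",
    "SurfacePartition",
]


class ChargingError(ValueError):
    """Inconsistent charging request."""


#: accepted charging modes
MODES = ("volumetric", "surface", "none")


class ChargeMode:
    VOLUMETRIC = "volumetric"
    SURFACE = "surface"
    NONE = "none"


@dataclass(frozen=True)
class ChargeAssignment:
    """Record of how an object was charged.

    ``density`` is in e/ų (volumetric) or e/Ų (surface); ``total_charge``
    is the exact object total in e; ``n_charged_atoms`` the number of atoms
    the total was split over.
    """

    mode: str = ChargeMode.NONE
    density: float = 0.0
    total_charge: float = 0.0
    n_charged_atoms: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ChargingError(f"unknown charge mode: {self.mode!r}")
        if self.mode == ChargeMode.NONE and self.total_charge != 0.0:
            raise ChargingError("mode 'none' requires total_charge == 0")


def total_object_charge(spec: geometry.ShapeSpec, mode: str, density: float) -> float:
    """Total charge of a shape at the given density: d*V or d*A, in e."""
    if not np.isfinite(density):
        raise ChargingError(f"density must be finite, got {density}")
    if mode == ChargeMode.VOLUMETRIC:
        return density * geometry.shape_volume(spec)
    if mode == ChargeMode.SURFACE:
        return density * geometry.shape_area(spec)
    if mode == ChargeMode.NONE:
        if density != 0.0:
            raise ChargingError(
                "mode 'none' with nonzero density is ambiguous; "
                "pick 'volumetric' or 'surface'")
        return 0.0
    raise ChargingError(f"unknown charge mode: {mode!r}")


@dataclass(frozen=True)
class SurfacePartition:
    """Exhaustive, disjoint split of object atom indices."""

    surface: np.ndarray    # indices into the object's atom list
    interior: np.ndarray


def classify_surface_atoms(obj: "NanoObject") -> SurfacePartition:
    """Partition an object's atoms into surface layer and interior.

    An atom is *surface* iff at least one of its 6 face-neighbour lattice
    sites (one spacing along each lattice axis) lies outside the solid the
    atoms were generated in (boundary points count as inside, matching the
    generation tie-break).
    """
    spec, lattice = obj.spec, obj.lattice
    pos = np.array([a.position for a in obj.atoms], dtype=float)
    _, axes = geometry.lattice_frame(spec)
    shrink = lattice.atom_radius if lattice.compensate_radius else 0.0
    inside_lim = shrink - 1e-9
    outside_any = np.zeros(len(pos), dtype=bool)
    for axis in axes:
        step = lattice.spacing * axis
        for sgn in (+1.0, -1.0):
            d = geometry.signed_distance(spec, pos + sgn * step)
            outside_any |= d < inside_lim
    idx = np.arange(len(pos))
    return SurfacePartition(surface=idx[outside_any], interior=idx[~outside_any])


def _spread(obj: "NanoObject", q_total: float, indices: np.ndarray,
            assignment: ChargeAssignment) -> "NanoObject":
    """Return a copy of ``obj`` with ``q_total`` split equally over ``indices``."""
    if len(obj.atoms) == 0:
        raise ChargingError("cannot charge an object with no atoms")
    per = q_total / len(indices) if len(indices) else 0.0
    chosen = set(int(i) for i in indices)
    atoms = [replace(a, charge=(per if i in chosen else 0.0))
             for i, a in enumerate(obj.atoms)]
    return replace(obj, atoms=atoms, charge=assignment)


def distribute_charge(obj: "NanoObject", mode: str, density: float) -> "NanoObject":
    """Charge an object from a density; see module docstring for the split.

    Volumetric mode spreads d*V over every atom; surface mode spreads d*A
    over the surface-layer atoms only (interior atoms get 0).  A
    single-atom object has no identifiable surface layer and receives the
    whole surface charge on its one atom, with a warning.
    """
    q_total = total_object_charge(obj.spec, mode, density)
    n = len(obj.atoms)
    if n == 0:
        raise ChargingError("cannot charge an object with no atoms")
    if mode == ChargeMode.SURFACE and not obj.surface_layer_only:
        # back-compatibility convention: surface-density total over all atoms
        indices = np.arange(n)
    elif mode == ChargeMode.SURFACE:
        part = classify_surface_atoms(obj)
        if len(part.surface) == 0 or n == 1:
            warnings.warn(
                f"object {obj.label!r}: no identifiable surface layer; "
                "placing all surface charge on the available atom(s)")
            indices = np.arange(n)
        else:
            indices = part.surface
    else:
        indices = np.arange(n)
    assignment = ChargeAssignment(mode=mode, density=density,
                                  total_charge=q_total,
                                  n_charged_atoms=len(indices))
    return _spread(obj, q_total, indices, assignment)


def distribute_total_charge(obj: "NanoObject", q_total: float) -> "NanoObject":
    """Split an explicit total charge equally over all atoms of the object."""
    n = len(obj.atoms)
    if n == 0:
        raise ChargingError("cannot charge an object with no atoms")
    assignment = ChargeAssignment(mode=ChargeMode.VOLUMETRIC, density=q_total /
                                  geometry.shape_volume(obj.spec),
                                  total_charge=q_total, n_charged_atoms=n)
    return _spread(obj, q_total, np.arange(n), assignment)
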