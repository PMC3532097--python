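"""Geometric shape specifications and pseudo-atom lattice generation.

A nano-object starts from one of four primitive solids — sphere, cylinder,
cone or box (general parallelepiped) — described in Cartesian Å coordinates
matching the PDB orthogonal frame.  The solid is discretised into
pseudo-atoms by filling it with the points of a regular cubic lattice
aligned to the shape's local frame.  The lattice step (``spacing``) is the
single resolution knob: as it shrinks the pseudo-atom cloud approaches a
homogeneous body, at the cost of atom count.

Conventions
-----------
* The inclusion test is applied to atom *centers*; a sphere of nominal
  radius 10 Å filled with 1 Å-radius atoms therefore has an effective outer
  radius of 11 Å.  Setting ``LatticeParams.compensate_radius`` shrinks the
  solid inward by ``atom_radius`` first, so the effective extent equals the
  nominal dimension.
* Points exactly on the boundary are included (``<=`` comparison), so a
  degenerate one-point object is representable.
* The lattice is anchored at the shape's geometric center (sphere: center;
  cylinder: axis midpoint; cone: midpoint of the base-to-apex axis) or at
  the origin corner for the box, and ordered lexicographically by lattice
  index, which makes generation fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Iterable, Union

import numpy as np

__all__ = [
    "InvalidShapeError",
    "EmptyObjectError",
    "SphereSpec",
    "CylinderSpec",
    "ConeSpec",
    "BoxSpec",
    "ShapeSpec",
    "LatticeParams",
    "shape_volume",
    "shape_area",
    "signed_distance",
    "lattice_frame",
    "generate_atoms",
    "transform_spec",
    "spec_to_config",
    "spec_from_config",
    "cone_from_diameter_angle",
]

#: tolerance used for boundary inclusion so that exactly-on-surface lattice
#: points survive floating-point round-off
_BOUNDARY_TOL = 1e-9


class InvalidShapeError(ValueError):
    """A shape specification violates one of its invariants."""


class EmptyObjectError(ValueError):
    """A shape/lattice combination produces no pseudo-atoms."""


def _vec(value: Iterable[float], field: str) -> np.ndarray:
    v = np.asarray(value, dtype=float).reshape(-1)
    if v.shape != (3,):
        raise InvalidShapeError(f"{field} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise InvalidShapeError(f"{field} must be finite, got {v}")
    return v


@dataclass(frozen=True, eq=False)
class SphereSpec:
    """Solid sphere: ``center`` and ``radius`` in Å."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _vec(self.center, "center"))
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise InvalidShapeError(f"radius must be > 0, got {self.radius}")


@dataclass(frozen=True, eq=False)
class CylinderSpec:
    """Solid circular cylinder between ``endpoint_a`` and ``endpoint_b``."""

    endpoint_a: np.ndarray
    endpoint_b: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "endpoint_a", _vec(self.endpoint_a, "endpoint_a"))
        object.__setattr__(self, "endpoint_b", _vec(self.endpoint_b, "endpoint_b"))
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise InvalidShapeError(f"radius must be > 0, got {self.radius}")
        if np.linalg.norm(self.endpoint_b - self.endpoint_a) == 0.0:
            raise InvalidShapeError("endpoint_b must differ from endpoint_a (zero-length axis)")

    @property
    def axis(self) -> np.ndarray:
        return self.endpoint_b - self.endpoint_a

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.axis))


@dataclass(frozen=True, eq=False)
class ConeSpec:
    """Solid right circular cone.

    ``axis`` points from the base center to the apex and its norm is the
    height ``h``; ``base_radius`` is the radius of the circular base.
    """

    base_center: np.ndarray
    axis: np.ndarray
    base_radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_center", _vec(self.base_center, "base_center"))
        object.__setattr__(self, "axis", _vec(self.axis, "axis"))
        if not (np.isfinite(self.base_radius) and self.base_radius > 0):
            raise InvalidShapeError(f"base_radius must be > 0, got {self.base_radius}")
        if np.linalg.norm(self.axis) == 0.0:
            raise InvalidShapeError("axis must have nonzero length (zero height)")

    @property
    def height(self) -> float:
        return float(np.linalg.norm(self.axis))


def cone_from_diameter_angle(base_center, axis_direction, base_diameter: float,
                             opening_angle_deg: float) -> ConeSpec:
    """Build a :class:`ConeSpec` from base diameter and full opening angle.

    The opening angle is the full apex angle in degrees, so
    ``h = r / tan(angle/2)``.  This is the parameterization an AFM-tip style
    cone is usually quoted in.
    """
    r = base_diameter / 2.0
    half = math.radians(opening_angle_deg) / 2.0
    if not 0.0 < half < math.pi / 2.0:
        raise InvalidShapeError(
            f"opening_angle_deg must be in (0, 180), got {opening_angle_deg}")
    h = r / math.tan(half)
    d = _vec(axis_direction, "axis_direction")
    n = np.linalg.norm(d)
    if n == 0.0:
        raise InvalidShapeError("axis_direction must have nonzero length")
    return ConeSpec(base_center=base_center, axis=d / n * h, base_radius=r)


@dataclass(frozen=True, eq=False)
class BoxSpec:
    """General parallelepiped spanned by edges a, b, c from ``origin``."""

    origin: np.ndarray
    edge_a: np.ndarray
    edge_b: np.ndarray
    edge_c: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", _vec(self.origin, "origin"))
        object.__setattr__(self, "edge_a", _vec(self.edge_a, "edge_a"))
        object.__setattr__(self, "edge_b", _vec(self.edge_b, "edge_b"))
        object.__setattr__(self, "edge_c", _vec(self.edge_c, "edge_c"))
        if abs(float(np.dot(self.edge_a, np.cross(self.edge_b, self.edge_c)))) == 0.0:
            raise InvalidShapeError(
                "edge_a, edge_b, edge_c must be linearly independent "
                "(zero scalar triple product)")

    @property
    def edges(self) -> np.ndarray:
        return np.stack([self.edge_a, self.edge_b, self.edge_c])


ShapeSpec = Union[SphereSpec, CylinderSpec, ConeSpec, BoxSpec]

#: short codes used as pseudo-residue names in PQR output and config files
SHAPE_CODES = {SphereSpec: "sphere", CylinderSpec: "cylinder",
               ConeSpec: "cone", BoxSpec: "box"}


@dataclass(frozen=True)
class LatticeParams:
    """Cubic-lattice discretisation parameters.

    spacing
        Lattice step in Å between neighbouring pseudo-atom centers.
    atom_radius
        Radius given to every pseudo-atom, in Å.
    compensate_radius
        If true, the solid is shrunk inward by ``atom_radius`` before
        filling, so the *effective* outer extent (center + atom radius)
        equals the nominal dimension.
    """

    spacing: float
    atom_radius: float = 0.0
    compensate_radius: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.spacing) and self.spacing > 0):
            raise InvalidShapeError(f"spacing must be > 0, got {self.spacing}")
        if not (np.isfinite(self.atom_radius) and self.atom_radius >= 0):
            raise InvalidShapeError(f"atom_radius must be >= 0, got {self.atom_radius}")


# ---------------------------------------------------------------------------
# volume / area
# ---------------------------------------------------------------------------

def shape_volume(spec: ShapeSpec) -> float:
    """Analytic volume of the nominal solid, in ų."""
    if isinstance(spec, SphereSpec):
        return 4.0 / 3.0 * math.pi * spec.radius ** 3
    if isinstance(spec, CylinderSpec):
        return math.pi * spec.radius ** 2 * spec.length
    if isinstance(spec, ConeSpec):
        return math.pi * spec.base_radius ** 2 * spec.height / 3.0
    if isinstance(spec, BoxSpec):
        return abs(float(np.dot(spec.edge_a, np.cross(spec.edge_b, spec.edge_c))))
    raise TypeError(f"not a shape spec: {spec!r}")


def shape_area(spec: ShapeSpec) -> float:
    """Analytic surface area of the nominal solid, in Ų.

    The cylinder area includes both caps; the cone area is base plus
    lateral surface with the slant length computed from the axis height.
    """
    if isinstance(spec, SphereSpec):
        return 4.0 * math.pi * spec.radius ** 2
    if isinstance(spec, CylinderSpec):
        return 2.0 * math.pi * spec.radius ** 2 + 2.0 * math.pi * spec.radius * spec.length
    if isinstance(spec, ConeSpec):
        r, h = spec.base_radius, spec.height
        return math.pi * r * (r + math.hypot(r, h))
    if isinstance(spec, BoxSpec):
        a, b, c = spec.edge_a, spec.edge_b, spec.edge_c
        return 2.0 * (np.linalg.norm(np.cross(a, b))
                      + np.linalg.norm(np.cross(a, c))
                      + np.linalg.norm(np.cross(b, c)))
    raise TypeError(f"not a shape spec: {spec!r}")


# ---------------------------------------------------------------------------
# signed distance (positive inside, negative outside; exact for all shapes)
# ---------------------------------------------------------------------------

def _seg_dist2d(p: np.ndarray, a, b) -> np.ndarray:
    """Distance from 2-D points ``p`` (n,2) to segment a-b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def _seg_dist3d(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def signed_distance(spec: ShapeSpec, points) -> np.ndarray:
    """Signed Euclidean distance from ``points`` to the shape surface.

    Positive inside, zero on the surface, negative outside.  Exact for all
    four (convex) primitives, including near edges and vertices.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if isinstance(spec, SphereSpec):
        return spec.radius - np.linalg.norm(p - spec.center, axis=1)

    if isinstance(spec, CylinderSpec):
        mid = 0.5 * (spec.endpoint_a + spec.endpoint_b)
        u = spec.axis / spec.length
        rel = p - mid
        t = rel @ u
        rho = np.linalg.norm(rel - np.outer(t, u), axis=1)
        hl = spec.length / 2.0
        dr = spec.radius - rho          # >0 inside radially
        dz = hl - np.abs(t)             # >0 inside axially
        inside = np.minimum(dr, dz)
        outside = -np.hypot(np.maximum(-dr, 0.0), np.maximum(-dz, 0.0))
        return np.where((dr >= 0) & (dz >= 0), inside, outside)

    if isinstance(spec, ConeSpec):
        R, h = spec.base_radius, spec.height
        u = spec.axis / h
        rel = p - spec.base_center
        z = rel @ u
        rho = np.linalg.norm(rel - np.outer(z, u), axis=1)
        # 2-D meridian problem: solid is {rho >= 0, 0 <= z, h*rho + R*z <= R*h}
        slant = math.hypot(R, h)
        d_lat = (R * h - h * rho - R * z) / slant   # >0 inside lateral face
        d_base = z                                   # >0 above base plane
        inside_mask = (d_lat >= 0) & (d_base >= 0)
        inside = np.minimum(d_lat, d_base)
        q = np.stack([rho, z], axis=1)
        out = np.minimum(_seg_dist2d(q, (0.0, 0.0), (R, 0.0)),
                         _seg_dist2d(q, (R, 0.0), (0.0, h)))
        return np.where(inside_mask, inside, -out)

    if isinstance(spec, BoxSpec):
        return _box_signed_distance(spec, p)

    raise TypeError(f"not a shape spec: {spec!r}")


def _box_signed_distance(spec: BoxSpec, p: np.ndarray) -> np.ndarray:
    o = spec.origin
    E = spec.edges            # rows a, b, c
    rel = p - o
    # affine coordinates: rel = alpha*a + beta*b + gamma*c
    coords = np.linalg.solve(E.T, rel.T).T
    inside_mask = np.all((coords >= -1e-12) & (coords <= 1.0 + 1e-12), axis=1)

    # inside distance: min Euclidean distance over the three slab pairs
    inside_d = np.full(len(p), np.inf)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        n = np.cross(E[j], E[k])
        n /= np.linalg.norm(n)
        t = rel @ n
        hvec = E[i] @ n          # slab thickness along n (signed)
        if hvec < 0:
            n, t, hvec = -n, -t, -hvec
        inside_d = np.minimum(inside_d, np.minimum(t, hvec - t))

    # outside distance: exact min distance to the 6 parallelogram faces
    out_d = np.full(len(p), np.inf)
    for i in range(3):
        u, v, w = E[i], E[(i + 1) % 3], E[(i + 2) % 3]
        for corner in (o, o + w):
            out_d = np.minimum(out_d, _parallelogram_dist(p, corner, u, v))
    return np.where(inside_mask, inside_d, -out_d)


def _parallelogram_dist(p: np.ndarray, corner: np.ndarray,
                        u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Exact distance from points to the parallelogram corner + s*u + t*v."""
    w = p - corner
    # Gram system for the in-plane affine coordinates
    g = np.array([[u @ u, u @ v], [u @ v, v @ v]])
    rhs = np.stack([w @ u, w @ v])
    st = np.linalg.solve(g, rhs)
    s, t = st[0], st[1]
    n = np.cross(u, v)
    n /= np.linalg.norm(n)
    plane_d = np.abs(w @ n)
    inside_face = (s >= 0) & (s <= 1) & (t >= 0) & (t <= 1)
    edge_d = np.minimum.reduce([
        _seg_dist3d(p, corner, corner + u),
        _seg_dist3d(p, corner + u, corner + u + v),
        _seg_dist3d(p, corner + u + v, corner + v),
        _seg_dist3d(p, corner + v, corner),
    ])
    return np.where(inside_face, plane_d, edge_d)


# ---------------------------------------------------------------------------
# lattice generation
# ---------------------------------------------------------------------------

def _orthonormal_frame(axis: np.ndarray) -> np.ndarray:
    """Deterministic right-handed orthonormal frame with row 2 along axis."""
    w = axis / np.linalg.norm(axis)
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(w)))] = 1.0   # least-aligned Cartesian axis
    u = np.cross(w, seed)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.stack([u, v, w])


def lattice_frame(spec: ShapeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Anchor point and lattice axes (rows, unit vectors) for a shape.

    Sphere: global axes at the center.  Cylinder/cone: one axis along the
    shape axis, anchored at the geometric center of the axis.  Box: axes
    along the normalized edges, anchored at the origin corner (edge
    directions need not be orthogonal; the lattice follows them).
    """
    if isinstance(spec, SphereSpec):
        return spec.center, np.eye(3)
    if isinstance(spec, CylinderSpec):
        mid = 0.5 * (spec.endpoint_a + spec.endpoint_b)
        return mid, _orthonormal_frame(spec.axis)
    if isinstance(spec, ConeSpec):
        return spec.base_center + 0.5 * spec.axis, _orthonormal_frame(spec.axis)
    if isinstance(spec, BoxSpec):
        axes = spec.edges / np.linalg.norm(spec.edges, axis=1)[:, None]
        return spec.origin, axes
    raise TypeError(f"not a shape spec: {spec!r}")


def _index_ranges(spec: ShapeSpec, spacing: float) -> list[range]:
    """Integer index ranges along each lattice axis covering the shape."""
    if isinstance(spec, SphereSpec):
        n = int(math.floor(spec.radius / spacing + 1e-9))
        return [range(-n, n + 1)] * 3
    if isinstance(spec, CylinderSpec):
        nr = int(math.floor(spec.radius / spacing + 1e-9))
        nz = int(math.floor(spec.length / 2.0 / spacing + 1e-9))
        return [range(-nr, nr + 1), range(-nr, nr + 1), range(-nz, nz + 1)]
    if isinstance(spec, ConeSpec):
        nr = int(math.floor(spec.base_radius / spacing + 1e-9))
        nz = int(math.floor(spec.height / 2.0 / spacing + 1e-9))
        return [range(-nr, nr + 1), range(-nr, nr + 1), range(-nz, nz + 1)]
    if isinstance(spec, BoxSpec):
        out = []
        for e in spec.edges:
            n = int(math.floor(np.linalg.norm(e) / spacing + 1e-9))
            out.append(range(0, n + 1))
        return out
    raise TypeError(f"not a shape spec: {spec!r}")


def generate_atoms(spec: ShapeSpec, lattice: LatticeParams) -> np.ndarray:
    """Fill a shape with pseudo-atom centers on a regular cubic lattice.

    Returns an ``(n, 3)`` array of centers in Å, ordered lexicographically
    by lattice index, containing every lattice point whose center lies
    inside the (possibly radius-compensated) solid; boundary points are
    included.  Raises :class:`EmptyObjectError` when no point fits.
    """
    s = lattice.spacing
    anchor, axes = lattice_frame(spec)
    ranges = _index_ranges(spec, s)
    gi, gj, gk = np.meshgrid(*[np.asarray(r) for r in ranges], indexing="ij")
    idx = np.stack([gi.ravel(), gj.ravel(), gk.ravel()], axis=1).astype(float)
    pts = anchor + (idx * s) @ axes
    shrink = lattice.atom_radius if lattice.compensate_radius else 0.0
    keep = signed_distance(spec, pts) >= shrink - _BOUNDARY_TOL
    pts = pts[keep]
    if len(pts) == 0:
        raise EmptyObjectError(
            f"{type(spec).__name__} at spacing {s} Å yields no pseudo-atoms "
            f"(shape smaller than one lattice cell"
            + (", after radius compensation" if shrink else "") + ")")
    return pts


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

def transform_spec(spec: ShapeSpec, translation=(0.0, 0.0, 0.0),
                   rotation=None) -> ShapeSpec:
    """Rigidly transform a shape spec: rotate about its anchor, then translate.

    ``rotation`` must be a proper orthonormal 3x3 matrix (within 1e-8);
    volume and area are invariant by construction.
    """
    t = _vec(translation, "translation")
    if rotation is None:
        rot = np.eye(3)
    else:
        rot = np.asarray(rotation, dtype=float)
        if rot.shape != (3, 3) or not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8):
            raise InvalidShapeError("rotation must be an orthonormal 3x3 matrix")
        if np.linalg.det(rot) < 0:
            raise InvalidShapeError("rotation must be proper (determinant +1)")

    anchor, _ = lattice_frame(spec)

    def pt(x):
        return rot @ (x - anchor) + anchor + t

    def vec(x):
        return rot @ x

    if isinstance(spec, SphereSpec):
        return replace(spec, center=pt(spec.center))
    if isinstance(spec, CylinderSpec):
        return replace(spec, endpoint_a=pt(spec.endpoint_a),
                       endpoint_b=pt(spec.endpoint_b))
    if isinstance(spec, ConeSpec):
        return replace(spec, base_center=pt(spec.base_center), axis=vec(spec.axis))
    if isinstance(spec, BoxSpec):
        return replace(spec, origin=pt(spec.origin), edge_a=vec(spec.edge_a),
                       edge_b=vec(spec.edge_b), edge_c=vec(spec.edge_c))
    raise TypeError(f"not a shape spec: {spec!r}")


# ---------------------------------------------------------------------------
# plain-text config serialization (key = value lines, mirroring CLI flags)
# ---------------------------------------------------------------------------

_SPEC_TYPES = {"sphere": SphereSpec, "cylinder": CylinderSpec,
               "cone": ConeSpec, "box": BoxSpec}


def _fmt(value) -> str:
    if isinstance(value, np.ndarray):
        return " ".join(repr(float(x)) for x in value)
    return repr(float(value))


def spec_to_config(spec: ShapeSpec) -> dict[str, str]:
    """Serialize a spec to a flat ``{key: value-string}`` mapping."""
    out = {"shape": SHAPE_CODES[type(spec)]}
    for f in fields(spec):
        out[f.name] = _fmt(getattr(spec, f.name))
    return out


def spec_from_config(config: dict[str, str]) -> ShapeSpec:
    """Inverse of :func:`spec_to_config`; full float precision round-trips."""
    kind = config.get("shape")
    if kind not in _SPEC_TYPES:
        raise InvalidShapeError(f"unknown shape type: {kind!r}")
    cls = _SPEC_TYPES[kind]
    kwargs = {}
    for f in fields(cls):
        if f.name not in config:
            raise InvalidShapeError(f"missing config key for {kind}: {f.name}")
        parts = [float(tok) for tok in str(config[f.name]).split()]
        kwargs[f.name] = parts[0] if len(parts) == 1 else parts
    return cls(**kwargs)
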