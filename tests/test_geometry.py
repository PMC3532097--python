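"""Geometry: analytic measures, lattice filling, signed distance, transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanopqr import geometry as g


SPHERE10 = g.SphereSpec(center=(0, 0, 0), radius=10.0)
CYL = g.CylinderSpec(endpoint_a=(0, 25, 0), endpoint_b=(0, -25, 0), radius=30.0)
CONE34 = g.ConeSpec(base_center=(0, 0, 0), axis=(0, 0, 4), base_radius=3.0)
BOX20 = g.BoxSpec(origin=(0, 0, 0), edge_a=(20, 0, 0), edge_b=(0, 20, 0),
                  edge_c=(0, 0, 20))
SKEW_BOX = g.BoxSpec(origin=(1, 2, 3), edge_a=(8, 1, 0), edge_b=(0, 7, 2),
                     edge_c=(1, 0, 9))


@pytest.mark.parametrize("spec, expected", [
    (SPHERE10, 4.0 / 3.0 * math.pi * 1000.0),
    (CYL, math.pi * 900.0 * 50.0),
    (CONE34, math.pi * 9.0 * 4.0 / 3.0),
    (BOX20, 8000.0),
])
def test_shape_volume_closed_forms(spec, expected):
    assert g.shape_volume(spec) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("spec, expected", [
    (SPHERE10, 4.0 * math.pi * 100.0),
    (CYL, 2 * math.pi * 900.0 + 2 * math.pi * 30.0 * 50.0),
    (CONE34, math.pi * 3.0 * (3.0 + 5.0)),   # 3-4-5 slant
    (BOX20, 2400.0),
])
def test_shape_area_closed_forms(spec, expected):
    assert g.shape_area(spec) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad, field", [
    (lambda: g.SphereSpec(center=(0, 0, 0), radius=-1.0), "radius"),
    (lambda: g.CylinderSpec(endpoint_a=(1, 1, 1), endpoint_b=(1, 1, 1),
                            radius=2.0), "endpoint_b"),
    (lambda: g.ConeSpec(base_center=(0, 0, 0), axis=(0, 0, 0),
                        base_radius=1.0), "axis"),
    (lambda: g.BoxSpec(origin=(0, 0, 0), edge_a=(1, 0, 0), edge_b=(2, 0, 0),
                       edge_c=(0, 0, 1)), "edge"),
    (lambda: g.SphereSpec(center=(0, np.nan, 0), radius=1.0), "center"),
    (lambda: g.LatticeParams(spacing=0.0), "spacing"),
])
def test_invariant_violations_name_the_field(bad, field):
    with pytest.raises(g.InvalidShapeError, match=field):
        bad()


class TestLatticeGeneration:
    def test_sphere_r2_has_33_centers(self, unit_lattice, small_sphere):
        """Integer lattice points with x²+y²+z² <= 4: brute-force count 33."""
        pts = g.generate_atoms(small_sphere, unit_lattice)
        assert len(pts) == 33
        brute = {(x, y, z) for x in range(-2, 3) for y in range(-2, 3)
                 for z in range(-2, 3) if x * x + y * y + z * z <= 4}
        assert {tuple(int(round(c)) for c in p) for p in pts} == brute

    def test_orthogonal_box_includes_boundary(self, unit_lattice):
        box = g.BoxSpec(origin=(0, 0, 0), edge_a=(2, 0, 0), edge_b=(0, 2, 0),
                        edge_c=(0, 0, 2))
        assert len(g.generate_atoms(box, unit_lattice)) == 27

    def test_tiny_sphere_keeps_anchor_point(self, unit_lattice):
        tiny = g.SphereSpec(center=(3.0, -1.0, 0.5), radius=0.4)
        pts = g.generate_atoms(tiny, unit_lattice)
        assert len(pts) == 1
        np.testing.assert_allclose(pts[0], [3.0, -1.0, 0.5])

    def test_empty_object_raises(self):
        tiny = g.SphereSpec(center=(0, 0, 0), radius=0.4)
        lat = g.LatticeParams(spacing=1.0, atom_radius=0.5,
                              compensate_radius=True)
        with pytest.raises(g.EmptyObjectError):
            g.generate_atoms(tiny, lat)

    def test_deterministic_and_lexicographic(self, unit_lattice, small_sphere):
        a = g.generate_atoms(small_sphere, unit_lattice)
        b = g.generate_atoms(small_sphere, unit_lattice)
        np.testing.assert_array_equal(a, b)
        # lexicographic order in lattice coordinates (here = Cartesian)
        keys = [tuple(p) for p in a]
        assert keys == sorted(keys)

    def test_radius_compensation_shrinks_extent(self):
        spec = g.SphereSpec(center=(0, 0, 0), radius=10.0)
        lat = g.LatticeParams(spacing=1.0, atom_radius=1.0,
                              compensate_radius=True)
        pts = g.generate_atoms(spec, lat)
        r = np.linalg.norm(pts, axis=1)
        # center + atom radius never exceeds the nominal 10 Å
        assert r.max() + lat.atom_radius <= 10.0 + 1e-9
        plain = g.generate_atoms(spec, g.LatticeParams(spacing=1.0,
                                                       atom_radius=1.0))
        assert len(pts) < len(plain)

    def test_lattice_count_tracks_volume(self):
        """count * spacing³ converges to the analytic volume (< 5% at 0.5 Å)."""
        spacing = 0.5
        pts = g.generate_atoms(SPHERE10, g.LatticeParams(spacing=spacing))
        vol = g.shape_volume(SPHERE10)
        assert len(pts) * spacing ** 3 == pytest.approx(vol, rel=0.05)
        # and the estimate tightens as the lattice refines
        coarse = g.generate_atoms(SPHERE10, g.LatticeParams(spacing=1.0))
        err_fine = abs(len(pts) * spacing ** 3 - vol)
        err_coarse = abs(len(coarse) * 1.0 - vol)
        assert err_fine < err_coarse


# independent membership predicates for the Monte-Carlo oracle -------------

def _inside(spec, pts):
    if isinstance(spec, g.SphereSpec):
        return np.linalg.norm(pts - spec.center, axis=1) <= spec.radius
    if isinstance(spec, g.CylinderSpec):
        u = spec.axis / spec.length
        rel = pts - spec.endpoint_a
        t = rel @ u
        rho = np.linalg.norm(rel - np.outer(t, u), axis=1)
        return (t >= 0) & (t <= spec.length) & (rho <= spec.radius)
    if isinstance(spec, g.ConeSpec):
        u = spec.axis / spec.height
        rel = pts - spec.base_center
        z = rel @ u
        rho = np.linalg.norm(rel - np.outer(z, u), axis=1)
        return (z >= 0) & (z <= spec.height) & (
            rho <= spec.base_radius * (1.0 - z / spec.height))
    coords = np.linalg.solve(spec.edges.T, (pts - spec.origin).T).T
    return np.all((coords >= 0) & (coords <= 1), axis=1)


def _mc_bounds(spec, pad):
    probe = g.generate_atoms(spec, g.LatticeParams(spacing=0.5))
    return probe.min(axis=0) - pad, probe.max(axis=0) + pad


MC_SHAPES = [SPHERE10, CYL, CONE34, BOX20, SKEW_BOX]


@pytest.mark.parametrize("spec", MC_SHAPES, ids=lambda s: type(s).__name__)
def test_monte_carlo_volume(spec, rng):
    """Rejection sampling (1e6 pts, fixed seed) matches the closed form < 2%."""
    lo, hi = _mc_bounds(spec, pad=1.0)
    pts = rng.uniform(lo, hi, size=(1_000_000, 3))
    est = np.mean(_inside(spec, pts)) * np.prod(hi - lo)
    assert est == pytest.approx(g.shape_volume(spec), rel=0.02)


def _grown_shrunk(spec, delta):
    """First-order parallel bodies used for the shell area estimate."""
    if isinstance(spec, g.SphereSpec):
        grow = lambda d: g.SphereSpec(center=spec.center,
                                      radius=spec.radius + d)
        return grow(delta), grow(-delta)
    if isinstance(spec, g.CylinderSpec):
        u = spec.axis / spec.length
        def grow(d):
            return g.CylinderSpec(endpoint_a=spec.endpoint_a - d * u,
                                  endpoint_b=spec.endpoint_b + d * u,
                                  radius=spec.radius + d)
        return grow(delta), grow(-delta)
    if isinstance(spec, g.ConeSpec):
        R, h = spec.base_radius, spec.height
        t = (R + math.hypot(R, h)) / (R * h)   # dV = A*delta under uniform scaling
        def grow(d):
            s = 1.0 + t * d
            return g.ConeSpec(base_center=spec.base_center, axis=spec.axis * s,
                              base_radius=R * s)
        return grow(delta), grow(-delta)
    # box: push each face outward by delta along its own normal
    def grow(d):
        E = spec.edges
        new_edges, shift = [], np.zeros(3)
        for i in range(3):
            n = np.cross(E[(i + 1) % 3], E[(i + 2) % 3])
            n = n / np.linalg.norm(n)
            if n @ E[i] < 0:
                n = -n
            ei = E[i] + 2 * d * (E[i] / (E[i] @ n))   # thicken the slab by 2d
            new_edges.append(ei)
            shift = shift + d * (E[i] / (E[i] @ n))
        return g.BoxSpec(origin=spec.origin - shift, edge_a=new_edges[0],
                         edge_b=new_edges[1], edge_c=new_edges[2])
    return grow(delta), grow(-delta)


@pytest.mark.parametrize("spec", MC_SHAPES, ids=lambda s: type(s).__name__)
def test_monte_carlo_area(spec, rng):
    """Shell-volume estimate (V_outer - V_inner)/(2 delta) matches area < 2%."""
    delta = 0.02 * g.shape_volume(spec) ** (1.0 / 3.0)
    outer, inner = _grown_shrunk(spec, delta)
    lo, hi = _mc_bounds(spec, pad=2 * delta + 0.5)
    pts = rng.uniform(lo, hi, size=(1_000_000, 3))
    vbox = np.prod(hi - lo)
    shell = np.mean(_inside(outer, pts) & ~_inside(inner, pts))
    est = shell * vbox / (2 * delta)
    assert est == pytest.approx(g.shape_area(spec), rel=0.02)


@pytest.mark.parametrize("spec", MC_SHAPES, ids=lambda s: type(s).__name__)
def test_signed_distance_sign_matches_membership(spec, rng):
    lo, hi = _mc_bounds(spec, pad=3.0)
    pts = rng.uniform(lo, hi, size=(20_000, 3))
    sd = g.signed_distance(spec, pts)
    inside = _inside(spec, pts)
    # strict interior/exterior must agree; |sd| < tol near the surface is fine
    assert np.array_equal(sd > 1e-9, inside & (sd > 1e-9))
    assert np.all(inside[sd > 1e-9])
    assert not np.any(inside[sd < -1e-9])


@pytest.mark.parametrize("spec, lat", [
    (SPHERE10, g.LatticeParams(spacing=1.3)),
    (CYL, g.LatticeParams(spacing=2.7)),
    (CONE34, g.LatticeParams(spacing=0.45)),
    (SKEW_BOX, g.LatticeParams(spacing=0.9)),
    (SPHERE10, g.LatticeParams(spacing=1.0, atom_radius=1.0,
                               compensate_radius=True)),
], ids=["sphere", "cylinder", "cone", "skew-box", "sphere-compensated"])
def test_containment_of_generated_centers(spec, lat):
    """Every generated center lies inside the (possibly shrunk) solid."""
    pts = g.generate_atoms(spec, lat)
    shrink = lat.atom_radius if lat.compensate_radius else 0.0
    assert np.all(g.signed_distance(spec, pts) >= shrink - 1e-9)


class TestTransforms:
    def test_identity_is_noop(self):
        out = g.transform_spec(CYL)
        np.testing.assert_allclose(out.endpoint_a, CYL.endpoint_a)
        np.testing.assert_allclose(out.endpoint_b, CYL.endpoint_b)

    def test_translation_moves_center(self):
        s = g.SphereSpec(center=(0, 0, 0), radius=1.0)
        out = g.transform_spec(s, translation=(5, 5, 0))
        np.testing.assert_allclose(out.center, [5, 5, 0])

    def test_rejects_non_orthonormal(self):
        with pytest.raises(g.InvalidShapeError, match="orthonormal"):
            g.transform_spec(SPHERE10, rotation=np.diag([1.0, 2.0, 1.0]))

    def test_rejects_improper_rotation(self):
        with pytest.raises(g.InvalidShapeError, match="proper"):
            g.transform_spec(SPHERE10, rotation=np.diag([1.0, 1.0, -1.0]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(-math.pi, math.pi), st.floats(-math.pi, math.pi),
           st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10))
    def test_rigid_invariance(self, angle1, angle2, tx, ty, tz):
        """Volume, area and atom count are invariant under rigid motion."""
        c1, s1 = math.cos(angle1), math.sin(angle1)
        c2, s2 = math.cos(angle2), math.sin(angle2)
        rot = (np.array([[1, 0, 0], [0, c1, -s1], [0, s1, c1]])
               @ np.array([[c2, -s2, 0], [s2, c2, 0], [0, 0, 1]]))
        for spec in (CONE34, SKEW_BOX, CYL):
            moved = g.transform_spec(spec, translation=(tx, ty, tz),
                                     rotation=rot)
            assert g.shape_volume(moved) == pytest.approx(
                g.shape_volume(spec), rel=1e-9)
            assert g.shape_area(moved) == pytest.approx(
                g.shape_area(spec), rel=1e-9)
        lat = g.LatticeParams(spacing=1.1)
        moved_cone = g.transform_spec(CONE34, translation=(tx, ty, tz),
                                      rotation=rot)
        assert len(g.generate_atoms(moved_cone, lat)) == len(
            g.generate_atoms(CONE34, lat))


class TestConfigRoundTrip:
    @pytest.mark.parametrize("spec", MC_SHAPES + [
        g.cone_from_diameter_angle((1, 2, 3), (0, 1, 1), base_diameter=40.0,
                                   opening_angle_deg=45.0)],
        ids=lambda s: f"{type(s).__name__}")
    def test_round_trip_is_exact(self, spec):
        back = g.spec_from_config(g.spec_to_config(spec))
        assert type(back) is type(spec)
        for f in ("center", "radius", "endpoint_a", "endpoint_b", "axis",
                  "base_center", "base_radius", "origin", "edge_a", "edge_b",
                  "edge_c"):
            if hasattr(spec, f):
                np.testing.assert_array_equal(
                    np.asarray(getattr(spec, f)),
                    np.asarray(getattr(back, f)))

    def test_unknown_shape_rejected(self):
        with pytest.raises(g.InvalidShapeError, match="unknown shape"):
            g.spec_from_config({"shape": "torus"})


def test_cone_from_diameter_and_opening_angle():
    """Base diameter 40 Å at a 45° full opening angle gives h = 20/tan(22.5°)."""
    cone = g.cone_from_diameter_angle((0, 0, 0), (0, 0, 1), 40.0, 45.0)
    assert cone.base_radius == pytest.approx(20.0)
    assert cone.height == pytest.approx(20.0 / math.tan(math.radians(22.5)))
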