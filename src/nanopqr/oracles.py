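"""Analytic continuum-electrostatics reference solutions.

These closed forms are the verification surface for pseudo-atom objects:
instead of running a finite-difference Poisson-Boltzmann solver, a
generated object's direct Coulomb sum is compared against the matching
analytic solution (homogeneously charged sphere, finite line of charge,
thin charged disc), and cavity/interface energetics are checked against the
Kirkwood two-dielectric-sphere series and the method of images.

Units
-----
Charges in e, lengths in Å, energies in kT, potentials in kT/e.  The
Coulomb constant ``k = e^2 / (4 pi eps0 * 1 Å * k_B T)`` is a parameter of
:class:`EnergyUnit`; the default 561.0 kT·Å·e⁻² is the constant
conventional in Poisson-Boltzmann solvers (room temperature near 297 K).
Alternative temperature conventions are one constructor argument away.

All functions here are pure: identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

__all__ = [
    "EnergyUnit",
    "DELPHI_UNIT",
    "DielectricSphereSystem",
    "OracleDomainError",
    "SeriesConvergenceError",
    "direct_coulomb_potential",
    "potential_charged_sphere",
    "potential_finite_line",
    "potential_charged_disc",
    "kirkwood_total_energy",
    "image_charge_solvation",
]

#: hard cap on Kirkwood series terms; hitting it raises, never truncates
_MAX_TERMS = 10_000


class OracleDomainError(ValueError):
    """Input outside the validity domain of the analytic solution."""


class SeriesConvergenceError(RuntimeError):
    """Legendre series failed to reach the requested tolerance."""


@dataclass(frozen=True)
class EnergyUnit:
    """Coulomb constant in solver units (kT·Å·e⁻²)."""

    kT_conversion: float = 561.0

    def __post_init__(self) -> None:
        if not self.kT_conversion > 0:
            raise OracleDomainError(
                f"kT_conversion must be > 0, got {self.kT_conversion}")


DELPHI_UNIT = EnergyUnit(561.0)


@dataclass(frozen=True)
class DielectricSphereSystem:
    """Point charges inside a dielectric sphere embedded in another medium.

    ``charges`` is a sequence of ``(q, position)`` with every position
    strictly inside the cavity of radius ``cavity_radius``; ``eps_in`` and
    ``eps_out`` are the cavity and solvent dielectric constants.
    """

    cavity_radius: float
    eps_in: float
    eps_out: float
    charges: tuple = ()

    def __post_init__(self) -> None:
        if not self.cavity_radius > 0:
            raise OracleDomainError(f"cavity_radius must be > 0, "
                                    f"got {self.cavity_radius}")
        if not (self.eps_in > 0 and self.eps_out > 0):
            raise OracleDomainError("dielectric constants must be > 0")
        charges = tuple((float(q), np.asarray(p, dtype=float).reshape(3))
                        for q, p in self.charges)
        object.__setattr__(self, "charges", charges)
        for q, p in charges:
            if np.linalg.norm(p) >= self.cavity_radius:
                raise OracleDomainError(
                    f"charge at {p} lies on or outside the cavity boundary "
                    f"(R = {self.cavity_radius}); the reaction-field series "
                    "diverges there")


def _positions_and_charges(atoms) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(atoms, np.ndarray):
        raise TypeError("pass a sequence of atom records (with .position and "
                        ".charge), not a bare array")
    pos = np.array([a.position for a in atoms], dtype=float)
    q = np.array([0.0 if a.charge is None else a.charge for a in atoms])
    return pos, q


def direct_coulomb_potential(atoms, point, eps: float,
                             unit: EnergyUnit = DELPHI_UNIT) -> float:
    """Potential at ``point`` from summing k/eps * q_i / |r - r_i| (kT/e)."""
    pos, q = _positions_and_charges(atoms)
    p = np.asarray(point, dtype=float).reshape(3)
    d = np.linalg.norm(pos - p, axis=1)
    if np.any(d == 0.0):
        raise OracleDomainError(
            "evaluation point coincides with an atom center")
    return float(unit.kT_conversion / eps * np.sum(q / d))


def potential_charged_sphere(Q: float, d: float, eps: float,
                             unit: EnergyUnit = DELPHI_UNIT) -> float:
    """Exterior potential of a homogeneously charged sphere: k Q / (eps d).

    Valid outside the sphere only; callers pass the distance from the
    center.  The interior form is not provided (the benchmark scans are
    exterior).
    """
    if d <= 0:
        raise OracleDomainError(f"distance must be > 0, got {d}")
    return unit.kT_conversion * Q / (eps * d)


def potential_finite_line(lam: float, L: float, d: float, eps: float,
                          unit: EnergyUnit = DELPHI_UNIT) -> float:
    """Potential of a finite line of charge, perpendicular from its midpoint.

    lam is the linear density (e/Å), L the line length (Å), d > 0 the
    perpendicular distance (Å) from the midpoint:

        V = k lam / eps * ln[(L/2 + sqrt((L/2)^2 + d^2))
                             / (-L/2 + sqrt((L/2)^2 + d^2))]
    """
    if d <= 0:
        raise OracleDomainError(f"distance must be > 0, got {d}")
    if L <= 0:
        raise OracleDomainError(f"line length must be > 0, got {L}")
    h = L / 2.0
    root = math.hypot(h, d)
    return unit.kT_conversion * lam / eps * math.log((h + root) / (root - h))


def potential_charged_disc(sigma: float, R_disc: float, d: float, eps: float,
                           unit: EnergyUnit = DELPHI_UNIT) -> float:
    """On-axis potential of a uniformly charged thin disc.

        V = 2 pi k sigma / eps * (sqrt(d^2 + R^2) - d),   d >= 0
    """
    if R_disc <= 0:
        raise OracleDomainError(f"disc radius must be > 0, got {R_disc}")
    if d < 0:
        raise OracleDomainError(f"on-axis distance must be >= 0, got {d}")
    return (2.0 * math.pi * unit.kT_conversion * sigma / eps
            * (math.hypot(d, R_disc) - d))


def kirkwood_total_energy(system: DielectricSphereSystem,
                          unit: EnergyUnit = DELPHI_UNIT,
                          tolerance: float = 1e-10) -> float:
    """Total electrostatic energy of charges in a two-dielectric sphere (kT).

    The intra-cavity Coulomb energy

        E_c = k/eps_in * sum_{i<j} q_i q_j / r_ij

    plus the reaction-field energy from the Legendre expansion

        E_r = k/(2 eps_in) * sum_{i,j} q_i q_j *
              sum_{n>=0} (eps_in - eps_out)(n+1) /
                         (n eps_in + (n+1) eps_out)
                       * (r_i r_j)^n / R^(2n+1) * P_n(cos theta_ij)

    The series is summed with upward Legendre recurrence and truncated when
    the last term's relative contribution drops below ``tolerance``; it
    converges for every valid system because r_i r_j / R^2 < 1.  Hitting
    the hard cap raises :class:`SeriesConvergenceError` rather than
    silently truncating.
    """
    if not tolerance > 0:
        raise OracleDomainError(f"tolerance must be > 0, got {tolerance}")
    k = unit.kT_conversion
    eps_in, eps_out, R = system.eps_in, system.eps_out, system.cavity_radius
    qs = np.array([q for q, _ in system.charges])
    pos = np.array([p for _, p in system.charges]).reshape(-1, 3)
    n_ch = len(qs)
    if n_ch == 0:
        return 0.0

    # direct Coulomb part
    e_coul = 0.0
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            e_coul += qs[i] * qs[j] / np.linalg.norm(pos[i] - pos[j])
    e_coul *= k / eps_in

    if eps_in == eps_out:
        return e_coul

    # pairwise geometry for the series (includes i == j self-reaction terms)
    r = np.linalg.norm(pos, axis=1)
    qq = np.outer(qs, qs).ravel()
    rr = np.outer(r, r).ravel() / R ** 2          # (r_i r_j / R^2) < 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ct = (pos @ pos.T).ravel() / np.outer(r, r).ravel()
    ct = np.nan_to_num(ct, nan=1.0)               # charge at center: P_n term 0^n
    ct = np.clip(ct, -1.0, 1.0)

    prefactor = k / (2.0 * eps_in) / R
    total = 0.0
    p_prev = np.ones_like(ct)                      # P_0
    p_curr = ct.copy()                             # P_1
    rad = np.ones_like(rr)                         # (r_i r_j / R^2)^n
    for n in range(_MAX_TERMS):
        f_n = (eps_in - eps_out) * (n + 1) / (n * eps_in + (n + 1) * eps_out)
        p_n = p_prev if n == 0 else p_curr
        term = prefactor * f_n * float(np.sum(qq * rad * p_n))
        total += term
        if n >= 1 and abs(term) < tolerance * max(abs(total), 1e-300):
            return e_coul + total
        # advance recurrences
        rad = rad * rr
        if n >= 1:
            p_next = ((2 * n + 1) * ct * p_curr - n * p_prev) / (n + 1)
            p_prev, p_curr = p_curr, p_next
    raise SeriesConvergenceError(
        f"Kirkwood series did not converge within {_MAX_TERMS} terms "
        f"(tolerance {tolerance})")


def image_charge_solvation(q: float, a: float, z: float,
                           eps_this_side: float, eps_other_side: float,
                           unit: EnergyUnit = DELPHI_UNIT) -> float:
    """Self-energy of a Born sphere near a planar dielectric interface (kT).

    A charge ``q`` in a sphere of radius ``a`` sits at signed distance
    ``z`` from a planar interface, in the medium ``eps_this_side`` facing
    ``eps_other_side``.  For |z| > a (the sphere does not touch the
    interface) the method of images gives

        E = k q^2 / (2 a eps_this)                       (Born self-energy)
          + k q^2 / (4 |z| eps_this)
            * (eps_this - eps_other) / (eps_this + eps_other)

    The formula is valid on either side of the interface; the excluded band
    |z| <= a, where the sphere straddles the interface, raises.
    """
    if a <= 0:
        raise OracleDomainError(f"Born radius must be > 0, got {a}")
    if not (eps_this_side > 0 and eps_other_side > 0):
        raise OracleDomainError("dielectric constants must be > 0")
    if abs(z) <= a:
        raise OracleDomainError(
            f"|z| = {abs(z)} <= a = {a}: the probe sphere touches the "
            "interface; no closed-form image solution there")
    k = unit.kT_conversion
    born = k * q * q / (2.0 * a * eps_this_side)
    image = (k * q * q / (4.0 * abs(z) * eps_this_side)
             * (eps_this_side - eps_other_side)
             / (eps_this_side + eps_other_side))
    return born + image
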