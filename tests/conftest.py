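"""Shared fixtures: generated structure files and common shapes."""

import numpy as np
import pytest

from nanopqr import geometry


def make_poly_alanine_pdb(n_residues: int = 3) -> str:
    """Fixed-column PDB text for a synthetic poly-alanine chain.

    Backbone (N, CA, C, O) plus CB per residue, 5 atoms each, laid out on
    an idealized straight chain.  Coordinates are synthetic — adequate for
    format and force-field lookup tests, not stereochemistry.
    """
    lines = ["REMARK   1 synthetic poly-alanine fixture"]
    serial = 0
    offsets = {           # local atom offsets within one residue (Å)
        "N": (0.0, 0.0, 0.0),
        "CA": (1.46, 0.0, 0.0),
        "C": (2.00, 1.42, 0.0),
        "O": (1.25, 2.39, 0.0),
        "CB": (2.00, -0.77, 1.21),
    }
    for res in range(n_residues):
        base = np.array([3.8 * res, 0.0, 0.0])
        for name, off in offsets.items():
            serial += 1
            x, y, z = base + np.array(off)
            pad_name = f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {pad_name:<4s} ALA A{res + 1:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           "
                f"{name[0]}")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def poly_ala_pdb(tmp_path):
    path = tmp_path / "polyala.pdb"
    path.write_text(make_poly_alanine_pdb(3))
    return path


@pytest.fixture
def unit_lattice():
    return geometry.LatticeParams(spacing=1.0, atom_radius=0.5)


@pytest.fixture
def small_sphere():
    return geometry.SphereSpec(center=(0.0, 0.0, 0.0), radius=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
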