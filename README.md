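# nanopqr

Build **atomic-style geometric nano-objects** — spheres, cylinders, cones and
boxes rendered as clouds of pseudo-atoms on a regular lattice — charge them by
surface or volumetric density, merge them with biological macromolecules from
PDB files, assign force-field charges and radii, and write the combined system
as a **PQR** (position, charge, radius) or **PQRE** (… + per-atom dielectric)
file ready for continuum-electrostatics solvers.

The package is for structural-bioinformatics and biophysics users who model
hybrid systems: proteins on implant surfaces, AFM tips (cones) probing a
molecular surface, macromolecules immobilized on plates or nanoparticles.
Such nano-objects have no deposited atomic structures; representing them as
pseudo-atom clouds makes them consumable by any software that reads PDB-family
files.

## The model

An object is a solid primitive filled with pseudo-atom centers on a cubic
lattice of step *s* (the **atomic spacing**); as *s* → 0 the cloud approaches
a homogeneous dielectric body. Charging converts a user density *d* into a
total object charge via the analytic measure of the solid,

```
q_V = d[e/Å³] · V        q_A = d[e/Å²] · A
V_sphere = 4/3 π r³      A_sphere = 4 π r²
V_cyl    = π r² |dir|    A_cyl    = 2πr² + 2πr|dir|
V_cone   = 1/3 π r² h    A_cone   = πr (r + √(r² + h²))
V_box    = |a·(b×c)|     A_box    = 2(|a×b| + |a×c| + |b×c|)
```

and splits it equally over the receiving atoms (all atoms for volumetric
charging, the lattice surface layer for surface charging), so the total is
exact at any resolution. Correctness is verified against built-in analytic
continuum-electrostatics oracles instead of an external Poisson–Boltzmann
solver: the Coulomb law of a homogeneously charged sphere, the finite line of
charge, the thin charged disc, the method of images at a planar dielectric
interface, and the Kirkwood Legendre series for point charges in a
two-dielectric sphere,

```
E = k/ε_in Σ_{i<j} q_i q_j / r_ij
  + k/(2 ε_in) Σ_{i,j} q_i q_j Σ_{n≥0} (ε_in−ε_out)(n+1) /
      (n ε_in + (n+1) ε_out) · (r_i r_j)^n / R^(2n+1) · P_n(cos θ_ij)
```

with the solver-convention Coulomb constant k = 561.0 kT·Å·e⁻².

## Worked example

Build a charged sphere, inspect it, and check it against the closed form:

```python
import nanopqr as npq

spec = npq.SphereSpec(center=(0, 0, 0), radius=2.0)
lat = npq.LatticeParams(spacing=1.0, atom_radius=0.5)
scene = npq.Assembly().add_object(spec, lat, label="ball", total_charge=33.0)
summary = scene.compile("ball.pqr", fmt="pqr")
print(summary.to_tsv())
```

```
component	n_atoms	net_charge_e
macromolecule	0	0.000000
ball	33	33.000000
TOTAL	33	33.000000
# charge rounding residual on output: 0.000e+00 e
```

The r = 2 Å sphere at 1 Å spacing holds exactly 33 pseudo-atoms (the integer
lattice points with x²+y²+z² ≤ 4); each carries 1 e. Far from the object the
discrete sum matches the homogeneously charged sphere:

```python
v = npq.direct_coulomb_potential(scene.objects[0].atoms, (40, 0, 0), eps=1.0)
print(v, npq.potential_charged_sphere(33.0, 40.0, eps=1.0))
# 462.8253... 462.8250...   (kT/e, 3e-7 relative)
```

The same workflow is available from the shell:

```sh
nanopqr generate --shape sphere --radius 2 --spacing 1 --total-charge 33 -o ball.pqr
nanopqr robot -o robot.pqr          # bundled 8-part composite, net charge 0 e
nanopqr convert protein.pdb --forcefield parse -o protein.pqr
nanopqr inspect robot.pqr
nanopqr verify --seed 1             # oracle comparison table (TSV)
```

`nanopqr convert` assigns charges/radii from SIZ/CRG tables with the cascade
*(residue, atom) → global atom → defaults (r = 1.0 Å, q = 0.0 e)* and reports
every entry that fell back to defaults. The bundled `amber98`, `charmm22`,
`opls` and `parse` tables are small illustrative subsets; supply full
published files with `--forcefield custom --siz … --crg …`.

Compiled files embed each object under a `REMARK 400` block holding its full
generation parameters, so `nanopqr inspect`/`merge` (or
`nanopqr.load_assembly`) can recover and regenerate every object exactly from
the file alone.

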