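# Methods

## Scope and model

`nanopqr` renders solid geometric primitives (sphere, cylinder, cone, general
parallelepiped) as clouds of pseudo-atoms so that continuum-electrostatics
and other structure-based software can treat nano-objects like molecules. A
pseudo-atom is a position, a radius, an optional charge and an optional
dielectric constant; a cloud of them at lattice spacing *s* approximates a
homogeneous body with an error that vanishes as *s* → 0. The package's
contribution is the generation/charging/bookkeeping pipeline plus an
analytic-oracle verification surface; it deliberately does **not** contain a
Poisson–Boltzmann solver (see Limitations).

## Lattice generation

Atoms sit on a cubic lattice of step *s* aligned to the shape's local frame:
global axes for the sphere, one axis along the symmetry axis for cylinder and
cone, the (normalized) edge directions for the box — for a non-orthogonal box
the lattice follows the edges and is cubic in edge coordinates. The lattice
is anchored at the shape's geometric center (box: origin corner), and points
are emitted in lexicographic lattice-index order, making generation fully
deterministic: two calls with identical inputs are bit-identical, which the
REMARK 400 regeneration contract relies on.

Membership is tested on atom **centers**, with boundary points included
(`≤` comparison, 1e−9 Å tolerance), so a sphere of nominal radius 10 Å built
from 1 Å atoms has an effective outer radius of 11 Å. When that matters,
`compensate_radius` shrinks the solid inward by the atom radius first —
implemented uniformly as a signed-distance threshold, so it is exact for all
four primitives. The anchoring choice (center vs corner) changes atom counts
at the O(surface) level between otherwise equivalent tools; files record the
full generation parameters, so counts are reproducible from the file itself.

The signed distance function (positive inside) is exact for every primitive,
including outside points near edges and vertices (cone via its 2-D meridian
triangle, box via face/edge projection). It backs membership, radius
compensation, the surface-layer classification and the containment and
Monte-Carlo test oracles.

## Charging

Density charging computes the total object charge analytically — `d·V`
(volumetric, e/Å³) or `d·A` (surface, e/Å²) — and divides it **equally** over
the receiving atoms. The alternative reading, density × measure as the charge
of *each* atom, would make the object total depend on lattice resolution;
equal division keeps the total exact at any spacing, which is what the
net-charge bookkeeping of a composite (and any downstream solver input)
needs. Explicit total-charge assignment (`distribute_total_charge`) uses the
same equal split.

Surface-density charge lands on the lattice **surface layer**: atoms with at
least one of their six face-neighbour lattice sites outside the solid
(boundary counted as inside, matching the generation tie-break). This is the
physically sensible choice for a conductor-like surface; a
`surface_layer_only=False` flag spreads a surface-density total over all
atoms instead for back-compatibility experiments. A single-atom object has no
surface layer and takes the whole charge with a warning. Charges are stored
at full float precision; PQR output quantizes to 4 decimals and the compile
summary reports the quantization residual, bounded by 0.5·10⁻⁴ e per atom.

## Force-field assignment

SIZ/CRG files are whitespace-separated `atom [residue] value` tables
(`!` comments; a missing residue column makes a global entry) — the
DelPhi-community convention. Assignment is per atom and per field: exact
(residue, atom) entry, else global atom entry, else radius 1.0 Å / charge
0.0 e with the miss recorded. Radius and charge fall back **independently**
(a SIZ-only hit keeps its radius and defaults only the charge); misses are
data, not errors, and the report is exhaustive and duplicate-free. The four
bundled tables are self-made illustrative subsets covering the 20 standard
amino acids' heavy atoms — enough for tests and demos, not the published
parameter sets.

## File formats

PDB input is parsed fixed-column; all non-atom records are kept as opaque
passthrough. PQR/PQRE output is the whitespace-delimited dialect accepted by
PB solvers (coordinates to 3 decimals, charges/radii/epsilons to 4), with the
chain column emitted only when present. Every compiled file starts with a
`REMARK 400 FILE FORMAT` sentinel so readers select the whitespace dialect
deterministically instead of guessing per line — whitespace PQR and
fixed-column PDB with occupancy/B-factor are otherwise ambiguous, and this
package never reinterprets occupancy as charge.

Objects are bracketed by `REMARK 400 OBJECT BEGIN/END <label>` with one
`REMARK 400 <key> <value>` line per generation parameter, written at full
float precision (`repr`), so `generate_atoms(spec, lattice)` rebuilds the
stored atoms exactly; write → parse → write is byte-stable. A block with an
unrecognized shape type is preserved opaquely (atoms kept, parameters
dropped) with a warning. PQRE materializes a per-atom epsilon from the object
or protein default when the atom has none.

## Assembly and the composite robot

An assembly is an ordered scene: macromolecule atoms first, then objects in
insertion order, serials renumbered strictly increasing at compile time.
Overlaps between components are allowed — composite objects are unions — and
are surfaced only through an advisory clash report (minimum inter-component
atom distance via a k-d tree). The bundled robot recipe builds eight parts
(head sphere, body box, arm/leg cylinders, feet boxes) with per-part totals
+2, −4, +1, +1, +1, +1, −1, −1 e, summing to exactly zero; it is an
illustrative ~1/10-scale desk model (≈31 × 36 × 73 Å, ≈13 000 atoms at 1 Å
spacing, built in seconds) with `scale` multiplying all dimensions, chosen so
the full test suite stays interactive.

## Oracles and numerical choices

* **Coulomb constant.** k = 561.0 kT·Å·e⁻², the PB-solver convention
  (T ≈ 297 K); it is a parameter of `EnergyUnit`, not a constant, because the
  kT scale shifts with the temperature convention. For the two-charge cavity
  benchmark the series with k = 561.0 gives −5074.17 kT, 0.18 % below the
  commonly quoted −5083.19 kT (which corresponds to k ≈ 562); the acceptance
  check allows 1 % for exactly this ambiguity.
* **Kirkwood series.** Upward Legendre recurrence (stable for |cos θ| ≤ 1),
  all charge pairs including the i = j self-reaction terms, truncated when a
  term's relative contribution falls below the tolerance (default 1e−10),
  hard cap 10⁴ terms — reaching the cap raises, never silently truncates.
  The recurrence is cross-checked against `scipy.special.eval_legendre` in
  the tests. Charges on or outside the boundary are rejected (divergent).
* **Image charges.** The planar-interface energy is the Born self-energy in
  the local medium plus the image correction
  k q²/(4|z| ε₁)·(ε₁−ε₂)/(ε₁+ε₂), valid only while the probe sphere does not
  touch the interface (|z| > a); the contact band raises.
* **Discretization consistency.** A charged cloud is compared to its
  continuum closed form with **total-charge matching** (λ = Nq/L,
  σ = Nq/πR²): at 1 Å spacing the sphere/line/disc constructions agree
  within 2 % for distances ≥ 10 Å with error decreasing monotonically in
  distance; distances of 1–4 Å are excluded because single-atom granularity
  dominates there. For the spacing-refinement property (error shrinking at
  1.0 → 0.75 → 0.5 Å) the reference is instead **extent-matched** to the
  realized cloud (λ = q/s over the realized span, σ = q/s² over the realized
  covered area): under total-charge matching the 0.75 Å line truncates at
  ±19.5 Å and its extent error partially cancels the discreteness error,
  breaking monotonicity for reasons unrelated to discretization. The line
  construction only stays a literal line while the cylinder radius is below
  the spacing; the refinement test therefore uses a 0.2 Å-radius cylinder.
* **Monte-Carlo test oracles.** Volume by rejection sampling with
  independent membership predicates (10⁶ points, fixed seeds); area by the
  shell estimate (V_outer − V_inner)/(2δ) with first-order parallel bodies
  (for the cone, uniform scaling by 1 ± δ(R+ℓ)/(Rh), which yields
  dV = A δ exactly to first order), δ = 0.02·V^{1/3}. Both agree with the
  closed forms within 2 %.

## What the synthetic fixtures do and do not show

All test structures are generated: a 3-residue poly-alanine chain (backbone +
Cβ on an idealized straight geometry) exercises PDB parsing and force-field
lookup, and all nano-objects are built by the package itself. These fixtures
validate formats, bookkeeping and the physics of the analytic benchmarks;
they do not probe real-protein pathologies (altLocs, insertion codes,
non-standard residues, multi-model files), which the parser does not claim to
handle beyond passthrough.

## Known limitations

* No Poisson–Boltzmann solving: solver-scale results (solvation energies of a
  protein on objects, large-grid potential maps) are out of scope; the
  analytic oracles and consistency properties are the verification surface.
* Uniform densities only; no position-dependent or self-consistent charging.
* Convex primitives only; no meshes, CSG booleans, or non-cubic lattices.
* PQR is the whitespace dialect; fixed-column PQR variants from other tools
  are read for coordinates but their charge columns are not guessed.
* Protonation, hydrogen building and ligand parameterization are delegated to
  dedicated tools; the custom SIZ/CRG path is the entry point for their
  output.
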