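# Methods

## The model

A magnetosensitive polymersome (MPS) is a vesicle whose amphiphilic double
membrane confines magnetic nanoparticles (MNPs) in the gap between its two
polymer shells.  `polymag` represents it with two nested, closed triangulated
spherical shells of polymer beads (equal bead counts, subdivided-icosahedron
meshes projected to the sphere) plus a monolayer of dipolar soft spheres in
the intershell gap.

All quantities are reduced: the intershell spring rest length `h` is the
length unit, `kBT` the energy unit, the bead mass the mass unit.  The
vesicle size is `q = D/h` with `D` the diameter of the as-built outer node
sphere; shells sit at node radii `D/2` and `D/2 - h`, which makes the
basic-state inner cavity close to the sphere of diameter `D - 2h`.

Forces on shell beads:

* **Stretching** — harmonic springs on every mesh edge,
  `E = (k_stretch/2) (l - l0)^2`, rest lengths from the as-built geometry.
* **Local area** — per-triangle restoring term
  `E = (k_area/2) (A - A0)^2 / A0`.
* **Bending** — dihedral term `E = (k_bend/2) (theta - theta0)^2` per shared
  edge, with the spontaneous angles `theta0` taken from the as-built sphere.
* **Intershell bonds** — harmonic springs of rest length `h` between
  subtending nodes of the two shells, on a random fraction `cb` of nodes.
* **Steric repulsion** — WCA (purely repulsive truncated-shifted
  Lennard-Jones, cutoff `2^{1/6} sigma`) between MNPs and between MNPs and
  shell beads, with `sigma_ij = (d_i + d_j)/2`.  Shell beads do not repel
  each other; the mesh itself is the steric wall.

Each MNP carries a rigid central point dipole of reduced moment
`mu = sqrt(lambda kBT dp^3)`, so that the dipolar coupling constant
`lambda = mu0 mu^2/(dp^3 kBT)` is an input.  Dipole–dipole forces and fields
are summed over all pairs with open boundaries (the vesicle is a finite,
non-periodic object; no Ewald).  A uniform field of Langevin parameter
`xi = mu0 mu H0 / kBT` adds the Zeeman torque `xi kBT (e x hhat)` and no
force.

Dynamics: underdamped Langevin equations for all positions and, for MNPs,
for the orientation unit vectors, integrated with the BAOAB splitting and
its rotational analogue (orientation rotated by the angular velocity with
per-step renormalization; moments are axially symmetric so quaternions are
unnecessary).  Noise amplitudes obey fluctuation–dissipation, making the
stationary distribution Boltzmann at `kBT`; the tests verify translational
and rotational equipartition to 2 % and the free-dipole magnetization
against the Langevin function `L(xi) = coth(xi) - 1/xi`.

## Parameters, defaults, and why

| parameter | default | meaning / rationale |
|---|---|---|
| `dp` | 0.3 | MNP diameter; 15 nm particles at `h` ≈ 50 nm |
| `hgap` | 0.35 | gap accessible to MNPs, `h - (din+dout)/2`; just over `dp`, so the layer is a monolayer |
| `din`, `dout` | 0.65 | bead diameters; only the sum is constrained by `hgap`, the symmetric split is one consistent choice |
| `cb` | 0.2 | fraction of nodes bonded across the gap |
| `phi` | 0.11 | MNP volume fraction of the accessible gap layer |
| `lambda_dd` | 5 | dipolar coupling of ~15 nm ferrite particles at room temperature |
| `k_area` | 500 | near-incompressible local area (relative-area fluctuations ~4 %) |
| `k_stretch` | 20 | soft in-plane shear: an amphiphilic membrane is a 2-D fluid, and elongating a sphere into a spheroid at conserved area is a local area-preserving shear.  Stiff edge springs (k ~ 500) make the shell shear-rigid and suppress field-induced deformation almost completely; the default keeps the *total* area drift well under 3 % per production run while leaving the shell shear-compliant |
| `k_bend` | 5 | dihedral bending.  A thermalized triangulated surface with zero bending rigidity crumples entropically (we observed full collapse of the cavity without this term), so a value above the ~1 kBT crumpling threshold and below the bending modulus of a stiff polymer membrane is required for the smooth spherical basic state |
| `k_bond` | 50 | softer than the in-shell terms so the layer thickness can fluctuate, more so at low `cb` |
| `wca_epsilon` | 1 | overlap stiffness only |
| `zeta_t` | 1 | thermostat friction; sets relaxation rates, not equilibria |
| `zeta_r` | `zeta_t dp^2/3` | rotational friction, sphere-like scaling |
| mass, inertia | 1, `dp^2/10` | equilibrium statistics are mass-independent |
| `dt` | 0.002 | ~100 steps per stiffest spring period; a per-step displacement above `0.25 dp` aborts the run |

MNP count: `N = round(phi * V_gap / ((pi/6) dp^3))` with `V_gap` the
closed-form volume of the spherical layer between the bead surfaces; the
realized `phi` is logged.  Initial MNP centers are sampled uniformly on the
gap mid-surface with radial jitter inside the band accessible to centers,
then relaxed by soft pushes to at least `0.9 dp` separation; this band
coincides with the region where both WCA walls are inactive, so the initial
state is mechanically quiet.

## Experiment protocol

Following the replica protocol of the underlying study: build the vesicle,
equilibrate at `xi = 0` (the *basic state*), measure, switch the field on
instantaneously, equilibrate again, measure.  Replicas share the geometry
and the MNP positions and differ only in the initial orientations of the
magnetic moments (and their noise streams); observables are replica means
with standard errors.  Equilibrium is declared when the windowed mean total
energy changes by less than a relative tolerance between consecutive
windows; measurements then average over a short production stretch.

Observables:

* Semi-axes from the gyration tensor of the outer-shell beads; `b` is the
  eigen-direction most aligned with the field.  Only ratios enter the
  elongation `epsilon = 2b/(a + c) - 1`, so the shell-vs-solid eigenvalue
  scaling cancels.  Gyration moments are robust to single-bead outliers,
  which is why they are preferred over extremal extents.
* Inner-cavity volume as the signed-tetrahedra sum over the polyhedron
  spanned by the inner-shell bead centers; the volume defect is
  `(V - V0)/V0` against the same replica's basic state.
* Chain statistics: two MNPs are linked when closer than `1.3 dp` *and*
  their dipolar pair energy is below `-1 kBT` (standard dipolar-cluster
  criteria; both thresholds configurable); chains are connected components.
  Because the field-free monolayer already percolates into large loose
  aggregates at `lambda = 5`, component size is a poor *order* metric; the
  chain order reported alongside it is the nematic order
  `<P2(rhat_ij . hhat)>` of the bonded-pair separation vectors (0 for an
  isotropic bond network, 1 for perfectly field-aligned chains).
  Polar-zone occupancy is the MNP fraction inside 30° polar caps about the
  field axis — inside the complement of the dipolar repulsion window.

## Numerical choices

* Force kernels are exact analytic gradients of the potential terms; the
  test suite checks each against central-difference gradients of the energy
  (the master oracle) and checks pairwise momentum/angular-momentum balance.
* The dipolar sum is all-pairs `O(N^2)`; MNP–shell WCA uses a linked-cell
  grid rebuilt every step; in-shell terms are `O(edges)`.
* WCA forces are capped below `0.6 sigma` (deep overlaps can only arise
  from pathological initial states); every capped evaluation is counted and
  reported.
* Degenerate geometry (zero-length edge, zero-area triangle, coincident
  dipoles) raises instead of silently producing NaNs.
* Same seed ⇒ bit-identical assembly and trajectory (single-threaded,
  one RNG stream).

## What the model does and does not emulate

The model reproduces the study conditions as published: sizes `q = 6…14`,
`phi ≈ 0.11`, `cb = 0.2`, `lambda = 5`, `xi` up to 10, ten replicas (desk
runs use fewer; means carry standard errors).  It is a solvent-free
Langevin description: no hydrodynamic coupling, no Néel relaxation
(moments are rigid in the particle body), no membrane viscosity, no
polydispersity.  The elastic constants of the shells are not fixed by the
published model description; the defaults above are this package's own
calibration of the membrane's mechanical regime (fluid, area-conserving,
weakly bending-rigid) and the elongation magnitudes depend on them.
Consequently, quantitative agreement of strain values with the published
curves should be read as model-family agreement, not as a parameter-free
prediction.

Desk-scale problem sizes: the package's own test and reproduction runs use
the full mesh resolution at `q = 6` (642 beads per shell, ~214 MNPs) with
five (reproduction) or three (tests) replicas and shortened
equilibration/production stages chosen at the observed plateau of the
energy and shape traces; `q = 14` (2562 beads per shell, ~1446 MNPs) runs
one replica with a shorter field stage.  Published-scale runs (10 replicas,
long equilibration) are available through the CLI.

## Known limitations

* The dimensional field correspondence printed in the source study
  (`xi ≈ 200 H0`, so `xi = 10` at 2 kOe) is inconsistent with the literal
  Zeeman-to-thermal ratio evaluated from its own moment (`xi ≈ 39` at
  2 kOe, 300 K); `polymag.units.xi_from_field` implements the literal
  formula and this note records the discrepancy.
* Similarly, the dipolar coupling evaluated exactly from `dp = 15` nm,
  `M = 500` emu/cm³, `T = 300` K is `lambda = 5.58`; the rounded moment
  `mu ≈ 8e-16` emu gives `lambda ≈ 4.6 ≈ 5`.
* Mesh coarsening (`coarsen > 1`) makes the shells porous to MNPs once the
  mean edge exceeds roughly the bead diameter, because the WCA barrier at
  triangle centers vanishes; coarse meshes are for smoke runs only.
* At strong squeezing or very soft `k_stretch` (< ~10) the inner-shell
  triangles can degenerate and the run aborts; the defaults are stable at
  `dt = 0.002`.
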