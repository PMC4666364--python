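# Methods

## Model

gistlab computes hydration-shell thermodynamics on a cubic voxel grid
populated from an ensemble of solvent snapshots around a rigid solute
(grid inhomogeneous solvation theory, GIST). A water belongs to voxel *k*
when its oxygen lies in the voxel; voxel membership uses half-open
intervals, so a coordinate exactly on a boundary belongs to the upper
voxel and is never double-counted. The relative density is

    g(r_k) = n(r_k) / (rho0 * V_k)

with `n(r_k)` the mean per-frame water count, `V_k` the voxel volume and
`rho0` the bulk number density (default 0.0329 Å⁻³ for TIP3P water at
298 K). Density is assumed uniform within a voxel; there is no sub-voxel
interpolation.

Per voxel the engine also accumulates:

* **E_sw(r_k)** — the mean summed interaction energy (Coulomb with
  k_e = 332.0637 kcal·Å/mol/e² plus Lennard-Jones with Lorentz–Berthelot
  mixing) between each in-voxel water and every non-water atom.
* **E_ww(r_k)** — water–water interaction energy with *half* of each
  molecular pair energy attributed to each partner's voxel, so the voxel
  sum reproduces the total water–water energy exactly and the bulk
  per-water reference `eps_ww0 = -9.565 kcal/mol` is a half-sum quantity.
* **TΔS_tr(r_k)** — translational solvation entropy from the first-order
  density formula `-kB T n ln g` (per water: `-kB T ln g`).
* **TΔS_or(r_k)** — orientational solvation entropy from a first-nearest-
  neighbour differential-entropy estimate over the voxel's observed water
  orientations (below).

Energies are direct pairwise sums under the minimum-image convention when
a box is present; no Ewald summation is performed at the analysis stage
and the default is no cutoff, which is appropriate for the desk-scale
systems the package targets. Intramolecular pairs are excluded.

### Water orientations

Each rigid 3-site water defines a body frame with z along the H–O–H
bisector, x in the molecular plane towards the first hydrogen and
y = z × x. The frame is stored as a unit quaternion with the scalar part
canonically non-negative; antipodal quaternions describe the same
rotation and are identified throughout. The rotation-manifold metric is
the rotation angle `theta(q_i, q_j) = 2 arccos |q_i · q_j|` in [0, π].

### Orientational entropy estimator

For N orientations in a voxel the differential entropy is estimated by
the first-nearest-neighbour construction on SO(3):

    H ≈ gamma + (1/N) Σ_i ln(N · B(d_i)),   B(r) = 4π (r − sin r),

with `gamma = 0.5772…` and `d_i` the nearest-neighbour rotation angle,
floored at 1e-6 rad so coincident orientations stay finite. The total
Haar volume is `Omega = 4π²`, and the per-water term is
`TΔS_or = kB T (H − ln Omega)`, clamped to ≤ 0 because the reference
(bulk) distribution is Haar-uniform — positive excursions are estimator
noise, not physical entropy gains. Voxels with fewer than `min_samples`
(default 10) observations report 0 and are flagged rather than treated
as errors.

**Convergence guidance.** The per-sample term `ln(N B(d_i))` has variance
≈ π²/6, so the estimator's standard deviation is ≈ 1.28/√N nats and the
clamp turns that spread into a negative bias of ≈ 0.30/√N kcal/mol at
298 K. Per-voxel estimates are therefore only meaningful once a voxel has
accumulated on the order of 10² samples. This is why the bulk-null
validation (below) uses 1.5 Å voxels for 2000 frames (~220 samples per
voxel, bias ≈ −0.02 kcal/mol) instead of the 0.5 Å production default,
which at that frame count would leave ~8 samples per voxel. Production
maps at 0.5 Å spacing need correspondingly longer ensembles for the
orientational term — energies converge much faster than orientational
entropy, which mirrors how these analyses behave on real simulation data.

The translational term deliberately uses the closed-form density formula
rather than a nearest-neighbour estimator: it is testable analytically
and adequate at first order. This choice is configurable in principle;
the per-voxel g maps are exported, so alternative estimators can be
applied downstream.

## Region aggregation and the density-corrected bulk reference

A region R is a set of voxels selected by the minimum distance `r_min`
from a designated solute atom set to the voxel center, with *strict*
inequalities at both bounds (the first hydration shell default is
2 Å < r_min < 4 Å; boundary voxels are excluded). Extensive voxel sums
normalize per water by `n(R)`:

    TΔS_tr^w(R) = Σ_k TΔS_tr(r_k) / n(R)        (likewise TΔS_or^w, ΔE_sw^w)
    ΔE_ww^w(R)  = [ Σ_k E_ww(r_k) − rho0 · V(R) · eps_ww0 ] / n(R)
    ΔG^w(R)     = −TΔS_tr^w − TΔS_or^w + ΔE_sw^w + ΔE_ww^w

The bulk water–water reference is `rho0 V(R) eps_ww0`, i.e. the energy
the region's *volume* would hold at bulk density — not `n(R) eps_ww0`.
The distinction matters whenever the region density ρ(R) differs from
bulk: with the uncorrected reference a region at ρ(R) = 2 rho0 whose
waters each carry exactly the bulk per-water energy would report
ΔE_ww^w = 0, while the corrected form reports eps_ww0/2 = −4.78 kcal/mol
— the extra waters above bulk occupancy are genuinely non-bulk-like. The
solute–water reference is zero (no solute exists in bulk).

Differences between two conditions (e.g. with and without cosolute) are
componentwise; standard errors come from non-overlapping frame-block
averages (default 5 blocks) combined as `sqrt(sem_a² + sem_b²)`.

## Density profiles

The minimum-distance density profile of a species is the voxel average of
`n_molecule(r_k)/V_k` over voxels whose `r_min` falls in each half-open
bin [r, r + Δr), Δr = 0.5 Å by default. A molecule is located by one
reference point: water by its oxygen, a cosolute by the geometric center
of its heavy atoms (configurable). Bins containing no voxels are flagged
undefined rather than zero-filled.

## Structure metrics

* **Shell surface.** The iso-minimum-distance surface at radius `r_min`
  is the boundary of the union of per-atom spheres: a deterministic
  Fibonacci lattice on each atom's sphere, retaining points whose global
  minimum distance to the atom set is within tolerance of `r_min`. The
  mean bare-Coulomb potential `V(r_min) = ⟨Σ_i q_i / r_ij⟩` over surface
  points is reported in e/Å with no dielectric and no cutoff.
* **Atom–surface distances.** The distribution of distances from every
  surface point to every solute atom, averaged over surface points. Its
  support length (the envelope within which the surface "sees" all
  atoms) discriminates compact from elongated solutes.
* **SASA.** Shrake–Rupley point sampling on the same deterministic
  lattice (default 960 points/atom; single-sphere areas are then exact
  and multi-sphere areas accurate to well under 0.5%). Radii default to
  the Bondi set by element. Exactly coincident equal spheres are
  deduplicated first. The probe scan `R_SASA(r_p) = SASA(r_p)/SASA(r_0)`
  with r_0 = 1.4 Å probes whether pockets admit cosolute-sized probes:
  convex bodies give R_SASA rising with r_p, pocket-bearing bodies give
  falling R_SASA while the pockets close.
* **Hydrogen bonds.** Geometric criteria: donor/acceptor heavy atoms are
  N or O, heavy-atom distance < 3.5 Å, donor–H–acceptor angle (measured
  at the hydrogen) within [135°, 180°]. Both solute-as-donor and
  solute-as-acceptor directions count, each (donor, H, acceptor) triple
  at most once, and counts normalize per partner molecule in the region.
* **Formal charge.** An unmodified single-stranded nucleic acid without
  terminal phosphates carries one negative charge per phosphodiester
  linkage: net charge −(n−1) for n residues, with as many neutralizing
  monovalent counterions.

## Synthetic ensembles (what they emulate, what they do not)

The generators place *non-interacting* rigid 3-site waters so that every
analysis target is analytic:

* Per-frame counts are Poisson (not fixed N), positions uniform or
  shell-modulated, so per-voxel counts are independent Poisson variates
  and binomial/Poisson error bounds apply exactly.
* The shell generator draws each voxel's count from
  Poisson(g(r_k) · rho0 · V_k), where g is the prescribed piecewise
  profile evaluated at the voxel-center r_min of the generator's own
  grid. Expected occupancy therefore matches the target *per voxel*,
  the same uniform-within-voxel convention the analysis assumes, and
  profile/region recovery is unbiased by construction.
* Orientations come from a one-parameter family: Haar-uniform within a
  geodesic ball of radius π/(1+κ) about the identity. κ = 0 is exactly
  Haar; the relative entropy has the closed form `ln(B(r)/4π²)`, which
  calibrates the NN estimator end to end.
* The two-site rigid toy cosolute replaces a water with a prescribed
  shell-dependent probability and is excluded from the solute core.

Because waters do not interact, passing the recovery tests demonstrates
correct *bookkeeping* (densities, energies attributed and summed
correctly, estimators calibrated) — it does not demonstrate anything
about liquid-water structure, hydrogen-bond networks or real hydration
free energies. Interaction energies on ideal-gas configurations can be
arbitrarily large (overlapping molecules); energy validation therefore
compares against an independent O(N²) oracle rather than against
physical expectations.

## Numerical choices

* Half-open voxel intervals everywhere; ties go to the upper voxel.
* Strict region bounds; voxels with r_min exactly at a bound are out.
* NN distances floored at 1e-6 rad; per-water TΔS_or clamped to ≤ 0.
* Degenerate inputs fail loudly: coincident distinct atoms in an energy
  sum, waters without two hydrogens, empty regions, unrealizable target
  densities (g · rho0 above a packable water density).
* Energies use an early exit when every charge and LJ epsilon is zero
  (the value is identically zero).
* All generators are deterministic given their seed; the pipeline is
  deterministic given config + input, and reruns are byte-identical.

## Problem sizes used in validation

The statistical checks run at sizes where their error bars are sharp:
the bulk null uses 2000 frames of ~263 waters in a 20 Å box (1.5 Å
voxels, see above); shell recovery uses 500 frames in a 24 Å box; energy
closure uses ~30 interacting waters over 3 frames; estimator calibration
uses 10⁴ orientations. Each tolerance in the tests is the analytic
2–4 SE band of the corresponding statistic, never a fitted number.

## Known limitations

* The voxel entropy terms are first-order (density and first-NN
  orientational); water–water correlation entropy and higher-order terms
  are out of scope.
* The translational formula and the orientational estimator are the
  package's stated contracts; published GIST implementations differ in
  estimator details, so absolute entropy values from other codes are not
  directly comparable.
* The shell-surface point placement (and hence N_P) is a stated
  convention; potentials averaged over differently constructed surfaces
  can differ at the few-percent level.
* PDB is the only trajectory format; binary MD formats are out of scope.
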