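# Methods

`symcoord` quantifies how far a near-symmetric molecular fragment has bent
away from an idealized point-group geometry by decomposing its atomic
coordinates into symmetry coordinates: displacement fields that transform
purely as single irreducible representations (irreps) of the chosen group.

## The decomposition model

Let X be the N×3 coordinates of the fragment after rigid alignment into
the symmetry frame, and let G be one of the supported point groups (C2v,
C2h, D2d, D2h, D3h, D4h, D6h; C1 is the trivial boundary case).  Every
operation g acts on the configuration through its 3×3 matrix realization
R(g) *and* a cached atom permutation π(g) telling which atom lands on
which.  The permutations are derived once from a symmetric reference model
by Hungarian assignment of each atom to its operation image; on a
symmetric model they compose exactly like the group (π(g∘h) = π(g)∘π(h)),
which makes every averaging operator below an exact projector and gives
the reconstruction identity to machine precision.

For a one-dimensional irrep Γ with kernel K (the index-2 subgroup of
operations with character +1) the component is the difference of two
symmetrized copies of X:

    M_Γ = avg_K(X) − avg_G(X)

where avg_H denotes iterative averaging of each atom with its symmetry
images over the subgroup H (tolerance 1e-10 Å maximum shift, capped at
100 iterations; with representation-consistent permutations one pass
converges).  The totally symmetric component is compared to the reference
model instead, avg_G(X) − M_model, and is reported as exactly zero when no
model is supplied — the internally generated model *is* avg_G(X) in that
case.  In C1 the whole procedure degenerates to the plain difference
between the aligned fragment and the model.

The reported magnitude of a mode is the plain sum of per-atom displacement
norms, Σᵢ‖vᵢ‖ in Å — not an RMS and not mass-weighted.  The decomposition
is purely geometric; masses never enter.

### Degenerate (E-type) irreps

Doubly degenerate irreps carry explicit 2×2 representation matrices D(g),
generated at table-construction time from basis-function pairs — (x, y),
(xz, yz), (x²−y², 2xy), (z(x²−y²), 2xyz) — and validated against the
characters and the group's composition table.  An oriented component along
the representation-space direction e_θ = (cos θ, sin θ) is the rank-1
projection

    P_θ X = (d/|G|) Σ_g ⟨e_θ, D(g) e_θ⟩ · (g·X).

We chose this construction over the superficially simpler "symmetrize over
the variant's stabilizer subgroup and subtract the totally symmetric
representation" because the latter is contaminated in D4h: the stabilizer
of an x-oriented Eu pattern, {E, C2(x), σ(xz), σh}, is a subgroup of
ker(B1g), so the subgroup difference carries the B1g component along with
the Eu one.  The oriented projection is exact for all seven groups,
including the D6h case where subgroup averaging additionally mixes the E1
and E2 pairs (the stabilizer of an x-oriented E1u pattern also fixes an
E2g pattern).  The variant stabilizer subgroups are still computed from
the representation matrices and stored on each irrep row; they are what a
mode's kernel-invariance contract is tested against.

Orientation variants are taken at 0°/45°/90°/135° for D4h and D2d
(reconstruction weight ½: the rank-1 projectors onto four directions at
45° spacing sum to twice the isotypic projector) and at 30° spacing
(0°…150°, weight ⅓) for D3h and D6h.  The D3h set is widened from the
three symmetry-axis orientations to six so that every variant has its
orthogonal counterpart in the list; the weight follows from Σ e_θe_θᵀ = 3·I.
Result tables report the greatest-magnitude variant and its orthogonal
counterpart (θ+90°); all variants are retained in the raw output, and the
per-irrep scalar magnitude is the sum over the reported pair, which is
invariant under the group's relabeling of equivalent orientations.

### Oracle

The textbook character projection (d_Γ/|G|) Σ_g χ_Γ(g)·(g·X) is kept as an
independent route: the test suite checks that every kernel-averaged 1-D
mode and every weighted variant sum agrees with it to < 1e-9 Å on random
inputs, and that the components over all irreps sum back to X
(completeness) with the ½ or ⅓ weight on degenerate variant sums.

## Alignment

**To a model.**  The query is centered, axis-conventioned, and matched to
the model by Hungarian assignment followed by closed-form Kabsch
superposition, iterating until the permutation stabilizes, from four
sign-flip starting orientations.  The result is accepted outright only
when the per-atom RMSD is below 8% of the model's minimum interatomic
distance — an unambiguous basin; otherwise the search sweeps six
principal-axis placements (each signed principal axis onto z) crossed with
in-plane rotations in 15° steps and keeps the global best.  The sweep
matters: frames with nearly higher rotational symmetry (an 18-atom
hexagonal frame whose outer ring is almost 12-fold) have spurious basins
whose fit quality is well under a bond length.

**To the operations (model-free).**  When only a group is given, the
orientation minimizes the total symmetry-operation distortion: the sum
over non-identity operations of the Hungarian-matched squared distance
between the coordinates and their operation image.  Six perpendicular
principal-axis starts are each swept through in-plane rotations (15°
grid), the best few candidates are refined with a derivative-free simplex
over a 3-parameter rotation-vector chart, and near-ties are broken towards
the identity so an already-oriented input keeps its frame (making model
generation idempotent).  A basin-hopping fallback flag exists for
pathological inputs.

**Axis conventions.**  After orientation, axes are relabeled by proper
moves from the group's normalizer (signed axis permutations, plus
half-angle in-plane rotations for 3/4/6-fold principal axes) so that
var(x) ≥ var(y) ≥ var(z) where axes are interchangeable — near-planar D2h
molecules lie in the x–y plane with the long axis on x; C2v keeps its C2
axis on z with the molecule in the x–z plane.  For groups whose principal
rotation order is ≥ 3 the variance cannot fix the in-plane phase (an
idealized porphyrin core has var(x) = var(y)), so a normalized n-fold
moment Σ ρⁿ cos(nθ) breaks the remaining half-angle ambiguity: models
rebuilt from arbitrarily rotated exemplars agree atom-for-atom.  Exact
variance ties keep the incoming order and emit a warning.

## Model generation

A symmetric reference model is built from a single exemplar: orient to the
operations, iteratively average every atom with its symmetry images
(re-deriving the assignment between rounds until it is stable), center,
apply the axis convention, and finally recompute and cache the per-operation
permutations from the symmetric coordinates, verifying that they compose
like the group — failure of that check means the assignment was ambiguous
and graph-based matching (`by_graph`) is advised.  Averaging over an orbit
of size m shrinks independent coordinate noise by √m; with σ = 0.05 Å on a
14-atom D2h frame (orbits of 4) the mean per-atom model error is ≈ 0.03 Å,
with extremes up to about 2σ.  Models serialize to a versioned JSON schema
with coordinates as 6-decimal strings, giving bit-stable round trips;
missing permutation caches are recomputed on load with a warning.

## Collections and pseudo-normal modes

For many structures decomposed against one model, the flattened per-irrep
vector sets are stacked into a structures × 3N matrix and factored by
*uncentered* PCA (plain SVD, no mean subtraction): components pass through
the origin so that an undistorted structure has zero coefficients — the
behaviour expected of normal-mode-like coordinates.  Component signs are
fixed deterministically (largest-magnitude entry positive).  Explained
variance fractions come from the squared singular values; coefficients are
inner products (the components are orthonormal) and the residual is the
norm of the leftover vector.  Nearest conformations are ranked by the
summed squared difference of per-irrep magnitudes, ties broken by
identifier order.

## Mondrian diagrams

One line per dissymmetric mode at log10(magnitude) over a default axis
range of 10⁻² to 10¹ Å: out-of-plane irreps draw vertical lines, in-plane
irreps horizontal ones.  The parity classification uses the character
under the reflection through the conventional molecular plane (σh for the
planar groups, σ(xz) for C2v); D2d, which has no such plane, routes by the
character under its S4 generator — a documented dialect choice, as is the
full-span line style.  Each rectangular cell is labeled with the residual
point group retained when exactly the modes whose lines bound it on the
large-magnitude side are accepted; the label comes from intersecting the
active irreps' kernels and classifying the resulting operation set by a
Schoenflies flowchart (principal axis, perpendicular C2 count, mirror
placement).  The lookup table is generated programmatically from those
kernel intersections, never hand-curated, and is property-tested against
direct enumeration for every subset of every shipped group.  The palette
maps residual group names to colors and is user-overridable; no claim is
made of reproducing any published artwork's aesthetics.

## Synthetic data

The fixtures module is the test bed: exactly symmetric frames (deviation
< 1e-12 Å under every operation) at an idealized 1.40 Å aromatic bond
scale — an anthracene-like C14 sheet (D2h), a porphyrin-like C20N4 core
(D4h), a BODIPY-like C9N2B core (C2v), and orbit-generated frames for
C2h, D2d, D3h, D6h.  Distortion patterns are displacement fields projected
onto a single irrep, stripped of rigid-body content, and normalized to
unit flattened norm; named forms cover the conventional shapes (twist
z∝xy, arch z∝x², saddle z∝x²−y², in-plane breathing).  Rigid-body removal
is essential to the linearity contract: translations and rotations are
themselves irrep-pure, and any rigid content in an injected pattern would
be silently absorbed by the alignment stage, breaking the proportionality
between injected amplitude and reported magnitude.  (A corollary: on a
planar frame the field (0, 0, x) *is* a rigid rotation about y, so
"bend-like" test patterns need curvature, e.g. z ∝ x².)  Collections add
Gaussian coordinate noise, a random rigid motion and an atom shuffle per
structure, and return the drawn coefficients and permutations as ground
truth.

These fixtures emulate idealized geometry with isotropic uncorrelated
noise.  They do not emulate real crystallographic effects — anisotropic
displacement, correlated thermal motion, disorder, libration, packing
strain, or chemically realistic bond-length changes — so passing tests
demonstrate the correctness of the decomposition machinery, not the
statistical behaviour of the method on real diffraction data.

## Numerical choices

* Symmetrization convergence 1e-10 Å; reconstruction residual contract
  1e-8 Å for groups with only 1-D irreps, 1e-6 Å with E irreps.
* Orientation screening: 15° in-plane grid; Nelder-Mead with initial
  simplex scale 0.12 rad, xatol 1e-9.
* Hungarian cross-element matches barred by a large finite cost (1e12)
  rather than block decomposition — same optimum, simpler bookkeeping.
* Graph-match tie-break: lowest summed squared distance after trial Kabsch
  superposition, then lexicographic atom order.
* Hydrogens are parsed but excluded from decomposition by default
  (`include_h` to keep them): heavy-atom frames are the reliable part of
  X-ray geometries.
* Two-decimal table printing rounds half-up on the decimal value
  (5.675 → 5.68).
* Degenerate variance ties in the axis convention keep the incoming axis
  order deterministically.

## Problem sizes used in verification

The shipped verification (test suite and `scripts/acceptance.py`) uses
50 seeded distorted fixtures per group for reconstruction and oracle
equivalence, amplitudes 0.1–1.0 Å for linearity, 20 rigid motions for
invariance, 100 random instances at N ≤ 7 for assignment optimality
against exhaustive enumeration, a 200-structure two-mode collection
(amplitude ratio 1 : 0.3, noise 0.01 Å) for principal-mode recovery, and
full subset enumeration (2 752 subsets across the seven groups) for the
Mondrian lookup.  These sizes were chosen as representative working sets
for a method whose contracts are scale-free identities.

## Known limitations

* Only the seven listed groups plus C1; no cubic, icosahedral, magnetic or
  double groups, and no site-symmetry analysis.
* Assignment assumes a complete fragment: no partial or substructure
  matching, no SMARTS patterns.
* The orientation search is heuristic global optimization; certified
  global optimality is out of scope (the basin-hopping flag mitigates).
* One altloc conformer is selected per file; disorder beyond that and
  crystal-packing generation are out of scope (no CIF handling; fragments
  are expected pre-extracted).
* Degenerate-irrep magnitudes depend on the orientation-variant dialect
  described above; raw outputs retain all variants so other conventions
  can be recomputed downstream.
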