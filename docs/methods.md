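# Methods

This note documents the models implemented in `insulatk`, their
assumptions, the numerical choices, and what the packaged surrogate data
can and cannot show.

## Ellipsoid geometry

The insula is represented by an axis-aligned ellipsoid in MNI millimetre
space. All lengths are millimetres, all angles radians; the axes follow
the MNI convention (x mediolateral, positive right; y anteroposterior,
positive anterior; z superoinferior, positive superior). Reference
parameters: centre (40, 5, 5) mm (right insula; the left is the
mediolateral mirror at (−40, 5, 5)) and semi-axes (12, 8, 6) mm.

Choices where the geometry admits more than one convention:

- **Boundary convention.** `contains()` is inclusive (implicit value
  ≤ 1). A closed set voxelizes and meshes consistently: surface points
  produced by the parametric form are members of the set they bound.
- **Meshing.** The parametric surface x = x₀ + a·cos u·sin v,
  y = y₀ + b·sin u·sin v, z = z₀ + c·cos v is sampled on an nu × nv
  grid, u on [0, 2π) (periodic, endpoint excluded) and v on [0, π]
  inclusive. Each grid quad is split into two triangles; the quads
  adjacent to the poles are degenerate and collapse to single triangles,
  so every emitted face has three geometrically distinct corners.
- **Voxelization.** A voxel is occupied iff its centre point is inside
  (no partial-volume weighting). This is the simplest deterministic rule
  and its occupied volume converges to the analytic volume as the voxel
  shrinks; at 1 mm the error for the reference ellipsoid is ≈ 0.13%, at
  0.5 mm ≈ 0.03%. The grid covers the bounding box padded by one voxel;
  the affine maps voxel indices to MNI mm voxel centres, RAS+ oriented,
  and NIfTI output carries sform/qform code 4 (MNI 152).
- **Surface area.** No elementary closed form exists for general
  ellipsoid area, so the morphometric comparison uses Thomsen's
  approximation (exponent p = 1.6075, accurate to ~1%) and labels it
  approximate.

Note on symbols: the geometric semi-axes (a, b, c) and the dynamics
gains (a, b, c, d) are unrelated quantities that happen to share
letters. They live in distinct types (`EllipsoidModel.semi_axes` vs
`LinearEIDynamics.a…d`) and never mix.

## Somatotopic coordinates and ANOVA

The packaged left posterior-insula coordinates — face (−40, −16, 11),
hand (−40, −19, 14), foot (−35, −21, 11) mm — are reference values from
the functional-imaging literature. Their component-wise mean is
(−38.33, −18.67, 12.00) mm at two-decimal reporting; full precision is
retained internally.

These are single points, and a one-way ANOVA is undefined on groups of
one observation. The toolkit therefore ships a seeded surrogate
generator: `jitter_samples` draws n replicates per region from an
isotropic Gaussian N(coord, σ²I) using numpy's PCG64 generator, regions
sampled in label order so a fixed seed reproduces the fixture bit for
bit. Defaults n = 30 and σ = 1.5 mm: 30 is a conventional
per-condition sample size in functional-localization group studies, and
1.5 mm is a realistic between-subject spatial scatter for
somatosensory peak coordinates after normalization (of the order of one
functional-MRI voxel).

The ANOVA itself is the classical fixed-effects decomposition computed
from explicit sums of squares, with p-values from the exact
F(k−1, N−k) distribution and no multiple-testing correction (a single
0.05 threshold per axis). Groups whose within-group variance is exactly
zero raise a degenerate-ANOVA error rather than returning an infinite F.

What the surrogate shows and does not show: F values computed on
jittered fixtures demonstrate that the operation is correct and
calibrated (the suite checks the empirical type-I error under the null,
0.05 ± 0.02 over 2000 seeded replicates), but they are functions of the
chosen n and σ, not empirical results about the insula. With the true
coordinates as group means, the y-axis means are all mutually distinct
(minimum pairwise gap 2 mm) whereas face and hand coincide
mediolaterally (minimum gap 0) — the sense in which anteroposterior
separation is the more robust effect. A related caveat: the packaged
functional coordinates lie far outside the reference left-insula
ellipsoid (implicit values ≈ 7.9–11.7); `containment_report` surfaces
this inconsistency between the two reference datasets instead of
harmonizing it.

## Linear excitatory–inhibitory dynamics

The excitatory population x(t) and inhibitory population y(t) follow
dx/dt = a·x − b·y, dy/dt = c·x + d·y, taken literally (no re-signing of
d), so the system matrix is A = [[a, −b], [c, d]]. With the reference
gains (1.0, 1.5, 1.0, −1.0): trace 0, determinant 0.5, eigenvalues
±i√0.5 — a neutral centre. The model is a deliberately minimal linear
caricature of excitatory–inhibitory balance; it has no sigmoidal
nonlinearity, noise, or parameter fitting, and is not a Wilson–Cowan
model.

- **Integrator.** Adaptive explicit Runge–Kutta (RK45) with rtol 1e−9,
  atol 1e−12, evaluated on the fixed uniform grid (1000 points on
  [0, 20] s, both endpoints included). The tolerances are tight enough
  that conservation of the quadratic invariant along the numerical
  trajectory is meaningful (relative drift < 1e−6).
- **Oracle.** The matrix exponential exp(At)·(x₀, y₀) is the exact
  solution and is computed independently (eigendecomposition, with a
  per-time `expm` fallback for defective matrices). Simulation and
  closed form agree to sup-norm < 1e−6 on the reference grid.
- **Conserved form.** For a centre, writing A = [[p, q], [r, −p]]
  (r ≠ 0 whenever the origin is a centre), the orbits conserve
  Q(x, y) = x² − (2p/r)·x·y − (q/r)·y², normalized to a leading
  coefficient of 1. Reference model: Q = x² − 2xy + 1.5y², with
  Q(1.0, 0.5) = 0.375.
- **Amplitude bounds.** On the invariant ellipse Q = Q₀, the coordinate
  extremes are max x² = Q₀·(Q⁻¹)₁₁ and max y² = Q₀·(Q⁻¹)₂₂ where Q is
  the symmetric form matrix. Reference: max|x| = √1.125 ≈ 1.0607,
  max|y| = √0.75 ≈ 0.8660. The conventional ±1.1 plotting range is
  treated as an upper bound to verify, not as an analytic quantity; the
  derived analytic maximum is ≈ 1.061.
- **Classification.** Trace–determinant taxonomy with an absolute
  tolerance of 1e−9 (scaled by the squared matrix norm) for the
  trace-zero and determinant-zero boundaries. Trace-zero systems with
  det ≤ 0 are saddles or degenerate and refuse the conserved form and
  period with explicit errors.

## Connectivity network

W is a 5 × 5 weighted directed matrix over the fixed region order
[insula, prefrontal cortex, amygdala, ACC, thalamus]; w_ij ∈ [0, 1] is
the directed gain from region i to region j and the diagonal is zero
(no self-connections). The region order is pinned by the identifications
w₁₂ = 0.8 (insula → PFC) and w₁₄ = 0.6 (insula → ACC). The weights are
treated as abstract directed gains, not as estimated functional or
effective connectivity.

The network dynamics are the simplest linear rate model consistent with
"output of i drives j scaled by w_ij":

    ds/dt = −γ·s + Wᵀ·s + u

with uniform leak γ ≥ 0 (default 1.0), constant drive u (default 0) and
default initial condition (1, 0, 0, 0, 0), a unit pulse in the insula.
Wᵀ appears because row i of W lists region i's *outgoing* weights. The
Jacobian Wᵀ − γI puts every Gershgorin disc at distance γ from the
largest out-strength, so γ > 2.3 (the insula's out-strength, the
maximum) guarantees asymptotic decay; at γ = 0 the Perron eigenvalue of
the nonnegative W (≈ 1.79) makes the network unstable. A spectrum whose
largest real part is zero within 1e−9 is flagged marginal and reported
not stable. The same RK45 contract as the E–I module applies.

## Reference morphometrics

The packaged reference table (diameter 35.5, length 40.2, width 20.8,
thickness 4.3, distance-to-midline 15.6, surface area 240.7 mm²,
volume 1200 mm³, plus four inter-structure distances) is
literature-averaged data stored verbatim. It is internally inconsistent
with the ellipsoid model — reference volume 1200 mm³ vs analytic
768π ≈ 2413 mm³, midline distance 15.6 mm vs |x₀| = 40 mm — and the
published insular grey-matter volume (≈ 9.9 cm³) differs from both.
`compare_morphometrics` therefore reports ratios and absolute
differences descriptively and never passes or fails anything.

## Pipeline and reproducibility

`run_all` executes geometry, somatotopy, dynamics and network stages,
writing OBJ/NIfTI/CSV/JSON artifacts and a summary recording the package
version, the seed, and the fully resolved configuration. All randomness
flows through the single configured seed, so two runs with the same seed
produce byte-identical CSV/JSON outputs (masks are written as
uncompressed `.nii` for the same reason). A stage failure removes the
partial outputs and raises with the stage name. CSV output uses 6
significant digits; JSON keeps full precision. Configuration files
(JSON or YAML) are validated strictly: unknown keys are rejected with
the offending field path, and an empty file yields the full reference
defaults.

## Problem sizes used by the test suite

The suite runs desk-scale problems throughout: Monte-Carlo volume
cross-check with 10⁶ rejection samples, voxel grids at 2.0/1.0/0.5 mm,
a 100 000-point dense trajectory over three periods for the amplitude
check, 500 random systems for classification consistency, and 2000
seeded null replicates for the ANOVA type-I calibration. Everything is
deterministic given the fixed seeds.

## Known limitations

- The ellipsoid ignores gyral/sulcal morphology, cortical thickness,
  inter-individual variability and cytoarchitectonic subdivisions; it is
  a spatial envelope, not a segmentation.
- The E–I system is linear: it cannot saturate, and its oscillation
  amplitude is set entirely by the initial condition.
- The connectivity weights are fixed constants; nothing is estimated
  from imaging data, and the brainstem pathway sometimes discussed
  alongside these five regions is not a row of W.
- The jittered ANOVA fixtures are surrogates; isotropic Gaussian scatter
  ignores spatial covariance and subject-level structure of real
  localization data.
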