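# insulatk

A computational-neuroanatomy toolkit for the human insula — the cortical
region hidden beneath the Sylvian sulcus — aimed at researchers who want a
simple, fully reproducible quantitative stand-in for the insula in
neuroimaging simulations, teaching, and method prototyping.

The toolkit has four scientific components:

1. **Geometry** — the insula as an axis-aligned ellipsoid in MNI millimetre
   space,

   (x − x₀)²/a² + (y − y₀)²/b² + (z − z₀)²/c² = 1,

   with reference centre (x₀, y₀, z₀) = (40, 5, 5) mm for the right insula
   (mirror x₀ = −40 for the left) and semi-axes (a, b, c) = (12, 8, 6) mm,
   giving full extents 24 × 16 × 12 mm and analytic volume
   (4/3)π·a·b·c = 768π ≈ 2412.7 mm³. Parametric surface meshing
   (spherical angles u ∈ [0, 2π], v ∈ [0, π]), voxelization into NIfTI
   binary masks, and mediolateral mirroring are provided.
2. **Somatotopy** — the packaged left posterior-insula functional
   coordinates face (−40, −16, 11), hand (−40, −19, 14), foot
   (−35, −21, 11) mm, their centroid, a containment report against any
   ellipsoid, and a classical one-way fixed-effects ANOVA per coordinate
   axis (F = MS_between / MS_within with exact F-distribution p-values)
   on seeded Gaussian-jittered replicates.
3. **Dynamics** — the linear excitatory–inhibitory system
   dx/dt = a·x − b·y, dy/dt = c·x + d·y with reference gains
   a = 1.0, b = 1.5, c = 1.0, d = −1.0. Its matrix [[a, −b], [c, d]] has
   trace 0 and determinant 0.5: a neutral centre whose orbits conserve
   Q(x, y) = x² − 2xy + 1.5y², oscillate with period 2π/√0.5 ≈ 8.886 s,
   and from the initial condition (1.0, 0.5) reach exact amplitude bounds
   max|x| = √1.125 ≈ 1.061 and max|y| = √0.75 ≈ 0.866.
4. **Connectivity** — a 5-region weighted directed matrix W (insula,
   prefrontal cortex, amygdala, ACC, thalamus; w_ij = strength of i → j,
   zero diagonal) with strong insula output to the PFC (w₁₂ = 0.8) and
   the ACC (w₁₄ = 0.6), graph summaries, spectral stability analysis, and
   a linear rate simulation ds/dt = −γ·s + Wᵀ·s + u.

## Worked example

```bash
$ insula simulate
fixed point: center (neutral); eigenvalues -1.3878e-17+0.70711j, -1.3878e-17-0.70711j
max |activity| on grid: 1.060660
period: 8.8858 s; amplitude bounds (|x|, |y|): 1.06066, 0.86603
```

The purely imaginary eigenvalues ±i√0.5 confirm a neutral centre: the
excitatory and inhibitory populations oscillate indefinitely without
growth or decay. The maximum absolute activity on the simulation grid,
1.0607, matches the analytic bound √1.125 and stays inside the
conventional ±1.1 plotting range.

```bash
$ insula somatotopy --anova --n 30 --sigma 1.5 --seed 42
face: (-40.0, -16.0, 11.0)
hand: (-40.0, -19.0, 14.0)
foot: (-35.0, -21.0, 11.0)
centroid (mm): (-38.33, -18.67, 12.00)
x-axis: F(2,87) = 127.587, p = 1.347e-26
y-axis: F(2,87) = 78.874, p = 2.883e-20
z-axis: F(2,87) = 43.303, p = 8.872e-14
```

The centroid is the component-wise mean of the three packaged
coordinates. The F statistics describe the separation of the jittered
surrogate samples (30 replicates per region, σ = 1.5 mm), not any
empirical dataset — see `docs/methods.md` for what they do and do not
show.

Other entry points: `insula ellipsoid` (mesh export to OBJ),
`insula mask` (NIfTI binary ROI mask), `insula network` (rate-model
simulation and stability), `insula compare` (model vs reference
morphometrics, descriptive only), and `insula run-all` (every stage plus
a JSON summary). The same operations are available as library functions
under `insulatk.geometry`, `insulatk.somatotopy`, `insulatk.dynamics`,
`insulatk.connectivity`, `insulatk.reference` and `insulatk.config`.

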