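# Methods

## Model and procedure

The bone rigidity error treats each connected bone as a rigid body and
measures how far the deformation field departs from that assumption. Given a
bone's voxel centres `x_i` (fixed-image world coordinates, mm) and their
deformed positions `y_i = x_i + d_i`, the proper-rigid least-squares problem

    min_{R ∈ SO(3), t}  Σ_i ‖(R x_i + t) − y_i‖²

is solved in closed form: centroids `c_X`, `c_Y`; cross-covariance
`H = Σ_i (x_i − c_X)(y_i − c_Y)ᵀ`; SVD `H = U Σ Vᵀ`; rotation
`R* = V diag(1, 1, det(V Uᵀ)) Uᵀ`; translation `t* = c_Y − R* c_X`. The
determinant factor flips the weakest singular direction instead of accepting
a reflection, so `det(R*) = +1` always — including adversarial near-planar
point sets, where the uncorrected solution would mirror. The BRE is the mean
residual distance `(1/N) Σ ‖(R* x_i + t*) − y_i‖`, an L1-of-norms summary
chosen for interpretability in mm (the fit itself minimises the squared
residuals; the two differ only in how the residuals are averaged). The tests
confirm global optimality of the rotation against dense and random rotation
searches rather than relying on the algebra alone.

Assumptions: bones transform rigidly (excludes growth, fractures, surgical
resection, intra-osseous tumours); the label map is defined on the fixed
image; displacements are fixed→moving vectors in world mm (`y = x + d`).
The declared convention is embedded in every report's metadata, since
ITK-style fields that follow a different sign or frame convention must be
converted by the caller.

## Coordinates and resampling

All fitting happens in world coordinates, `x = origin + D (i ∘ s)` with
0-based voxel-centre indices, spacing `s` (mm/voxel) and an orthonormal
direction matrix `D`. This keeps the BRE in mm and correct under anisotropic
or oblique grids. Correspondences are always generated on the label-map
(fixed) grid; the DVF is trilinearly interpolated at those points — an exact
lookup when the grids coincide, and exact for rigid fields even off-grid,
since a rigid displacement is affine in `x`. Every bone voxel is sampled by
default; a stride option subsamples for speed. Bones with more than 1 % of
their voxels outside the DVF extent are flagged `out-of-field` and excluded
(edge bones on cropped scans would otherwise poison averages); smaller
fractions are dropped silently.

## Connected components and small bones

A "bone" is a single connected piece: pooled labels are split into
26-connected components before fitting (6-connectivity fragments thin
oblique ribs). Bones under 10 voxels are flagged `too-small` and excluded —
near-collinear point sets leave the rotation ill-determined; 10 is
conservative and configurable. Collinear or coplanar sets above the cutoff
still return the SVD minimiser: the residual is unique even where the
rotation is not.

## Aggregation and inspection thresholds

BREs are averaged within anatomical groups and then across groups; the
overall score is the unweighted mean of group means, so rib-rich anatomies
do not drown out the pelvis. Summation is order-independent (values sorted
before averaging) to make reports exactly permutation-invariant. Inspection
thresholds per group follow the boxplot outlier rule Q3 + 1.5·IQR computed
from reference registrations the user trusts; quartiles use linear
interpolation between order statistics, and both the multiplier and the
convention are recorded in the output because boxplot conventions vary.
Flagging uses a strict `>`: a bone exactly at the outlier limit passes.
Thresholds are anatomy-, algorithm- and protocol-dependent; users should
calibrate them on their own accepted registrations rather than reuse
numbers across sites.

## Complementary metrics

* **MAE** — mean |fixed − moved| in HU, over the full common extent by
  default or an optional mask; requires pre-resampled volumes.
* **TRE** — per landmark, ‖(x_f + d(x_f)) − x_m‖ with trilinear `d`;
  pairing is by list order, out-of-field landmarks are reported as missing
  rather than extrapolated.
* **Jacobian determinant** — det(I + ∇d) with world-unit gradients: central
  differences in the interior, one-sided at borders, direction matrix
  applied by the chain rule. Rigid fields score exactly 1 (their
  displacement is linear, which finite differences reproduce); a
  volume-preserving shear also scores 1 while its BRE is positive — the
  pair of tests that encodes "rigidity implies incompressibility, not
  conversely".
* **BRE–TRE correlation** — Pearson r of paired per-registration values,
  for studying how far bone rigidity can proxy landmark accuracy.

## Synthetic data

The generator stands in for patient CTs: ellipsoid/cylinder/box primitives
rasterised at CT-like intensities (soft tissue 0 HU, bone 700 HU, Gaussian
noise σ = 20 HU, 2 mm voxels by default), deformed by per-bone rigid motions
(rotation about the bone centroid + translation) with optional violations:

* **scaling `s`** about the centroid — expected BRE `|s−1|·mean‖x_i−c‖`,
  exact;
* **shear `γ`** — expected BRE from the affine closed form (optimal rotation
  from the SVD of scatter·Aᵀ on the generated voxels), recorded as such;
* **constructed residual `α`** — white noise projected off the translational
  and linearised-rotational modes, so the identity remains optimal to first
  order and the expected BRE `α·mean‖e_i‖` holds to O(α²).

Outside the bones the field is Gaussian-filtered white noise (default 2 mm
amplitude, 20 mm correlation length — interfraction-like soft-tissue motion)
blended towards each bone's rigid field over a 6 mm margin, so the field is
continuous at bone surfaces while intra-bone values stay exact. The
background is deliberately simple: it exercises interpolation and boundary
behaviour but does not emulate sliding organ interfaces, contrast changes or
real CT texture, so passing tests certify the metric pipeline, not any DIR
algorithm's behaviour on real anatomy. All generation is seeded and
bit-reproducible; one named generator per operation, no global RNG state.

## Numerical choices and scale

Grid extent membership uses a 1e-9-voxel tolerance; boundary samples clamp
to the border voxel. Rigid-transform constructors verify orthogonality and
`det = +1` to 1e-9. Test problems use 24³–40³ volumes at 2 mm spacing
(≈ 300–1600 voxels per bone) — large enough that voxelisation effects are
representative, small enough to keep the whole suite near seconds. The
optimality checks probe 10⁴ random rotations per case and a 5°-step
axis–angle grid; the landmark-jitter check uses 10⁴ landmarks against the
analytic 3-dof chi mean √(8/π)·σ.

## Known limitations

BRE = 0 does not imply a correct registration (any global rigid map scores
zero); the metric is blind to errors outside bones; it must not be applied
where the rigidity assumption fails (paediatric growth, fractures,
resections); and inspection thresholds shipped as examples are placeholders
until calibrated on local reference data. Label maps and DVFs from different
sources must already share one world frame — the package reads headers at
face value and does not reconcile RAS/LPS conventions across formats.
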