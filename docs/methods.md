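# Methods

## The problem

Rigid-body realignment of an fMRI series yields six parameters per volume:
three translations (mm) and three rotations (radians).  Quality control
often inspects only the translations (or only the rotations), but the six
parameters are jointly optimized — only together do they describe the
recovered motion trajectory.  `motionqc` quantifies what is lost by the
reduced views across four linked analyses: scalar displacement metrics,
motion scrubbing, phantom-replay signal-change scoring, and motion-variance
GLMs.  Everything is exercised on synthetic data with known ground truth.

## Rigid-body kinematics

A parameter row `p = (tx, ty, tz, rx, ry, rz)` maps to the world-space
transform

```
M = T(tx, ty, tz) · Rx(rx) · Ry(ry) · Rz(rz)
```

the composition order used by SPM-style realignment, whose `rp_*.txt` files
this package consumes.  The order is a single centralized constant
(`motionqc.kinematics.ROTATION_ORDER`); changing the convention means
changing that one definition.  Rotations are stored in radians; degree input
is converted only on an explicit reader flag — there is no unit heuristic.

### Total displacement

Rotations become millimetres only at a reference distance from the rotation
origin: the **average cortical distance** `d_avg` (default 65 mm, the
field's representative adult value).  Three scalarizations of a row are
provided:

- `fig1_vector_sum` (default): `TD = ‖(tx,ty,tz) + d_avg·(rx,ry,rz)‖₂`.
  Each rotation angle is converted to an arc length at `d_avg` and paired
  component-wise with the translation along the same axis.  This is the
  literal reading of the orthogonal-arrow construction commonly used to
  illustrate the combined measure; it is cheap, monotone in every parameter
  magnitude, and exhibits the characteristic non-additivity (a rotation can
  *cancel* a same-axis translation).
- `sphere_mean`: the mean displacement `‖M p − p‖` over points sampled
  quasi-uniformly (Fibonacci lattice, default n = 500) on the sphere of
  radius `d_avg`.  This is the geometrically exact per-point reading; for a
  pure rotation by φ about one axis it converges to
  `(π/4)·2·d_avg·sin(φ/2)`, since the mean of sin(inclination) over the
  sphere is π/4.  It serves as the reference implementation in tests.
- `reference_point`: displacement of a single probe at `d_avg` along a
  configurable direction.

Neither of the first two is claimed to be bit-identical to any historical
implementation; both are shipped precisely because the combination rule is
under-determined by the usual figure-level description, and the test suite
pins each to its own closed form or Monte-Carlo oracle.

**Absolute vs relative motion.**  Absolute displacement evaluates row *t*
directly (the first volume is the realignment reference, so its row is
zero); relative (scan-to-scan) displacement feeds the row differences
`Δp_t = p_t − p_{t−1}` through the same formula, with the first value fixed
at 0.  Differencing parameters rather than composing transforms
(`M_t·M_{t−1}⁻¹`) keeps reduced-set zeroing well defined and matches how
scan-to-scan motion is read off parameter traces; the compositional variant
is available via `relative_via_transforms` and agrees to second order while
rotations are small.

**Reduced sets.**  `translation_only` and `rotation_only` zero the
complementary three columns *before* any displacement computation, exactly
mirroring post-hoc isolation of one parameter class.

**Sensitivity sweep.**  `davg_sensitivity_sweep` recomputes the series over
d_avg ∈ [50, 80] mm in 0.5 mm steps and reports the median over timepoints
as a percentage of the median at the 65 mm reference (medians because the
displacement distributions are heavy-tailed; the reference row is exactly
100%).

**Sign discordance.**  For each axis pair (tx,rx), (ty,ry), (tz,rz) a
volume is discordant when the product of the two values is strictly
negative.  Values of exactly zero have no sign and count as concordant.

## Average cortical distance

`d_avg` is estimated from a gray-matter mask as the mean Euclidean distance
from the image's world origin to the voxels on the *outer* cortical
surface:

1. Probability maps are binarized at 0.5 (the threshold is a package
   decision; the upstream convention is unstated).
2. The mask is resliced to 1 mm isotropic (7th-order B-spline, re-binarized
   at 0.5) so voxel size never biases the surface sample.
3. Surface voxels are the mask voxels 6-adjacent to background that is
   reachable from the volume border (flood fill).  This *exterior-boundary*
   definition excludes ventricle and closed-sulcus cavity walls, which a
   naive boundary detector would count and which would bias `d_avg`
   downward; the naive mode remains available (`exterior_only=False`) for
   comparison.
4. `d_avg` = mean of `‖world(v) − origin‖₂` over surface voxels.  The
   origin defaults to the affine's world origin (0, 0, 0); an origin
   outside the field of view warns but computes.

The discrete estimate carries a small inward bias (surface voxel *centers*
sit up to one voxel inside the continuous surface), on the order of half
the voxel size — the reslicing step is what keeps it uniform across inputs.
`cohort_trend` summarizes a set of (age, d_avg) pairs with a least-squares
slope (converted to mm/year) plus Spearman rank correlation, delegated to
`scipy.stats`.

## Motion scrubbing

`censor` flags volumes whose displacement **strictly exceeds** the
admissible-motion cutoff ("exceeding": ties at the cutoff are kept).  The
first volume is the reference (zero displacement by construction) and is
never flagged but is counted in the total.  `scrub_table` crosses
{complete, translation_only, rotation_only} × {absolute, relative} × the
standard cutoffs (0.5–3 mm) and reports reduced-set counts as a percentage
of the complete-set count; a zero reference makes the percentage undefined
(null/—, never 0).  Multiple subjects pool additively — thresholding pooled
datapoints and summing per-subject exceedance counts are the same number,
which is why the table accepts either one series or a list.

## Phantom replay

To isolate the purely geometric signal change a trajectory induces, the
first volume is replicated T times and copy *t* is resampled through the
inverse of that volume's motion transform (pull-back sampling: output
intensity at world point x is the input intensity at `M_t⁻¹x`).  Signal
change is scored in 9 automatically derived ROIs:

- 8 ROIs at the brain/non-brain interface near the volume corners: the
  corner-to-centroid ray is walked to the first in-mask voxel and a ball of
  radius 2 voxels is intersected with a two-sided shell around the mask
  boundary.  Edge voxels at large lever arms respond most strongly to
  rotation, which is the point of placing them there.
- 1 ball at the mask centroid (center of the brain).

Overlaps are trimmed by first-claim priority; an empty ROI is a geometry
error, so a returned set always has exactly 9 disjoint, non-empty regions.
The exact ROI geometry (radius, shell thickness, "near the corner"
distance) is a package decision — the construction is specified only
qualitatively in the literature.

Each ROI trace is converted to absolute deviation from its t = 0 value (the
replay's reference volume; mean-baseline available via a flag) and the
score is the mean over ROIs and timepoints t ≥ 1.  Reduced-set scores are
reported as percent of the complete-set score.  The replay is **geometric
only**: susceptibility-by-motion (motion × B₀) interactions are not
modelled, and every score carries that statement in its metadata.

**Motion fingerprint.**  The 9 ROI traces double as nuisance regressors:
`k=9` uses the mean-centered traces, `k=3` their first three
principal-component score series (an approximation chosen by this package;
the historical definition is not restated in the sources we follow), each
optionally with a one-timepoint-back shifted copy (first row zero-padded).

## Motion-variance GLMs

`build_design` produces mean-centered regressor sets: the 6 parameters
(complete or reduced), the 24-parameter Volterra expansion
`[p, p_lag1, p², p_lag1²]` ("shifted back in time" = row t holds the value
from t−1, first row 0 — the standard lagged-regressor construction), and
the fingerprint sets.  No drift regressors are included by default
(`add_drift` adds Legendre polynomials for realistic synthetic tests).

`fit_glm` runs voxel-wise OLS with an intercept.  Rank-deficient designs
(e.g. a reduced set with three zero columns) are pruned by pivoted QR and
all degrees of freedom use the effective column count `K_eff`:

```
R² = 1 − SSE/SST        F = (R²/K_eff) / ((1 − R²)/(T − K_eff − 1))
```

The F↔R² identity is asserted on every fit in the test suite.  "Variance
explained" is summarized as the mean R² over the analysis mask (median also
reported — the within-subject aggregate is not fixed by convention), and
`percent_of_reference` expresses a set against the volterra24 reference
(100%).  No adjusted-R² correction is applied: that larger sets explain
more variance by construction is deliberately left visible, matching how
such comparisons are usually reported.

## Synthetic data: what it does and does not emulate

`simulate_motion` — Gaussian random-walk drift (per-step SDs, defaults
0.03 mm / 5·10⁻⁴ rad) plus sparse discrete spikes.  `step` spikes (default)
are sustained repositionings, so each produces exactly one large
scan-to-scan displacement; `transient` spikes perturb a single row, giving
per-row-independent sign structure.  Spike rotation amplitudes are drawn as
(mm amplitude)/lever-arm so both parameter halves contribute commensurately
at `d_avg`; `sign_concordance ∈ [−1, 1]` couples same-axis translation and
rotation signs (0 = independent).  Defaults were set to produce
resting-state-like trajectories (sub-millimetre drift, a few sub-1.5 mm
repositionings per run).  The first row is always zero.  Not emulated:
respiratory/cardiac periodicity, spin-history effects, any scanner-specific
spectral structure.

`synthetic_brain` — an ellipsoid with a smooth radial intensity gradient
plus seeded smooth texture (so motion produces edge signal), its binary
mask, and a gray-matter shell of configurable thickness; the affine puts
the world origin at the ellipsoid center (plus an optional offset).  Zero
contrast gives a zero image, closing the loop that replay scores vanish
without edges.  No gyrification, no multi-tissue anatomy.

`simulate_cohort` — spherical shells whose radius is linear in age
(default slope 0.18 mm/year over ages 4–18, 0.5 mm scatter around 60 mm at
the midpoint), so `cohort_trend` can be tested as parameter recovery.

`simulate_fmri` — the brain volume pushed through each row's transform plus
white Gaussian noise; sharing the transform convention with `build_phantom`
makes forward simulation / inverse replay an exact round trip, which the
suite asserts.  Physiological noise and drift are out of scope.

Because the phantoms are smooth convex bodies and the noise is white,
passing tests demonstrate the *mechanics* (geometry, accounting,
estimation) are right; they do not certify effect sizes on real brains,
where tissue contrast, susceptibility artifacts and correlated noise all
modulate the numbers.

## Numerical choices

- **Interpolation.**  7th-order B-spline is the default wherever volumes
  are resampled, to keep interpolation artifacts at the edge-ROI scale
  negligible.  `scipy.ndimage` stops at order 5, so orders 6–7 are
  implemented natively: the recursive inverse filter (poles computed as the
  unit-circle-interior roots of the kernel's integer samples; for degree 7
  they are ≈ −0.5353, −0.1226, −0.00915) turns samples into coefficients —
  so interpolation is *exact* at lattice points — and evaluation uses the
  tensor-product kernel with per-tap weights expressed as exact polynomials
  in the coordinate's fractional part.  Orders ≤ 5 delegate to scipy; the
  native path is cross-checked against scipy at low orders and against
  lattice exactness at 6–7.
- **Boundary model.**  Volumes are assumed embedded in a constant (zero)
  background: out-of-field voxels are filled with 0, and the native-order
  prefilter pads with that constant.  This is exact for the phantoms used
  here and is the stated contract for user data.
- **Reslice lattice.**  The output grid is axis-aligned in world space,
  anchored at the minimum corner of the input field of view, leaving the
  world frame untouched.
- **Ties and zeros.**  Censoring uses strict `>`; sign discordance treats
  exact zeros as concordant; mask binarization uses `≥ 0.5`.
- **Degenerate inputs.**  Empty masks, non-finite parameters, singular
  affines, rank-0 designs and too-short series raise typed errors
  (`EmptyMaskError`, `InvalidParameterError`, `GeometryError`,
  `DegenerateDesignError`); an all-zero design after centering warns.
- **PCA sign.**  Fingerprint component signs are fixed (largest-magnitude
  loading positive) so outputs are reproducible across BLAS builds.

## Problem sizes

The shipped tests and the reproduction script run entirely on synthetic
inputs sized for a desktop: 24–32-voxel phantom grids with 40–120-volume
series for replay and GLM analyses, a 141³ voxel (1 mm) sphere for the
d_avg closure, a 60-subject cohort for slope recovery, and 10⁵-point
Monte-Carlo oracles for the displacement geometry.  These sizes were chosen
so every oracle comparison is tight at the tolerances asserted while the
whole suite stays in the minutes range.

## Known limitations

- Motion × B₀ interaction, spin-history, slice timing and EPI distortion
  are not modelled anywhere; replay scores are lower bounds on real
  motion-induced signal change.
- The package consumes realignment parameters; it never estimates motion
  from images, so errors of the upstream realignment pass through
  untouched.
- `d_avg` on real pediatric data depends on the upstream segmentation; the
  synthetic cohort only tests the estimator, not segmentation quality.
- The k=3 fingerprint is a PCA reduction chosen here; other reductions of
  the 9 traces are plausible and would give slightly different
  variance-explained figures.
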