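# Methods

## The phantom model

The synthetic proximal tibia is a solid of revolution around the shaft
axis (+z superior, +x anterior, +y medial–lateral, world units mm):

* a cylindrical diaphysis of radius `shaft_radius` (default 12 mm);
* a metaphyseal flare interpolating the radius from `shaft_radius` to
  `flare_radius_at_epiphysis` (default 14 mm) with a smoothstep
  `3t² − 2t³` between `flare_start_z` (55 mm) and `epiphyseal_z` (85 mm)
  — differentiable, so sub-voxel boundary tests are meaningful;
* an anterior tuberosity bump added to the radius on the anterior half
  (`x > 0`) only:
  `Δr(z, y) = h · exp(−(z − z_t)²/2σ_z²) · exp(−y²/2σ_y²)`,
  with height `h` (default 4 mm), apex height `z_t` (70 mm), and
  Gaussian footprint `σ_z` = 5 mm, `σ_y` = 10 mm.

The default flare is deliberately modest: only the **anterior** cortex
enters the index, and in the sagittal midline the anterior margin of the
proximal tibia widens far less than the plateau does laterally.  With
these defaults the analytic index is ≈ 0.174, matching the center of the
simulated cohort distribution.

### Analytic ground truth

The apex distance is `a_t = R(z_t) + h` (the full bump height over the
local base radius) and the cortex distance at the epiphyseal plane is
`c_e = R(z_e) + Δr(z_e, 0)`, *including* the bump's Gaussian tail
(≈ 0.04 mm at the defaults — the true surface, not an idealization).
The index is `(a_t − c_e)/a_t`.  Because the bump rides on the sloped
flare, the true surface maximum sits slightly superior to `z_t` (by
`R′σ_z²/h`, ≈ 0.6 mm at the defaults, worth ≈ 0.002 in the index); this
is inside the stated recovery tolerance and is the reason the recovery
sweep is specified at |error| ≤ 0.01 rather than at voxel precision.
Specs whose bump never rises above the cortex level produce a negative
index and are flagged (warning), not rejected.

### Voxelization

Volumes are rendered by **partial-volume sampling**: each voxel stores
the bone fraction obtained from a signed clearance to the surface,
ramped linearly over one voxel width, times the bone intensity
(bone = 1000, background = 0, arbitrary units).  This matters: with
binary occupancy sampling, rays aligned with the voxel lattice see the
discrete boundary up to half a voxel outside the true surface, a
lattice-phase-dependent bias of ~0.2 mm that partial-volume rendering
removes entirely (it also better emulates how an imaging system
integrates tissue over a voxel).  An optional Gaussian blur
(`blur_fwhm`, default 0.8 mm) and additive Gaussian noise (`noise_sd`,
default 20, i.e. 2% of bone signal — seeded, deterministic) follow.
The half-maximum iso-surface of the blurred partial-volume field
coincides with the analytic surface for locally planar geometry.

`cortical_thickness` is carried in the spec for provenance but the
phantom is rendered as solid bone — threshold segmentation and the
surface measurements never see the medullary canal.

## The 3D measurement protocol

1. **Segmentation** — Otsu (or fixed) threshold, largest 26-connected
   component, axial hole filling.
2. **Shaft axis (line C)** — Taubin algebraic circle fits to the outer
   boundary of every axial slice in the distal 25% of the bone's z
   extent, then a total-least-squares line through the fitted centers.
   Slices cut by the volume or bone end planes are partial disks whose
   fits are biased; a consensus filter (radius within 5% of the median,
   rms residual within 2.5× the median) removes them.  An optional
   ×2 weighting of posterior-arc points mirrors the reading-room habit
   of matching the posterior cortical line; it is off by default because
   it only matters for aspheric cross-sections.
3. **Epiphyseal plane** — always an *input* (world z or a landmark
   point), never detected from image content: on real images it is a
   reader-identified physeal scar, and automating it would add method
   that the protocol does not contain.
4. **Tuberosity apex (line A)** — two passes.  The surface voxel in a
   band 2–40 mm below the epiphyseal plane with maximal perpendicular
   distance to the axis gives a provisional anterior direction (ties
   broken toward lowest z, then lowest y).  Because the bump crest is
   flat in azimuth, the voxel argmax alone is a poor direction estimate
   (±10° observed); the refinement therefore maximizes the sub-voxel
   surface-crossing radius jointly over axial position *and* azimuth
   (coarse 2° grid ± 20°, then 0.25° locally), with parabolic refinement
   along the axis.
5. **Anterior cortex (line B)** — sub-voxel crossing of the anterior ray
   at the epiphyseal plane.
6. **Index** — AB and AC are projections on the anterior direction
   (all three tangent lines are parallel to the shaft axis);
   `ATTI = AB/AC`.

Surface crossings are located on the blurred intensity field at the
half-maximum level (midpoint of robust interior/exterior medians),
sampled along rays at 0.1-voxel steps with linear interpolation and
taking the outermost above-to-below crossing.  A signed-distance field
of the binary mask is the fallback when the volume lacks usable contrast.
Intensity-based localization is what makes the measurement stable under
resampling: linear interpolation of a smooth field commutes with rigid
motion to second order, whereas interpolating a binary mask does not.

Measured performance at the defaults (0.5 mm voxels, 2% noise): absolute
index error ≤ 0.006 across a 2–8 mm bump-height sweep; change under
rigid rotations up to 15° ≤ 0.006; doubling the noise moves the index
by < 0.001.

## The lateral-projection (2D) measurement

The radiograph simulator is an orthographic line integral of fractional
bone occupancy along the medial–lateral axis; positioning error
(rotation about the shaft, flexion) is applied to the volume first, with
an expanding field of view so nothing clips.  Beam divergence at typical
focus–film distances changes a distance *ratio* negligibly, so only an
optional image-plane shear (tube tilt) is modeled.

The 2D protocol fits the mid-diaphysis line through per-row silhouette
midpoints of the distal band, then measures perpendicular distances of
the anterior contour: the maximum below the epiphyseal row (line A) and
the contour at the epiphyseal row (line B).  Two numerical choices:

* **Silhouette threshold at 5% of the peak line integral**, not 50%.
  A half-maximum threshold would erase the tuberosity entirely: a chord
  through the bump apex is millimetres long while the peak chord through
  the shaft is ~28 mm.  At 5% the silhouette edge sits within ~0.02 mm
  of the true tangent for the default geometry.
* **Edge interpolation on the squared profile.**  Near a smooth convex
  silhouette edge the chord length scales as √depth, so the squared
  chord is locally linear; interpolating the squared profile removes a
  lattice-phase jitter of ~0.1 mm that linear interpolation of the raw
  profile exhibits.

The positioning-error study tabulates 2D and 3D readings of the same
misaligned volume over a rotation/flexion grid.  At the defaults the 3D
column is constant to 0.002 across 0–15° of shaft rotation while the 2D
column drifts by ~0.009 — the quantitative version of the argument for
measuring on reformatted 3D images.  For a laterally near-uniform ridge
(σ_y ≥ 5 × shaft radius) the projection is faithful and 2D and 3D agree
within 0.01.

## The simulated cohort

Paired index readings are drawn from a bivariate normal whose default
moments are the published cohort summary this package validates against:
n = 47, means 0.1700 (MRI) / 0.1751 (radiograph), SDs 0.04408 / 0.05283,
correlation 0.8746.  Normality of the real data was reported, and no
higher-order information is published, so the bivariate normal is the
minimal faithful model.  Values are clipped to (0.001, 0.999) with a
warning; at the default moments the bounds are ~3–4 SD away.  Observer
and session replicates add independent zero-mean Gaussian reader noise
(`observer_noise_sd`, default 0.01 — there is no published
within-observer noise magnitude, so this default is a plausibility
choice, not an anchored one).

What the simulator does **not** emulate: any dependence of reader noise
on prominence, demographic structure, laterality, or the discreteness of
caliper readings.  Tests passing on this cohort show the statistics are
computed correctly at the published operating point; they do not certify
reader behavior on real images.

## The statistics

All method-comparison statistics are computed from first principles
(Shapiro–Wilk delegates to scipy's implementation of the published
algorithm); pingouin, scikit-learn and scipy serve as independent
cross-checks in the test suite only.

* **t-test** — the headline comparison is the *unpaired pooled* form on
  the two columns, which is the computation that reproduces the
  published p-value from the summary statistics; a paired t-test is
  reported alongside and is statistically preferable for paired designs.
* **Pearson** — Fisher-z interval `tanh(atanh r ± z/√(n−3))`; p from the
  t transform.  Collinear inputs give a flagged degenerate interval.
* **ICC** — two-way consistency from the subjects × methods ANOVA:
  single `= (MSR − MSE)/(MSR + (k−1) MSE)`, average `= (MSR − MSE)/MSR`;
  the Spearman–Brown identity between them holds algebraically and is
  asserted to 1e−12.  Confidence intervals use the F bounds on MSR/MSE
  (McGraw–Wong); other software may use variants, so printed CIs from
  other tools are not comparison targets.
* **Bland–Altman** — differences MRI − radiograph; bias ± 1.96 SD limits
  of agreement; least-squares trend of differences on means with its CI.
* **Passing–Bablok** — all pairwise slopes with identical points
  skipped, slopes of exactly −1 excluded, and vertical pairs entering as
  signed infinities; the estimate is the order statistic at the median
  position offset by K = #{slopes < −1} (averaging two central values on
  even counts), which makes slope(x,y) = 1/slope(y,x) exact on tie-free
  data.  Rank-based CI via `w = z·√(n(n−1)(2n+5)/18)`; intercept
  `median(y − b·x)` with bounds from the slope bounds.  The **cusum
  linearity test** scores residual signs (+√(L/l) above, −√(l/L) below),
  accumulates in order of x (ties broken by y), and refers
  max|cusum|/√(l+L) to the asymptotic Kolmogorov–Smirnov tail; measured
  type-I error at α = 0.05 over 2,000 null cohorts of n = 47 is ~0.04.
  Residual SD is reported both vertically and perpendicular to the fitted
  line, as the published definition is ambiguous.
* **Cohen's kappa** — from the confusion matrix, with linear/quadratic
  weights available.  Continuous indices are binned by default at
  terciles of the pooled sample (the published categorization is
  unknown, so published kappa values are not comparison targets); the
  scheme used is always recorded in the report.

No multiple-testing correction is applied (none was used in the study
design this mirrors); significance is fixed at 0.05.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is deterministic
given it.  The validation computations use: 200,000 pairs for the ICC
moment-recovery check, 500 cohorts of n = 47 for the median
Passing–Bablok slope, 2,000 cohorts for cusum calibration, a 20-spec
bump-height sweep at 0.5 mm voxels for parameter recovery, and a
0–15° grid for the rotation study.  These sizes hold the Monte-Carlo
error of each quantity well below its comparison tolerance.

## Known limitations

* The phantom has circular cross-sections; robustness of the circle fit
  to aspheric shafts is exercised only as a property (posterior
  weighting, noisy-fit oracle), not against real anatomy.
* No imaging physics: no relaxation contrast, bias fields, chemical
  shift, scatter or detector blur; the radiograph is parallel-beam.
* The epiphyseal plane is an input everywhere; the pipeline cannot be
  run fully unattended on real data without a reader landmark.
* Published confidence intervals for the ICC and regression of the real
  cohort depend on the raw 47-pair data, which is not public; only the
  point summaries are recoverable and only those are validated.
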