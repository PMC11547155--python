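# attikit

Tools for measuring the **anterior tibial tuberosity index (ATTI)** — a
scale-free descriptor of how far the tibial tubercle protrudes beyond the
anterior tibial cortex — on 3D image volumes and on lateral-projection
radiographs, together with the complete method-comparison statistics used
to validate one measurement protocol against another.

A prominent tibial tuberosity (typically a sequela of Osgood–Schlatter
disease) is traditionally measured on lateral knee radiographs.  A
reformatted 3D acquisition permits the same construction free of
projection and positioning error: the reader aligns a tibial reference
frame, marks three parallel tangent lines, and reports a ratio of
distances.  `attikit` implements that protocol as code, and — because no
public dataset with ground truth exists — validates it on **synthetic
tibia phantoms whose ATTI is known in closed form**.

## The measurement

With the shaft axis (line **C**) established, let **A** be the tangent
line (parallel to C) through the most prominent point of the tuberosity,
and **B** the tangent through the anterior cortex at the level of the
epiphyseal line.  Then

```
ATTI = AB / AC
```

where AB and AC are the perpendicular distances between the lines.  On
the phantom, with apex distance `a_t` and anterior cortex distance `c_e`
from the axis, the analytic counterpart is `(a_t − c_e) / a_t`.

The package has five layers:

| module | contents |
|---|---|
| `attikit.phantom` | parametric proximal-tibia phantom (cylindrical shaft, smoothstep metaphyseal flare, Gaussian tuberosity bump), partial-volume voxelization, rigid transforms, analytic ground truth |
| `attikit.mpr` | the 3D protocol: threshold segmentation, Taubin circle fits on distal axial slices → shaft axis, sub-voxel apex and cortex localization, `ATTI = AB/AC` |
| `attikit.projection` | orthographic lateral radiograph simulation and the classic 2D tangent-line measurement; positioning-error grid studies |
| `attikit.cohort` | bivariate-normal simulator of paired MRI/radiograph cohorts and observer replicates |
| `attikit.stats` | Shapiro–Wilk gatekeeping, Student's t, Pearson with Fisher-z CI, two-way consistency ICC (single/average, F-based CIs), Bland–Altman, Passing–Bablok with cusum linearity test, Cohen's kappa |

## Worked example

```python
from attikit import PhantomSpec, build_phantom, measure_volume, MeasureConfig
from attikit.projection import project, measure_radiograph

spec = PhantomSpec()                      # 0.5 mm voxels, 4 mm tuberosity bump
vol, truth = build_phantom(spec)
res3d = measure_volume(vol, MeasureConfig(epiphyseal_z=spec.epiphyseal_z))
res2d = measure_radiograph(project(vol), epiphyseal_z=spec.epiphyseal_z)
print(f"analytic ATTI: {truth.atti_true:.4f}")
print(f"3D measured:   {res3d.atti:.4f}  (AB = {res3d.ab:.2f} mm, AC = {res3d.ac:.2f} mm)")
print(f"2D measured:   {res2d.atti:.4f}  (AB = {res2d.ab:.2f} mm, AC = {res2d.ac:.2f} mm)")
```

prints

```
analytic ATTI: 0.1739
3D measured:   0.1768  (AB = 3.02 mm, AC = 17.06 mm)
2D measured:   0.1696  (AB = 2.95 mm, AC = 17.37 mm)
```

Both protocols recover the analytic index of the noisy phantom to within
0.01 (here the tubercle protrudes ~17% of its distance to the shaft
axis).  Comparing the two methods on a simulated 47-knee cohort:

```python
from attikit import simulate_pairs, compare_methods
from attikit.cohort import CohortParams

report = compare_methods(simulate_pairs(CohortParams(seed=1)))
print(f"Pearson r = {report.pearson.r:.4f}, "
      f"95% CI ({report.pearson.ci[0]:.4f}, {report.pearson.ci[1]:.4f})")
print(f"ICC single = {report.icc.icc_single:.4f}, average = {report.icc.icc_average:.4f}")
print(f"Bland-Altman bias = {report.bland_altman.bias:.4f}, "
      f"LoA ({report.bland_altman.loa_low:.4f}, {report.bland_altman.loa_high:.4f})")
print(f"Passing-Bablok slope = {report.passing_bablok.slope:.4f}, "
      f"intercept = {report.passing_bablok.intercept:.4f}, "
      f"cusum p = {report.passing_bablok.cusum_p:.2f}")
```

```
Pearson r = 0.9173, 95% CI (0.8555, 0.9533)
ICC single = 0.8862, average = 0.9396
Bland-Altman bias = -0.0026, LoA (-0.0440, 0.0389)
Passing-Bablok slope = 0.7375, intercept = 0.0415, cusum p = 0.12
```

A bias near zero, tight limits of agreement, a Passing–Bablok slope whose
confidence interval covers 1 and a non-significant cusum test are the
signature of two interchangeable methods.

## Command line

```sh
attikit simulate-phantom --out vol.nii.gz --config spec.json
attikit measure vol.nii.gz --epiphyseal-z 85 --out result.json
attikit project vol.nii.gz --rotation 10 --out xray.npy
attikit error-study --out study.csv --rotations 0,5,10,15
attikit simulate-pairs --n 47 --seed 1 --out pairs.csv
attikit compare pairs.csv --out report.json --plots out/
attikit end-to-end --out-dir run/ --n-phantoms 10
```

Exit codes: 0 success, 1 stage failure, 2 configuration error.  Every
run writes a `manifest.json` (configuration, input hashes, package
version) sufficient to reproduce deterministic outputs.

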