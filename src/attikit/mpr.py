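"""Multiplanar-reformatting measurement of the anterior tibial tuberosity index.

The protocol mirrors what a reader does at the console: establish the
shaft axis by fitting circles to distal axial cross-sections of the
segmented bone, find the most prominent anterior surface point of the
tuberosity (line A), drop a parallel tangent at the anterior cortex on
the epiphyseal plane (line B), and divide the A-B distance by the A-axis
distance (line C): ATTI = AB / AC.  All three lines are parallel to the
shaft axis, so both distances are measured along the anterior direction,
perpendicular to the axis.

The epiphyseal plane is always an input (a world coordinate or landmark
point), never detected from image content: on real images it is a
reader-identified physeal scar.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import linalg, ndimage
from skimage.filters import threshold_otsu

from .phantom import Volume3D

__all__ = [
    "CircleFit",
    "TibialFrame",
    "LandmarkSet",
    "ATTIResult",
    "MeasureConfig",
    "MeasurementError",
    "segment_bone",
    "fit_circle",
    "estimate_shaft_axis",
    "locate_tuberosity_apex",
    "anterior_cortex_at_plane",
    "compute_atti",
    "measure_volume",
]


class MeasurementError(RuntimeError):
    """Raised when a measurement stage cannot produce a valid result."""


@dataclass(frozen=True)
class CircleFit:
    center: tuple[float, float]
    radius: float
    rms_residual: float
    n_points: int


@dataclass
class TibialFrame:
    """Tibial reference frame: shaft axis (line C) plus anterior direction.

    ``epiphyseal_s`` is the position of the epiphyseal plane measured in mm
    along the axis from ``axis_point``.
    """

    axis_point: np.ndarray
    axis_direction: np.ndarray
    anterior_direction: np.ndarray | None = None
    epiphyseal_s: float | None = None

    def foot(self, s: float) -> np.ndarray:
        return self.axis_point + s * self.axis_direction

    def along(self, p) -> float:
        return float(np.dot(np.asarray(p) - self.axis_point, self.axis_direction))


@dataclass(frozen=True)
class LandmarkSet:
    apex: tuple[float, float, float]
    cortex_at_epiphysis: tuple[float, float, float]
    axis_point: tuple[float, float, float]
    axis_direction: tuple[float, float, float]


@dataclass(frozen=True)
class ATTIResult:
    ab: float
    ac: float
    atti: float
    landmarks: LandmarkSet
    frame_axis_point: tuple[float, float, float]
    frame_axis_direction: tuple[float, float, float]
    anterior_direction: tuple[float, float, float]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["landmarks"] = dataclasses.asdict(self.landmarks)
        return d


@dataclass
class MeasureConfig:
    """Configuration of the end-to-end volume measurement.

    Exactly one of ``epiphyseal_z`` (world z of the epiphyseal plane,
    valid for near-axial volumes) or ``epiphyseal_landmark`` (a world
    point on the plane, usable after arbitrary rigid motion) must be set.
    """

    threshold_mode: str = "otsu"  # "otsu" | "fixed"
    threshold_value: float | None = None
    distal_fraction: float = 0.25
    epiphyseal_z: float | None = None
    epiphyseal_landmark: tuple[float, float, float] | None = None
    search_band: tuple[float, float] = (2.0, 40.0)
    posterior_weighting: bool = False


# -- segmentation -----------------------------------------------------------

def segment_bone(volume: Volume3D, threshold_mode: str = "otsu", threshold_value: float | None = None) -> np.ndarray:
    """Threshold segmentation of bone: largest component, slice-filled.

    ``threshold_mode='otsu'`` picks the threshold automatically;
    ``'fixed'`` uses ``threshold_value``.  The largest 26-connected
    component is kept and holes are filled in every axial slice.
    """

    data = np.asarray(volume.data)
    if threshold_mode == "otsu":
        lo, hi = float(data.min()), float(data.max())
        if not hi > lo:
            raise MeasurementError("no bone found at threshold: volume has a single intensity level")
        thr = float(threshold_otsu(data))
    elif threshold_mode == "fixed":
        if threshold_value is None:
            raise MeasurementError("fixed threshold mode requires threshold_value")
        thr = float(threshold_value)
    else:
        raise MeasurementError(f"unknown threshold mode {threshold_mode!r}")
    mask = data > thr
    if not mask.any():
        raise MeasurementError("no bone found at threshold")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))
    filled = np.empty_like(mask)
    for k in range(mask.shape[2]):
        filled[:, :, k] = ndimage.binary_fill_holes(mask[:, :, k])
    return filled


# -- circle fitting ---------------------------------------------------------

def fit_circle(points: np.ndarray, weights: np.ndarray | None = None) -> CircleFit:
    """Taubin algebraic least-squares circle fit to 2D points (mm).

    Minimizes the algebraic circle residual under Taubin's gradient
    normalization, which is exact on noiseless circular data and nearly
    unbiased for small noise.  Optional per-point weights (used to
    emphasize the posterior cortical arc on real, aspheric bones).
    """

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise MeasurementError("fit_circle expects an (n, 2) array")
    n = pts.shape[0]
    if n < 3:
        raise MeasurementError("circle fit requires at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() <= 0:
            raise MeasurementError("weights must be nonnegative with positive sum")
    wsum = w.sum()
    xm, ym = (w @ pts) / wsum
    u = pts[:, 0] - xm
    v = pts[:, 1] - ym
    z = u * u + v * v
    # collinearity check on the centered scatter
    cuu = w @ (u * u) / wsum
    cvv = w @ (v * v) / wsum
    cuv = w @ (u * v) / wsum
    scatter = np.array([[cuu, cuv], [cuv, cvv]])
    eigvals = np.linalg.eigvalsh(scatter)
    if eigvals[0] <= 1e-12 * max(eigvals[1], 1e-30):
        raise MeasurementError("circle fit requires non-collinear points")
    zbar = w @ z / wsum
    # minimize <(A z + B u + C v + D)^2> s.t. Taubin constraint
    # 4 zbar A^2 + B^2 + C^2 = 1; D eliminated via D = -A zbar.
    zc = z - zbar
    m = np.empty((3, 3))
    m[0, 0] = w @ (zc * zc) / wsum
    m[0, 1] = m[1, 0] = w @ (zc * u) / wsum
    m[0, 2] = m[2, 0] = w @ (zc * v) / wsum
    m[1, 1] = cuu
    m[1, 2] = m[2, 1] = cuv
    m[2, 2] = cvv
    nmat = np.diag([4.0 * zbar, 1.0, 1.0])
    vals, vecs = linalg.eigh(m, nmat)
    a, b, c = vecs[:, int(np.argmin(vals))]
    if abs(a) < 1e-12:
        raise MeasurementError("circle fit degenerate (points nearly collinear)")
    uc = -b / (2.0 * a)
    vc = -c / (2.0 * a)
    radius = float(np.sqrt(uc * uc + vc * vc + zbar))
    center = (float(uc + xm), float(vc + ym))
    dist = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    rms = float(np.sqrt(w @ ((dist - radius) ** 2) / wsum))
    return CircleFit(center=center, radius=radius, rms_residual=rms, n_points=n)


def _slice_boundary_points(slice_mask: np.ndarray) -> np.ndarray:
    """Outer-boundary pixel indices (i, j) of a filled 2D mask."""
    er = ndimage.binary_erosion(slice_mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool))
    return np.argwhere(slice_mask & ~er)


def estimate_shaft_axis(
    mask: np.ndarray,
    volume: Volume3D,
    distal_fraction: float = 0.25,
    posterior_weighting: bool = False,
) -> TibialFrame:
    """Shaft axis from per-slice circle fits on the distal diaphysis.

    Fits a circle to the outer boundary of each axial slice in the distal
    ``distal_fraction`` of the bone's z extent (the straight shaft, below
    the metaphyseal flare), then passes a total-least-squares line through
    the fitted centers.  The axis is oriented toward increasing z.

    ``posterior_weighting`` doubles the weight of boundary points posterior
    to the slice centroid, honoring the reading-room habit of matching the
    posterior cortical line; it matters only for aspheric cross-sections.
    """

    zs_any = np.flatnonzero(mask.any(axis=(0, 1)))
    if zs_any.size == 0:
        raise MeasurementError("empty mask")
    z0, z1 = zs_any[0], zs_any[-1]
    extent = z1 - z0 + 1
    band_n = max(int(np.ceil(extent * distal_fraction)), 1)
    band = range(z0, z0 + band_n)
    sx, sy, _ = volume.spacing
    ox, oy, _ = volume.origin
    centers = []
    for k in band:
        sl = mask[:, :, k]
        if sl.sum() < 8:
            continue
        bpts = _slice_boundary_points(sl)
        if bpts.shape[0] < 8:
            continue
        xy = np.column_stack([ox + bpts[:, 0] * sx, oy + bpts[:, 1] * sy])
        wts = None
        if posterior_weighting:
            wts = np.where(xy[:, 0] < xy[:, 0].mean(), 2.0, 1.0)
        fit = fit_circle(xy, weights=wts)
        zw = volume.origin[2] + k * volume.spacing[2]
        centers.append([fit.center[0], fit.center[1], zw, fit.radius, fit.rms_residual])
    if len(centers) < 10:
        raise MeasurementError(
            f"shaft axis needs >= 10 usable distal slices, got {len(centers)}"
        )
    all_fits = np.asarray(centers)
    # consensus filter: slices cut by the volume/bone end planes are partial
    # disks whose circle fits are biased; they stand out by residual and radius
    med_r = np.median(all_fits[:, 3])
    med_rms = np.median(all_fits[:, 4])
    keep = (np.abs(all_fits[:, 3] - med_r) <= max(0.05 * med_r, 2.0 * min(volume.spacing))) & (
        all_fits[:, 4] <= max(2.5 * med_rms, 0.5 * min(volume.spacing))
    )
    if keep.sum() < 10:
        raise MeasurementError(
            f"shaft axis needs >= 10 consistent distal slices, got {int(keep.sum())}"
        )
    pts = all_fits[keep, :3]
    mean = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - mean, full_matrices=False)
    direction = vt[0]
    if direction[2] < 0:
        direction = -direction
    return TibialFrame(axis_point=mean, axis_direction=direction / np.linalg.norm(direction))


# -- landmark localization --------------------------------------------------

def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance to the mask surface (positive inside), mm."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return (inside - outside).astype(np.float32)


def _surface_field(
    volume: Volume3D, mask: np.ndarray, use_intensity: bool = True
) -> tuple[np.ndarray, float]:
    """Scalar field and iso-level whose crossing defines the bone surface.

    When the volume has usable contrast the blurred intensity itself is
    the best sub-voxel surface localizer (the half-maximum crossing of a
    blurred step sits exactly on the surface, and linear interpolation of
    a smooth field is stable under resampling).  Otherwise fall back to
    the signed distance field of the mask at level zero.
    """

    if use_intensity:
        data = np.asarray(volume.data, dtype=np.float32)
        interior = ndimage.binary_erosion(mask, np.ones((3, 3, 3), bool), iterations=2)
        exterior = ~ndimage.binary_dilation(mask, np.ones((3, 3, 3), bool), iterations=2)
        if interior.any() and exterior.any():
            mu_in = float(np.median(data[interior]))
            mu_out = float(np.median(data[exterior]))
            if mu_in > mu_out:
                return data, 0.5 * (mu_in + mu_out)
    return _signed_distance(mask, volume.spacing), 0.0


def _ray_surface_crossing(
    field: np.ndarray,
    level: float,
    volume: Volume3D,
    feet: np.ndarray,
    direction: np.ndarray,
    r_max: float,
    step: float,
) -> np.ndarray:
    """Outermost surface crossing radius along rays from axis feet, mm.

    Samples the surface field along each ray and locates, per ray, the
    last above-to-below-level crossing by linear interpolation.  Returns
    NaN for rays that never enter the bone.
    """

    radii = np.arange(0.0, r_max + step, step)
    pts = feet[:, None, :] + radii[None, :, None] * direction[None, None, :]
    idx = volume.world_to_index(pts.reshape(-1, 3)).T
    vals = ndimage.map_coordinates(field, idx, order=1, mode="constant", cval=level - 1.0)
    vals = vals.reshape(feet.shape[0], radii.size) - level
    pos = vals > 0
    out = np.full(feet.shape[0], np.nan)
    any_pos = pos.any(axis=1)
    if not any_pos.any():
        return out
    last_pos = pos.shape[1] - 1 - np.argmax(pos[:, ::-1], axis=1)
    rows = np.flatnonzero(any_pos & (last_pos < radii.size - 1))
    k = last_pos[rows]
    v0 = vals[rows, k]
    v1 = vals[rows, k + 1]
    frac = v0 / (v0 - v1)
    out[rows] = radii[k] + frac * step
    return out


def locate_tuberosity_apex(
    mask: np.ndarray,
    volume: Volume3D,
    frame: TibialFrame,
    search_band: tuple[float, float] = (2.0, 40.0),
    surface_field: tuple[np.ndarray, float] | None = None,
) -> TibialFrame:
    """Find the most prominent anterior surface point of the tuberosity.

    Two passes: the surface voxel in the search band (mm below the
    epiphyseal plane, along the axis) with maximum perpendicular distance
    to the shaft axis fixes the anterior direction; sub-voxel refinement
    then marches the anterior ray over a fine grid of axial positions in
    the band and takes the maximum surface-crossing radius, with parabolic
    refinement across axial positions.  Ties in the voxel pass are broken
    toward the lowest z, then the lowest y.

    Returns a copy of the frame with ``anterior_direction`` set and the
    apex stored on the returned object as ``apex_point`` / ``apex_distance``.
    """

    if frame.epiphyseal_s is None:
        raise MeasurementError("frame.epiphyseal_s must be set before apex search")
    lo_off, hi_off = search_band
    if not (hi_off > lo_off >= 0):
        raise MeasurementError("empty or inverted search band")
    s_lo = frame.epiphyseal_s - hi_off
    s_hi = frame.epiphyseal_s - lo_off
    er = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3), bool))
    bidx = np.argwhere(mask & ~er)
    if bidx.shape[0] == 0:
        raise MeasurementError("mask has no surface voxels")
    pts = volume.index_to_world(bidx)
    s = (pts - frame.axis_point) @ frame.axis_direction
    in_band = (s >= s_lo) & (s <= s_hi)
    if not in_band.any():
        raise MeasurementError("search band contains no surface voxels")
    pts = pts[in_band]
    s = s[in_band]
    radial = pts - frame.axis_point - np.outer(s, frame.axis_direction)
    dist = np.linalg.norm(radial, axis=1)
    # deterministic tie-break: max distance, then lowest z, then lowest y
    key = np.round(dist / 1e-6).astype(np.int64)
    order = np.lexsort((pts[:, 1], pts[:, 2], -key))
    best = order[0]
    anterior = radial[best] / dist[best]

    if surface_field is None:
        surface_field = _surface_field(volume, mask)
    field, level = surface_field
    # in-plane orthonormal basis around the provisional anterior direction
    e1 = anterior
    e2 = np.cross(frame.axis_direction, e1)
    e2 /= np.linalg.norm(e2)
    r_max = float(dist.max() + 5.0)
    step_r = 0.1 * min(volume.spacing)

    def _scan(s_vals: np.ndarray, th_vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Crossing radius r[s, theta] for rays at azimuth theta from e1."""
        dirs = np.cos(th_vals)[:, None] * e1[None, :] + np.sin(th_vals)[:, None] * e2[None, :]
        feet = frame.axis_point[None, :] + s_vals[:, None] * frame.axis_direction[None, :]
        out = np.empty((s_vals.size, th_vals.size))
        for t, dvec in enumerate(dirs):
            out[:, t] = _ray_surface_crossing(field, level, volume, feet, dvec, r_max, step_r)
        return out

    # coarse joint search over axial position and azimuth, then local refine:
    # the ridge crest is flat in azimuth, so the voxel argmax alone is a poor
    # estimate of the anterior direction
    step_s = 0.5 * min(volume.spacing)
    s_grid = np.arange(s_lo, s_hi + step_s, step_s)
    th_grid = np.deg2rad(np.arange(-20.0, 20.0 + 2.0, 2.0))
    r_coarse = _scan(s_grid, th_grid)
    if np.all(np.isnan(r_coarse)):
        raise MeasurementError("anterior ray never crosses the bone surface")
    i, j = np.unravel_index(int(np.nanargmax(r_coarse)), r_coarse.shape)
    th_fine = th_grid[j] + np.deg2rad(np.arange(-2.0, 2.0 + 0.25, 0.25))
    s_fine = np.clip(s_grid[i] + np.arange(-1.0, 1.0 + 0.1, 0.1) * step_s * 2, s_lo, s_hi)
    r_fine = _scan(s_fine, th_fine)
    i, j = np.unravel_index(int(np.nanargmax(r_fine)), r_fine.shape)
    s_apex = float(s_fine[i])
    theta = float(th_fine[j])
    r_apex = float(r_fine[i, j])
    anterior = np.cos(theta) * e1 + np.sin(theta) * e2

    def _parab(vals, grid, idx):
        if 0 < idx < len(grid) - 1 and np.isfinite(vals[idx - 1]) and np.isfinite(vals[idx + 1]):
            denom = vals[idx - 1] - 2 * vals[idx] + vals[idx + 1]
            if denom < -1e-12:
                delta = 0.5 * (vals[idx - 1] - vals[idx + 1]) / denom
                if abs(delta) <= 1.0:
                    step = grid[1] - grid[0]
                    return (
                        float(grid[idx] + delta * step),
                        float(vals[idx] - 0.25 * (vals[idx - 1] - vals[idx + 1]) * delta),
                    )
        return float(grid[idx]), float(vals[idx])

    s_apex, r_apex = _parab(r_fine[:, j], s_fine, i)
    out = TibialFrame(
        axis_point=frame.axis_point.copy(),
        axis_direction=frame.axis_direction.copy(),
        anterior_direction=anterior,
        epiphyseal_s=frame.epiphyseal_s,
    )
    out.apex_point = out.foot(s_apex) + r_apex * anterior  # type: ignore[attr-defined]
    out.apex_distance = r_apex  # type: ignore[attr-defined]
    return out


def anterior_cortex_at_plane(
    mask: np.ndarray,
    volume: Volume3D,
    frame: TibialFrame,
    surface_field: tuple[np.ndarray, float] | None = None,
) -> np.ndarray:
    """Anterior cortex point at the epiphyseal plane, sub-voxel.

    Intersects the anterior ray anchored at the axis foot on the
    epiphyseal plane with the outer bone surface.
    """

    if frame.epiphyseal_s is None or frame.anterior_direction is None:
        raise MeasurementError("frame requires epiphyseal_s and anterior_direction")
    if surface_field is None:
        surface_field = _surface_field(volume, mask)
    field, level = surface_field
    foot = frame.foot(frame.epiphyseal_s)[None, :]
    extent = max(volume.shape[a] * volume.spacing[a] for a in range(3))
    r = _ray_surface_crossing(
        field, level, volume, foot, frame.anterior_direction, r_max=extent, step=0.1 * min(volume.spacing)
    )
    if np.isnan(r[0]):
        raise MeasurementError("anterior ray at the epiphyseal plane misses the bone")
    return foot[0] + float(r[0]) * frame.anterior_direction


def compute_atti(landmarks: LandmarkSet, frame: TibialFrame) -> ATTIResult:
    """AB / AC from apex and cortex landmarks in a tibial frame.

    AB is the apex-to-cortex separation and AC the apex-to-axis
    separation, both projected on the anterior direction (all three
    tangent lines are parallel to the shaft axis).
    """

    if frame.anterior_direction is None:
        raise MeasurementError("frame.anterior_direction is required")
    apex = np.asarray(landmarks.apex, dtype=float)
    cortex = np.asarray(landmarks.cortex_at_epiphysis, dtype=float)
    ant = np.asarray(frame.anterior_direction, dtype=float)
    s_apex = frame.along(apex)
    foot = frame.foot(s_apex)
    ac = float(np.dot(apex - foot, ant))
    if ac <= 0:
        raise MeasurementError("apex not anterior to axis (AC <= 0)")
    ab = float(np.dot(apex - cortex, ant))
    return ATTIResult(
        ab=ab,
        ac=ac,
        atti=ab / ac,
        landmarks=landmarks,
        frame_axis_point=tuple(frame.axis_point),
        frame_axis_direction=tuple(frame.axis_direction),
        anterior_direction=tuple(ant),
    )


def measure_volume(volume: Volume3D, config: MeasureConfig | None = None) -> ATTIResult:
    """End-to-end tuberosity-index measurement of a 3D volume.

    Chains segmentation, shaft-axis estimation, apex localization,
    anterior-cortex localization at the epiphyseal plane, and the final
    ratio.  Stage failures propagate as ``MeasurementError`` prefixed with
    the stage name.
    """

    config = config or MeasureConfig()
    if (config.epiphyseal_z is None) == (config.epiphyseal_landmark is None):
        raise MeasurementError(
            "config must set exactly one of epiphyseal_z or epiphyseal_landmark"
        )

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except MeasurementError as exc:
            raise MeasurementError(f"{name}: {exc}") from exc

    mask = _stage(
        "segment_bone", segment_bone, volume, config.threshold_mode, config.threshold_value
    )
    frame = _stage(
        "estimate_shaft_axis",
        estimate_shaft_axis,
        mask,
        volume,
        config.distal_fraction,
        config.posterior_weighting,
    )
    if config.epiphyseal_landmark is not None:
        frame.epiphyseal_s = frame.along(np.asarray(config.epiphyseal_landmark, dtype=float))
    else:
        dz = frame.axis_direction[2]
        if abs(dz) < 1e-6:
            raise MeasurementError("axis nearly horizontal; provide epiphyseal_landmark")
        frame.epiphyseal_s = (config.epiphyseal_z - frame.axis_point[2]) / dz
    sfield = _surface_field(volume, mask)
    frame = _stage(
        "locate_tuberosity_apex",
        locate_tuberosity_apex,
        mask,
        volume,
        frame,
        config.search_band,
        sfield,
    )
    cortex = _stage("anterior_cortex_at_plane", anterior_cortex_at_plane, mask, volume, frame, sfield)
    landmarks = LandmarkSet(
        apex=tuple(frame.apex_point),  # type: ignore[attr-defined]
        cortex_at_epiphysis=tuple(cortex),
        axis_point=tuple(frame.axis_point),
        axis_direction=tuple(frame.axis_direction),
    )
    return _stage("compute_atti", compute_atti, landmarks, frame)
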