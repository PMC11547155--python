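"""Synthetic lateral knee radiograph and the 2D tuberosity-index measurement.

The radiograph is an orthographic (parallel-beam) line integral of the
bone indicator along the medial-lateral axis, optionally after rigid
misalignment of the volume (internal/external rotation about the shaft,
flexion) and an in-plane shear standing in for tube tilt.  Beam
divergence is neglected: the index is a ratio of two in-plane distances
and is scale-free.

The 2D measurement follows the classic lateral-film construction: a
mid-diaphysis line fitted through silhouette midpoints of the distal
shaft (line C), a parallel tangent at the most anterior contour point of
the tuberosity (line A), and a parallel tangent at the anterior cortex
on the epiphyseal row (line B); the index is AB / AC.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .mpr import MeasureConfig, MeasurementError, measure_volume
from .phantom import (
    PhantomSpec,
    RigidTransform,
    Volume3D,
    apply_rigid_transform,
    build_phantom,
)

__all__ = [
    "ProjectionConfig",
    "Radiograph2D",
    "ATTI2DResult",
    "project",
    "measure_radiograph",
    "positioning_error_study",
]

# fraction of the peak line integral treated as the silhouette edge; small
# so that thin chords through the bump apex are not eroded away
SILHOUETTE_THRESHOLD_FRACTION = 0.05


@dataclass(frozen=True)
class ProjectionConfig:
    """Idealized lateral-projection geometry.

    Angles in degrees: ``rotation_about_shaft`` is internal/external
    rotation positioning error, ``flexion`` rotates about the
    medial-lateral (projection) axis, ``tube_tilt`` is applied as an
    image-plane shear.  ``pixel_spacing`` defaults to the volume spacing.
    """

    projection_axis: str = "y"
    rotation_about_shaft: float = 0.0
    flexion: float = 0.0
    tube_tilt: float = 0.0
    pixel_spacing: float | None = None
    rotation_center: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.projection_axis != "y":
            raise MeasurementError("only medial-lateral ('y') projection is supported")
        for a in (self.rotation_about_shaft, self.flexion, self.tube_tilt):
            if not np.isfinite(a):
                raise MeasurementError("projection angles must be finite")
        if self.pixel_spacing is not None and self.pixel_spacing <= 0:
            raise MeasurementError("pixel_spacing must be > 0")


@dataclass
class Radiograph2D:
    """Line-integral image indexed [i_x, i_z]: columns anterior, rows superior."""

    image: np.ndarray
    pixel_spacing: tuple[float, float]  # (x, z) mm
    origin: tuple[float, float]  # world (x, z) of pixel (0, 0)
    config: ProjectionConfig = field(default_factory=ProjectionConfig)

    def __post_init__(self) -> None:
        if self.image.ndim != 2:
            raise MeasurementError("Radiograph2D requires a 2D array")
        if (np.asarray(self.image) < -1e-6).any():
            raise MeasurementError("radiograph intensities must be nonnegative")

    def x_of(self, i: np.ndarray) -> np.ndarray:
        return self.origin[0] + np.asarray(i, float) * self.pixel_spacing[0]

    def z_of(self, j: np.ndarray) -> np.ndarray:
        return self.origin[1] + np.asarray(j, float) * self.pixel_spacing[1]


@dataclass(frozen=True)
class ATTI2DResult:
    ab: float
    ac: float
    atti: float
    apex_xz: tuple[float, float]
    cortex_xz: tuple[float, float]
    shaft_point_xz: tuple[float, float]
    shaft_direction_xz: tuple[float, float]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def project(volume: Volume3D, config: ProjectionConfig | None = None) -> Radiograph2D:
    """Orthographic lateral projection of the bone indicator.

    The volume is binarized at half the bone intensity, optionally
    rigidly misaligned (with an expanding field of view, so nothing is
    clipped), then summed along the medial-lateral axis; pixel values are
    chord lengths through bone, in mm.
    """

    config = config or ProjectionConfig()
    vol = volume
    if config.rotation_about_shaft != 0.0 or config.flexion != 0.0:
        vol = apply_rigid_transform(
            volume,
            rotation=(0.0, config.flexion, config.rotation_about_shaft),
            center=config.rotation_center,
            fov="expand",
        )
    peak = float(np.max(vol.data))
    if peak <= 0:
        raise MeasurementError("no bone in the field of view")
    # fractional bone occupancy per voxel: preserves partial-volume edges
    occupancy = np.clip(np.asarray(vol.data, dtype=np.float64) / peak, 0.0, 1.0)
    img = occupancy.sum(axis=1) * vol.spacing[1]
    if config.tube_tilt != 0.0:
        # image-plane shear: x -> x + tan(tilt) * (z - z_mid)
        shear = np.tan(np.deg2rad(config.tube_tilt)) * vol.spacing[2] / vol.spacing[0]
        jmid = (img.shape[1] - 1) / 2.0
        mat = np.array([[1.0, -shear], [0.0, 1.0]])
        img = ndimage.affine_transform(
            img, mat, offset=[shear * jmid, 0.0], order=1, mode="constant", cval=0.0
        )
    if not (img > 0).any():
        raise MeasurementError("bone left the field after rotation")
    return Radiograph2D(
        image=img,
        pixel_spacing=(vol.spacing[0], vol.spacing[2]),
        origin=(vol.origin[0], vol.origin[2]),
        config=config,
    )


def _anterior_edge(profile: np.ndarray, thr: float) -> float:
    """Sub-pixel index of the anterior (last) threshold crossing of a row.

    Interpolates on the squared profile: a chord through a smooth convex
    silhouette scales as sqrt(depth) near the edge, so the squared chord
    is locally linear and its interpolated crossing is phase-stable.
    """

    above = profile > thr
    if not above.any():
        return np.nan
    k = int(np.flatnonzero(above)[-1])
    if k == profile.size - 1:
        return float(k)
    v0, v1 = float(profile[k]) ** 2, float(profile[k + 1]) ** 2
    return k + (v0 - thr**2) / (v0 - v1)


def measure_radiograph(
    radiograph: Radiograph2D,
    epiphyseal_z: float | None = None,
    epiphyseal_row: int | None = None,
    distal_fraction: float = 0.25,
    search_band: tuple[float, float] = (2.0, 40.0),
    silhouette_threshold: float = SILHOUETTE_THRESHOLD_FRACTION,
) -> ATTI2DResult:
    """Tuberosity index from a lateral silhouette.

    The epiphyseal level is an input, as a world z (mm) or a pixel row.
    The shaft line is fitted through per-row silhouette midpoints of the
    distal band; anterior contour points are located sub-pixel at a small
    fraction of the peak line integral; distances are perpendicular to
    the shaft line.
    """

    img = np.asarray(radiograph.image, dtype=float)
    thr = silhouette_threshold * float(img.max())
    if not (img > thr).any():
        raise MeasurementError("silhouette empty at threshold")
    if (epiphyseal_z is None) == (epiphyseal_row is None):
        raise MeasurementError("provide exactly one of epiphyseal_z or epiphyseal_row")
    if epiphyseal_z is None:
        epiphyseal_z = float(radiograph.z_of(epiphyseal_row))
    sx, sz = radiograph.pixel_spacing
    sil = img > thr
    rows = np.flatnonzero(sil.any(axis=0))
    z_support = radiograph.z_of(rows)
    if not (z_support.min() <= epiphyseal_z <= z_support.max()):
        raise MeasurementError("epiphyseal level outside the silhouette support")

    # shaft line from distal-band midpoints
    extent = rows[-1] - rows[0] + 1
    band_rows = rows[rows < rows[0] + max(int(np.ceil(extent * distal_fraction)), 1)]
    if band_rows.size < 10:
        raise MeasurementError("too few distal rows to fit the shaft line")
    mids = []
    for j in band_rows:
        cols = np.flatnonzero(sil[:, j])
        mids.append(0.5 * (radiograph.x_of(cols[0]) + radiograph.x_of(cols[-1])))
    zb = radiograph.z_of(band_rows)
    coef = np.polyfit(zb, np.asarray(mids), 1)  # x = b*z + a
    b = float(coef[0])
    p0 = np.array([np.polyval(coef, zb.mean()), zb.mean()])  # (x, z) on line C
    d = np.array([b, 1.0]) / np.hypot(b, 1.0)  # along-shaft direction
    nvec = np.array([1.0, -b]) / np.hypot(b, 1.0)  # anterior normal

    def signed_dist(x, z):
        return (x - p0[0]) * nvec[0] + (z - p0[1]) * nvec[1]

    # anterior contour, sub-pixel, per row
    edges_x = np.full(img.shape[1], np.nan)
    for j in rows:
        e = _anterior_edge(img[:, j], thr)
        if np.isfinite(e):
            edges_x[j] = radiograph.x_of(e)
    zs = radiograph.z_of(np.arange(img.shape[1]))
    valid = np.isfinite(edges_x)
    dist = signed_dist(edges_x[valid], zs[valid])
    zv = zs[valid]

    in_band = (zv >= epiphyseal_z - search_band[1]) & (zv <= epiphyseal_z - search_band[0])
    if not in_band.any():
        raise MeasurementError("apex search band contains no contour points")
    i_apex = int(np.argmax(np.where(in_band, dist, -np.inf)))
    d_apex = float(dist[i_apex])
    apex_xz = (float(edges_x[valid][i_apex]), float(zv[i_apex]))

    # anterior cortex at the epiphyseal level, interpolated between rows
    d_cortex = float(np.interp(epiphyseal_z, zv, dist))
    x_cortex = float(np.interp(epiphyseal_z, zv, edges_x[valid]))

    ac = d_apex
    if ac <= 0:
        raise MeasurementError("apex not anterior to the shaft line (AC <= 0)")
    ab = d_apex - d_cortex
    return ATTI2DResult(
        ab=ab,
        ac=ac,
        atti=ab / ac,
        apex_xz=apex_xz,
        cortex_xz=(x_cortex, float(epiphyseal_z)),
        shaft_point_xz=(float(p0[0]), float(p0[1])),
        shaft_direction_xz=(float(d[0]), float(d[1])),
    )


def positioning_error_study(
    spec: PhantomSpec,
    rotations: list[float],
    flexions: list[float] | None = None,
    margin: float = 8.0,
    measure_config: MeasureConfig | None = None,
) -> pd.DataFrame:
    """Grid study of positioning error: 2D vs 3D index under misalignment.

    For every (rotation-about-shaft, flexion) pair the phantom volume is
    rigidly misaligned; the 2D index is measured on its lateral
    projection and the 3D index on the same misaligned volume (with the
    correspondingly transformed epiphyseal landmark).  Per-cell failures
    are recorded, not raised.
    """

    rotations = list(rotations)
    flexions = list(flexions) if flexions is not None else [0.0]
    if not rotations or not flexions:
        raise MeasurementError("rotation and flexion grids must be nonempty")
    vol, gt = build_phantom(spec, margin=margin)
    center = (
        vol.origin[0] + (vol.shape[0] - 1) * vol.spacing[0] / 2.0,
        vol.origin[1] + (vol.shape[1] - 1) * vol.spacing[1] / 2.0,
        vol.origin[2] + (vol.shape[2] - 1) * vol.spacing[2] / 2.0,
    )
    epi_landmark = np.array([0.0, 0.0, spec.epiphyseal_z])
    records = []
    for flex in flexions:
        for rot in rotations:
            rec = {
                "rotation_deg": rot,
                "flexion_deg": flex,
                "atti_true": gt.atti_true,
                "atti_2d": np.nan,
                "atti_3d": np.nan,
                "delta": np.nan,
                "error": "",
            }
            try:
                tfm = RigidTransform(rotation=(0.0, flex, rot), center=center)
                moved = apply_rigid_transform(
                    vol, rotation=(0.0, flex, rot), center=center, fov="expand"
                )
                landmark = tfm.apply_point(epi_landmark)
                rad = project(moved)
                res2d = measure_radiograph(rad, epiphyseal_z=float(landmark[2]))
                cfg = dataclasses.replace(
                    measure_config or MeasureConfig(),
                    epiphyseal_z=None,
                    epiphyseal_landmark=tuple(landmark),
                )
                res3d = measure_volume(moved, cfg)
                rec.update(
                    atti_2d=res2d.atti,
                    atti_3d=res3d.atti,
                    delta=res2d.atti - res3d.atti,
                )
            except MeasurementError as exc:  # record, keep going
                rec["error"] = str(exc)
            records.append(rec)
    return pd.DataFrame.from_records(records)
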