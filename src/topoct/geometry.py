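"""Fan-beam projection geometry and sparse tomographic operators.

This module models a per-slice fan-beam acquisition: X-rays diverge from a
point source within each axial plane onto a flat detector row.  From a single
:class:`FanBeamGeometry` three operators are derived:

* a pixel-driven backprojection matrix ``T`` (:class:`SystemMatrix`) that
  distributes each detector channel onto the image pixels whose rays hit it —
  used to lift 2D feature maps into a 3D grid;
* a ray-driven forward projector (:class:`FanBeamProjector`) computing
  line integrals in mm·intensity units — used to simulate topograms and for
  projection-consistency losses;
* exact adjoints of both (sparse transposes), so inner-product identities
  hold to machine precision.

Coordinate convention: the image grid is square with ``n_image`` pixels per
axis, voxel centers at ``(i + 0.5) * spacing - extent / 2`` (isocenter at the
volume center), ``z`` the vertical slice-stacking axis.  The AP source sits on
the +y axis, the LAT source on the +x axis; the flat detector is centered on
and perpendicular to the central ray at distance ``sdd_mm`` from the source.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
from scipy import sparse


class View(str, enum.Enum):
    """Topogram acquisition direction (rotation about the vertical axis)."""

    AP = "AP"  # anterior-posterior: source at 0 deg, on the +y axis
    LAT = "LAT"  # lateral: source at 90 deg, on the +x axis

    @property
    def angle_rad(self) -> float:
        return 0.0 if self is View.AP else math.pi / 2.0


@dataclass(frozen=True)
class FanBeamGeometry:
    """Scanner model from which all projection operators derive.

    Parameters
    ----------
    sdd_mm:
        Source-to-detector distance in mm.
    sid_mm:
        Source-to-isocenter distance in mm.
    n_detector:
        Number of detector channels in the fan.
    detector_spacing_mm:
        Channel pitch at the detector, in mm.  If ``None`` it is derived so
        that the detector exactly covers the magnified in-slice field of
        view: ``n_image * voxel_spacing * (sdd / sid) / n_detector``.
    n_image:
        In-slice grid size (square).
    voxel_spacing_mm:
        Voxel pitch in mm.
    view:
        :class:`View` selecting the source position.
    """

    sdd_mm: float = 1085.6
    sid_mm: float = 595.0
    n_detector: int = 128
    detector_spacing_mm: float | None = None
    n_image: int = 128
    voxel_spacing_mm: float = 2.5
    view: View = View.AP

    def __post_init__(self) -> None:
        if not self.sdd_mm > self.sid_mm > 0:
            raise ValueError(
                "geometry requires sdd_mm > sid_mm > 0 "
                f"(got sdd_mm={self.sdd_mm}, sid_mm={self.sid_mm})"
            )
        if self.n_detector < 1:
            raise ValueError(f"n_detector must be >= 1 (got {self.n_detector})")
        if self.n_image < 1:
            raise ValueError(f"n_image must be >= 1 (got {self.n_image})")
        if self.voxel_spacing_mm <= 0:
            raise ValueError(
                f"voxel_spacing_mm must be > 0 (got {self.voxel_spacing_mm})"
            )
        if self.detector_spacing_mm is None:
            object.__setattr__(
                self, "detector_spacing_mm", self._derived_detector_spacing()
            )
        if self.detector_spacing_mm <= 0:
            raise ValueError(
                f"detector_spacing_mm must be > 0 (got {self.detector_spacing_mm})"
            )
        coverage = self.n_detector * self.detector_spacing_mm
        needed = self.n_image * self.voxel_spacing_mm * self.magnification
        if coverage < needed * (1.0 - 1e-9):
            raise ValueError(
                "detector does not cover the magnified field of view: "
                f"n_detector * detector_spacing_mm = {coverage:.3f} mm < "
                f"n_image * voxel_spacing_mm * sdd/sid = {needed:.3f} mm"
            )
        object.__setattr__(self, "view", View(self.view))

    def _derived_detector_spacing(self) -> float:
        return (
            self.n_image * self.voxel_spacing_mm * self.magnification / self.n_detector
        )

    @property
    def magnification(self) -> float:
        """Geometric magnification at the isocenter, sdd / sid."""
        return self.sdd_mm / self.sid_mm

    @property
    def fov_mm(self) -> float:
        """In-slice field-of-view extent covered by the image grid."""
        return self.n_image * self.voxel_spacing_mm

    def with_view(self, view: View | str) -> "FanBeamGeometry":
        return replace(self, view=View(view))

    def downsampled(self, factor: int) -> "FanBeamGeometry":
        """Geometry of the same physical setup on a grid coarsened by ``factor``.

        Used to build per-level system matrices for network feature maps:
        the field of view and detector extent are preserved while pixel and
        channel counts shrink.
        """
        if factor < 1 or self.n_image % factor or self.n_detector % factor:
            raise ValueError(
                f"factor {factor} must divide n_image={self.n_image} "
                f"and n_detector={self.n_detector}"
            )
        return replace(
            self,
            n_image=self.n_image // factor,
            voxel_spacing_mm=self.voxel_spacing_mm * factor,
            n_detector=self.n_detector // factor,
            detector_spacing_mm=self.detector_spacing_mm * factor,
        )

    # --- source / detector layout -------------------------------------------------
    def source_position(self) -> np.ndarray:
        th = self.view.angle_rad
        return self.sid_mm * np.array([math.sin(th), math.cos(th)])

    def detector_axis(self) -> np.ndarray:
        th = self.view.angle_rad
        return np.array([math.cos(th), -math.sin(th)])

    def central_direction(self) -> np.ndarray:
        th = self.view.angle_rad
        return -np.array([math.sin(th), math.cos(th)])

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of in-slice pixel center coordinates, shape (n, n) each."""
        n, s = self.n_image, self.voxel_spacing_mm
        coords = (np.arange(n) + 0.5) * s - n * s / 2.0
        return np.meshgrid(coords, coords, indexing="ij")

    def detector_channel_offsets_mm(self) -> np.ndarray:
        """Signed channel center coordinates along the detector axis."""
        k = np.arange(self.n_detector)
        return (k - (self.n_detector - 1) / 2.0) * self.detector_spacing_mm


@dataclass(frozen=True)
class ProjectionImage:
    """A 2D projection: axis 0 = detector channel, axis 1 = vertical (z).

    Values are in line-integral units (mm·intensity) for physical
    projections and arbitrary units for network feature maps.
    """

    values: np.ndarray
    geometry: FanBeamGeometry

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"projection must be 2D (got shape {v.shape})")
        if v.shape[0] != self.geometry.n_detector:
            raise ValueError(
                f"projection has {v.shape[0]} channels, geometry expects "
                f"{self.geometry.n_detector}"
            )
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SystemMatrix:
    """Pixel-driven backprojection matrix for one view.

    ``weights`` has one row per in-slice pixel (row-major over (x, y)) and one
    column per detector channel.  Each row carries the linear-interpolation
    weights of the pixel's projection onto the detector: at most two non-zero
    entries summing to one, or an all-zero row when the pixel projects outside
    the span of the channel centers.
    """

    weights: sparse.csr_matrix
    geometry: FanBeamGeometry

    @property
    def n_pixels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_detector(self) -> int:
        return self.weights.shape[1]

    def apply(self, detector_values: np.ndarray) -> np.ndarray:
        """Backproject one detector row into an (n, n) in-slice image."""
        detector_values = np.asarray(detector_values)
        if detector_values.shape[-1] != self.n_detector:
            raise ValueError(
                f"detector row has {detector_values.shape[-1]} channels, "
                f"matrix expects {self.n_detector}"
            )
        n = self.geometry.n_image
        return (self.weights @ detector_values.reshape(-1)).reshape(n, n)

    def adjoint(self, image: np.ndarray) -> np.ndarray:
        """Exact transpose: accumulate an (n, n) image onto detector channels."""
        image = np.asarray(image)
        if image.size != self.n_pixels:
            raise ValueError(
                f"image has {image.size} pixels, matrix expects {self.n_pixels}"
            )
        return self.weights.T @ image.reshape(-1)


def build_system_matrix(geom: FanBeamGeometry) -> SystemMatrix:
    """Construct the pixel-driven fan-beam backprojection matrix ``T``.

    For each pixel center the ray from the source through the pixel is
    intersected with the flat detector; the continuous channel coordinate
    distributes unit weight onto its two neighboring channels by linear
    interpolation.  Pixels projecting outside the span of channel centers get
    an all-zero row.  Construction is deterministic.
    """
    n = geom.n_image
    px, py = geom.pixel_centers_mm()
    src = geom.source_position()
    e_u = geom.detector_axis()
    d_c = geom.central_direction()

    vx = px.reshape(-1) - src[0]
    vy = py.reshape(-1) - src[1]
    # distance along the central ray and signed offset along the detector axis
    depth = vx * d_c[0] + vy * d_c[1]
    lateral = vx * e_u[0] + vy * e_u[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = lateral * geom.sdd_mm / depth
    # continuous channel index; channel centers at (k - (n_det-1)/2) * du
    c = u / geom.detector_spacing_mm + (geom.n_detector - 1) / 2.0
    inside = (depth > 0) & (c >= 0.0) & (c <= geom.n_detector - 1)

    rows_idx = np.nonzero(inside)[0]
    c_in = c[inside]
    c0 = np.floor(c_in).astype(np.int64)
    c0 = np.minimum(c0, geom.n_detector - 2) if geom.n_detector > 1 else c0 * 0
    frac = c_in - c0

    rows = np.concatenate([rows_idx, rows_idx])
    cols = np.concatenate([c0, np.minimum(c0 + 1, geom.n_detector - 1)])
    vals = np.concatenate([1.0 - frac, frac])
    keep = vals > 0
    mat = sparse.csr_matrix(
        (vals[keep], (rows[keep], cols[keep])),
        shape=(n * n, geom.n_detector),
        dtype=np.float64,
    )
    mat.sum_duplicates()
    return SystemMatrix(weights=mat, geometry=geom)


@dataclass(frozen=True)
class FanBeamProjector:
    """Ray-driven fan-beam forward projector for one view.

    ``matrix`` maps a flattened (n, n) slice (row-major over (x, y)) to
    ``n_detector`` line integrals.  Rays are sampled Joseph-style at a fixed
    step along each source-to-channel ray with bilinear in-slice
    interpolation; samples outside the grid contribute zero; the result is
    scaled by the sampling step in mm.  The operator is linear, deterministic
    and its adjoint is the exact sparse transpose.
    """

    matrix: sparse.csr_matrix
    geometry: FanBeamGeometry
    step_mm: float

    def apply(self, slice_image: np.ndarray) -> np.ndarray:
        slice_image = np.asarray(slice_image)
        if slice_image.size != self.matrix.shape[1]:
            raise ValueError(
                f"slice has {slice_image.size} pixels, projector expects "
                f"{self.matrix.shape[1]}"
            )
        return self.matrix @ slice_image.reshape(-1)

    def adjoint(self, detector_values: np.ndarray) -> np.ndarray:
        detector_values = np.asarray(detector_values)
        if detector_values.shape[-1] != self.geometry.n_detector:
            raise ValueError(
                f"detector row has {detector_values.shape[-1]} channels, "
                f"projector expects {self.geometry.n_detector}"
            )
        n = self.geometry.n_image
        return (self.matrix.T @ detector_values.reshape(-1)).reshape(n, n)


def build_projector(
    geom: FanBeamGeometry, step_fraction: float = 0.5
) -> FanBeamProjector:
    """Build the sparse ray-driven forward projection matrix for ``geom``.

    ``step_fraction`` sets the ray sampling step as a fraction of the voxel
    spacing (must be <= 1 so no voxel is stepped over).
    """
    if not 0 < step_fraction <= 1.0:
        raise ValueError("step_fraction must lie in (0, 1]")
    n = geom.n_image
    s = geom.voxel_spacing_mm
    half = n * s / 2.0
    step = s * step_fraction
    src = geom.source_position()
    e_u = geom.detector_axis()
    d_c = geom.central_direction()
    det_center = src + geom.sdd_mm * d_c
    offsets = geom.detector_channel_offsets_mm()

    rows, cols, vals = [], [], []
    for k, u in enumerate(offsets):
        det_pt = det_center + u * e_u
        direction = det_pt - src
        direction = direction / np.linalg.norm(direction)
        t0, t1 = _ray_box_interval(src, direction, half)
        if t1 <= t0:
            continue
        m = int(np.ceil((t1 - t0) / step))
        t = t0 + (np.arange(m) + 0.5) * step
        t = t[t < t1]
        pts_x = src[0] + t * direction[0]
        pts_y = src[1] + t * direction[1]
        fx = pts_x / s + n / 2.0 - 0.5
        fy = pts_y / s + n / 2.0 - 0.5
        ix = np.floor(fx).astype(np.int64)
        iy = np.floor(fy).astype(np.int64)
        wx = fx - ix
        wy = fy - iy
        for dx, dy, w in (
            (0, 0, (1 - wx) * (1 - wy)),
            (1, 0, wx * (1 - wy)),
            (0, 1, (1 - wx) * wy),
            (1, 1, wx * wy),
        ):
            gx = ix + dx
            gy = iy + dy
            ok = (gx >= 0) & (gx < n) & (gy >= 0) & (gy < n) & (w > 0)
            if not np.any(ok):
                continue
            rows.append(np.full(ok.sum(), k, dtype=np.int64))
            cols.append(gx[ok] * n + gy[ok])
            vals.append(w[ok] * step)
    if rows:
        mat = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(geom.n_detector, n * n),
            dtype=np.float64,
        )
        mat.sum_duplicates()
    else:  # pragma: no cover - degenerate geometry
        mat = sparse.csr_matrix((geom.n_detector, n * n), dtype=np.float64)
    return FanBeamProjector(matrix=mat, geometry=geom, step_mm=step)


def _ray_box_interval(
    src: np.ndarray, direction: np.ndarray, half: float
) -> tuple[float, float]:
    """Parameter interval where the ray src + t*dir lies in [-half, half]^2."""
    t0, t1 = 0.0, np.inf
    for axis in range(2):
        d = direction[axis]
        o = src[axis]
        if abs(d) < 1e-300:
            if abs(o) > half:
                return 0.0, 0.0
            continue
        ta = (-half - o) / d
        tb = (half - o) / d
        lo, hi = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, lo), min(t1, hi)
    return t0, max(t0, t1)


_PROJECTOR_CACHE: dict[tuple, FanBeamProjector] = {}
_SYSTEM_MATRIX_CACHE: dict[tuple, SystemMatrix] = {}


def _geom_key(geom: FanBeamGeometry) -> tuple:
    return (
        geom.sdd_mm,
        geom.sid_mm,
        geom.n_detector,
        geom.detector_spacing_mm,
        geom.n_image,
        geom.voxel_spacing_mm,
        geom.view.value,
    )


def get_projector(geom: FanBeamGeometry) -> FanBeamProjector:
    """Cached :func:`build_projector` (operators are deterministic per geometry)."""
    key = _geom_key(geom)
    if key not in _PROJECTOR_CACHE:
        _PROJECTOR_CACHE[key] = build_projector(geom)
    return _PROJECTOR_CACHE[key]


def get_system_matrix(geom: FanBeamGeometry) -> SystemMatrix:
    """Cached :func:`build_system_matrix`."""
    key = _geom_key(geom)
    if key not in _SYSTEM_MATRIX_CACHE:
        _SYSTEM_MATRIX_CACHE[key] = build_system_matrix(geom)
    return _SYSTEM_MATRIX_CACHE[key]


def forward_project(volume: np.ndarray, geom: FanBeamGeometry) -> ProjectionImage:
    """Simulate a topogram: fan-beam line integrals of each axial slice.

    ``volume`` must be cubic with ``geom.n_image`` voxels per axis, axes
    ordered (x, y, z).  Each z-slice is projected independently; the result
    has shape ``(n_detector, n_z)``.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3 or len(set(volume.shape)) != 1:
        raise ValueError(f"volume must be cubic 3D (got shape {volume.shape})")
    n = geom.n_image
    if volume.shape[0] != n:
        raise ValueError(
            f"volume size {volume.shape[0]} does not match geometry n_image {n}"
        )
    proj = get_projector(geom)
    values = proj.matrix @ volume.reshape(n * n, n)
    return ProjectionImage(values=values, geometry=geom)


def lift_2d_to_3d(features: np.ndarray, T: SystemMatrix) -> np.ndarray:
    """Backproject a stack of 2D feature maps into a 3D feature volume.

    ``features`` has shape (channels, n_detector, n_z); each (channel, z)
    detector row is multiplied by ``T`` to give one in-slice map.  The result
    has shape (channels, n, n, n_z).  Rows at different z never mix; the map
    is linear, so it is differentiable with the transpose as gradient.
    """
    features = np.asarray(features)
    if features.ndim != 3:
        raise ValueError(f"features must be (C, D, Z) (got shape {features.shape})")
    C, D, Z = features.shape
    if D != T.n_detector:
        raise ValueError(
            f"feature detector size {D} does not match system matrix "
            f"column count {T.n_detector}"
        )
    n = T.geometry.n_image
    flat = features.transpose(1, 0, 2).reshape(D, C * Z)
    lifted = T.weights @ flat  # (n*n, C*Z)
    return lifted.reshape(n, n, C, Z).transpose(2, 0, 1, 3)


def adjoint_apply(
    values: np.ndarray, operator: Union[SystemMatrix, FanBeamProjector]
) -> np.ndarray:
    """Apply the exact transpose of a stored sparse operator.

    For a :class:`FanBeamProjector` this maps detector values back to a slice
    image; for a :class:`SystemMatrix` it accumulates a slice image onto
    detector channels.  Satisfies <A x, p> == <x, adjoint_apply(p, A)>.
    """
    return operator.adjoint(values)
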