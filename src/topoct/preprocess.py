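"""Volume preprocessing: resampling, cropping/padding, normalization, topograms.

The training pipeline expects cubic volumes of a fixed grid size (default
128 at 2.5 mm), intensities mapped affinely from a fixed HU window onto
[0, 1], and topogram pairs simulated by fan-beam forward projection and
scaled by a single run-level constant.  Everything here is deterministic and
config-reproducible: the same raw volume and the same stored parameters give
bitwise-identical network input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from topoct.geometry import FanBeamGeometry, ProjectionImage, View, forward_project

AIR_HU = -1000.0
#: default normalization window: the standard 12-bit CT range
DEFAULT_HU_WINDOW = (-1024.0, 3071.0)


@dataclass(frozen=True)
class NormalizedVolume:
    """A volume mapped from a fixed HU window onto [0, 1]."""

    values: np.ndarray
    hu_window: tuple[float, float]
    spacing_mm: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("normalized values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def denormalize(self) -> np.ndarray:
        """Invert the normalization; recovers HU clipped to the window."""
        lo, hi = self.hu_window
        return self.values * (hi - lo) + lo


def resample_volume(
    vol: np.ndarray, spacing_mm, target_spacing_mm
) -> np.ndarray:
    """Trilinearly resample an HU volume onto a grid of ``target_spacing_mm``.

    ``spacing_mm`` and ``target_spacing_mm`` may be scalars (isotropic) or
    per-axis triples.  The output physical extent matches the input within
    one voxel.  Identical source and target spacing returns the input copy
    unchanged (aligned grids).
    """
    vol = np.asarray(vol, dtype=np.float64)
    src = np.broadcast_to(np.atleast_1d(np.asarray(spacing_mm, float)), (3,))
    tgt = np.broadcast_to(np.atleast_1d(np.asarray(target_spacing_mm, float)), (3,))
    if np.any(src <= 0) or np.any(tgt <= 0):
        raise ValueError("spacings must be positive")
    if np.allclose(src, tgt):
        return vol.copy()
    zoom = src / tgt
    return ndimage.zoom(vol, zoom, order=1, mode="nearest", grid_mode=True)


def crop_or_pad(vol: np.ndarray, size: int = 128, fill: float = AIR_HU) -> np.ndarray:
    """Center-crop axes larger than ``size`` and pad smaller ones with air HU."""
    vol = np.asarray(vol)
    out = np.full((size,) * 3, fill, dtype=vol.dtype)
    src_slices, dst_slices = [], []
    for axis in range(3):
        n = vol.shape[axis]
        if n >= size:
            start = (n - size) // 2
            src_slices.append(slice(start, start + size))
            dst_slices.append(slice(0, size))
        else:
            start = (size - n) // 2
            src_slices.append(slice(0, n))
            dst_slices.append(slice(start, start + n))
    out[tuple(dst_slices)] = vol[tuple(src_slices)]
    return out


def normalize_hu(
    vol: np.ndarray,
    hu_min: float = DEFAULT_HU_WINDOW[0],
    hu_max: float = DEFAULT_HU_WINDOW[1],
    spacing_mm: float = 2.5,
) -> NormalizedVolume:
    """Clip to [hu_min, hu_max] and map affinely onto [0, 1].

    The same fixed window must be applied to every volume in a run; it is
    therefore part of the experiment config and stored on the result for
    later denormalization.
    """
    if hu_max <= hu_min:
        raise ValueError(f"inverted HU window: ({hu_min}, {hu_max})")
    v = np.clip(np.asarray(vol, dtype=np.float64), hu_min, hu_max)
    return NormalizedVolume(
        values=(v - hu_min) / (hu_max - hu_min),
        hu_window=(hu_min, hu_max),
        spacing_mm=spacing_mm,
    )


def simulate_topograms(
    vol: NormalizedVolume,
    geom: FanBeamGeometry,
    proj_norm_constant: float | None,
) -> tuple[ProjectionImage, ProjectionImage]:
    """Forward-project a normalized volume in AP and LAT views, scaled to [0, 1].

    Projections are divided by ``proj_norm_constant`` — a fixed run-level
    constant (the maximum projection value over the training corpus, stored
    in the config) — and clipped to [0, 1], so attenuation magnitudes remain
    comparable across the corpus.
    """
    if proj_norm_constant is None:
        raise ValueError(
            "proj_norm_constant is missing: supply the run-level projection "
            "normalization constant from the training config"
        )
    if proj_norm_constant <= 0:
        raise ValueError("proj_norm_constant must be positive")
    pair = []
    for view in (View.AP, View.LAT):
        p = forward_project(vol.values, geom.with_view(view))
        scaled = np.clip(p.values / proj_norm_constant, 0.0, 1.0)
        pair.append(ProjectionImage(values=scaled, geometry=p.geometry))
    return pair[0], pair[1]


def save_projection(values: np.ndarray, path, fmt: str = "nifti") -> None:
    """Write a 2D projection as NIfTI (float32) or 16-bit TIFF.

    The TIFF path quantizes [0, 1] data onto the uint16 range; NIfTI keeps
    float values exactly.
    """
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError(f"projection must be 2D (got shape {values.shape})")
    path = str(path)
    if fmt == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(values.astype(np.float32), np.eye(4)), path)
    elif fmt == "tiff":
        import tifffile

        scaled = np.clip(values, 0.0, 1.0) * np.iinfo(np.uint16).max
        tifffile.imwrite(path, scaled.round().astype(np.uint16))
    else:
        raise ValueError(f"unknown projection format {fmt!r} (nifti or tiff)")


def load_projection(path) -> np.ndarray:
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        return tifffile.imread(path).astype(np.float64) / np.iinfo(np.uint16).max
    import nibabel as nib

    return np.asarray(nib.load(path).dataobj, dtype=np.float64)


def projection_norm_constant(
    volumes: list[NormalizedVolume], geom: FanBeamGeometry
) -> float:
    """Corpus-level projection maximum used to scale topograms into [0, 1]."""
    m = 0.0
    for vol in volumes:
        for view in (View.AP, View.LAT):
            m = max(m, float(forward_project(vol.values, geom.with_view(view)).values.max()))
    if m <= 0:
        raise ValueError("corpus projections are identically zero")
    return m
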