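"""Seeded synthetic thorax phantom corpus with paired organ labels.

Each phantom is a body of soft tissue on an air background containing two
low-attenuation lungs, a liver, and high-attenuation bone (a vertical spine
plus a handful of rib arcs), with a voxel-wise label mask painted from the
same geometric primitives.  The corpus plays the role of a chest-CT
reconstruction dataset and an organ-segmentation dataset: analytic shapes
with tissue-realistic HU ranges, deterministic per (seed, index).

Primitives are ellipsoids and cylinders, optionally rotated about the
vertical axis, which keeps organ placement auditable: every lung voxel is
guaranteed well below -500 HU and every bone voxel well above 300 HU.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: label codes in the organ mask
LABELS = {"background": 0, "lung": 1, "liver": 2, "bone": 3}

_DEFAULT_HU = {
    "air": (-1000.0, 0.0),
    "soft_tissue": (40.0, 20.0),
    "lung": (-800.0, 50.0),
    "liver": (60.0, 15.0),
    "bone": (700.0, 100.0),
}

# per-organ geometry ranges as fractions of the grid extent:
# centers (cx, cy, cz), half-axes (ax, ay, az), rotation about z in degrees
_DEFAULT_SHAPES = {
    "body": {"center": [(0.5, 0.5), (0.5, 0.5), (0.5, 0.5)],
             "half_axes": [(0.38, 0.44), (0.28, 0.34), (1.1, 1.3)],
             "rot_deg": (0.0, 0.0)},
    "lung": {"center": [(0.31, 0.35), (0.46, 0.52), (0.56, 0.64)],
             "half_axes": [(0.09, 0.12), (0.11, 0.14), (0.18, 0.24)],
             "rot_deg": (-8.0, 8.0)},
    "liver": {"center": [(0.58, 0.63), (0.48, 0.54), (0.26, 0.32)],
              "half_axes": [(0.12, 0.16), (0.10, 0.14), (0.10, 0.14)],
              "rot_deg": (-10.0, 10.0)},
    "spine": {"center": [(0.49, 0.51), (0.66, 0.70), (0.5, 0.5)],
              "half_axes": [(0.03, 0.045), (0.03, 0.045), (0.40, 0.48)],
              "rot_deg": (0.0, 0.0)},
    "ribs": {"count": (4, 8), "z": (0.40, 0.85), "scale": (0.80, 0.90),
             "band": (0.035, 0.055), "arc_deg": (60.0, 160.0),
             "thickness_vox": (1.5, 2.5)},
}


class PlacementError(RuntimeError):
    """Raised when an organ cannot be placed inside the body."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generator settings: grid, tissue HU statistics, and shape ranges.

    ``hu_values`` maps tissue name to (mean HU, jitter HU); one value per
    organ per phantom is drawn uniformly from mean +/- jitter, and mild
    voxel-wise Gaussian noise (``noise_hu``) is added on top.  ``shape_ranges``
    gives per-organ center / half-axis / rotation ranges as fractions of the
    grid extent.
    """

    grid_size: int = 128
    voxel_spacing_mm: float = 2.5
    hu_values: dict = field(default_factory=lambda: dict(_DEFAULT_HU))
    shape_ranges: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULT_SHAPES)))
    noise_hu: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 8:
            raise ValueError(f"grid_size must be >= 8 (got {self.grid_size})")
        if self.voxel_spacing_mm <= 0:
            raise ValueError("voxel_spacing_mm must be > 0")
        means = {t: mv[0] for t, mv in self.hu_values.items()}
        if not means["lung"] < means["soft_tissue"] < means["liver"] < means["bone"]:
            raise ValueError(
                "hu ordering violated: need lung < soft_tissue < liver < bone means"
            )
        for organ, rng in self.shape_ranges.items():
            if organ == "ribs":
                continue
            for lo, hi in rng["half_axes"]:
                if lo <= 0 or hi < lo:
                    raise ValueError(f"non-positive half-axis range for {organ}")

    def sha256(self) -> str:
        """Stable hash of the spec used to fingerprint generated datasets."""
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class LabeledPhantom:
    """An HU volume with its voxel-wise organ label mask."""

    hu_volume: np.ndarray
    labels: np.ndarray
    spacing_mm: float

    def validate(self) -> None:
        if self.hu_volume.shape != self.labels.shape:
            raise ValueError("hu_volume and labels must have identical shapes")
        lung = self.labels == LABELS["lung"]
        bone = self.labels == LABELS["bone"]
        if lung.any() and self.hu_volume[lung].max() >= -500:
            raise ValueError("lung-labeled voxel with HU >= -500")
        if bone.any() and self.hu_volume[bone].min() <= 300:
            raise ValueError("bone-labeled voxel with HU <= 300")


def _uniform(rng: np.random.Generator, lo_hi) -> float:
    lo, hi = lo_hi
    return float(rng.uniform(lo, hi))


def _ellipsoid_mask(coords, center_mm, half_axes_mm, rot_deg: float) -> np.ndarray:
    x, y, z = coords
    dx, dy, dz = x - center_mm[0], y - center_mm[1], z - center_mm[2]
    th = math.radians(rot_deg)
    rx = math.cos(th) * dx + math.sin(th) * dy
    ry = -math.sin(th) * dx + math.cos(th) * dy
    return (rx / half_axes_mm[0]) ** 2 + (ry / half_axes_mm[1]) ** 2 + (
        dz / half_axes_mm[2]
    ) ** 2 <= 1.0


def sample_phantom(spec: PhantomSpec, index: int) -> LabeledPhantom:
    """Generate one labeled phantom, deterministic given (spec.seed, index)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(index,)))
    n = spec.grid_size
    s = spec.voxel_spacing_mm
    extent = n * s
    ax1d = (np.arange(n) + 0.5) * s
    coords = np.meshgrid(ax1d, ax1d, ax1d, indexing="ij")

    def frac_pt(fracs):
        return [f * extent for f in fracs]

    hu = {t: _uniform(rng, (m - j, m + j)) for t, (m, j) in spec.hu_values.items()}
    vol = np.full((n, n, n), hu["air"], dtype=np.float64)
    labels = np.zeros((n, n, n), dtype=np.uint8)

    sh = spec.shape_ranges
    body = _ellipsoid_mask(
        coords,
        frac_pt([_uniform(rng, r) for r in sh["body"]["center"]]),
        frac_pt([_uniform(rng, r) for r in sh["body"]["half_axes"]]),
        _uniform(rng, sh["body"]["rot_deg"]),
    )
    vol[body] = hu["soft_tissue"]

    def place(organ: str, mirror_x: bool = False) -> np.ndarray:
        """Draw a mask for ``organ`` fully inside the body, with retries."""
        for _ in range(30):
            cf = [_uniform(rng, r) for r in sh[organ]["center"]]
            if mirror_x:
                cf[0] = 1.0 - cf[0]
            mask = _ellipsoid_mask(
                coords,
                frac_pt(cf),
                frac_pt([_uniform(rng, r) for r in sh[organ]["half_axes"]]),
                _uniform(rng, sh[organ]["rot_deg"]),
            )
            if mask.any() and (mask & ~body).sum() <= 0.01 * mask.sum():
                return mask
        raise PlacementError(f"could not place organ '{organ}' inside the body")

    lung_l = place("lung")
    lung_r = place("lung", mirror_x=True)
    for m in (lung_l, lung_r):
        vol[m] = hu["lung"]
        labels[m] = LABELS["lung"]

    liver = place("liver")
    vol[liver] = hu["liver"]
    labels[liver] = LABELS["liver"]

    spine = place("spine")
    bone_mask = spine.copy()

    ribs = sh["ribs"]
    n_ribs = int(rng.integers(ribs["count"][0], ribs["count"][1] + 1))
    body_ax = _uniform(rng, sh["body"]["half_axes"][0]) * extent
    body_ay = _uniform(rng, sh["body"]["half_axes"][1]) * extent
    cx = cy = extent / 2.0
    x, y, z = coords
    ang = np.arctan2(y - cy, x - cx)
    rho = np.sqrt(((x - cx) / body_ax) ** 2 + ((y - cy) / body_ay) ** 2)
    for _ in range(n_ribs):
        zc = _uniform(rng, ribs["z"]) * extent
        scale = _uniform(rng, ribs["scale"])
        band = _uniform(rng, ribs["band"])
        th0 = rng.uniform(-math.pi, math.pi)
        arc = math.radians(_uniform(rng, ribs["arc_deg"]))
        thick = _uniform(rng, ribs["thickness_vox"]) * s
        dth = np.mod(ang - th0 + math.pi, 2 * math.pi) - math.pi
        rib = (
            (np.abs(rho - scale) < band)
            & (np.abs(z - zc) < thick)
            & (np.abs(dth) < arc / 2.0)
        )
        bone_mask |= rib
    bone_mask &= body
    vol[bone_mask] = hu["bone"]
    labels[bone_mask] = LABELS["bone"]

    if spec.noise_hu > 0:
        vol += rng.normal(0.0, spec.noise_hu, size=vol.shape)

    ph = LabeledPhantom(
        hu_volume=vol.astype(np.float32), labels=labels, spacing_mm=s
    )
    ph.validate()
    return ph


def save_phantom(ph: LabeledPhantom, image_path: Path, labels_path: Path) -> None:
    affine = np.diag([ph.spacing_mm, ph.spacing_mm, ph.spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(ph.hu_volume.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(ph.labels.astype(np.uint8), affine), str(labels_path))


def load_phantom(image_path: Path, labels_path: Path | None = None) -> LabeledPhantom:
    img = nib.load(str(image_path))
    spacing = float(img.header.get_zooms()[0])
    hu = np.asarray(img.dataobj, dtype=np.float32)
    labels = (
        np.asarray(nib.load(str(labels_path)).dataobj, dtype=np.uint8)
        if labels_path is not None
        else np.zeros(hu.shape, dtype=np.uint8)
    )
    return LabeledPhantom(hu_volume=hu, labels=labels, spacing_mm=spacing)


def make_dataset(spec: PhantomSpec, n: int, out_dir: Path) -> Path:
    """Write ``n`` phantoms as paired NIfTI files plus a manifest.

    Re-running with identical arguments reproduces identical files (volumes
    are written uncompressed).  Returns the manifest path; the manifest lists
    one (image, labels, index) row per phantom and records seed and spec hash
    in comment lines.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1 (got {n})")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        ph = sample_phantom(spec, i)
        img_p = out_dir / f"phantom_{i:04d}_image.nii"
        lab_p = out_dir / f"phantom_{i:04d}_labels.nii"
        save_phantom(ph, img_p, lab_p)
        rows.append((img_p.name, lab_p.name, i))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write(f"# seed\t{spec.seed}\n")
        fh.write(f"# spec_sha256\t{spec.sha256()}\n")
        fh.write(f"# grid_size\t{spec.grid_size}\n")
        fh.write(f"# voxel_spacing_mm\t{spec.voxel_spacing_mm}\n")
        fh.write("path_image\tpath_labels\tindex\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")
    return manifest


def read_manifest(manifest_path: Path) -> dict:
    """Parse a dataset manifest into header metadata and file-pair entries."""
    meta, entries = {}, []
    base = Path(manifest_path).parent
    with open(manifest_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, val = line[1:].strip().split("\t")
                meta[key] = val
            elif line and not line.startswith("path_image"):
                img, lab, idx = line.split("\t")
                entries.append({"image": base / img, "labels": base / lab, "index": int(idx)})
    return {"meta": meta, "entries": entries}
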