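"""Training objectives for the reconstruction GAN.

Least-squares adversarial terms score patch maps against target labels 1
(real) and 0 (fake).  Four consistency terms shape the generator output y' =
G(x) toward the reference volume y: voxel-wise MSE, projection-space MSE in
the AP and LAT views, a Dice term computed through a frozen organ segmenter
(anatomy guidance), and a perceptual term that slices both volumes along the
vertical axis and compares multi-scale features of a fixed 2D extractor over
the first four pyramid levels.  The total generator objective is

    L_G = lambda_gen * L_gen + lambda_r * L_r + lambda_proj * L_proj
          + lambda_s * L_s + lambda_p * L_p

with lambda_gen = 0.1, lambda_r = 10, lambda_proj = 10 fixed and the
anatomy weights defaulting to lambda_s = 2.0, lambda_p = 0.5; setting
lambda_s = lambda_p = 0 recovers the plain voxel-similarity baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse as _sparse

from topoct import nn
from topoct.geometry import FanBeamGeometry, get_projector
from topoct.network import DiscriminatorOutput, SegNet

DICE_EPS = 1e-6
FOREGROUND_CLASSES = (1, 2, 3)  # lung, liver, bone


@dataclass(frozen=True)
class LossWeights:
    """The lambda vector weighting the generator objective."""

    lambda_gen: float = 0.1
    lambda_r: float = 10.0
    lambda_proj: float = 10.0
    lambda_s: float = 2.0
    lambda_p: float = 0.5

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative (got {v})")


def _scores(x) -> nn.Tensor:
    if isinstance(x, DiscriminatorOutput):
        x = x.score_map
    if not isinstance(x, nn.Tensor):
        x = nn.Tensor(np.asarray(x, dtype=np.float64))
    if not np.all(np.isfinite(x.data)):
        raise ValueError("non-finite discriminator scores")
    return x


def _volume(x, name: str = "volume") -> nn.Tensor:
    """Coerce to a (N, 1, X, Y, Z) tensor; raw 3D arrays are wrapped."""
    if isinstance(x, nn.Tensor):
        t = x
    else:
        arr = np.asarray(x)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float32)
        t = nn.Tensor(arr)
    if t.ndim == 3:
        t = t.reshape((1, 1) + t.shape)
    if t.ndim != 5:
        raise ValueError(f"{name} must be 3D or (N, 1, X, Y, Z), got shape {t.shape}")
    return t


def loss_discriminator(d_real, d_fake) -> nn.Tensor:
    """LSGAN discriminator loss: 1/2 (E[(D(y)-1)^2] + E[D(y')^2])."""
    r, f = _scores(d_real), _scores(d_fake)
    return 0.5 * (((r - 1.0) ** 2).mean() + (f**2).mean())


def loss_generator_adv(d_fake) -> nn.Tensor:
    """LSGAN generator adversarial loss: E[(D(G(x))-1)^2]."""
    return ((_scores(d_fake) - 1.0) ** 2).mean()


def loss_reconstruction(y_pred, y_true) -> nn.Tensor:
    """Voxel-wise mean squared error between volumes."""
    p, t = _volume(y_pred, "y_pred"), _volume(y_true, "y_true")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    d = p - t.detach()
    return (d * d).mean()


_PROJ32: dict[tuple, _sparse.csr_matrix] = {}


def _projector32(geom: FanBeamGeometry) -> _sparse.csr_matrix:
    key = (geom.sdd_mm, geom.sid_mm, geom.n_detector, geom.detector_spacing_mm,
           geom.n_image, geom.voxel_spacing_mm, geom.view.value)
    if key not in _PROJ32:
        # work in average-attenuation units (line integral / FOV extent) so
        # projection-space errors are commensurate with voxel-space errors
        # and the lambda weights keep their intended balance
        _PROJ32[key] = (get_projector(geom).matrix * (1.0 / geom.fov_mm)).astype(
            np.float32
        )
    return _PROJ32[key]


def loss_projection(
    y_pred, y_true, geom_ap: FanBeamGeometry, geom_lat: FanBeamGeometry
) -> nn.Tensor:
    """Projection-consistency loss: mean squared AP and LAT topogram error."""
    p, t = _volume(y_pred, "y_pred"), _volume(y_true, "y_true")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if geom_ap.n_image != p.shape[2] or geom_lat.n_image != p.shape[2]:
        raise ValueError("geometry n_image does not match volume size")
    total = None
    for geom in (geom_ap, geom_lat):
        mat = _projector32(geom)
        d = nn.fan_project(p, mat) - nn.fan_project(t.detach(), mat)
        term = (d * d).mean()
        total = term if total is None else total + term
    return 0.5 * total


def soft_dice_loss(
    probs: nn.Tensor,
    reference: nn.Tensor,
    classes=FOREGROUND_CLASSES,
    eps: float = DICE_EPS,
) -> nn.Tensor:
    """Mean soft Dice loss over ``classes``: 1 - 2|A.B| / (|A| + |B| + eps).

    ``probs`` and ``reference`` are (N, C, ...) probability (or one-hot)
    volumes; the epsilon keeps empty classes finite.
    """
    terms = None
    for c in classes:
        a = probs[:, c]
        b = reference[:, c]
        inter = (a * b).sum()
        denom = a.sum() + b.sum() + eps
        term = 1.0 - 2.0 * inter / denom
        terms = term if terms is None else terms + term
    return terms * (1.0 / len(classes))


def loss_segmentation(y_pred, y_true, segnet: SegNet) -> nn.Tensor:
    """Anatomy-guidance Dice loss through the frozen segmenter.

    Both volumes are passed through the segmenter; the soft per-class Dice
    loss between the two probability maps is averaged over the three
    foreground organs.  Gradients flow into ``y_pred`` only — the reference
    branch is detached and the segmenter parameters are expected frozen.
    """
    if segnet.config.n_classes != 4:
        raise ValueError("segmenter must have 4 classes (background + 3 organs)")
    p, t = _volume(y_pred, "y_pred"), _volume(y_true, "y_true")
    y_m = segnet(t.detach())
    yp_m = segnet(p)
    return soft_dice_loss(yp_m, y_m.detach())


class FeatureExtractor(nn.Module):
    """Fixed multi-scale 2D feature pyramid for the perceptual loss.

    Four levels: a stride-1 stem then three stride-2 stages, each
    conv + ReLU.  Inputs are 2D slices replicated to 3 channels.  Weights are
    immutable during training (seeded random by default; a pretrained-weight
    array file can be loaded instead via :meth:`from_arrays`).
    """

    N_LEVELS_USED = 4

    def __init__(self, base_channels: int = 8, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(77,)))
        c = base_channels
        self.stages = [
            nn.Conv(2, 3, c, k=3, rng=rng),
            nn.Conv(2, c, 2 * c, k=3, stride=2, rng=rng),
            nn.Conv(2, 2 * c, 4 * c, k=3, stride=2, rng=rng),
            nn.Conv(2, 4 * c, 8 * c, k=3, stride=2, rng=rng),
        ]
        self.freeze()

    @classmethod
    def from_arrays(cls, arrays: list[np.ndarray]) -> "FeatureExtractor":
        ex = cls()
        ex.load_state_arrays(arrays)
        ex.freeze()
        return ex

    def forward(self, x: nn.Tensor) -> list[nn.Tensor]:
        feats = []
        h = x
        for stage in self.stages:
            h = nn.relu(stage(h))
            feats.append(h)
        return feats[: self.N_LEVELS_USED]


def loss_perceptual(
    y_pred, y_true, extractor: FeatureExtractor, metric: str = "l2"
) -> nn.Tensor:
    """3D perceptual loss aggregated from vertical (axial) slices.

    Both volumes are sliced perpendicular to z; each slice is replicated to
    3 channels and embedded by the fixed extractor.  At each of the first
    four feature levels the feature difference is summed over channels and
    averaged over slices and positions; levels are summed.  ``metric`` is
    "l2" (squared difference, default) or "l1" (absolute difference).
    """
    if metric not in ("l2", "l1"):
        raise ValueError(f"metric must be 'l2' or 'l1' (got {metric!r})")
    p, t = _volume(y_pred, "y_pred"), _volume(y_true, "y_true")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    n, _, X, Y, Z = p.shape

    def slices(v: nn.Tensor) -> nn.Tensor:
        # (N, 1, X, Y, Z) -> slice batch (N*Z, 3, X, Y)
        s = v.transpose((0, 4, 1, 2, 3)).reshape((n * Z, 1, X, Y))
        return nn.concat([s, s, s], axis=1)

    fp = extractor(slices(p))
    ft = extractor(slices(t.detach()))
    total = None
    for a, b in zip(fp, ft):
        d = a - b.detach()
        if metric == "l2":
            term = (d * d).sum(axis=1).mean()
        else:
            term = nn.abs_(d).sum(axis=1).mean()
        total = term if total is None else total + term
    return total


def total_generator_loss(components: dict, w: LossWeights) -> nn.Tensor:
    """Aggregate the weighted generator objective from its named components.

    ``components`` maps the keys gen, r, proj, s, p to scalar losses
    (tensors or floats); terms with zero weight may be omitted.
    """
    pairs = [
        ("gen", w.lambda_gen),
        ("r", w.lambda_r),
        ("proj", w.lambda_proj),
        ("s", w.lambda_s),
        ("p", w.lambda_p),
    ]
    total = None
    for key, weight in pairs:
        if weight == 0 and key not in components:
            continue
        if key not in components:
            raise ValueError(f"missing loss component '{key}' with weight {weight}")
        c = components[key]
        if not isinstance(c, nn.Tensor):
            c = nn.Tensor(np.asarray(c, dtype=np.float64))
        if not np.all(np.isfinite(c.data)):
            raise ValueError(f"non-finite loss component '{key}'")
        term = weight * c
        total = term if total is None else total + term
    return total if total is not None else nn.Tensor(np.array(0.0))
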