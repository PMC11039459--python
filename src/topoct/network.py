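"""Network architectures: generator G, patch discriminator D, and segmenter.

The generator maps an (AP, LAT) topogram pair to a CT volume in [0, 1].  Each
projection is encoded by its own 2D U-Net pathway; at every decoder level the
2D feature maps are lifted into the 3D grid by the geometry module's sparse
backprojection matrix for that resolution (no learned projection), the two
lifted stacks are fused by elementwise addition, and a single 3D decoder
aggregates the fused pyramid into the output volume (sigmoid activation).
The LAT pathway's system matrix is built directly in the common frame
(source on the +x axis), so both lifted stacks share one coordinate system.

The discriminator is a 3D patch classifier (three stride-2 blocks and a
1-channel head, one score per receptive-field patch, no global pooling).
The segmenter is a 3D U-Net with five downsampling levels and four output
classes (background, lung, liver, bone) under a voxel-wise softmax; during
adversarial training it is frozen and acts purely as a loss feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as _sparse

from topoct import nn
from topoct.geometry import FanBeamGeometry, View, get_system_matrix

N_CLASSES = 4  # background, lung, liver, bone


def _channels(base: int, level: int, cap_factor: int = 8) -> int:
    return min(base * 2**level, base * cap_factor)


@dataclass(frozen=True)
class GeneratorConfig:
    """Topology and geometry of the generator."""

    grid_size: int = 128
    n_levels: int = 4
    base_channels: int = 64
    geometry: FanBeamGeometry = field(default_factory=FanBeamGeometry)
    output_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        down = 2 ** (self.n_levels - 1)
        if self.grid_size % down:
            raise ValueError(
                f"grid_size {self.grid_size} not divisible by 2^(n_levels-1)={down}"
            )
        if self.geometry.n_image != self.grid_size:
            raise ValueError(
                f"geometry n_image {self.geometry.n_image} != grid_size {self.grid_size}"
            )
        if self.geometry.n_detector % down:
            raise ValueError(
                f"n_detector {self.geometry.n_detector} not divisible by {down}"
            )
        if self.output_activation != "sigmoid":
            raise ValueError("only sigmoid output activation is supported")


@dataclass(frozen=True)
class SegNetConfig:
    """Topology of the frozen organ segmenter (five downsampling levels)."""

    grid_size: int = 128
    base_channels: int = 16
    n_levels: int = 5
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.n_levels != 5:
            raise ValueError("segmenter uses exactly five downsampling levels")
        if self.grid_size % 2**self.n_levels:
            raise ValueError(
                f"grid_size {self.grid_size} not divisible by 2^{self.n_levels}"
            )
        if self.n_classes != N_CLASSES:
            raise ValueError(f"segmenter must have {N_CLASSES} classes")


@dataclass(frozen=True)
class DiscriminatorOutput:
    """Patch-score map of the discriminator: one score per receptive patch."""

    score_map: np.ndarray | nn.Tensor

    def __post_init__(self) -> None:
        data = self.score_map.data if isinstance(self.score_map, nn.Tensor) else self.score_map
        if not np.all(np.isfinite(data)):
            raise ValueError("discriminator produced non-finite scores")


def _block(dims, cin, cout, rng, stride=1, slope=None, k=3):
    act = nn.relu if slope is None else (lambda x: nn.leaky_relu(x, slope))
    return nn.Sequential(
        nn.Conv(dims, cin, cout, k=k, stride=stride, pad=(k - 1) // 2, rng=rng),
        nn.InstanceNorm(cout),
        nn.Lambda(act),
    )


class _Pathway2D(nn.Module):
    """2D U-Net encoder-decoder producing one feature map per decoder level."""

    def __init__(self, n_levels: int, base: int, rng):
        self.n_levels = n_levels
        self.enc0 = _block(2, 1, _channels(base, 0), rng)
        self.downs = [
            _block(2, _channels(base, l - 1), _channels(base, l), rng, stride=2)
            for l in range(1, n_levels)
        ]
        self.decs = [
            _block(2, _channels(base, l + 1) + _channels(base, l), _channels(base, l), rng)
            for l in range(n_levels - 1)
        ]

    def forward(self, x: nn.Tensor) -> list[nn.Tensor]:
        feats = [self.enc0(x)]
        for down in self.downs:
            feats.append(down(feats[-1]))
        decoded = [None] * self.n_levels
        decoded[-1] = feats[-1]
        for l in range(self.n_levels - 2, -1, -1):
            up = nn.upsample_nearest(decoded[l + 1], 2)
            decoded[l] = self.decs[l](nn.concat([up, feats[l]], axis=1))
        return decoded  # finest first


class Generator(nn.Module):
    """Dual-pathway 2D encoder, per-level sparse lifting, fused 3D decoder."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.config = config
        base = config.base_channels
        self.path_ap = _Pathway2D(config.n_levels, base, rng)
        self.path_lat = _Pathway2D(config.n_levels, base, rng)
        self.bottleneck3d = _block(
            3, _channels(base, config.n_levels - 1), _channels(base, config.n_levels - 1), rng
        )
        self.dec3d = [
            _block(3, _channels(base, l + 1) + _channels(base, l), _channels(base, l), rng)
            for l in range(config.n_levels - 1)
        ]
        self.head = nn.Conv(3, _channels(base, 0), 1, k=3, rng=rng)
        # per-(level, view) lifting matrices from the geometry module,
        # cached in float32 for network use
        self._lift: dict[tuple[int, str], _sparse.csr_matrix] = {}
        for l in range(config.n_levels):
            for view in (View.AP, View.LAT):
                geom = config.geometry.with_view(view).downsampled(2**l)
                self._lift[(l, view.value)] = get_system_matrix(geom).weights.astype(
                    np.float32
                )

    def forward(self, proj_ap: nn.Tensor, proj_lat: nn.Tensor) -> nn.Tensor:
        cfg = self.config
        for name, p in (("AP", proj_ap), ("LAT", proj_lat)):
            if p.shape[2] != cfg.geometry.n_detector or p.shape[3] != cfg.grid_size:
                raise ValueError(
                    f"{name} projection shape {p.shape[2:]} does not match geometry "
                    f"({cfg.geometry.n_detector}, {cfg.grid_size})"
                )
        feats_ap = self.path_ap(proj_ap)
        feats_lat = self.path_lat(proj_lat)
        fused = []
        for l in range(cfg.n_levels):
            n_l = cfg.grid_size // 2**l
            lifted_ap = nn.sparse_lift(feats_ap[l], self._lift[(l, "AP")], n_l)
            lifted_lat = nn.sparse_lift(feats_lat[l], self._lift[(l, "LAT")], n_l)
            fused.append(lifted_ap + lifted_lat)
        h = self.bottleneck3d(fused[-1])
        for l in range(cfg.n_levels - 2, -1, -1):
            h = nn.upsample_nearest(h, 2)
            h = self.dec3d[l](nn.concat([h, fused[l]], axis=1))
        return nn.sigmoid(self.head(h))


class Discriminator(nn.Module):
    """3D convolutional patch classifier (pix2pix-style, LSGAN scores)."""

    def __init__(self, grid_size: int, base_channels: int, rng: np.random.Generator):
        self.grid_size = grid_size
        c = base_channels
        self.net = nn.Sequential(
            nn.Conv(3, 1, c, k=4, stride=2, pad=1, rng=rng),
            nn.Lambda(lambda x: nn.leaky_relu(x, 0.2)),
            _block(3, c, 2 * c, rng, stride=2, slope=0.2, k=4),
            _block(3, 2 * c, 4 * c, rng, stride=2, slope=0.2, k=4),
            nn.Conv(3, 4 * c, 1, k=3, rng=rng),
        )

    def forward(self, volume: nn.Tensor) -> DiscriminatorOutput:
        if volume.shape[2:] != (self.grid_size,) * 3:
            raise ValueError(
                f"discriminator expects {(self.grid_size,)*3} volumes, got {volume.shape[2:]}"
            )
        return DiscriminatorOutput(score_map=self.net(volume))


class SegNet(nn.Module):
    """3D U-Net organ segmenter with five downsampling levels and softmax head."""

    def __init__(self, config: SegNetConfig, rng: np.random.Generator):
        self.config = config
        base = config.base_channels
        L = config.n_levels
        self.enc0 = _block(3, 1, _channels(base, 0), rng)
        self.downs = [
            _block(3, _channels(base, l - 1), _channels(base, l), rng, stride=2)
            for l in range(1, L + 1)
        ]
        self.decs = [
            _block(3, _channels(base, l + 1) + _channels(base, l), _channels(base, l), rng)
            for l in range(L)
        ]
        self.head = nn.Conv(3, _channels(base, 0), config.n_classes, k=1, pad=0, rng=rng)

    def forward(self, volume: nn.Tensor) -> nn.Tensor:
        """Per-class probability volume (N, 4, g, g, g), channels sum to 1."""
        if volume.shape[2:] != (self.config.grid_size,) * 3:
            raise ValueError(
                f"segmenter expects {(self.config.grid_size,)*3} volumes, "
                f"got {volume.shape[2:]}"
            )
        feats = [self.enc0(volume)]
        for down in self.downs:
            feats.append(down(feats[-1]))
        h = feats[-1]
        for l in range(self.config.n_levels - 1, -1, -1):
            h = nn.upsample_nearest(h, 2)
            h = self.decs[l](nn.concat([h, feats[l]], axis=1))
        return nn.softmax(self.head(h), axis=1)


def segment_labels(segnet: SegNet, volume: np.ndarray) -> np.ndarray:
    """Hard organ labels: argmax of the segmenter probabilities."""
    t = nn.Tensor(volume[None, None].astype(np.float32))
    probs = segnet(t).data[0]
    return np.argmax(probs, axis=0).astype(np.uint8)
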