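"""Loss closed forms, oracles, and monotonicity properties."""

import numpy as np
import pytest

from topoct import nn
from topoct.geometry import FanBeamGeometry, View
from topoct.losses import (
    FeatureExtractor,
    LossWeights,
    loss_discriminator,
    loss_generator_adv,
    loss_perceptual,
    loss_projection,
    loss_reconstruction,
    loss_segmentation,
    soft_dice_loss,
    total_generator_loss,
)
from topoct.network import SegNet, SegNetConfig
from topoct.phantom import PhantomSpec, sample_phantom
from topoct.preprocess import normalize_hu


class TestAdversarial:
    @pytest.mark.parametrize(
        "real,fake,expected",
        [(1.0, 0.0, 0.0), (0.5, 0.5, 0.25), (0.0, 1.0, 1.0)],
    )
    def test_discriminator_closed_forms(self, real, fake, expected):
        shape = (1, 1, 4, 4, 4)
        val = loss_discriminator(np.full(shape, real), np.full(shape, fake)).item()
        assert val == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("fake,expected", [(1.0, 0.0), (0.5, 0.25), (0.0, 1.0)])
    def test_generator_closed_forms(self, fake, expected):
        val = loss_generator_adv(np.full((1, 1, 2, 2, 2), fake)).item()
        assert val == pytest.approx(expected, abs=1e-12)

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            loss_generator_adv(np.array([[np.nan]]))


class TestReconstruction:
    def test_zero_on_identical_and_constant_offset(self):
        v = np.random.default_rng(0).random((8, 8, 8))
        assert loss_reconstruction(v, v).item() == 0.0
        assert loss_reconstruction(v + 0.1, v).item() == pytest.approx(0.01)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        acc = 0.0
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    acc += (a[i, j, k] - b[i, j, k]) ** 2
        assert loss_reconstruction(a, b).item() == pytest.approx(acc / 8**3, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            loss_reconstruction(np.zeros((4, 4, 4)), np.zeros((8, 8, 8)))


@pytest.fixture(scope="module")
def geoms():
    g = FanBeamGeometry(n_detector=32, n_image=32, voxel_spacing_mm=2.5)
    return g.with_view(View.AP), g.with_view(View.LAT)


class TestProjectionLoss:
    def test_zero_on_identical_and_swap_symmetric(self, geoms):
        rng = np.random.default_rng(2)
        a, b = rng.random((32, 32, 32)), rng.random((32, 32, 32))
        assert loss_projection(a, a, *geoms).item() == pytest.approx(0.0, abs=1e-10)
        l1 = loss_projection(a, b, *geoms).item()
        l2 = loss_projection(b, a, *geoms).item()
        assert l1 == pytest.approx(l2, rel=1e-6)

    def test_sensitive_to_lung_attenuation(self, geoms):
        spec = PhantomSpec(grid_size=32, seed=5)
        ph = sample_phantom(spec, 0)
        v1 = normalize_hu(ph.hu_volume).values
        shifted = ph.hu_volume.copy()
        shifted[ph.labels == 1] += 150.0
        v2 = normalize_hu(shifted).values
        assert loss_projection(v2, v1, *geoms).item() > 0


class TestDice:
    def _one_hot(self, labels, n=4):
        out = np.zeros((1, n) + labels.shape, dtype=np.float64)
        for c in range(n):
            out[0, c] = labels == c
        return nn.Tensor(out)

    def test_identical_masks_zero(self):
        labels = np.random.default_rng(3).integers(0, 4, size=(6, 6, 6))
        oh = self._one_hot(labels)
        assert soft_dice_loss(oh, oh).item() == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_masks_one(self):
        a = np.zeros((4, 4, 4), dtype=int)
        b = np.zeros((4, 4, 4), dtype=int)
        a[:2], b[2:] = 1, 1
        a[0, 0, 0], b[3, 3, 3] = 2, 2
        a[1, 0, 0], b[2, 3, 3] = 3, 3
        val = soft_dice_loss(self._one_hot(a), self._one_hot(b)).item()
        assert val == pytest.approx(1.0, abs=1e-5)

    def test_half_overlap_closed_form(self):
        """|A|=|B|=100 with overlap 50 in one class, others identical: mean 1/6."""
        a = np.zeros(400, dtype=int)
        b = np.zeros(400, dtype=int)
        a[0:100], b[50:150] = 1, 1
        a[200:250], b[200:250] = 2, 2
        a[300:350], b[300:350] = 3, 3
        val = soft_dice_loss(self._one_hot(a), self._one_hot(b)).item()
        assert val == pytest.approx(1.0 / 6.0, abs=1e-5)

    def test_segmentation_loss_through_frozen_segnet(self):
        """Identical inputs give the self-overlap Dice; gradients reach only y_pred.

        The Dice expression is exactly zero for identical hard masks (checked
        above); for identical soft probability maps it equals the map's
        self-overlap deficit, which must match a direct evaluation.
        """
        segnet = SegNet(SegNetConfig(grid_size=32, base_channels=2), np.random.default_rng(4))
        segnet.freeze()
        before = [a.copy() for a in segnet.state_arrays()]
        v = np.random.default_rng(5).random((32, 32, 32)).astype(np.float32)
        probs = segnet(nn.Tensor(v[None, None]))
        expected = soft_dice_loss(probs, probs.detach()).item()
        assert loss_segmentation(v, v, segnet).item() == pytest.approx(expected, abs=1e-6)
        y = nn.Tensor(v[None, None], requires_grad=True)
        loss_segmentation(y, v, segnet).backward()
        assert y.grad is not None and np.abs(y.grad).max() > 0
        for p, b in zip(segnet.state_arrays(), before):
            np.testing.assert_array_equal(p, b)

    def test_wrong_class_count_rejected(self):
        class FakeCfg:
            n_classes = 5

        class FakeSeg:
            config = FakeCfg()

        with pytest.raises(ValueError, match="4 classes"):
            loss_segmentation(np.zeros((8, 8, 8)), np.zeros((8, 8, 8)), FakeSeg())


class _IdentityExtractor:
    """Single-level identity pyramid used as an analytic oracle."""

    def __call__(self, x):
        return [x]


class TestPerceptual:
    def test_zero_on_identical_and_nonnegative(self):
        rng = np.random.default_rng(6)
        v = rng.random((16, 16, 16)).astype(np.float32)
        ex = FeatureExtractor(base_channels=2, seed=0)
        assert loss_perceptual(v, v, ex).item() == pytest.approx(0.0, abs=1e-10)
        w = rng.random((16, 16, 16)).astype(np.float32)
        assert loss_perceptual(v, w, ex).item() >= 0

    def test_identity_extractor_equals_3x_mse(self):
        rng = np.random.default_rng(7)
        a, b = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        lp = loss_perceptual(a, b, _IdentityExtractor()).item()
        lr = loss_reconstruction(a, b).item()
        assert lp == pytest.approx(3.0 * lr, rel=1e-6)

    def test_l1_option(self):
        rng = np.random.default_rng(8)
        a, b = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        l1 = loss_perceptual(a, b, _IdentityExtractor(), metric="l1").item()
        assert l1 == pytest.approx(3.0 * np.abs(a - b).mean(), rel=1e-6)
        with pytest.raises(ValueError, match="metric"):
            loss_perceptual(a, b, _IdentityExtractor(), metric="huber")

    def test_extractor_is_frozen_and_deterministic(self):
        ex = FeatureExtractor(base_channels=2, seed=1)
        assert ex.trainable_parameters() == []  # frozen
        assert len(ex.parameters()) > 0  # but state remains inspectable
        x = nn.Tensor(np.random.default_rng(9).random((2, 3, 8, 8)).astype(np.float32))
        f1 = ex(x)
        f2 = ex(x)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.data, b.data)


class TestTotalLoss:
    def test_paper_weights_with_unit_components(self):
        w = LossWeights()
        comps = {k: 1.0 for k in ("gen", "r", "proj", "s", "p")}
        assert total_generator_loss(comps, w).item() == pytest.approx(22.6)

    def test_baseline_reduction(self):
        w = LossWeights(lambda_s=0.0, lambda_p=0.0)
        comps = {"gen": 1.0, "r": 1.0, "proj": 1.0}
        assert total_generator_loss(comps, w).item() == pytest.approx(20.1)

    def test_zero_components(self):
        comps = {k: 0.0 for k in ("gen", "r", "proj", "s", "p")}
        assert total_generator_loss(comps, LossWeights()).item() == 0.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            LossWeights(lambda_s=-1.0)


class TestMonotonicity:
    def test_losses_increase_with_perturbation(self):
        """Every non-adversarial loss grows monotonically with noise amplitude."""
        spec = PhantomSpec(grid_size=32, seed=6)
        y = normalize_hu(sample_phantom(spec, 0).hu_volume).values.astype(np.float32)
        noise = np.random.default_rng(10).standard_normal(y.shape).astype(np.float32)
        g = FanBeamGeometry(n_detector=32, n_image=32, voxel_spacing_mm=2.5)
        segnet = SegNet(SegNetConfig(grid_size=32, base_channels=2), np.random.default_rng(11))
        segnet.freeze()
        ex = FeatureExtractor(base_channels=2, seed=2)
        curves = {"r": [], "proj": [], "s": [], "p": []}
        for delta in (0.0, 0.05, 0.1):
            yp = np.clip(y + delta * noise, 0, 1)
            curves["r"].append(loss_reconstruction(yp, y).item())
            curves["proj"].append(
                loss_projection(yp, y, g.with_view(View.AP), g.with_view(View.LAT)).item()
            )
            curves["s"].append(loss_segmentation(yp, y, segnet).item())
            curves["p"].append(loss_perceptual(yp, y, ex).item())
        for name, vals in curves.items():
            assert vals[0] < vals[1] < vals[2], f"{name} not monotone: {vals}"
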