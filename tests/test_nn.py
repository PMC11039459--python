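"""Autodiff engine: finite-difference gradient checks and optimizer behavior."""

import numpy as np
import pytest
from scipy import sparse

from topoct import nn


def numerical_grad(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of scalar-valued f at x (float64)."""
    g = np.zeros_like(x)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g


def check_input_grad(op, x0: np.ndarray, rtol=1e-5, atol=1e-7):
    """Compare autodiff input gradient of sum(op(x)) with finite differences."""
    x = nn.Tensor(x0.copy(), requires_grad=True)
    y = op(x)
    y.sum().backward()
    num = numerical_grad(lambda a: float(op(nn.Tensor(a)).data.sum()), x0.copy())
    np.testing.assert_allclose(x.grad, num, rtol=rtol, atol=atol)


class TestConvGradients:
    @pytest.mark.parametrize("dims,stride,size", [(2, 1, 6), (2, 2, 6), (2, 2, 7), (3, 1, 5), (3, 2, 6)])
    def test_conv_input_gradient(self, dims, stride, size):
        rng = np.random.default_rng(0)
        cin, cout, k = 2, 3, 3
        w = nn.Tensor(rng.standard_normal((cout, cin) + (k,) * dims))
        x0 = rng.standard_normal((2, cin) + (size,) * dims)
        check_input_grad(lambda x: nn.conv_nd(x, w, None, stride=stride, pad=1), x0)

    def test_conv_weight_and_bias_gradient(self):
        rng = np.random.default_rng(1)
        x0 = rng.standard_normal((1, 2, 5, 5))
        w0 = rng.standard_normal((3, 2, 3, 3))
        b0 = rng.standard_normal(3)
        x = nn.Tensor(x0)
        w = nn.Tensor(w0.copy(), requires_grad=True)
        b = nn.Tensor(b0.copy(), requires_grad=True)
        nn.conv_nd(x, w, b, stride=1, pad=1).sum().backward()
        num_w = numerical_grad(
            lambda a: float(nn.conv_nd(x, nn.Tensor(a), nn.Tensor(b0), 1, 1).data.sum()),
            w0.copy(),
        )
        np.testing.assert_allclose(w.grad, num_w, rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(b.grad, np.full(3, 25.0), rtol=1e-10)

    def test_conv4_stride2(self):
        """The k=4, stride-2 discriminator block halves even sizes exactly."""
        rng = np.random.default_rng(2)
        w = nn.Tensor(rng.standard_normal((1, 1, 4, 4, 4)))
        x0 = rng.standard_normal((1, 1, 8, 8, 8))
        y = nn.conv_nd(nn.Tensor(x0), w, None, stride=2, pad=1)
        assert y.shape == (1, 1, 4, 4, 4)
        check_input_grad(lambda x: nn.conv_nd(x, w, None, stride=2, pad=1), x0)


class TestOtherOps:
    def test_instance_norm_gradient_and_stats(self):
        rng = np.random.default_rng(3)
        layer = nn.InstanceNorm(2)
        x0 = rng.standard_normal((2, 2, 4, 4))
        y = layer(nn.Tensor(x0))
        np.testing.assert_allclose(y.data.mean(axis=(2, 3)), 0.0, atol=1e-6)
        np.testing.assert_allclose(y.data.std(axis=(2, 3)), 1.0, atol=1e-2)
        check_input_grad(lambda x: layer(x) * layer(x), x0, rtol=1e-4, atol=1e-6)

    def test_softmax_sums_to_one_and_gradient(self):
        rng = np.random.default_rng(4)
        x0 = rng.standard_normal((1, 4, 3, 3))
        y = nn.softmax(nn.Tensor(x0), axis=1)
        np.testing.assert_allclose(y.data.sum(axis=1), 1.0, rtol=1e-12)
        check_input_grad(lambda x: nn.softmax(x, axis=1) ** 2, x0)

    def test_upsample_nearest_round_trip_gradient(self):
        rng = np.random.default_rng(5)
        x0 = rng.standard_normal((1, 2, 3, 3, 3))
        y = nn.upsample_nearest(nn.Tensor(x0), 2)
        assert y.shape == (1, 2, 6, 6, 6)
        check_input_grad(lambda x: nn.upsample_nearest(x, 2) ** 2, x0)

    def test_activations_gradients(self):
        rng = np.random.default_rng(6)
        x0 = rng.standard_normal((2, 3)) * 2
        for op in (nn.relu, lambda x: nn.leaky_relu(x, 0.2), nn.sigmoid, nn.abs_):
            check_input_grad(lambda x: op(x) * op(x), x0, atol=1e-6)

    def test_concat_gradient(self):
        rng = np.random.default_rng(7)
        a0 = rng.standard_normal((1, 2, 3, 3))
        b = nn.Tensor(rng.standard_normal((1, 3, 3, 3)))
        check_input_grad(lambda x: nn.concat([x, b], axis=1) ** 2, a0)


class TestSparseOps:
    def test_sparse_lift_gradient_is_transpose(self):
        rng = np.random.default_rng(8)
        n, d, c, z = 4, 5, 2, 3
        W = sparse.random(n * n, d, density=0.4, random_state=1, format="csr")
        x = nn.Tensor(rng.standard_normal((1, c, d, z)), requires_grad=True)
        y = nn.sparse_lift(x, W, n)
        assert y.shape == (1, c, n, n, z)
        g = rng.standard_normal(y.shape)
        y.backward(g)
        expected = np.empty_like(x.data)
        for ci in range(c):
            for zi in range(z):
                expected[0, ci, :, zi] = W.T @ g[0, ci, :, :, zi].reshape(-1)
        np.testing.assert_allclose(x.grad, expected, rtol=1e-10)

    def test_fan_project_adjoint_identity(self):
        rng = np.random.default_rng(9)
        n = 6
        P = sparse.random(8, n * n, density=0.3, random_state=2, format="csr")
        x = nn.Tensor(rng.standard_normal((1, 1, n, n, n)), requires_grad=True)
        y = nn.fan_project(x, P)
        p = rng.standard_normal(y.shape)
        y.backward(p)
        lhs = np.sum(y.data * p)
        rhs = np.sum(x.data * x.grad)
        assert abs(lhs - rhs) < 1e-10 * max(abs(lhs), abs(rhs))


class TestTraining:
    def test_adam_minimizes_quadratic(self):
        p = nn.Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = nn.Adam([p], lr=0.2)
        for _ in range(200):
            opt.zero_grad()
            loss = (p * p).sum()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-3

    def test_detach_blocks_gradient(self):
        x = nn.Tensor(np.array([2.0]), requires_grad=True)
        y = (x * 3.0).detach() * 2.0
        z = x * 1.0 + y
        z.sum().backward()
        np.testing.assert_allclose(x.grad, [1.0])

    def test_composite_network_gradcheck(self):
        """End-to-end check through conv + norm + activation + upsample."""
        rng = np.random.default_rng(10)
        net = nn.Sequential(
            nn.Conv(2, 1, 2, k=3, stride=2, rng=rng),
            nn.InstanceNorm(2),
            nn.Lambda(lambda x: nn.leaky_relu(x, 0.2)),
            nn.Lambda(lambda x: nn.upsample_nearest(x, 2)),
            nn.Conv(2, 2, 1, k=3, rng=rng),
        )
        for p in net.parameters():
            p.data = p.data.astype(np.float64)
        x0 = rng.standard_normal((1, 1, 6, 6))
        check_input_grad(lambda x: net(x) ** 2, x0, rtol=1e-4, atol=1e-6)

    def test_state_round_trip(self):
        rng = np.random.default_rng(11)
        net = nn.Sequential(nn.Conv(2, 1, 2, rng=rng), nn.Conv(2, 2, 1, rng=rng))
        arrays = [a.copy() for a in net.state_arrays()]
        net2 = nn.Sequential(
            nn.Conv(2, 1, 2, rng=np.random.default_rng(99)),
            nn.Conv(2, 2, 1, rng=np.random.default_rng(98)),
        )
        net2.load_state_arrays(arrays)
        x = nn.Tensor(rng.standard_normal((1, 1, 8, 8)).astype(np.float32))
        np.testing.assert_array_equal(net(x).data, net2(x).data)
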