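"""Fan-beam operator correctness: oracles, adjoints, and geometric invariants."""

import math

import numpy as np
import pytest
from scipy import sparse

from topoct.geometry import (
    FanBeamGeometry,
    View,
    adjoint_apply,
    build_projector,
    build_system_matrix,
    forward_project,
    get_system_matrix,
    lift_2d_to_3d,
)


from conftest import brute_force_system_matrix


@pytest.fixture(scope="module")
def paper_geom_small():
    return FanBeamGeometry(n_detector=16, n_image=16, voxel_spacing_mm=2.5)


class TestGeometryValidation:
    def test_rejects_inverted_distances(self):
        with pytest.raises(ValueError, match="sdd_mm > sid_mm"):
            FanBeamGeometry(sdd_mm=500.0, sid_mm=600.0)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"n_detector": 0}, "n_detector"),
            ({"voxel_spacing_mm": -1.0}, "voxel_spacing_mm"),
            ({"detector_spacing_mm": 0.1}, "cover"),
        ],
    )
    def test_rejects_invalid_fields(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            FanBeamGeometry(**kwargs)

    def test_derived_detector_spacing_covers_fov(self):
        g = FanBeamGeometry()
        assert g.n_detector * g.detector_spacing_mm == pytest.approx(
            g.n_image * g.voxel_spacing_mm * g.sdd_mm / g.sid_mm
        )


class TestSystemMatrix:
    def test_matches_brute_force_oracle(self, paper_geom_small):
        """Full sparse matrix equals an explicit-trigonometry dense build."""
        for view in (View.AP, View.LAT):
            geom = paper_geom_small.with_view(view)
            T = build_system_matrix(geom)
            dense = brute_force_system_matrix(geom)
            np.testing.assert_allclose(T.weights.toarray(), dense, atol=1e-9)

    def test_row_sums_and_sparsity(self):
        geom = FanBeamGeometry(n_detector=128, n_image=128, voxel_spacing_mm=2.5)
        T = build_system_matrix(geom)
        assert T.weights.min() >= 0
        rowsum = np.asarray(T.weights.sum(axis=1)).ravel()
        nnz_per_row = np.diff(T.weights.indptr)
        assert nnz_per_row.max() <= 2
        inside = nnz_per_row > 0
        assert inside.any() and (~inside).any()  # corners project off-detector
        np.testing.assert_allclose(rowsum[inside], 1.0, atol=1e-12)
        np.testing.assert_array_equal(rowsum[~inside], 0.0)

    def test_isocenter_pixel_hits_detector_center(self):
        # odd grid: central pixel sits exactly at the isocenter, and with an
        # even channel count its projection falls midway between the two
        # central channels, splitting the weight equally by symmetry
        geom = FanBeamGeometry(
            n_detector=16, n_image=15, voxel_spacing_mm=2.5, detector_spacing_mm=10.0
        )
        T = build_system_matrix(geom)
        row = T.weights[(15 * 15) // 2].toarray().ravel()
        np.testing.assert_allclose(row[7:9], [0.5, 0.5], atol=1e-12)
        assert row.sum() == pytest.approx(1.0)

    def test_deterministic(self, paper_geom_small):
        a = build_system_matrix(paper_geom_small).weights
        b = build_system_matrix(paper_geom_small).weights
        assert (a != b).nnz == 0


class TestForwardProjector:
    def test_linearity_and_zero(self, paper_geom_small):
        rng = np.random.default_rng(0)
        vol = rng.random((16, 16, 16))
        p1 = forward_project(vol, paper_geom_small).values
        p2 = forward_project(2.0 * vol, paper_geom_small).values
        assert np.all(forward_project(np.zeros((16, 16, 16)), paper_geom_small).values == 0)
        np.testing.assert_allclose(p2, 2.0 * p1, rtol=1e-9)

    def test_rejects_bad_volumes(self, paper_geom_small):
        with pytest.raises(ValueError, match="cubic"):
            forward_project(np.zeros((16, 16, 8)), paper_geom_small)
        with pytest.raises(ValueError, match="n_image"):
            forward_project(np.zeros((8, 8, 8)), paper_geom_small)

    def test_chord_length_oracle(self):
        """Fan-beam integrals of a centered uniform disk match 2*sqrt(r^2-d^2).

        The ray at fan angle gamma passes the isocenter at distance
        d = sid*sin(gamma); its integral through a unit disk of radius r is
        the chord length.  Checked within 2% away from tangent rays.
        """
        geom = FanBeamGeometry(n_detector=128, n_image=128, voxel_spacing_mm=1.0)
        n, s = geom.n_image, geom.voxel_spacing_mm
        r = 50.0
        x, y = geom.pixel_centers_mm()
        dist = np.sqrt(x**2 + y**2)
        # antialiased disk: linear partial-volume ramp across the boundary
        disk = np.clip((r - dist) / s + 0.5, 0.0, 1.0)
        vol = np.repeat(disk[:, :, None], n, axis=2)
        proj = forward_project(vol, geom).values[:, n // 2]
        u = geom.detector_channel_offsets_mm()
        gamma = np.arctan(u / geom.sdd_mm)
        d = geom.sid_mm * np.sin(gamma)
        mask = np.abs(d) < 0.9 * r
        expected = 2.0 * np.sqrt(r**2 - d[mask] ** 2)
        assert np.all(np.abs(proj[mask] - expected) / expected < 0.02)

    def test_rotational_consistency(self):
        """AP projection of a 90deg-rotated phantom equals the LAT projection."""
        geom = FanBeamGeometry(n_detector=32, n_image=32, voxel_spacing_mm=2.5)
        rng = np.random.default_rng(7)
        vol = np.zeros((32, 32, 32))
        # a few random off-center blobs
        x, y = geom.pixel_centers_mm()
        for _ in range(4):
            cx, cy = rng.uniform(-25, 25, size=2)
            blob = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * 8.0**2))
            vol += blob[:, :, None] * rng.random(32)
        lat = forward_project(vol, geom.with_view(View.LAT)).values
        ap_rot = forward_project(
            np.rot90(vol, 1, axes=(0, 1)).copy(), geom.with_view(View.AP)
        ).values
        assert np.abs(ap_rot - lat).mean() < 0.01 * lat.max()

    def test_backprojected_channel_lies_on_ray(self):
        """Backprojecting one unit channel lights up only pixels on its ray."""
        geom = FanBeamGeometry(n_detector=32, n_image=32, voxel_spacing_mm=2.5)
        T = build_system_matrix(geom)
        k = 20
        one = np.zeros(32)
        one[k] = 1.0
        img = T.apply(one)
        src = geom.source_position()
        e_u = geom.detector_axis()
        det_pt = src + geom.sdd_mm * geom.central_direction()
        det_pt = det_pt + geom.detector_channel_offsets_mm()[k] * e_u
        direction = det_pt - src
        direction /= np.linalg.norm(direction)
        normal = np.array([-direction[1], direction[0]])
        x, y = geom.pixel_centers_mm()
        # perpendicular distance of every nonzero pixel from the ray line
        perp = np.abs((x - src[0]) * normal[0] + (y - src[1]) * normal[1])
        lit = img > 1e-12
        assert lit.any()
        # interpolation spreads weight to channels adjacent to the ray: allow
        # a corridor of one channel pitch (demagnified to the pixel plane)
        corridor = geom.detector_spacing_mm * geom.sid_mm / geom.sdd_mm
        assert perp[lit].max() < corridor


class TestLifting:
    def test_shape_contract_and_zero(self):
        geom = FanBeamGeometry(n_detector=32, n_image=32, voxel_spacing_mm=2.5)
        T = get_system_matrix(geom)
        out = lift_2d_to_3d(np.zeros((8, 32, 32)), T)
        assert out.shape == (8, 32, 32, 32)
        assert np.all(out == 0)

    def test_detector_mismatch_rejected(self):
        geom = FanBeamGeometry(n_detector=32, n_image=32, voxel_spacing_mm=2.5)
        T = get_system_matrix(geom)
        with pytest.raises(ValueError, match="detector size"):
            lift_2d_to_3d(np.zeros((2, 16, 32)), T)

    def test_uniform_row_lifts_to_row_sum(self):
        """A row of ones lifts to 1.0 exactly where pixels see the detector."""
        geom = FanBeamGeometry(n_detector=16, n_image=16, voxel_spacing_mm=2.5)
        T = build_system_matrix(geom)
        lifted = lift_2d_to_3d(np.ones((1, 16, 3)), T)
        dense = brute_force_system_matrix(geom)
        inside = (dense.sum(axis=1) > 0).reshape(16, 16)
        for z in range(3):
            np.testing.assert_allclose(lifted[0, :, :, z][inside], 1.0, atol=1e-12)
            np.testing.assert_array_equal(lifted[0, :, :, z][~inside], 0.0)

    def test_z_rows_never_mix(self):
        geom = FanBeamGeometry(n_detector=16, n_image=16, voxel_spacing_mm=2.5)
        T = build_system_matrix(geom)
        feats = np.zeros((1, 16, 4))
        feats[0, :, 2] = 1.0
        lifted = lift_2d_to_3d(feats, T)
        assert np.all(lifted[0, :, :, [0, 1, 3]] == 0)
        assert lifted[0, :, :, 2].max() > 0


class TestAdjoints:
    @pytest.mark.parametrize("view", [View.AP, View.LAT])
    def test_projector_adjoint_identity(self, view):
        geom = FanBeamGeometry(n_detector=32, n_image=32, voxel_spacing_mm=2.5, view=view)
        P = build_projector(geom)
        rng = np.random.default_rng(42)
        x = rng.standard_normal((32, 32))
        p = rng.standard_normal(32)
        lhs = np.dot(P.apply(x), p)
        rhs = np.dot(x.reshape(-1), P.adjoint(p).reshape(-1))
        assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), abs(rhs))

    def test_system_matrix_adjoint_identity(self):
        geom = FanBeamGeometry(n_detector=32, n_image=32, voxel_spacing_mm=2.5)
        T = build_system_matrix(geom)
        rng = np.random.default_rng(43)
        d = rng.standard_normal(32)
        img = rng.standard_normal((32, 32))
        lhs = np.sum(T.apply(d) * img)
        rhs = np.dot(d, adjoint_apply(img, T))
        assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), abs(rhs))

    def test_zero_maps_to_zero(self):
        geom = FanBeamGeometry(n_detector=16, n_image=16, voxel_spacing_mm=2.5)
        P = build_projector(geom)
        assert np.all(adjoint_apply(np.zeros(16), P) == 0)

    def test_dense_adjoint_matches_sparse(self):
        geom = FanBeamGeometry(n_detector=16, n_image=16, voxel_spacing_mm=2.5)
        T = build_system_matrix(geom)
        dense = brute_force_system_matrix(geom)
        rng = np.random.default_rng(44)
        img = rng.standard_normal((16, 16))
        np.testing.assert_allclose(
            adjoint_apply(img, T), dense.T @ img.reshape(-1), atol=1e-9
        )

    def test_shape_mismatch_rejected(self):
        geom = FanBeamGeometry(n_detector=16, n_image=16, voxel_spacing_mm=2.5)
        P = build_projector(geom)
        with pytest.raises(ValueError):
            P.adjoint(np.zeros(8))
        with pytest.raises(ValueError):
            P.apply(np.zeros((8, 8)))
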