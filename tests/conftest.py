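"""Shared test utilities: independent geometric oracles."""

import math

import numpy as np


def brute_force_system_matrix(geom) -> np.ndarray:
    """Independent dense construction of the backprojection weights.

    Loops over every pixel, solves the ray-detector intersection as an
    explicit 2x2 linear system (no shared code with the implementation), and
    assigns linear-interpolation weights to the two neighboring channels.
    """
    n = geom.n_image
    s = geom.voxel_spacing_mm
    th = geom.view.angle_rad
    src = np.array([geom.sid_mm * math.sin(th), geom.sid_mm * math.cos(th)])
    e_u = np.array([math.cos(th), -math.sin(th)])
    det_center = src - geom.sdd_mm * np.array([math.sin(th), math.cos(th)])
    dense = np.zeros((n * n, geom.n_detector))
    for i in range(n):
        for j in range(n):
            p = np.array([(i + 0.5) * s - n * s / 2, (j + 0.5) * s - n * s / 2])
            # solve src + a*(p - src) == det_center + u*e_u for (a, u)
            A = np.column_stack([p - src, -e_u])
            try:
                a, u = np.linalg.solve(A, det_center - src)
            except np.linalg.LinAlgError:  # pragma: no cover
                continue
            if a <= 0:
                continue
            c = u / geom.detector_spacing_mm + (geom.n_detector - 1) / 2
            if c < 0 or c > geom.n_detector - 1:
                continue
            c0 = min(int(math.floor(c)), geom.n_detector - 2)
            f = c - c0
            dense[i * n + j, c0] += 1 - f
            dense[i * n + j, c0 + 1] += f
    return dense
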