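"""Shared helpers for morphometrics oracle tests."""

import math

import numpy as np
from scipy.integrate import quad

from epiderm.cells import nucleus_morphometrics, sphericity
from epiderm.core import VIABLE_EPIDERMIS, LabeledVolume, VoxelSpec


def measure_single_ellipsoid(a: float, b: float, c: float, offset=(0.3, 0.1, -0.2)):
    """Digitize one axis-aligned ellipsoid at 1 um voxels and measure it."""
    nx = int(2 * a + 10)
    ny = int(2 * b + 10)
    nz = int(2 * c + 10)
    spec = VoxelSpec(nx=nx, ny=ny, nz=nz)
    cx, cy, cz = nx / 2 + offset[0], ny / 2 + offset[1], nz / 2 + offset[2]
    xs, ys, zs = spec.x_centers(), spec.y_centers(), spec.z_centers()
    m = (
        ((xs[None, None, :] - cx) / a) ** 2
        + ((ys[None, :, None] - cy) / b) ** 2
        + ((zs[:, None, None] - cz) / c) ** 2
    ) <= 1.0
    tissue = np.full(spec.shape, VIABLE_EPIDERMIS, dtype=np.uint8)
    vol = LabeledVolume(tissue, spec, instances=m.astype(np.int32))
    (rec,) = nucleus_morphometrics(vol)
    return rec


def prolate_sphericity_quadrature(a: float, b: float) -> float:
    """Sphericity of a prolate spheroid (a > b = c) via area quadrature."""

    def integrand(x):
        y = b * math.sqrt(max(0.0, 1 - x**2 / a**2))
        dy = -b * x / (a**2 * math.sqrt(max(1e-300, 1 - x**2 / a**2)))
        return y * math.sqrt(1 + dy**2)

    area, _ = quad(integrand, -a + 1e-9, a - 1e-9, limit=200)
    area *= 2 * math.pi
    volume = 4.0 / 3.0 * math.pi * a * b * b
    return sphericity(volume, area)
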