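"""Shared fixtures: small analytic volumes and one cached generated subject."""

from __future__ import annotations

import numpy as np
import pytest

from epiderm.core import (
    DERMIS,
    STRATUM_CORNEUM,
    VIABLE_EPIDERMIS,
    HeightMap,
    LabeledVolume,
    VoxelSpec,
)
from epiderm.params import default_subject_params
from epiderm.synthetic import generate_subject_volume, suggest_voxel_spec


def make_flat_volume(
    spec: VoxelSpec, surface: int = 5, sc_ve: int = 18, dej: int = 50, roi=None
) -> LabeledVolume:
    """Three-band volume with flat interfaces at integer slice indices."""
    tissue = np.zeros(spec.shape, dtype=np.uint8)
    tissue[surface:] = STRATUM_CORNEUM
    tissue[sc_ve:] = VIABLE_EPIDERMIS
    tissue[dej:] = DERMIS
    return LabeledVolume(tissue, spec, roi_mask=roi)


def flat_heightmap(shape, depth: float, dx: float = 1.0, dy: float = 1.0) -> HeightMap:
    return HeightMap(np.full(shape, float(depth)), dx, dy)


@pytest.fixture(scope="session")
def small_spec() -> VoxelSpec:
    return VoxelSpec(nx=80, ny=60, nz=70)


@pytest.fixture(scope="session")
def flat_volume(small_spec) -> LabeledVolume:
    return make_flat_volume(small_spec)


@pytest.fixture(scope="session")
def generated_subject():
    """One mandible youngest-group subject with nuclei (cached per session)."""
    params = default_subject_params("mandible", "[20,30]", seed=314)
    spec = suggest_voxel_spec([params], nx=200, ny=150)
    volume, gt = generate_subject_volume(params, spec, include_nuclei=True)
    return params, spec, volume, gt
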