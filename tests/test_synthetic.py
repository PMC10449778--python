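"""Synthetic cohort generator: calibration, determinism, ground-truth layout."""

import numpy as np
import pytest

from epiderm.core import (
    VIABLE_EPIDERMIS,
    GridTooSmallError,
    HeightMap,
    PackingError,
    VoxelSpec,
)
from epiderm.layers import dej_undulation
from epiderm.params import (
    AGE_GROUPS,
    BANDS,
    SITES,
    CohortConfig,
    default_subject_params,
    subject_seed,
)
from epiderm.synthetic import (
    generate_cohort,
    generate_dej_heightmap,
    generate_subject_volume,
    oblate_axis_ratio,
    oblate_sphericity,
    required_depth,
    suggest_voxel_spec,
)

SPEC = VoxelSpec(nx=200, ny=120, nz=60)


class TestDejHeightmap:
    def test_zero_target_is_exactly_flat(self):
        hm = generate_dej_heightmap(SPEC, 0.0, seed=1)
        assert np.all(hm.values == 0.0)
        assert dej_undulation(hm) == 0.0

    def test_calibration_hits_target_within_tolerance(self):
        hm = generate_dej_heightmap(SPEC, 2.5, seed=4)
        measured = dej_undulation(hm)
        assert 2.25 <= measured <= 2.75

    @pytest.mark.parametrize("target", [0.3, 1.2, 5.0])
    def test_calibration_over_target_range(self, target):
        measured = dej_undulation(generate_dej_heightmap(SPEC, target, seed=8))
        assert measured == pytest.approx(target, rel=0.10)

    def test_monotone_in_target_for_fixed_seed(self):
        values = [
            dej_undulation(generate_dej_heightmap(SPEC, t, seed=21))
            for t in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_dej_heightmap(SPEC, -1.0)
        with pytest.raises(ValueError):
            generate_dej_heightmap(SPEC, 1.0, correlation_length=0.0)


class TestOblateShape:
    def test_sphericity_roundtrip(self):
        q = np.array([0.2, 0.45, 0.8, 1.0])
        assert np.allclose(oblate_axis_ratio(oblate_sphericity(q)), q, atol=5e-3)

    def test_sphere_has_unit_sphericity(self):
        assert oblate_sphericity(np.array([1.0]))[0] == pytest.approx(1.0)


class TestSubjectVolume:
    def test_degenerate_distributions_give_exact_regular_structure(self):
        params = default_subject_params("mandible", "[20,30]", seed=0)
        for band in params.bands.values():
            band.csd_sd = band.nv_between_sd = band.nv_within_sd = 0.0
            band.nc_between_sd = band.nc_within_sd = 0.0
            band.atypical_mean = band.atypical_sd = 0.0
        params = params.replace(
            sc_thickness_sd=0.0,
            ve_thickness_sd=0.0,
            dej_undulation_mean=0.0,
            dej_undulation_sd=0.0,
            n_layers_mean=6.0,
            n_layers_sd=0.0,
            layer_sd_mean=0.0,
            layer_sd_sd=0.0,
        )
        spec = suggest_voxel_spec([params], nx=150, ny=100)
        volume, gt = generate_subject_volume(params, spec, surface_tilt=0.0)
        assert gt.sc_thickness == 13.1
        assert gt.ve_thickness == 55.1
        assert gt.layer_mean_realized == 6.0
        assert gt.layer_sd_realized == 0.0
        assert np.all(gt.layer_field == 6)
        # flat DEJ: every nucleus of a layer sits on the same depth shell
        for _, layer in gt.nuclei.groupby("layer"):
            assert layer["z"].std() < 0.5  # only the bounded z jitter remains

    def test_table_defaults_reach_ground_truth(self):
        params = default_subject_params("temple", "[20,30]")
        assert (params.sc_thickness_mean, params.sc_thickness_sd) == (13.2, 0.8)
        assert (params.ve_thickness_mean, params.ve_thickness_sd) == (54.6, 6.8)
        assert params.bands["M5"].csd_mean == 2934
        assert params.bands["M5"].nv_mean == 208
        assert params.bands["M1"].nc_mean == 0.805
        m = default_subject_params("mandible", "[61,70]")
        assert m.bands["M5"].nv_mean == 245
        assert (m.n_layers_mean, m.n_layers_sd) == (5.64, 0.57)

    def test_partition_and_instances_inside_ve(self, generated_subject):
        _, _, volume, _ = generated_subject
        volume.check_partition()
        inside = volume.tissue[volume.instances > 0]
        assert (inside == VIABLE_EPIDERMIS).all()

    def test_determinism_same_seed_bit_identical(self):
        params = default_subject_params("cheekbone", "[31,40]", seed=99)
        spec = suggest_voxel_spec([params], nx=120, ny=80)
        v1, g1 = generate_subject_volume(params, spec)
        v2, g2 = generate_subject_volume(params, spec)
        assert np.array_equal(v1.tissue, v2.tissue)
        assert np.array_equal(v1.instances, v2.instances)
        assert g1.nuclei.equals(g2.nuclei)

    def test_replicates_share_subject_draws_but_differ_structurally(self):
        params = default_subject_params("temple", "[41,50]", seed=5)
        spec = suggest_voxel_spec([params], nx=120, ny=80)
        _, g0 = generate_subject_volume(params, spec, replicate=0)
        _, g1 = generate_subject_volume(params, spec, replicate=1)
        assert g0.sc_thickness == g1.sc_thickness
        assert g0.ve_thickness == g1.ve_thickness
        assert not g0.nuclei.equals(g1.nuclei)

    def test_packing_limit_raises_named_band_error(self):
        params = default_subject_params("mandible", "[20,30]", seed=1)
        limit_density = params.bands["M3"].csd_mean
        params.bands["M3"].csd_mean = 10 * 6135.0 * 6  # ~10x the packing bound
        params.bands["M3"].csd_sd = 0.0
        assert params.bands["M3"].csd_mean > 10 * limit_density
        spec = suggest_voxel_spec([params], nx=120, ny=80)
        with pytest.raises(PackingError) as exc:
            generate_subject_volume(params, spec)
        assert exc.value.band == "M3"

    def test_grid_too_small_raises(self):
        params = default_subject_params("mandible", "[20,30]", seed=1)
        spec = VoxelSpec(nx=100, ny=80, nz=40)
        assert required_depth(params) > spec.depth_extent
        with pytest.raises(GridTooSmallError):
            generate_subject_volume(params, spec)

    def test_band_counts_match_csd_draws(self, generated_subject):
        """Allocation: realized per-band counts track the subject CSD draws."""
        _, spec, _, gt = generated_subject
        area = spec.lateral_area_mm2
        counts = gt.band_counts()
        for band in BANDS:
            expected = gt.band_draws[band]["csd"] * area
            assert counts[band] == pytest.approx(expected, rel=0.08)


class TestCohort:
    def test_subject_count_and_determinism(self):
        config = CohortConfig(
            sites=("temple", "mandible"),
            age_groups=("[20,30]", "[61,70]"),
            subjects_per_group=2,
            master_seed=7,
        )
        spec = VoxelSpec(nx=80, ny=60, nz=140)
        run1 = list(generate_cohort(config, spec, include_nuclei=False))
        run2 = list(generate_cohort(config, spec, include_nuclei=False))
        assert len(run1) == 2 * 2 * 2 == config.n_subjects
        for (m1, v1, _), (m2, v2, _) in zip(run1, run2):
            assert m1 == m2
            assert np.array_equal(v1.tissue, v2.tissue)

    def test_seed_splitting_is_stable_and_bounded(self):
        s = subject_seed(42, "temple", "[20,30]", 3)
        assert s == subject_seed(42, "temple", "[20,30]", 3)
        assert 0 <= s < 2**31
        assert s != subject_seed(42, "temple", "[20,30]", 4)
        assert s != subject_seed(42, "mandible", "[20,30]", 3)
        assert s != subject_seed(43, "temple", "[20,30]", 3)

    def test_default_config_covers_all_cells(self):
        config = CohortConfig(subjects_per_group=2)
        assert set(config.params) == {(s, g) for s in SITES for g in AGE_GROUPS}
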