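"""Nucleus morphometrics, maturation banding, densities and layer counts."""

import math
import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from epiderm.core import VIABLE_EPIDERMIS, LabeledVolume, VoxelSpec
from epiderm.cells import (
    NucleusRecord,
    assign_maturation,
    band_of,
    band_statistics,
    cell_surface_density,
    layer_counts,
    maturation_index,
    nucleus_morphometrics,
    records_to_frame,
    sphericity,
)

from conftest import flat_heightmap


def ball_volume(radius: float, center, spec: VoxelSpec, label: int = 1) -> LabeledVolume:
    xs = spec.x_centers()
    ys = spec.y_centers()
    zs = spec.z_centers()
    m = (
        (xs[None, None, :] - center[0]) ** 2
        + (ys[None, :, None] - center[1]) ** 2
        + (zs[:, None, None] - center[2]) ** 2
    ) <= radius**2
    tissue = np.full(spec.shape, VIABLE_EPIDERMIS, dtype=np.uint8)
    return LabeledVolume(tissue, spec, instances=(m * label).astype(np.int32))


def prolate_area_quadrature(a: float, b: float) -> float:
    """Surface of revolution of y = b sqrt(1 - x^2/a^2) about the x axis."""

    def integrand(x):
        y = b * math.sqrt(max(0.0, 1 - x**2 / a**2))
        dy = -b * x / (a**2 * math.sqrt(max(1e-300, 1 - x**2 / a**2)))
        return y * math.sqrt(1 + dy**2)

    area, _ = quad(integrand, -a + 1e-9, a - 1e-9, limit=200)
    return 2 * math.pi * area


class TestMorphometrics:
    def test_digital_ball_volume_and_sphericity(self):
        spec = VoxelSpec(nx=26, ny=26, nz=26)
        vol = ball_volume(8.0, (13.2, 12.9, 13.1), spec)
        (rec,) = nucleus_morphometrics(vol)
        true_v = 4.0 / 3.0 * math.pi * 8.0**3
        assert rec.volume == pytest.approx(true_v, rel=0.02)
        assert rec.compactness >= 0.97
        assert not rec.boundary

    def test_prolate_ellipsoid_compactness_vs_quadrature(self):
        a, b = 12.0, 6.0  # 2:1:1 axes
        spec = VoxelSpec(nx=34, ny=22, nz=22)
        xs, ys, zs = spec.x_centers(), spec.y_centers(), spec.z_centers()
        m = (
            ((xs[None, None, :] - 17.3) / a) ** 2
            + ((ys[None, :, None] - 11.2) / b) ** 2
            + ((zs[:, None, None] - 10.8) / b) ** 2
        ) <= 1.0
        tissue = np.full(spec.shape, VIABLE_EPIDERMIS, dtype=np.uint8)
        vol = LabeledVolume(tissue, spec, instances=m.astype(np.int32))
        (rec,) = nucleus_morphometrics(vol)
        v_true = 4.0 / 3.0 * math.pi * a * b * b
        psi_true = sphericity(v_true, prolate_area_quadrature(a, b))
        assert rec.compactness == pytest.approx(psi_true, rel=0.03)

    def test_translation_invariance(self):
        spec = VoxelSpec(nx=40, ny=20, nz=20)
        v1 = ball_volume(5.0, (10.0, 10.0, 10.0), spec)
        v2 = ball_volume(5.0, (27.0, 10.0, 10.0), spec)
        (r1,) = nucleus_morphometrics(v1)
        (r2,) = nucleus_morphometrics(v2)
        assert r1.volume == r2.volume
        assert r1.surface_area == pytest.approx(r2.surface_area, rel=1e-12)
        assert r1.compactness == pytest.approx(r2.compactness, rel=1e-12)

    def test_boundary_touching_flagged_and_excluded_from_stats(self):
        spec = VoxelSpec(nx=20, ny=20, nz=20)
        vol = ball_volume(6.0, (2.0, 10.0, 10.0), spec)  # sticks out at x=0
        (rec,) = nucleus_morphometrics(vol)
        assert rec.boundary
        rec.band = "M3"
        bm = band_statistics([rec], "M3")
        assert bm.n == 0 and np.isnan(bm.nv_mean)

    def test_no_instances_raises(self, flat_volume):
        with pytest.raises(ValueError):
            nucleus_morphometrics(flat_volume)


class TestMaturation:
    def test_band_boundaries(self):
        assert band_of(0.10) == "M1"
        assert band_of(0.20) == "M2"  # half-open lower bins
        assert band_of(0.4 - 1e-9) == "M2"
        assert band_of(0.75) == "M4"
        assert band_of(1.0) == "M5"  # closed top bin

    def test_depth_normalization_against_flat_maps(self):
        sc_ve = flat_heightmap((30, 30), 20.0)
        dej = flat_heightmap((30, 30), 70.0)
        rec = NucleusRecord(label=1, x=15, y=15, z=70.0 - 0.10 * 50.0, volume=100.0)
        assert maturation_index(rec, sc_ve, dej) == "M1"
        assert rec.depth == pytest.approx(0.10)

    def test_centroid_outside_ve_excluded_with_warning(self):
        sc_ve = flat_heightmap((30, 30), 20.0)
        dej = flat_heightmap((30, 30), 70.0)
        inside = NucleusRecord(label=1, x=5, y=5, z=45.0, volume=100.0)
        below = NucleusRecord(label=2, x=5, y=5, z=72.0, volume=100.0)
        with pytest.warns(UserWarning, match="excluded"):
            kept = assign_maturation([inside, below], sc_ve, dej)
        assert [r.label for r in kept] == [1]

    def test_band_partition_on_generated_subject(self, generated_subject):
        _, _, volume, _ = generated_subject
        from epiderm.layers import extract_heightmaps

        _, sc_ve, dej = extract_heightmaps(volume)
        records = nucleus_morphometrics(volume, compute_mesh=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept = assign_maturation(records, sc_ve, dej)
        counts = {b: sum(1 for r in kept if r.band == b) for b in ("M1", "M2", "M3", "M4", "M5")}
        assert sum(counts.values()) == len(kept)
        assert all(v > 0 for v in counts.values())


class TestDensityAndBandStats:
    def _records(self, band, n):
        return [
            NucleusRecord(label=i, x=0, y=0, z=0, volume=100.0, band=band)
            for i in range(n)
        ]

    def test_csd_arithmetic(self):
        recs = self._records("M4", 1800)
        assert cell_surface_density(recs, "M4", 0.6) == pytest.approx(3000.0)

    def test_empty_band_is_zero(self):
        assert cell_surface_density(self._records("M4", 5), "M2", 0.5) == 0.0

    def test_invalid_area(self):
        with pytest.raises(ValueError):
            cell_surface_density([], "M1", 0.0)

    def test_hand_computed_mean_and_sd(self):
        vols = [100.0, 120.0, 90.0, 150.0, 140.0]
        comps = [0.7, 0.8, 0.75, 0.72, 0.78]
        recs = [
            NucleusRecord(label=i, x=0, y=0, z=0, volume=v, compactness=c, band="M2")
            for i, (v, c) in enumerate(zip(vols, comps))
        ]
        bm = band_statistics(recs, "M2")
        assert bm.nv_mean == pytest.approx(np.mean(vols))
        assert bm.nv_sd == pytest.approx(np.std(vols, ddof=1))
        assert bm.nc_mean == pytest.approx(np.mean(comps))
        assert bm.nc_sd == pytest.approx(np.std(comps, ddof=1))

    def test_identical_nuclei_sd_zero_and_single_record_missing_sd(self):
        recs = self._records("M1", 4)
        bm = band_statistics(recs, "M1")
        assert bm.nv_sd == 0.0
        bm1 = band_statistics(recs[:1], "M1")
        assert np.isnan(bm1.nv_sd)


class TestLayerCounts:
    def _lattice_records(self, n_layers=6, tiles=4, per_layer=5):
        """Regular lattice: `tiles` x `tiles` tiles of 50 um, flat VE 20..80 um."""
        rng = np.random.default_rng(0)
        recs = []
        lid = 1
        for ty in range(tiles):
            for tx in range(tiles):
                for li in range(n_layers):
                    d = (li + 0.5) / n_layers
                    for _ in range(per_layer):
                        x = tx * 50 + rng.uniform(2, 48)
                        y = ty * 50 + rng.uniform(2, 48)
                        z = 80.0 - d * 60.0
                        recs.append(
                            NucleusRecord(
                                label=lid, x=x, y=y, z=z, volume=100.0,
                                z_extent=5.0, depth=d, band=str(band_of(d)),
                            )
                        )
                        lid += 1
        return recs

    def test_regular_six_layer_lattice(self):
        recs = self._lattice_records()
        sc_ve = flat_heightmap((200, 200), 20.0)
        dej = flat_heightmap((200, 200), 80.0)
        lc = layer_counts(recs, sc_ve, dej, tile_size=50.0)
        assert lc.mean == 6.0
        assert lc.sd == 0.0
        assert lc.n_tiles == 16

    def test_single_layer_sheet(self):
        recs = self._lattice_records(n_layers=1)
        sc_ve = flat_heightmap((200, 200), 20.0)
        dej = flat_heightmap((200, 200), 80.0)
        assert layer_counts(recs, sc_ve, dej).mean == 1.0

    def test_recovers_generator_layer_field(self, generated_subject):
        _, _, volume, gt = generated_subject
        from epiderm.layers import extract_heightmaps

        _, sc_ve, dej = extract_heightmaps(volume)
        records = nucleus_morphometrics(volume, compute_mesh=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records = assign_maturation(records, sc_ve, dej)
            lc = layer_counts(records, sc_ve, dej)
        assert lc.mean == pytest.approx(gt.layer_mean_realized, abs=0.15)
        assert lc.sd == pytest.approx(gt.layer_sd_realized, abs=0.2)


class TestRecovery:
    def test_band_volume_mean_recovery_without_atypia(self):
        """Mandible oldest-group M5 volumes: measured mean tracks the 245 um^3
        generator parameter within 2 SEM over a small cohort (atypia off)."""
        from epiderm.params import default_subject_params, subject_seed
        from epiderm.synthetic import generate_subject_volume, suggest_voxel_spec
        from epiderm.layers import extract_heightmaps

        base = default_subject_params("mandible", "[61,70]")
        for bp in base.bands.values():
            bp.atypical_mean = bp.atypical_sd = 0.0
        spec = suggest_voxel_spec([base], nx=180, ny=120)
        n = 15
        means = []
        for i in range(n):
            params = base.replace(seed=subject_seed(77, "mandible", "[61,70]", i))
            volume, _ = generate_subject_volume(params, spec)
            _, sc_ve, dej = extract_heightmaps(volume)
            records = nucleus_morphometrics(volume, compute_mesh=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                records = assign_maturation(records, sc_ve, dej)
            means.append(band_statistics(records, "M5").nv_mean)
        sem = 25.0 / math.sqrt(n)  # printed between-subject sd
        assert np.mean(means) == pytest.approx(245.0, abs=2 * sem)

    def test_compactness_plausible_and_near_generator(self, generated_subject):
        _, _, volume, gt = generated_subject
        from epiderm.layers import extract_heightmaps

        _, sc_ve, dej = extract_heightmaps(volume)
        records = nucleus_morphometrics(volume)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records = assign_maturation(records, sc_ve, dej)
        frame = records_to_frame(records)
        for band in ("M1", "M3", "M5"):
            measured = frame.loc[(frame.band == band) & ~frame.boundary, "compactness"].mean()
            drawn = gt.band_draws[band]["nc_mean"]
            assert 0.5 < measured <= 1.0
            assert measured == pytest.approx(drawn, abs=0.05)
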