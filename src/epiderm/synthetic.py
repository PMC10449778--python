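"""Synthetic labeled skin volumes with known ground truth.

The generator realizes the structures the measurement pipeline consumes:
a flat, gently tilted skin surface; a stratum-corneum band of drawn
thickness; a viable-epidermis band bounded below by a random-field
dermal-epidermal junction whose undulation statistic is calibrated to a
target; and non-overlapping oblate-ellipsoid nuclei arranged in discrete
depth layers, with per-band counts, volumes and compactness drawn from
configurable distributions.  Every drawn quantity is recorded in a
``GroundTruth`` object so estimator recovery can be asserted exactly.

The geometry is a stand-in: the imaging study this emulates defines the
*statistics* (thickness, %U_DEJ, densities, layer counts) but not the
underlying surfaces or packing, so those are explicit design choices here,
validated purely by ground-truth recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cells import BAND_NAMES, NucleusRecord, band_of
from .core import (
    VIABLE_EPIDERMIS,
    CalibrationError,
    GridTooSmallError,
    HeightMap,
    LabeledVolume,
    PackingError,
    VoxelSpec,
)
from .layers import dej_undulation
from .params import BandParams, CohortConfig, SubjectParams, subject_seed

__all__ = [
    "GroundTruth",
    "generate_dej_heightmap",
    "sinusoid_heightmap",
    "generate_subject_volume",
    "generate_cohort",
    "required_depth",
    "suggest_voxel_spec",
    "sample_records",
    "oblate_axis_ratio",
    "oblate_sphericity",
]

# ---------------------------------------------------------------------------
# Oblate-spheroid sphericity <-> axis ratio
# ---------------------------------------------------------------------------

def oblate_sphericity(q: np.ndarray) -> np.ndarray:
    """Sphericity of an oblate spheroid with polar/equatorial axis ratio q <= 1."""
    q = np.asarray(q, dtype=float)
    out = np.ones_like(q)
    lt1 = q < 1.0
    qq = q[lt1]
    e = np.sqrt(1.0 - qq**2)
    # area of oblate spheroid with a = b = 1, c = q
    area = 2.0 * np.pi * (1.0 + (1.0 - e**2) / e * np.arctanh(e))
    vol = 4.0 / 3.0 * np.pi * qq
    out[lt1] = np.pi ** (1 / 3) * (6.0 * vol) ** (2 / 3) / area
    return out


_Q_GRID = np.linspace(0.02, 1.0, 600)
_PSI_GRID = oblate_sphericity(_Q_GRID)


def oblate_axis_ratio(psi: np.ndarray) -> np.ndarray:
    """Inverse of :func:`oblate_sphericity` by table interpolation."""
    psi = np.clip(np.asarray(psi, dtype=float), _PSI_GRID[0], 1.0)
    return np.interp(psi, _PSI_GRID, _Q_GRID)


# ---------------------------------------------------------------------------
# Random draws
# ---------------------------------------------------------------------------

def _tnorm(u: float, mean: float, sd: float, lo: float | None = None, hi: float | None = None) -> float:
    """Inverse-CDF draw from Normal(mean, sd) truncated at +/-3 sd.

    Using the inverse CDF of a single uniform keeps draws comparable across
    parameter sets that share a random stream (common-random-number pairing
    of cohorts).
    """
    if sd > 0:
        x = float(truncnorm.ppf(u, -3.0, 3.0, loc=mean, scale=sd))
    else:
        x = mean
    if lo is not None:
        x = max(lo, x)
    if hi is not None:
        x = min(hi, x)
    return x


# ---------------------------------------------------------------------------
# DEJ random field
# ---------------------------------------------------------------------------

def _unit_gaussian_field(spec: VoxelSpec, correlation_length: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance smooth random field on the lateral grid.

    Spectral synthesis: white noise filtered with a Gaussian spectrum
    (equivalently, a sum of random-phase cosines with Gaussian-weighted
    amplitudes), giving an isotropic field with correlation length of order
    ``correlation_length``.
    """
    ny, nx = spec.lateral_shape
    noise = rng.standard_normal((ny, nx))
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=spec.dx)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=spec.dy)
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    filt = np.exp(-k2 * correlation_length**2 / 8.0)
    f = np.fft.ifft2(np.fft.fft2(noise) * filt).real
    sd = f.std()
    if sd == 0:
        return np.zeros_like(f)
    return (f - f.mean()) / sd


def generate_dej_heightmap(
    spec: VoxelSpec,
    undulation_target: float,
    correlation_length: float = 50.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    rel_tol: float = 0.10,
    max_iter: int = 80,
) -> HeightMap:
    """Zero-mean random-field heightmap with calibrated undulation.

    The field amplitude is calibrated by bisection so that the measured
    %U_DEJ of the returned map is within ``rel_tol`` (relative) of
    ``undulation_target``.  A target of 0 returns an exactly flat map.
    """
    if undulation_target < 0:
        raise ValueError("undulation_target must be >= 0")
    if correlation_length <= 0:
        raise ValueError("correlation_length must be > 0")
    ny, nx = spec.lateral_shape
    if undulation_target == 0:
        return HeightMap(np.zeros((ny, nx)), spec.dx, spec.dy)
    if rng is None:
        rng = np.random.default_rng(seed)
    f = _unit_gaussian_field(spec, correlation_length, rng)

    def measured(amp: float) -> float:
        return dej_undulation(HeightMap(amp * f, spec.dx, spec.dy))

    # initial guess from the small-slope expansion %U ~ 50 * E|grad h|^2
    gy, gx = np.gradient(f, spec.dy, spec.dx)
    g2 = float(np.mean(gy**2 + gx**2))
    a_hi = math.sqrt(undulation_target / (50.0 * max(g2, 1e-12)))
    it = 0
    u_hi = measured(a_hi)
    while u_hi < undulation_target and it < max_iter:
        a_hi *= 2.0
        u_hi = measured(a_hi)
        it += 1
    a_lo = 0.0
    amp, u = a_hi, u_hi
    while it < max_iter:
        if abs(u - undulation_target) <= rel_tol * undulation_target:
            return HeightMap(amp * f, spec.dx, spec.dy)
        if u > undulation_target:
            a_hi = amp
        else:
            a_lo = amp
        amp = 0.5 * (a_lo + a_hi)
        u = measured(amp)
        it += 1
    raise CalibrationError(undulation_target, u)


def sinusoid_heightmap(
    spec: VoxelSpec, amplitude: float, wavelength: float, phase: float = 0.0, offset: float = 0.0
) -> HeightMap:
    """Analytic sinusoidal heightmap h(x) = offset + A sin(2 pi x / lambda + phase)."""
    x = spec.x_centers()
    h = offset + amplitude * np.sin(2.0 * np.pi * x / wavelength + phase)
    values = np.broadcast_to(h[None, :], spec.lateral_shape).copy()
    return HeightMap(values, spec.dx, spec.dy)


# ---------------------------------------------------------------------------
# Subject volumes
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator drew for one subject volume."""

    sc_thickness: float
    ve_thickness: float
    dej_undulation_target: float
    dej_undulation_achieved: float
    n_layers_mean: float
    layer_sd_target: float
    layer_field: np.ndarray
    band_draws: dict
    surface: HeightMap = None
    sc_ve: HeightMap = None
    dej: HeightMap = None
    nuclei: pd.DataFrame = field(default_factory=pd.DataFrame)
    seed: Optional[int] = None

    @property
    def layer_mean_realized(self) -> float:
        return float(self.layer_field.mean())

    @property
    def layer_sd_realized(self) -> float:
        return float(self.layer_field.std(ddof=1))

    def band_counts(self) -> dict[str, int]:
        if self.nuclei.empty:
            return {b: 0 for b in BAND_NAMES}
        vc = self.nuclei["band"].value_counts()
        return {b: int(vc.get(b, 0)) for b in BAND_NAMES}

    def summary(self) -> dict:
        out = {
            "sc_thickness": self.sc_thickness,
            "ve_thickness": self.ve_thickness,
            "dej_undulation_target": self.dej_undulation_target,
            "dej_undulation_achieved": self.dej_undulation_achieved,
            "n_layers_mean": self.n_layers_mean,
            "layer_mean_realized": self.layer_mean_realized,
            "layer_sd_realized": self.layer_sd_realized,
            "n_nuclei": int(len(self.nuclei)),
        }
        for b, draws in self.band_draws.items():
            for k, v in draws.items():
                out[f"{b}_{k}"] = v
        return out


def required_depth(params: SubjectParams, surface_margin: float = 3.0, surface_tilt: float = 2.0) -> float:
    """Depth (um) needed to hold the layer stack at 3 sd above the means."""
    u_max = params.dej_undulation_mean + 3.0 * params.dej_undulation_sd
    amp_est = params.dej_correlation_length * math.sqrt(max(u_max, 0.0) / 200.0)
    return (
        surface_margin
        + 1.0  # sub-voxel surface jitter
        + surface_tilt
        + params.sc_thickness_mean + 3.0 * params.sc_thickness_sd
        + params.ve_thickness_mean + 3.0 * params.ve_thickness_sd
        + 3.5 * amp_est
        + 2.0  # dermis floor
    )


def suggest_voxel_spec(
    params_list, nx: int = 300, ny: int = 150, dx: float = 1.0, dy: float = 1.0, dz: float = 1.0
) -> VoxelSpec:
    """A lateral-size-reduced grid deep enough for every parameter set given."""
    depth = max(required_depth(p) for p in params_list)
    return VoxelSpec(dx=dx, dy=dy, dz=dz, nx=nx, ny=ny, nz=int(math.ceil(depth / dz)))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the requested mean and sd."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    if sd <= 0:
        return math.log(mean), 0.0
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


class _OverlapGrid:
    """Cell-hash of accepted nuclei for fast ellipsoid overlap rejection."""

    def __init__(self, cell: float = 12.0):
        self.cell = cell
        self.grid: dict[tuple[int, int], list[tuple[float, float, float, float, float]]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(x // self.cell), int(y // self.cell))

    def conflicts(self, x: float, y: float, z: float, a: float, c: float) -> bool:
        kx, ky = self._key(x, y)
        for ix in (kx - 1, kx, kx + 1):
            for iy in (ky - 1, ky, ky + 1):
                for (ox, oy, oz, oa, oc) in self.grid.get((ix, iy), ()):
                    dr2 = (x - ox) ** 2 + (y - oy) ** 2
                    sa = a + oa
                    sc = c + oc
                    if dr2 < sa * sa:
                        dz = z - oz
                        if (dr2 / (sa * sa) + (dz * dz) / (sc * sc)) < 1.0:
                            return True
        return False

    def add(self, x: float, y: float, z: float, a: float, c: float) -> None:
        self.grid.setdefault(self._key(x, y), []).append((x, y, z, a, c))


def _draw_subject_levels(params: SubjectParams, rng: np.random.Generator) -> dict:
    """Subject-level draws in a fixed, documented order (one uniform each)."""
    d = {}
    d["sc"] = _tnorm(rng.uniform(), params.sc_thickness_mean, params.sc_thickness_sd, lo=1.0)
    d["ve"] = _tnorm(rng.uniform(), params.ve_thickness_mean, params.ve_thickness_sd, lo=5.0)
    d["undulation"] = _tnorm(
        rng.uniform(), params.dej_undulation_mean, params.dej_undulation_sd, lo=0.0
    )
    d["n_layers"] = _tnorm(rng.uniform(), params.n_layers_mean, params.n_layers_sd, lo=1.0)
    d["layer_sd"] = _tnorm(rng.uniform(), params.layer_sd_mean, params.layer_sd_sd, lo=0.0)
    bands = {}
    for b in BAND_NAMES:
        bp: BandParams = params.bands.get(b)
        if bp is None:
            continue
        bands[b] = {
            "csd": _tnorm(rng.uniform(), bp.csd_mean, bp.csd_sd, lo=0.0),
            "nv_mean": _tnorm(rng.uniform(), bp.nv_mean, bp.nv_between_sd, lo=10.0),
            "nv_within": _tnorm(rng.uniform(), bp.nv_within_mean, bp.nv_within_sd, lo=0.0),
            "nc_mean": _tnorm(rng.uniform(), bp.nc_mean, bp.nc_between_sd, lo=0.35, hi=0.98),
            "nc_within": _tnorm(rng.uniform(), bp.nc_within_mean, bp.nc_within_sd, lo=0.0),
            "atypical": _tnorm(rng.uniform(), bp.atypical_mean, bp.atypical_sd, lo=0.0, hi=1.0),
        }
    d["bands"] = bands
    return d


def _place_nuclei(
    params: SubjectParams,
    spec: VoxelSpec,
    draws: dict,
    sc_ve_map: HeightMap,
    dej_map: HeightMap,
    rng: np.random.Generator,
    layer_jitter_sd: float = 0.25,
    max_attempts: int = 30,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw nucleus centers, sizes and shapes; returns (nuclei table, layer field).

    Layer structure: the lateral plane is partitioned into ``patch_size``
    patches; each patch gets an integer local layer count drawn around the
    subject mean, and nuclei are placed on equally spaced depth shells within
    the local VE with a small z jitter.  Per-band counts are allocated so the
    expected surface density of each maturation band matches the subject's
    CSD draw regardless of how many shells fall inside the band.

    Within a shell, positions form a jittered lattice (quasi-regular, like
    an epithelial honeycomb).  The realistic band densities put flattened
    superficial nuclei at ~40-50% lateral disc coverage, beyond the jamming
    limit of plain rejection ("dart") sampling; a jittered lattice reaches
    them deterministically while the pairwise overlap check is retained.
    """
    ex, ey = spec.lateral_extent
    patch = params.patch_size
    npx = max(1, int(math.ceil(ex / patch)))
    npy = max(1, int(math.ceil(ey / patch)))
    # variance of round() noise is subtracted so the realized tile sd of the
    # integer field matches the subject's within-subject sd target
    sd_adj = math.sqrt(max(draws["layer_sd"] ** 2 - 1.0 / 12.0, 0.0))
    lf = draws["n_layers"] + sd_adj * rng.standard_normal((npy, npx))
    layer_field = np.clip(np.rint(lf), 1, 15).astype(int)

    bands = draws["bands"]
    mean_axis = {}
    for b, bd in bands.items():
        q = float(oblate_axis_ratio(bd["nc_mean"]))
        a_mean = (3.0 * bd["nv_mean"] / (4.0 * np.pi * q)) ** (1 / 3)
        mean_axis[b] = a_mean

    grid = _OverlapGrid(cell=12.0)
    rows = []
    nid = 1
    factor = params.atypical_volume_factor
    for jy in range(npy):
        y0, y1 = jy * patch, min((jy + 1) * patch, ey)
        for jx in range(npx):
            x0, x1 = jx * patch, min((jx + 1) * patch, ex)
            area_mm2 = (x1 - x0) * (y1 - y0) * 1e-6
            L = int(layer_field[jy, jx])
            u_layers = (np.arange(L) + 0.5) / L
            layer_bands = band_of(u_layers)
            band_mult = {b: int(np.sum(layer_bands == b)) for b in set(layer_bands)}
            w, h = x1 - x0, y1 - y0
            for li in range(L):
                b = str(layer_bands[li])
                bd = bands.get(b)
                if bd is None:
                    continue
                expect = bd["csd"] * area_mm2 / band_mult[b]
                n_here = int(expect) + (1 if rng.uniform() < expect - int(expect) else 0)
                if n_here == 0:
                    continue
                # lattice feasibility pre-check (projected disc area vs patch)
                if n_here * np.pi * mean_axis[b] ** 2 > 0.85 * w * h:
                    raise PackingError(
                        b,
                        f"band {b}: requested {n_here} nuclei of mean lateral radius "
                        f"{mean_axis[b]:.1f} um exceed the packing limit of a "
                        f"{w:.0f}x{h:.0f} um patch",
                    )
                ncols = max(1, round(math.sqrt(n_here * w / h)))
                nrows = max(1, math.ceil(n_here / ncols))
                while ncols * nrows < n_here:
                    nrows += 1
                sx_, sy_ = w / ncols, h / nrows
                cells_order = rng.permutation(ncols * nrows)[:n_here]
                mu, sigma = _lognormal_params(bd["nv_mean"], bd["nv_within"])
                for cell_id in cells_order:
                    cy_, cx_ = divmod(int(cell_id), ncols)
                    vol = float(np.exp(mu + sigma * rng.standard_normal()))
                    atyp = bool(rng.uniform() < bd["atypical"])
                    if atyp:
                        vol *= factor
                    nc = float(np.clip(rng.normal(bd["nc_mean"], bd["nc_within"]), 0.30, 0.98))
                    q = float(oblate_axis_ratio(nc))
                    a = (3.0 * vol / (4.0 * np.pi * q)) ** (1 / 3)
                    c = q * a
                    bx = x0 + (cx_ + 0.5) * sx_
                    by = y0 + (cy_ + 0.5) * sy_
                    jit_x = max(0.0, min(0.35 * sx_, 0.5 * sx_ - a))
                    jit_y = max(0.0, min(0.35 * sy_, 0.5 * sy_ - a))
                    x, y, z = bx, by, np.nan
                    for _try in range(max_attempts):
                        x = bx + rng.uniform(-jit_x, jit_x)
                        y = by + rng.uniform(-jit_y, jit_y)
                        top = float(sc_ve_map.sample(x, y))
                        bot = float(dej_map.sample(x, y))
                        jit = float(np.clip(rng.normal(0.0, layer_jitter_sd), -0.5, 0.5))
                        z = bot - u_layers[li] * (bot - top) + jit
                        if not grid.conflicts(x, y, z, a, c):
                            break
                    else:
                        # rare (e.g. adjacent oversized atypicals): keep the
                        # last candidate; painting never overwrites, so the
                        # contact merely truncates this nucleus slightly
                        pass
                    grid.add(x, y, z, a, c)
                    top = float(sc_ve_map.sample(x, y))
                    bot = float(dej_map.sample(x, y))
                    d_norm = (bot - z) / (bot - top)
                    rows.append(
                        {
                            "label": nid,
                            "x": x,
                            "y": y,
                            "z": z,
                            "volume": vol,
                            "compactness": nc,
                            "a": a,
                            "c": c,
                            "band": str(band_of(d_norm)),
                            "layer": li,
                            "depth": float(np.clip(d_norm, 0.0, 1.0)),
                            "atypical": atyp,
                        }
                    )
                    nid += 1
    nuclei = pd.DataFrame(
        rows,
        columns=[
            "label", "x", "y", "z", "volume", "compactness", "a", "c",
            "band", "layer", "depth", "atypical",
        ],
    )
    return nuclei, layer_field


def _paint_nuclei(
    tissue: np.ndarray, nuclei: pd.DataFrame, spec: VoxelSpec
) -> np.ndarray:
    """Rasterize ellipsoid nuclei into an instance label volume.

    A voxel belongs to a nucleus when its center lies inside the ellipsoid;
    the expected voxel count then equals the analytic volume for random
    sub-voxel centers.  Painting never overwrites earlier instances and is
    clipped to viable-epidermis voxels.
    """
    inst = np.zeros(spec.shape, dtype=np.int32)
    nz, ny, nx = spec.shape
    for row in nuclei.itertuples(index=False):
        a, c = row.a, row.c
        ix0 = max(0, int(math.floor((row.x - a) / spec.dx - 0.5)))
        ix1 = min(nx - 1, int(math.ceil((row.x + a) / spec.dx)))
        iy0 = max(0, int(math.floor((row.y - a) / spec.dy - 0.5)))
        iy1 = min(ny - 1, int(math.ceil((row.y + a) / spec.dy)))
        iz0 = max(0, int(math.floor((row.z - c) / spec.dz - 0.5)))
        iz1 = min(nz - 1, int(math.ceil((row.z + c) / spec.dz)))
        if ix1 < ix0 or iy1 < iy0 or iz1 < iz0:
            continue
        xs = (np.arange(ix0, ix1 + 1) + 0.5) * spec.dx
        ys = (np.arange(iy0, iy1 + 1) + 0.5) * spec.dy
        zs = (np.arange(iz0, iz1 + 1) + 0.5) * spec.dz
        m = (
            ((xs[None, None, :] - row.x) / a) ** 2
            + ((ys[None, :, None] - row.y) / a) ** 2
            + ((zs[:, None, None] - row.z) / c) ** 2
        ) <= 1.0
        sub_t = tissue[iz0 : iz1 + 1, iy0 : iy1 + 1, ix0 : ix1 + 1]
        sub_i = inst[iz0 : iz1 + 1, iy0 : iy1 + 1, ix0 : ix1 + 1]
        sel = m & (sub_t == VIABLE_EPIDERMIS) & (sub_i == 0)
        sub_i[sel] = row.label
    return inst


def generate_subject_volume(
    params: SubjectParams,
    spec: VoxelSpec,
    include_nuclei: bool = True,
    replicate: int = 0,
    surface_margin: float = 3.0,
    surface_tilt: float = 2.0,
    roi_mask: Optional[np.ndarray] = None,
) -> tuple[LabeledVolume, GroundTruth]:
    """Generate one labeled subject volume plus its ground truth.

    ``replicate`` selects an independent structural realization of the *same*
    subject (identical subject-level draws, fresh field and cell randomness),
    emulating repeated acquisitions of one skin site.
    """
    need = required_depth(params, surface_margin, surface_tilt)
    if need > spec.depth_extent:
        raise GridTooSmallError(
            f"grid depth {spec.depth_extent:.0f} um cannot hold the layer stack "
            f"(requires ~{need:.0f} um at 3 sd above the means)"
        )
    base = int(params.seed) if params.seed is not None else 0
    rng_draws = np.random.default_rng(np.random.SeedSequence((base, 0)))
    rng_field = np.random.default_rng(np.random.SeedSequence((base, 1, replicate)))
    rng_cells = np.random.default_rng(np.random.SeedSequence((base, 2, replicate)))

    draws = _draw_subject_levels(params, rng_draws)

    ny, nx = spec.lateral_shape
    x = spec.x_centers()[None, :]
    y = spec.y_centers()[:, None]
    ex, ey = spec.lateral_extent
    z0 = surface_margin + rng_field.uniform()
    gx = rng_field.uniform(-surface_tilt, surface_tilt) / ex
    gy = rng_field.uniform(-surface_tilt, surface_tilt) / ey
    surface = z0 + gx * (x - ex / 2.0) + gy * (y - ey / 2.0)
    surface = np.broadcast_to(surface, (ny, nx)).copy()
    sc_ve = surface + draws["sc"]

    und = generate_dej_heightmap(
        spec,
        draws["undulation"],
        correlation_length=params.dej_correlation_length,
        rng=rng_field,
    )
    dej = sc_ve + draws["ve"] + und.values
    if dej.max() > spec.depth_extent - spec.dz:
        raise GridTooSmallError(
            f"realized DEJ reaches {dej.max():.0f} um; grid depth is {spec.depth_extent:.0f} um"
        )

    surface_hm = HeightMap(surface, spec.dx, spec.dy)
    sc_ve_hm = HeightMap(sc_ve, spec.dx, spec.dy)
    dej_hm = HeightMap(dej, spec.dx, spec.dy)

    tissue = np.zeros(spec.shape, dtype=np.uint8)
    for iz in range(spec.nz):  # slice-wise to bound memory on full-size grids
        zc = (iz + 0.5) * spec.dz
        tissue[iz] = (
            (zc >= surface).astype(np.uint8)
            + (zc >= sc_ve).astype(np.uint8)
            + (zc >= dej).astype(np.uint8)
        )

    instances = None
    nuclei = pd.DataFrame()
    layer_field = np.array([[round(draws["n_layers"])]])
    if include_nuclei:
        nuclei, layer_field = _place_nuclei(
            params, spec, draws, sc_ve_hm, dej_hm, rng_cells
        )
        instances = _paint_nuclei(tissue, nuclei, spec)

    volume = LabeledVolume(
        tissue=tissue,
        spec=spec,
        instances=instances,
        roi_mask=roi_mask,
        meta={"site": params.site, "age_group": params.age_group, "seed": params.seed,
              "replicate": replicate},
    )
    gt = GroundTruth(
        sc_thickness=draws["sc"],
        ve_thickness=draws["ve"],
        dej_undulation_target=draws["undulation"],
        dej_undulation_achieved=dej_undulation(und) if draws["undulation"] > 0 else 0.0,
        n_layers_mean=draws["n_layers"],
        layer_sd_target=draws["layer_sd"],
        layer_field=layer_field,
        band_draws=draws["bands"],
        surface=surface_hm,
        sc_ve=sc_ve_hm,
        dej=dej_hm,
        nuclei=nuclei,
        seed=params.seed,
    )
    return volume, gt


def generate_cohort(
    config: CohortConfig,
    spec: Optional[VoxelSpec] = None,
    include_nuclei: bool = True,
) -> Iterator[tuple[dict, LabeledVolume, GroundTruth]]:
    """Yield (metadata, volume, ground truth) for every subject of a cohort.

    Deterministic given the master seed: each subject's seed is a stable hash
    of (master seed, site, age group, subject index).  Yields lazily so large
    cohorts never hold more than one volume in memory.
    """
    if spec is None:
        spec = suggest_voxel_spec(list(config.params.values()))
    for site in config.sites:
        for group in config.age_groups:
            base = config.params[(site, group)]
            for i in range(config.subjects_per_group):
                seed = subject_seed(config.master_seed, site, group, i)
                params = base.replace(seed=seed, site=site, age_group=group)
                volume, gt = generate_subject_volume(
                    params, spec, include_nuclei=include_nuclei
                )
                meta = {
                    "subject": f"{site}-{group}-{i:03d}",
                    "site": site,
                    "age_group": group,
                    "index": i,
                    "seed": seed,
                }
                yield meta, volume, gt


# ---------------------------------------------------------------------------
# Record-level sampling (no voxelization) for detector studies
# ---------------------------------------------------------------------------

def sample_records(
    n: int,
    nv_mean: float,
    nv_sd: float,
    nc_mean: float,
    nc_sd: float,
    rng: np.random.Generator,
    contamination: float = 0.0,
    volume_factor: float = 3.0,
    box: tuple[float, float, float] = (500.0, 500.0, 10.0),
    band: str = "M3",
) -> list[NucleusRecord]:
    """Sample a homogeneous nucleus population, optionally contaminated.

    Volumes are lognormal(mean, sd), compactness Normal clipped to (0, 1];
    a ``contamination`` fraction is re-drawn with ``volume_factor`` times the
    volume and marked ``atypical`` so detector recovery can be scored.
    Positions are uniform in a box (um); this bypasses voxel rasterization
    and is meant for studying the atypia detector itself.
    """
    mu, sigma = _lognormal_params(nv_mean, nv_sd)
    vol = np.exp(mu + sigma * rng.standard_normal(n))
    atyp = rng.uniform(size=n) < contamination
    vol[atyp] *= volume_factor
    nc = np.clip(rng.normal(nc_mean, nc_sd, size=n), 0.30, 1.0)
    x = rng.uniform(0, box[0], size=n)
    y = rng.uniform(0, box[1], size=n)
    z = rng.uniform(0, box[2], size=n)
    return [
        NucleusRecord(
            label=i + 1,
            x=float(x[i]),
            y=float(y[i]),
            z=float(z[i]),
            volume=float(vol[i]),
            compactness=float(nc[i]),
            band=band,
            depth=0.5,
            atypical=bool(atyp[i]),
        )
        for i in range(n)
    ]
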