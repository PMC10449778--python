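"""End-to-end orchestration: simulate -> extract -> score -> report.

``run`` drives the whole chain for a configured cohort: per subject it
generates ``replicates`` structural realizations of the same skin site,
measures each (layer metrics, nucleus morphometrics, band metrics, layer
counts, atypia), averages the replicate metrics, and finally feeds the
subject-level table to the group-statistics report.  A manifest with the
config hash makes reruns byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cells, layers
from .atypia import AtypiaConfig, atypia_scores, build_neighbor_graph
from .core import LabeledVolume, VoxelSpec
from .params import CohortConfig, default_cohort_config, subject_seed
from .stats import Report, build_report
from .synthetic import generate_subject_volume, suggest_voxel_spec

logger = logging.getLogger("epiderm")

__all__ = ["RunConfig", "RunResult", "process_volume", "run", "fixtures"]


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=default_cohort_config)
    voxel_spec: Optional[VoxelSpec] = None   # None -> auto-sized reduced grid
    tile_size: float = 50.0
    atypia: AtypiaConfig = field(default_factory=AtypiaConfig)
    alpha: float = 0.05
    normality_alpha: float = 0.10
    replicates: int = 3
    include_nuclei: bool = True
    undulation_smooth_sigma: float = 2.0
    save_volumes: bool = False
    volume_format: str = "tiff"
    out_dir: str = "epiderm_out"
    log_level: str = "INFO"
    max_failed_fraction: float = 0.10

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "voxel_spec": self.voxel_spec.to_dict() if self.voxel_spec else None,
            "tile_size": self.tile_size,
            "atypia": self.atypia.to_dict(),
            "alpha": self.alpha,
            "normality_alpha": self.normality_alpha,
            "replicates": self.replicates,
            "include_nuclei": self.include_nuclei,
            "undulation_smooth_sigma": self.undulation_smooth_sigma,
            "save_volumes": self.save_volumes,
            "volume_format": self.volume_format,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "max_failed_fraction": self.max_failed_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["cohort"] = CohortConfig.from_dict(d.get("cohort", {}))
        vs = d.get("voxel_spec")
        d["voxel_spec"] = VoxelSpec.from_dict(vs) if vs else None
        d["atypia"] = AtypiaConfig.from_dict(d.get("atypia", AtypiaConfig().to_dict()))
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))


@dataclass
class RunResult:
    metrics: pd.DataFrame       # long table: subject, site, age_group, metric, value
    report: Report
    manifest: dict


def process_volume(
    volume: LabeledVolume,
    tile_size: float = 50.0,
    atypia_config: AtypiaConfig = AtypiaConfig(),
    undulation_smooth_sigma: float = 2.0,
) -> dict[str, float]:
    """All metrics of one labeled volume as a flat {metric: value} dict."""
    surface, sc_ve, dej = layers.extract_heightmaps(volume)
    out: dict[str, float] = {
        "sc_thickness": layers.mean_thickness(surface, sc_ve),
        "ve_thickness": layers.mean_thickness(sc_ve, dej),
        "dej_undulation": layers.dej_undulation(dej, smooth_sigma=undulation_smooth_sigma),
    }
    if volume.instances is None:
        return out
    records = cells.nucleus_morphometrics(volume)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = cells.assign_maturation(records, sc_ve, dej)
        lc = cells.layer_counts(records, sc_ve, dej, tile_size=tile_size)
        graph = build_neighbor_graph(records, k=atypia_config.k, radius=atypia_config.radius)
    # ground-truth-free measurement: clear any generator labels before scoring
    for r in records:
        r.atypical = None
    aty = atypia_scores(records, graph, config=atypia_config)
    out["layer_number"] = lc.mean
    out["layer_number_sd"] = lc.sd
    roi_area = float(volume.roi.sum()) * volume.spec.dx * volume.spec.dy * 1e-6
    for bm in cells.subject_band_table(records, roi_area, cna=aty.cna):
        b = bm.band
        out[f"csd_{b}"] = bm.csd
        out[f"nv_{b}"] = bm.nv_mean
        out[f"std_nv_{b}"] = bm.nv_sd
        out[f"nc_{b}"] = bm.nc_mean
        out[f"std_c_{b}"] = bm.nc_sd
        out[f"cna_{b}"] = bm.cna
    return out


def run(config: RunConfig) -> RunResult:
    """Execute the full simulate-measure-report chain for a cohort."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = config.cohort
    spec = config.voxel_spec or suggest_voxel_spec(list(cohort.params.values()))
    rows = []
    statuses = []
    n_failed = 0
    for site in cohort.sites:
        for group in cohort.age_groups:
            base = cohort.params[(site, group)]
            for i in range(cohort.subjects_per_group):
                seed = subject_seed(cohort.master_seed, site, group, i)
                params = base.replace(seed=seed, site=site, age_group=group)
                subject = f"{site}-{group}-{i:03d}"
                try:
                    per_rep = []
                    for rep in range(config.replicates):
                        volume, _gt = generate_subject_volume(
                            params, spec,
                            include_nuclei=config.include_nuclei,
                            replicate=rep,
                        )
                        if config.save_volumes:
                            from .io import save_volume

                            save_volume(
                                volume, out_dir / "volumes", f"{subject}_r{rep}",
                                fmt=config.volume_format,
                            )
                        per_rep.append(
                            process_volume(
                                volume,
                                tile_size=config.tile_size,
                                atypia_config=config.atypia,
                                undulation_smooth_sigma=config.undulation_smooth_sigma,
                            )
                        )
                    averaged = pd.DataFrame(per_rep).mean().to_dict()
                    for metric, value in averaged.items():
                        rows.append(
                            {
                                "subject": subject,
                                "site": site,
                                "age_group": group,
                                "metric": metric,
                                "value": float(value),
                            }
                        )
                    statuses.append({"subject": subject, "status": "ok"})
                    logger.info("subject %s done", subject)
                except Exception as exc:  # noqa: BLE001 - per-subject isolation
                    n_failed += 1
                    statuses.append({"subject": subject, "status": f"error: {exc}"})
                    logger.error("subject %s failed: %s", subject, exc)
    n_total = cohort.n_subjects
    if n_total and n_failed / n_total > config.max_failed_fraction:
        raise RuntimeError(
            f"{n_failed}/{n_total} subjects failed (> {config.max_failed_fraction:.0%})"
        )
    metrics = pd.DataFrame(rows, columns=["subject", "site", "age_group", "metric", "value"])
    report = build_report(
        metrics,
        alpha=config.alpha,
        normality_alpha=config.normality_alpha,
        group_order=list(cohort.age_groups),
    )
    metrics_csv = metrics.to_csv(index=False, float_format="%.10g")
    manifest = {
        "config": config.to_dict(),
        "master_seed": cohort.master_seed,
        "voxel_spec": spec.to_dict(),
        "n_subjects": n_total,
        "n_failed": n_failed,
        "subjects": statuses,
        "metrics_sha256": hashlib.sha256(metrics_csv.encode()).hexdigest(),
    }
    (out_dir / "metrics.csv").write_text(metrics_csv)
    report.frame.to_csv(out_dir / "report.csv", index=False, float_format="%.4g")
    (out_dir / "report.txt").write_text(report.to_text() + "\n")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(metrics=metrics, report=report, manifest=manifest)


def fixtures(out_dir: str | Path) -> dict:
    """Write tiny analytic test volumes with machine-readable expected values.

    Cases: a flat three-band stack, a 45-degree tilted DEJ plane, a regular
    six-layer nucleus lattice and a digitized ball; the expected values are
    closed-form.
    """
    import math

    from .core import DERMIS, STRATUM_CORNEUM, VIABLE_EPIDERMIS
    from .io import save_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expected: dict[str, dict] = {}

    spec = VoxelSpec(nx=60, ny=40, nz=60)
    tissue = np.zeros(spec.shape, dtype=np.uint8)
    tissue[5:] = STRATUM_CORNEUM
    tissue[18:] = VIABLE_EPIDERMIS
    tissue[50:] = DERMIS
    save_volume(LabeledVolume(tissue, spec), out_dir, "flat_stack")
    expected["flat_stack"] = {
        "sc_thickness": 13.0,
        "ve_thickness": 32.0,
        "dej_undulation": 0.0,
    }

    theta = math.radians(45.0)
    spec2 = VoxelSpec(nx=64, ny=32, nz=100)
    tissue2 = np.zeros(spec2.shape, dtype=np.uint8)
    x = spec2.x_centers()[None, :]
    dej_depth = 20.0 + np.tan(theta) * x  # (1, nx)
    zc = spec2.z_centers()[:, None, None]
    tissue2[:] = VIABLE_EPIDERMIS
    deeper = np.broadcast_to(zc >= dej_depth[None, :, :], spec2.shape)
    tissue2[deeper] = DERMIS
    save_volume(LabeledVolume(tissue2, spec2), out_dir, "tilted_dej")
    expected["tilted_dej"] = {
        "dej_undulation": 100.0 * (1.0 / math.cos(theta) - 1.0),
    }

    r = 8.0
    spec3 = VoxelSpec(nx=24, ny=24, nz=24)
    xs = spec3.x_centers()
    m = (
        (xs[None, None, :] - 12.2) ** 2
        + (xs[None, :, None] - 12.1) ** 2
        + (xs[:, None, None] - 11.9) ** 2
    ) <= r**2
    ball_tissue = np.full(spec3.shape, VIABLE_EPIDERMIS, dtype=np.uint8)
    save_volume(
        LabeledVolume(ball_tissue, spec3, instances=m.astype(np.int32)), out_dir, "ball"
    )
    expected["ball"] = {"volume": 4.0 / 3.0 * math.pi * r**3, "compactness": 1.0}

    # regular 6-layer lattice of small balls inside a flat VE slab
    spec4 = VoxelSpec(nx=120, ny=120, nz=80)
    t4 = np.zeros(spec4.shape, dtype=np.uint8)
    t4[4:] = STRATUM_CORNEUM
    t4[10:] = VIABLE_EPIDERMIS
    t4[70:] = DERMIS
    inst = np.zeros(spec4.shape, dtype=np.int32)
    xs4, ys4, zs4 = spec4.x_centers(), spec4.y_centers(), spec4.z_centers()
    nid = 1
    for li in range(6):
        z = 70.0 - (li + 0.5) / 6.0 * 60.0
        z_sel = (np.abs(zs4 - z) <= 3.0)[:, None, None]
        for gy in range(6):
            for gx in range(6):
                cx, cy = 10.0 + gx * 20.0, 10.0 + gy * 20.0
                lat = ((xs4[None, :] - cx) ** 2 + (ys4[:, None] - cy) ** 2) <= 9.0
                mask = z_sel & lat[None, :, :]
                inst[mask & (t4 == VIABLE_EPIDERMIS) & (inst == 0)] = nid
                nid += 1
    save_volume(LabeledVolume(t4, spec4, instances=inst), out_dir, "lattice6")
    expected["lattice6"] = {"layer_number": 6.0, "layer_number_sd": 0.0}

    (out_dir / "expected.json").write_text(json.dumps(expected, indent=2, sort_keys=True))
    return expected
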