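"""Reading and writing labeled volumes, heightmaps and metric tables.

Volumes are stored either as multi-page TIFF (one page per z slice; tissue
and instance labels in separate files) or as NIfTI-1 with the voxel pitch
in the affine.  A JSON sidecar carries the voxel spec and metadata; an
optional ROI mask is stored as its own single-page image.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .core import LabeledVolume, VoxelSpec

__all__ = ["save_volume", "load_volume", "save_ground_truth"]


def _nifti_from(data: np.ndarray, spec: VoxelSpec) -> nib.Nifti1Image:
    # NIfTI convention is (x, y, z); volumes are (z, y, x) in memory
    img = nib.Nifti1Image(np.ascontiguousarray(data.transpose(2, 1, 0)),
                          np.diag([spec.dx, spec.dy, spec.dz, 1.0]))
    return img


def save_volume(
    volume: LabeledVolume, directory: str | Path, stem: str, fmt: str = "tiff"
) -> Path:
    """Write tissue (+ instances, ROI) and a JSON sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = volume.spec
    files: dict[str, str] = {}
    if fmt == "tiff":
        tifffile.imwrite(directory / f"{stem}_tissue.tif", volume.tissue.astype(np.uint8))
        files["tissue"] = f"{stem}_tissue.tif"
        if volume.instances is not None:
            tifffile.imwrite(directory / f"{stem}_instances.tif", volume.instances.astype(np.int32))
            files["instances"] = f"{stem}_instances.tif"
        if volume.roi_mask is not None:
            tifffile.imwrite(directory / f"{stem}_roi.tif", volume.roi_mask.astype(np.uint8))
            files["roi"] = f"{stem}_roi.tif"
    elif fmt == "nifti":
        nib.save(_nifti_from(volume.tissue.astype(np.uint8), spec), directory / f"{stem}_tissue.nii.gz")
        files["tissue"] = f"{stem}_tissue.nii.gz"
        if volume.instances is not None:
            nib.save(_nifti_from(volume.instances.astype(np.int32), spec), directory / f"{stem}_instances.nii.gz")
            files["instances"] = f"{stem}_instances.nii.gz"
        if volume.roi_mask is not None:
            tifffile.imwrite(directory / f"{stem}_roi.tif", volume.roi_mask.astype(np.uint8))
            files["roi"] = f"{stem}_roi.tif"
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'tiff' or 'nifti')")
    sidecar = directory / f"{stem}.json"
    sidecar.write_text(
        json.dumps(
            {"voxel_spec": spec.to_dict(), "format": fmt, "files": files, "meta": volume.meta},
            indent=2,
            sort_keys=True,
        )
    )
    return sidecar


def load_volume(sidecar: str | Path) -> LabeledVolume:
    """Load a volume written by :func:`save_volume` from its JSON sidecar."""
    sidecar = Path(sidecar)
    info = json.loads(sidecar.read_text())
    spec = VoxelSpec.from_dict(info["voxel_spec"])
    directory = sidecar.parent
    fmt = info["format"]
    files = info["files"]

    def _read(name: str) -> np.ndarray:
        path = directory / files[name]
        if fmt == "tiff" or path.suffix == ".tif":
            return np.asarray(tifffile.imread(path))
        img = nib.load(path)
        return np.asarray(img.dataobj).transpose(2, 1, 0)

    tissue = _read("tissue")
    instances = _read("instances") if "instances" in files else None
    roi = _read("roi").astype(bool) if "roi" in files else None
    return LabeledVolume(
        tissue=tissue, spec=spec, instances=instances, roi_mask=roi, meta=info.get("meta", {})
    )


def save_ground_truth(gt, directory: str | Path, stem: str) -> None:
    """Ground truth as a per-nucleus CSV plus a JSON summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not gt.nuclei.empty:
        gt.nuclei.to_csv(directory / f"{stem}_nuclei.csv", index=False)
    summary = {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
               for k, v in gt.summary().items()}
    (directory / f"{stem}_truth.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
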