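"""Core data containers: voxel grids, labeled skin volumes and interface heightmaps.

Conventions
-----------
* Volumes are indexed ``(z, y, x)`` with ``z`` increasing downward from the
  skin surface (slice 0 is the topmost, shallowest slice).
* The voxel ``(iz, iy, ix)`` is the axis-aligned box whose *center* sits at
  ``((iz + 0.5) * dz, (iy + 0.5) * dy, (ix + 0.5) * dx)`` in micrometres.
* Interface depths are continuous, in micrometres, measured from the top of
  the grid.  An interface between two tissue bands is located at the first
  voxel of the deeper band (half-open intervals, 0-based z).
* Tissue labels partition every voxel: background above the skin, then
  stratum corneum, viable epidermis and dermis.  Nuclei instance labels are
  positive integers and occur only inside viable-epidermis voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "BACKGROUND",
    "STRATUM_CORNEUM",
    "VIABLE_EPIDERMIS",
    "DERMIS",
    "TISSUE_NAMES",
    "VoxelSpec",
    "HeightMap",
    "LabeledVolume",
    "EmptyMaskError",
    "DegenerateVolumeError",
    "GridTooSmallError",
    "PackingError",
    "CalibrationError",
]

BACKGROUND = 0
STRATUM_CORNEUM = 1
VIABLE_EPIDERMIS = 2
DERMIS = 3

TISSUE_NAMES = {
    BACKGROUND: "background",
    STRATUM_CORNEUM: "stratum_corneum",
    VIABLE_EPIDERMIS: "viable_epidermis",
    DERMIS: "dermis",
}


class EmptyMaskError(ValueError):
    """Raised when an operation receives a heightmap pair with no joint support."""


class DegenerateVolumeError(ValueError):
    """Raised when too many columns of a volume are missing a tissue interface."""


class GridTooSmallError(ValueError):
    """Raised when a voxel grid cannot hold the requested layer stack."""


class PackingError(RuntimeError):
    """Raised when a requested nuclear density is geometrically unachievable."""

    def __init__(self, band: str, message: str):
        self.band = band
        super().__init__(message)


class CalibrationError(RuntimeError):
    """Raised when amplitude calibration fails to reach the undulation target."""

    def __init__(self, target: float, achieved: float, message: str | None = None):
        self.target = target
        self.achieved = achieved
        super().__init__(
            message
            or f"undulation calibration did not converge: target={target:g}, achieved={achieved:g}"
        )


@dataclass(frozen=True)
class VoxelSpec:
    """Voxel pitch and grid size of a 3D acquisition.

    Defaults follow the acquisition geometry of the imaging system being
    emulated: a 1200 um x 500 um lateral field of view with a 1 um z step.
    The lateral pixel pitch is taken as 1 um as well (isotropic ~1 um
    resolution); it is configurable.
    """

    dx: float = 1.0
    dy: float = 1.0
    dz: float = 1.0
    nx: int = 1200
    ny: int = 500
    nz: int = 350

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError("voxel pitches must be positive")
        if not (self.nx >= 1 and self.ny >= 1 and self.nz >= 1):
            raise ValueError("grid sizes must be >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape in ``(z, y, x)`` order."""
        return (self.nz, self.ny, self.nx)

    @property
    def lateral_shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in um^3."""
        return self.dx * self.dy * self.dz

    @property
    def lateral_extent(self) -> tuple[float, float]:
        """Physical lateral extent ``(x, y)`` in um."""
        return (self.nx * self.dx, self.ny * self.dy)

    @property
    def lateral_area_mm2(self) -> float:
        ex, ey = self.lateral_extent
        return ex * ey * 1e-6

    @property
    def depth_extent(self) -> float:
        return self.nz * self.dz

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz

    def to_dict(self) -> dict:
        return {
            "dx": self.dx,
            "dy": self.dy,
            "dz": self.dz,
            "nx": self.nx,
            "ny": self.ny,
            "nz": self.nz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelSpec":
        return cls(**{k: d[k] for k in ("dx", "dy", "dz", "nx", "ny", "nz")})


@dataclass
class HeightMap:
    """Lateral grid of interface depths in micrometres.

    ``values`` is a ``(ny, nx)`` float array; positions outside ``mask`` hold
    NaN.  The grid node ``(iy, ix)`` refers to the center of the image column
    ``(iy, ix)``, i.e. the lateral point ``((iy + 0.5) dy, (ix + 0.5) dx)``.
    """

    values: np.ndarray
    dx: float = 1.0
    dy: float = 1.0
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("heightmap values must be 2D (ny, nx)")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
            self.values = np.where(self.mask, self.values, np.nan)
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("lateral pitches must be positive")
        if self.mask.any() and not np.isfinite(self.values[self.mask]).all():
            raise ValueError("heightmap depths must be finite inside the mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Depth at lateral physical positions (nearest grid node)."""
        ix = np.clip(np.rint(np.asarray(x) / self.dx - 0.5).astype(int), 0, self.shape[1] - 1)
        iy = np.clip(np.rint(np.asarray(y) / self.dy - 0.5).astype(int), 0, self.shape[0] - 1)
        return self.values[iy, ix]

    def copy(self) -> "HeightMap":
        return HeightMap(self.values.copy(), self.dx, self.dy, self.mask.copy())


@dataclass
class LabeledVolume:
    """A 3D labeled skin volume: tissue labels, optional nuclei instances, ROI.

    ``roi_mask`` is a lateral boolean map (True = analysed column); it encodes
    exclusion of hair follicles / appendages from the region of interest.
    """

    tissue: np.ndarray
    spec: VoxelSpec
    instances: Optional[np.ndarray] = None
    roi_mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tissue = np.asarray(self.tissue)
        if self.tissue.shape != self.spec.shape:
            raise ValueError(
                f"tissue shape {self.tissue.shape} does not match spec {self.spec.shape}"
            )
        if self.instances is not None:
            self.instances = np.asarray(self.instances)
            if self.instances.shape != self.tissue.shape:
                raise ValueError("instance labels must share the tissue grid")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != self.spec.lateral_shape:
                raise ValueError("roi_mask must be a lateral (ny, nx) map")

    @property
    def roi(self) -> np.ndarray:
        """Effective lateral ROI (all-True when no mask was supplied)."""
        if self.roi_mask is None:
            return np.ones(self.spec.lateral_shape, dtype=bool)
        return self.roi_mask

    def check_partition(self) -> None:
        """Assert the labeling invariants (partition; nuclei inside VE)."""
        labels = np.unique(self.tissue)
        if not np.isin(labels, list(TISSUE_NAMES)).all():
            raise ValueError(f"unexpected tissue labels {labels}")
        if self.instances is not None:
            inside = self.tissue[self.instances > 0]
            if inside.size and not (inside == VIABLE_EPIDERMIS).all():
                raise ValueError("nuclei instance labels occur outside the viable epidermis")
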