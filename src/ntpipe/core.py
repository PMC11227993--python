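"""Shared domain containers for the intrinsic-neural-timescale pipeline.

Conventions
-----------
* Image arrays are indexed ``(x, y, z)`` or ``(x, y, z, t)``.
* Millimetre coordinates follow a nominal MNI-like RAS convention defined by
  :class:`AtlasGeometry`: voxel index ``(0, 0, 0)`` sits at ``origin_mm`` and
  axes scale by ``voxel_size_mm``.  The mapping is affine and invertible.
* Background voxels in a parcellation carry label ``0``; every nonzero label
  has a human-readable name and belongs to a named functional network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

GROUPS = ("CN", "AD")
SEXES = ("F", "M")


@dataclass(frozen=True)
class AtlasGeometry:
    """Voxel grid geometry: dimensions, spacing and mm origin.

    Parameters
    ----------
    grid_dims
        Number of voxels along x, y, z (each >= 1).
    voxel_size_mm
        Strictly positive voxel edge lengths in mm.
    origin_mm
        Millimetre coordinate of the centre of voxel ``(0, 0, 0)``.
    """

    grid_dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.grid_dims) != 3 or any(int(d) < 1 for d in self.grid_dims):
            raise ValueError(f"grid_dims must be three integers >= 1, got {self.grid_dims}")
        if len(self.voxel_size_mm) != 3 or any(not (s > 0) for s in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be strictly positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "grid_dims", tuple(int(d) for d in self.grid_dims))
        object.__setattr__(self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (diagonal scaling plus origin)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def voxel_to_mm(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.voxel_size_mm) + np.asarray(self.origin_mm)

    def mm_to_voxel(self, mm) -> np.ndarray:
        """Inverse mapping; returns fractional voxel indices."""
        mm = np.asarray(mm, dtype=float)
        return (mm - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-centre mm coordinates."""
        grids = np.meshgrid(*(np.arange(d) for d in self.grid_dims), indexing="ij")
        idx = np.stack(grids, axis=-1).astype(float)
        return self.voxel_to_mm(idx)

    def contains_mm(self, mm) -> bool:
        """True if ``mm`` lies inside the grid bounding box (voxel edges)."""
        frac = self.mm_to_voxel(mm)
        dims = np.asarray(self.grid_dims)
        return bool(np.all(frac >= -0.5) and np.all(frac <= dims - 0.5))


@dataclass
class Bold4D:
    """A subject's 4D BOLD-like signal with its sampling interval."""

    values: np.ndarray  # (x, y, z, t)
    tr_s: float
    geometry: AtlasGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError(f"values must be 4D (x,y,z,t), got ndim={self.values.ndim}")
        if self.values.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        if not (self.tr_s > 0):
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD values must be finite")
        if tuple(self.values.shape[:3]) != tuple(self.geometry.grid_dims):
            raise ValueError(
                f"spatial shape {self.values.shape[:3]} does not match geometry {self.geometry.grid_dims}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[3]


@dataclass
class IntMap:
    """3D map of per-voxel intrinsic neural timescale, in seconds.

    ``mask`` flags voxels where the estimate is defined; outside the mask
    (or at degenerate voxels) ``values`` is NaN, never silently zero.
    """

    values: np.ndarray
    mask: np.ndarray
    geometry: AtlasGeometry
    tr_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 3:
            raise ValueError("values and mask must be matching 3D arrays")
        inside = self.values[self.mask]
        if inside.size and (not np.all(np.isfinite(inside)) or np.any(inside < 0)):
            raise ValueError("in-mask INT values must be finite and nonnegative")

    @property
    def n_defined(self) -> int:
        return int(self.mask.sum())


@dataclass
class Parcellation:
    """Labelled 3D grid mapping voxels to named parcels and networks."""

    labels: np.ndarray
    label_names: Mapping[int, str]
    network_of: Mapping[str, str]  # parcel name -> network name
    geometry: AtlasGeometry

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels without a name: {sorted(missing)}")
        for name in self.label_names.values():
            if name not in self.network_of:
                raise ValueError(f"parcel {name!r} has no network assignment")

    @property
    def parcel_names(self) -> list[str]:
        return [self.label_names[k] for k in sorted(self.label_names)]

    @property
    def networks(self) -> list[str]:
        seen: list[str] = []
        for name in self.parcel_names:
            net = self.network_of[name]
            if net not in seen:
                seen.append(net)
        return seen

    def label_for(self, name: str) -> int:
        for lab, nm in self.label_names.items():
            if nm == name:
                return lab
        raise KeyError(f"unknown parcel name {name!r}")

    def parcel_mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_for(name)

    def network_mask(self, network: str) -> np.ndarray:
        labs = [lab for lab, nm in self.label_names.items() if self.network_of[nm] == network]
        if not labs:
            raise KeyError(f"unknown network {network!r}")
        return np.isin(self.labels, labs)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def parcel_centroid_mm(self, name: str) -> np.ndarray:
        idx = np.argwhere(self.parcel_mask(name))
        if idx.size == 0:
            raise ValueError(f"parcel {name!r} has no voxels")
        return self.geometry.voxel_to_mm(idx.mean(axis=0))


@dataclass
class SubjectRecord:
    """Phenotype row for one subject."""

    id: str
    group: str
    age: float
    sex: str
    mmse: int
    roi_gmv: dict[str, float] = field(default_factory=dict)
    mean_motion_mm: float = 0.0
    cognitive_z: Optional[dict[str, float]] = None
    battery: Optional[dict[str, float]] = None  # raw neuropsychological scores

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (0 <= self.mmse <= 30):
            raise ValueError(f"mmse must lie in [0, 30], got {self.mmse}")
        if self.mean_motion_mm < 0:
            raise ValueError("mean_motion_mm must be nonnegative")
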