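"""Summaries of INT maps over networks, parcels and small spherical ROIs.

Network and parcel means are arithmetic means over *defined* voxels only;
undefined (degenerate or out-of-mask) voxels are excluded, and a network
with no defined voxel at all is an error rather than a silent NaN.

Spherical ROIs use the voxel-centre criterion with an inclusive boundary
(distance <= radius), which makes a 4 mm sphere on a 4 mm grid pick up the
centre voxel plus its six face neighbours.  A sphere is never empty: when
no voxel centre falls within the radius the nearest voxel is included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AtlasGeometry, IntMap, Parcellation


@dataclass(frozen=True)
class SphereRoi:
    center_mm: tuple[float, float, float]
    radius_mm: float
    voxel_indices: np.ndarray  # (N, 3) int

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxel_indices",
                           np.asarray(self.voxel_indices, dtype=int).reshape(-1, 3))
        if not (self.radius_mm > 0):
            raise ValueError("radius_mm must be positive")
        if self.voxel_indices.shape[0] == 0:
            raise ValueError("a sphere ROI can never be empty")


def sphere_roi(center_mm, radius_mm: float, geometry: AtlasGeometry) -> SphereRoi:
    """Voxels whose centres lie within ``radius_mm`` (Euclidean, mm) of
    ``center_mm``; falls back to the single nearest voxel if none do."""
    center = np.asarray(center_mm, dtype=float)
    if center.shape != (3,):
        raise ValueError("center_mm must be a 3-vector")
    if not (radius_mm > 0):
        raise ValueError("radius_mm must be positive")
    if not geometry.contains_mm(center):
        raise ValueError(f"sphere centre {tuple(center)} lies outside the grid")
    centers = geometry.voxel_centers_mm()  # (nx, ny, nz, 3)
    dist = np.linalg.norm(centers - center, axis=-1)
    inside = np.argwhere(dist <= radius_mm + 1e-9)
    if inside.shape[0] == 0:
        inside = np.argwhere(dist == dist.min())[:1]
    return SphereRoi(center_mm=tuple(center), radius_mm=float(radius_mm),
                     voxel_indices=inside)


def roi_mean(intmap: IntMap, roi: SphereRoi) -> float:
    """Mean INT over the defined voxels of a sphere ROI."""
    idx = roi.voxel_indices
    defined = intmap.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    if not defined.any():
        raise ValueError("every voxel of the ROI is undefined")
    vals = intmap.values[idx[:, 0], idx[:, 1], idx[:, 2]][defined]
    return float(vals.mean())


def parcel_mean(intmap: IntMap, parc: Parcellation, name: str) -> float:
    """Mean INT over the defined voxels of one named parcel."""
    sel = parc.parcel_mask(name) & intmap.mask
    if not sel.any():
        raise ValueError(f"parcel {name!r} has no defined voxels")
    return float(intmap.values[sel].mean())


def network_mean(intmap: IntMap, parc: Parcellation, network: str) -> float:
    """Mean INT across all defined voxels of a named network."""
    sel = parc.network_mask(network) & intmap.mask
    if not sel.any():
        raise ValueError(f"network {network!r} has no defined voxels")
    return float(intmap.values[sel].mean())


def summarize_subject(
    intmap: IntMap,
    parc: Parcellation,
    rois: dict[str, SphereRoi] | None = None,
) -> dict[str, float]:
    """Per-subject summary row: mean INT of every network plus optional
    sphere ROIs.  Keys follow the ``<name>_int`` convention used by the
    mediation suite (the DMN appears as ``DMN_int``)."""
    row: dict[str, float] = {}
    for network in parc.networks:
        row[f"{network}_int"] = network_mean(intmap, parc, network)
    for name, roi in (rois or {}).items():
        row[f"{name}_int"] = roi_mean(intmap, roi)
    return row


def summary_table(
    int_maps: dict[str, IntMap],
    parc: Parcellation,
    rois: dict[str, SphereRoi] | None = None,
) -> pd.DataFrame:
    """Stack per-subject summaries into a tidy subject x variable table."""
    rows = []
    for sid, imap in int_maps.items():
        row = {"subject": sid}
        row.update(summarize_subject(imap, parc, rois))
        rows.append(row)
    return pd.DataFrame(rows)
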