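"""NIfTI / TSV / JSON serialization of the pipeline's artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import AtlasGeometry, Bold4D, IntMap, Parcellation


def _geometry_from_affine(affine: np.ndarray, shape) -> AtlasGeometry:
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot))):
        raise ValueError("only axis-aligned (diagonal) affines are supported")
    voxel = tuple(float(v) for v in np.diag(rot))
    if any(v <= 0 for v in voxel):
        raise ValueError("voxel sizes in the affine must be positive")
    return AtlasGeometry(tuple(int(s) for s in shape[:3]), voxel,
                         tuple(float(o) for o in affine[:3, 3]))


def save_bold(bold: Bold4D, path) -> None:
    img = nib.Nifti1Image(bold.values.astype(np.float32), bold.geometry.affine)
    img.header.set_zooms((*bold.geometry.voxel_size_mm, bold.tr_s))
    nib.save(img, str(path))


def load_bold(path, tr_s: float | None = None) -> Bold4D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if tr_s is None:
        zooms = img.header.get_zooms()
        if len(zooms) < 4 or not (zooms[3] > 0):
            raise ValueError("TR missing from NIfTI header; pass tr_s explicitly")
        tr_s = float(zooms[3])
    geom = _geometry_from_affine(img.affine, data.shape)
    return Bold4D(values=data, tr_s=tr_s, geometry=geom)


def save_int_map(intmap: IntMap, path, sidecar_path=None, options: dict | None = None) -> None:
    """Write the INT map (float32 seconds, NaN where undefined) and an
    optional JSON sidecar recording TR, estimator options and the
    undefined-voxel count."""
    img = nib.Nifti1Image(intmap.values.astype(np.float32), intmap.geometry.affine)
    nib.save(img, str(path))
    if sidecar_path is not None:
        meta = {
            "tr_s": intmap.tr_s,
            "n_defined": intmap.n_defined,
            "n_undefined": int(intmap.values.size - intmap.n_defined),
            "units": "seconds",
        }
        meta.update(options or {})
        Path(sidecar_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_int_map(path, tr_s: float | None = None, sidecar_path=None) -> IntMap:
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=float)
    if tr_s is None:
        if sidecar_path is None:
            raise ValueError("pass tr_s or a sidecar path")
        tr_s = float(json.loads(Path(sidecar_path).read_text())["tr_s"])
    geom = _geometry_from_affine(img.affine, values.shape)
    return IntMap(values=values, mask=np.isfinite(values), geometry=geom, tr_s=tr_s)


def save_atlas(parc: Parcellation, nii_path, json_path) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int16), parc.geometry.affine)
    nib.save(img, str(nii_path))
    meta = {
        "label_names": {str(k): v for k, v in parc.label_names.items()},
        "network_of": dict(parc.network_of),
    }
    Path(json_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_atlas(nii_path, json_path) -> Parcellation:
    img = nib.load(str(nii_path))
    labels = np.asarray(img.get_fdata()).astype(np.int32)
    meta = json.loads(Path(json_path).read_text())
    geom = _geometry_from_affine(img.affine, labels.shape)
    return Parcellation(labels=labels,
                        label_names={int(k): v for k, v in meta["label_names"].items()},
                        network_of=meta["network_of"], geometry=geom)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(str(path), sep="\t", index=False, float_format="%.10g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")
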