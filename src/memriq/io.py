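"""NIfTI, sidecar and metrics-table I/O.

Volumes and label maps are written as NIfTI-1 with a diagonal affine built
from the voxel spacing; dynamic series go to a single 4D NIfTI plus a JSON
sidecar holding timestamps (min) and window tags.  Acquisition metadata
(flip angles, TR/TE) and ground-truth manifests are JSON; metrics tables
are CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicSeries, ImageVolume, LabelMap


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def save_volume(vol: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.voxel_size)), str(path))


def load_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(np.asanyarray(img.dataobj, dtype=np.float64), tuple(zooms))


def save_labelmap(labels: LabelMap, path: str | Path, sector_path: str | Path | None = None) -> None:
    aff = _affine(labels.voxel_size)
    nib.save(nib.Nifti1Image(labels.tissue.astype(np.int16), aff), str(path))
    if sector_path is not None:
        nib.save(nib.Nifti1Image(labels.sector.astype(np.int16), aff), str(sector_path))


def load_labelmap(path: str | Path, sector_path: str | Path | None = None) -> LabelMap:
    img = nib.load(str(path))
    zooms = tuple(img.header.get_zooms()[:3])
    tissue = np.asanyarray(img.dataobj).astype(np.int16)
    sector = None
    if sector_path is not None:
        sector = np.asanyarray(nib.load(str(sector_path)).dataobj).astype(np.int16)
    return LabelMap(tissue=tissue, voxel_size=zooms, sector=sector)


def save_series(series: DynamicSeries, path: str | Path, sidecar_path: str | Path) -> None:
    data4d = np.stack([f.data for f in series.frames], axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(data4d, _affine(series.voxel_size)), str(path))
    sidecar = {
        "times_min": [float(t) for t in series.times_min],
        "windows": list(series.windows),
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def load_series(path: str | Path, sidecar_path: str | Path) -> DynamicSeries:
    img = nib.load(str(path))
    zooms = tuple(img.header.get_zooms()[:3])
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {data.shape}")
    meta = json.loads(Path(sidecar_path).read_text())
    frames = [ImageVolume(data[..., k], zooms) for k in range(data.shape[-1])]
    return DynamicSeries(frames, np.asarray(meta["times_min"]), list(meta["windows"]))


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_metrics(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def load_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
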