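"""Readers and writers: TSV cohort tables, NIfTI masks/series/maps, HDF5 dense matrices.

NIfTI handling goes through nibabel; dense N x N matrices (which outgrow text
formats quickly) are stored as chunked HDF5 datasets with provenance metadata
(mask hash, K, df) in the attributes so downstream stages can verify inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py
import nibabel as nib

from .core import CohortTable, GridMask, MaskedSeries, SpatialMapSet, ValidationError

__all__ = [
    "read_cohort",
    "read_mask",
    "read_masked_series",
    "write_series",
    "write_mask",
    "write_map_set",
    "read_map_set",
    "write_dense_h5",
    "read_dense_h5",
]


class SchemaError(ValueError):
    """A tabular input lacks required structure."""


def read_cohort(path) -> CohortTable:
    """Read a cohort TSV with columns ``subject_id`` and ``age`` (weeks GA).

    Row order is preserved.  Motion traces, when used, are attached separately
    (they are per-subject arrays, not tabular columns).
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as e:
        raise SchemaError(f"empty cohort table: {path}") from e
    for col in ("subject_id", "age"):
        if col not in df.columns:
            raise SchemaError(f"cohort table missing required column '{col}'")
    age = pd.to_numeric(df["age"], errors="coerce").to_numpy()
    if np.any(~np.isfinite(age)):
        bad = df["age"][~np.isfinite(age)].iloc[0]
        raise SchemaError(f"non-numeric age value: {bad!r}")
    return CohortTable(df["subject_id"].astype(str).tolist(), age)


def write_cohort(cohort: CohortTable, path) -> None:
    pd.DataFrame({"subject_id": cohort.subject_id, "age": cohort.age}).to_csv(
        path, sep="\t", index=False
    )


def _affine(mask: GridMask) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(mask.voxel_size)
    return aff


def read_mask(path, mirror_axis: int | None = None) -> GridMask:
    """Build a :class:`GridMask` from a binary/label NIfTI image."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError("mask image must be 3D")
    vox = np.argwhere(data > 0)
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    mask = GridMask(vox, data.shape, voxel_size)
    if mirror_axis is not None:
        mask = mask.with_mirror_pairs(axis=mirror_axis)
    return mask


def write_mask(mask: GridMask, path) -> None:
    vol = mask.boolean_volume().astype(np.uint8)
    nib.save(nib.Nifti1Image(vol, _affine(mask)), str(path))


def read_masked_series(path, mask: GridMask, subject_id: str | None = None,
                       t_r: float | None = None) -> MaskedSeries:
    """Read a 4D NIfTI into an (N, T) matrix in canonical mask order.

    The image grid must match the mask grid; in-mask NaNs are a data error.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValidationError("series image must be 4D")
    if data.shape[:3] != tuple(mask.shape):
        raise ValidationError(
            f"grid mismatch: image {data.shape[:3]} vs mask {mask.shape}"
        )
    series = mask.from_volume(data.astype(float))
    if not np.all(np.isfinite(series)):
        raise ValidationError(f"non-finite in-mask values in {path}")
    if t_r is None:
        zooms = img.header.get_zooms()
        t_r = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    sid = subject_id if subject_id is not None else str(path)
    return MaskedSeries(sid, series, t_r)


def write_series(series: MaskedSeries, mask: GridMask, path) -> None:
    vol = mask.to_volume(series.data)
    img = nib.Nifti1Image(vol, _affine(mask))
    img.header.set_zooms(tuple(mask.voxel_size) + (series.t_r,))
    nib.save(img, str(path))


def write_map_set(maps: SpatialMapSet, mask: GridMask, path) -> None:
    """Write M spatial maps as a 4D NIfTI (one volume per map, 0 outside mask)."""
    if maps.n_maps < 1:
        raise ValidationError("cannot write an empty map set")
    if not np.all(np.isfinite(maps.maps)):
        raise ValidationError("non-finite value in map set")
    if maps.n_voxels != mask.n_voxels:
        raise ValidationError("map set / mask voxel count mismatch")
    vol = mask.to_volume(maps.maps.T.astype(np.float64))
    nib.save(nib.Nifti1Image(vol, _affine(mask)), str(path))


def read_map_set(path, mask: GridMask, kind: str = "matnet") -> SpatialMapSet:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 3:
        data = data[..., None]
    if data.shape[:3] != tuple(mask.shape):
        raise ValidationError("grid mismatch between map image and mask")
    return SpatialMapSet(mask.from_volume(data).T, kind=kind)


def write_dense_h5(path, values: np.ndarray, *, name: str = "t_values",
                   attrs: dict | None = None, chunk_rows: int = 256) -> None:
    """Store a dense N x N matrix as a row-major-chunked HDF5 dataset."""
    values = np.asarray(values)
    n = values.shape[0]
    with h5py.File(path, "w") as f:
        d = f.create_dataset(
            name, data=values, chunks=(min(chunk_rows, n), n)
        )
        for k, v in (attrs or {}).items():
            d.attrs[k] = v


def read_dense_h5(path, name: str = "t_values"):
    """Return (matrix, attrs) from :func:`write_dense_h5` output."""
    with h5py.File(path, "r") as f:
        d = f[name]
        return d[...], dict(d.attrs)
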