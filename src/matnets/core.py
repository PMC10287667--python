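"""Core data model shared by every pipeline stage.

The single source of truth for voxel ordering lives here: an in-mask voxel's
position in every N-length vector of the package is its rank in the
lexicographic ordering of its (x, y, z) lattice index.  All readers, writers
and simulators go through :class:`GridMask` so that ordering can never drift
between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "GridMask",
    "CohortTable",
    "MaskedSeries",
    "SpatialMapSet",
    "smooth_series",
    "FWHM_TO_SIGMA",
]

# FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


@dataclass
class GridMask:
    """An N-voxel brain mask on a shared lattice.

    Parameters
    ----------
    voxel_index : (N, 3) int array
        Lattice coordinates of in-mask voxels, lexicographically sorted.
    shape : tuple of int
        Shape of the enclosing 3D grid.
    voxel_size : (3,) float array
        Voxel edge length per axis in mm.
    tissue_label : (N,) array of str, optional
        e.g. ``{"cortex", "white-matter", "other"}``.
    mirror_pair : (N,) int array, optional
        Index of the homologous contralateral voxel; -1 where undefined
        (midline / unpaired).  Must be an involution where defined.
    """

    voxel_index: np.ndarray
    shape: tuple
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    tissue_label: np.ndarray | None = None
    mirror_pair: np.ndarray | None = None

    def __post_init__(self):
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_index.ndim != 2 or self.voxel_index.shape[1] != 3:
            raise ValidationError("voxel_index must be (N, 3)")
        if self.n_voxels == 0:
            raise ValidationError("mask is empty")
        order = np.lexsort(self.voxel_index.T[::-1])
        if not np.array_equal(order, np.arange(self.n_voxels)):
            # enforce the canonical ordering rather than erroring
            self.voxel_index = self.voxel_index[order]
            if self.tissue_label is not None:
                self.tissue_label = np.asarray(self.tissue_label)[order]
            if self.mirror_pair is not None:
                inv = np.empty(self.n_voxels, dtype=np.intp)
                inv[order] = np.arange(self.n_voxels)
                mp = np.asarray(self.mirror_pair)[order]
                self.mirror_pair = np.where(mp >= 0, inv[mp], -1)
        uniq = np.unique(self.voxel_index, axis=0)
        if uniq.shape[0] != self.n_voxels:
            raise ValidationError("duplicate voxel coordinates in mask")
        if np.any(self.voxel_index < 0) or np.any(
            self.voxel_index >= np.asarray(self.shape)
        ):
            raise ValidationError("mask voxel outside grid bounds")
        if self.mirror_pair is not None:
            mp = np.asarray(self.mirror_pair, dtype=np.intp)
            defined = mp >= 0
            if np.any(mp[defined] >= self.n_voxels):
                raise ValidationError("mirror_pair index out of range")
            back = mp[mp[defined]]
            if not np.array_equal(back, np.flatnonzero(defined)):
                raise ValidationError("mirror_pair is not an involution")
            self.mirror_pair = mp

    @property
    def n_voxels(self) -> int:
        return self.voxel_index.shape[0]

    @property
    def coords_mm(self) -> np.ndarray:
        """(N, 3) physical coordinates of voxel centres in mm."""
        return self.voxel_index * self.voxel_size

    # ---- dense-volume round trips ------------------------------------
    def flat_index(self) -> np.ndarray:
        """Raveled (C-order) grid index of each in-mask voxel."""
        return np.ravel_multi_index(tuple(self.voxel_index.T), self.shape)

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Embed an (N,) or (N, M) array into the full 3D/4D grid."""
        values = np.asarray(values)
        extra = values.shape[1:]
        vol = np.full(self.shape + extra, fill, dtype=values.dtype)
        vol[tuple(self.voxel_index.T)] = values
        return vol

    def from_volume(self, vol: np.ndarray) -> np.ndarray:
        """Extract in-mask values (mask order) from a 3D/4D grid array."""
        if vol.shape[:3] != tuple(self.shape):
            raise ValidationError(
                f"grid mismatch: volume {vol.shape[:3]} vs mask {self.shape}"
            )
        return vol[tuple(self.voxel_index.T)]

    def boolean_volume(self) -> np.ndarray:
        return self.to_volume(np.ones(self.n_voxels, dtype=bool), fill=False)

    def with_mirror_pairs(self, axis: int = 0) -> "GridMask":
        """Pair each voxel with its reflection through the grid midplane.

        Voxels whose reflection falls outside the mask get pair -1.
        """
        reflected = self.voxel_index.copy()
        reflected[:, axis] = self.shape[axis] - 1 - reflected[:, axis]
        lut = {tuple(v): i for i, v in enumerate(self.voxel_index)}
        mp = np.array([lut.get(tuple(v), -1) for v in reflected], dtype=np.intp)
        # self-paired midline voxels are treated as unpaired
        mp[mp == np.arange(self.n_voxels)] = -1
        # drop one-sided pairs so the involution holds
        ok = mp >= 0
        mp[ok & (mp[mp[ok]] != np.flatnonzero(ok))] = -1
        return GridMask(
            self.voxel_index.copy(),
            self.shape,
            self.voxel_size.copy(),
            None if self.tissue_label is None else self.tissue_label.copy(),
            mp,
        )

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.voxel_index).tobytes())
        h.update(np.asarray(self.shape, dtype=np.int64).tobytes())
        h.update(np.ascontiguousarray(self.voxel_size).tobytes())
        return h.hexdigest()[:16]


@dataclass
class CohortTable:
    """K subjects with gestational ages and optional motion traces.

    ``motion_trace`` maps subject_id to a (n_params, n_stacks, T) array of
    rigid-body motion-parameter values over time.
    """

    subject_id: list
    age: np.ndarray
    motion_trace: dict | None = None

    def __post_init__(self):
        self.subject_id = [str(s) for s in self.subject_id]
        self.age = np.asarray(self.age, dtype=float)
        if len(set(self.subject_id)) != len(self.subject_id):
            raise ValidationError("duplicate subject_id in cohort")
        if self.n_subjects < 3:
            raise ValidationError(
                "cohort needs K >= 3 subjects for the [1, age] regression"
            )
        if not np.all(np.isfinite(self.age)):
            raise ValidationError("non-finite age in cohort")
        if np.var(self.age) == 0:
            raise ValidationError("age has zero variance: degenerate regressor")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)

    @property
    def df(self) -> int:
        """Residual degrees of freedom of the [intercept, age] design."""
        return self.n_subjects - 2


@dataclass
class MaskedSeries:
    """One subject's voxels-by-time data matrix restricted to a mask."""

    subject_id: str
    data: np.ndarray  # (N, T)
    t_r: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("series data must be (N, T)")
        if self.data.shape[1] < 10:
            raise ValidationError("series needs T >= 10 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(f"non-finite values in series {self.subject_id}")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def zero_variance_voxels(self) -> np.ndarray:
        """Indices of voxels with no temporal variance (flagged, never dropped)."""
        return np.flatnonzero(self.data.std(axis=1) == 0)


@dataclass
class SpatialMapSet:
    """M z-scored spatial maps over the mask.

    Each map has mean 0 and sd 1 over in-mask voxels and non-negative skewness
    (the ICA sign convention).  ``mixing`` holds the R x M (or T x M) mixing
    matrix of the factorisation that produced the maps.
    """

    maps: np.ndarray  # (M, N)
    mixing: np.ndarray | None = None
    kind: str = "matnet"
    ica_seed: int | None = None

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] == 0:
            raise ValidationError("map set must be a nonempty (M, N) array")
        if not np.all(np.isfinite(self.maps)):
            raise ValidationError("non-finite values in spatial maps")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.maps.shape[1]


def zscore_maps(maps: np.ndarray) -> np.ndarray:
    """Z-score each row over the mask and flip signs to non-negative skewness."""
    maps = np.asarray(maps, dtype=float)
    m = maps - maps.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = m / sd
    skew = (z**3).mean(axis=1)
    z[skew < 0] *= -1.0
    return z


def smooth_series(
    series: MaskedSeries, mask: GridMask, fwhm_mm: float
) -> MaskedSeries:
    """Spatially smooth a masked series with a separable Gaussian kernel.

    The series is embedded into the 3D grid (zeros outside the mask), smoothed
    volume-by-volume with sigma = fwhm / (2 sqrt(2 ln 2)) per axis in voxel
    units, and re-extracted.  Intended as the optional pre-stage analogue of
    template-space smoothing; synthetic data may already embed smoothness.
    """
    if fwhm_mm <= 0:
        return series
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / mask.voxel_size
    vol = mask.to_volume(series.data)  # (nx, ny, nz, T)
    out = np.empty_like(vol)
    for t in range(vol.shape[-1]):
        out[..., t] = gaussian_filter(vol[..., t], sigma=sigma_vox)
    return MaskedSeries(series.subject_id, mask.from_volume(out), series.t_r)
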