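"""Univariate signal-property diagnostics and the motion-confound model.

These analyses characterise the raw material the two network pipelines work
from: seed-to-brain correlation maps and their age effects, homologous
interhemispheric connectivity, the distance-vs-similarity relationship over
a k-means parcellation, and the framewise-displacement (FD) principal
component used to assess whether global motion confounds the age regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label
from sklearn.cluster import KMeans

from ._stats import age_ols
from .core import CohortTable, GridMask, ValidationError

__all__ = [
    "SeedMapPair",
    "Parcellation",
    "FDModel",
    "seed_to_brain",
    "homologous_connectivity",
    "seeds_from_age_map",
    "parcellate",
    "distance_similarity",
    "fd_global",
]


@dataclass
class SeedMapPair:
    """Group-mean seed-to-brain correlations and their age-effect t-map."""

    group_mean: np.ndarray  # (N,)
    age_t: np.ndarray  # (N,)
    seed_mask: np.ndarray  # voxel indices of the seed
    excluded_subjects: list


@dataclass
class Parcellation:
    """Spatial k-means parcellation of the mask (labels 1..P, COGs in mm)."""

    labels: np.ndarray  # (N,) in 1..P
    centres_mm: np.ndarray  # (P, 3)

    @property
    def n_parcels(self) -> int:
        return self.centres_mm.shape[0]

    @property
    def n_pairs(self) -> int:
        p = self.n_parcels
        return p * (p - 1) // 2


@dataclass
class FDModel:
    """Per-subject motion summary matrix and its first principal component."""

    summary: np.ndarray  # (K, n_params * n_stacks), column-standardised
    pc1_scores: np.ndarray  # (K,)
    explained_variance_ratio: float
    dropped_columns: np.ndarray


def _corr_rows_with(data: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``data`` with the vector ``ref``."""
    x = data - data.mean(axis=1, keepdims=True)
    r = ref - ref.mean()
    xn = np.linalg.norm(x, axis=1)
    rn = np.linalg.norm(r)
    denom = xn * rn
    out = np.zeros(data.shape[0])
    ok = denom > 0
    out[ok] = (x[ok] @ r) / denom[ok]
    return np.clip(out, -1.0, 1.0)


def seed_to_brain(series_list, cohort: CohortTable,
                  seed_mask: np.ndarray) -> SeedMapPair:
    """Correlate each seed's mean timecourse with every voxel, per subject;
    average the maps across subjects and fit the per-voxel age effect.

    Subjects whose seed timecourse is constant are excluded from this seed
    with a warning (and from the age fit, which then uses their reduced K).
    """
    seed_mask = np.asarray(seed_mask, dtype=np.intp)
    if seed_mask.size == 0:
        raise ValidationError("seed mask is empty")
    series_list = list(series_list)
    maps, kept_ages, excluded = [], [], []
    for s, age in zip(series_list, cohort.age):
        data = s.data if hasattr(s, "data") else np.asarray(s)
        seed_tc = data[seed_mask].mean(axis=0)
        if seed_tc.std() == 0:
            excluded.append(getattr(s, "subject_id", "?"))
            continue
        maps.append(_corr_rows_with(data, seed_tc))
        kept_ages.append(age)
    if excluded:
        warnings.warn(
            f"excluded subjects with constant seed timecourse: {excluded}"
        )
    if len(maps) < 3:
        raise ValidationError("fewer than 3 usable subjects for this seed")
    stack = np.stack(maps)
    _, t, _, _ = age_ols(stack, np.asarray(kept_ages))
    return SeedMapPair(stack.mean(axis=0), t, seed_mask, excluded)


def homologous_connectivity(series, mask: GridMask) -> np.ndarray:
    """Per-voxel correlation with the homologous contralateral voxel.

    Returns an N-length map, NaN where no mirror partner is defined
    (midline/unpaired voxels).  The map equals its own mirror image by
    construction.  Cohort-level age effects are obtained by stacking these
    maps and using :func:`matnets._stats.age_ols`.
    """
    if mask.mirror_pair is None:
        raise ValidationError("mask has no mirror pairing")
    data = series.data if hasattr(series, "data") else np.asarray(series)
    mp = mask.mirror_pair
    out = np.full(mask.n_voxels, np.nan)
    ok = mp >= 0
    x = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    idx = np.flatnonzero(ok)
    denom = norms[idx] * norms[mp[idx]]
    valid = denom > 0
    r = np.zeros(idx.size)
    r[valid] = np.einsum(
        "ij,ij->i", x[idx[valid]], x[mp[idx][valid]]
    ) / denom[valid]
    out[idx] = np.clip(r, -1.0, 1.0)
    return out


def seeds_from_age_map(age_t_map: np.ndarray, mask: GridMask,
                       z_pos: float | None = 3.0,
                       z_neg: float | None = None):
    """Threshold an age-effect map and extract 26-connected clusters.

    Returns a list of (voxel-index array, sign) tuples sorted by decreasing
    size; positive clusters (map > z_pos) first, then negative clusters
    (map < z_neg) for white-matter-style seeds.  An empty result is not an
    error.
    """
    age_t_map = np.asarray(age_t_map, dtype=float)
    if not np.all(np.isfinite(age_t_map)):
        raise ValidationError("age map must be finite")
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    clusters = []
    for thr, sign in ((z_pos, +1), (z_neg, -1)):
        if thr is None:
            continue
        supra = age_t_map > thr if sign > 0 else age_t_map < thr
        vol = mask.to_volume(supra, fill=False)
        labelled, n = cc_label(vol, structure=structure)
        in_mask = mask.from_volume(labelled)
        for c in range(1, n + 1):
            vox = np.flatnonzero(in_mask == c)
            if vox.size:
                clusters.append((vox, sign))
    clusters.sort(key=lambda c: -c[0].size)
    return clusters


def parcellate(mask: GridMask, n_parcels: int = 300, seed: int = 0,
               max_retries: int = 3) -> Parcellation:
    """k-means parcellation of the mask on voxel mm-coordinates."""
    if n_parcels > mask.n_voxels:
        raise ValidationError("more parcels than voxels")
    coords = mask.coords_mm
    for attempt in range(max_retries):
        km = KMeans(
            n_clusters=n_parcels, init="k-means++", n_init=1,
            random_state=seed + attempt,
        ).fit(coords)
        counts = np.bincount(km.labels_, minlength=n_parcels)
        if counts.min() > 0:
            labels = km.labels_ + 1
            centres = np.stack(
                [coords[labels == p + 1].mean(axis=0) for p in range(n_parcels)]
            )
            return Parcellation(labels, centres)
    raise ValidationError(
        f"k-means produced an empty parcel in {max_retries} attempts"
    )


def distance_similarity(series_list, cohort: CohortTable, mask: GridMask,
                        n_parcels: int = 300, kmeans_seed: int = 0):
    """Distance vs seed-map similarity over all unordered parcel pairs.

    Each parcel is used as a seed for :func:`seed_to_brain`; for every pair
    the Euclidean distance between parcel centres-of-gravity is related to
    the spatial correlation of the two group-mean maps and of the two
    age-effect t-maps.  Returns (pair DataFrame, r_distance_vs_groupmean,
    r_distance_vs_aget, parcellation).
    """
    parc = parcellate(mask, n_parcels, kmeans_seed)
    series_list = list(series_list)
    gm = np.empty((parc.n_parcels, mask.n_voxels))
    at = np.empty_like(gm)
    for p in range(parc.n_parcels):
        seed = np.flatnonzero(parc.labels == p + 1)
        pair = seed_to_brain(series_list, cohort, seed)
        gm[p], at[p] = pair.group_mean, pair.age_t
    iu = np.triu_indices(parc.n_parcels, k=1)
    dists = np.linalg.norm(
        parc.centres_mm[iu[0]] - parc.centres_mm[iu[1]], axis=1
    )

    def rows_corr(a):
        x = a - a.mean(axis=1, keepdims=True)
        x /= np.maximum(np.linalg.norm(x, axis=1, keepdims=True), 1e-30)
        return (x @ x.T)[iu]

    sim_gm = rows_corr(gm)
    sim_at = rows_corr(at)
    table = pd.DataFrame(
        {
            "parcel_a": iu[0] + 1,
            "parcel_b": iu[1] + 1,
            "distance_mm": dists,
            "r_groupmean_maps": sim_gm,
            "r_ageT_maps": sim_at,
        }
    )
    if len(dists) > 1:
        r_gm = float(np.corrcoef(dists, sim_gm)[0, 1])
        r_at = float(np.corrcoef(dists, sim_at)[0, 1])
    else:  # a single pair has no distance variance
        r_gm = r_at = float("nan")
    return table, r_gm, r_at, parc


def fd_global(cohort: CohortTable, n_params: int = 6,
              n_stacks: int = 16) -> FDModel:
    """Global motion measure from per-parameter framewise displacements.

    Per subject and per (parameter, stack): the mean absolute frame-to-frame
    difference of the motion parameter.  The K x (n_params * n_stacks)
    summary matrix is standardised column-wise across subjects (constant
    columns dropped with a warning) and its first principal component gives
    the per-subject global motion score, sign-aligned to correlate
    positively with row-mean motion.
    """
    if cohort.motion_trace is None:
        raise ValidationError("cohort has no motion traces")
    rows = []
    for sid in cohort.subject_id:
        trace = np.asarray(cohort.motion_trace[sid], dtype=float)
        if trace.shape[:2] != (n_params, n_stacks):
            raise ValidationError(
                f"motion trace for {sid} has shape {trace.shape}, expected "
                f"({n_params}, {n_stacks}, T)"
            )
        fd = np.abs(np.diff(trace, axis=-1)).mean(axis=-1)  # (params, stacks)
        rows.append(fd.reshape(-1))
    summary = np.stack(rows)  # (K, params*stacks)
    mu = summary.mean(axis=0)
    sd = summary.std(axis=0)
    # relative tolerance: identical rows leave only accumulation rounding
    constant = sd <= 1e-10 * np.maximum(np.abs(mu), 1.0)
    dropped = np.flatnonzero(constant)
    if dropped.size == summary.shape[1]:
        raise ValidationError(
            "all motion summary columns are constant across subjects"
        )
    if dropped.size:
        warnings.warn(f"dropping {dropped.size} constant motion columns")
    keep = ~constant
    z = (summary[:, keep] - mu[keep]) / sd[keep]
    u, s, _ = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    pc1 = u[:, 0] * s[0]
    rowmean = z.mean(axis=1)
    if np.corrcoef(pc1, rowmean)[0, 1] < 0:
        pc1 = -pc1
    evr = float(s[0] ** 2 / np.sum(s**2))
    return FDModel(z, pc1, evr, dropped)
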