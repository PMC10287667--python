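"""Downstream maturational-connectome analysis.

Everything that follows the matnet factorisation: emerging-connectivity
profiles (each matnet's "complementary map" of targets for age-increasing
coupling), the M x M maturational connectome of profile similarities, its
3-D spectral embedding, Ward grouping with the finest-no-singleton rule,
per-group maturational hub maps, and matnet/complementary-map coupling
trajectories across the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
import statsmodels.api as sm

from .core import CohortTable, SpatialMapSet, ValidationError
from .connectome import MaturationalDense

__all__ = [
    "ConnectivityProfiles",
    "MatnetConnectome",
    "EmbeddingCoords",
    "GroupPartition",
    "HubMaps",
    "CouplingTrajectory",
    "connectivity_profiles",
    "maturational_connectome",
    "LaplacianEmbedding",
    "laplacian_embedding",
    "WardPartition",
    "ward_partition",
    "hub_maps",
    "coupling_trajectory",
]


@dataclass
class ConnectivityProfiles:
    """M x N regression slopes: row m is matnet m's complementary map."""

    slopes: np.ndarray

    def __post_init__(self):
        self.slopes = np.asarray(self.slopes, dtype=float)
        if not np.all(np.isfinite(self.slopes)):
            raise ValidationError("non-finite values in connectivity profiles")

    @property
    def n_maps(self) -> int:
        return self.slopes.shape[0]


@dataclass
class MatnetConnectome:
    """Pairwise Pearson correlation between emerging-connectivity profiles."""

    corr: np.ndarray
    zero_variance: np.ndarray | None = None

    def __post_init__(self):
        self.corr = np.asarray(self.corr, dtype=float)


@dataclass
class EmbeddingCoords:
    """Spectral coordinates of the networks (M x dim) plus retained eigenvalues."""

    coords: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class GroupPartition:
    """Network grouping: labels (1..G), selected G, and the full Ward linkage."""

    labels: np.ndarray
    n_groups: int
    linkage: np.ndarray


@dataclass
class HubMaps:
    """Per-group first principal component of the complementary maps."""

    maps: np.ndarray  # (G, N)
    explained_variance: np.ndarray  # (G,)
    group_ids: np.ndarray


@dataclass
class CouplingTrajectory:
    """Per-subject matnet/complementary-map coupling plus its age trajectory."""

    coupling: np.ndarray  # (K,) Pearson r per subject
    ages: np.ndarray
    poly_order: int
    coefficients: np.ndarray  # ascending powers of age
    predicted: np.ndarray  # fitted values at the subject ages
    ci_low: np.ndarray
    ci_high: np.ndarray
    bic_by_order: dict


def connectivity_profiles(matnets: SpatialMapSet,
                          m_dense: MaturationalDense) -> ConnectivityProfiles:
    """Regress every column of the thresholded maturational dense connectome
    on the demeaned matnet maps (plus an intercept).

    Column v's slopes say how strongly each matnet's territory predicts
    voxel v's age-related connectivity increase; collected over v they form
    the matnets' complementary maps.
    """
    if not m_dense.thresholded:
        raise ValidationError(
            "connectivity profiles require the *thresholded* maturational "
            "dense connectome"
        )
    maps = matnets.maps
    n = maps.shape[1]
    if m_dense.n_voxels != n:
        raise ValidationError("matnet maps and dense connectome mask mismatch")
    x = (maps - maps.mean(axis=1, keepdims=True)).T  # (N, M)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        d = np.abs(np.diag(np.linalg.qr(x, mode="reduced")[1]))
        bad = np.flatnonzero(d < d.max() * 1e-10).tolist()
        raise ValidationError(
            f"collinear matnet maps (rank {rank} < {x.shape[1]}): "
            f"components {bad}"
        )
    design = np.column_stack([np.ones(n), x])
    coef = np.linalg.lstsq(design, m_dense.factorisation_input(), rcond=None)[0]
    return ConnectivityProfiles(coef[1:])


def maturational_connectome(profiles: ConnectivityProfiles) -> MatnetConnectome:
    """Pearson correlation between every pair of complementary maps."""
    p = profiles.slopes
    if p.shape[0] < 2:
        raise ValidationError("maturational connectome needs M >= 2 profiles")
    x = p - p.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    flagged = np.flatnonzero(norms == 0)
    safe = norms.copy()
    safe[flagged] = 1.0
    c = (x / safe[:, None]) @ (x / safe[:, None]).T
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    if flagged.size:
        warnings.warn(f"zero-variance profiles: {flagged.tolist()}")
        c[flagged, :] = 0.0
        c[:, flagged] = 0.0
    return MatnetConnectome(c, flagged)


class LaplacianEmbedding:
    """Spectral embedding of the maturational connectome.

    The affinity is the positive off-diagonal part of the correlation matrix
    (alternative: affinity="shifted" uses (1 + r) / 2).  Coordinates are the
    eigenvectors of the symmetric normalised Laplacian
    L = I - D^{-1/2} W D^{-1/2} for the ``n_dims`` smallest strictly positive
    eigenvalues, ordered ascending.  Optionally scaled by 1/sqrt(eigenvalue)
    (diffusion-style), off by default.
    """

    def __init__(self, n_dims: int = 3, affinity: str = "positive",
                 scale_by_eigenvalue: bool = False, tol: float = 1e-10):
        self.n_dims = n_dims
        self.affinity = affinity
        self.scale_by_eigenvalue = scale_by_eigenvalue
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_dims": self.n_dims,
            "affinity": self.affinity,
            "scale_by_eigenvalue": self.scale_by_eigenvalue,
            "tol": self.tol,
        }

    def set_params(self, **params) -> "LaplacianEmbedding":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(self, connectome) -> np.ndarray:
        corr = (
            connectome.corr
            if isinstance(connectome, MatnetConnectome)
            else np.asarray(connectome, dtype=float)
        )
        m = corr.shape[0]
        if m <= self.n_dims:
            raise ValidationError(
                f"need more networks ({m}) than embedding dimensions "
                f"({self.n_dims})"
            )
        if self.affinity == "positive":
            w = np.maximum(corr, 0.0)
        elif self.affinity == "shifted":
            w = (1.0 + corr) / 2.0
        else:
            raise ValidationError(f"unknown affinity {self.affinity!r}")
        np.fill_diagonal(w, 0.0)
        deg = w.sum(axis=1)
        isolated = np.flatnonzero(deg <= 0)
        if isolated.size:
            raise ValidationError(
                f"isolated networks (zero affinity degree): {isolated.tolist()}"
            )
        n_comp, comp_labels = connected_components(w > 0, directed=False)
        if n_comp > self.n_dims + 1:
            groups = [np.flatnonzero(comp_labels == c).tolist()
                      for c in range(n_comp)]
            raise ValidationError(
                f"affinity graph has {n_comp} connected components: {groups}"
            )
        d_isqrt = 1.0 / np.sqrt(deg)
        lap = np.eye(m) - d_isqrt[:, None] * w * d_isqrt[None, :]
        lap = (lap + lap.T) / 2.0
        evals, evecs = np.linalg.eigh(lap)
        pos = evals > self.tol
        if pos.sum() < self.n_dims:
            raise ValidationError("not enough strictly positive eigenvalues")
        idx = np.flatnonzero(pos)[: self.n_dims]
        coords = evecs[:, idx]
        if self.scale_by_eigenvalue:
            coords = coords / np.sqrt(evals[idx])[None, :]
        self.eigenvalues_ = evals[idx]
        self.coords_ = coords
        return coords


def laplacian_embedding(connectome, dim: int = 3, **kwargs) -> EmbeddingCoords:
    """Functional wrapper over :class:`LaplacianEmbedding`."""
    est = LaplacianEmbedding(n_dims=dim, **kwargs)
    coords = est.fit_transform(connectome)
    return EmbeddingCoords(coords, est.eigenvalues_)


class WardPartition:
    """Ward hierarchical clustering with the finest-no-singleton rule.

    The number of groups G is the largest cut count in {2..M} whose clusters
    all have at least 2 members; if no such cut exists, G = 1.  The full
    linkage is retained for dendrogram rendering.
    """

    def __init__(self, max_groups: int | None = None):
        self.max_groups = max_groups

    def get_params(self, deep: bool = True) -> dict:
        return {"max_groups": self.max_groups}

    def set_params(self, **params) -> "WardPartition":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, coords) -> "WardPartition":
        coords = (
            coords.coords if isinstance(coords, EmbeddingCoords)
            else np.asarray(coords, dtype=float)
        )
        m = coords.shape[0]
        if m < 2:
            raise ValidationError("need at least 2 networks to partition")
        self.linkage_ = linkage(coords, method="ward")
        upper = m if self.max_groups is None else min(self.max_groups, m)
        chosen, labels = 1, np.ones(m, dtype=int)
        for g in range(upper, 1, -1):
            lab = fcluster(self.linkage_, t=g, criterion="maxclust")
            if len(np.unique(lab)) != g:
                continue  # ties can make this cut unreachable
            if np.min(np.bincount(lab)[1:]) >= 2:
                chosen, labels = g, lab
                break
        self.labels_ = labels
        self.n_groups_ = chosen
        return self


def ward_partition(coords, max_groups: int | None = None) -> GroupPartition:
    """Functional wrapper over :class:`WardPartition`."""
    est = WardPartition(max_groups=max_groups).fit(coords)
    return GroupPartition(est.labels_, est.n_groups_, est.linkage_)


def hub_maps(profiles: ConnectivityProfiles,
             partition: GroupPartition) -> HubMaps:
    """First principal component of each group's complementary maps.

    Maps are treated as observations: each map in the group is centred over
    voxels and the first right singular vector of the stacked group is the
    hub map, sign-aligned to correlate non-negatively with the group-mean
    map.  (Centring per map rather than per voxel keeps a group of identical
    maps well-defined: its hub is that map, with explained variance 1.)
    """
    labels = np.asarray(partition.labels)
    groups = np.unique(labels)
    n = profiles.slopes.shape[1]
    maps = np.zeros((groups.size, n))
    ev = np.zeros(groups.size)
    for gi, g in enumerate(groups):
        rows = profiles.slopes[labels == g]
        if rows.shape[0] == 1:
            warnings.warn(f"group {g} has a single map; hub = that map")
            maps[gi] = rows[0]
            ev[gi] = 1.0
            continue
        centred = rows - rows.mean(axis=1, keepdims=True)
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        hub = vt[0]
        mean_map = rows.mean(axis=0)
        if hub @ (mean_map - mean_map.mean()) < 0:
            hub = -hub
        maps[gi] = hub
        ev[gi] = s[0] ** 2 / np.sum(s**2) if np.sum(s**2) > 0 else 0.0
    return HubMaps(maps, ev, groups)


def _weighted_timecourse(map_z: np.ndarray, data: np.ndarray,
                         z_thresh: float) -> np.ndarray:
    above = map_z > z_thresh
    if not np.any(above):
        raise ValidationError(
            f"no voxels above z = {z_thresh}; lower the threshold"
        )
    w = map_z[above]
    return (w @ data[above]) / w.sum()


def coupling_trajectory(matnet_map: np.ndarray, complementary_map: np.ndarray,
                        series_list, cohort: CohortTable, z_thresh: float = 5.0,
                        orders=(1, 2, 3), alpha: float = 0.05) -> CouplingTrajectory:
    """Age trajectory of the temporal coupling between a matnet and its
    complementary map.

    Both maps are thresholded at z > ``z_thresh`` (reducing their spatial
    overlap); each subject's two timecourses are z-weighted averages over the
    suprathreshold voxels, and the coupling is their Pearson correlation.
    A polynomial in age is fitted to the couplings with the order chosen by
    BIC over ``orders``; the confidence band on the mean trajectory is
    reported at level ``alpha``.
    """
    matnet_map = np.asarray(matnet_map, dtype=float)
    complementary_map = np.asarray(complementary_map, dtype=float)
    series_list = list(series_list)
    if len(series_list) != cohort.n_subjects:
        raise ValidationError("series list does not match cohort size")
    coupling = np.empty(cohort.n_subjects)
    for i, s in enumerate(series_list):
        data = s.data if hasattr(s, "data") else np.asarray(s)
        a = _weighted_timecourse(matnet_map, data, z_thresh)
        b = _weighted_timecourse(complementary_map, data, z_thresh)
        a = a - a.mean()
        b = b - b.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        coupling[i] = a @ b / denom if denom > 0 else 0.0
    ages = cohort.age
    bics = {}
    fits = {}
    for order in sorted(orders):
        x = np.vander(ages, N=order + 1, increasing=True)
        model = sm.OLS(coupling, x).fit()
        bics[order] = float(model.bic)
        fits[order] = model
    best_order = min(bics, key=bics.get)
    model = fits[best_order]
    pred = model.get_prediction(
        np.vander(ages, N=best_order + 1, increasing=True)
    )
    frame = pred.summary_frame(alpha=alpha)
    return CouplingTrajectory(
        coupling=coupling,
        ages=ages,
        poly_order=best_order,
        coefficients=np.asarray(model.params),
        predicted=frame["mean"].to_numpy(),
        ci_low=frame["mean_ci_lower"].to_numpy(),
        ci_high=frame["mean_ci_upper"].to_numpy(),
        bic_by_order=bics,
    )
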