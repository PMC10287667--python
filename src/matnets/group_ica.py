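"""Reference pipeline: group ICA, dual regression, mass-univariate age modelling.

This is the standard group-analysis route the maturational-network approach
is compared against: temporally concatenated subjects are reduced with the
incremental block SVD (subjects as blocks), factorised with spatial ICA, and
subject-specific variants of the group maps are obtained by dual regression
and modelled voxelwise with age as covariate.  The spatial correlation
between each group map and its age-effect t-map is the pipeline's bias
diagnostic: a strong negative value signals that connectivity *within* a
network's own territory shrinks with age, the signature of age-dependent
effective resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stats import age_ols
from .core import CohortTable, MaskedSeries, SpatialMapSet, ValidationError
from .decomposition import SpatialICA, incremental_block_svd

__all__ = [
    "SubjectNetworkEstimates",
    "AgeEffectMaps",
    "GroupICA",
    "group_ica",
    "DualRegression",
    "dual_regression",
    "mass_univariate_age",
    "map_ageeffect_bias",
    "fdr_correct",
]


@dataclass
class SubjectNetworkEstimates:
    """Dual-regression output for one subject."""

    subject_id: str
    timecourses: np.ndarray  # (T, M), variance-normalised
    maps: np.ndarray  # (M, N)


@dataclass
class AgeEffectMaps:
    """Voxelwise age-effect t-maps per group component."""

    t_maps: np.ndarray  # (M, N)
    beta: np.ndarray  # (M, N)
    df: int


def _variance_normalise_voxels(data: np.ndarray) -> np.ndarray:
    """Demean each voxel timecourse and scale it to unit sd (sd 0 left at 0)."""
    x = data - data.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


class GroupICA:
    """Group spatial ICA over temporally concatenated subjects.

    fit() streams per-subject voxelwise-variance-normalised T x N matrices
    through the incremental block SVD (one block per subject) and factorises
    the reduced data with :class:`SpatialICA`.

    Attributes
    ----------
    maps_ : (M, N) z-scored group spatial maps.
    reduced_ : the retained :class:`~matnets.decomposition.ReducedBasis`.
    """

    def __init__(self, n_components: int = 25, r_keep: int = 500,
                 variance_normalise: bool = True, random_state: int = 0,
                 **ica_kwargs):
        self.n_components = n_components
        self.r_keep = r_keep
        self.variance_normalise = variance_normalise
        self.random_state = random_state
        self.ica_kwargs = ica_kwargs

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components,
            "r_keep": self.r_keep,
            "variance_normalise": self.variance_normalise,
            "random_state": self.random_state,
            **self.ica_kwargs,
        }

    def set_params(self, **params) -> "GroupICA":
        for k, v in params.items():
            if hasattr(self, k):
                setattr(self, k, v)
            else:
                self.ica_kwargs[k] = v
        return self

    def fit(self, series_list) -> "GroupICA":
        series_list = list(series_list)
        if len(series_list) < 2:
            raise ValidationError("group ICA needs at least 2 subjects")

        def blocks():
            for s in series_list:
                data = s.data if isinstance(s, MaskedSeries) else np.asarray(s)
                x = (
                    _variance_normalise_voxels(data)
                    if self.variance_normalise
                    else data - data.mean(axis=1, keepdims=True)
                )
                yield x.T  # (T, N) rows

        self.reduced_ = incremental_block_svd(
            blocks(), n_blocks=len(series_list), r_keep=self.r_keep
        )
        ica = SpatialICA(
            n_components=self.n_components,
            random_state=self.random_state,
            **self.ica_kwargs,
        ).fit(self.reduced_)
        self.maps_ = ica.maps_
        self.mixing_ = ica.mixing_
        self.explained_variance_ = ica.explained_variance_
        return self


def group_ica(series_list, m_components: int, r_keep: int = 500,
              seed: int = 0, **kwargs) -> SpatialMapSet:
    """Functional wrapper over :class:`GroupICA`; returns the group map set."""
    est = GroupICA(
        n_components=m_components, r_keep=r_keep, random_state=seed, **kwargs
    ).fit(series_list)
    return SpatialMapSet(est.maps_, mixing=est.mixing_, kind="group_ica",
                         ica_seed=seed)


class DualRegression:
    """Two-stage subject-level estimation against group maps.

    Stage 1 regresses each timepoint's voxel pattern on the demeaned group
    maps (spatial regression), giving per-subject component timecourses;
    stage 2 regresses each voxel's timecourse on those (variance-normalised)
    timecourses (temporal regression), giving subject-specific maps.
    """

    def __init__(self, normalise_timecourses: bool = True):
        self.normalise_timecourses = normalise_timecourses

    def get_params(self, deep: bool = True) -> dict:
        return {"normalise_timecourses": self.normalise_timecourses}

    def set_params(self, **params) -> "DualRegression":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, group_maps) -> "DualRegression":
        maps = group_maps.maps if isinstance(group_maps, SpatialMapSet) else group_maps
        maps = np.asarray(maps, dtype=float)
        design = maps - maps.mean(axis=1, keepdims=True)  # (M, N)
        m = design.shape[0]
        rank = np.linalg.matrix_rank(design)
        if rank < m:
            # name offenders: components whose map is (near-)linearly dependent
            # on the others, detected by a tiny diagonal in the QR of the design
            d = np.abs(np.diag(np.linalg.qr(design.T, mode="reduced")[1]))
            bad = np.flatnonzero(d < d.max() * 1e-10).tolist()
            raise ValidationError(
                f"group-map design is rank deficient (rank {rank} < {m}); "
                f"collinear components (QR order): {bad}"
            )
        self.design_ = design
        self.pinv_ = np.linalg.pinv(design.T)  # (M, N)^T pseudo-inverse
        return self

    def transform(self, series: MaskedSeries) -> SubjectNetworkEstimates:
        if not hasattr(self, "design_"):
            raise RuntimeError("DualRegression must be fitted with group maps first")
        data = series.data  # (N, T)
        if data.shape[0] != self.design_.shape[1]:
            raise ValidationError("series and group maps are on different masks")
        # stage 1: spatial regression, one multiple regression per timepoint
        x = data - data.mean(axis=0, keepdims=True)
        tc = (self.pinv_ @ x).T  # (T, M)
        tc = tc - tc.mean(axis=0, keepdims=True)
        if self.normalise_timecourses:
            sd = tc.std(axis=0, keepdims=True)
            sd[sd == 0] = 1.0
            tc = tc / sd
        # stage 2: temporal regression, one multiple regression per voxel
        y = data - data.mean(axis=1, keepdims=True)  # (N, T)
        maps = np.linalg.lstsq(tc, y.T, rcond=None)[0]  # (M, N)
        return SubjectNetworkEstimates(series.subject_id, tc, maps)


def dual_regression(group_maps, series: MaskedSeries,
                    normalise_timecourses: bool = True) -> SubjectNetworkEstimates:
    """Functional wrapper over :class:`DualRegression` for one subject."""
    return DualRegression(normalise_timecourses).fit(group_maps).transform(series)


def mass_univariate_age(subject_maps, cohort: CohortTable) -> AgeEffectMaps:
    """Voxelwise OLS of subject map values on [1, age], per component.

    ``subject_maps`` is a sequence of (M, N) arrays or
    :class:`SubjectNetworkEstimates`, one per subject, in cohort order.
    """
    stack = np.stack(
        [
            s.maps if isinstance(s, SubjectNetworkEstimates) else np.asarray(s)
            for s in subject_maps
        ]
    )  # (K, M, N)
    if stack.shape[0] != cohort.n_subjects:
        raise ValidationError("subject map count does not match cohort size")
    beta, t, _, _ = age_ols(stack, cohort.age)
    return AgeEffectMaps(t_maps=t, beta=beta, df=cohort.df)


def fdr_correct(age_maps: AgeEffectMaps, alpha: float = 0.05):
    """Benjamini-Hochberg FDR over all voxels of all components.

    Two-sided p-values from the t-maps at the maps' df.  Returns (boolean
    rejection mask shaped like t_maps, q-values).  No correction is applied
    anywhere by default; this is an opt-in utility.
    """
    from scipy import stats as _stats
    from statsmodels.stats.multitest import multipletests

    t = age_maps.t_maps
    p = 2.0 * _stats.t.sf(np.abs(t), df=age_maps.df)
    reject, q, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return reject.reshape(t.shape), q.reshape(t.shape)


def map_ageeffect_bias(group_maps, age_maps: AgeEffectMaps) -> np.ndarray:
    """Spatial Pearson r between each group map and its age-effect t-map.

    The distribution of these correlations is the pipeline's bias
    diagnostic; a strongly negative median indicates that the apparent age
    effect within each network mirrors the network's own layout.
    """
    maps = group_maps.maps if isinstance(group_maps, SpatialMapSet) else group_maps
    maps = np.asarray(maps, dtype=float)
    t = age_maps.t_maps
    if maps.shape != t.shape:
        raise ValidationError("group maps and t-maps have mismatched shapes")
    out = np.empty(maps.shape[0])
    for i in range(maps.shape[0]):
        ti = t[i]
        finite = np.isfinite(ti)
        a, b = maps[i, finite], ti[finite]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        out[i] = float(a @ b / denom) if denom > 0 else 0.0
    return out
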