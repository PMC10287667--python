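"""End-to-end convenience drivers for the two network pipelines.

The matnet route: per-subject dense connectomes -> cross-subject age
regression -> positive thresholding -> incremental block SVD -> spatial ICA.
The reference route: voxelwise variance normalisation -> temporal
concatenation (incremental block SVD with subjects as blocks) -> spatial ICA
-> dual regression -> mass-univariate age modelling.
"""

from __future__ import annotations

import numpy as np

from .connectome import (
    MaturationalDense,
    compute_dense_connectome,
    fit_age_effect,
    threshold_positive,
)
from .core import CohortTable, SpatialMapSet
from .decomposition import incremental_block_svd, spatial_ica
from .group_ica import DualRegression, group_ica, map_ageeffect_bias, mass_univariate_age

__all__ = [
    "maturational_dense_connectome",
    "matnet_maps",
    "matnets_from_series",
    "reference_pipeline",
    "split_half_replicability",
]


def default_r_keep(n_voxels: int, requested: int = 500) -> int:
    """Cap the reduction rank at N/4 on small grids (500 otherwise)."""
    return int(min(requested, max(2, n_voxels // 4)))


def maturational_dense_connectome(series_list, cohort: CohortTable,
                                  fisher_z: bool = False) -> MaturationalDense:
    """Dense connectome per subject, streamed into the age regression,
    positively thresholded."""
    stream = (compute_dense_connectome(s) for s in series_list)
    m = fit_age_effect(stream, cohort, fisher_z=fisher_z)
    return threshold_positive(m)


def matnet_maps(m_dense: MaturationalDense, m_components: int = 25,
                r_keep: int | None = None, n_blocks: int = 200,
                seed: int = 0, **ica_kwargs) -> SpatialMapSet:
    """Factorise a thresholded maturational dense connectome into matnets."""
    n = m_dense.n_voxels
    r_keep = default_r_keep(n) if r_keep is None else r_keep
    n_blocks = min(n_blocks, max(1, n // 2))
    reduced = incremental_block_svd(
        m_dense.factorisation_input(), n_blocks=n_blocks, r_keep=r_keep
    )
    maps = spatial_ica(reduced, m_components, seed=seed, **ica_kwargs)
    maps.kind = "matnet"
    return maps


def matnets_from_series(series_list, cohort: CohortTable,
                        m_components: int = 25, r_keep: int | None = None,
                        n_blocks: int = 200, seed: int = 0,
                        fisher_z: bool = False):
    """Full matnet pipeline; returns (map set, thresholded MaturationalDense)."""
    m_dense = maturational_dense_connectome(list(series_list), cohort,
                                            fisher_z=fisher_z)
    maps = matnet_maps(m_dense, m_components, r_keep, n_blocks, seed)
    return maps, m_dense


def split_half_replicability(series_list, cohort: CohortTable,
                             m_components: int, seed: int = 0, **kwargs):
    """Independent matnet estimation on approximately age-matched halves.

    Subjects are sorted by age and dealt alternately into two halves, so the
    half age distributions interleave.  Returns (maps_a, maps_b,
    matched-similarity table) where the table is the Hungarian matching of
    the two map sets on |spatial r|.
    """
    from .simulate import score_recovery

    series_list = list(series_list)
    order = np.argsort(cohort.age, kind="stable")
    halves = (order[0::2], order[1::2])
    maps = []
    for h, idx in enumerate(halves):
        sub_cohort = CohortTable(
            [cohort.subject_id[i] for i in idx], cohort.age[idx]
        )
        sub_series = [series_list[i] for i in idx]
        m, _ = matnets_from_series(sub_series, sub_cohort, m_components,
                                   seed=seed + h, **kwargs)
        maps.append(m)
    table = score_recovery(maps[1], maps[0].maps)
    return maps[0], maps[1], table


def reference_pipeline(series_list, cohort: CohortTable,
                       m_components: int = 25, r_keep: int | None = None,
                       seed: int = 0, strict_ica: bool = True):
    """Group ICA + dual regression + mass-univariate age modelling.

    Returns (group map set, list of SubjectNetworkEstimates, AgeEffectMaps,
    per-component map/age-t spatial correlations).  ``strict_ica=False``
    accepts the best ICA attempt when the fixed point cycles above
    tolerance (noise-dominated data); the downstream diagnostics depend on
    the component subspace, not a certified rotation.
    """
    series_list = list(series_list)
    n = series_list[0].data.shape[0]
    r_keep = default_r_keep(n) if r_keep is None else r_keep
    gmaps = group_ica(series_list, m_components, r_keep=r_keep, seed=seed,
                      strict=strict_ica)
    dr = DualRegression().fit(gmaps)
    estimates = [dr.transform(s) for s in series_list]
    age_maps = mass_univariate_age(estimates, cohort)
    bias = map_ageeffect_bias(gmaps, age_maps)
    return gmaps, estimates, age_maps, bias
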