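"""Synthetic fetal-cohort generator with known ground truth.

The generator emulates the statistical structure the maturational-network
method assumes about in-utero fMRI registered to a common space:

* P non-negative spatial network maps (optionally mirror-symmetric
  bilateral) whose latent timecourses are correlated according to an
  age-dependent covariance ``Sigma(age) = baseline + slope * (age - age_ref)``,
  with positive slopes only on declared *emerging* edges;
* spatially autocorrelated noise whose Gaussian kernel width shrinks with
  age, emulating the larger common-space smearing of smaller/younger brains
  (the mechanism behind the negative local age effect);
* an optional per-subject motion factor weakly anti-correlated with age,
  expressed through multiband-stack motion-parameter traces.

Latents are generated first and projected onto the maps, so Sigma(age) is
auditable and cost stays linear in the voxel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment

from .core import CohortTable, GridMask, MaskedSeries, FWHM_TO_SIGMA

__all__ = [
    "TruthSpec",
    "SpecificationError",
    "default_mask",
    "default_truth_spec",
    "generate_cohort",
    "default_ages",
    "score_recovery",
    "estimate_autocorr_length",
]


class SpecificationError(ValueError):
    """The truth specification is internally inconsistent."""


@dataclass
class TruthSpec:
    """Ground truth for a synthetic cohort.

    ``smear_fwhm`` maps age (weeks GA) to a noise-smoothing kernel FWHM in
    mm and must be non-increasing in age.  ``coupling_slope`` is the
    per-week increment of latent correlation on emerging edges; it is zero
    elsewhere.  ``motion_target_r`` is the target correlation between the
    per-subject motion factor and age (the cohort-level default of -0.25
    mirrors the small age/FD collinearity the design assumes).
    """

    mask: GridMask
    network_maps: np.ndarray  # (P, N) non-negative
    baseline_coupling: np.ndarray  # (P, P) at age_ref
    coupling_slope: np.ndarray  # (P, P), per week
    noise_sd: float = 0.5
    smear_fwhm_young: float = 6.0  # mm at age_min
    smear_fwhm_old: float = 2.0  # mm at age_max
    age_min: float = 25.0
    age_max: float = 38.0
    age_ref: float = 25.0
    motion_target_r: float | None = -0.25
    n_motion_params: int = 6
    n_motion_stacks: int = 16
    seed: int = 0
    smear_signal: bool = False  # smear the full series, not just noise

    def __post_init__(self):
        self.network_maps = np.asarray(self.network_maps, dtype=float)
        self.baseline_coupling = np.asarray(self.baseline_coupling, dtype=float)
        self.coupling_slope = np.asarray(self.coupling_slope, dtype=float)
        if np.any(self.network_maps < 0):
            raise SpecificationError("network maps must be non-negative")
        for name in ("baseline_coupling", "coupling_slope"):
            m = getattr(self, name)
            if not np.allclose(m, m.T):
                raise SpecificationError(f"{name} must be symmetric")
        if self.smear_fwhm_old > self.smear_fwhm_young:
            raise SpecificationError("smear FWHM must be non-increasing in age")

    @property
    def n_networks(self) -> int:
        return self.network_maps.shape[0]

    @property
    def emerging_edges(self) -> list:
        iu = np.triu_indices(self.n_networks, k=1)
        nz = self.coupling_slope[iu] != 0
        return list(zip(iu[0][nz].tolist(), iu[1][nz].tolist()))

    def covariance_at(self, age: float) -> np.ndarray:
        return self.baseline_coupling + self.coupling_slope * (age - self.age_ref)

    def smear_fwhm(self, age: float) -> float:
        """Non-increasing linear interpolation of the smearing FWHM (mm)."""
        frac = np.clip(
            (age - self.age_min) / (self.age_max - self.age_min), 0.0, 1.0
        )
        return float(
            self.smear_fwhm_young
            + (self.smear_fwhm_old - self.smear_fwhm_young) * frac
        )


def default_mask(shape=(16, 16, 12), voxel_size=(2.0, 2.0, 2.0),
                 mirror_axis: int = 0) -> GridMask:
    """Ellipsoidal brain-like mask, mirror-symmetric about the x midplane."""
    shape = tuple(shape)
    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    centre = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) / 2.0
    inside = np.sum(((grid - centre) / semi) ** 2, axis=1) <= 1.0
    vox = grid[inside].astype(np.intp)
    mask = GridMask(vox, shape, np.asarray(voxel_size, dtype=float))
    return mask.with_mirror_pairs(axis=mirror_axis)


def _gaussian_blob(mask: GridMask, centre_vox, fwhm_vox: float) -> np.ndarray:
    d2 = np.sum((mask.voxel_index - np.asarray(centre_vox)) ** 2, axis=1)
    sigma = fwhm_vox * FWHM_TO_SIGMA
    return np.exp(-d2 / (2.0 * sigma**2))


def default_truth_spec(mask: GridMask | None = None, n_networks: int = 5,
                       coupling_slope_per_week: float = 0.045,
                       noise_sd: float = 0.5, seed: int = 0,
                       bilateral: bool = True, **kwargs) -> TruthSpec:
    """The stock 5-network truth: two emerging edges and one static network.

    Networks 0-3 participate in the emerging edges (0, 1) and (2, 3), whose
    latent correlation grows linearly from 0 at 25 w GA; network 4 (and any
    further networks) have coherent internal activity throughout but no
    age-related coupling change, so only a correlation-driven method (group
    ICA) should recover them from the age-effect pipeline's point of view.
    The default slope of 0.045/week takes an emerging edge from r = 0 to
    r ~ 0.59 across the 25-38 w range.
    """
    if mask is None:
        mask = default_mask()
    rng = np.random.default_rng(seed)
    shape = np.asarray(mask.shape)
    # blob centres spread over one hemisphere (x < midplane); bilateral
    # networks add the mirrored blob
    maps = np.zeros((n_networks, mask.n_voxels))
    fwhm_vox = max(2.5, min(shape) / 4.0)
    # well-separated blob centres within one hemisphere, as (y, z) fractions
    centres_yz = [(0.19, 0.25), (0.81, 0.25), (0.50, 0.50),
                  (0.19, 0.75), (0.75, 0.70)]
    for p in range(n_networks):
        cx = 0.22 * shape[0]
        if p < len(centres_yz):
            fy, fz = centres_yz[p]
        else:  # extra networks get random interior centres
            fy, fz = rng.uniform(0.25, 0.75, size=2)
        cy, cz = fy * shape[1], fz * shape[2]
        blob = _gaussian_blob(mask, (cx, cy, cz), fwhm_vox)
        if bilateral:
            blob = blob + _gaussian_blob(
                mask, (shape[0] - 1 - cx, cy, cz), fwhm_vox
            )
        maps[p] = blob
    baseline = np.eye(n_networks)
    slope = np.zeros((n_networks, n_networks))
    for i, j in ((0, 1), (2, 3)):
        if j < n_networks:
            slope[i, j] = slope[j, i] = coupling_slope_per_week
    return TruthSpec(
        mask=mask,
        network_maps=maps,
        baseline_coupling=baseline,
        coupling_slope=slope,
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )


def default_ages(n_subjects: int, age_min: float = 25.0,
                 age_max: float = 38.0) -> np.ndarray:
    """Evenly spread gestational ages over the studied 25-38 w range."""
    return np.linspace(age_min, age_max, n_subjects)


def _smeared_noise(rng, mask: GridMask, n_timepoints: int, sigma_vox,
                   sd: float) -> np.ndarray:
    """Unit-free spatially autocorrelated noise, rescaled to overall sd."""
    vol = rng.standard_normal(tuple(mask.shape) + (n_timepoints,))
    if np.any(np.asarray(sigma_vox) > 0):
        for t in range(n_timepoints):
            vol[..., t] = gaussian_filter(vol[..., t], sigma=sigma_vox)
    noise = mask.from_volume(vol)
    scale = noise.std()
    if scale > 0:
        noise *= sd / scale
    return noise


def generate_cohort(spec: TruthSpec, n_subjects: int = 60,
                    n_timepoints: int = 100,
                    ages: np.ndarray | None = None):
    """Draw a full synthetic cohort.

    Returns ``(CohortTable, list[MaskedSeries], TruthSpec)``.  Per subject:
    latent network timecourses with covariance ``Sigma(age)``, projected onto
    the truth maps, plus age-smeared noise; fully reproducible from
    ``spec.seed``.
    """
    if n_subjects < 3:
        raise SpecificationError("need K >= 3 subjects")
    if n_timepoints < 50:
        raise SpecificationError("need T >= 50 timepoints")
    if ages is None:
        ages = default_ages(n_subjects, spec.age_min, spec.age_max)
    ages = np.asarray(ages, dtype=float)
    if ages.size != n_subjects or np.ptp(ages) <= 0:
        raise SpecificationError("ages must span a nondegenerate range")
    # positive definiteness over the sampled range, checked up front
    chols = {}
    for age in ages:
        sigma = spec.covariance_at(age)
        try:
            chols[age] = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as e:
            raise SpecificationError(
                f"Sigma(age={age:.2f}) is not positive definite"
            ) from e
    rng = np.random.default_rng(spec.seed)
    subject_ids = [f"sub-{i:03d}" for i in range(n_subjects)]
    series = []
    sigma_vox_of = lambda age: (
        spec.smear_fwhm(age) * FWHM_TO_SIGMA / spec.mask.voxel_size
    )
    for sid, age in zip(subject_ids, ages):
        latents = rng.standard_normal((n_timepoints, spec.n_networks))
        latents = latents @ chols[age].T  # cov Sigma(age)
        signal = (latents @ spec.network_maps).T  # (N, T)
        sv = sigma_vox_of(age)
        if spec.smear_signal:
            vol = spec.mask.to_volume(signal)
            for t in range(n_timepoints):
                vol[..., t] = gaussian_filter(vol[..., t], sigma=sv)
            signal = spec.mask.from_volume(vol)
        noise = _smeared_noise(rng, spec.mask, n_timepoints, sv, spec.noise_sd)
        series.append(MaskedSeries(sid, signal + noise, t_r=1.0))
    motion = None
    if spec.motion_target_r is not None:
        motion = _motion_traces(rng, ages, spec)
    cohort = CohortTable(subject_ids, ages, motion_trace=motion)
    return cohort, series, spec


def _motion_traces(rng, ages: np.ndarray, spec: TruthSpec,
                   n_motion_timepoints: int = 50) -> dict:
    """One-factor motion model tied to age at the target correlation.

    The per-subject factor f has corr(f, age) = motion_target_r in
    expectation; each (parameter, stack) trace is a random walk whose step
    size scales with loading * (1 + 0.25 f), so the mean absolute framewise
    displacement inherits the one-factor structure.
    """
    k = ages.size
    z_age = (ages - ages.mean()) / ages.std()
    rho = spec.motion_target_r
    f = rho * z_age + np.sqrt(1 - rho**2) * rng.standard_normal(k)
    n_cols = spec.n_motion_params * spec.n_motion_stacks
    loadings = rng.uniform(0.5, 1.5, size=n_cols)
    traces = {}
    for s in range(k):
        amp = np.maximum(loadings * (1.0 + 0.25 * f[s]), 0.05)
        steps = rng.standard_normal((n_cols, n_motion_timepoints)) * amp[:, None]
        walk = np.cumsum(steps, axis=1)
        traces[f"sub-{s:03d}"] = walk.reshape(
            spec.n_motion_params, spec.n_motion_stacks, n_motion_timepoints
        )
    return traces


def score_recovery(estimated, truth_maps: np.ndarray) -> pd.DataFrame:
    """Optimally match estimated maps to truth maps on |spatial Pearson r|.

    One-to-one Hungarian assignment maximising total |r|.  If fewer maps
    were estimated than truths exist, the matching is partial and flagged in
    the ``matched`` column (unmatched truths get matched=False, abs_r=NaN).
    """
    est = estimated.maps if hasattr(estimated, "maps") else np.asarray(estimated)
    truth = np.asarray(truth_maps, dtype=float)
    if truth.shape[0] == 0:
        raise ValueError("need at least one truth map")

    def _rows_norm(a):
        x = a - a.mean(axis=1, keepdims=True)
        return x / np.maximum(np.linalg.norm(x, axis=1, keepdims=True), 1e-30)

    r = _rows_norm(truth) @ _rows_norm(est).T  # (P, M)
    cost = -np.abs(r)
    ti, ei = linear_sum_assignment(cost)
    rows = {int(t): (int(e), float(r[t, e])) for t, e in zip(ti, ei)}
    records = []
    for t in range(truth.shape[0]):
        if t in rows:
            e, rv = rows[t]
            records.append((t, e, rv, abs(rv), True))
        else:
            records.append((t, -1, np.nan, np.nan, False))
    return pd.DataFrame(
        records, columns=["truth", "estimated", "r", "abs_r", "matched"]
    )


def estimate_autocorr_length(series: MaskedSeries, mask: GridMask,
                             axis: int = 0, max_lag: int = 4) -> float:
    """Spatial autocorrelation length (voxels) along one axis.

    Computes the lagged spatial correlation of each volume along ``axis``,
    averages across timepoints, and fits an exponential decay
    rho(d) = exp(-d / length) to lags 1..max_lag by log-linear regression.
    """
    vol = mask.to_volume(series.data)
    inmask = mask.boolean_volume()
    rhos = []
    for d in range(1, max_lag + 1):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -d)
        sl_b[axis] = slice(d, None)
        both = inmask[tuple(sl_a)] & inmask[tuple(sl_b)]
        a = vol[tuple(sl_a)][both]
        b = vol[tuple(sl_b)][both]
        a = a - a.mean()
        b = b - b.mean()
        rho = float(
            np.sum(a * b) / max(np.linalg.norm(a) * np.linalg.norm(b), 1e-30)
        )
        rhos.append(max(rho, 1e-6))
    lags = np.arange(1, max_lag + 1)
    slope = np.polyfit(lags, np.log(rhos), 1)[0]
    return float(-1.0 / slope) if slope < 0 else np.inf
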