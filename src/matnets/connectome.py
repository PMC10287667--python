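"""Per-subject dense connectomes and the maturational dense connectome.

The maturational dense connectome is the package's central object: the N x N
matrix of t-statistics for the effect of gestational age on each voxel-pair
Pearson correlation across subjects.  Thresholding it at zero keeps only
age-related *increases* in coupling, which is what the matnet factorisation
leverages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._stats import RunningAgeOLS
from .core import CohortTable, MaskedSeries, ValidationError

__all__ = [
    "DenseConnectome",
    "MaturationalDense",
    "compute_dense_connectome",
    "AgeEffectRegression",
    "fit_age_effect",
    "threshold_positive",
]

logger = logging.getLogger(__name__)


@dataclass
class DenseConnectome:
    """One subject's N x N voxel-pair Pearson correlation matrix."""

    values: np.ndarray
    subject_id: str = ""
    zero_variance: np.ndarray = field(default_factory=lambda: np.zeros(0, np.intp))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValidationError("connectome must be square")


@dataclass
class MaturationalDense:
    """Age-effect t-values (and slopes) on voxel-pair connectivity.

    The diagonal is zero: self-connectivity is constant 1 and carries no age
    information.  Once ``thresholded``, all entries are >= 0.
    """

    t_values: np.ndarray
    df: int
    beta: np.ndarray | None = None
    thresholded: bool = False
    degenerate: np.ndarray | None = None  # boolean mask of +/-inf sentinels

    def __post_init__(self):
        self.t_values = np.asarray(self.t_values, dtype=float)
        n = self.t_values.shape[0]
        if self.t_values.ndim != 2 or self.t_values.shape[1] != n:
            raise ValidationError("maturational dense connectome must be square")
        if self.df < 1:
            raise ValidationError("df must be >= 1 (K >= 3)")

    @property
    def n_voxels(self) -> int:
        return self.t_values.shape[0]

    def factorisation_input(self) -> np.ndarray:
        """t-matrix with +/-inf sentinels zeroed (with a logged warning)."""
        t = self.t_values
        if self.degenerate is not None and self.degenerate.any():
            n_bad = int(self.degenerate.sum())
            logger.warning(
                "excluding %d degenerate (infinite-t) elements from factorisation",
                n_bad,
            )
            t = np.where(self.degenerate, 0.0, t)
        return t


def compute_dense_connectome(series: MaskedSeries) -> DenseConnectome:
    """Pearson correlation between every pair of in-mask voxel timecourses.

    Zero-variance voxels have their rows/columns set to 0 and are flagged,
    not dropped, so voxel indexing stays aligned with the mask.
    """
    x = series.data - series.data.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(x * x, axis=1))
    flagged = np.flatnonzero(norms == 0)
    safe = norms.copy()
    safe[flagged] = 1.0
    xn = x / safe[:, None]
    r = xn @ xn.T
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0  # symmetrise exactly
    np.fill_diagonal(r, 1.0)
    if flagged.size:
        r[flagged, :] = 0.0
        r[:, flagged] = 0.0
    return DenseConnectome(r, series.subject_id, flagged)


class AgeEffectRegression:
    """Mass-univariate OLS of connectivity on [1, age], sklearn-style.

    Responses stream one subject at a time, so a dense N x N regression holds
    only a constant number of N x N accumulators.

    Parameters
    ----------
    fisher_z : bool
        Regress Fisher-transformed correlations instead of raw r.  Off by
        default (slopes are then per-week change in r).

    Attributes
    ----------
    beta_, t_, se_ : arrays of the element-wise slope, t-value and slope se.
    df_ : residual degrees of freedom (K - 2).
    degenerate_ : boolean mask of elements with zero residual variance.
    """

    def __init__(self, fisher_z: bool = False):
        self.fisher_z = fisher_z

    def get_params(self, deep: bool = True) -> dict:
        return {"fisher_z": self.fisher_z}

    def set_params(self, **params) -> "AgeEffectRegression":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, connectome_stream, cohort: CohortTable) -> "AgeEffectRegression":
        reg = RunningAgeOLS(cohort.age)
        n_seen = 0
        for c in connectome_stream:
            y = c.values if isinstance(c, DenseConnectome) else np.asarray(c, float)
            if self.fisher_z:
                y = np.arctanh(np.clip(y, -1 + 1e-15, 1 - 1e-15))
            reg.add(y)
            n_seen += 1
        if n_seen != cohort.n_subjects:
            raise ValidationError(
                f"stream yielded {n_seen} connectomes for {cohort.n_subjects} subjects"
            )
        self.beta_, self.t_, self.se_, self.degenerate_ = reg.finalize()
        self.df_ = reg.df
        return self

    def to_maturational(self) -> MaturationalDense:
        t = (self.t_ + self.t_.T) / 2.0
        beta = (self.beta_ + self.beta_.T) / 2.0
        deg = self.degenerate_ | self.degenerate_.T
        # averaging +inf with +inf is fine; mixed signs give nan -> zero, flagged
        bad = ~np.isfinite(t) & ~deg
        if bad.any():
            deg = deg | bad
        t = np.where(deg & ~np.isfinite(t), np.where(np.isnan(t), 0.0, t), t)
        np.fill_diagonal(t, 0.0)
        np.fill_diagonal(beta, 0.0)
        # the diagonal is structurally constant (r = 1), not a data defect
        np.fill_diagonal(deg, False)
        return MaturationalDense(t, self.df_, beta=beta, degenerate=deg)


def fit_age_effect(connectome_stream, cohort: CohortTable,
                   fisher_z: bool = False) -> MaturationalDense:
    """OLS of each voxel-pair correlation on [1, age] across subjects.

    Returns the maturational dense connectome: element-wise t = beta / se(beta)
    with df = K - 2, diagonal zeroed.  The design deliberately contains age
    only (no motion covariate); see :mod:`matnets.diagnostics` for the
    framewise-displacement analysis that motivates this.
    """
    est = AgeEffectRegression(fisher_z=fisher_z).fit(connectome_stream, cohort)
    return est.to_maturational()


def threshold_positive(m: MaturationalDense) -> MaturationalDense:
    """Clamp negative t-values to zero (keep age-related increases only).

    Idempotent; refuses a second explicit application to catch pipeline
    wiring mistakes.
    """
    if m.thresholded:
        warnings.warn("maturational connectome already thresholded; no-op")
        return m
    t = np.maximum(m.t_values, 0.0)
    return MaturationalDense(
        t, m.df, beta=m.beta, thresholded=True, degenerate=m.degenerate
    )
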