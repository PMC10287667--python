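"""Streaming mass-univariate OLS on the two-parameter design [1, age].

Every element (voxel pair, voxel, or map value) is fitted independently across
K subjects.  Only sufficient statistics (sum y, sum y^2, sum a*y) are ever
resident, so a dense N x N regression needs a constant number of N x N
accumulators regardless of K.  Ages are centred before accumulation for
numerical conditioning; this leaves slope, t and se unchanged.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RunningAgeOLS", "age_ols"]


class RunningAgeOLS:
    """Accumulate one subject at a time; finalise to (beta, t, se, flags).

    For element y across subjects with centred ages a:
    beta = S_ay / S_aa,  RSS = S_yy - beta^2 S_aa,  se = sqrt(RSS / df / S_aa),
    t = beta / se with df = K - 2.  Exact equality with per-element OLS.
    """

    def __init__(self, ages: np.ndarray):
        ages = np.asarray(ages, dtype=float)
        if ages.size < 3:
            raise ValueError("age regression needs K >= 3 subjects")
        if np.var(ages) == 0:
            raise ValueError("age regressor has zero variance")
        self.a = ages - ages.mean()
        self.s_aa = float(np.sum(self.a**2))
        self.k = ages.size
        self.df = self.k - 2
        self._i = 0
        self._sum_y = None
        self._sum_yy = None
        self._sum_ay = None

    def add(self, y: np.ndarray) -> None:
        y = np.asarray(y, dtype=float)
        if self._i >= self.k:
            raise ValueError("more subjects than ages supplied")
        if self._sum_y is None:
            self._sum_y = np.zeros_like(y)
            self._sum_yy = np.zeros_like(y)
            self._sum_ay = np.zeros_like(y)
        self._sum_y += y
        self._sum_yy += y * y
        self._sum_ay += self.a[self._i] * y
        self._i += 1

    def finalize(self):
        """Return (beta, t, se, degenerate_mask).

        Elements with (numerically) zero residual variance but a nonzero slope
        get t = +/-inf sentinels and are flagged; elements constant across
        subjects get beta = t = 0 and are flagged too.
        """
        if self._i != self.k:
            raise ValueError(f"saw {self._i} subjects, expected {self.k}")
        s_y, s_yy, s_ay = self._sum_y, self._sum_yy, self._sum_ay
        s_yy_c = s_yy - s_y * s_y / self.k  # total SS around the mean
        beta = s_ay / self.s_aa
        rss = s_yy_c - beta * beta * self.s_aa
        # guard tiny negative values from cancellation
        np.maximum(rss, 0.0, out=rss)
        tol = np.maximum(s_yy_c, 1.0) * 1e-12
        degenerate = rss <= tol
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(rss / (self.df * self.s_aa))
            t = beta / se
        constant = degenerate & (s_yy_c <= tol)
        sentinel = np.where(beta > 0, np.inf, np.where(beta < 0, -np.inf, 0.0))
        t = np.where(degenerate, sentinel, t)
        t = np.where(constant, 0.0, t)
        beta = np.where(constant, 0.0, beta)
        return beta, t, se, degenerate


def age_ols(stack: np.ndarray, ages: np.ndarray):
    """Vectorised one-shot variant: ``stack`` is (K, ...) of responses."""
    reg = RunningAgeOLS(ages)
    for y in np.asarray(stack, dtype=float):
        reg.add(y)
    return reg.finalize()
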