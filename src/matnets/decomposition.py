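"""Dimensionality reduction and spatial ICA.

Two engines shared by the matnet and group-ICA pipelines:

* an incremental block SVD (MIGP-style): data arrive as row-blocks over the
  N voxels; blocks are concatenated and repeatedly SVD-reduced to a fixed
  rank, so the full matrix is never resident;
* a spatial fixed-point ICA (logcosh contrast, symmetric decorrelation) over
  the reduced data, with restarts, deterministic seeding, z-scored output
  maps, a non-negative-skewness sign convention and explained-variance
  ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import SpatialMapSet, ValidationError, zscore_maps

__all__ = [
    "ReducedBasis",
    "incremental_block_svd",
    "SpatialICA",
    "ICAConvergenceError",
    "spatial_ica",
    "threshold_maps_for_display",
]


class ICAConvergenceError(RuntimeError):
    """Fixed-point ICA failed to reach tolerance in every restart.

    ``best_n_iter`` records the closest attempt; the estimator that raised
    carries that attempt's fitted attributes, so callers that only need the
    component subspace (not a certified rotation) may use them explicitly
    via ``strict=False``.
    """

    def __init__(self, msg: str, best_n_iter: int):
        super().__init__(msg)
        self.best_n_iter = best_n_iter


@dataclass
class ReducedBasis:
    """R x N reduced representation of a tall matrix over the mask.

    Rows are right singular vectors of the accumulated matrix, scaled by
    their singular values (so downstream SVD/ICA sees correctly weighted
    variance); ``basis`` holds the orthonormal (unweighted) vectors.
    """

    components: np.ndarray  # (R, N), singular-value weighted
    basis: np.ndarray  # (R, N), orthonormal rows
    singular_values: np.ndarray
    rank_kept: int

    @property
    def n_voxels(self) -> int:
        return self.components.shape[1]


def _iter_row_blocks(matrix_source, n_blocks: int):
    """Yield row-blocks (n_i, N) over the voxel dimension.

    An ndarray is split *column-wise* into ``n_blocks`` contiguous blocks and
    each block transposed (columns become observations), matching the way a
    symmetric N x N connectome is streamed.  Any iterable of 2-D arrays is
    consumed as row-blocks directly (e.g. per-subject T x N series).
    """
    if isinstance(matrix_source, np.ndarray):
        if matrix_source.ndim != 2:
            raise ValidationError("matrix source must be 2-D")
        for block in np.array_split(matrix_source, n_blocks, axis=1):
            yield block.T
    else:
        for block in matrix_source:
            block = np.asarray(block, dtype=float)
            if block.ndim != 2:
                raise ValidationError("each block must be 2-D")
            yield block


def incremental_block_svd(matrix_source, n_blocks: int = 200,
                          r_keep: int = 500, weighted: bool = True) -> ReducedBasis:
    """Reduce a tall matrix to its top right-singular subspace block by block.

    The first two blocks are concatenated and SVD-reduced to ``r_keep`` rows
    (retained as singular-value-weighted right singular vectors); each further
    block is appended to the current reduction and the SVD repeated until all
    blocks are exhausted.  The span of the result approximates the top-r_keep
    right-singular subspace of the full stacked matrix, exactly so when the
    matrix rank never exceeds ``r_keep``.

    Parameters
    ----------
    matrix_source : ndarray or iterable of (n_i, N) arrays
        An N x N (or R x N) array is split column-wise into ``n_blocks`` and
        streamed; an iterable is consumed as row-blocks directly.
    n_blocks : int
        Number of column blocks when ``matrix_source`` is an array.
    r_keep : int
        Target rank.  If fewer rows are ever seen, the achievable rank is
        returned with a warning.
    weighted : bool
        Keep singular-value weighting on the retained rows between steps
        (variance-faithful); the unweighted variant treats retained rows as
        an orthonormal basis only.
    """
    if n_blocks < 1:
        raise ValidationError("n_blocks must be >= 1")
    blocks = _iter_row_blocks(matrix_source, n_blocks)
    w = None
    pending = []
    n_pending_rows = 0

    def reduce_now(rows):
        _, s, vt = np.linalg.svd(rows, full_matrices=False)
        r = min(r_keep, vt.shape[0])
        return s[:r], vt[:r]

    s_cur = None
    for i, block in enumerate(blocks):
        pending.append(block)
        n_pending_rows += block.shape[0]
        first_flush = w is None and (i >= 1)
        if first_flush or (w is not None):
            stack = [w] if w is not None else []
            stack.extend(pending)
            s_cur, vt = reduce_now(np.vstack(stack))
            w = (s_cur[:, None] * vt) if weighted else vt
            pending, n_pending_rows = [], 0
    if pending:
        stack = [w] if w is not None else []
        stack.extend(pending)
        s_cur, vt = reduce_now(np.vstack(stack))
        w = (s_cur[:, None] * vt) if weighted else vt
    if w is None:
        raise ValidationError("matrix source yielded no blocks")
    basis = w / s_cur[:, None] if weighted else w
    if w.shape[0] < r_keep:
        warnings.warn(
            f"requested rank {r_keep} but only {w.shape[0]} rows available; "
            "returning reduced rank"
        )
    return ReducedBasis(
        components=s_cur[:, None] * basis,
        basis=basis,
        singular_values=s_cur.copy(),
        rank_kept=w.shape[0],
    )


class SpatialICA:
    """Spatial ICA over reduced data, sklearn estimator-style.

    Whitens the voxels-by-components view of the reduced data, then runs
    fixed-point ICA (logcosh contrast, symmetric/parallel decorrelation) with
    up to ``n_restarts`` differently-seeded attempts.  Fitted maps are
    z-scored over the mask, sign-flipped to non-negative skewness and ordered
    by the variance of the reduced data each component explains.

    Attributes
    ----------
    maps_ : (M, N) z-scored spatial maps.
    mixing_ : (R, M) mixing matrix onto the reduced rows.
    explained_variance_ : (M,) variance of the reduced data per component.
    n_iter_ : iterations of the successful ICA run.
    """

    def __init__(self, n_components: int = 25, tol: float = 1e-6,
                 max_iter: int = 1000, n_restarts: int = 5,
                 random_state: int = 0, strict: bool = True):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.strict = strict

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "n_restarts": self.n_restarts,
            "random_state": self.random_state,
            "strict": self.strict,
        }

    def set_params(self, **params) -> "SpatialICA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, reduced: ReducedBasis) -> "SpatialICA":
        if self.n_components > reduced.rank_kept:
            raise ValidationError(
                f"m_components={self.n_components} exceeds reduced rank "
                f"{reduced.rank_kept}"
            )
        x = reduced.components.T  # (N voxels, R features)
        rng = np.random.default_rng(self.random_state)
        best = None
        converged = False
        for attempt in range(max(1, self.n_restarts)):
            seed = int(rng.integers(0, 2**31 - 1))
            ica = FastICA(
                n_components=self.n_components,
                algorithm="parallel",
                fun="logcosh",
                whiten="unit-variance",
                tol=self.tol,
                max_iter=self.max_iter,
                random_state=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                sources = ica.fit_transform(x)  # (N, M)
            converged = ica.n_iter_ < self.max_iter
            if best is None or ica.n_iter_ < best[2]:
                best = (sources, ica, ica.n_iter_)
            if converged:
                break
        sources, ica, _ = best
        maps = sources.T  # (M, N)
        mixing = ica.mixing_  # (R, M): x ~= sources @ mixing.T
        # explained variance of the reduced data per rank-1 term
        ev = np.sum(sources**2, axis=0) * np.sum(mixing**2, axis=0)
        order = np.argsort(ev)[::-1]
        maps, mixing, ev = maps[order], mixing[:, order], ev[order]
        z = maps - maps.mean(axis=1, keepdims=True)
        sd = z.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z /= sd
        flip = (z**3).mean(axis=1) < 0
        z[flip] *= -1.0
        mixing[:, flip] *= -1.0
        self.maps_ = z
        self.mixing_ = mixing
        self.explained_variance_ = ev
        self.n_iter_ = ica.n_iter_
        self.converged_ = converged
        if not converged:
            msg = (
                f"spatial ICA failed to converge in {self.n_restarts} "
                f"restarts (best attempt: {best[2]} iterations)"
            )
            if self.strict:
                # the estimator raising the error carries the best attempt
                raise ICAConvergenceError(msg, best[2])
            warnings.warn(msg + "; using the best attempt")
        return self


def spatial_ica(reduced: ReducedBasis, m_components: int,
                seed: int = 0, **kwargs) -> SpatialMapSet:
    """Functional wrapper over :class:`SpatialICA`; returns a map set."""
    est = SpatialICA(n_components=m_components, random_state=seed, **kwargs)
    est.fit(reduced)
    return SpatialMapSet(est.maps_, mixing=est.mixing_, ica_seed=seed)


def threshold_maps_for_display(maps: SpatialMapSet, z_abs: float):
    """Zero sub-threshold voxels; report surviving counts per map.

    Returns (thresholded (M, N) array, per-map surviving voxel counts).
    Note the result is no longer z-scored, so it is a display product, not a
    :class:`SpatialMapSet`.
    """
    if z_abs < 0:
        raise ValidationError("z_abs must be >= 0")
    out = np.where(np.abs(maps.maps) >= z_abs if z_abs > 0 else True,
                   maps.maps, 0.0)
    if z_abs == 0:
        out = maps.maps.copy()
    counts = (out != 0).sum(axis=1)
    return out, counts
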