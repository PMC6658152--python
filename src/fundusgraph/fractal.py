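"""Box-counting fractal dimension of binary masks and the (D_skel, D_raw) plane.

The dimension D is the scaling exponent in N(eps) ~ eps^-D, estimated as the
least-squares slope of log N versus log(1/eps) over a dyadic sequence of box
sizes with the grid anchored at the image origin.  Both the raw vessel mask
and its one-pixel skeleton are characterized; the pair (D_skeleton, D_raw)
places each image as a point in a plane, and a Fisher linear discriminant
("best direction") gives the single most group-separating projection of that
plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoxCountTable",
    "FractalResult",
    "FdPoint",
    "Direction2D",
    "box_count",
    "default_scales",
    "fit_dimension",
    "fractal_dimension",
    "fd_pair",
    "best_direction",
    "fisher_direction",
]


@dataclass
class BoxCountTable:
    scales: np.ndarray  # box sizes eps, strictly increasing
    counts: np.ndarray  # occupied boxes N(eps)


@dataclass
class FractalResult:
    dimension: float
    fit_range: tuple[float, float]  # (eps_min, eps_max) actually used
    r_squared: float
    table: BoxCountTable
    excluded_scales: tuple[float, ...] = ()
    degenerate: bool = False


@dataclass
class FdPoint:
    d_skeleton: float
    d_raw: float


@dataclass
class Direction2D:
    """Unit vector in the (D_skeleton, D_raw) plane plus scalar projections."""

    vector: np.ndarray
    projections: np.ndarray
    labels: np.ndarray
    fallback_mean_difference: bool = False


def default_scales(shape: tuple[int, int]) -> np.ndarray:
    """Dyadic box sizes 2, 4, ..., min(rows, cols) / 4."""
    top = min(shape) // 4
    scales = []
    e = 2
    while e <= top:
        scales.append(e)
        e *= 2
    return np.asarray(scales, dtype=int)


def box_count(mask: np.ndarray, scales: np.ndarray | None = None) -> BoxCountTable:
    """Count occupied boxes per scale, grid anchored at pixel (0, 0).

    Partial boxes at the right/bottom edges count if any of their pixels is
    set (the mask is zero-padded up to a multiple of the box size).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("box_count requires a nonempty mask")
    if scales is None:
        scales = default_scales(mask.shape)
    scales = np.asarray(scales, dtype=int)
    if len(scales) == 0 or np.any(np.diff(scales) <= 0) or scales[0] < 1:
        raise ValueError("scales must be a strictly increasing positive sequence")
    counts = np.empty(len(scales), dtype=np.int64)
    h, w = mask.shape
    for i, e in enumerate(scales):
        hh = -(-h // e) * e
        ww = -(-w // e) * e
        padded = np.zeros((hh, ww), dtype=bool)
        padded[:h, :w] = mask
        blocks = padded.reshape(hh // e, e, ww // e, e).any(axis=(1, 3))
        counts[i] = int(blocks.sum())
    return BoxCountTable(scales=scales.astype(float), counts=counts)


def fit_dimension(table: BoxCountTable, min_scales: int = 4) -> FractalResult:
    """Least-squares slope of log N(eps) vs log(1/eps).

    The single largest scale is dropped from the fit when its residual exceeds
    3x the median residual of a first-pass fit (saturation guard); the
    exclusion is reported.  A degenerate table (all counts equal) yields D = 0
    with a warning.
    """
    eps = np.asarray(table.scales, float)
    n = np.asarray(table.counts, float)
    if len(eps) < min_scales:
        raise ValueError(f"need at least {min_scales} scales, got {len(eps)}")
    if np.all(n == n[0]):
        warnings.warn("degenerate box-count table (constant N); D set to 0")
        return FractalResult(0.0, (eps[0], eps[-1]), 1.0, table, degenerate=True)
    x = np.log(1.0 / eps)
    y = np.log(n)
    slope, intercept = np.polyfit(x, y, 1)
    resid = np.abs(y - (slope * x + intercept))
    excluded: tuple[float, ...] = ()
    med = np.median(resid)
    if len(eps) > min_scales and resid[-1] > 3.0 * med + 1e-12:
        excluded = (float(eps[-1]),)
        x, y = x[:-1], y[:-1]
        slope, intercept = np.polyfit(x, y, 1)
        resid = np.abs(y - (slope * x + intercept))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    used_eps = eps[: len(x)] if excluded else eps
    return FractalResult(
        dimension=float(slope),
        fit_range=(float(used_eps[0]), float(used_eps[-1])),
        r_squared=r2,
        table=table,
        excluded_scales=excluded,
    )


def fractal_dimension(mask: np.ndarray, scales: np.ndarray | None = None) -> FractalResult:
    """Convenience: box_count then fit_dimension."""
    return fit_dimension(box_count(mask, scales))


def fd_pair(mask: np.ndarray, scales: np.ndarray | None = None) -> FdPoint:
    """Box-counting dimensions of the raw mask and of its skeleton.

    Both fits use identical scale settings so the two coordinates of the
    fractal plane are directly comparable.
    """
    from .vessel_graph import skeletonize

    mask = np.asarray(mask, dtype=bool)
    if scales is None:
        scales = default_scales(mask.shape)
    d_raw = fit_dimension(box_count(mask, scales)).dimension
    skel = skeletonize(mask).data
    d_skel = fit_dimension(box_count(skel, scales)).dimension
    return FdPoint(d_skeleton=d_skel, d_raw=d_raw)


def fisher_direction(x0: np.ndarray, x1: np.ndarray) -> tuple[np.ndarray, bool]:
    """Fisher LDA direction between two point clouds (rows = observations).

    Returns (unit vector, used_mean_difference_fallback).  The pooled
    within-class scatter is inverted unless (numerically) singular, in which
    case the plain mean-difference direction is used with a warning.
    """
    x0 = np.atleast_2d(np.asarray(x0, float))
    x1 = np.atleast_2d(np.asarray(x1, float))
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("need at least 2 points per group")
    diff = x1.mean(axis=0) - x0.mean(axis=0)
    sw = np.cov(x0, rowvar=False, ddof=1) * (len(x0) - 1) + np.cov(
        x1, rowvar=False, ddof=1
    ) * (len(x1) - 1)
    sw = np.atleast_2d(sw) / (len(x0) + len(x1) - 2)
    fallback = False
    try:
        cond = np.linalg.cond(sw)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError
        w = np.linalg.solve(sw, diff)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; using mean-difference direction")
        w = diff
        fallback = True
    norm = np.linalg.norm(w)
    if norm == 0:
        w = np.zeros_like(diff)
        w[0] = 1.0
        norm = 1.0
    return w / norm, fallback


def best_direction(points, labels) -> Direction2D:
    """Most group-separating direction of the (D_skeleton, D_raw) plane.

    ``points`` may be a list of :class:`FdPoint` or an (n, 2) array; ``labels``
    must contain exactly two distinct values with >= 2 members each.
    """
    if len(points) and isinstance(points[0], FdPoint):
        arr = np.array([[p.d_skeleton, p.d_raw] for p in points])
    else:
        arr = np.atleast_2d(np.asarray(points, float))
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("best_direction requires exactly two groups")
    x0, x1 = arr[labels == uniq[0]], arr[labels == uniq[1]]
    w, fallback = fisher_direction(x0, x1)
    return Direction2D(
        vector=w,
        projections=arr @ w,
        labels=labels,
        fallback_mean_difference=fallback,
    )
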