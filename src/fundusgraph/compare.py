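"""Cohort-level comparison of per-image feature distributions.

Each image's feature sample set (C-NDD, CMWD or WDD values) is histogrammed
on bin edges shared across the cohort, pairs of histograms are compared with
the Jensen-Shannon divergence (natural-log convention, range [0, ln 2]),
the resulting N x N divergence matrix is embedded into two coordinates with
IsoMap (k-nearest-neighbour geodesics + classical MDS), and group
differences are assessed with two-sample t statistics.

For the 2-D planes (IsoMap embedding, fractal-dimension plane) the scalar
test projects the points onto the Fisher discriminant direction.  Because
that direction maximizes the projected t^2, the projected statistic equals
Hotelling's T^2; the default p-value therefore uses the exact T^2 / F null
reference, which is uniform under the null hypothesis.  The naive p-value
obtained by treating the projected t as an ordinary two-sample t statistic
is also reported (``p_projected``) but is optimistically biased.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import connected_components, shortest_path

from .fractal import FdPoint, fisher_direction

__all__ = [
    "HistogramSet",
    "DivergenceMatrix",
    "Embedding2D",
    "GroupTest",
    "common_bin_edges",
    "to_histogram",
    "js_divergence",
    "divergence_matrix",
    "isomap_2d",
    "ttest2",
    "group_separation",
]


@dataclass
class HistogramSet:
    edges: np.ndarray  # shared bin edges, len = n_bins + 1
    probabilities: np.ndarray  # (n_images, n_bins), each row sums to 1
    ids: list = field(default_factory=list)


@dataclass
class DivergenceMatrix:
    values: np.ndarray  # (N, N) symmetric, zero diagonal, entries in [0, ln 2]
    ids: list = field(default_factory=list)


@dataclass
class Embedding2D:
    coords: np.ndarray  # (N, 2)
    ids: list = field(default_factory=list)
    k_used: int = 0


@dataclass
class GroupTest:
    method: str
    labels: tuple
    t: float
    p: float
    df: float
    p_projected: float | None = None  # naive projected-t p (2-D inputs only)
    calibrated: bool = False
    note: str = ""


# ---------------------------------------------------------------------------
# histograms and divergence
# ---------------------------------------------------------------------------


def common_bin_edges(sample_sets, n_bins: int = 64) -> np.ndarray:
    """Uniform bin edges spanning the pooled 0.5th-99.5th percentile."""
    pooled = np.concatenate([np.asarray(s, float).ravel() for s in sample_sets])
    if pooled.size == 0:
        raise ValueError("no samples supplied")
    lo, hi = np.percentile(pooled, [0.5, 99.5])
    if hi <= lo:
        raise ValueError("pooled samples have zero range; cannot build bins")
    return np.linspace(lo, hi, n_bins + 1)


def to_histogram(samples, edges: np.ndarray) -> np.ndarray:
    """Normalized histogram; out-of-range samples are clipped to end bins."""
    x = np.asarray(samples, float).ravel()
    if x.size == 0:
        raise ValueError("empty sample set")
    half_bin = (edges[1] - edges[0]) / 2.0
    x = np.clip(x, edges[0] + 1e-12, edges[-1] - 1e-12 * max(1.0, abs(edges[-1])))
    counts, _ = np.histogram(x, bins=edges)
    return counts / counts.sum()


def js_divergence(p, q, tol: float = 1e-6) -> float:
    """Jensen-Shannon divergence in nats: H((P+Q)/2) - (H(P)+H(Q))/2.

    Zero-probability bins contribute zero; both inputs must be probability
    vectors of equal length summing to 1 within ``tol``.
    """
    p = np.asarray(p, float).ravel()
    q = np.asarray(q, float).ravel()
    if p.shape != q.shape:
        raise ValueError("probability vectors must have equal length")
    for v in (p, q):
        if abs(v.sum() - 1.0) > tol or (v < -tol).any():
            raise ValueError("inputs must be probability vectors summing to 1")
    m = 0.5 * (p + q)

    def h(v):
        nz = v > 0
        return -float(np.sum(v[nz] * np.log(v[nz])))

    return max(0.0, h(m) - 0.5 * (h(p) + h(q)))


def divergence_matrix(histograms: HistogramSet) -> DivergenceMatrix:
    """Pairwise JS divergences between all image histograms."""
    probs = np.asarray(histograms.probabilities, float)
    n = len(probs)
    if n < 3:
        raise ValueError("need at least 3 images")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = js_divergence(probs[i], probs[j])
    return DivergenceMatrix(values=out, ids=list(histograms.ids))


# ---------------------------------------------------------------------------
# IsoMap from a precomputed distance matrix
# ---------------------------------------------------------------------------


def _classical_mds(d: np.ndarray, n_components: int = 2) -> np.ndarray:
    n = len(d)
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals)
    # deterministic sign convention: largest-magnitude entry positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def isomap_2d(matrix: DivergenceMatrix | np.ndarray, k_neighbors: int = 10) -> Embedding2D:
    """IsoMap embedding of a precomputed distance matrix into the plane.

    Builds the symmetrized k-nearest-neighbour graph, computes geodesic
    distances over it, and applies classical MDS.  If the k-NN graph is
    disconnected, k is incremented (with a warning) until it connects.
    Deterministic given the matrix and k.
    """
    ids = matrix.ids if isinstance(matrix, DivergenceMatrix) else []
    d = matrix.values if isinstance(matrix, DivergenceMatrix) else np.asarray(matrix, float)
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 images to embed")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    k = min(max(1, k_neighbors), n - 1)
    while True:
        adj = np.full((n, n), np.inf)
        order = np.argsort(d, axis=1, kind="stable")
        for i in range(n):
            neigh = [j for j in order[i] if j != i][:k]
            adj[i, neigh] = d[i, neigh]
        adj = np.minimum(adj, adj.T)  # union-symmetrized
        finite = np.isfinite(adj)
        n_comp, _ = connected_components(finite, directed=False)
        if n_comp == 1 or k >= n - 1:
            break
        k += 1
        warnings.warn(f"k-NN graph disconnected; increased k to {k}")
    # sparse with explicit zeros so zero-divergence pairs stay connected
    from scipy.sparse import csr_matrix

    rows, cols = np.nonzero(finite)
    graph = csr_matrix((adj[rows, cols], (rows, cols)), shape=(n, n))
    geo = shortest_path(graph, method="D", directed=False, unweighted=False)
    if not np.isfinite(geo).all():
        raise ValueError("geodesic distances are not all finite")
    return Embedding2D(coords=_classical_mds(geo, 2), ids=list(ids), k_used=k)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def ttest2(sample_a, sample_b, method: str = "") -> GroupTest:
    """Pooled-variance two-sample t-test, two-sided.

    Degenerate case: zero pooled variance yields p = 1 when the means agree
    and p = 0 (flagged in ``note``) when they differ.
    """
    a = np.asarray(sample_a, float).ravel()
    b = np.asarray(sample_b, float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample must have at least 2 observations")
    df = len(a) + len(b) - 2
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if pooled_var <= 0:
        if np.isclose(a.mean(), b.mean()):
            return GroupTest(method, ("a", "b"), 0.0, 1.0, df, note="zero variance")
        return GroupTest(
            method,
            ("a", "b"),
            math.inf if a.mean() > b.mean() else -math.inf,
            0.0,
            df,
            note="zero variance, unequal means",
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupTest(method, ("a", "b"), float(t), float(p), df)


def group_separation(
    features, labels, method: str = "", calibrated: bool = True, use_first_coordinate: bool = False
) -> GroupTest:
    """Scalar group test for 2-D per-image features.

    Projects the points onto the Fisher discriminant direction and t-tests
    the projections.  With ``calibrated=True`` (default) the p-value refers
    the projected t^2 — which equals Hotelling's T^2 — to its exact
    F-distribution null, giving uniform p-values under the null hypothesis;
    ``p_projected`` carries the naive (biased) projected-t p-value.  With
    ``use_first_coordinate=True`` the first feature coordinate is tested
    directly with an ordinary t-test.
    """
    if isinstance(features, Embedding2D):
        arr = features.coords
    elif len(features) and isinstance(features[0], FdPoint):
        arr = np.array([[p.d_skeleton, p.d_raw] for p in features])
    else:
        arr = np.atleast_2d(np.asarray(features, float))
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("group_separation requires exactly two groups")
    x0, x1 = arr[labels == uniq[0]], arr[labels == uniq[1]]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("each group needs at least 2 members")

    if use_first_coordinate or arr.shape[1] == 1:
        base = ttest2(x0[:, 0], x1[:, 0], method=method)
        return GroupTest(method, tuple(uniq), base.t, base.p, base.df, note=base.note)

    w, fallback = fisher_direction(x0, x1)
    proj = ttest2(x0 @ w, x1 @ w, method=method)
    n0, n1, dim = len(x0), len(x1), arr.shape[1]
    note = "mean-difference fallback" if fallback else ""
    if not calibrated or fallback or not np.isfinite(proj.t):
        return GroupTest(
            method, tuple(uniq), proj.t, proj.p, proj.df, p_projected=proj.p, note=note
        )
    # projected t^2 on the Fisher direction == Hotelling's T^2
    t2 = proj.t**2
    dfe = n0 + n1 - 2
    f_stat = t2 * (dfe - dim + 1) / (dfe * dim)
    p = float(stats.f.sf(f_stat, dim, dfe - dim + 1))
    return GroupTest(
        method,
        tuple(uniq),
        proj.t,
        p,
        dfe,
        p_projected=proj.p,
        calibrated=True,
        note=note,
    )
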