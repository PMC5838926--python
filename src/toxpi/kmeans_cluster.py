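"""Hartigan–Wong k-means on slice-score vectors, with PCA display coordinates.

The algorithm is the classic two-stage iteration: an *optimal-transfer*
pass considers moving each point to every other cluster, and a
*quick-transfer* stage reconsiders only each point's closest and
second-closest clusters.  A point in cluster L1 (size n1) moves to L2
(size n2) when the within-cluster sum of squares strictly decreases, i.e.

    n2 * ||x - c2||^2 / (n2 + 1)  <  n1 * ||x - c1||^2 / (n1 - 1)

with centers updated incrementally after every transfer.  The run converges
when a full optimal-transfer pass makes no move.  Each of ``n_start``
restarts draws its initial centers as distinct random entities from one
seeded generator stream; the restart with the smallest total within-cluster
sum of squares wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["KMeansResult", "PcaProjection", "kmeans", "pca_project"]

logger = logging.getLogger(__name__)

MAX_SWEEPS = 100


class KMeansError(ValueError):
    pass


@dataclass
class KMeansResult:
    labels: np.ndarray  # 1..n_clusters per entity
    centers: np.ndarray  # (n_clusters, n_features)
    withinss: np.ndarray  # per-cluster sum of squares
    tot_withinss: float
    totss: float
    betweenss: float
    n_clusters: int
    n_start: int
    seed: int
    converged: bool


@dataclass
class PcaProjection:
    coords: np.ndarray  # (n, 2), column-centered
    var_explained: tuple[float, float]
    flip_x: bool
    flip_y: bool


def _closest_two(X: np.ndarray, centers: np.ndarray):
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, 0], order[:, 1], d2


def _hartigan_wong(X: np.ndarray, centers: np.ndarray):
    """One Hartigan–Wong run from given initial centers.

    Returns (labels0, centers, converged) or None if a cluster empties at
    the initial assignment (the caller re-draws that start).
    """
    n, _ = X.shape
    k = centers.shape[0]
    ic1, ic2, _ = _closest_two(X, centers)
    nc = np.bincount(ic1, minlength=k)
    if (nc == 0).any():
        return None
    centers = np.vstack([X[ic1 == l].mean(axis=0) for l in range(k)])

    converged = False
    for _sweep in range(MAX_SWEEPS):
        # ---- optimal-transfer pass
        moved = 0
        for i in range(n):
            l1 = ic1[i]
            if nc[l1] == 1:
                continue
            d1 = float(((X[i] - centers[l1]) ** 2).sum())
            r1 = nc[l1] * d1 / (nc[l1] - 1)
            d_all = ((centers - X[i]) ** 2).sum(axis=1)
            gain = nc * d_all / (nc + 1)
            gain[l1] = np.inf
            l2 = int(np.argmin(gain))
            if gain[l2] < r1:
                _transfer(X, centers, nc, i, l1, l2)
                ic1[i], ic2[i] = l2, l1
                moved += 1
            else:
                ic2[i] = l2
        if moved == 0:
            converged = True
            break
        # ---- quick-transfer stage: only ic1 <-> ic2 swaps
        for _q in range(MAX_SWEEPS):
            swapped = 0
            for i in range(n):
                l1, l2 = ic1[i], ic2[i]
                if nc[l1] == 1:
                    continue
                r1 = nc[l1] * float(((X[i] - centers[l1]) ** 2).sum()) / (nc[l1] - 1)
                r2 = nc[l2] * float(((X[i] - centers[l2]) ** 2).sum()) / (nc[l2] + 1)
                if r2 < r1:
                    _transfer(X, centers, nc, i, l1, l2)
                    ic1[i], ic2[i] = l2, l1
                    swapped += 1
            if swapped == 0:
                break
    else:
        logger.warning("k-means did not converge within %d sweeps", MAX_SWEEPS)

    return ic1, centers, converged


def _transfer(X, centers, nc, i, l1, l2) -> None:
    centers[l1] = (centers[l1] * nc[l1] - X[i]) / (nc[l1] - 1)
    centers[l2] = (centers[l2] * nc[l2] + X[i]) / (nc[l2] + 1)
    nc[l1] -= 1
    nc[l2] += 1


def kmeans(
    slice_scores: np.ndarray,
    n_clusters: int,
    n_start: int = 1,
    seed: int | None = None,
) -> KMeansResult:
    """Multi-start Hartigan–Wong k-means; smallest total within-SS wins."""
    X = np.asarray(slice_scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not (1 <= n_clusters <= n):
        raise KMeansError(f"n_clusters={n_clusters} out of range 1..{n}")
    if n_start < 1:
        raise KMeansError("n_start must be >= 1")
    if seed is None:
        raise KMeansError("an explicit seed is required for reproducibility")
    rng = np.random.default_rng(seed)

    best = None
    best_converged = True
    for _s in range(n_start):
        for _attempt in range(100):
            init = X[rng.choice(n, size=n_clusters, replace=False)]
            run = _hartigan_wong(X, init.copy())
            if run is not None:
                break
        else:  # pragma: no cover - requires pathological duplicated data
            raise KMeansError("could not seed non-empty initial clusters")
        labels0, centers, converged = run
        tw = _tot_withinss(X, labels0, n_clusters)
        if best is None or tw < best[0] - 1e-12:
            best = (tw, labels0.copy(), centers.copy())
            best_converged = converged

    tot_withinss, labels0, _ = best
    # final centers recomputed exactly as member means
    centers = np.vstack([X[labels0 == l].mean(axis=0) for l in range(n_clusters)])
    withinss = np.array(
        [((X[labels0 == l] - centers[l]) ** 2).sum() for l in range(n_clusters)]
    )
    totss = float(((X - X.mean(axis=0)) ** 2).sum())
    tot_withinss = float(withinss.sum())
    return KMeansResult(
        labels=labels0 + 1,
        centers=centers,
        withinss=withinss,
        tot_withinss=tot_withinss,
        totss=totss,
        betweenss=totss - tot_withinss,
        n_clusters=n_clusters,
        n_start=n_start,
        seed=int(seed),
        converged=best_converged,
    )


def _tot_withinss(X: np.ndarray, labels0: np.ndarray, k: int) -> float:
    tw = 0.0
    for l in range(k):
        pts = X[labels0 == l]
        if len(pts):
            tw += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return tw


def pca_project(
    slice_scores: np.ndarray, flip_x: bool = False, flip_y: bool = False
) -> PcaProjection:
    """Top-2 principal-component coordinates for cluster display.

    Columns are centered (no standardization: slice scores already share
    the unit interval); the sample covariance uses divisor n-1.  The sign of
    each component is fixed by making its largest-magnitude loading
    positive, then the optional flips are applied.  Rank-deficient input
    yields a zero second component.
    """
    X = np.asarray(slice_scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise KMeansError("need at least 2 entities for PCA")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (n - 1)
    total = var.sum()
    coords = np.zeros((n, 2))
    shares = [0.0, 0.0]
    for c in range(min(2, len(s))):
        v = Vt[c]
        sign = 1.0 if v[np.argmax(np.abs(v))] >= 0 else -1.0
        coords[:, c] = sign * Xc @ v
        shares[c] = float(var[c] / total) if total > 0 else 0.0
    if flip_x:
        coords[:, 0] = -coords[:, 0]
    if flip_y:
        coords[:, 1] = -coords[:, 1]
    return PcaProjection(
        coords=coords, var_explained=(shares[0], shares[1]),
        flip_x=flip_x, flip_y=flip_y,
    )
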