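"""K-means clustering of fingerprints under Euclidean or cosine distance.

Lloyd's algorithm with greedy farthest-point seeding plus random
restarts.  For the Euclidean metric the objective is the classic
within-cluster sum of squares (WCSS); for the cosine metric a spherical
variant is used — centroids are renormalized means of unit-normalized
members and the objective is the summed cosine distance of each point to
its centroid, a consistent minimizer for cosine dissimilarity.

Everything is deterministic given the seed; nearest-centroid ties break
toward the lowest cluster index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError

__all__ = [
    "ClusterResult",
    "euclidean_distance",
    "cosine_distance",
    "kmeans",
    "align_labels",
]


def euclidean_distance(x, y) -> float:
    """sqrt(sum (x_i - y_i)^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(x - y))


def cosine_distance(x, y) -> float:
    """1 - cos(angle between x and y); in [0, 2], scale-invariant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValidationError("cosine distance undefined for zero vectors")
    return float(1.0 - np.dot(x, y) / (nx * ny))


@dataclass
class ClusterResult:
    """Labels in {1..k}, centroids, final objective and run metadata."""

    labels: np.ndarray
    centroids: np.ndarray
    objective: float
    metric: str
    seed: int
    n_iter: int

    @property
    def wcss(self) -> float:
        return self.objective


def _pairwise(points: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    """(n, k) matrix of the metric's per-assignment cost: squared
    Euclidean distance, or cosine distance."""
    if metric == "euclidean":
        d = points[:, None, :] - centroids[None, :, :]
        return np.einsum("nkd,nkd->nk", d, d)
    # cosine
    pn = points / np.linalg.norm(points, axis=1, keepdims=True)
    cn = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    return 1.0 - pn @ cn.T


def _update_centroids(points: np.ndarray, labels: np.ndarray, k: int,
                      metric: str, old: np.ndarray) -> np.ndarray:
    cents = old.copy()
    cost = _pairwise(points, old, metric)
    for c in range(k):
        members = points[labels == c]
        if len(members) == 0:
            # re-seed an empty cluster with the overall worst-fit point
            cents[c] = points[int(np.argmax(cost[np.arange(len(points)), labels]))]
            continue
        if metric == "euclidean":
            cents[c] = members.mean(axis=0)
        else:
            u = members / np.linalg.norm(members, axis=1, keepdims=True)
            m = u.mean(axis=0)
            norm = np.linalg.norm(m)
            cents[c] = m / norm if norm > 0 else members[0]
    return cents


def _farthest_point_seed(points: np.ndarray, k: int, metric: str,
                         first: int) -> np.ndarray:
    """Greedy farthest-point initial centroids, starting from ``first``."""
    chosen = [first]
    for _ in range(1, k):
        d = _pairwise(points, points[chosen], metric).min(axis=1)
        d[chosen] = -np.inf
        chosen.append(int(np.argmax(d)))
    return points[chosen].copy()


def _lloyd(points: np.ndarray, init: np.ndarray, metric: str,
           max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float, int]:
    k = len(init)
    cents = init.copy()
    labels = np.full(len(points), -1)
    prev_obj = np.inf
    for it in range(1, max_iter + 1):
        cost = _pairwise(points, cents, metric)
        new_labels = np.argmin(cost, axis=1)  # ties -> lowest index
        obj = float(cost[np.arange(len(points)), new_labels].sum())
        # Lloyd objective never increases across iterations
        assert obj <= prev_obj + 1e-9, "k-means objective increased"
        prev_obj = obj
        if np.array_equal(new_labels, labels):
            return labels, cents, obj, it
        labels = new_labels
        cents = _update_centroids(points, labels, k, metric, cents)
    cost = _pairwise(points, cents, metric)
    obj = float(cost[np.arange(len(points)), labels].sum())
    return labels, cents, obj, max_iter


def kmeans(
    points,
    k: int,
    metric: str = "euclidean",
    seed: int = 0,
    n_restarts: int = 100,
) -> ClusterResult:
    """Best-of-restarts Lloyd k-means under the chosen metric.

    The first restart uses greedy farthest-point seeding from a seeded
    starting point; the rest draw k distinct random points as initial
    centroids.  Returns labels in {1..k}.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValidationError("points must be a 2D array (subjects x features)")
    n = len(points)
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} must be in [1, n={n}]")
    if metric not in ("euclidean", "cosine"):
        raise ValidationError(f"metric must be 'euclidean' or 'cosine', got {metric!r}")
    if metric == "cosine" and np.any(np.linalg.norm(points, axis=1) == 0):
        raise ValidationError("cosine metric undefined for zero vectors")

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            init = _farthest_point_seed(points, k, metric, int(rng.integers(n)))
        else:
            init = points[rng.choice(n, size=k, replace=False)].copy()
        labels, cents, obj, n_iter = _lloyd(points, init, metric)
        if best is None or obj < best[2] - 1e-12:
            best = (labels, cents, obj, n_iter)
    labels, cents, obj, n_iter = best
    return ClusterResult(labels + 1, cents, obj, metric, seed, n_iter)


def _agreement(ref: np.ndarray, lab: np.ndarray) -> int:
    return int((ref == lab).sum())


def align_labels(labels, reference_labels) -> np.ndarray:
    """Relabel clusters one-to-one onto reference classes so the number
    of agreeing subjects is maximal (optimal rectangular assignment).

    Cluster labels from k-means are arbitrary; this resolves the
    permutation before accuracies are compared."""
    lab = np.asarray(labels, int)
    ref = np.asarray(reference_labels, int)
    if lab.shape != ref.shape:
        raise ValidationError("label vectors of unequal length")
    lab_ids = np.unique(lab)
    ref_ids = np.unique(ref)
    # contingency: rows = cluster ids, cols = reference ids
    cont = np.zeros((lab_ids.size, ref_ids.size), int)
    for i, c in enumerate(lab_ids):
        for j, p in enumerate(ref_ids):
            cont[i, j] = int(((lab == c) & (ref == p)).sum())
    rows, cols = linear_sum_assignment(-cont)
    mapping = {int(lab_ids[r]): int(ref_ids[c]) for r, c in zip(rows, cols)}
    # unmatched clusters (more clusters than classes) keep a fresh label
    spare = iter(sorted(set(range(1, lab_ids.size + ref_ids.size + 1))
                        - set(mapping.values())))
    out = np.array([mapping.get(int(c), -1) for c in lab])
    for c in lab_ids:
        if int(c) not in mapping:
            m = next(spare)
            out[lab == c] = m
    return out


def align_result(result: ClusterResult, reference_labels) -> ClusterResult:
    """A ClusterResult with its labels aligned to a reference."""
    aligned = align_labels(result.labels, reference_labels)
    return ClusterResult(aligned, result.centroids, result.objective,
                         result.metric, result.seed, result.n_iter)
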