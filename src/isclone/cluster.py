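"""Partition-around-medoids (PAM) clustering of the similarity matrix and
silhouette-based selection of the number of clones.

Clustering operates on the dissimilarity D = 1 - S.  The PAM implementation
is deterministic: a greedy BUILD phase (first medoid minimizes total
dissimilarity, subsequent medoids maximize cost reduction) followed by a
best-improvement SWAP phase iterated to a local optimum, with ties broken
toward the lowest index.  Determinism makes small instances exactly
verifiable against exhaustive search over all medoid sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_samples

from .io_model import ClusteringResult, SimilarityMatrix

__all__ = ["KRange", "pam", "silhouette_score", "select_best_clustering"]

#: Cap of the default cluster-number search range.
DEFAULT_K_MAX = 15


@dataclass(frozen=True)
class KRange:
    """Inclusive range of cluster numbers to scan."""

    k_min: int = 2
    k_max: int = DEFAULT_K_MAX

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.k_min > self.k_max:
            raise ValueError("k_min must not exceed k_max")

    def clipped(self, n_is: int) -> "KRange":
        return KRange(self.k_min, min(self.k_max, n_is - 1))


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    first = int(np.argmin(d.sum(axis=1)))
    medoids = [first]
    dnear = d[:, first].copy()
    while len(medoids) < k:
        gains = np.maximum(dnear[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        dnear = np.minimum(dnear, d[:, best])
    return medoids


def _nearest_two(d: np.ndarray, medoids: list[int]
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sub = d[:, medoids]  # (n, k)
    order = np.argsort(sub, axis=1, kind="stable")
    nearest = np.asarray(medoids)[order[:, 0]]
    dnear = np.take_along_axis(sub, order[:, :1], axis=1).ravel()
    dsecond = (np.take_along_axis(sub, order[:, 1:2], axis=1).ravel()
               if len(medoids) > 1 else np.full(d.shape[0], np.inf))
    return nearest, dnear, dsecond


def _pam_swap(d: np.ndarray, medoids: list[int]) -> list[int]:
    n = d.shape[0]
    medoids = list(medoids)
    while True:
        nearest, dnear, dsecond = _nearest_two(d, medoids)
        in_medoids = np.zeros(n, dtype=bool)
        in_medoids[medoids] = True
        candidates = np.flatnonzero(~in_medoids)
        if not len(candidates):
            return medoids
        best_delta = -1e-12
        best_swap = None
        for mi, m in enumerate(medoids):
            owned = nearest == m
            dh = d[:, candidates]  # (n, n_cand)
            gain_owned = (np.minimum(dh[owned], dsecond[owned, None])
                          - dnear[owned, None]).sum(axis=0)
            gain_other = np.minimum(dh[~owned] - dnear[~owned, None], 0.0).sum(axis=0)
            delta = gain_owned + gain_other  # total-cost change per candidate
            ci = int(np.argmin(delta))
            if delta[ci] < best_delta:
                best_delta = float(delta[ci])
                best_swap = (mi, int(candidates[ci]))
        if best_swap is None:
            return medoids
        medoids[best_swap[0]] = best_swap[1]


def pam_indices(d: np.ndarray, k: int) -> tuple[list[int], np.ndarray, float]:
    """PAM on a raw dissimilarity matrix; returns (medoids, labels, cost).

    Labels are 1..k in order of increasing medoid index; points tied between
    medoids go to the lower-index medoid.
    """
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} items")
    if k == n:
        medoids = list(range(n))
    else:
        medoids = _pam_swap(d, _pam_build(d, k))
    medoids = sorted(medoids)
    sub = d[:, medoids]
    assign = np.argmin(sub, axis=1)  # argmin takes the first (lowest) medoid
    # a medoid always represents its own cluster, even when another medoid
    # sits at zero dissimilarity (duplicate rows)
    for mi, m in enumerate(medoids):
        assign[m] = mi
    labels = assign + 1
    cost = float(np.take_along_axis(sub, assign[:, None], axis=1).sum())
    return medoids, labels, cost


def pam(s: SimilarityMatrix, k: int) -> ClusteringResult:
    """Cluster the IS of ``s`` into ``k`` clusters on D = 1 - S."""
    n = len(s.is_ids)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range (2..{n})")
    d = s.dissimilarity()
    medoids, labels, _ = pam_indices(d, k)
    sil = silhouette_score(s, labels) if k < n else float("nan")
    ids = s.is_ids
    return ClusteringResult(
        is_ids=ids,
        labels=labels,
        k=k,
        silhouette=sil,
        medoids=[ids[m] for m in medoids],
    )


def silhouette_score(s: SimilarityMatrix, labels) -> float:
    """Mean silhouette width on D = 1 - S.

    Per IS: (b - a)/max(a, b) with a = mean dissimilarity to its own
    cluster's other members and b = the smallest mean dissimilarity to any
    other cluster; a singleton contributes 0.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    if len(uniq) >= len(labels):
        raise ValueError("silhouette needs at least one non-singleton cluster")
    d = s.dissimilarity()
    return float(np.mean(silhouette_samples(d, labels, metric="precomputed")))


def select_best_clustering(s: SimilarityMatrix,
                           k_range: KRange | None = None) -> ClusteringResult:
    """Run PAM for every k in the range and keep the best silhouette.

    Ties break toward smaller k.  The default range is [2, min(n-1, 15)].
    """
    n = len(s.is_ids)
    if n < 3:
        raise ValueError("need at least 3 IS to select a clustering")
    k_range = (k_range or KRange()).clipped(n)
    best: ClusteringResult | None = None
    for k in range(k_range.k_min, k_range.k_max + 1):
        res = pam(s, k)
        if best is None or res.silhouette > best.silhouette:
            best = res
    assert best is not None
    return best
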