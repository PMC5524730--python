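"""Binary-vector similarity, cluster references and classical multidimensional scaling.

Similarity between fingerprints is the Jaccard-Tanimoto coefficient
|A∩B| / |A∪B|; its complement is used as a distance throughout.  Reference
clusters of structurally homogeneous sweeteners are summarized by the set of
member fingerprints plus a distance cutoff, and a query's average distance to
the members decides whether it falls inside the cluster's neighborhood.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import FingerprintMatrix, InputError


@dataclass
class ClusterReference:
    """A reference cluster: name, member fingerprints, distance threshold."""

    name: str
    member_fps: FingerprintMatrix
    threshold: float

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.member_fps.n_molecules == 0:
            raise ValueError("cluster reference needs at least one member")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"name": self.name, "threshold": self.threshold,
                        "member_ids": self.member_fps.ids})
        )


@dataclass
class MdsResult:
    """Coordinates and per-coordinate explained-variance fractions."""

    coords: np.ndarray
    explained_variance: np.ndarray


def tanimoto_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard-Tanimoto similarity of two binary vectors.

    Two all-zero vectors are identical objects and score 1 (with a warning).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InputError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("both fingerprints empty; similarity defined as 1")
        return 1.0
    return np.count_nonzero(a & b) / union


def _pairwise_tanimoto(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Tanimoto similarity between every row of A and every row of B."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    inter = A @ B.T
    pop_a = A.sum(axis=1)[:, None]
    pop_b = B.sum(axis=1)[None, :]
    union = pop_a + pop_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def average_cluster_distance(fp: np.ndarray, ref: ClusterReference) -> float:
    """Mean Jaccard-Tanimoto distance of one fingerprint to the reference members."""
    fp = np.atleast_2d(np.asarray(fp))
    if fp.shape[1] != ref.member_fps.n_bits:
        raise InputError("fingerprint length does not match reference")
    sims = _pairwise_tanimoto(fp, ref.member_fps.bits)[0]
    return float(np.mean(1.0 - sims))


def average_cluster_distances(fps: FingerprintMatrix, ref: ClusterReference) -> np.ndarray:
    """Vectorized :func:`average_cluster_distance` over a fingerprint matrix."""
    sims = _pairwise_tanimoto(fps.bits, ref.member_fps.bits)
    return np.mean(1.0 - sims, axis=1)


def distance_matrix(fps: FingerprintMatrix) -> np.ndarray:
    """Symmetric n x n Jaccard-Tanimoto distance matrix with zero diagonal."""
    sim = _pairwise_tanimoto(fps.bits, fps.bits)
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, 1.0)


def derive_threshold(
    train_fps: FingerprintMatrix,
    ref: ClusterReference,
    member_ids: set[str] | None = None,
    fallback: float | None = None,
) -> float:
    """Distance cutoff from the widest empty gap separating members from the rest.

    Computes every training molecule's average distance to the reference,
    sorts them, and returns the midpoint of the widest gap between
    consecutive distances that lies at or above every member's own distance.
    Falls back to ``fallback`` (with a warning) when no gap exists.
    """
    if train_fps.n_molecules < 2:
        raise InputError("need at least two training molecules")
    member_ids = member_ids if member_ids is not None else set(ref.member_fps.ids)
    dists = average_cluster_distances(train_fps, ref)
    is_member = np.array([mol_id in member_ids for mol_id in train_fps.ids])
    if np.ptp(dists) == 0:
        raise InputError("all average distances identical; choose a threshold manually")
    member_max = dists[is_member].max() if is_member.any() else dists.min()
    order = np.sort(dists)
    gaps = np.diff(order)
    valid = order[:-1] >= member_max - 1e-12
    if not valid.any() or gaps[valid].max() <= 0:
        if fallback is None:
            raise InputError("no separating gap found and no fallback configured")
        warnings.warn("no separating gap; returning fallback threshold")
        return fallback
    candidates = np.where(valid, gaps, -1.0)
    best = int(np.argmax(candidates))
    return float((order[best] + order[best + 1]) / 2.0)


def classical_mds(D: np.ndarray, k: int = 2) -> MdsResult:
    """Classical (Torgerson) metric MDS by eigendecomposition.

    Double-centers -D²/2 and eigendecomposes; coordinates are ordered by
    decreasing explained variance.  Negative eigenvalues (non-Euclidean
    distances) are clipped to zero for the explained-variance accounting.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise InputError("distance matrix must be symmetric")
    if k < 1:
        raise InputError("k must be >= 1")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = np.clip(eigval, 0.0, None)
    rank = int(np.count_nonzero(positive > max(1e-12, 1e-9 * positive.max(initial=0.0))))
    if rank == 0:
        return MdsResult(np.zeros((n, k)), np.zeros(k))
    if k > rank:
        warnings.warn(f"k={k} exceeds embedding rank {rank}; truncating")
        k = rank
    coords = eigvec[:, :k] * np.sqrt(positive[:k])
    total = positive.sum()
    explained = positive[:k] / total if total > 0 else np.zeros(k)
    return MdsResult(coords, explained)


def _k_medoids(D: np.ndarray, k: int, rng: np.random.Generator, n_iter: int = 100) -> np.ndarray:
    """Plain alternating k-medoids (PAM-style) on a precomputed distance matrix."""
    n = D.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    labels = np.argmin(D[:, medoids], axis=1)
    for _ in range(n_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.where(labels == c)[0]
            if members.size == 0:
                continue
            costs = D[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[np.argmin(costs)]
        new_labels = np.argmin(D[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return labels


def discover_sweet_clusters(
    fps: FingerprintMatrix,
    labels,
    thresholds: tuple[float, ...] = (0.6, 0.8),
    k_range: tuple[int, int] = (2, 6),
    min_size: int = 10,
    min_purity: float = 0.9,
    max_clusters: int = 2,
    seed: int = 0,
) -> list[ClusterReference]:
    """Identify sweet-dominated structural clusters as gate references.

    Clusters the Jaccard-Tanimoto distance matrix with k-medoids (k chosen by
    silhouette on the MDS embedding), keeps clusters whose sweet fraction is
    at least ``min_purity`` with at least ``min_size`` members, and returns
    up to ``max_clusters`` of them (largest first) with the configured
    distance thresholds attached.
    """
    from sklearn.metrics import silhouette_score

    labels = np.asarray(labels)
    D = distance_matrix(fps)
    rng = np.random.default_rng(seed)
    best_assign, best_score = None, -np.inf
    for k in range(k_range[0], min(k_range[1], fps.n_molecules - 1) + 1):
        assign = _k_medoids(D, k, rng)
        if len(np.unique(assign)) < 2:
            continue
        score = silhouette_score(D, assign, metric="precomputed")
        if score > best_score:
            best_assign, best_score = assign, score
    if best_assign is None:
        return []
    refs: list[ClusterReference] = []
    candidates = []
    for c in np.unique(best_assign):
        members = np.where(best_assign == c)[0]
        purity = np.mean(labels[members] == "sweet")
        if members.size >= min_size and purity >= min_purity:
            candidates.append(members)
    candidates.sort(key=len, reverse=True)
    for rank, members in enumerate(candidates[:max_clusters]):
        threshold = thresholds[min(rank, len(thresholds) - 1)]
        refs.append(
            ClusterReference(f"S{rank + 1}", fps.subset(members), threshold)
        )
    return refs
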