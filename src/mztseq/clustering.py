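"""Trajectory clustering of differential genes.

Increased and decreased genes are clustered independently.  For each gene
the UIC and MO GP median trajectories are divided by the shared maximum
of the two and concatenated; k-means (Lloyd, k-means++ seeding, fixed
seed 1618033) partitions these features, with k chosen by the maximal
mean silhouette over k = 2..10.  Cluster labels are ordered by the
divergence-onset time of the cluster mean, earliest first (U1/D1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import silhouette_score

DEFAULT_SEED = 1618033


@dataclass
class TrajectoryFeatures:
    gene_ids: list[str]
    features: np.ndarray  # (n_genes, 2 * n_timepoints), values in [0, 1]
    normalizer: np.ndarray  # per-gene shared max of the two medians
    n_timepoints: int


def normalize_trajectories(gene_ids, uic_medians, mo_medians) -> TrajectoryFeatures:
    """Max-normalize and concatenate UIC and MO median trajectories.

    Both vectors are divided by the maximum value experienced by either
    condition, so the concatenated feature vector of every gene has max 1.
    """
    uic = np.atleast_2d(np.asarray(uic_medians, dtype=float))
    mo = np.atleast_2d(np.asarray(mo_medians, dtype=float))
    if uic.shape != mo.shape:
        raise ValueError("UIC and MO median arrays must have equal shape")
    norm = np.maximum(uic.max(axis=1), mo.max(axis=1))
    if np.any(norm <= 0):
        bad = [gene_ids[i] for i in np.flatnonzero(norm <= 0)]
        raise ValueError(f"all-zero trajectory for gene(s): {bad[:5]}")
    feats = np.concatenate([uic / norm[:, None], mo / norm[:, None]], axis=1)
    return TrajectoryFeatures(list(gene_ids), feats, norm, uic.shape[1])


@dataclass
class ClusterAssignment:
    labels: dict[str, str]
    k: int
    wcss: float
    rng_seed: int
    raw_labels: np.ndarray = field(repr=False, default=None)
    silhouette_by_k: dict[int, float] = field(default_factory=dict)


def _lloyd(X: np.ndarray, k: int, rng_seed: int, max_iter: int = 300, tol: float = 1e-9):
    """Lloyd k-means with k-means++ seeding; objective asserted non-increasing.

    An empty cluster is re-seeded with the point farthest from its centroid.
    """
    rng = np.random.RandomState(rng_seed)
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=rng)
    prev_obj = np.inf
    labels = np.zeros(len(X), dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        obj = float(d2[np.arange(len(X)), labels].sum())
        assert obj <= prev_obj + 1e-8, "k-means objective increased"
        for c in range(k):
            mask = labels == c
            if not mask.any():
                far = int(d2[np.arange(len(X)), labels].argmax())
                centers[c] = X[far]
                labels[far] = c
                mask = labels == c
            centers[c] = X[mask].mean(axis=0)
        if prev_obj - obj < tol:
            break
        prev_obj = obj
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    wcss = float(d2[np.arange(len(X)), labels].sum())
    return labels, centers, wcss


def _divergence_onset(center: np.ndarray, n_t: int) -> float:
    """First grid index where |MO - UIC| of a cluster mean reaches half its max."""
    uic, mo = center[:n_t], center[n_t:]
    d = np.abs(mo - uic)
    if d.max() <= 0:
        return float(n_t)  # never diverges; sort last
    return float(np.argmax(d >= 0.5 * d.max()))


def kmeans_cluster(
    features: TrajectoryFeatures,
    k: int,
    rng_seed: int = DEFAULT_SEED,
    direction_prefix: str = "U",
) -> ClusterAssignment:
    """Seeded Lloyd k-means on trajectory features.

    Cluster names ``{prefix}1..{prefix}k`` are assigned by ascending
    divergence-onset time of the cluster mean, so U1 diverges earliest.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = features.features
    if len(X) < k:
        raise ValueError("fewer genes than clusters")
    raw, centers, wcss = _lloyd(X, k, rng_seed)
    onsets = [_divergence_onset(centers[c], features.n_timepoints) for c in range(k)]
    order = np.argsort(onsets, kind="stable")
    name = {int(c): f"{direction_prefix}{rank + 1}" for rank, c in enumerate(order)}
    labels = {g: name[int(c)] for g, c in zip(features.gene_ids, raw)}
    return ClusterAssignment(labels, k, wcss, rng_seed, raw_labels=raw)


def silhouette_select_k(
    features: TrajectoryFeatures,
    k_range=range(2, 11),
    rng_seed: int = DEFAULT_SEED,
    direction_prefix: str = "U",
):
    """Choose k by maximal mean silhouette (Euclidean) over ``k_range``.

    Returns the assignment at the selected k with the per-k silhouette
    table attached.
    """
    X = features.features
    if len(X) <= max(k_range):
        raise ValueError("need more genes than the largest k")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate all-identical features")
    scores: dict[int, float] = {}
    assignments: dict[int, ClusterAssignment] = {}
    for k in k_range:
        a = kmeans_cluster(features, k, rng_seed, direction_prefix)
        scores[k] = float(silhouette_score(X, a.raw_labels, metric="euclidean"))
        assignments[k] = a
    k_star = max(scores, key=lambda k: (scores[k], -k))
    best = assignments[k_star]
    best.silhouette_by_k = scores
    return k_star, best


def mode_of_selected_k(selected: list[int]) -> int:
    """Mode of per-run selected k values; ties resolved to the smallest k."""
    counts = Counter(selected)
    top = max(counts.values())
    return min(k for k, c in counts.items() if c == top)
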