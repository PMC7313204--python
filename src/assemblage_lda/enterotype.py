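"""Enterotype assignment: PAM clustering under Jensen-Shannon divergence.

Samples are clustered on their genus-level relative-abundance profiles with
partitioning around medoids (PAM), using the Jensen-Shannon divergence (JSD,
natural log) as the dissimilarity, repeated over random restarts with the
highest-silhouette result kept. Clusters are named after their most abundant
genus (classically Bacteroides, Prevotella, and Ruminococcus/Blautia types).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr, xlogy

from .datatypes import RelativeAbundanceTable


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative sample-by-sample dissimilarities, zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if values.shape != (n, n):
            raise ValueError("values must be square and match ids")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12, rtol=0):
            raise ValueError("diagonal must be zero")
        if (values < 0).any():
            raise ValueError("dissimilarities must be nonnegative")
        self.values = values

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class ClusteringResult:
    """PAM output: labels in 0..k-1, medoid sample indices, and provenance."""

    labels: np.ndarray
    medoid_indices: np.ndarray
    silhouette: float
    n_iterations: int
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.medoid_indices = np.asarray(self.medoid_indices, dtype=int)
        for c, m in enumerate(self.medoid_indices):
            if self.labels[m] != c:
                raise ValueError(f"medoid {m} is not labeled with its own cluster {c}")
        if not (-1.0 - 1e-12 <= self.silhouette <= 1.0 + 1e-12):
            raise ValueError("silhouette must lie in [-1, 1]")

    @property
    def k(self) -> int:
        return len(self.medoid_indices)


def _validate_prob(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError(f"{name} has negative entries")
    if not np.isclose(p.sum(), 1.0, atol=1e-9, rtol=0):
        raise ValueError(f"{name} must sum to 1 (got {p.sum()!r})")
    return p


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in nats: JSD = KL(p||m)/2 + KL(q||m)/2, m=(p+q)/2.

    Symmetric, bounded by ln 2; zero-probability entries contribute nothing
    to their own KL term (0 log 0 = 0).
    """
    p = _validate_prob(p, "p")
    q = _validate_prob(q, "q")
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    m = 0.5 * (p + q)
    return float(0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum())


def pairwise_jsd(profiles: RelativeAbundanceTable) -> DissimilarityMatrix:
    """All-pairs JSD matrix, computed via JSD(p,q) = H(m) - (H(p)+H(q))/2."""
    X = profiles.proportions
    H = -xlogy(X, X).sum(axis=1)  # per-row Shannon entropy, nats
    n = X.shape[0]
    values = np.zeros((n, n))
    for i in range(n):
        M = 0.5 * (X[i][None, :] + X[i + 1:])
        Hm = -xlogy(M, M).sum(axis=1)
        values[i, i + 1:] = Hm - 0.5 * (H[i] + H[i + 1:])
    values = values + values.T
    values[values < 0] = 0.0  # clip rounding noise
    return DissimilarityMatrix(list(profiles.sample_ids), values)


def _assign(dissim: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # ties go to the lower cluster index (argmin picks the first minimum)
    return np.argmin(dissim[:, medoids], axis=1)


def _pam_objective(dissim: np.ndarray, medoids: np.ndarray, labels: np.ndarray) -> float:
    return float(dissim[np.arange(len(labels)), medoids[labels]].sum())


def _pam_single(
    dissim: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int, list[float]]:
    n = dissim.shape[0]
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    objective_trace: list[float] = []
    for iteration in range(1, 10_000):
        labels = _assign(dissim, medoids)
        # re-seed empty clusters: move the stale medoid to the non-medoid
        # sample farthest from every current medoid, then reassign
        for c in range(k):
            if not (labels == c).any():
                medoids = medoids.copy()
                candidates = np.setdiff1d(np.arange(n), medoids)
                farthest = dissim[np.ix_(candidates, medoids)].min(axis=1)
                medoids[c] = int(candidates[np.argmax(farthest)])
                labels = _assign(dissim, medoids)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            within = dissim[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        objective_trace.append(
            _pam_objective(dissim, new_medoids, _assign(dissim, new_medoids))
        )
        if set(new_medoids) == set(medoids):
            return labels, medoids, iteration, objective_trace
        medoids = new_medoids
    return labels, medoids, iteration, objective_trace


def silhouette(labels: np.ndarray, dissim: DissimilarityMatrix) -> float:
    """Mean silhouette coefficient over samples from a precomputed matrix.

    s(i) = (b - a) / max(a, b) with a = mean dissimilarity to the other
    members of i's cluster and b = the smallest mean dissimilarity to any
    other cluster; singleton clusters take s = 0 by convention.
    """
    labels = np.asarray(labels, dtype=int)
    D = dissim.values
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    s = np.zeros(len(labels))
    for i in range(len(labels)):
        own = np.flatnonzero(labels == labels[i])
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = D[i, own[own != i]].mean()
        b = min(D[i, labels == c].mean() for c in clusters if c != labels[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(s.mean())


def pam_cluster(
    dissim: DissimilarityMatrix, k: int, n_trials: int = 10, base_seed: int = 0
) -> ClusteringResult:
    """Best-of-``n_trials`` PAM clustering, selected by silhouette coefficient.

    Each trial starts from k distinct random medoids, then alternates
    (assign each sample to the nearest medoid by dissimilarity; replace each
    cluster's medoid by the member minimizing summed dissimilarity to its
    co-members) until the medoid set stops changing. Ties across trials go
    to the earliest trial (lowest seed).
    """
    n = dissim.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    best: ClusteringResult | None = None
    for seed in range(base_seed, base_seed + n_trials):
        rng = np.random.default_rng(seed)
        labels, medoids, iters, _ = _pam_single(dissim.values, k, rng)
        # canonical cluster order: by medoid index
        order = np.argsort(medoids)
        medoids = medoids[order]
        relabel = np.empty(k, dtype=int)
        relabel[order] = np.arange(k)
        labels = relabel[labels]
        sil = silhouette(labels, dissim) if k >= 2 else 0.0
        result = ClusteringResult(labels, medoids, sil, iters, seed)
        if best is None or result.silhouette > best.silhouette:
            best = result
    assert best is not None
    return best


def name_clusters_by_dominant_feature(
    result: ClusteringResult, profiles: RelativeAbundanceTable
) -> dict[int, str]:
    """Name each cluster by the feature with the highest mean relative abundance.

    Ties are broken by feature (column) order.
    """
    names: dict[int, str] = {}
    for c in range(result.k):
        members = result.labels == c
        mean_profile = profiles.proportions[members].mean(axis=0)
        names[c] = profiles.feature_ids[int(np.argmax(mean_profile))]
    return names
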