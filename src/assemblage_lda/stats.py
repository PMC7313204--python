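"""Entropy and posterior statistics over assemblages.

Given fitted LDA parameters theta (samples x assemblages) and phi
(assemblages x features), computes:

* the assemblage prior P(k), the average of theta[:, k] across samples;
* the per-feature posterior P(k|j) = phi[k, j] P(k) / sum_k phi[k, j] P(k);
* Shannon entropies (nats, 0 log 0 = 0) of each sample's assemblage
  distribution H(i) = -sum_k theta[i, k] log theta[i, k] and of each
  feature's posterior H(j) = -sum_k P(k|j) log P(k|j);
* group-averaged assemblage distributions (per enterotype or per country).

Low H(j) marks assemblage-specific features; high H(j) marks features shared
across assemblages (the generalist pattern).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy


@dataclass
class AssemblageStats:
    p_k: np.ndarray            # (K,) assemblage prior
    p_k_given_j: np.ndarray    # (D, K) per-feature posterior, rows sum to 1
    sample_entropies: np.ndarray  # (N,) H(i), nats
    feature_entropies: np.ndarray  # (D,) H(j), nats


@dataclass
class GroupedDistribution:
    """Per-group mean and population standard deviation of theta columns."""

    group_ids: list[str]
    mean: np.ndarray  # (G, K), rows sum to 1
    sd: np.ndarray    # (G, K), population convention (divide by n)
    n_per_group: np.ndarray  # (G,)


def _entropy(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("probability vector has negative entries")
    if not np.isclose(p.sum(), 1.0, atol=1e-9, rtol=0):
        raise ValueError(f"probability vector sums to {p.sum()!r}, not 1")
    return float(-xlogy(p, p).sum())


def sample_entropy(theta_row: np.ndarray) -> float:
    """Entropy H(i) of one sample's assemblage distribution, in nats."""
    return _entropy(theta_row)


def feature_entropy(p_k_given_j_row: np.ndarray) -> float:
    """Entropy H(j) of one feature's assemblage posterior, in nats."""
    return _entropy(p_k_given_j_row)


def assemblage_prior(theta: np.ndarray) -> np.ndarray:
    """P(k): the average of theta[:, k] across samples."""
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] == 0:
        raise ValueError("theta must be a nonempty N x K matrix")
    return theta.mean(axis=0)


def feature_posterior(phi: np.ndarray, p_k: np.ndarray) -> np.ndarray:
    """P(k|j) = phi[k, j] P(k) / sum_k phi[k, j] P(k), one row per feature."""
    phi = np.asarray(phi, dtype=float)
    p_k = np.asarray(p_k, dtype=float)
    joint = phi.T * p_k[None, :]  # (D, K)
    denom = joint.sum(axis=1)
    if (denom <= 0).any():
        bad = int(np.argmax(denom <= 0))
        raise ValueError(f"feature at index {bad} has zero probability in every assemblage")
    return joint / denom[:, None]


def compute_assemblage_stats(theta: np.ndarray, phi: np.ndarray) -> AssemblageStats:
    """All assemblage statistics from one fitted (theta, phi) pair."""
    p_k = assemblage_prior(theta)
    pkj = feature_posterior(phi, p_k)
    return AssemblageStats(
        p_k=p_k,
        p_k_given_j=pkj,
        sample_entropies=np.array([sample_entropy(row) for row in theta]),
        feature_entropies=np.array([feature_entropy(row) for row in pkj]),
    )


def average_by_group(theta: np.ndarray, labels) -> GroupedDistribution:
    """Group-averaged assemblage distributions (group order = first appearance)."""
    theta = np.asarray(theta, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != theta.shape[0]:
        raise ValueError("labels must align with theta rows")
    group_ids = list(dict.fromkeys(labels.tolist()))
    means, sds, ns = [], [], []
    for g in group_ids:
        block = theta[labels == g]
        means.append(block.mean(axis=0))
        sds.append(block.std(axis=0))  # population sd
        ns.append(block.shape[0])
    return GroupedDistribution(
        group_ids=[str(g) for g in group_ids],
        mean=np.asarray(means),
        sd=np.asarray(sds),
        n_per_group=np.asarray(ns),
    )


def top_features(
    phi_row: np.ndarray, n: int, feature_ids: list[str]
) -> list[tuple[str, float]]:
    """The ``n`` most probable features of one assemblage, ties by column order."""
    phi_row = np.asarray(phi_row, dtype=float)
    if n > len(feature_ids):
        raise ValueError("n exceeds the number of features")
    order = np.argsort(-phi_row, kind="stable")[:n]
    return [(feature_ids[j], float(phi_row[j])) for j in order]


def entropy_histogram(
    entropies: np.ndarray, n_bins: int, k: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Equal-width histogram of entropy scores over [0, ln k], plus the median.

    Returns (bin_edges, counts, median); counts sum to the input length.
    """
    entropies = np.asarray(entropies, dtype=float)
    if entropies.size == 0:
        raise ValueError("empty entropy vector")
    if not np.isfinite(entropies).all():
        raise ValueError("entropies must be finite")
    if n_bins < 1 or k < 2:
        raise ValueError("need n_bins >= 1 and k >= 2")
    edges = np.linspace(0.0, np.log(k), n_bins + 1)
    counts, _ = np.histogram(np.clip(entropies, 0.0, np.log(k)), bins=edges)
    return edges, counts, float(np.median(entropies))
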