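"""Synthetic gut-microbiome corpora with known ground truth.

Data are generated by the LDA forward process itself: each sample draws an
assemblage mixture theta_i from a Dirichlet prior, each read draws a latent
assemblage from theta_i and a genus from that assemblage's phi row. The
enterotype design builds a K=4 structure emulating the reported gut
assemblage pattern: three specialist assemblages, each dominated by a single
signature genus (default masses 0.71 and 0.66 for the Bacteroides- and
Prevotella-like assemblages), plus one generalist assemblage spreading
moderate mass (<= 0.20 per genus) over a block of genera shared by all
sample groups. Group (enterotype) structure is injected through the theta
prior: each group concentrates on its own specialist assemblage with a
common ~0.3 weight on the generalist.

Functional profiles are coupled to the same theta: KO counts are drawn from
a mixture over per-assemblage KO loadings in which designated
butyrate-production KOs load several-fold more on the generalist assemblage,
so the generalist theta column correlates positively with their relative
abundance by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import CountTable
from .preprocess import write_count_table

ROW_TOL = 1e-12
DEFAULT_SIGNATURE_NAMES = ("Bacteroides", "Prevotella", "Blautia")
GENERALIST_BLOCK_SIZE = 12
# specialists spread their non-signature mass from this feature index on, so
# the first half of the generalist block (features 3..8) is exclusive to the
# generalist (anchor features, making the decomposition identifiable) while
# the second half (features 9..14) is shared with the specialists
SPECIALIST_SPREAD_START = 9
# Each group's theta prior is a two-component Dirichlet mixture: a
# generalist-rich majority and a generalist-poor minority, with the group
# MEAN generalist weight equal to the designed value (0.3 by default).
# Generalist abundance must vary across individuals for the 4-assemblage
# decomposition to be identifiable: if every sample carried the same
# generalist weight, blending specialist rows of phi with the generalist row
# (and adjusting theta) would leave every sample's read distribution exactly
# unchanged, so no estimator could pin down the split. The generalist-poor
# samples break that ridge; they also reflect the person-to-person
# variability of the generalist assemblage seen in real cohorts.


@dataclass
class GroupDesign:
    """Group-structured theta prior: theta ~ Dirichlet(concentration * mean_g)."""

    group_names: list[str]
    group_means: np.ndarray  # (G, K), rows sum to 1
    concentration: float
    group_probs: np.ndarray  # (G,)

    def __post_init__(self) -> None:
        self.group_means = np.asarray(self.group_means, dtype=float)
        self.group_probs = np.asarray(self.group_probs, dtype=float)
        if not np.allclose(self.group_means.sum(axis=1), 1.0, atol=ROW_TOL, rtol=0):
            raise ValueError("group_means rows must sum to 1")
        if not np.isclose(self.group_probs.sum(), 1.0):
            raise ValueError("group_probs must sum to 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass
class GenerativeConfig:
    """Full specification of one synthetic corpus."""

    n_samples: int
    n_features: int
    n_assemblages: int
    reads_per_sample: int
    alpha_true: np.ndarray  # (K,)
    phi_true: np.ndarray    # (K, D), row-stochastic
    seed: int
    group_design: GroupDesign | None = None
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.alpha_true = np.asarray(self.alpha_true, dtype=float)
        self.phi_true = np.asarray(self.phi_true, dtype=float)
        if min(self.n_samples, self.n_features, self.n_assemblages, self.reads_per_sample) < 1:
            raise ValueError("sizes must be positive integers")
        if self.alpha_true.shape != (self.n_assemblages,) or (self.alpha_true <= 0).any():
            raise ValueError("alpha_true must be a K-vector of positive reals")
        if self.phi_true.shape != (self.n_assemblages, self.n_features):
            raise ValueError("phi_true must be K x D")
        if (self.phi_true < 0).any():
            raise ValueError("phi_true entries must be nonnegative")
        if not np.allclose(self.phi_true.sum(axis=1), 1.0, atol=ROW_TOL, rtol=0):
            bad = int(np.argmax(np.abs(self.phi_true.sum(axis=1) - 1.0)))
            raise ValueError(f"phi_true row {bad} is not a probability vector")


@dataclass
class SyntheticDataset:
    """Generated corpus with its ground truth."""

    counts: CountTable
    theta_true: np.ndarray  # (N, K)
    phi_true: np.ndarray    # (K, D)
    group_labels: np.ndarray  # (N,) strings
    config: GenerativeConfig
    assemblage_read_counts: np.ndarray  # (N, K) latent reads per assemblage
    function_counts: CountTable | None = None
    ko_assemblage_loadings: np.ndarray | None = None
    butyrate_ko_ids: list[str] | None = None
    generalist_assemblage: int | None = None


def sample_lda_corpus(config: GenerativeConfig) -> SyntheticDataset:
    """Draw one corpus from the LDA forward process (deterministic per seed).

    theta_i ~ Dirichlet(alpha_true) (or the group design's Dirichlet), then
    per-sample assemblage read counts ~ Multinomial(reads, theta_i) and
    genus counts ~ Multinomial per assemblage from phi_true. Every counts
    row sums exactly to ``reads_per_sample``.
    """
    rng = np.random.default_rng(config.seed)
    N, D, K = config.n_samples, config.n_features, config.n_assemblages
    gd = config.group_design
    if gd is not None:
        if gd.group_means.shape[1] != K:
            raise ValueError("group design K mismatch")
        groups = rng.choice(len(gd.group_names), size=N, p=gd.group_probs)
        theta = np.empty((N, K))
        for i, g in enumerate(groups):
            theta[i] = rng.dirichlet(gd.concentration * gd.group_means[g])
        labels = np.array([gd.group_names[g] for g in groups])
    else:
        theta = rng.dirichlet(config.alpha_true, size=N)
        labels = np.array(["all"] * N)

    counts = np.zeros((N, D), dtype=np.int64)
    z_counts = np.empty((N, K), dtype=np.int64)
    for i in range(N):
        z_counts[i] = rng.multinomial(config.reads_per_sample, theta[i])
        for k in range(K):
            if z_counts[i, k]:
                counts[i] += rng.multinomial(z_counts[i, k], config.phi_true[k])

    sample_ids = [f"sample_{i + 1:04d}" for i in range(N)]
    feature_ids = config.feature_ids or [f"genus_{j + 1:03d}" for j in range(D)]
    return SyntheticDataset(
        counts=CountTable(sample_ids, list(feature_ids), counts),
        theta_true=theta,
        phi_true=config.phi_true.copy(),
        group_labels=labels,
        config=config,
        assemblage_read_counts=z_counts,
    )


def make_enterotype_design(
    n_features: int,
    dominant_mass_b: float = 0.71,
    dominant_mass_p: float = 0.66,
    dominant_mass_r: float = 0.40,
    n_samples: int = 300,
    reads_per_sample: int = 5000,
    generalist_weight: float = 0.3,
    other_weight: float = 0.04,
    generalist_poor_frac: float = 0.2,
    generalist_poor_weight: float = 0.04,
    group_concentration: float = 50.0,
    seed: int = 0,
) -> GenerativeConfig:
    """K=4 enterotype-structured generative design.

    Assemblages 1-3 are specialists: each places its dominant mass on a
    unique signature genus (the first three feature indices, by convention),
    with the remainder spread by a fixed low-concentration Dirichlet draw
    over the genera from ``SPECIALIST_SPREAD_START`` on. Assemblage 4 is the
    generalist: its mass is spread over a block of >= 8 genera shared across
    all sample groups, capped at 0.20 per genus by construction; the first
    half of the block is exclusive to the generalist (anchor genera, which
    make the mixture decomposition identifiable) and the second half is also
    used by the specialists (shared genera, giving the high-entropy peak of
    the feature-entropy distribution). Each sample group's theta prior
    concentrates on its own specialist assemblage plus a common mean
    ``generalist_weight`` (default 0.3) on the generalist, realized as a
    rich/poor Dirichlet mixture (see the module comment on identifiability):
    a ``generalist_poor_frac`` minority carries ``generalist_poor_weight``
    and the majority carries the complementary weight so the group mean is
    exactly ``generalist_weight``.
    """
    if n_features < 20:
        raise ValueError("need n_features >= 20 to allocate disjoint signature features")
    for name, m in (("b", dominant_mass_b), ("p", dominant_mass_p), ("r", dominant_mass_r)):
        if not 0 < m <= 1:
            raise ValueError(f"dominant_mass_{name} must lie in (0, 1]")
    K = 4
    design_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))

    phi = np.zeros((K, n_features))
    masses = (dominant_mass_b, dominant_mass_p, dominant_mass_r)
    spread_idx = np.arange(SPECIALIST_SPREAD_START, n_features)
    for k, mass in enumerate(masses):
        phi[k, k] = mass
        remainder = 1.0 - mass
        if remainder > 0:
            spread = design_rng.dirichlet(np.full(spread_idx.size, 0.5))
            phi[k, spread_idx] = remainder * spread
    # generalist: jittered uniform over a shared block; max entry provably
    # <= 1.3 / (0.7 * block) ~ 0.155 < 0.20
    block = np.arange(3, 3 + GENERALIST_BLOCK_SIZE)
    raw = 1.0 + 0.3 * design_rng.uniform(-1.0, 1.0, size=block.size)
    phi[3, block] = raw / raw.sum()
    phi /= phi.sum(axis=1, keepdims=True)

    f = generalist_poor_frac
    if not 0 <= f < 1:
        raise ValueError("generalist_poor_frac must lie in [0, 1)")
    gen_rich = (generalist_weight - f * generalist_poor_weight) / (1.0 - f)
    if not 0 < gen_rich < 1:
        raise ValueError("inconsistent generalist weights")
    names, means, probs = [], [], []
    for g in range(3):
        for gen_w, frac in ((gen_rich, 1.0 - f), (generalist_poor_weight, f)):
            if frac == 0:
                continue
            row = np.full(K, other_weight)
            row[g] = 1.0 - gen_w - 2.0 * other_weight
            row[3] = gen_w
            if row[g] <= 0:
                raise ValueError("weights leave no mass for the specialist assemblage")
            names.append("BPR"[g])
            means.append(row)
            probs.append(frac / 3.0)
    gd = GroupDesign(
        group_names=names,
        group_means=np.asarray(means),
        concentration=group_concentration,
        group_probs=np.asarray(probs),
    )
    marginal = (np.asarray(means) * np.asarray(probs)[:, None]).sum(axis=0)
    alpha_true = group_concentration * marginal  # nominal marginal prior

    feature_ids = list(DEFAULT_SIGNATURE_NAMES) + [
        f"genus_{j + 1:03d}" for j in range(3, n_features)
    ]
    return GenerativeConfig(
        n_samples=n_samples,
        n_features=n_features,
        n_assemblages=K,
        reads_per_sample=reads_per_sample,
        alpha_true=alpha_true,
        phi_true=phi,
        seed=seed,
        group_design=gd,
        feature_ids=feature_ids,
    )


def sample_functional_profiles(
    dataset: SyntheticDataset,
    n_kos: int = 60,
    butyrate_ko_indices: tuple[int, ...] = (0, 1, 2),
    generalist_assemblage: int = 3,
    reads_per_sample: int = 10_000,
    seed: int = 0,
    butyrate_mass_generalist: float = 0.30,
    butyrate_mass_other: float = 0.02,
) -> SyntheticDataset:
    """Couple KO count profiles to the corpus through the same true theta.

    Builds K x M row-stochastic KO loadings in which the designated butyrate
    KOs carry ``butyrate_mass_generalist`` total mass in the generalist
    assemblage and ``butyrate_mass_other`` elsewhere (>= 3x less by
    default), then draws each sample's KO counts from
    Multinomial(reads, theta_i @ loadings).
    """
    if dataset.theta_true is None:
        raise ValueError("dataset lacks theta_true")
    K = dataset.theta_true.shape[1]
    if not 0 <= generalist_assemblage < K:
        raise ValueError(f"generalist_assemblage must be in 0..{K - 1}")
    b_idx = np.asarray(sorted(set(butyrate_ko_indices)), dtype=int)
    if b_idx.size == 0:
        raise ValueError("butyrate_ko_indices must be nonempty")
    if b_idx.min() < 0 or b_idx.max() >= n_kos:
        raise ValueError("butyrate_ko_indices out of range")

    rng = np.random.default_rng(seed)
    other_idx = np.setdiff1d(np.arange(n_kos), b_idx)
    loadings = np.zeros((K, n_kos))
    for k in range(K):
        b_mass = butyrate_mass_generalist if k == generalist_assemblage else butyrate_mass_other
        loadings[k, b_idx] = b_mass / b_idx.size
        spread = rng.dirichlet(np.ones(other_idx.size))
        loadings[k, other_idx] = (1.0 - b_mass) * spread
    loadings /= loadings.sum(axis=1, keepdims=True)

    mixture = dataset.theta_true @ loadings
    N = mixture.shape[0]
    ko_counts = np.empty((N, n_kos), dtype=np.int64)
    for i in range(N):
        ko_counts[i] = rng.multinomial(reads_per_sample, mixture[i])

    butyrate_names = ["K00929", "K01034", "K01035"]
    ko_ids = [f"KO_{j + 1:04d}" for j in range(n_kos)]
    for pos, j in enumerate(b_idx):
        ko_ids[j] = butyrate_names[pos] if pos < 3 else f"butyrate_KO_{pos + 1}"

    return dataclasses.replace(
        dataset,
        function_counts=CountTable(list(dataset.counts.sample_ids), ko_ids, ko_counts),
        ko_assemblage_loadings=loadings,
        butyrate_ko_ids=[ko_ids[j] for j in b_idx],
        generalist_assemblage=generalist_assemblage,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write counts.tsv (plus ko_counts.tsv, labels.tsv) and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_table(dataset.counts, out / "counts.tsv")
    with open(out / "labels.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, g in zip(dataset.counts.sample_ids, dataset.group_labels):
            fh.write(f"{sid}\t{g}\n")
    truth = {
        "seed": dataset.config.seed,
        "alpha_true": dataset.config.alpha_true.tolist(),
        "phi_true": dataset.phi_true.tolist(),
        "theta_true": dataset.theta_true.tolist(),
        "group_labels": dataset.group_labels.tolist(),
    }
    if dataset.function_counts is not None:
        write_count_table(dataset.function_counts, out / "ko_counts.tsv")
        truth["ko_assemblage_loadings"] = dataset.ko_assemblage_loadings.tolist()
        truth["butyrate_ko_ids"] = dataset.butyrate_ko_ids
        truth["generalist_assemblage"] = dataset.generalist_assemblage
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh)
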