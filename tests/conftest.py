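import numpy as np
import pytest

from assemblage_lda import (
    CountTable,
    drop_empty_features,
    fit_lda,
    make_enterotype_design,
    normalize_to_constant,
    sample_functional_profiles,
    sample_lda_corpus,
)

# Study-condition constants for the enterotype-design simulation shared by
# the recovery, generalist-detection, association, and matching tests.
ENTEROTYPE_SEED = 11
ENTEROTYPE_N = 300
ENTEROTYPE_D = 50
ENTEROTYPE_READS = 5000


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_table():
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 30, size=(6, 9))
    counts[:, 0] += 1  # no zero rows
    return CountTable(
        [f"s{i}" for i in range(6)], [f"g{j}" for j in range(9)], counts
    )


@pytest.fixture(scope="session")
def enterotype_dataset():
    """Synthetic gut corpus with coupled KO profiles (ground truth known)."""
    config = make_enterotype_design(
        ENTEROTYPE_D,
        n_samples=ENTEROTYPE_N,
        reads_per_sample=ENTEROTYPE_READS,
        seed=ENTEROTYPE_SEED,
    )
    dataset = sample_lda_corpus(config)
    return sample_functional_profiles(dataset, seed=ENTEROTYPE_SEED + 1)


@pytest.fixture(scope="session")
def enterotype_norm(enterotype_dataset):
    return drop_empty_features(normalize_to_constant(enterotype_dataset.counts))


@pytest.fixture(scope="session")
def enterotype_fit(enterotype_norm):
    """Best-of-10-trials K=4 fit on the enterotype corpus (shared; expensive)."""
    return fit_lda(enterotype_norm, 4, n_trials=10, base_seed=0)


@pytest.fixture(scope="session")
def functional_norm(enterotype_dataset):
    return drop_empty_features(normalize_to_constant(enterotype_dataset.function_counts))


@pytest.fixture(scope="session")
def functional_fit(functional_norm):
    """K=4 LDA fit on the coupled KO profiles (shared; expensive)."""
    return fit_lda(functional_norm, 4, n_trials=5, base_seed=100)


def match_to_truth(fit, dataset, norm):
    """Optimal fit-to-truth assemblage matching by theta-column correlation.

    Returns (pairs, theta_r, phi_tv): matched (fit, true) index pairs, the
    matched theta-column Pearson correlations, and the matched total
    variation distances between estimated and true phi rows (the true rows
    restricted and renormalized to the features surviving preprocessing).
    """
    from scipy.optimize import linear_sum_assignment

    K = fit.K
    score = np.array(
        [
            [np.corrcoef(fit.theta[:, a], dataset.theta_true[:, b])[0, 1] for b in range(K)]
            for a in range(K)
        ]
    )
    rows, cols = linear_sum_assignment(-score)
    keep = [dataset.counts.feature_ids.index(f) for f in norm.feature_ids]
    tv = []
    for a, b in zip(rows, cols):
        truth = dataset.phi_true[b][keep]
        truth = truth / truth.sum()
        tv.append(0.5 * np.abs(fit.phi[a] - truth).sum())
    return list(zip(rows, cols)), score[rows, cols], np.asarray(tv)
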