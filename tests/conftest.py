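import numpy as np
import pytest

from assayval import (
    GeneratorTruth,
    gen_count_matrix,
    gen_score_table,
    normalize_counts,
    size_factors,
    train_classifier,
)


@pytest.fixture(scope="session")
def count_matrix():
    """Small two-class count matrix with a clear expression signal."""
    return gen_count_matrix(
        n_genes=300, n_per_class=15, n_informative=40, effect_size=1.5,
        dispersion=0.1, libsize_cv=0.2, seed=7,
    )


@pytest.fixture(scope="session")
def normalized(count_matrix):
    f = size_factors(count_matrix)
    return normalize_counts(count_matrix, f)


@pytest.fixture(scope="session")
def model(count_matrix, normalized):
    return train_classifier(
        normalized, count_matrix.genes,
        count_matrix.meta["true_class"].to_numpy(), ridge_penalty=0.5,
    )


@pytest.fixture()
def balanced_truth():
    return GeneratorTruth(
        n_samples_per_class=5, class_mean_separation=4.0, sigma_sample=0.5,
        sigma_run=0.2, sigma_interaction=0.15, sigma_residual=0.1, seed=11,
    )


@pytest.fixture()
def balanced_table(balanced_truth):
    return gen_score_table(balanced_truth, n_runs=3, n_reps=3)


def rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC, independent of any classifier internals."""
    from scipy.stats import mannwhitneyu

    pos = scores[positive]
    neg = scores[~positive]
    u = mannwhitneyu(pos, neg).statistic
    return u / (len(pos) * len(neg))
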