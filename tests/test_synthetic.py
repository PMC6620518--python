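"""Generator tests: seeded determinism, design arithmetic, and convergence
of empirical moments to the generator truths."""

import numpy as np
import pandas as pd
import pytest

from assayval import (
    GeneratorTruth,
    gen_count_matrix,
    gen_interference_profile,
    gen_score_table,
    normalize_counts,
    size_factors,
    train_classifier,
    score_samples,
)
from assayval.synthetic import BLOOD_MARKER_FRACTION

from conftest import rank_auc


class TestCountMatrix:
    def test_seeded_determinism(self):
        a = gen_count_matrix(n_genes=100, n_per_class=5, n_informative=20, seed=3)
        b = gen_count_matrix(n_genes=100, n_per_class=5, n_informative=20, seed=3)
        assert np.array_equal(a.counts, b.counts)
        assert a.samples == b.samples

    def test_counts_nonnegative_and_metadata_complete(self):
        m = gen_count_matrix(n_genes=150, n_per_class=8, n_informative=20, seed=1)
        assert np.all(m.counts >= 0)
        assert list(m.meta["sample_id"]) == m.samples
        assert set(m.meta["true_class"]) == {"positive", "negative"}

    @pytest.mark.parametrize("bad", [
        {"n_genes": 0}, {"n_per_class": 0}, {"dispersion": 0.0},
        {"n_informative": 50, "n_genes": 10},
    ])
    def test_invalid_parameters_rejected_by_name(self, bad):
        with pytest.raises(ValueError):
            gen_count_matrix(seed=0, **bad)

    def test_no_signal_means_chance_discrimination(self):
        """With zero informative genes a classifier trained on one draw
        scores an independent draw at chance AUC (0.5 +/- 0.05)."""
        aucs = []
        for seed in (101, 202, 303):
            train = gen_count_matrix(n_genes=400, n_per_class=100, n_informative=0, seed=seed)
            test = gen_count_matrix(n_genes=400, n_per_class=100, n_informative=0, seed=seed + 1)
            model = train_classifier(
                normalize_counts(train, size_factors(train)), train.genes,
                train.meta["true_class"].to_numpy(),
            )
            s, _ = score_samples(model, normalize_counts(test, size_factors(test)), test.genes)
            aucs.append(rank_auc(s, test.meta["true_class"].to_numpy() == "positive"))
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_law_of_large_numbers_on_gene_means(self):
        """With no differential signal, small dispersion and no library-size
        variation, per-gene sample means sit within 5% of generator means."""
        m = gen_count_matrix(
            n_genes=50, n_per_class=200, n_informative=0, effect_size=0.0,
            dispersion=0.01, libsize_cv=0.0, seed=5,
        )
        observed = m.counts.mean(axis=1)
        # regenerate the baseline means from the same seed stream
        rng = np.random.default_rng(5)
        expected = rng.lognormal(mean=4.0, sigma=1.0, size=50)
        assert np.all(np.abs(observed / expected - 1) < 0.05)


class TestScoreTable:
    def test_zero_sds_give_exact_class_means(self):
        truth = GeneratorTruth(
            n_samples_per_class=3, class_mean_separation=4.0, sigma_sample=0.0,
            sigma_run=0.0, sigma_interaction=0.0, sigma_residual=0.0, seed=0,
        )
        t = gen_score_table(truth, n_runs=2, n_reps=2)
        by_class = t.df.groupby("true_class")["score"].unique()
        assert list(by_class["positive"]) == [2.0]
        assert list(by_class["negative"]) == [-2.0]

    def test_record_count_is_design_product(self):
        # 15 samples x 3 runs x 3 replicates in one lab: 135 assays,
        # or 134 with the drop-one QC flag
        truth = GeneratorTruth(n_samples_per_class=8, seed=2)
        t = gen_score_table(truth, n_runs=3, n_reps=3)
        assert len(t) == 16 * 3 * 3
        t134 = gen_score_table(truth, n_runs=3, n_reps=3, drop_one=True)
        assert len(t134) == 16 * 3 * 3 - 1

    def test_within_cell_sd_converges_to_residual_truth(self):
        truth = GeneratorTruth(
            n_samples_per_class=50, sigma_sample=0.5, sigma_run=0.2,
            sigma_interaction=0.1, sigma_residual=0.2, seed=4,
        )
        t = gen_score_table(truth, n_runs=5, n_reps=10)
        cell_sd = t.df.groupby(["sample_id", "run_id"])["score"].std(ddof=1)
        pooled = np.sqrt(np.mean(cell_sd**2))
        assert abs(pooled / 0.2 - 1) < 0.10

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="sigma_run"):
            GeneratorTruth(sigma_run=-0.1)

    def test_fully_crossed_balanced(self):
        truth = GeneratorTruth(n_samples_per_class=4, seed=9)
        t = gen_score_table(truth, n_runs=3, n_reps=2, n_labs=2)
        counts = t.df.groupby(["sample_id", "run_id", "lab_id"]).size()
        assert counts.nunique() == 1 and counts.iloc[0] == 2


class TestInterferenceProfile:
    def test_seeded_determinism(self):
        a = gen_interference_profile("blood", n_genes=500, seed=8)
        b = gen_interference_profile("blood", n_genes=500, seed=8)
        assert np.array_equal(a, b)

    def test_gdna_flatter_than_blood(self):
        gdna = gen_interference_profile("gDNA", n_genes=500, seed=1)
        blood = gen_interference_profile("blood", n_genes=500, seed=1)
        cv = lambda x: np.std(x) / np.mean(x)  # noqa: E731
        assert cv(gdna) < cv(blood)

    def test_blood_mass_concentrated_in_markers(self):
        n = 1000
        blood = gen_interference_profile("blood", n_genes=n, seed=2)
        n_marker = int(round(BLOOD_MARKER_FRACTION * n))
        assert blood[:n_marker].sum() / blood.sum() >= 0.80

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            gen_interference_profile("plasma", n_genes=100, seed=0)
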