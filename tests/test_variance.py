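"""Effect models, variance components, pooled SDs, bootstrap CIs, and the
two-laboratory comparison."""

import numpy as np
import pandas as pd
import pytest

from assayval import (
    GeneratorTruth,
    ScoreTable,
    bootstrap_sd_ci,
    estimate_variance_components,
    fit_effect_model,
    gen_score_table,
    interclass_sd,
    interlab_analysis,
    intra_run_sd,
    pooled_sd,
)


def _condition_table(n_samples=6, conditions=("a", "b"), n_reps=3, shift=None,
                     sigma=0.1, seed=0):
    rng = np.random.default_rng(seed)
    mu = rng.normal(0, 1, n_samples)
    shift = shift or {c: 0.0 for c in conditions}
    rows = []
    for i in range(n_samples):
        for c in conditions:
            for k in range(n_reps):
                rows.append({
                    "sample_id": f"s{i}", "true_class": "positive",
                    "condition": c, "run_id": "run1", "lab_id": "lab1",
                    "replicate_id": f"r{k}",
                    "score": mu[i] + shift[c] + rng.normal(0, sigma),
                })
    return ScoreTable(pd.DataFrame(rows))


class TestEffectModel:
    def test_single_condition_rejected(self):
        t = _condition_table(conditions=("only",))
        with pytest.raises(ValueError, match="2 conditions"):
            fit_effect_model(t)

    def test_unbalanced_design_rejected_with_guidance(self):
        t = _condition_table()
        df = t.df.iloc[:-1]
        with pytest.raises(ValueError, match="balanced|aggregate"):
            fit_effect_model(ScoreTable(df))

    def test_large_shift_detected(self):
        t = _condition_table(shift={"a": 0.0, "b": 1.0}, sigma=0.1, seed=1)
        fit = fit_effect_model(t)
        assert fit.p_value < 1e-6
        effects = dict(zip(fit.condition_labels, fit.condition_effects))
        assert effects["b"] - effects["a"] == pytest.approx(1.0, abs=0.15)

    def test_sample_variance_recovered_from_block_mean_square(self):
        t = _condition_table(n_samples=60, sigma=0.05, seed=2)
        fit = fit_effect_model(t)
        assert fit.sigma2_sample == pytest.approx(1.0, rel=0.4)

    def test_zero_residual_gives_undefined_p(self):
        rows = [
            {"sample_id": s, "true_class": "positive", "condition": c,
             "run_id": "run1", "lab_id": "lab1", "replicate_id": "r0",
             "score": float(i)}
            for i, s in enumerate(["s0", "s1", "s2"]) for c in ("a", "b")
        ]
        fit = fit_effect_model(ScoreTable(pd.DataFrame(rows)))
        assert fit.p_value is None


class TestVarianceComponents:
    def test_zero_noise_table_gives_zero_components(self):
        truth = GeneratorTruth(n_samples_per_class=3, sigma_sample=0.0,
                               sigma_run=0.0, sigma_interaction=0.0,
                               sigma_residual=0.0, seed=0)
        vc = estimate_variance_components(gen_score_table(truth, 2, 2))
        assert vc.sigma2_run == 0.0
        assert vc.sigma2_interaction == 0.0
        assert vc.sigma2_residual == 0.0
        assert vc.intra_run_sd == 0.0 and vc.inter_run_sd == 0.0

    def test_intra_run_sd_equals_pooled_replicate_sd(self, balanced_table):
        """Algebraic identity: sqrt(residual MS) is the pooled SD over
        sample-by-run cells."""
        vc = estimate_variance_components(balanced_table)
        assert vc.intra_run_sd == pytest.approx(intra_run_sd(balanced_table), rel=1e-12)

    def test_inter_run_at_least_intra_run(self, balanced_table):
        vc = estimate_variance_components(balanced_table)
        assert vc.inter_run_sd >= vc.intra_run_sd

    def test_invariant_to_constant_score_shift(self, balanced_table):
        vc = estimate_variance_components(balanced_table)
        shifted = ScoreTable(balanced_table.df.assign(score=balanced_table.df["score"] + 100))
        vc2 = estimate_variance_components(shifted)
        assert vc2.intra_run_sd == pytest.approx(vc.intra_run_sd)
        assert vc2.inter_run_sd == pytest.approx(vc.inter_run_sd)

    def test_single_replicate_leaves_residual_absent(self):
        truth = GeneratorTruth(n_samples_per_class=3, seed=1)
        vc = estimate_variance_components(gen_score_table(truth, n_runs=3, n_reps=1))
        assert vc.sigma2_residual is None
        assert vc.intra_run_sd is None and vc.inter_run_sd is None

    def test_single_run_leaves_run_component_absent(self):
        truth = GeneratorTruth(n_samples_per_class=3, seed=1)
        vc = estimate_variance_components(gen_score_table(truth, n_runs=1, n_reps=3))
        assert vc.sigma2_run is None
        assert vc.sigma2_residual is not None

    def test_unbalanced_rejected(self, balanced_table):
        with pytest.raises(ValueError, match="balanced|unbalanced"):
            estimate_variance_components(ScoreTable(balanced_table.df.iloc[:-1]))


class TestPooledSd:
    def test_constant_groups_pool_to_zero(self):
        assert pooled_sd([np.array([1.0, 1.0]), np.array([2.0, 2.0])]) == 0.0

    def test_two_point_group(self):
        assert pooled_sd([np.array([0.0, 2.0])]) == pytest.approx(np.sqrt(2))

    def test_all_singletons_undefined(self):
        assert pooled_sd([np.array([1.0]), np.array([2.0])]) is None


class TestInterclassSd:
    def test_two_point_masses(self):
        rows = [
            {"sample_id": f"s{i}", "true_class": cls, "condition": "c",
             "run_id": "run1", "lab_id": "lab1", "replicate_id": "r0",
             "score": mu}
            for i, (cls, mu) in enumerate([("positive", 1.0), ("positive", 1.0),
                                           ("negative", -1.0), ("negative", -1.0)])
        ]
        t = ScoreTable(pd.DataFrame(rows))
        assert interclass_sd(t) == pytest.approx(np.std([1, 1, -1, -1], ddof=1))


class TestBootstrap:
    def test_same_seed_identical_ci(self, balanced_table):
        a = bootstrap_sd_ci(balanced_table, "intra_run_sd", B=300, seed=5)
        b = bootstrap_sd_ci(balanced_table, "intra_run_sd", B=300, seed=5)
        assert a["ci"] == b["ci"]

    def test_zero_noise_table_gives_degenerate_ci(self):
        truth = GeneratorTruth(n_samples_per_class=3, sigma_sample=0.0,
                               sigma_run=0.0, sigma_interaction=0.0,
                               sigma_residual=0.0, seed=0)
        t = gen_score_table(truth, 2, 2)
        assert bootstrap_sd_ci(t, "intra_run_sd", B=250, seed=1)["ci"] == (0.0, 0.0)

    def test_named_fast_path_matches_callable_path(self, balanced_table):
        fast = bootstrap_sd_ci(balanced_table, "intra_run_sd", B=200, seed=9)
        slow = bootstrap_sd_ci(balanced_table, intra_run_sd, B=200, seed=9)
        assert fast["ci"] == pytest.approx(slow["ci"], rel=1e-12)

    def test_minimum_resamples_enforced(self, balanced_table):
        with pytest.raises(ValueError, match="B"):
            bootstrap_sd_ci(balanced_table, "intra_run_sd", B=50, seed=0)


class TestInterlab:
    @staticmethod
    def _paired_table(noise_sd=0.0, n=10, seed=0):
        truth = GeneratorTruth(n_samples_per_class=n // 2, sigma_sample=1.0,
                               class_mean_separation=4.0, sigma_run=0.0,
                               sigma_interaction=0.0, sigma_residual=noise_sd,
                               seed=seed)
        return gen_score_table(truth, n_runs=1, n_reps=1, n_labs=2)

    def test_identical_labs(self):
        t = self._paired_table(noise_sd=0.0)
        out = interlab_analysis(t, bootstrap_B=None)
        assert out["concordance"] == 1.0
        assert out["r2"] == pytest.approx(1.0)
        assert out["pooled_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_three_labs_rejected(self):
        truth = GeneratorTruth(n_samples_per_class=3, seed=0)
        t = gen_score_table(truth, n_runs=1, n_reps=1, n_labs=3)
        with pytest.raises(ValueError, match="2 labs"):
            interlab_analysis(t)

    def test_pair_sd_convention_root_two_relation(self):
        """When only lab B carries independent noise of SD s, the per-pair
        pooled SD estimates s/sqrt(2) (pair SD = |a-b|/sqrt(2))."""
        rng = np.random.default_rng(42)
        mu = rng.normal(0, 2, 300)
        rows = []
        for i, m in enumerate(mu):
            for lab, score in (("lab1", m), ("lab2", m + rng.normal(0, 0.13))):
                rows.append({"sample_id": f"s{i:03d}", "true_class": "positive",
                             "condition": "c", "run_id": "run1", "lab_id": lab,
                             "replicate_id": "r0", "score": score})
        out = interlab_analysis(ScoreTable(pd.DataFrame(rows)), bootstrap_B=None)
        assert out["pooled_sd"] == pytest.approx(0.13 / np.sqrt(2), rel=0.15)

    def test_reports_lab_effect_p_value(self):
        t = self._paired_table(noise_sd=0.1, n=20, seed=3)
        out = interlab_analysis(t, bootstrap_B=None)
        assert 0.0 <= out["lab_effect_p"] <= 1.0
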