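"""Count mixing, in-silico titration, and limit-of-detection rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assayval import in_silico_titration, in_vitro_lod, mix_counts
from assayval.classifier import ClassifierModel


class TestMixCounts:
    def test_hand_arithmetic_equal_totals(self):
        c1 = np.array([10.0, 0.0, 4.0])
        c2 = np.array([2.0, 8.0, 4.0])
        assert np.allclose(mix_counts(c1, c2, 0.25), [4.0, 6.0, 4.0])

    def test_endpoints_exact(self):
        rng = np.random.default_rng(0)
        c1 = rng.uniform(0, 100, 50)
        c2 = rng.uniform(0, 100, 50)
        c2 *= c1.sum() / c2.sum()  # equal totals: endpoints return parents exactly
        assert np.allclose(mix_counts(c1, c2, 1.0), c1)
        assert np.allclose(mix_counts(c1, c2, 0.0), c2)

    @given(p=st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_total_mass_is_linear_in_p(self, p):
        rng = np.random.default_rng(1)
        c1 = rng.uniform(0, 50, 30)
        c2 = rng.uniform(0, 50, 30)
        mixed = mix_counts(c1, c2, p)
        common = (c1.sum() + c2.sum()) / 2
        assert mixed.sum() == pytest.approx(common, rel=1e-9)
        assert np.all(mixed >= 0)

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="gene sets"):
            mix_counts(np.ones(3), np.ones(4), 0.5)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            mix_counts(np.ones(3), np.ones(3), 1.2)


def _linear_model(n_genes, threshold, rng):
    w = rng.normal(0, 1, n_genes)
    span = 10 * (abs(threshold) + 1)
    return ClassifierModel(genes=[f"g{i}" for i in range(n_genes)], weights=w,
                           intercept=0.0, threshold=threshold, score_range=2 * span)


class TestInSilicoTitration:
    def test_default_grid_has_101_points(self):
        rng = np.random.default_rng(2)
        model = _linear_model(20, 0.0, rng)
        series = in_silico_titration(
            rng.uniform(1, 100, 20), rng.uniform(1, 100, 20), model,
            transform="identity", check_valid_pair=False,
        )
        assert len(series.fractions) == 101
        assert series.fractions[0] == 0.0 and series.fractions[-1] == 1.0

    def test_everything_positive_model_gives_smallest_nonzero_lod(self):
        rng = np.random.default_rng(3)
        model = _linear_model(10, 0.0, rng)
        c = rng.uniform(1, 50, 10)
        # force all scores above threshold via a large negative threshold
        model = ClassifierModel(genes=model.genes, weights=np.abs(model.weights),
                                intercept=0.0, threshold=-1e9, score_range=1e10)
        series = in_silico_titration(c, c * 0.9, model, transform="identity",
                                     check_valid_pair=False)
        assert series.lod == pytest.approx(0.01)

    def test_negative_control_failure_flags_pair_invalid(self):
        rng = np.random.default_rng(4)
        model = ClassifierModel(genes=[f"g{i}" for i in range(10)],
                                weights=np.abs(rng.normal(0, 1, 10)),
                                intercept=0.0, threshold=-1e9, score_range=1e10)
        series = in_silico_titration(rng.uniform(1, 50, 10), rng.uniform(1, 50, 10),
                                     model, transform="identity")
        assert not series.valid_pair and series.lod is None

    def test_closed_form_crossing_on_identity_route(self):
        """Linear score, threshold 0, s(pos)=2, s(neg)=-2: the crossing is at
        p*=0.5, so the first strictly positive grid point is 0.51."""
        model = ClassifierModel(genes=["g0", "g1"], weights=np.array([1.0, -1.0]),
                                intercept=0.0, threshold=0.0, score_range=20.0)
        pos = np.array([6.0, 4.0])  # score +2, total 10
        neg = np.array([4.0, 6.0])  # score -2, total 10
        series = in_silico_titration(pos, neg, model, transform="identity")
        assert series.valid_pair
        assert series.lod == pytest.approx(0.51)

    def test_grid_step_must_divide_one(self):
        model = _linear_model(5, 0.0, np.random.default_rng(5))
        with pytest.raises(ValueError, match="grid_step"):
            in_silico_titration(np.ones(5), 2 * np.ones(5), model, grid_step=0.03)

    def test_log_route_normalizes_over_series_plus_parents(self, count_matrix, model):
        pos = count_matrix.column("s000")
        neg = count_matrix.column("s015")
        series = in_silico_titration(pos, neg, model, genes=count_matrix.genes,
                                     grid_step=0.05)
        assert series.metadata["normalization_scope"] == "series_plus_parents"
        assert len(series.fractions) == 21
        assert series.valid_pair
        assert series.lod is not None and 0 < series.lod <= 1


class TestInVitroLod:
    @pytest.mark.parametrize("levels, calls, expected", [
        # correct positive calls at 0/40/60/80% dilution, control negative at 100%
        ([0, 40, 60, 80, 100], [1, 1, 1, 1, 0], 20.0),
        # correct only undiluted
        ([0, 40, 60, 80, 100], [1, 0, 0, 0, 0], 100.0),
        # contiguity: correct at 0/40 but not 60
        ([0, 40, 60, 80, 100], [1, 1, 0, 1, 0], 60.0),
    ])
    def test_lod_from_dilution_design(self, levels, calls, expected):
        out = in_vitro_lod(np.array(levels, float), np.array(calls, bool))
        assert out["lod_percent_positive"] == expected
        assert not out["negative_control_failure"]

    def test_positive_call_at_pure_negative_is_control_failure(self):
        out = in_vitro_lod(np.array([0.0, 50.0, 100.0]), np.array([True, True, True]))
        assert out["negative_control_failure"]
        assert out["lod_percent_positive"] == 50.0  # 100 - 50 tolerated

    def test_missing_zero_level_rejected(self):
        with pytest.raises(ValueError, match="0%"):
            in_vitro_lod(np.array([40.0, 80.0]), np.array([True, True]))


def test_fine_grid_lod_never_exceeds_coarse_grid_lod(count_matrix, model):
    """On the same pair with the same call rule, the in-silico fine grid
    finds an LOD no larger than a coarse in-vitro-style grid."""
    pos = count_matrix.column("s001")
    neg = count_matrix.column("s016")
    fine = in_silico_titration(pos, neg, model, genes=count_matrix.genes,
                               grid_step=0.01)
    coarse = in_silico_titration(pos, neg, model, genes=count_matrix.genes,
                                 grid_step=0.20)
    if fine.lod is not None and coarse.lod is not None:
        assert fine.lod <= coarse.lod
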