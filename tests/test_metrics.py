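"""Predictive entropy, the uncertainty confusion matrix and its metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uqeval import (LabeledPredictions, ValidationError, group_uncertainty_summary,
                    predictive_entropy, threshold_sweep, uncertainty_confusion,
                    uncertainty_metrics)
from uqeval.metrics import DEFAULT_THRESHOLD_GRID

from conftest import random_labeled_predictions


class TestPredictiveEntropy:
    @pytest.mark.parametrize("probs, base, expected", [
        ([0.5, 0.5], 2.0, 1.0),                                  # maximal binary
        ([1.0, 0.0], 2.0, 0.0),                                  # 0 log 0 = 0
        ([1.0, 0.0], math.e, 0.0),
        ([0.9, 0.1], 2.0, -0.9 * math.log2(0.9) - 0.1 * math.log2(0.1)),
        ([1 / 3] * 3, 3.0, 1.0),                                 # uniform hits log_base C
    ])
    def test_known_values(self, probs, base, expected):
        assert predictive_entropy(probs, base=base) == pytest.approx(expected, abs=1e-12)

    def test_batch_shape_and_uniform_bound(self):
        probs = np.array([[0.5, 0.5], [1.0, 0.0], [0.25, 0.75]])
        ent = predictive_entropy(probs)
        assert ent.shape == (3,)
        assert ent[0] == pytest.approx(1.0)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=5),
           st.floats(1.5, 10.0))
    @settings(max_examples=60, derandomize=True)
    def test_bounds_hold_for_any_distribution(self, raw, base):
        p = np.asarray(raw) / np.sum(raw)
        ent = predictive_entropy(p, base=base)
        assert 0.0 <= ent <= math.log(len(p), base) + 1e-9

    @pytest.mark.parametrize("bad", [[0.4, 0.4], [0.7, 0.5], [-0.1, 1.1]])
    def test_rejects_non_normalized(self, bad):
        with pytest.raises(ValidationError):
            predictive_entropy(bad)

    def test_rejects_bad_base(self):
        with pytest.raises(ValidationError):
            predictive_entropy([0.5, 0.5], base=1.0)


class TestUncertaintyConfusion:
    def test_enumerated_four_samples(self, four_sample_lp):
        uc = uncertainty_confusion(four_sample_lp, 0.3)
        assert (uc.tc, uc.tu, uc.fu, uc.fc) == (2, 1, 0, 1)
        assert uc.n == 4

    def test_all_correct_and_certain(self):
        lp = LabeledPredictions([0, 1, 0], [0, 1, 0], [0.0, 0.0, 0.0],
                                [1.0, 1.0, 1.0], 2)
        uc = uncertainty_confusion(lp, 0.3)
        assert (uc.tc, uc.tu, uc.fu, uc.fc) == (3, 0, 0, 0)

    def test_threshold_above_max_entropy_flags_nothing(self, four_sample_lp):
        uc = uncertainty_confusion(four_sample_lp, 1.0)  # binary PE <= 1
        assert uc.tu == 0 and uc.fu == 0

    def test_tie_counts_as_certain(self):
        lp = LabeledPredictions([0], [0], [0.3], [0.9], 2)
        uc = uncertainty_confusion(lp, 0.3)
        assert uc.tc == 1 and uc.fu == 0

    def test_matches_per_sample_loop_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            lp = random_labeled_predictions(rng)
            thr = rng.uniform(0, 1.6)
            uc = uncertainty_confusion(lp, thr)
            tc = tu = fu = fc = 0
            for i in range(len(lp)):
                correct = lp.predicted_class[i] == lp.true_label[i]
                uncertain = lp.uncertainty[i] > thr
                tc += correct and not uncertain
                tu += (not correct) and uncertain
                fu += correct and uncertain
                fc += (not correct) and not uncertain
            assert (uc.tc, uc.tu, uc.fu, uc.fc) == (tc, tu, fu, fc)
            assert uc.n == len(lp)


class TestUncertaintyMetrics:
    def test_enumerated_example_metrics(self, four_sample_lp):
        um = uncertainty_metrics(uncertainty_confusion(four_sample_lp, 0.3))
        assert um.usen == pytest.approx(0.5)
        assert um.uspe == pytest.approx(1.0)
        assert um.upre == pytest.approx(1.0)
        assert um.uacc == pytest.approx(0.75)

    def test_no_errors_yields_undefined_usen(self):
        lp = LabeledPredictions([0, 1], [0, 1], [0.0, 0.9], [1.0, 0.6], 2)
        um = uncertainty_metrics(uncertainty_confusion(lp, 0.3))
        assert math.isnan(um.usen)
        assert not math.isnan(um.uspe)

    def test_perfect_self_awareness(self):
        # every correct prediction certain, every error flagged
        lp = LabeledPredictions([0, 0, 1], [0, 1, 1], [0.1, 0.9, 0.2],
                                [0.9, 0.55, 0.85], 2)
        um = uncertainty_metrics(uncertainty_confusion(lp, 0.5))
        assert (um.usen, um.uspe, um.uacc) == (1.0, 1.0, 1.0)

    def test_matches_direct_arithmetic_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            lp = random_labeled_predictions(rng)
            uc = uncertainty_confusion(lp, rng.uniform(0, 1.6))
            um = uncertainty_metrics(uc)
            for got, num, den in [(um.usen, uc.tu, uc.tu + uc.fc),
                                  (um.uspe, uc.tc, uc.tc + uc.fu),
                                  (um.upre, uc.tu, uc.tu + uc.fu)]:
                if den == 0:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(num / den)
            assert um.uacc == pytest.approx((uc.tu + uc.tc) / uc.n)


class TestThresholdSweep:
    def test_single_point_grid_equals_direct_computation(self, four_sample_lp):
        sweep = threshold_sweep(four_sample_lp, [0.3])
        assert sweep.confusions[0] == uncertainty_confusion(four_sample_lp, 0.3)
        assert sweep.metrics[0] == uncertainty_metrics(sweep.confusions[0])

    def test_partition_and_accuracy_link_at_every_threshold(self):
        rng = np.random.default_rng(3)
        lp = random_labeled_predictions(rng, n=50)
        sweep = threshold_sweep(lp)
        acc = lp.accuracy
        for uc in sweep.confusions:
            assert uc.tc + uc.tu + uc.fu + uc.fc == len(lp)
            assert (uc.tc + uc.fu) / uc.n == pytest.approx(acc)

    def test_usen_nonincreasing_uspe_nondecreasing(self):
        # raising the threshold shrinks the flagged set (set inclusion)
        rng = np.random.default_rng(19)
        for _ in range(20):
            lp = random_labeled_predictions(rng, n=40)
            frame = threshold_sweep(lp).to_frame()
            usen = frame["usen"].dropna().to_numpy()
            uspe = frame["uspe"].dropna().to_numpy()
            assert np.all(np.diff(usen) <= 1e-12)
            assert np.all(np.diff(uspe) >= -1e-12)

    def test_constant_uncertainty_gives_step_structure(self):
        lp = LabeledPredictions([0, 1, 1, 0], [0, 1, 0, 0], [0.45] * 4,
                                [0.8] * 4, 2)
        frame = threshold_sweep(lp).to_frame()
        below = frame[frame.threshold < 0.45].drop(columns="threshold")
        above = frame[frame.threshold >= 0.45].drop(columns="threshold")
        assert (below.nunique() <= 1).all()
        assert (above.nunique() <= 1).all()

    def test_default_grid_and_column_order(self, four_sample_lp):
        frame = threshold_sweep(four_sample_lp).to_frame()
        assert list(frame.columns) == ["threshold", "tc", "tu", "fu", "fc",
                                       "usen", "uspe", "upre", "uacc"]
        assert np.allclose(frame["threshold"], np.arange(1, 10) * 0.1)
        assert 0.3 in DEFAULT_THRESHOLD_GRID

    def test_rejects_unsorted_or_empty_grid(self, four_sample_lp):
        with pytest.raises(ValidationError):
            threshold_sweep(four_sample_lp, [0.5, 0.3])
        with pytest.raises(ValidationError):
            threshold_sweep(four_sample_lp, [])


class TestGroupSummary:
    def test_known_group_means(self):
        lp = LabeledPredictions([0, 0, 1], [0, 0, 0], [0.1, 0.2, 0.5],
                                [0.9, 0.85, 0.6], 2)
        gs = group_uncertainty_summary(lp)
        assert gs.table.loc["correct", "uncertainty_mean"] == pytest.approx(0.15)
        assert gs.table.loc["incorrect", "uncertainty_mean"] == pytest.approx(0.5)
        assert gs.mean_uncertainty_difference == pytest.approx(0.35)
        assert gs.complete

    def test_equal_uncertainties_give_zero_difference(self):
        lp = LabeledPredictions([0, 1], [0, 0], [0.4, 0.4], [0.8, 0.8], 2)
        assert group_uncertainty_summary(lp).mean_uncertainty_difference == pytest.approx(0.0)

    def test_single_group_is_flagged_incomplete(self):
        lp = LabeledPredictions([0, 1], [0, 1], [0.1, 0.2], [0.9, 0.8], 2)
        gs = group_uncertainty_summary(lp)
        assert not gs.complete
        assert math.isnan(gs.mean_uncertainty_difference)
        assert list(gs.table.index) == ["correct"]


class TestLabeledPredictionsValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(true_label=[], predicted_class=[], uncertainty=[], confidence=[]),
        dict(true_label=[0, 2], predicted_class=[0, 1], uncertainty=[0, 0],
             confidence=[1, 1]),
        dict(true_label=[0, 1], predicted_class=[0, 1], uncertainty=[-0.1, 0],
             confidence=[1, 1]),
        dict(true_label=[0, 1], predicted_class=[0, 1], uncertainty=[0, 0],
             confidence=[1.2, 1]),
    ])
    def test_rejects_invalid_tables(self, kwargs):
        with pytest.raises(ValidationError):
            LabeledPredictions(n_classes=2, **kwargs)
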