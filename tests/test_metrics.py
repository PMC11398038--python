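"""Evaluation mathematics: standard metrics, curves, composites, CV."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import afibvote as av
from afibvote.metrics import (
    ConfusionMatrix,
    MetricSeries,
    composite_indices,
    kfold_cv,
    roc_pr_curves,
    round_half_away,
    screening_ppv,
    standard_metrics,
    weighted_composite_indices,
)


class TestStandardMetrics:
    def test_published_watch_row(self):
        ms = standard_metrics(ConfusionMatrix(tp=212, tn=2247, fp=10, fn=24))
        assert round_half_away(ms.sensitivity) == 0.898
        assert round_half_away(ms.specificity) == 0.996
        assert round_half_away(ms.ppv) == 0.955
        assert round_half_away(ms.npv) == 0.989
        assert round_half_away(ms.f1_avg) == 0.959

    def test_published_handheld_row(self):
        ms = standard_metrics(ConfusionMatrix(tp=762, tn=3629, fp=269, fn=16))
        assert round_half_away(ms.sensitivity) == 0.979
        assert round_half_away(ms.ppv) == 0.739

    def test_zero_denominators_flagged(self):
        ms = standard_metrics(ConfusionMatrix(tp=0, tn=50, fp=0, fn=0))
        assert ms.specificity == 1.0
        assert ms.sensitivity is None
        assert ms.ppv is None
        assert ms.f1_avg is None
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=0, tn=0, fp=0, fn=0)

    def test_counts_validated(self):
        with pytest.raises(ValueError, match="non-negative"):
            ConfusionMatrix(tp=-1, tn=1, fp=0, fn=0)

    @given(st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_matches_recount_from_raw_pairs(self, tp, tn, fp, fn):
        """standard_metrics agrees with a brute-force recount over the
        implied (truth, prediction) pairs."""
        if tp + tn + fp + fn == 0:
            return
        truth = np.array([True] * (tp + fn) + [False] * (tn + fp))
        pred = np.array([True] * tp + [False] * fn
                        + [False] * tn + [True] * fp)
        cm = ConfusionMatrix.from_predictions(truth, pred)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)
        ms = standard_metrics(cm)
        if ms.sensitivity is not None:
            assert ms.sensitivity == pytest.approx(pred[truth].mean())
        if ms.specificity is not None:
            assert ms.specificity == pytest.approx((~pred[~truth]).mean())
        if ms.ppv is not None:
            assert ms.ppv == pytest.approx(truth[pred].mean())


class TestCurves:
    def test_perfect_and_reversed(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        assert roc_pr_curves(s, y)[2] == 1.0
        assert roc_pr_curves(-s, y)[2] == 0.0

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(0)
        y = rng.random(500) < 0.4
        s = rng.random(500) + 0.3 * y
        auc = roc_pr_curves(s, y)[2]
        assert roc_pr_curves(-s, y)[2] == pytest.approx(1.0 - auc, abs=1e-12)

    def test_independent_scores_chance_auc(self):
        rng = np.random.default_rng(5)
        n = 10_000
        y = rng.random(n) < 0.3
        s = rng.random(n)
        auc = roc_pr_curves(s, y)[2]
        n1, n0 = int(y.sum()), int((~y).sum())
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))  # Mann-Whitney null SE
        assert abs(auc - 0.5) < 3 * se

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_pr_curves([0.2, 0.4], [1, 1])


class TestCompositeIndices:
    def test_published_sensitivity_efficacy(self):
        ci = composite_indices(MetricSeries((0.898, 0.900, 0.854)))
        assert round_half_away(ci.ep) == 0.884

    def test_identical_values(self):
        ci = composite_indices(MetricSeries((0.9, 0.9, 0.9)))
        assert ci.ep == pytest.approx(0.9)
        assert ci.vp == 0.0
        assert ci.cp == pytest.approx(0.1)

    def test_convex_mode_arithmetic(self):
        # E=0.943, V=0.014 -> convex alpha=0.5 gives 0.5*0.057+0.5*0.014
        vals = av.voting_metric_series("f1_avg")
        ci = composite_indices(vals, alpha=0.5, mode="convex")
        assert ci.cp == pytest.approx(0.0355, abs=5e-4)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_unit_weights_doubles_half_alpha_convex(self, vals):
        series = MetricSeries(tuple(vals))
        unit = composite_indices(series, mode="unit_weights")
        convex = composite_indices(series, alpha=0.5, mode="convex")
        assert unit.cp == pytest.approx(2 * convex.cp, abs=1e-12)
        assert unit.ep == convex.ep and unit.vp == convex.vp

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_order_invariance_and_two_pass_variance(self, vals, rnd):
        series = MetricSeries(tuple(vals))
        shuffled = list(vals)
        rnd.shuffle(shuffled)
        a = composite_indices(series)
        b = composite_indices(MetricSeries(tuple(shuffled)))
        assert a.ep == pytest.approx(b.ep, abs=1e-12)
        assert a.vp == pytest.approx(b.vp, abs=1e-12)
        # explicit two-pass sample standard deviation
        m = sum(vals) / len(vals)
        two_pass = (sum((v - m) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert a.vp == pytest.approx(two_pass, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            composite_indices(MetricSeries((0.9, 0.8)), alpha=1.5)
        with pytest.raises(ValueError, match="undefined"):
            MetricSeries((0.9, float("nan")))
        with pytest.raises(ValueError, match="mode"):
            composite_indices(MetricSeries((0.9, 0.8)), mode="geometric")
        with pytest.warns(UserWarning, match="single dataset"):
            ci = composite_indices(MetricSeries((0.9,)))
        assert ci.vp == 0.0

    def test_weighted_variant_reduces_to_unweighted(self):
        series = MetricSeries((0.9, 0.8, 0.85))
        w = weighted_composite_indices(series, [100, 100, 100])
        u = composite_indices(series)
        assert w.ep == pytest.approx(u.ep, abs=1e-12)
        assert w.vp == pytest.approx(u.vp, abs=1e-12)


class TestScreening:
    def test_million_recording_example(self):
        ppv = screening_ppv(1_000_000, 0.15, 1.0, 0.90)
        assert round(ppv) == 64

    def test_perfect_specificity(self):
        assert screening_ppv(1000, 0.15, 0.9, 1.0) == 100.0

    def test_zero_prevalence_rejected(self):
        with pytest.raises(ValueError, match="PPV undefined"):
            screening_ppv(1000, 0.0, 1.0, 1.0)


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (0.0715, 0.072), (0.8985, 0.899), (0.9595, 0.960), (0.1195, 0.120),
        (0.898305, 0.898),
    ])
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestKFoldCV:
    @pytest.fixture(scope="class")
    def perfect_task(self):
        rng = np.random.default_rng(3)
        y = rng.choice(["AFib", "non-AFib", "noise"], size=400,
                       p=[0.3, 0.5, 0.2])
        X = pd.DataFrame({
            "a": (y == "AFib").astype(float),
            "b": (y == "noise").astype(float),
        })
        return X, y

    def test_perfect_detectors_near_perfect_metrics(self, perfect_task):
        X, y = perfect_task
        df = kfold_cv(X, y, k=5, seed=0, n_trees=30)
        mean = df[df["fold"] == "mean"].iloc[0]
        assert mean["sensitivity"] > 0.99
        assert mean["specificity"] > 0.99

    def test_leave_one_out_runs(self):
        y = np.array(["AFib", "non-AFib"] * 6)
        X = pd.DataFrame({"a": (y == "AFib").astype(float),
                          "b": np.arange(12.0)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = kfold_cv(X, y, k=12, seed=0, n_trees=20)
        assert len(df) == 12 + 2

    def test_fold_assignment_deterministic(self, perfect_task):
        X, y = perfect_task
        a = kfold_cv(X, y, k=4, seed=9, n_trees=20)
        b = kfold_cv(X, y, k=4, seed=9, n_trees=20)
        pd.testing.assert_frame_equal(a, b)

    def test_too_rare_class(self):
        y = np.array(["AFib"] * 2 + ["non-AFib"] * 30)
        X = pd.DataFrame({"a": np.arange(32.0), "b": np.arange(32.0)})
        with pytest.raises(ValueError, match="stratify"):
            kfold_cv(X, y, k=8, seed=0, n_trees=10)
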