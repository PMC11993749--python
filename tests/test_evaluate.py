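"""Metric suite: tolerance matching, confusion counts, error metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stoichbench.evaluate import (
    ConfusionCounts,
    PairedVectors,
    ToleranceRule,
    acceptance_interval,
    accuracy,
    confusion_counts,
    evaluate,
    f1,
    mae,
    match_predictions,
    max_deviation,
    median_ae,
    min_deviation,
    rmse,
)

from .conftest import make_site
from .oracles import brute_force_matching


class TestAcceptanceInterval:
    @pytest.mark.parametrize(
        "y,factor,expected",
        [
            (0.2, 0.6, (0.08, 0.32)),
            (1.0, 0.6, (0.4, 1.0)),  # upper clip
            (0.5, 0.0, (0.5, 0.5)),  # zero tolerance
        ],
    )
    def test_interval_bounds(self, y, factor, expected):
        lo, hi = acceptance_interval(y, ToleranceRule(freq_tol_factor=factor))
        assert (lo, hi) == pytest.approx(expected)

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            acceptance_interval(0.0)


class TestMatching:
    def test_one_base_window_matches(self, site_factory):
        truth = [site_factory(10, 0.2)]
        pred = [site_factory(11, 0.2)]
        assert len(match_predictions(truth, pred)) == 1

    def test_frequency_outside_interval_rejected(self, site_factory):
        truth = [site_factory(10, 0.2)]
        pred = [site_factory(10, 0.5)]  # 0.5 not in [0.08, 0.32]
        assert match_predictions(truth, pred) == []

    def test_single_prediction_cannot_satisfy_two_truths(self, site_factory):
        truth = [site_factory(10, 0.2), site_factory(11, 0.2)]
        pred = [site_factory(10, 0.2)]
        assert len(match_predictions(truth, pred)) == 1

    def test_unsorted_input_rejected(self, site_factory):
        truth = [site_factory(11, 0.2), site_factory(10, 0.2)]
        with pytest.raises(ValueError, match="sorted"):
            match_predictions(truth, [])
        with pytest.raises(ValueError, match="sorted"):
            match_predictions([], truth)

    def test_prefers_smaller_total_offset(self, site_factory):
        # prediction at 10 can pair with truth 10 (offset 0) or truth 11 (offset 1);
        # second prediction at 12 only reaches truth 11.
        truth = [site_factory(10, 0.2), site_factory(11, 0.2)]
        pred = [site_factory(10, 0.2), site_factory(12, 0.2)]
        matching = match_predictions(truth, pred)
        assert sorted(matching) == [(0, 0), (1, 1)]

    @settings(max_examples=150, deadline=None)
    @given(
        truth_sites=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=15),
                st.floats(min_value=0.01, max_value=1.0, allow_nan=False),
            ),
            max_size=5,
        ),
        pred_sites=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=15),
                st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            ),
            max_size=5,
        ),
        window=st.integers(min_value=0, max_value=2),
    )
    def test_matches_brute_force_oracle(self, truth_sites, pred_sites, window):
        truth_sites = sorted(set(truth_sites))
        pred_sites = sorted(set(pred_sites))
        rule = ToleranceRule(pos_window=window)
        truth = [make_site(p, f) for p, f in truth_sites]
        pred = [make_site(p, f) for p, f in pred_sites]
        matching = match_predictions(truth, pred, rule)
        count, offset = brute_force_matching(truth_sites, pred_sites, pos_window=window)
        assert len(matching) == count
        got_offset = sum(abs(truth[i].start - pred[j].start) for i, j in matching)
        assert got_offset == offset

    def test_widening_tolerance_never_loses_matches(self, site_factory):
        rng = np.random.default_rng(0)
        truth = sorted(
            (site_factory(int(p), float(f)) for p, f in zip(
                rng.choice(50, size=8, replace=False), rng.uniform(0.1, 0.9, 8)
            )),
            key=lambda r: r.start,
        )
        pred = sorted(
            (site_factory(int(p), float(f)) for p, f in zip(
                rng.choice(50, size=8, replace=False), rng.uniform(0.1, 0.9, 8)
            )),
            key=lambda r: r.start,
        )
        last = -1
        for factor, window in [(0.2, 0), (0.4, 1), (0.6, 1), (0.8, 2), (1.0, 3)]:
            n = len(match_predictions(truth, pred, ToleranceRule(factor, window)))
            assert n >= last
            last = n


class TestConfusion:
    def test_perfect_predictions(self, site_factory):
        truth = [site_factory(p, 0.4) for p in (5, 9, 20)]
        matching = match_predictions(truth, truth)
        counts = confusion_counts(matching, truth, truth, n_positions=100)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (3, 0, 0, 97)

    def test_empty_prediction_set(self, site_factory):
        truth = [site_factory(p, 0.4) for p in (5, 9)]
        counts = confusion_counts([], truth, [], n_positions=50)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (0, 2, 0, 48)

    def test_mixed_fixture(self, site_factory):
        # 2 matched, 1 stray prediction, 1 missed truth, N = 100
        truth = [site_factory(5, 0.4), site_factory(9, 0.4), site_factory(20, 0.4)]
        pred = [site_factory(5, 0.4), site_factory(9, 0.4), site_factory(60, 0.3)]
        matching = match_predictions(truth, pred)
        counts = confusion_counts(matching, truth, pred, n_positions=100)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (2, 1, 1, 96)
        assert counts.n == 100

    def test_zero_frequency_prediction_is_not_false_positive(self, site_factory):
        truth = [site_factory(5, 0.4)]
        pred = [site_factory(5, 0.4), site_factory(60, 0.0)]
        matching = match_predictions(truth, pred)
        counts = confusion_counts(matching, truth, pred, n_positions=100)
        assert counts.fp == 0

    def test_n_smaller_than_truth_rejected(self, site_factory):
        truth = [site_factory(p, 0.4) for p in (5, 9)]
        with pytest.raises(ValueError):
            confusion_counts([], truth, [], n_positions=1)


class TestErrorMetrics:
    @pytest.fixture
    def pair(self):
        return PairedVectors(y=[0.1, 0.2, 0.3], yhat=[0.2, 0.2, 0.2])

    def test_frozen_three_point_example(self, pair):
        assert rmse(pair) == pytest.approx(0.08164965809277261, abs=1e-12)
        assert mae(pair) == pytest.approx(0.2 / 3, abs=1e-12)
        assert median_ae(pair) == pytest.approx(0.1, abs=1e-12)

    def test_identity_gives_zero(self):
        pair = PairedVectors(y=[0.1, 0.5], yhat=[0.1, 0.5])
        assert rmse(pair) == mae(pair) == median_ae(pair) == 0.0

    def test_single_position_closed_form(self):
        pair = PairedVectors(y=[0.7], yhat=[0.4])
        assert rmse(pair) == pytest.approx(0.3)
        assert mae(pair) == pytest.approx(0.3)

    def test_deviation_range_restricted_to_modified(self):
        pair = PairedVectors(y=[0.0, 0.5, 0.4], yhat=[0.9, 0.45, 0.2])
        # |0.9 - 0| excluded: position 0 is unmodified
        assert max_deviation(pair) == pytest.approx(0.2)
        assert min_deviation(pair) == pytest.approx(0.05)

    def test_single_modified_position_max_equals_min(self):
        pair = PairedVectors(y=[0.0, 0.5], yhat=[0.0, 0.3])
        assert max_deviation(pair) == min_deviation(pair)

    def test_no_modified_positions_rejected(self):
        pair = PairedVectors(y=[0.0], yhat=[0.1])
        with pytest.raises(ValueError):
            max_deviation(pair)

    def test_rmse_dominates_mae(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pair = PairedVectors(y=rng.uniform(0, 1, 30), yhat=rng.uniform(0, 1, 30))
            assert rmse(pair) >= mae(pair) >= 0


class TestClassificationMetrics:
    def test_accuracy_fixture(self):
        counts = ConfusionCounts(tp=200, tn=2100, fp=38, fn=100)
        assert accuracy(counts, 2438) == pytest.approx(2300 / 2438)

    def test_f1_fixture(self):
        assert f1(ConfusionCounts(tp=2, tn=0, fp=1, fn=1)) == pytest.approx(4 / 6)

    def test_f1_degenerate_cases(self):
        assert f1(ConfusionCounts(tp=0, tn=10, fp=0, fn=0)) == 1.0
        assert f1(ConfusionCounts(tp=0, tn=10, fp=3, fn=0)) == 0.0
        assert f1(ConfusionCounts(tp=5, tn=10, fp=0, fn=0)) == 1.0

    def test_accuracy_requires_consistent_n(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(tp=1, tn=1, fp=0, fn=0), 10)


class TestEvaluate:
    def test_truth_against_itself_is_perfect(self, site_factory):
        truth = [site_factory(p, 0.1 + 0.02 * i) for i, p in enumerate(range(5, 100, 7))]
        report = evaluate(truth, truth, reference_length=120)
        assert report.rmse == report.mae == report.median_ae == 0.0
        assert report.accuracy == 1.0 and report.f1 == 1.0
        assert report.confusion.tp == len(truth)

    def test_row_order_invariance(self, site_factory):
        truth = [site_factory(p, 0.3) for p in (4, 9, 17)]
        pred = [site_factory(p, 0.31) for p in (17, 4, 10)]
        r1 = evaluate(truth, pred, 30)
        r2 = evaluate(list(reversed(truth)), list(reversed(pred)), 30)
        assert r1.to_dict() == r2.to_dict()

    def test_chromosome_mismatch_rejected(self, site_factory):
        truth = [site_factory(4, 0.3)]
        pred = [site_factory(4, 0.3, chrom="other")]
        with pytest.raises(ValueError, match="multiple references"):
            evaluate(truth, pred, 30)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="empty truth"):
            evaluate([], [], 30)

    def test_report_json_schema(self, site_factory):
        truth = [site_factory(4, 0.3)]
        report = evaluate(truth, truth, 30)
        d = report.to_dict()
        assert set(d["metrics"]) == {
            "rmse", "mae", "median_ae", "max_deviation", "min_deviation", "accuracy", "f1",
        }
        assert d["confusion"]["tp"] + d["confusion"]["tn"] + d["confusion"]["fp"] + d[
            "confusion"
        ]["fn"] == d["n_positions"]
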