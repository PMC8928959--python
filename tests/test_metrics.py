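import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deeplse.metrics import (ConfusionCounts, aggregate_reports, bacc_from_rates,
                             compute_confusion, compute_metrics, mse_db,
                             youden_from_rates)


def transcription_oracle(tp, fp, tn, fn):
    """Second, independent transcription of the metric formulas."""
    n = tp + fp + tn + fn
    res = {}
    res["sensitivity"] = tp / (tp + fn) if tp + fn else math.nan
    res["specificity"] = tn / (tn + fp) if tn + fp else math.nan
    res["precision"] = tp / (tp + fp) if tp + fp else math.nan
    res["accuracy"] = (tp + tn) / n
    den = math.sqrt((tp + fp) * (tn + fn) * (tp + fn) * (tn + fp))
    res["mcc"] = (tp * tn - fp * fn) / den if den else math.nan
    res["balanced_accuracy"] = (res["sensitivity"] + res["specificity"]) / 2
    res["youdens_index"] = res["sensitivity"] + res["specificity"] - 1
    p, r = res["precision"], res["sensitivity"]
    res["f1"] = (2 * p * r / (p + r)) if (not math.isnan(p) and not math.isnan(r) and p + r) else math.nan
    res["po"] = (tp + tn) / n
    res["pe"] = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
    res["kappa"] = (res["po"] - res["pe"]) / (1 - res["pe"]) if res["pe"] != 1 else math.nan
    return res


class TestConfusion:
    def test_mixed_example(self):
        c = compute_confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_predictions(self):
        c = compute_confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    def test_counts_partition_samples(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 2, size=500)
        p = rng.integers(0, 2, size=500)
        c = compute_confusion(t, p)
        # loop oracle
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for ti, pi in zip(t, p):
            key = ("t" if ti == pi else "f") + ("p" if pi == 1 else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tally["tp"], tally["fp"], tally["tn"], tally["fn"])
        assert c.tp + c.fn == int((t == 1).sum())
        assert c.tn + c.fp == int((t == 0).sum())

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="equal length"):
            compute_confusion([1, 0], [1])

    def test_nonbinary_labels_error(self):
        with pytest.raises(ValueError, match="binary"):
            compute_confusion([1, 2], [1, 0])


class TestMetricsExamples:
    def test_chance_classifier(self):
        rep = compute_metrics(ConfusionCounts(tp=50, fp=50, tn=50, fn=50))
        assert rep.sensitivity == rep.specificity == rep.accuracy == 0.5
        assert rep.balanced_accuracy == 0.5
        assert rep.mcc == 0.0
        assert rep.youdens_index == 0.0
        assert rep.kappa == 0.0

    def test_perfect_and_inverted_classifiers(self):
        perfect = compute_metrics(ConfusionCounts(tp=30, fp=0, tn=70, fn=0))
        assert perfect.mcc == 1.0 and perfect.kappa == 1.0 and perfect.youdens_index == 1.0
        inverted = compute_metrics(ConfusionCounts(tp=0, fp=70, tn=0, fn=30))
        assert inverted.mcc == -1.0

    def test_rates_identities(self):
        assert bacc_from_rates(0.674, 0.849) == pytest.approx(0.7615)
        assert youden_from_rates(0.674, 0.849) == pytest.approx(0.523)

    def test_undefined_precision_flagged_not_zeroed(self):
        rep = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=90, fn=10))
        assert math.isnan(rep.precision)
        assert math.isnan(rep.mcc)  # zero predicted-positive marginal
        assert rep.specificity == 1.0


tables = st.tuples(
    st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
).filter(lambda t: sum(t) >= 1)


@settings(max_examples=300, deadline=None)
@given(table=tables)
def test_metrics_match_independent_transcription(table):
    tp, fp, tn, fn = table
    rep = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)).as_dict()
    ref = transcription_oracle(tp, fp, tn, fn)
    for key, expected in ref.items():
        if math.isnan(expected):
            assert math.isnan(rep[key]), key
        else:
            assert rep[key] == pytest.approx(expected, abs=1e-12), key


@settings(max_examples=100, deadline=None)
@given(table=tables)
def test_metrics_match_sklearn_on_nondegenerate_tables(table):
    from sklearn.metrics import (balanced_accuracy_score, cohen_kappa_score,
                                 f1_score, matthews_corrcoef)

    tp, fp, tn, fn = table
    if min(tp + fn, tn + fp, tp + fp, tn + fn) == 0:
        return  # degenerate marginals: our policy is NaN, sklearn coerces to 0
    y_true = np.array([1] * (tp + fn) + [0] * (tn + fp))
    y_pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
    rep = compute_metrics(compute_confusion(y_true, y_pred))
    assert rep.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-10)
    assert rep.kappa == pytest.approx(cohen_kappa_score(y_true, y_pred), abs=1e-10)
    assert rep.balanced_accuracy == pytest.approx(balanced_accuracy_score(y_true, y_pred), abs=1e-10)
    if tp > 0:  # with tp=0, F1 is 0/0: undefined under our policy, coerced by sklearn
        assert rep.f1 == pytest.approx(f1_score(y_true, y_pred), abs=1e-10)


@settings(max_examples=100, deadline=None)
@given(table=tables)
def test_mcc_symmetric_under_class_swap(table):
    tp, fp, tn, fn = table
    a = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)).mcc
    b = compute_metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp)).mcc
    assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b, abs=1e-12)


@settings(max_examples=100, deadline=None)
@given(table=tables)
def test_f1_is_harmonic_mean_of_precision_recall(table):
    tp, fp, tn, fn = table
    rep = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
    if math.isnan(rep.precision) or math.isnan(rep.sensitivity) or rep.precision + rep.sensitivity == 0:
        return
    hm = 2 / (1 / rep.precision + 1 / rep.sensitivity) if rep.precision and rep.sensitivity else 0.0
    assert rep.f1 == pytest.approx(hm, abs=1e-12)


class TestMseDb:
    def test_forced_value(self):
        a = np.zeros((2, 2))
        b = np.full((2, 2), 1e-2)  # MSE = 1e-4
        assert mse_db(a, b) == pytest.approx(40.0)

    def test_identical_matrices_flag_infinite(self):
        a = np.ones((3, 3))
        assert mse_db(a, a) == math.inf

    def test_agrees_with_elementwise_loop(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((5, 7)), rng.random((5, 7))
        total = 0.0
        for i in range(5):
            for j in range(7):
                total += (a[i, j] - b[i, j]) ** 2
        expected = -10 * math.log10(total / 35)
        assert mse_db(a, b) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            mse_db(np.zeros((2, 2)), np.zeros((2, 3)))


class TestAggregation:
    def test_undefined_values_skipped_and_counted(self):
        reports = [{"m": 0.5}, {"m": float("nan")}, {"m": 0.7}]
        agg = aggregate_reports(reports)
        assert agg["m"]["mean"] == pytest.approx(0.6)
        assert agg["m"]["n"] == 2
        assert agg["m"]["n_undefined"] == 1
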