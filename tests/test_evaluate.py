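import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contourtl.errors import AmbiguousSolution, NoSolution, ValidationError
from contourtl.evaluate import (
    ConfusionMatrix,
    confusion,
    metrics,
    roc_auc,
    round2,
    solve_confusion,
)


def pair_count_auc(y_true, scores):
    """Independent oracle: P(pos score > neg score) with ties counted half."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self):
        cm = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 0, 2, 0)

    def test_all_positive_predictions(self):
        cm = confusion([1, 0], [1, 1])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 1, 0, 0)

    def test_counts_sum_to_length(self, rng):
        y = rng.integers(0, 2, 40)
        p = rng.integers(0, 2, 40)
        assert confusion(y, p).total == 40

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            confusion([0, 2], [0, 1])
        with pytest.raises(ValidationError):
            confusion([0, 1], [0])


class TestMetrics:
    def test_reported_unseen_case_row(self):
        """TP=1240, FP=11, TN=773, FN=0 reproduces the published unseen-data
        row: 100 / 98.60 / 99.12 / 100 / 99.46 / 99.56."""
        rep = metrics(ConfusionMatrix(tp=1240, fp=11, tn=773, fn=0)).rounded()
        assert rep.sensitivity == 100.00
        assert rep.specificity == 98.60
        assert rep.precision == 99.12
        assert rep.npv == 100.00
        assert rep.accuracy == 99.46
        assert rep.f1 == 99.56

    def test_all_correct_gives_all_hundred(self):
        rep = metrics(ConfusionMatrix(tp=5, fp=0, tn=5, fn=0)).rounded()
        assert all(
            v == 100.00
            for k, v in rep.as_dict().items()
            if k != "roc_auc"
        )

    def test_uniform_matrix_gives_fifty(self):
        rep = metrics(ConfusionMatrix(1, 1, 1, 1)).rounded()
        for name in ("sensitivity", "specificity", "precision", "npv", "accuracy", "f1"):
            assert rep.as_dict()[name] == 50.00

    def test_zero_denominator_reported_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            rep = metrics(ConfusionMatrix(tp=0, fp=1, tn=3, fn=0))
        assert rep.sensitivity is None
        assert rep.f1 is None
        assert rep.specificity is not None

    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        tn=st.integers(0, 500), fn=st.integers(0, 500),
    )
    @settings(max_examples=100, deadline=None)
    def test_f1_identity_and_accuracy_convexity(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        cm = ConfusionMatrix(tp, fp, tn, fn)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = metrics(cm)
        if rep.f1 is not None:
            assert rep.f1 == pytest.approx(100.0 * 2 * tp / (2 * tp + fp + fn))
        # accuracy = prevalence-weighted mix of sensitivity and specificity
        if rep.sensitivity is not None and rep.specificity is not None:
            n_pos, n_neg = tp + fn, tn + fp
            mix = (rep.sensitivity * n_pos + rep.specificity * n_neg) / (n_pos + n_neg)
            assert rep.accuracy == pytest.approx(mix)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_identical_scores_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_example_against_pair_counting(self):
        y = [1, 1, 0, 0]
        s = [0.9, 0.4, 0.6, 0.3]
        assert roc_auc(y, s) == pytest.approx(pair_count_auc(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 1], [0.5, 0.6])

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_pair_counting_oracle(self, data):
        n = data.draw(st.integers(4, 200))
        y = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda v: 0 < sum(v) < len(v)
            )
        )
        s = data.draw(
            st.lists(
                st.floats(0, 1, allow_nan=False, width=32), min_size=n, max_size=n
            )
        )
        assert roc_auc(y, s) == pytest.approx(pair_count_auc(y, s), abs=1e-9)


class TestSolveConfusion:
    def test_reconstructs_published_unseen_matrix(self):
        """Class totals 1240/784 (155 and 98 sources through the 8-op plan)
        plus the printed sensitivity and specificity pin down one matrix."""
        cm = solve_confusion(1240, 784, {"sensitivity": 100.0, "specificity": 98.60})
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1240, 11, 773, 0)

    def test_perfect_metrics_give_diagonal(self):
        cm = solve_confusion(50, 30, {"sensitivity": 100.0, "specificity": 100.0})
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (50, 0, 30, 0)

    def test_contradictory_values_unsolvable(self):
        with pytest.raises(NoSolution):
            solve_confusion(10, 10, {"sensitivity": 100.0, "accuracy": 10.0})

    def test_underdetermined_input_ambiguous(self):
        with pytest.raises(AmbiguousSolution):
            solve_confusion(100, 100, {"sensitivity": 50.0})

    def test_round_trip_random_matrices(self, rng):
        for _ in range(5):
            n_pos, n_neg = int(rng.integers(20, 80)), int(rng.integers(20, 80))
            tp, tn = int(rng.integers(0, n_pos + 1)), int(rng.integers(0, n_neg + 1))
            cm = ConfusionMatrix(tp, n_neg - tn, tn, n_pos - tp)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = metrics(cm).rounded()
            printed = {
                k: v for k, v in rep.as_dict().items()
                if v is not None and k != "roc_auc"
            }
            try:
                solved = solve_confusion(n_pos, n_neg, printed)
            except AmbiguousSolution:
                continue  # small totals can genuinely collide after rounding
            assert solved == cm


def test_round2_half_up():
    assert round2(99.555) == 99.56
    assert round2(98.5964) == 98.60
    assert round2(50.0) == 50.00
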