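"""CV protocol, metrics and the hypothesis battery vs hand oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal

import neuroexpertise.evalstats as ev
from neuroexpertise.evalstats import (
    CVReport,
    compute_metrics,
    kw_baseline_test,
    kw_paired_datasets_test,
    multicompare_dunn_sidak,
    percent_change,
    repeated_stratified_cv,
)
from neuroexpertise.models import ClassifierConfig
from _oracles import naive_kw_statistic, naive_metrics


def _report(f1, name="clf", variant="DS1"):
    n = len(f1)
    df = pd.DataFrame({
        "repeat": np.repeat(np.arange(max(n // 5, 1)), 5)[:n],
        "fold": np.tile(np.arange(5), max(n // 5, 1))[:n],
        "accuracy": f1, "precision": f1, "recall": f1, "f1": f1,
    })
    return CVReport(records=df, classifier=name, variant=variant)


class TestMetrics:
    def test_perfect_prediction_scores_100(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        assert compute_metrics(y, y) == (100.0, 100.0, 100.0, 100.0)

    def test_majority_prediction_on_balanced_labels(self):
        y_true = np.repeat([0, 1, 2], 150)
        y_pred = np.zeros(450, dtype=int)
        with pytest.warns(UserWarning):
            acc, prec, rec, f1 = compute_metrics(y_true, y_pred)
        assert acc == pytest.approx(33.33, abs=0.01)
        assert f1 == pytest.approx(16.67, abs=0.01)

    def test_matches_tally_oracle_on_seeded_labels(self, rng):
        import warnings

        for _ in range(60):
            n = int(rng.integers(20, 120))
            y_true = rng.integers(0, 3, n)
            y_pred = rng.integers(0, 3, n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = compute_metrics(y_true, y_pred)
            np.testing.assert_allclose(
                got, naive_metrics(y_true, y_pred), atol=1e-10
            )

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0, 5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1, 2], [0, 1])


@pytest.fixture(scope="module")
def data90():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((90, 6))
    y = np.repeat([0, 1, 2], 30)
    return X, rng.permutation(y)


class TestRepeatedCV:
    def test_record_count_and_fold_sizes(self, data90):
        X, y = data90
        rep = repeated_stratified_cv(X, y, ClassifierConfig(name="GNB"),
                                     n_repeats=10, n_splits=5, seed=0)
        assert len(rep.records) == 50
        assert set(rep.records["repeat"]) == set(range(10))

    def test_stratification_within_one_trial(self, data90):
        X, y = data90
        from sklearn.model_selection import RepeatedStratifiedKFold

        rskf = RepeatedStratifiedKFold(n_splits=5, n_repeats=2, random_state=0)
        global_props = np.bincount(y) / len(y)
        for _, te in rskf.split(X, y):
            props = np.bincount(y[te], minlength=3)
            expected = global_props * len(te)
            assert (np.abs(props - expected) <= 1.0 + 1e-9).all()

    def test_perfect_classifier_stub_scores_100(self, data90, monkeypatch):
        X, y = data90
        full = {tuple(row): lab for row, lab in zip(X, y)}
        monkeypatch.setattr(ev, "make_classifier",
                            lambda cfg: _Prefit(full))
        rep = repeated_stratified_cv(X, y, ClassifierConfig(name="GNB"),
                                     n_repeats=2, n_splits=5, seed=0)
        assert (rep.records["f1"] == 100.0).all()

    def test_deterministic_report_for_deterministic_model(self, data90):
        X, y = data90
        a = repeated_stratified_cv(X, y, ClassifierConfig(name="kNN"),
                                   n_repeats=2, n_splits=5, seed=5)
        b = repeated_stratified_cv(X, y, ClassifierConfig(name="kNN"),
                                   n_repeats=2, n_splits=5, seed=5)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_class_smaller_than_n_splits_rejected(self):
        X = np.zeros((7, 2))
        y = np.array([0, 0, 0, 1, 1, 1, 2])
        with pytest.raises(ValueError, match="class"):
            repeated_stratified_cv(X, y, ClassifierConfig(name="GNB"),
                                   n_splits=5)


class _Prefit:
    def __init__(self, mapping):
        self._map = mapping

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self._map[tuple(row)] for row in X])


class TestKwTests:
    def test_kw_statistic_matches_hand_ranks(self, rng):
        for _ in range(50):
            a = rng.standard_normal(30)
            b = rng.standard_normal(25) + rng.normal()
            want = naive_kw_statistic([a, b])
            got = kruskal(a, b).statistic
            assert got == pytest.approx(want, abs=1e-10)

    def test_identical_distributions_accept_h01(self):
        f1 = np.linspace(40, 60, 50)
        rep = kw_baseline_test(_report(f1), _report(f1, "baseline"))
        assert rep.comparisons[0]["decision"] == "accepted"
        assert rep.comparisons[0]["p_value"] == 1.0

    def test_large_shift_rejects_h01(self, rng):
        base = 30 + rng.normal(0, 5, 50)
        rep = kw_baseline_test(_report(base + 30), _report(base, "baseline"))
        assert rep.comparisons[0]["decision"] == "rejected"

    def test_wrong_direction_shift_accepts_h01(self, rng):
        base = 50 + rng.normal(0, 5, 50)
        rep = kw_baseline_test(_report(base - 30), _report(base, "baseline"))
        assert rep.comparisons[0]["decision"] == "accepted"

    def test_h02_directionality(self, rng):
        ds1 = 50 + rng.normal(0, 5, 50)
        assert kw_paired_datasets_test(
            _report(ds1), _report(ds1 + 20, variant="DS2")
        ).comparisons[0]["decision"] == "rejected"
        assert kw_paired_datasets_test(
            _report(ds1), _report(ds1 - 20, variant="DS2")
        ).comparisons[0]["decision"] == "accepted"
        assert kw_paired_datasets_test(
            _report(ds1), _report(ds1, variant="DS2")
        ).comparisons[0]["decision"] == "accepted"

    def test_type_one_error_near_alpha(self):
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(50, 5, 50)
            b = rng.normal(50, 5, 50)
            h = kw_baseline_test(_report(a), _report(b, "baseline"))
            rejections += h.comparisons[0]["decision"] == "rejected"
        rate = rejections / reps
        assert 0.01 <= rate <= 0.09


class TestDunnSidak:
    def test_identical_groups_yield_null_interval(self):
        f1 = np.linspace(40, 60, 50)
        rep = multicompare_dunn_sidak([_report(f1, "a"), _report(f1, "b")])
        c = rep.comparisons[0]
        assert c["estimate"] == pytest.approx(0.0, abs=1e-9)
        assert c["lower"] < 0 < c["upper"]
        assert c["p_value"] == pytest.approx(1.0, abs=1e-6)
        assert c["decision"] == "accepted"

    def test_interval_excludes_zero_iff_significant(self, rng):
        for _ in range(100):
            groups = [
                _report(rng.normal(50 + rng.normal(0, 6), 5, 30), f"g{i}")
                for i in range(4)
            ]
            rep = multicompare_dunn_sidak(groups)
            for c in rep.comparisons:
                excludes = (c["lower"] > 0) or (c["upper"] < 0)
                assert excludes == (c["decision"] == "rejected")
                assert excludes == (c["p_value"] < rep.alpha)

    def test_shifted_groups_flagged_exactly(self, rng):
        names = list("abcdefg")
        shifted = {"c", "f", "g"}
        reports = []
        for n in names:
            loc = 90 if n in shifted else 30
            reports.append(_report(rng.normal(loc, 2, 50), n))
        rep = multicompare_dunn_sidak(reports)
        for c in rep.comparisons:
            cross = (c["a"] in shifted) != (c["b"] in shifted)
            assert (c["decision"] == "rejected") == cross

    def test_unequal_record_counts_rejected(self, rng):
        with pytest.raises(ValueError, match="unequal"):
            multicompare_dunn_sidak(
                [_report(rng.normal(0, 1, 50)), _report(rng.normal(0, 1, 40))]
            )


def test_percent_change_printed_example():
    assert percent_change(50.79, 71.55) == pytest.approx(40.87, abs=0.005)
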