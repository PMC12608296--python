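import numpy as np
import pytest

from wardtriage.evaluate import (
    NAN_CLASS,
    ConfusionMatrix,
    alarm_load,
    compare_strategies,
    confusion,
    label_pairs,
    metrics,
)
from wardtriage.pipeline import build_alarms, detect_session, run_session
from wardtriage.simulate import ground_truth_labels
from wardtriage.triage import Strategy, TriageParams, TriageResult


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        t = ["N1", "N2", None, "N1"]
        cm = confusion(t, t, classes=("N1", "N2", NAN_CLASS))
        assert np.all(cm.counts == np.diag([2, 1, 1]))

    def test_all_nan_predictions_single_off_diagonal(self):
        cm = confusion(["N1"] * 5, [None] * 5, classes=("N1", NAN_CLASS))
        assert cm.counts[0, 1] == 5 and cm.total == 5

    def test_hand_built_ten_event_case_with_two_swaps(self):
        truth = ["N1"] * 5 + ["N2"] * 5
        pred = ["N1"] * 4 + ["N2"] + ["N2"] * 4 + ["N1"]
        cm = confusion(truth, pred, classes=("N1", "N2", NAN_CLASS))
        expected = np.array([[4, 1, 0], [1, 4, 0], [0, 0, 0]])
        assert np.all(cm.counts == expected)

    def test_event_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["N1"], ["N1", "N2"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["ghost"], ["ghost"], classes=("N1", NAN_CLASS))


class TestMetrics:
    def test_diagonal_matrix_perfect_scores(self):
        cm = ConfusionMatrix(("a", "b", "c"), np.diag([3, 4, 5]))
        m = metrics(cm)
        assert m.accuracy == 1.0 and m.macro_f1 == 1.0
        assert m.fpr == 0.0 and m.fnr == 0.0

    def test_binary_closed_form(self):
        """TP=3 FP=1 FN=1 TN=5 -> P = R = F1 = 0.75 for the positive class."""
        cm = ConfusionMatrix(("pos", "neg"), np.array([[3, 1], [1, 5]]))
        m = metrics(cm)
        row = m.per_class.loc["pos"]
        assert row.precision == pytest.approx(0.75)
        assert row.recall == pytest.approx(0.75)
        assert row.f1 == pytest.approx(0.75)

    def test_absent_class_scored_zero_and_flagged(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[4, 0], [0, 0]]))
        m = metrics(cm)
        assert m.per_class.loc["b"].f1 == 0.0
        assert m.undefined_classes == ("b",)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(("a",), np.zeros((1, 1))))

    def test_agrees_with_sklearn_on_random_matrices(self):
        """Independent oracle: expand each random matrix into label lists
        and score with scikit-learn; agreement to 1e-12."""
        from sklearn.metrics import accuracy_score, precision_recall_fscore_support

        rng = np.random.default_rng(42)
        classes = ("n1", "n2", "n3", "n4", NAN_CLASS)
        for _ in range(100):
            counts = rng.integers(0, 20, size=(5, 5))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ConfusionMatrix(classes, counts)
            truth, pred = [], []
            for i, ci in enumerate(classes):
                for j, cj in enumerate(classes):
                    truth += [ci] * counts[i, j]
                    pred += [cj] * counts[i, j]
            p, r, f1, _ = precision_recall_fscore_support(
                truth, pred, labels=list(classes), zero_division=0
            )
            m = metrics(cm)
            np.testing.assert_allclose(m.per_class.precision.to_numpy(), p, atol=1e-12)
            np.testing.assert_allclose(m.per_class.recall.to_numpy(), r, atol=1e-12)
            np.testing.assert_allclose(m.per_class.f1.to_numpy(), f1, atol=1e-12)
            assert m.accuracy == pytest.approx(accuracy_score(truth, pred), abs=1e-12)
            assert m.macro_f1 == pytest.approx(f1.mean(), abs=1e-12)

    def test_fpr_fnr_against_brute_force_tally(self):
        rng = np.random.default_rng(7)
        classes = ("a", "b", "c")
        counts = rng.integers(0, 15, size=(3, 3))
        m = metrics(ConfusionMatrix(classes, counts))
        total = counts.sum()
        fprs, fnrs = [], []
        for i in range(3):
            tp = counts[i, i]
            fp = counts[:, i].sum() - tp
            fn = counts[i, :].sum() - tp
            tn = total - tp - fp - fn
            fprs.append(fp / (fp + tn) if fp + tn else 0.0)
            fnrs.append(fn / (fn + tp) if fn + tp else 0.0)
        assert m.fpr == pytest.approx(np.mean(fprs), abs=1e-12)
        assert m.fnr == pytest.approx(np.mean(fnrs), abs=1e-12)


class TestAlarmLoad:
    def _result(self, strategy, notifications):
        return TriageResult(
            strategy=Strategy(strategy), decisions=[], shadow_log=[],
            notifications=notifications,
        )

    def test_baseline_load_is_identically_100(self):
        res = {"baseline": self._result("baseline", {"N1": 8, "N2": 8})}
        df = alarm_load(res)
        assert (df.load_pct == 100.0).all()
        assert (df.reduction_pct == 0.0).all()

    def test_quarter_load_is_75_percent_reduction(self):
        res = {
            "baseline": self._result("baseline", {"N1": 4}),
            "proposed": self._result("proposed", {"N1": 1}),
        }
        df = alarm_load(res)
        row = df[(df.strategy == "proposed")].iloc[0]
        assert row.load_pct == pytest.approx(25.0)
        assert row.reduction_pct == pytest.approx(75.0)

    def test_silent_nurse_gets_full_reduction(self):
        res = {
            "baseline": self._result("baseline", {"N1": 4}),
            "proposed": self._result("proposed", {"N1": 0}),
        }
        df = alarm_load(res)
        assert df[df.strategy == "proposed"].iloc[0].reduction_pct == pytest.approx(100.0)

    def test_zero_baseline_reported_undefined(self):
        res = {
            "baseline": self._result("baseline", {"N1": 0}),
            "proposed": self._result("proposed", {"N1": 0}),
        }
        df = alarm_load(res)
        assert np.isnan(df[df.strategy == "proposed"].iloc[0].load_pct)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            alarm_load({"proposed": self._result("proposed", {"N1": 1})})


class TestCompareStrategies:
    def test_easy_scenario_preserves_strategy_ordering(self, small_session):
        report = compare_strategies(small_session)
        f1 = report.overall.macro_f1
        assert f1["proposed"] >= f1["rsdv"] - 1e-12
        assert f1["rsdv"] >= f1["rsd"] - 1e-12
        assert f1["proposed"] > f1["baseline"]

    def test_single_session_has_one_day_slice(self, small_session):
        report = compare_strategies(small_session)
        day_rows = report.per_slice[report.per_slice.slice_type == "day"]
        assert set(day_rows["slice"]) == {"day1"}
        room_rows = report.per_slice[report.per_slice.slice_type == "room"]
        assert set(room_rows["slice"]) == set(small_session.rooms.values())

    def test_deterministic_rerun_identical_report(self, small_session):
        r1 = compare_strategies(small_session)
        r2 = compare_strategies(small_session)
        assert r1.overall.equals(r2.overall)
        assert r1.per_slice.equals(r2.per_slice)
        assert r1.loads.equals(r2.loads)

    def test_baseline_loads_are_100(self, small_session):
        report = compare_strategies(small_session)
        base = report.loads[report.loads.strategy == "baseline"]
        assert (base.load_pct.dropna() == 100.0).all()


class TestLabelPairs:
    def test_baseline_expands_per_notification(self, small_session):
        params = TriageParams(nurse_speed=small_session.config.nurse_speed)
        eps = detect_session(small_session)
        alarms = build_alarms(small_session, eps, params)
        truth = ground_truth_labels(small_session, params)
        run_b = run_session(small_session, "baseline", params, episodes=eps, alarms=alarms)
        run_p = run_session(small_session, "proposed", params, episodes=eps, alarms=alarms)
        pairs_b = label_pairs(run_b, truth)
        pairs_p = label_pairs(run_p, truth)
        n_nurses = len(small_session.roster)
        matched = sum(m is not None for m in run_b.matches)
        missed = len(truth) - matched
        assert len(pairs_b) == matched * n_nurses + missed + len(run_b.spurious) * n_nurses
        assert len(pairs_p) == len(truth) + len(run_p.spurious)
        assert all(p is not None for _, p, _ in pairs_b[: matched * n_nurses])
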