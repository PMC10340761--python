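import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from metpanel.errors import InconsistencyError
from metpanel.panel import (
    CountRulePanelClassifier,
    PanelDefinition,
    PanelMarker,
    builtin_panels,
    call_events,
    classify_count_rule,
    panel_performance,
    reconstruct_confusion,
    round_half_up,
)
from metpanel.roc import youden_cutoff


class TestEvents:
    def test_builtin_panels_use_study_rules(self):
        panels = builtin_panels()
        assert [m.name for m in panels["expression"].markers] == [
            "CA9", "NDUFA4L2", "EGLN3", "BHLHE41"
        ]
        assert panels["expression"].k_events == 3
        assert panels["methylation"].k_events == 4
        assert len(panels["combined"].markers) == 9
        assert panels["combined"].k_events == 6

    def test_expression_loss_and_hypermethylation_fire(self):
        # group-median-level values versus the published cutoffs
        assert PanelMarker("CA9", "low_positive", 51.3).fires(17.8)
        assert not PanelMarker("CA9", "low_positive", 51.3).fires(92.7)
        assert PanelMarker("MIR125B-1", "high_positive", 55.18).fires(66.34)
        assert not PanelMarker("MIR125B-1", "high_positive", 55.18).fires(36.27)

    def test_boundary_convention_inclusive_low_exclusive_high(self):
        assert PanelMarker("g", "low_positive", 2.6).fires(2.6)
        assert not PanelMarker("g", "high_positive", 55.18).fires(55.18)

    def test_missing_panel_marker_column_raises(self, study_cohort):
        pdef = PanelDefinition(
            "bad", (PanelMarker("NOT_THERE", "low_positive", 1.0),), 1
        )
        with pytest.raises(KeyError, match="NOT_THERE"):
            call_events(study_cohort, pdef)

    def test_samples_with_missing_values_excluded_and_counted(self, study_cohort):
        cohort = study_cohort.copy()
        cohort.loc[cohort.index[:3], "CA9"] = np.nan
        events, n_excl = call_events(cohort, builtin_panels()["expression"])
        assert n_excl == 3
        assert len(events) == len(cohort) - 3
        assert set(events["CA9"].unique()) <= {0, 1}


class TestCountRule:
    def test_three_of_four_positive(self):
        pred, counts = classify_count_rule(np.array([[1, 1, 1, 0]]), k=3)
        assert pred[0] == 1 and counts[0] == 3

    def test_five_of_nine_negative_at_k6(self):
        row = np.array([[1, 1, 1, 1, 1, 0, 0, 0, 0]])
        pred, _ = classify_count_rule(row, k=6)
        assert pred[0] == 0

    def test_k1_equals_logical_or(self, rng):
        mat = rng.integers(0, 2, size=(50, 5))
        pred, _ = classify_count_rule(mat, k=1)
        np.testing.assert_array_equal(pred, mat.any(axis=1).astype(int))

    def test_k_beyond_m_rejected(self):
        with pytest.raises(ValueError):
            classify_count_rule(np.zeros((2, 3), dtype=int), k=4)

    def test_monotonicity_in_k(self, rng):
        # raising k can only lose sensitivity and gain specificity
        for _ in range(25):
            n, m = int(rng.integers(10, 60)), int(rng.integers(2, 9))
            mat = rng.integers(0, 2, size=(n, m))
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            prev_sens, prev_spec = None, None
            for k in range(1, m + 1):
                pred, counts = classify_count_rule(mat, k)
                perf = panel_performance(pred, counts, y)
                if prev_sens is not None:
                    assert perf.sensitivity <= prev_sens + 1e-9
                    assert perf.specificity >= prev_spec - 1e-9
                prev_sens, prev_spec = perf.sensitivity, perf.specificity


class TestPerformance:
    def test_published_combined_panel_counts_reproduce_predictive_values(self):
        # tp=27 fn=4 tn=47 fp=2 on the 31/49 cohort
        y = np.array([1] * 31 + [0] * 49)
        pred = np.array([1] * 27 + [0] * 4 + [1] * 2 + [0] * 47)
        perf = panel_performance(pred, pred, y, "combined")
        assert (perf.tp, perf.fp, perf.tn, perf.fn) == (27, 2, 47, 4)
        assert round_half_up(perf.npv, 2) == 92.16
        assert round_half_up(perf.ppv, 2) == 93.10
        assert perf.tp + perf.fn == 31 and perf.tn + perf.fp == 49

    def test_perfect_classifier(self):
        y = np.array([1, 1, 0, 0])
        perf = panel_performance(y, y, y)
        assert perf.sensitivity == perf.specificity == perf.ppv == perf.npv == 100.0
        for lo, hi in (perf.sensitivity_ci, perf.npv_ci):
            assert 0 <= lo <= 100 and hi == 100.0

    def test_undefined_ppv_reported_as_nan(self):
        y = np.array([1, 0, 1, 0])
        pred = np.zeros(4, dtype=int)
        perf = panel_performance(pred, pred, y)
        assert np.isnan(perf.ppv)
        assert perf.npv == 50.0

    def test_string_outcomes_accepted(self):
        y = np.array(["met", "met", "nonmet", "nonmet"])
        perf = panel_performance([1, 0, 0, 0], [3, 1, 1, 0], y)
        assert perf.tp == 1 and perf.fn == 1 and perf.tn == 2

    def test_count_score_auc_is_trapezoid_over_k_thresholds(self, rng):
        # the reported ordinal AUC must equal the trapezoidal area under the
        # ROC traced by sweeping the count threshold k over 0..m
        for _ in range(50):
            n, m = int(rng.integers(10, 40)), int(rng.integers(2, 7))
            mat = rng.integers(0, 2, size=(n, m))
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            _, counts = classify_count_rule(mat, 1)
            perf = panel_performance((counts >= 1).astype(int), counts, y)
            tpr = [(counts[y == 1] >= k).mean() for k in range(m + 1, -1, -1)]
            fpr = [(counts[y == 0] >= k).mean() for k in range(m + 1, -1, -1)]
            assert perf.auc_count_score == pytest.approx(np.trapezoid(tpr, fpr))


class TestReconstruction:
    @pytest.mark.parametrize(
        "sens, spec, n1, n0, expected",
        [
            (87.10, 95.92, 31, 49, (27, 2, 47, 4)),
            (74.19, 79.59, 31, 49, (23, 10, 39, 8)),
            (100.0, 100.0, 10, 10, (10, 0, 10, 0)),
        ],
    )
    def test_inversion(self, sens, spec, n1, n0, expected):
        assert reconstruct_confusion(sens, spec, n1, n0) == expected

    def test_inconsistent_percentages_raise(self):
        with pytest.raises(InconsistencyError):
            reconstruct_confusion(87.10, 90.00, 31, 49)

    def test_round_trip_with_performance(self):
        tp, fp, tn, fn = reconstruct_confusion(70.97, 81.63, 31, 49)
        y = np.array([1] * 31 + [0] * 49)
        pred = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
        perf = panel_performance(pred, pred, y)
        assert round_half_up(perf.sensitivity, 2) == 70.97
        assert round_half_up(perf.specificity, 2) == 81.63


class TestRoundHalfUp:
    @pytest.mark.parametrize(
        "x, nd, expected",
        [(92.155, 2, 92.16), (0.5, 0, 1.0), (2.675, 2, 2.68), (93.103, 2, 93.10)],
    )
    def test_half_up_not_bankers(self, x, nd, expected):
        assert round_half_up(x, nd) == expected


class TestClassifier:
    def test_fit_learns_youden_cutoffs(self, study_cohort):
        X = study_cohort.drop(columns=["sample_id", "outcome"])
        y = study_cohort["outcome"].to_numpy()
        clf = CountRulePanelClassifier(
            markers=["CA9", "NDUFA4L2", "EGLN3", "BHLHE41"], k=3
        ).fit(X, y)
        y01 = (y == "met").astype(float)
        for m in clf.markers_:
            expected, _, _, _ = youden_cutoff(
                X[m].to_numpy(dtype=float), y01, "low_positive"
            )
            assert clf.cutoffs_[m] == expected
        assert set(clf.predict(X)) <= {"met", "nonmet"}

    def test_fixed_cutoffs_match_functional_path(self, study_cohort):
        X = study_cohort.drop(columns=["sample_id", "outcome"])
        y = study_cohort["outcome"].to_numpy()
        pdef = builtin_panels()["combined"]
        clf = CountRulePanelClassifier(
            markers=[m.name for m in pdef.markers],
            cutoffs={m.name: m.cutoff for m in pdef.markers},
            k=pdef.k_events,
        ).fit(X, y)
        events, _ = call_events(study_cohort, pdef)
        pred_fn, counts_fn = classify_count_rule(events, pdef.k_events)
        np.testing.assert_array_equal(clf.decision_function(X), counts_fn)
        np.testing.assert_array_equal(
            clf.predict(X) == "met", pred_fn.astype(bool)
        )

    def test_sklearn_protocol(self, study_cohort):
        clf = CountRulePanelClassifier(markers=["CA9"], k=1)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()
        X = study_cohort.drop(columns=["sample_id", "outcome"])
        y = study_cohort["outcome"].to_numpy()
        cloned.fit(X, y)
        assert cloned.classes_.tolist() == ["met", "nonmet"]
        assert 0.0 <= cloned.score(X, y) <= 1.0
        with pytest.raises(RuntimeError):
            clf.predict(X)  # unfitted original

    def test_unknown_marker_direction_rejected(self):
        X = pd.DataFrame({"mystery": [1.0, 2.0, 3.0, 4.0]})
        y = np.array([0, 0, 1, 1])
        with pytest.raises(KeyError, match="mystery"):
            CountRulePanelClassifier().fit(X, y)
        clf = CountRulePanelClassifier(
            directions={"mystery": "high_positive"}, k=1
        ).fit(X, y)
        assert clf.cutoffs_["mystery"] == 2.0
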