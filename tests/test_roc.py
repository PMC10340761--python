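import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from metpanel.roc import (
    analyze_marker,
    delong_ci,
    empirical_auc,
    roc_points,
    youden_cutoff,
)


def brute_force_auc(values, outcome, direction):
    """Pairwise concordance with ties counted 1/2, by explicit double loop."""
    v = np.asarray(values, dtype=float)
    if direction == "low_positive":
        v = -v
    pos, neg = v[np.asarray(outcome) == 1], v[np.asarray(outcome) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(values, outcome, direction):
    """Exhaustive sweep over observed cutoffs, recomputing each confusion
    matrix from scratch."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome)
    best = None
    for t in np.unique(v):
        call = (v <= t) if direction == "low_positive" else (v > t)
        sens = call[y == 1].mean()
        spec = (~call[y == 0]).mean()
        j = sens + spec - 1
        key = (round(j, 12), round(spec, 12))
        if best is None or key > best[0]:
            best = (key, t, 100 * sens, 100 * spec, j)
    return best[1:]


def test_perfect_separation_low_positive():
    auc = empirical_auc([1, 2, 8, 9], [1, 1, 0, 0], "low_positive")
    assert auc == 1.0


def test_auc_matches_brute_force_on_random_instances(rng):
    for _ in range(100):
        n1, n0 = rng.integers(2, 16, size=2)
        v = np.round(rng.normal(size=n1 + n0), 1)  # rounding induces ties
        y = np.concatenate([np.ones(n1), np.zeros(n0)])
        direction = rng.choice(["low_positive", "high_positive"])
        assert empirical_auc(v, y, direction) == pytest.approx(
            brute_force_auc(v, y, direction)
        )


def test_auc_cross_checked_against_sklearn(rng):
    v = rng.normal(size=60)
    y = rng.integers(0, 2, size=60)
    y[:2] = [0, 1]
    assert empirical_auc(v, y, "high_positive") == pytest.approx(roc_auc_score(y, v))
    assert empirical_auc(v, y, "low_positive") == pytest.approx(roc_auc_score(y, -v))


def test_direction_flip_symmetry_on_tie_free_data(rng):
    v = rng.normal(size=50)
    y = rng.integers(0, 2, size=50)
    y[:2] = [0, 1]
    a = empirical_auc(v, y, "high_positive")
    b = empirical_auc(v, y, "low_positive")
    assert a + b == pytest.approx(1.0)


def test_auc_invariant_under_increasing_transform(rng):
    v = rng.lognormal(size=40)
    y = rng.integers(0, 2, size=40)
    y[:2] = [0, 1]
    assert empirical_auc(v, y, "high_positive") == pytest.approx(
        empirical_auc(np.log(v), y, "high_positive")
    )


def test_null_auc_near_half(rng):
    v = rng.normal(size=1000)
    y = rng.integers(0, 2, size=1000)
    assert empirical_auc(v, y, "high_positive") == pytest.approx(0.5, abs=0.05)


def test_roc_points_monotone_and_anchored(rng):
    v = np.round(rng.normal(size=60), 1)
    y = rng.integers(0, 2, size=60)
    y[:2] = [0, 1]
    for direction in ("low_positive", "high_positive"):
        _, fpr, tpr = roc_points(v, y, direction)
        assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


class TestDeLong:
    def test_ci_contains_point_estimate(self, rng):
        v = rng.normal(size=80)
        y = np.concatenate([np.ones(31), np.zeros(49)])
        auc, lo, hi, _ = delong_ci(v, y, "high_positive")
        assert lo <= auc <= hi

    def test_symmetric_null_data_gives_p_near_one(self):
        # mirror-symmetric values make the empirical AUC exactly 0.5
        v = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        auc, _, _, p = delong_ci(v, y, "high_positive")
        assert auc == 0.5
        assert p == pytest.approx(1.0)

    def test_degenerate_auc_warns_and_clips(self):
        with pytest.warns(UserWarning, match="degenerate"):
            auc, lo, hi, p = delong_ci([1, 2, 8, 9], [1, 1, 0, 0], "low_positive")
        assert (auc, lo, hi) == (1.0, 1.0, 1.0)

    def test_variance_agrees_with_bootstrap(self, rng):
        # synthetic marker on a study-sized cohort
        v = np.concatenate([rng.normal(1.0, 1.0, 31), rng.normal(0.0, 1.0, 49)])
        y = np.concatenate([np.ones(31), np.zeros(49)])
        auc, lo, hi, _ = delong_ci(v, y, "high_positive")
        se_delong = (hi - lo) / (2 * 1.959963984540054)
        boot = []
        for _ in range(2000):
            ip = rng.integers(0, 31, 31)
            ineg = 31 + rng.integers(0, 49, 49)
            idx = np.concatenate([ip, ineg])
            boot.append(empirical_auc(v[idx], y[idx], "high_positive"))
        se_boot = np.std(boot, ddof=1)
        assert se_delong == pytest.approx(se_boot, rel=0.15)


class TestYouden:
    def test_separable_data(self):
        cutoff, sens, spec, j = youden_cutoff(
            [1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0], "low_positive"
        )
        assert cutoff == 3 and sens == 100.0 and spec == 100.0 and j == 1.0

    def test_matches_exhaustive_sweep_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(6, 30)
            v = np.round(rng.normal(size=n), 1)
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            direction = rng.choice(["low_positive", "high_positive"])
            got = youden_cutoff(v, y, direction)
            exp = brute_force_youden(v, y, direction)
            assert got[0] == exp[0]
            assert got[1] == pytest.approx(exp[1])
            assert got[2] == pytest.approx(exp[2])

    def test_reported_rates_match_confusion_recount(self, study_cohort, study_outcome):
        v = study_cohort["CA9"].to_numpy(dtype=float)
        cutoff, sens, spec, j = youden_cutoff(v, study_outcome, "low_positive")
        call = v <= cutoff
        assert sens == pytest.approx(100 * call[study_outcome == 1].mean())
        assert spec == pytest.approx(100 * (~call[study_outcome == 0]).mean())
        assert j == pytest.approx(sens / 100 + spec / 100 - 1)


def test_analyze_marker_is_internally_consistent(study_cohort, study_outcome):
    res = analyze_marker(
        study_cohort["MIR125B-1"].to_numpy(dtype=float), study_outcome,
        "high_positive", "MIR125B-1",
    )
    assert res.auc_ci_low <= res.auc <= res.auc_ci_high
    assert res.cutoff_rule.startswith(">")
    assert res.youden_j == pytest.approx(
        res.sensitivity / 100 + res.specificity / 100 - 1
    )
    assert res.n_pos == 31 and res.n_neg == 49


def test_one_class_inputs_rejected():
    with pytest.raises(ValueError):
        empirical_auc([1.0, 2.0], [1, 1], "high_positive")
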