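"""Concordance, AUC, calibration, bootstrap — against brute-force oracles."""

import numpy as np
import pytest

from ckdval import (
    CENSORED,
    COMPETING,
    EVENT,
    FirstEventData,
    UndefinedResultError,
    binary_auc,
    bootstrap_ci,
    calibration_groups,
    calibration_in_the_large,
    validation_report,
    wolbers_c,
)


def _fed(times, causes):
    return FirstEventData(np.asarray(times, dtype=float),
                          np.asarray(causes, dtype=object))


def bruteforce_concordance(pred, time, cause, horizon):
    """Literal pair enumeration of the competing-risks concordance rules:
    truncate at the horizon; (i, j) comparable iff i has the event of
    interest and j either has a competing event (event-free at infinity)
    or an event/censoring strictly after T_i; prediction ties 1/2."""
    raw_time = np.asarray(time, dtype=float)
    cause = np.asarray(
        [c if t <= horizon else CENSORED
         for t, c in zip(raw_time, np.asarray(cause, dtype=object))],
        dtype=object)
    time = np.minimum(raw_time, horizon)
    pairs = conc = ties = 0
    n = len(time)
    for i in range(n):
        if cause[i] != EVENT:
            continue
        for j in range(n):
            if j == i:
                continue
            if cause[j] == COMPETING:
                comparable = True
            elif time[j] > time[i]:
                comparable = True  # later event or censoring after T_i
            else:
                comparable = False
            if not comparable:
                continue
            pairs += 1
            if pred[i] > pred[j]:
                conc += 1
            elif pred[i] == pred[j]:
                ties += 1
    return pairs, conc, ties


def _random_instance(rng, n=None, competing=True, tied_times=True):
    n = n or int(rng.integers(4, 31))
    time = rng.exponential(2.0, n)
    if tied_times:
        time = time.round(1) + 0.1  # rounding forces time ties
    labels = [EVENT, COMPETING, CENSORED] if competing else [EVENT, CENSORED]
    cause = rng.choice(labels, size=n).astype(object)
    pred = rng.choice(np.linspace(0, 1, 7), size=n)  # coarse grid forces ties
    return pred, time, cause


# --------------------------------------------------------------------------
# Concordance
# --------------------------------------------------------------------------

def test_perfect_separation_gives_c_one_and_zero():
    time = np.array([1.0, 2.0, 5.0, 6.0])
    cause = np.array([EVENT, EVENT, CENSORED, CENSORED], dtype=object)
    pred = np.array([0.9, 0.8, 0.2, 0.1])
    assert wolbers_c(pred, _fed(time, cause), 10.0).c == 1.0
    assert wolbers_c(-pred, _fed(time, cause), 10.0).c == 0.0


def test_concordance_matches_bruteforce_on_small_instances(rng):
    for _ in range(200):
        pred, time, cause = _random_instance(rng)
        horizon = float(rng.choice([1.0, 2.0, 4.0]))
        pairs, conc, ties = bruteforce_concordance(pred, time, cause, horizon)
        if pairs == 0:
            with pytest.raises(UndefinedResultError):
                wolbers_c(pred, _fed(time, cause), horizon)
            continue
        res = wolbers_c(pred, _fed(time, cause), horizon)
        assert (res.comparable_pairs, res.concordant, res.tied) == (pairs, conc, ties)
        assert res.c == pytest.approx((conc + 0.5 * ties) / pairs)


def test_reduces_to_harrell_without_competing_events(rng):
    from lifelines.utils import concordance_index

    for _ in range(20):
        # continuous times: with an event/censoring time tie the conventions
        # differ (we require censoring strictly after the event time)
        pred, time, cause = _random_instance(rng, n=60, competing=False,
                                             tied_times=False)
        horizon = 4.0
        d = _fed(time, cause).truncated(horizon)
        res = wolbers_c(pred, _fed(time, cause), horizon)
        harrell = concordance_index(d.time, -np.asarray(pred),
                                    event_observed=(d.cause == EVENT))
        assert res.c == pytest.approx(harrell, abs=1e-12)


def test_invariant_under_monotone_transform(rng):
    pred, time, cause = _random_instance(rng, n=40)
    d = _fed(time, cause)
    base = wolbers_c(pred, d, 4.0)
    for f in (lambda p: 3 * p + 1, lambda p: np.expm1(p), lambda p: p ** 3):
        assert wolbers_c(f(np.asarray(pred)), d, 4.0).c == pytest.approx(base.c)


def test_true_risk_beats_random_predictor(small_synthetic):
    cohort, oracle = small_synthetic
    from ckdval import outcome_riskset

    data = outcome_riskset(cohort, "any_krt")
    truth = oracle["any_krt"].to_numpy()
    rng = np.random.default_rng(5)
    c_true = wolbers_c(truth, data, 2.0).c
    c_rand = wolbers_c(rng.random(len(cohort)), data, 2.0).c
    assert c_true > 0.6
    assert abs(c_rand - 0.5) < 0.12


# --------------------------------------------------------------------------
# Binary AUC
# --------------------------------------------------------------------------

def test_auc_trivials_and_oracle(rng):
    assert binary_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    assert binary_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5
    with pytest.raises(UndefinedResultError):
        binary_auc([0.1, 0.2], [1, 1])
    from sklearn.metrics import roc_auc_score

    for _ in range(30):
        n = int(rng.integers(4, 31))
        scores = rng.choice(np.linspace(0, 1, 5), size=n)
        labels = rng.integers(0, 2, n).astype(bool)
        if labels.all() or not labels.any():
            continue
        assert binary_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

def test_citl_with_constant_predictions_returns_definition():
    time = [1, 2, 3, 4]
    cause = [EVENT, COMPETING, CENSORED, EVENT]
    d = _fed(time, cause)
    mean_pred, observed = calibration_in_the_large(np.full(4, 0.3), d, 4.0)
    assert mean_pred == pytest.approx(0.3)
    from ckdval import aalen_johansen, cif_at

    assert observed == pytest.approx(cif_at(aalen_johansen(d), 4.0)[EVENT])


def test_citl_all_censored_observed_zero():
    d = _fed([5, 6, 7], [CENSORED] * 3)
    _, observed = calibration_in_the_large(np.full(3, 0.2), d, 4.0)
    assert observed == 0.0


def test_calibration_groups_partition_and_ranking(rng):
    n = 100
    pred = rng.random(n)
    d = _fed(rng.exponential(2, n), rng.choice([EVENT, CENSORED], n).astype(object))
    tab = calibration_groups(pred, d, 2.0, n_groups=10)
    assert list(tab.groups["n"]) == [10] * 10
    assert tab.groups["mean_predicted"].is_monotonic_increasing
    # constant predictions -> all group means equal
    tab2 = calibration_groups(np.full(n, 0.4), d, 2.0, n_groups=10)
    assert np.allclose(tab2.groups["mean_predicted"], 0.4)


def test_calibration_groups_validation():
    d = _fed([1.0] * 5, [EVENT] * 5)
    from ckdval import ConfigurationError, DomainError

    with pytest.raises(ConfigurationError):
        calibration_groups(np.ones(5), d, 2.0, n_groups=1)
    with pytest.raises(DomainError):
        calibration_groups(np.ones(5), d, 2.0, n_groups=10)


# --------------------------------------------------------------------------
# Bootstrap
# --------------------------------------------------------------------------

def test_bootstrap_constant_statistic_zero_width():
    lo, hi = bootstrap_ci(lambda idx: 1.0, n=50, B=200, seed=3)
    assert lo == hi == 1.0


def test_bootstrap_reproducible():
    data = np.random.default_rng(0).normal(size=80)
    stat = lambda idx: float(data[idx].mean())
    assert bootstrap_ci(stat, 80, B=300, seed=11) == bootstrap_ci(stat, 80, B=300, seed=11)


def test_bootstrap_undefined_majority_fails():
    def stat(idx):
        raise UndefinedResultError("always")

    with pytest.raises(UndefinedResultError):
        bootstrap_ci(stat, 20, B=100, seed=0)


def test_bootstrap_coverage_of_normal_mean():
    """Percentile-interval coverage for the mean of n=200 normals, 500
    Monte-Carlo repetitions: close to the nominal 95%."""
    rng = np.random.default_rng(42)
    hits = 0
    reps = 500
    for _ in range(reps):
        data = rng.normal(size=200)
        lo, hi = bootstrap_ci(lambda idx: float(data[idx].mean()), 200,
                              B=400, seed=int(rng.integers(2 ** 31)))
        hits += lo <= 0.0 <= hi
    assert abs(hits / reps - 0.95) <= 0.02


# --------------------------------------------------------------------------
# Report assembly
# --------------------------------------------------------------------------

def test_validation_report_shape(small_synthetic):
    cohort, oracle = small_synthetic
    report, tables = validation_report(oracle, cohort, horizons=(2.0,), n_groups=5)
    assert set(report["outcome"]) == {
        "any_krt", "any_cvd", "death", "death_without_krt", "death_after_krt",
        "no_event"}
    assert ((report["c_statistic"] >= 0) & (report["c_statistic"] <= 1)).all()
    assert ("any_krt", 2.0) in tables
    g = tables[("any_krt", 2.0)].groups
    assert g["n"].sum() == len(cohort)
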