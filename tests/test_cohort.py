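"""Cohort I/O, PCR->ACR preprocessing, and outcome-sequence classification."""

import itertools
import math
from dataclasses import fields

import pytest

from ckdval import (
    Cohort,
    ConfigurationError,
    DataError,
    DomainError,
    PatientRecord,
    classify_outcomes,
    convert_pcr_to_acr,
    load_cohort,
    load_pcr_to_acr_coeffs,
    resolve_acr,
    save_cohort,
)
from conftest import make_record


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

def test_header_only_file_gives_empty_cohort(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text("id,age,sex,race_black,cvd_history,diabetes,smoker,sbp,egfr\n")
    assert len(load_cohort(p)) == 0


def test_cohort_roundtrips_through_csv(tmp_path):
    records = [
        make_record(id="a", acr=100.0, krt_time=0.5, death_time=1.5),
        make_record(id="b", sex="female", acr=None, pcr=300.0, censor_time=2.0),
        make_record(id="c", cvd_time=1.0, censor_time=4.0, hypertension=True),
    ]
    path = tmp_path / "c.csv"
    save_cohort(Cohort(records=records), path)
    loaded = load_cohort(path)
    assert len(loaded) == 3
    for orig, back in zip(records, loaded):
        for f in fields(PatientRecord):
            a, b = getattr(orig, f.name), getattr(back, f.name)
            if isinstance(a, float):
                assert b == pytest.approx(a)
            else:
                assert a == b


def test_event_after_death_rejected_with_row_index(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text(
        "id,age,sex,race_black,cvd_history,diabetes,smoker,sbp,egfr,acr,"
        "krt_time,death_time\n"
        "x,76,M,0,0,0,0,143,18,391,2.0,1.0\n"
    )
    with pytest.raises(DataError, match="row 0"):
        load_cohort(p)


def test_negative_time_rejected(tmp_path):
    p = tmp_path / "neg.csv"
    p.write_text(
        "id,age,sex,race_black,cvd_history,diabetes,smoker,sbp,egfr,acr,censor_time\n"
        "x,76,M,0,0,0,0,143,18,391,-1.0\n"
    )
    with pytest.raises(DataError, match="row 0"):
        load_cohort(p)


def test_missing_required_column_is_configuration_error(tmp_path):
    p = tmp_path / "m.csv"
    p.write_text("id,age\nx,76\n")
    with pytest.raises(ConfigurationError):
        load_cohort(p)


def test_dialect_renames_columns(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text(
        "patient,age,gender,race_black,cvd_history,diabetes,smoker,sbp,egfr,acr,censor_time\n"
        "x,76,F,0,0,0,0,143,18,391,3.0\n"
    )
    c = load_cohort(p, dialect={"id": "patient", "sex": "gender"})
    assert c.records[0].sex == "female"


def test_duplicate_ids_rejected():
    with pytest.raises(DataError, match="duplicate"):
        Cohort(records=[make_record(id="a"), make_record(id="a")])


def test_record_requires_exactly_one_terminal_boundary():
    with pytest.raises(DataError):
        make_record(death_time=1.0, censor_time=2.0).validate()
    with pytest.raises(DataError):
        PatientRecord(id="x", age=70, sex="male", race_black=False,
                      cvd_history=False, diabetes=False, smoker=False,
                      sbp=140, egfr=15).validate()


# --------------------------------------------------------------------------
# PCR -> ACR
# --------------------------------------------------------------------------

def test_measured_acr_takes_precedence_over_pcr():
    c = Cohort(records=[make_record(acr=200.0, pcr=900.0)])
    assert resolve_acr(c).records[0].acr == 200.0


def test_conversion_strictly_increasing_in_pcr():
    coeffs = load_pcr_to_acr_coeffs()
    pcrs = [5, 30, 50, 120, 500, 900, 4000]
    acrs = [convert_pcr_to_acr(p, "female", True, True, coeffs) for p in pcrs]
    assert all(a > 0 for a in acrs)
    assert all(a1 < a2 for a1, a2 in zip(acrs, acrs[1:]))


def test_conversion_worked_values():
    # hand evaluation of the spline equation with the shipped coefficients:
    # PCR=500 zeroes every spline term -> ACR = exp(intercept) = 219.6 mg/g
    coeffs = load_pcr_to_acr_coeffs()
    assert convert_pcr_to_acr(500.0, "male", False, False, coeffs) == pytest.approx(
        219.6422, rel=1e-4)
    # PCR=1000, female, diabetic, hypertensive:
    # exp(5.3920 + 1.1266*ln(2) - 0.0773 + 0.0797 + 0.1265) = 545.55 mg/g
    assert convert_pcr_to_acr(1000.0, "female", True, True, coeffs) == pytest.approx(
        545.5528, rel=1e-4)


def test_nonpositive_pcr_is_domain_error():
    with pytest.raises(DomainError):
        convert_pcr_to_acr(0.0, "male", False, False, load_pcr_to_acr_coeffs())


def test_resolve_acr_requires_acr_or_pcr():
    with pytest.raises(DataError):
        resolve_acr(Cohort(records=[make_record(acr=None, pcr=None)]))


# --------------------------------------------------------------------------
# Outcome classification
# --------------------------------------------------------------------------

def test_death_after_krt_example():
    r = make_record(krt_time=0.5, death_time=1.5)
    c = classify_outcomes(r, horizon=2.0)
    assert c.category == "death_after_krt"
    assert c.combined["any_krt"] and c.combined["death"]
    assert c.combined["death_after_krt"] and not c.combined["death_without_krt"]
    assert c.first_event_cause == "krt" and c.first_event_time == 0.5


def test_krt_after_cvd_example():
    r = make_record(cvd_time=0.3, krt_time=1.0, censor_time=2.5)
    c = classify_outcomes(r, horizon=2.0)
    assert c.category == "krt_after_cvd"
    assert c.combined["any_krt"] and c.combined["any_cvd"] and not c.combined["death"]


def test_censored_before_horizon_has_undefined_category():
    r = make_record(censor_time=1.0)
    c = classify_outcomes(r, horizon=2.0)
    assert c.censored_before_horizon and c.category is None
    assert c.combined is None and c.first_event_cause == "none"


def test_event_at_exact_horizon_counts():
    r = make_record(krt_time=2.0, censor_time=3.0)
    assert classify_outcomes(r, 2.0).category == "krt_only"


def test_simultaneous_times_resolve_deterministically():
    # krt == death -> death-containing category with krt counted as prior
    assert classify_outcomes(make_record(krt_time=1.0, death_time=1.0),
                             2.0).category == "death_after_krt"
    # krt == cvd -> krt first
    assert classify_outcomes(make_record(krt_time=1.0, cvd_time=1.0, censor_time=3.0),
                             2.0).category == "cvd_after_krt"


def test_nonpositive_horizon_is_domain_error():
    with pytest.raises(DomainError):
        classify_outcomes(make_record(), 0.0)


def _rule_table(krt, cvd, death, censor, horizon):
    """Independent brute-force classification: a literal rule table over
    which events fall inside the horizon and their order."""
    k = krt if krt is not None and krt <= horizon else None
    v = cvd if cvd is not None and cvd <= horizon else None
    d = death if death is not None and death <= horizon else None
    followed = (death if death is not None else censor) >= horizon
    if d is None and not followed:
        return None  # censored before horizon
    if d is not None:
        pk = k is not None and k <= d
        pv = v is not None and v <= d
        if pk and pv:
            return "death_after_krt_and_cvd"
        if pk:
            return "death_after_krt"
        if pv:
            return "death_after_cvd"
        return "death_only"
    if k is not None and v is not None:
        return "cvd_after_krt" if k <= v else "krt_after_cvd"
    if k is not None:
        return "krt_only"
    if v is not None:
        return "cvd_only"
    return "no_event"


def test_classification_agrees_with_bruteforce_rule_table():
    """Exhaustive sweep over presence patterns x time orderings on a grid."""
    grid = [0.5, 1.0, 1.5, 2.0, 2.5]
    horizon = 2.0
    checked = 0
    for k_on, v_on, d_on in itertools.product([False, True], repeat=3):
        for kt, vt, dt, ct in itertools.product(grid, repeat=4):
            krt = kt if k_on else None
            cvd = vt if v_on else None
            death = dt if d_on else None
            censor = None if d_on else ct
            # keep only invariant-respecting histories
            boundary = death if death is not None else censor
            if any(t is not None and t > boundary for t in (krt, cvd)):
                continue
            r = make_record(krt_time=krt, cvd_time=cvd,
                            **({"death_time": death} if d_on else {"censor_time": censor}))
            got = classify_outcomes(r, horizon)
            expected = _rule_table(krt, cvd, death, censor, horizon)
            if expected is None:
                assert got.censored_before_horizon and got.category is None
            else:
                assert got.category == expected, (krt, cvd, death, censor)
                # exactly one of the six combined flags per aggregation family
                assert got.combined["death"] == (
                    got.combined["death_without_krt"] or got.combined["death_after_krt"])
            checked += 1
    assert checked > 500


def test_classification_monotone_in_horizon():
    """An event counted at horizon h stays counted at h' > h for subjects
    followed to h'."""
    r = make_record(krt_time=0.8, cvd_time=1.7, censor_time=5.0)
    c2 = classify_outcomes(r, 2.0)
    c4 = classify_outcomes(r, 4.0)
    assert c2.combined["any_krt"] and c4.combined["any_krt"]
    assert c2.combined["any_cvd"] and c4.combined["any_cvd"]
    r2 = make_record(krt_time=0.8, death_time=3.0)
    assert classify_outcomes(r2, 2.0).category == "krt_only"
    assert classify_outcomes(r2, 4.0).category == "death_after_krt"
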