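"""Cohort data model, CSV I/O, predictor preprocessing and outcome-sequence
classification for advanced-CKD event histories.

A patient record carries the baseline predictors of the multinomial
competing-risks model (age, sex, race, CVD history, diabetes, smoking,
systolic blood pressure, eGFR, urine ACR) together with the raw event
history: times (in years from baseline) of KRT initiation, first
cardiovascular event and death, or an administrative censoring time.
Exactly one terminal boundary — death or censoring — is present per subject.

Raw histories are classified deterministically into the nine mutually
exclusive outcome sequences the model predicts (no event; KRT only; KRT
after CVD; CVD only; CVD after KRT; death only; death after KRT; death
after CVD; death after both) at a fixed horizon, plus the non-exclusive
combined endpoints used in the main validation (any KRT, any CVD, death,
death without/after KRT, no event).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .exceptions import ConfigurationError, DataError, DomainError

# --------------------------------------------------------------------------
# Outcome-sequence vocabulary
# --------------------------------------------------------------------------

NO_EVENT = "no_event"
KRT_ONLY = "krt_only"
KRT_AFTER_CVD = "krt_after_cvd"
CVD_ONLY = "cvd_only"
CVD_AFTER_KRT = "cvd_after_krt"
DEATH_ONLY = "death_only"
DEATH_AFTER_KRT = "death_after_krt"
DEATH_AFTER_CVD = "death_after_cvd"
DEATH_AFTER_KRT_AND_CVD = "death_after_krt_and_cvd"

#: The nine mutually exclusive outcome-sequence categories, reference first.
CATEGORIES: tuple[str, ...] = (
    NO_EVENT,
    KRT_ONLY,
    KRT_AFTER_CVD,
    CVD_ONLY,
    CVD_AFTER_KRT,
    DEATH_ONLY,
    DEATH_AFTER_KRT,
    DEATH_AFTER_CVD,
    DEATH_AFTER_KRT_AND_CVD,
)

#: The eight non-reference sequences, in the order model coefficient files use.
EVENT_CATEGORIES: tuple[str, ...] = CATEGORIES[1:]

#: Fixed mapping from combined (non-exclusive) endpoints to the sequence
#: categories they aggregate. ``death = death_without_krt + death_after_krt``
#: is a partition of the death categories.
COMBINED_ENDPOINTS: dict[str, frozenset[str]] = {
    "any_krt": frozenset(
        {KRT_ONLY, KRT_AFTER_CVD, CVD_AFTER_KRT, DEATH_AFTER_KRT, DEATH_AFTER_KRT_AND_CVD}
    ),
    "any_cvd": frozenset(
        {CVD_ONLY, KRT_AFTER_CVD, CVD_AFTER_KRT, DEATH_AFTER_CVD, DEATH_AFTER_KRT_AND_CVD}
    ),
    "death": frozenset(
        {DEATH_ONLY, DEATH_AFTER_KRT, DEATH_AFTER_CVD, DEATH_AFTER_KRT_AND_CVD}
    ),
    "death_without_krt": frozenset({DEATH_ONLY, DEATH_AFTER_CVD}),
    "death_after_krt": frozenset({DEATH_AFTER_KRT, DEATH_AFTER_KRT_AND_CVD}),
    "no_event": frozenset({NO_EVENT}),
}

COMBINED_NAMES: tuple[str, ...] = tuple(COMBINED_ENDPOINTS)


# --------------------------------------------------------------------------
# Patient record and cohort containers
# --------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """One subject: baseline covariates plus raw event-history times.

    Times are years from baseline. ``krt_time``/``cvd_time`` (first CVD)
    are present only if the event was observed; exactly one of
    ``death_time``/``censor_time`` terminates follow-up.
    """

    id: str
    age: float
    sex: str  # "male" | "female"
    race_black: bool
    cvd_history: bool
    diabetes: bool
    smoker: bool
    sbp: float
    egfr: float
    acr: Optional[float] = None
    pcr: Optional[float] = None
    hypertension: Optional[bool] = None
    krt_time: Optional[float] = None
    cvd_time: Optional[float] = None
    death_time: Optional[float] = None
    censor_time: Optional[float] = None

    def validate(self) -> None:
        """Raise :class:`DataError` on any invariant violation."""
        if self.sex not in ("male", "female"):
            raise DataError(f"record {self.id}: sex must be male/female, got {self.sex!r}")
        if not (self.egfr > 0):
            raise DataError(f"record {self.id}: egfr must be positive, got {self.egfr}")
        times = {
            "krt_time": self.krt_time,
            "cvd_time": self.cvd_time,
            "death_time": self.death_time,
            "censor_time": self.censor_time,
        }
        for name, t in times.items():
            if t is not None and (not math.isfinite(t) or t < 0):
                raise DataError(f"record {self.id}: {name} must be >= 0, got {t}")
        if (self.death_time is None) == (self.censor_time is None):
            raise DataError(
                f"record {self.id}: exactly one of death_time/censor_time required"
            )
        boundary = self.death_time if self.death_time is not None else self.censor_time
        for name in ("krt_time", "cvd_time"):
            t = times[name]
            if t is not None and t > boundary + 1e-12:
                raise DataError(
                    f"record {self.id}: {name}={t} exceeds terminal boundary {boundary}"
                )

    @property
    def followup_end(self) -> float:
        """Time at which the subject's history stops being observed."""
        return self.death_time if self.death_time is not None else self.censor_time  # type: ignore[return-value]


@dataclass
class Cohort:
    """Ordered collection of patient records with unique ids."""

    records: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate patient ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def require_nonempty(self) -> None:
        if not self.records:
            raise DataError("cohort is empty; analysis operations need >= 1 record")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {f.name: getattr(r, f.name) for f in fields(PatientRecord)}
            row["sex"] = "M" if r.sex == "male" else "F"
            rows.append(row)
        df = pd.DataFrame(rows, columns=[f.name for f in fields(PatientRecord)])
        return df


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

#: Default CSV column names; a dialect mapping can rename any of them.
DEFAULT_COLUMNS: tuple[str, ...] = tuple(f.name for f in fields(PatientRecord))

_REQUIRED = ("id", "age", "sex", "race_black", "cvd_history", "diabetes",
             "smoker", "sbp", "egfr")
_BOOL_FIELDS = ("race_black", "cvd_history", "diabetes", "smoker", "hypertension")
_TIME_FIELDS = ("krt_time", "cvd_time", "death_time", "censor_time")


def _parse_bool(value, column: str, row: int) -> bool:
    s = str(value).strip().lower()
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n"):
        return False
    raise DataError(f"row {row}: column {column!r} not interpretable as 0/1: {value!r}")


def _parse_sex(value, row: int) -> str:
    s = str(value).strip().lower()
    if s in ("m", "male", "1"):
        return "male"
    if s in ("f", "female", "0"):
        return "female"
    raise DataError(f"row {row}: sex not interpretable: {value!r}")


def load_cohort(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    provenance: str = "",
) -> Cohort:
    """Read a patient-level cohort CSV.

    Parameters
    ----------
    path
        CSV file with a mandatory header; empty cells are missing values.
    dialect
        Mapping of canonical field name -> column name in the file, for
        files using different headers. Unmapped fields keep default names.
    """
    dialect = dict(dialect or {})
    unknown = set(dialect) - set(DEFAULT_COLUMNS)
    if unknown:
        raise ConfigurationError(f"dialect maps unknown fields: {sorted(unknown)}")
    colname = {f: dialect.get(f, f) for f in DEFAULT_COLUMNS}

    df = pd.read_csv(path, dtype=str)
    missing = [colname[f] for f in _REQUIRED if colname[f] not in df.columns]
    if missing:
        raise ConfigurationError(f"required columns missing from {path}: {missing}")

    records: list[PatientRecord] = []
    for i, row in df.iterrows():
        def get(fname: str):
            col = colname[fname]
            if col not in df.columns:
                return None
            v = row[col]
            if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
                return None
            return v

        def get_float(fname: str, required: bool = False) -> Optional[float]:
            v = get(fname)
            if v is None:
                if required:
                    raise DataError(f"row {i}: required value {fname!r} missing")
                return None
            try:
                return float(v)
            except ValueError:
                raise DataError(f"row {i}: column {fname!r} not numeric: {v!r}") from None

        rid = get("id")
        if rid is None:
            raise DataError(f"row {i}: id missing")
        try:
            rec = PatientRecord(
                id=str(rid),
                age=get_float("age", required=True),  # type: ignore[arg-type]
                sex=_parse_sex(get("sex"), i),
                race_black=_parse_bool(get("race_black"), "race_black", i),
                cvd_history=_parse_bool(get("cvd_history"), "cvd_history", i),
                diabetes=_parse_bool(get("diabetes"), "diabetes", i),
                smoker=_parse_bool(get("smoker"), "smoker", i),
                sbp=get_float("sbp", required=True),  # type: ignore[arg-type]
                egfr=get_float("egfr", required=True),  # type: ignore[arg-type]
                acr=get_float("acr"),
                pcr=get_float("pcr"),
                hypertension=(
                    _parse_bool(get("hypertension"), "hypertension", i)
                    if get("hypertension") is not None else None
                ),
                krt_time=get_float("krt_time"),
                cvd_time=get_float("cvd_time"),
                death_time=get_float("death_time"),
                censor_time=get_float("censor_time"),
            )
            rec.validate()
        except DataError as e:
            raise DataError(f"row {i}: {e}") from None
        records.append(rec)
    return Cohort(records=records, provenance=provenance or str(path))


def save_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV in the default column layout (round-trips
    through :func:`load_cohort`)."""
    df = cohort.to_dataframe()
    bool_cols = [c for c in _BOOL_FIELDS if c in df.columns]
    for c in bool_cols:
        df[c] = df[c].map(lambda v: "" if v is None else int(bool(v)))
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# PCR -> ACR conversion
# --------------------------------------------------------------------------

def load_pcr_to_acr_coeffs(path=None) -> dict:
    """Load conversion coefficients from YAML (key ``pcr_to_acr``).

    With no path, the packaged default coefficient file is used. The default
    is the published crosswalk from urine protein-to-creatinine ratio to
    albumin-to-creatinine ratio: a piecewise-linear spline in ln(PCR) with
    knots at PCR 50 and 500 mg/g plus female/diabetes/hypertension
    indicator terms.
    """
    if path is None:
        src = resources.files("ckdval").joinpath("data/pcr_to_acr.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if "pcr_to_acr" not in raw:
        raise ConfigurationError("coefficient file lacks key 'pcr_to_acr'")
    return raw["pcr_to_acr"]


def convert_pcr_to_acr(
    pcr: float,
    sex: str,
    diabetes: bool,
    hypertension: bool,
    coeffs: Optional[Mapping[str, float]] = None,
) -> float:
    """Convert a urine protein-to-creatinine ratio (mg/g) to an estimated
    albumin-to-creatinine ratio (mg/g).

    ln(ACR) = b0 + b1·ln(min(PCR/50, 1)) + b2·ln(max(min(PCR/500, 1), 0.1))
              + b3·ln(max(PCR/500, 1)) + b_f·female + b_d·diabetes
              + b_h·hypertension
    """
    if coeffs is None:
        coeffs = load_pcr_to_acr_coeffs()
    if not (pcr > 0):
        raise DomainError(f"pcr must be positive, got {pcr}")
    female = 1.0 if sex == "female" else 0.0
    ln_acr = (
        coeffs["intercept"]
        + coeffs["spline_low"] * math.log(min(pcr / 50.0, 1.0))
        + coeffs["spline_mid"] * math.log(max(min(pcr / 500.0, 1.0), 0.1))
        + coeffs["spline_high"] * math.log(max(pcr / 500.0, 1.0))
        + coeffs["female"] * female
        + coeffs["diabetes"] * (1.0 if diabetes else 0.0)
        + coeffs["hypertension"] * (1.0 if hypertension else 0.0)
    )
    return math.exp(ln_acr)


def resolve_acr(
    cohort: Cohort,
    coeffs: Optional[Mapping[str, float]] = None,
    default_hypertension: bool = True,
) -> Cohort:
    """Return a cohort in which every record has an ACR.

    ACR present -> kept unchanged (conversion never overrides a measured
    value). ACR missing with PCR present -> converted. Both missing ->
    :class:`DataError` (imputation is out of scope; cohorts must be
    complete after this step). Records lacking a hypertension flag use
    ``default_hypertension`` (the validation population is predominantly
    hypertensive).
    """
    if coeffs is None:
        coeffs = load_pcr_to_acr_coeffs()
    out = []
    for r in cohort:
        if r.acr is not None:
            out.append(r)
        elif r.pcr is not None:
            htn = r.hypertension if r.hypertension is not None else default_hypertension
            acr = convert_pcr_to_acr(r.pcr, r.sex, r.diabetes, htn, coeffs)
            out.append(replace(r, acr=acr))
        else:
            raise DataError(f"record {r.id}: neither acr nor pcr present")
    return Cohort(records=out, provenance=cohort.provenance)


# --------------------------------------------------------------------------
# Outcome classification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeClassification:
    """Deterministic classification of one record at a fixed horizon."""

    category: Optional[str]
    horizon: float
    censored_before_horizon: bool
    combined: Optional[dict[str, bool]]
    first_event_cause: str  # "krt" | "cvd" | "death" | "none"
    first_event_time: Optional[float]


def _combined_flags(category: str) -> dict[str, bool]:
    return {name: category in members for name, members in COMBINED_ENDPOINTS.items()}


def classify_outcomes(record: PatientRecord, horizon: float) -> OutcomeClassification:
    """Classify a raw event history into one of the nine outcome sequences
    at ``horizon`` years.

    Only events at times <= horizon count (closed interval). Tie rules:
    an event at exactly the death time counts as preceding death (so a
    simultaneous KRT/death pair is "death after KRT"); a KRT/CVD tie puts
    KRT first. If the subject neither dies nor is followed to the horizon,
    the category is undefined and ``censored_before_horizon`` is set.
    """
    if not (horizon > 0):
        raise DomainError(f"horizon must be positive, got {horizon}")
    record.validate()

    krt = record.krt_time if record.krt_time is not None and record.krt_time <= horizon else None
    cvd = record.cvd_time if record.cvd_time is not None and record.cvd_time <= horizon else None
    death = (
        record.death_time
        if record.death_time is not None and record.death_time <= horizon
        else None
    )

    # first event among those within the horizon; tie priority death > krt > cvd
    candidates = [(t, c) for t, c in ((death, "death"), (krt, "krt"), (cvd, "cvd")) if t is not None]
    if candidates:
        first_time = min(t for t, _ in candidates)
        first_cause = next(c for t, c in candidates if t == first_time)
    else:
        first_time, first_cause = None, "none"

    if death is not None:
        prior_krt = krt is not None and krt <= death
        prior_cvd = cvd is not None and cvd <= death
        if prior_krt and prior_cvd:
            category = DEATH_AFTER_KRT_AND_CVD
        elif prior_krt:
            category = DEATH_AFTER_KRT
        elif prior_cvd:
            category = DEATH_AFTER_CVD
        else:
            category = DEATH_ONLY
    elif record.followup_end >= horizon:
        if krt is not None and cvd is not None:
            category = CVD_AFTER_KRT if krt <= cvd else KRT_AFTER_CVD
        elif krt is not None:
            category = KRT_ONLY
        elif cvd is not None:
            category = CVD_ONLY
        else:
            category = NO_EVENT
    else:
        return OutcomeClassification(
            category=None,
            horizon=horizon,
            censored_before_horizon=True,
            combined=None,
            first_event_cause=first_cause,
            first_event_time=first_time,
        )

    return OutcomeClassification(
        category=category,
        horizon=horizon,
        censored_before_horizon=False,
        combined=_combined_flags(category),
        first_event_cause=first_cause,
        first_event_time=first_time,
    )
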