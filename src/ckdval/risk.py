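"""Multinomial absolute-risk engine and the 4-variable KFRE comparator.

The prognostic model is a multinomial logistic model over the nine outcome
sequences with "no event" as reference: for non-reference category k,

    LP_k = intercept_k + sum_j beta_kj * transform_j(x_j)
    P(no_event) = 1 / (1 + sum_k exp(LP_k)),   P(k) = exp(LP_k) * P(no_event)

Predictor transforms are declarative — identity or natural log, followed by
a centering offset and scaling divisor — so the engine is coefficient-
agnostic: any coefficient file in the ModelSpec YAML format can be
evaluated, including synthetic test specs. Probabilities are computed with
log-sum-exp stabilisation and always sum to one to within 1e-12.

Combined (non-mutually-exclusive) endpoints — any KRT, any CVD, death,
death without/after KRT, no event — are fixed sums over the nine sequence
probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import logsumexp

from .cohort import (
    CATEGORIES,
    COMBINED_ENDPOINTS,
    COMBINED_NAMES,
    EVENT_CATEGORIES,
    NO_EVENT,
    Cohort,
    PatientRecord,
)
from .exceptions import ConfigurationError, DataError, DomainError

PROB_TOL = 1e-12


# --------------------------------------------------------------------------
# Model specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorSpec:
    """One predictor with its declarative transform.

    value -> (f(value) - offset) / scale, f = identity or natural log.
    """

    name: str
    transform: str = "identity"  # "identity" | "log"
    offset: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log"):
            raise ConfigurationError(f"unknown transform {self.transform!r}")
        if self.scale == 0:
            raise ConfigurationError(f"predictor {self.name}: scale must be nonzero")

    def apply(self, value: float) -> float:
        if self.transform == "log":
            if not (value > 0):
                raise DomainError(f"predictor {self.name}: log of non-positive {value}")
            value = math.log(value)
        return (value - self.offset) / self.scale


@dataclass
class ModelSpec:
    """Coefficient set for the multinomial sequence model at one horizon."""

    horizon: float
    categories: tuple[str, ...]
    predictors: tuple[PredictorSpec, ...]
    intercepts: np.ndarray  # (K,)
    coefficients: np.ndarray  # (K, P) row-major by category

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        k, p = len(self.categories), len(self.predictors)
        if self.intercepts.shape != (k,):
            raise ConfigurationError(
                f"intercepts shape {self.intercepts.shape} != ({k},)")
        if self.coefficients.shape != (k, p):
            raise ConfigurationError(
                f"coefficient matrix shape {self.coefficients.shape} != ({k}, {p})")


def load_model_spec(path) -> ModelSpec:
    """Load a ModelSpec from YAML (see the packaged synthetic example for
    the format)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        predictors = tuple(PredictorSpec(**p) for p in raw["predictors"])
        return ModelSpec(
            horizon=float(raw["horizon"]),
            categories=tuple(raw["categories"]),
            predictors=predictors,
            intercepts=np.asarray(raw["intercepts"], dtype=float),
            coefficients=np.asarray(raw["coefficients"], dtype=float),
        )
    except KeyError as e:
        raise ConfigurationError(f"model spec missing key: {e}") from None


def example_model_spec() -> ModelSpec:
    """The packaged SYNTHETIC demonstration spec (not the published model)."""
    src = resources.files("ckdval").joinpath("data/example_multinomial_synthetic.yaml")
    raw = yaml.safe_load(src.read_text())
    predictors = tuple(PredictorSpec(**p) for p in raw["predictors"])
    return ModelSpec(
        horizon=float(raw["horizon"]),
        categories=tuple(raw["categories"]),
        predictors=predictors,
        intercepts=np.asarray(raw["intercepts"], dtype=float),
        coefficients=np.asarray(raw["coefficients"], dtype=float),
    )


# --------------------------------------------------------------------------
# Risk vectors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryRiskVector:
    """Probabilities of the nine mutually exclusive outcome sequences."""

    probabilities: dict[str, float]
    horizon: float

    def __post_init__(self) -> None:
        if set(self.probabilities) != set(CATEGORIES):
            raise DataError("category risk vector must cover the 9 categories")
        vals = np.array([self.probabilities[c] for c in CATEGORIES])
        if np.any(vals < -PROB_TOL) or np.any(vals > 1 + PROB_TOL):
            raise DataError("probabilities outside [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise DataError(f"probabilities sum to {vals.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.probabilities[c] for c in CATEGORIES])


@dataclass(frozen=True)
class CombinedRiskVector:
    """Non-exclusive combined endpoint probabilities (need not sum to 1)."""

    any_krt: float
    any_cvd: float
    death: float
    death_without_krt: float
    death_after_krt: float
    no_event: float
    horizon: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COMBINED_NAMES}


# --------------------------------------------------------------------------
# Engine
# --------------------------------------------------------------------------

def _predictor_value(record: PatientRecord, name: str) -> float:
    if name == "male":
        return 1.0 if record.sex == "male" else 0.0
    if name == "female":
        return 1.0 if record.sex == "female" else 0.0
    if not hasattr(record, name):
        raise DataError(f"record {record.id}: unresolvable predictor {name!r}")
    v = getattr(record, name)
    if v is None:
        raise DataError(f"record {record.id}: predictor {name!r} missing")
    return float(v)


def linear_predictors(record: PatientRecord, spec: ModelSpec) -> np.ndarray:
    """Evaluate the 8 category linear predictors for one record."""
    x = np.array([p.apply(_predictor_value(record, p.name)) for p in spec.predictors])
    return spec.intercepts + spec.coefficients @ x


def multinomial_risks(lps: Sequence[float], horizon: float = 2.0,
                      categories: Sequence[str] = EVENT_CATEGORIES) -> CategoryRiskVector:
    """Softmax with a fixed reference category (no_event, LP ≡ 0).

    Uses log-sum-exp so arbitrarily large linear predictors do not
    overflow; the nine probabilities sum to one within 1e-12.
    """
    lps = np.asarray(lps, dtype=float)
    if lps.shape != (len(categories),):
        raise DomainError(f"expected {len(categories)} linear predictors, got {lps.shape}")
    if not np.all(np.isfinite(lps)):
        raise DomainError("non-finite linear predictor")
    full = np.concatenate(([0.0], lps))  # reference first
    log_probs = full - logsumexp(full)
    probs = np.exp(log_probs)
    probs /= probs.sum()  # removes the last O(eps) drift
    mapping = {NO_EVENT: float(probs[0])}
    mapping.update({c: float(p) for c, p in zip(categories, probs[1:])})
    return CategoryRiskVector(probabilities=mapping, horizon=horizon)


def aggregate_combined(v: CategoryRiskVector) -> CombinedRiskVector:
    """Aggregate the nine sequence probabilities to the combined endpoints."""
    p = v.probabilities
    vals = {
        name: float(sum(p[c] for c in members))
        for name, members in COMBINED_ENDPOINTS.items()
    }
    return CombinedRiskVector(horizon=v.horizon, **vals)


def predict_record(record: PatientRecord, spec: ModelSpec) -> CategoryRiskVector:
    """End-to-end absolute risks for one record under a ModelSpec."""
    return multinomial_risks(
        linear_predictors(record, spec), horizon=spec.horizon, categories=spec.categories
    )


def predict_cohort(cohort: Cohort, spec: ModelSpec) -> pd.DataFrame:
    """Per-patient risk table: the 9 sequence probabilities and 6 combined
    endpoints, one row per record (id-indexed)."""
    cohort.require_nonempty()
    rows = []
    for r in cohort:
        v = predict_record(r, spec)
        # sequence categories get a seq_ prefix: two combined endpoints
        # (death_after_krt, no_event) share names with categories
        row = {"id": r.id}
        row.update({f"seq_{c}": p for c, p in v.probabilities.items()})
        row.update(aggregate_combined(v).as_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


# --------------------------------------------------------------------------
# KFRE comparator
# --------------------------------------------------------------------------

def load_kfre_spec(path=None) -> dict:
    """Load a KFRE coefficient set; default is the packaged published
    4-variable, 2-year equation."""
    if path is None:
        src = resources.files("ckdval").joinpath("data/kfre_2yr.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if "kfre" not in raw:
        raise ConfigurationError("KFRE file lacks key 'kfre'")
    return raw["kfre"]


_KFRE_INPUTS = {
    "age_per_10yr": lambda r: r.age / 10.0,
    "male": lambda r: 1.0 if r.sex == "male" else 0.0,
    "egfr_per_5": lambda r: r.egfr / 5.0,
    "log_acr": lambda r: math.log(r.acr),
}


def kfre_risk(record: PatientRecord, spec: Optional[Mapping] = None) -> float:
    """Kidney-failure probability from the 4-variable KFRE.

    risk = 1 - S0 ^ exp(sum_j beta_j (t_j(x_j) - center_j)) with the
    published centering constants; strictly decreasing in eGFR and
    increasing in ACR.
    """
    if spec is None:
        spec = load_kfre_spec()
    if record.acr is None:
        raise DataError(f"record {record.id}: acr required for KFRE (resolve_acr first)")
    lp = 0.0
    for term in spec["terms"]:
        name = term["name"]
        if name not in _KFRE_INPUTS:
            raise ConfigurationError(f"unknown KFRE term {name!r}")
        lp += term["beta"] * (_KFRE_INPUTS[name](record) - term["center"])
    return 1.0 - spec["baseline_survival"] ** math.exp(lp)


def kfre_cohort(cohort: Cohort, spec: Optional[Mapping] = None) -> pd.Series:
    """KFRE risk per record, id-indexed."""
    cohort.require_nonempty()
    if spec is None:
        spec = load_kfre_spec()
    return pd.Series({r.id: kfre_risk(r, spec) for r in cohort}, name="kfre_risk")
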