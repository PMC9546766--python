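"""Multistate competing-risks cohort simulator with analytic risk oracles.

The generator emulates the covariate structure of an elderly advanced-CKD
validation cohort (age median 76, 66% male, eGFR 18 +/- 4 truncated to the
10-30 ml/min/1.73m^2 inclusion window, heavily right-skewed albuminuria)
and produces event histories from a multistate process over first events
{KRT, CVD, death} with cause-specific hazards

    lambda_k(x) = lambda0_k * exp(beta_k . z(x))

over standardised covariates z. After a non-death first event the remaining
cause hazards are multiplied by post-event modifiers and the clock restarts
(semi-Markov); death absorbs; an administrative censoring time drawn
uniformly on a window truncates observation. Because all sojourn hazards
are constant given x, the semi-Markov restart is immaterial and the process
is a 9-state continuous-time Markov chain, so the exact probability of each
of the nine outcome sequences at any horizon is available from a matrix
exponential — the per-subject "true risk" oracle used for end-to-end
parameter-recovery tests.

Randomness: one independent child stream per subject, spawned from the
master seed, so the first m subjects of a size-n cohort are identical to a
size-m cohort (prefix stability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import expm
from scipy.stats import norm, truncnorm

from .cohort import CATEGORIES, Cohort, PatientRecord
from .exceptions import ConfigurationError
from .risk import CategoryRiskVector, aggregate_combined

CAUSES = ("krt", "cvd", "death")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Generating process parameters; defaults emulate the target cohort.

    covariates: per-covariate distribution parameters. ``age`` and ``egfr``
    are truncated normals (location solved so the age population median is
    76 years within the 65-100 support); ``acr`` is log-normal (median
    391 mg/g) clipped to [1, 25000]; binaries are Bernoulli prevalences.

    hazards: baseline first-event rates per year. betas: log hazard ratios
    per standard-deviation of each covariate. post_event: multiplicative
    hazard modifiers applied after a non-death first event (modifiers on
    the death hazard compound when both KRT and CVD have occurred).
    """

    n: int = 1517
    seed: int = 0
    covariates: dict = field(default_factory=lambda: {
        "age": {"dist": "truncnorm", "loc": 74.9300791591636, "scale": 8.0,
                "low": 65.0, "high": 100.0},
        "male": {"dist": "bernoulli", "p": 0.66},
        "race_black": {"dist": "bernoulli", "p": 0.013},
        "cvd_history": {"dist": "bernoulli", "p": 0.397},
        "diabetes": {"dist": "bernoulli", "p": 0.423},
        "smoker": {"dist": "bernoulli", "p": 0.09},
        "hypertension": {"dist": "bernoulli", "p": 0.892},
        "sbp": {"dist": "normal", "loc": 143.0, "scale": 22.0},
        "egfr": {"dist": "truncnorm", "loc": 18.0, "scale": 4.0,
                 "low": 10.0, "high": 30.0},
        "acr": {"dist": "lognormal", "log_median": math.log(391.0),
                "log_sd": 2.456, "low": 1.0, "high": 25000.0},
    })
    hazards: dict = field(default_factory=lambda: {
        # calibrated so default 2-year marginal any-KRT / any-CVD / death
        # land near 0.196 / 0.204 / 0.204 (see docs/methods.md)
        "krt": 0.0978, "cvd": 0.1044, "death": 0.0728,
    })
    betas: dict = field(default_factory=lambda: {
        "krt": {"egfr": -0.8, "log_acr": 0.5, "age": -0.2, "diabetes": 0.1},
        "cvd": {"age": 0.3, "cvd_history": 0.4, "diabetes": 0.25,
                "sbp": 0.2, "smoker": 0.15, "egfr": -0.1},
        "death": {"age": 0.5, "cvd_history": 0.3, "diabetes": 0.15,
                  "smoker": 0.2, "egfr": -0.2},
    })
    post_event: dict = field(default_factory=lambda: {
        "death_after_krt": 1.6, "death_after_cvd": 2.2,
        "krt_after_cvd": 1.3, "cvd_after_krt": 1.3,
    })
    censoring: dict = field(default_factory=lambda: {"min": 1.0, "max": 6.0})

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        for k, v in self.hazards.items():
            if v < 0:
                raise ConfigurationError(f"hazard {k} must be >= 0, got {v}")
        cmin, cmax = self.censoring["min"], self.censoring["max"]
        if not (0 < cmin <= cmax):
            raise ConfigurationError("censoring window needs max >= min > 0")
        for name, spec in self.covariates.items():
            if spec["dist"] == "bernoulli" and not (0 <= spec["p"] <= 1):
                raise ConfigurationError(f"prevalence of {name} outside [0, 1]")
            if spec["dist"] in ("normal", "truncnorm") and spec["scale"] <= 0:
                raise ConfigurationError(f"scale of {name} must be positive")
        for cause in CAUSES:
            for cov in self.betas.get(cause, {}):
                if cov not in self._z_names():
                    raise ConfigurationError(f"beta on unknown covariate {cov!r}")

    def _z_names(self) -> tuple[str, ...]:
        return ("age", "male", "race_black", "cvd_history", "diabetes",
                "smoker", "hypertension", "sbp", "egfr", "log_acr")


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg


def config_to_yaml(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


# --------------------------------------------------------------------------
# Covariate sampling
# --------------------------------------------------------------------------

_U_COLS = ("age", "male", "race_black", "cvd_history", "diabetes", "smoker",
           "hypertension", "sbp", "egfr", "acr")


def _subject_rngs(config: SimulationConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(config.n)
    return [np.random.default_rng(c) for c in children]


def _covariates_from_uniforms(u: np.ndarray, config: SimulationConfig) -> pd.DataFrame:
    cols = {}
    for j, name in enumerate(_U_COLS):
        spec = config.covariates[name]
        uj = u[:, j]
        if spec["dist"] == "bernoulli":
            cols[name] = uj < spec["p"]
        elif spec["dist"] == "normal":
            cols[name] = norm.ppf(uj, loc=spec["loc"], scale=spec["scale"])
        elif spec["dist"] == "truncnorm":
            a = (spec["low"] - spec["loc"]) / spec["scale"]
            b = (spec["high"] - spec["loc"]) / spec["scale"]
            cols[name] = truncnorm.ppf(uj, a, b, loc=spec["loc"], scale=spec["scale"])
        elif spec["dist"] == "lognormal":
            v = np.exp(norm.ppf(uj, loc=spec["log_median"], scale=spec["log_sd"]))
            cols[name] = np.clip(v, spec["low"], spec["high"])
        else:
            raise ConfigurationError(f"unknown distribution {spec['dist']!r} for {name}")
    return pd.DataFrame(cols)


def sample_covariates(config: SimulationConfig,
                      rngs: Optional[list[np.random.Generator]] = None) -> pd.DataFrame:
    """Draw the baseline covariate table (deterministic given the seed)."""
    config.validate()
    if rngs is None:
        rngs = _subject_rngs(config)
    u = np.vstack([rng.random(len(_U_COLS)) for rng in rngs])
    return _covariates_from_uniforms(u, config)


def standardized(covariates: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Z-scores using the configured (not sample) location/scale: continuous
    covariates by (x - loc)/scale, ACR on the log scale, binaries by
    (x - p)/sqrt(p(1-p))."""
    z = {}
    for name in config._z_names():
        if name == "log_acr":
            spec = config.covariates["acr"]
            z[name] = (np.log(covariates["acr"]) - spec["log_median"]) / spec["log_sd"]
            continue
        spec = config.covariates[name]
        x = covariates[name].astype(float)
        if spec["dist"] == "bernoulli":
            p = spec["p"]
            sd = math.sqrt(p * (1 - p)) if 0 < p < 1 else 1.0
            z[name] = (x - p) / sd
        else:
            z[name] = (x - spec["loc"]) / spec["scale"]
    return pd.DataFrame(z)


def cause_specific_rates(covariates: pd.DataFrame,
                         config: SimulationConfig) -> pd.DataFrame:
    """Per-subject first-event hazards lambda_k(x) for the three causes."""
    z = standardized(covariates, config)
    out = {}
    for cause in CAUSES:
        lp = np.zeros(len(covariates))
        for cov, beta in config.betas.get(cause, {}).items():
            lp += beta * z[cov].to_numpy()
        out[cause] = config.hazards[cause] * np.exp(lp)
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# Event-history simulation
# --------------------------------------------------------------------------

def simulate_history(rates: dict, config: SimulationConfig,
                     rng: np.random.Generator) -> dict:
    """One subject's observed history given first-event rates.

    Returns krt_time / cvd_time / death_time / censor_time (None when
    unobserved). The latent process runs to absorption; administrative
    censoring then truncates what is observed.
    """
    m = config.post_event

    def draw(rate: float) -> float:
        e = rng.exponential()  # one draw per potential transition, fixed order
        return e / rate if rate > 0 else math.inf

    censor = rng.uniform(config.censoring["min"], config.censoring["max"])

    t = 0.0
    latent: dict[str, float] = {}
    r_krt, r_cvd, r_death = rates["krt"], rates["cvd"], rates["death"]
    while True:
        active = {}
        if "krt" not in latent:
            active["krt"] = r_krt
        if "cvd" not in latent:
            active["cvd"] = r_cvd
        active["death"] = r_death
        waits = {k: draw(v) for k, v in active.items()}
        cause = min(waits, key=lambda k: (waits[k], CAUSES.index(k)))
        if math.isinf(waits[cause]):
            break
        t += waits[cause]
        latent[cause] = t
        if cause == "death":
            break
        if cause == "krt":
            r_cvd *= m.get("cvd_after_krt", 1.0)
            r_death *= m.get("death_after_krt", 1.0)
        else:
            r_krt *= m.get("krt_after_cvd", 1.0)
            r_death *= m.get("death_after_cvd", 1.0)

    death = latent.get("death")
    if death is not None and death <= censor:
        boundary, censored = death, False
    else:
        boundary, censored = censor, True
    out = {
        "krt_time": latent.get("krt") if latent.get("krt", math.inf) <= boundary else None,
        "cvd_time": latent.get("cvd") if latent.get("cvd", math.inf) <= boundary else None,
        "death_time": None if censored else death,
        "censor_time": boundary if censored else None,
    }
    return out


# --------------------------------------------------------------------------
# Analytic oracle
# --------------------------------------------------------------------------

# CTMC states: 0 baseline, 1 KRT, 2 CVD, 3 KRT->CVD, 4 CVD->KRT,
# 5..8 absorbing death states by history (none, KRT, CVD, both).
_STATE_TO_CATEGORY = {
    0: "no_event", 1: "krt_only", 2: "cvd_only", 3: "cvd_after_krt",
    4: "krt_after_cvd", 5: "death_only", 6: "death_after_krt",
    7: "death_after_cvd", 8: "death_after_krt_and_cvd",
}


def _generator_matrix(rates: dict, post_event: dict) -> np.ndarray:
    k, c, d = rates["krt"], rates["cvd"], rates["death"]
    m_ck = post_event.get("cvd_after_krt", 1.0)
    m_kc = post_event.get("krt_after_cvd", 1.0)
    m_dk = post_event.get("death_after_krt", 1.0)
    m_dc = post_event.get("death_after_cvd", 1.0)
    Q = np.zeros((9, 9))
    Q[0, 1], Q[0, 2], Q[0, 5] = k, c, d
    Q[1, 3], Q[1, 6] = c * m_ck, d * m_dk
    Q[2, 4], Q[2, 7] = k * m_kc, d * m_dc
    Q[3, 8] = d * m_dk * m_dc
    Q[4, 8] = d * m_dk * m_dc
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def true_category_risks(rates: dict, config: SimulationConfig,
                        horizon: float) -> CategoryRiskVector:
    """Exact outcome-sequence probabilities at ``horizon`` for one subject
    under the generating process (no censoring), via the matrix exponential
    of the 9-state generator."""
    if horizon < 0:
        raise ConfigurationError("horizon must be >= 0")
    P = expm(_generator_matrix(rates, config.post_event) * horizon)
    row = P[0]
    row = np.clip(row, 0.0, 1.0)
    row = row / row.sum()
    probs = {_STATE_TO_CATEGORY[s]: float(row[s]) for s in range(9)}
    return CategoryRiskVector(probabilities=probs, horizon=horizon)


def oracle_risk_table(covariates: pd.DataFrame, config: SimulationConfig,
                      horizon: float) -> pd.DataFrame:
    """Per-subject true sequence and combined-endpoint probabilities."""
    rates = cause_specific_rates(covariates, config)
    rows = []
    for i in range(len(covariates)):
        v = true_category_risks(
            {c: rates[c].iloc[i] for c in CAUSES}, config, horizon)
        row = {f"seq_{c}": p for c, p in v.probabilities.items()}
        row.update(aggregate_combined(v).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def first_event_closed_form(rates: dict, horizon: float) -> dict:
    """Closed-form P(first event is cause k by tau) for constant competing
    exponentials: (lambda_k / Lambda) * (1 - exp(-Lambda * tau))."""
    lam = np.array([rates[c] for c in CAUSES], dtype=float)
    total = lam.sum()
    if total == 0:
        return {c: 0.0 for c in CAUSES}
    p = lam / total * (1.0 - math.exp(-total * horizon))
    return dict(zip(CAUSES, p))


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig, with_oracle: bool = False,
                    oracle_horizons: tuple[float, ...] = (2.0,)
                    ) -> tuple[Cohort, Optional[dict[float, pd.DataFrame]]]:
    """Full synthetic cohort (and, optionally, per-subject true risks).

    Returns ``(cohort, oracle)`` where ``oracle`` maps horizon ->
    per-subject risk table (or None when not requested).
    """
    config.validate()
    rngs = _subject_rngs(config)
    covariates = sample_covariates(config, rngs=rngs)
    rates = cause_specific_rates(covariates, config)

    width = len(str(config.n))
    records = []
    for i in range(config.n):
        hist = simulate_history(
            {c: float(rates[c].iloc[i]) for c in CAUSES}, config, rngs[i])
        rec = PatientRecord(
            id=f"s{i:0{width}d}",
            age=float(covariates["age"].iloc[i]),
            sex="male" if covariates["male"].iloc[i] else "female",
            race_black=bool(covariates["race_black"].iloc[i]),
            cvd_history=bool(covariates["cvd_history"].iloc[i]),
            diabetes=bool(covariates["diabetes"].iloc[i]),
            smoker=bool(covariates["smoker"].iloc[i]),
            hypertension=bool(covariates["hypertension"].iloc[i]),
            sbp=float(covariates["sbp"].iloc[i]),
            egfr=float(covariates["egfr"].iloc[i]),
            acr=float(covariates["acr"].iloc[i]),
            **hist,
        )
        rec.validate()
        records.append(rec)
    cohort = Cohort(records=records, provenance=f"synthetic seed={config.seed}")

    oracle = None
    if with_oracle:
        oracle = {h: oracle_risk_table(covariates, config, h) for h in oracle_horizons}
    return cohort, oracle
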