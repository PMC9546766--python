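"""Referral decision rules, diagnostic tables and decision-curve analysis.

A referral rule flags patients for vascular-access (AVF) preparation from
either a predicted 2-year KRT risk (flag when risk > cutoff, strict) or an
eGFR threshold (flag when eGFR < cutoff, strict), or the logical OR of
sub-rules (the guideline "2-year KRT risk >50% and/or eGFR <15"). Flags are
scored against KRT initiation within 1 year: initiation within the window
is the positive outcome, anything else (no event, death, censoring) is
negative — censoring inside the window is deliberately ignored, mirroring
how such clinical-impact projections are usually reported.

Net benefit at a threshold probability p_t (the harm-benefit ratio):

    NB = TP/n - (FP/n) * p_t / (1 - p_t)

Decision curves tabulate NB over a p_t grid for each rule next to the
treat-all and treat-none references. Diagnostic proportions carry Wilson
score intervals and integer-percent rounding (half away from zero) for
reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort
from .exceptions import ConfigurationError, DataError, DomainError


# --------------------------------------------------------------------------
# Rules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionRule:
    """A referral rule: risk threshold, eGFR threshold, or OR-composite."""

    kind: str  # "risk_threshold" | "egfr_threshold" | "composite_or"
    name: str = ""
    risk_cutoff: Optional[float] = None
    egfr_cutoff: Optional[float] = None
    components: tuple["DecisionRule", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "risk_threshold":
            if self.risk_cutoff is None or not (0 < self.risk_cutoff < 1):
                raise ConfigurationError("risk_threshold needs risk_cutoff in (0, 1)")
        elif self.kind == "egfr_threshold":
            if self.egfr_cutoff is None or self.egfr_cutoff <= 0:
                raise ConfigurationError("egfr_threshold needs positive egfr_cutoff")
        elif self.kind == "composite_or":
            if len(self.components) < 2:
                raise ConfigurationError("composite_or needs >= 2 components")
        else:
            raise ConfigurationError(f"unknown rule kind {self.kind!r}")
        if not self.name:
            object.__setattr__(self, "name", self._default_name())

    def _default_name(self) -> str:
        if self.kind == "risk_threshold":
            return f"2-yr KRT risk >{self.risk_cutoff:.0%}"
        if self.kind == "egfr_threshold":
            return f"eGFR <{self.egfr_cutoff:g}"
        return " or ".join(c.name for c in self.components)


def default_rules() -> list[DecisionRule]:
    """The predefined referral-rule set: eGFR <30/<25/<20/<15, 2-year KRT
    risk >20/30/40/50%, and the composite risk>50% or eGFR<15 guideline."""
    egfr = [DecisionRule("egfr_threshold", egfr_cutoff=c) for c in (30, 25, 20, 15)]
    risk = [DecisionRule("risk_threshold", risk_cutoff=c) for c in (0.2, 0.3, 0.4, 0.5)]
    combo = DecisionRule(
        "composite_or",
        components=(
            DecisionRule("risk_threshold", risk_cutoff=0.5),
            DecisionRule("egfr_threshold", egfr_cutoff=15),
        ),
    )
    return egfr + risk + [combo]


def apply_rule(cohort: Cohort, preds: Optional[Sequence[float]],
               rule: DecisionRule) -> np.ndarray:
    """Per-subject referral flags. Risk rules need ``preds`` (2-year
    any-KRT risk, aligned with the cohort); comparisons are strict
    (risk > cutoff, eGFR < cutoff)."""
    cohort.require_nonempty()
    n = len(cohort)
    if rule.kind == "risk_threshold":
        if preds is None:
            raise ConfigurationError(f"rule {rule.name!r} needs predictions")
        preds = np.asarray(preds, dtype=float)
        if preds.shape != (n,):
            raise DataError("predictions not aligned with cohort")
        return preds > rule.risk_cutoff
    if rule.kind == "egfr_threshold":
        egfr = np.array([r.egfr for r in cohort], dtype=float)
        return egfr < rule.egfr_cutoff
    flags = np.zeros(n, dtype=bool)
    for c in rule.components:
        flags |= apply_rule(cohort, preds, c)
    return flags


# --------------------------------------------------------------------------
# Contingency and diagnostics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def total_referrals(self) -> int:
        return self.tp + self.fp


def contingency(flags: Sequence[bool], cohort: Cohort,
                window: float = 1.0) -> ContingencyTable:
    """Score referral flags against KRT initiation within ``window`` years.

    Positive outcome: krt_time <= window. Everything else — including
    subjects censored or dying inside the window — counts as negative.
    """
    if not (window > 0):
        raise DomainError(f"window must be positive, got {window}")
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (len(cohort),):
        raise DataError("flags not aligned with cohort")
    outcome = np.array(
        [r.krt_time is not None and r.krt_time <= window for r in cohort]
    )
    tp = int((flags & outcome).sum())
    fp = int((flags & ~outcome).sum())
    fn = int((~flags & outcome).sum())
    tn = int((~flags & ~outcome).sum())
    return ContingencyTable(tp=tp, fp=fp, tn=tn, fn=fn)


def round_percent(x: float) -> int:
    """Round a proportion to the nearest integer percent, halves away from
    zero (so 76.5% -> 77)."""
    return int(math.floor(x * 100.0 + 0.5))


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity / specificity / PPV / NPV with Wilson score intervals.

    A measure whose denominator is zero is None (flagged undefined, never
    fabricated). ``*_pct`` fields are integer-percent renderings for
    reporting.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    sensitivity_ci: Optional[tuple[float, float]]
    specificity_ci: Optional[tuple[float, float]]
    ppv_ci: Optional[tuple[float, float]]
    npv_ci: Optional[tuple[float, float]]
    total_referrals: int
    ci_method: str = "wilson"

    def percents(self) -> dict[str, Optional[int]]:
        return {
            name: (None if v is None else round_percent(v))
            for name, v in (("sensitivity", self.sensitivity),
                            ("specificity", self.specificity),
                            ("ppv", self.ppv), ("npv", self.npv))
        }


def _prop(successes: int, total: int, level: float):
    if total == 0:
        return None, None
    p = successes / total
    lo, hi = proportion_confint(successes, total, alpha=1 - level, method="wilson")
    return p, (float(lo), float(hi))


def diagnostics(t: ContingencyTable, level: float = 0.95) -> DiagnosticSummary:
    """Diagnostic measures of a referral rule against 1-year KRT initiation."""
    sens, sens_ci = _prop(t.tp, t.tp + t.fn, level)
    spec, spec_ci = _prop(t.tn, t.tn + t.fp, level)
    ppv, ppv_ci = _prop(t.tp, t.tp + t.fp, level)
    npv, npv_ci = _prop(t.tn, t.tn + t.fn, level)
    return DiagnosticSummary(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        sensitivity_ci=sens_ci, specificity_ci=spec_ci, ppv_ci=ppv_ci, npv_ci=npv_ci,
        total_referrals=t.total_referrals,
    )


# --------------------------------------------------------------------------
# Net benefit and decision curves
# --------------------------------------------------------------------------

def net_benefit(t: ContingencyTable, n: int, p_t: float) -> float:
    """NB = TP/n - (FP/n) * p_t / (1 - p_t)."""
    if not (0 < p_t < 1):
        raise DomainError(f"threshold probability must be in (0, 1), got {p_t}")
    if n != t.n:
        raise DataError(f"n={n} != table total {t.n}")
    return t.tp / n - (t.fp / n) * p_t / (1.0 - p_t)


def default_grid(start: float = 0.01, stop: float = 0.50,
                 step: float = 0.01) -> np.ndarray:
    """Default threshold-probability grid 0.01–0.50 in steps of 0.01."""
    return np.round(np.arange(start, stop + step / 2, step), 10)


@dataclass
class DecisionCurve:
    """Tidy net-benefit table over a p_t grid: one row per (rule, p_t),
    including treat-all and treat-none references."""

    table: pd.DataFrame  # columns: rule, threshold, net_benefit
    prevalence: float


def decision_curve(cohort: Cohort, preds: Optional[Sequence[float]],
                   rules: Sequence[DecisionRule],
                   grid: Optional[Sequence[float]] = None,
                   window: float = 1.0) -> DecisionCurve:
    """Decision-curve analysis of a rule set.

    Each rule yields fixed flags, so its net benefit varies over the grid
    only through the false-positive weight p_t/(1-p_t). Treat-all and
    treat-none references are always included; treat-none is identically 0
    and treat-all equals pi - (1-pi) * p_t/(1-p_t) with pi the 1-year KRT
    prevalence.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(grid >= 1):
        raise DomainError("p_t grid must be non-empty and within (0, 1)")
    n = len(cohort)
    rows = []
    all_flags = np.ones(n, dtype=bool)
    none_flags = np.zeros(n, dtype=bool)
    named = [("treat_all", all_flags), ("treat_none", none_flags)]
    named += [(rule.name, apply_rule(cohort, preds, rule)) for rule in rules]
    for name, flags in named:
        tab = contingency(flags, cohort, window=window)
        for p_t in grid:
            rows.append({"rule": name, "threshold": float(p_t),
                         "net_benefit": net_benefit(tab, n, float(p_t))})
    prevalence = contingency(all_flags, cohort, window=window).tp / n
    return DecisionCurve(table=pd.DataFrame(rows), prevalence=prevalence)


def diagnostics_table(cohort: Cohort, preds: Optional[Sequence[float]],
                      rules: Sequence[DecisionRule], window: float = 1.0,
                      level: float = 0.95) -> pd.DataFrame:
    """Table of counts and diagnostic measures, one row per rule (the
    shape of a published impact-projection table)."""
    rows = []
    for rule in rules:
        flags = apply_rule(cohort, preds, rule)
        tab = contingency(flags, cohort, window=window)
        d = diagnostics(tab, level=level)
        pct = d.percents()
        row = {
            "rule": rule.name, "total_referrals": tab.total_referrals,
            "tp": tab.tp, "fp": tab.fp, "tn": tab.tn, "fn": tab.fn,
        }
        for m in ("sensitivity", "specificity", "ppv", "npv"):
            row[m] = getattr(d, m)
            ci = getattr(d, f"{m}_ci")
            row[f"{m}_pct"] = pct[m]
            row[f"{m}_ci_low"] = None if ci is None else ci[0]
            row[f"{m}_ci_high"] = None if ci is None else ci[1]
        rows.append(row)
    return pd.DataFrame(rows)
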