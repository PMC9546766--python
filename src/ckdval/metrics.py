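"""Discrimination and calibration metrics for competing-risks validation.

Discrimination uses the concordance statistic adapted to competing events:
subjects who experience the competing event are kept in the comparison as
"never experiences the event of interest" comparators rather than being
censored away. With everything truncated at the validation horizon, a pair
(i, j) with i experiencing the event of interest at T_i is comparable when
j's event-free status is known beyond T_i — j has the event later, j has a
competing event (event-free for all time), or j is censored after T_i.
The pair is concordant when the predicted risk of i exceeds that of j;
prediction ties count 1/2. On data without competing events this reduces
exactly to Harrell's C.

Calibration compares mean predicted risk with the Aalen–Johansen observed
cumulative incidence at the horizon: overall (calibration-in-the-large) and
within groups ranked by predicted risk (the calibration-plot deciles).
Confidence intervals are seeded percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError, UndefinedResultError
from .incidence import CENSORED, COMPETING, EVENT, FirstEventData, aalen_johansen, cif_at


# --------------------------------------------------------------------------
# Concordance
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceResult:
    c: float
    comparable_pairs: int
    concordant: int
    tied: int
    horizon: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def wolbers_c(pred: Sequence[float], data: FirstEventData, horizon: float,
              event_cause: str = EVENT) -> ConcordanceResult:
    """Competing-risks concordance at a fixed horizon.

    Parameters
    ----------
    pred
        Predicted risk of the event of interest, one per subject (higher =
        riskier). Any strictly monotone transform gives the same c.
    data
        First-event coding; causes other than ``event_cause`` and
        ``censored`` are treated as competing events.
    horizon
        Events after the horizon are recoded as censored at the horizon.
    """
    pred = np.asarray(pred, dtype=float)
    if pred.shape != data.time.shape:
        raise DomainError("pred and data must be aligned")
    d = data.truncated(horizon)
    is_event = d.cause == event_cause
    is_competing = (d.cause != event_cause) & (d.cause != CENSORED)
    t = d.time

    concordant_w = 0.0  # concordant + 0.5*tied, accumulated
    concordant = 0
    tied = 0
    pairs = 0
    for i in np.flatnonzero(is_event):
        ti = t[i]
        # comparable j: competing (any time), or event/censored strictly after ti
        comp = is_competing | (t > ti)
        comp[i] = False
        n_comp = int(comp.sum())
        if n_comp == 0:
            continue
        pairs += n_comp
        diff = pred[i] - pred[comp]
        concordant += int((diff > 0).sum())
        tied += int((diff == 0).sum())
    if pairs == 0:
        raise UndefinedResultError("no comparable pairs at this horizon")
    concordant_w = concordant + 0.5 * tied
    return ConcordanceResult(
        c=concordant_w / pairs,
        comparable_pairs=pairs,
        concordant=concordant,
        tied=tied,
        horizon=horizon,
    )


def binary_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Mann–Whitney area under the ROC curve (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedResultError("binary AUC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

def calibration_in_the_large(pred: Sequence[float], data: FirstEventData,
                             horizon: float,
                             event_cause: str = EVENT) -> tuple[float, float]:
    """(mean predicted risk, observed Aalen–Johansen incidence at horizon)."""
    pred = np.asarray(pred, dtype=float)
    if pred.shape != data.time.shape:
        raise DomainError("pred and data must be aligned")
    est = aalen_johansen(data.truncated(horizon))
    observed = cif_at(est, horizon).get(event_cause, 0.0)
    return float(pred.mean()), float(observed)


@dataclass
class CalibrationTable:
    """Grouped calibration: one row per risk group plus the overall pair."""

    groups: pd.DataFrame  # columns: group, n, mean_predicted, observed[, ci_low, ci_high]
    overall: tuple[float, float]
    horizon: float


def calibration_groups(pred: Sequence[float], data: FirstEventData,
                       horizon: float, n_groups: int = 10,
                       event_cause: str = EVENT) -> CalibrationTable:
    """Calibration table over ``n_groups`` near-equal groups ranked by
    predicted risk (group sizes differ by at most one; the remainder goes
    to the lowest-risk groups). Observed risk per group is the within-group
    Aalen–Johansen incidence at the horizon."""
    if n_groups < 2:
        raise ConfigurationError("n_groups must be >= 2")
    pred = np.asarray(pred, dtype=float)
    n = pred.size
    if n < n_groups:
        raise DomainError(f"cohort size {n} < n_groups {n_groups}")
    order = np.argsort(pred, kind="stable")
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if g < rem else 0) for g in range(n_groups)]
    rows = []
    start = 0
    for g, size in enumerate(sizes):
        idx = order[start:start + size]
        start += size
        mean_pred = float(pred[idx].mean())
        est = aalen_johansen(data.subset(idx).truncated(horizon))
        observed = cif_at(est, horizon).get(event_cause, 0.0)
        rows.append({"group": g + 1, "n": size,
                     "mean_predicted": mean_pred, "observed": observed})
    overall = calibration_in_the_large(pred, data, horizon, event_cause)
    return CalibrationTable(groups=pd.DataFrame(rows), overall=overall, horizon=horizon)


def lowess_curve(pred: Sequence[float], observed: Sequence[float],
                 frac: float = 2.0 / 3.0) -> np.ndarray:
    """Optional display smoother for calibration plots (local linear)."""
    import statsmodels.api as sm

    return sm.nonparametric.lowess(observed, pred, frac=frac)


# --------------------------------------------------------------------------
# Bootstrap
# --------------------------------------------------------------------------

def bootstrap_ci(statistic: Callable[[np.ndarray], float], n: int,
                 B: int = 2000, seed: Optional[int] = None,
                 level: float = 0.95) -> tuple[float, float]:
    """Seeded percentile bootstrap interval.

    ``statistic`` receives an index array (a with-replacement resample of
    ``range(n)``) and returns a scalar; it may raise
    :class:`UndefinedResultError` or return NaN on degenerate resamples —
    if more than half the replicates are undefined the interval fails.
    """
    if B < 100:
        raise ConfigurationError("bootstrap needs B >= 100")
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            vals[b] = statistic(idx)
        except UndefinedResultError:
            vals[b] = np.nan
    ok = np.isfinite(vals)
    if ok.sum() < B / 2:
        raise UndefinedResultError(
            f"statistic undefined on {B - int(ok.sum())}/{B} bootstrap replicates")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals[ok], [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# Report assembly (Table-2 shape)
# --------------------------------------------------------------------------

def validation_report(predictions: pd.DataFrame, cohort, horizons=(2.0, 4.0),
                      n_groups: int = 10, bootstrap_B: int = 0,
                      seed: Optional[int] = None
                      ) -> tuple[pd.DataFrame, dict]:
    """Per-outcome, per-horizon concordance and calibration-in-the-large,
    plus grouped calibration tables.

    ``predictions`` must hold one column per combined endpoint, rows
    aligned with the cohort (id-indexed). For the ``no_event`` endpoint the
    composite first-event coding is used and the prediction enters negated
    (a high event-free probability ranks as low composite-event risk); the
    choice is recorded in the output's ``coding`` column.

    With ``bootstrap_B`` > 0, seeded percentile-bootstrap intervals are
    attached to each concordance.
    """
    from .incidence import outcome_riskset

    rows = []
    tables: dict[tuple[str, float], CalibrationTable] = {}
    for outcome in ("any_krt", "any_cvd", "death", "death_without_krt",
                    "death_after_krt", "no_event"):
        if outcome not in predictions.columns:
            continue
        pred = predictions[outcome].to_numpy(dtype=float)
        rank_pred = -pred if outcome == "no_event" else pred
        data = outcome_riskset(cohort, outcome)
        for horizon in horizons:
            try:
                cres = wolbers_c(rank_pred, data, horizon)
                c, pairs = cres.c, cres.comparable_pairs
            except UndefinedResultError:
                c, pairs = np.nan, 0
            ci_lo = ci_hi = np.nan
            if bootstrap_B and pairs:
                def stat(idx, _d=data, _p=rank_pred, _h=horizon):
                    return wolbers_c(_p[idx], _d.subset(idx), _h).c
                try:
                    ci_lo, ci_hi = bootstrap_ci(stat, len(data), B=bootstrap_B, seed=seed)
                except UndefinedResultError:
                    pass
            mean_pred, observed = calibration_in_the_large(pred, data, horizon)
            try:
                tables[(outcome, horizon)] = calibration_groups(
                    pred, data, horizon, n_groups=n_groups)
            except (DomainError, UndefinedResultError):
                pass
            rows.append({
                "outcome": outcome, "horizon": horizon,
                "c_statistic": c, "c_ci_low": ci_lo, "c_ci_high": ci_hi,
                "comparable_pairs": pairs,
                "mean_predicted": mean_pred, "observed": observed,
                "coding": "composite first event, prediction negated"
                          if outcome == "no_event" else "standard",
            })
    return pd.DataFrame(rows), tables
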