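"""Nonparametric cumulative incidence under competing risks.

The Aalen–Johansen estimator generalises Kaplan–Meier: at each distinct
event time t with risk set n(t) and d_k(t) events of cause k,

    CIF_k(t) = CIF_k(t-) + S(t-) * d_k(t) / n(t)
    S(t)     = S(t-) * (1 - sum_k d_k(t) / n(t))

so that sum_k CIF_k(t) + S(t) = 1 at every jump. Ties between events and
censorings at the same time are resolved events-first (the censored
subject is still in the risk set at that time). Step functions are
right-continuous and horizon evaluation is inclusive at t.

``outcome_riskset`` converts raw cohort histories into the
(event / competing / censored) first-event coding each combined endpoint
induces — the "observed risk" side of every calibration quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import Cohort
from .exceptions import ConfigurationError, DataError, DomainError

CENSORED = "censored"


@dataclass
class FirstEventData:
    """Per-subject first-event time and cause label (``censored`` allowed)."""

    time: np.ndarray
    cause: np.ndarray  # array of str labels

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.cause = np.asarray(self.cause, dtype=object)
        if self.time.shape != self.cause.shape or self.time.ndim != 1:
            raise DataError("time and cause must be aligned 1-d arrays")
        if self.time.size == 0:
            raise DomainError("empty first-event data")
        if np.any(self.time < 0) or not np.all(np.isfinite(self.time)):
            raise DataError("event times must be finite and >= 0")

    def __len__(self) -> int:
        return self.time.size

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.cause) - {CENSORED}))

    def truncated(self, horizon: float) -> "FirstEventData":
        """Recode anything after the horizon as censored at the horizon
        (events at exactly the horizon still count)."""
        if not (horizon > 0):
            raise DomainError(f"horizon must be positive, got {horizon}")
        time = np.minimum(self.time, horizon)
        cause = self.cause.copy()
        cause[self.time > horizon] = CENSORED
        return FirstEventData(time=time, cause=cause)

    def subset(self, idx) -> "FirstEventData":
        return FirstEventData(time=self.time[idx], cause=self.cause[idx])


@dataclass
class CIFEstimate:
    """Aalen–Johansen step functions: per-cause CIFs plus event-free survival."""

    jump_times: np.ndarray
    cif: dict[str, np.ndarray]
    event_free_survival: np.ndarray


def aalen_johansen(data: FirstEventData,
                   causes: Optional[Sequence[str]] = None) -> CIFEstimate:
    """Aalen–Johansen cumulative incidence for every cause in ``data``.

    Parameters
    ----------
    data
        First-event times and causes; ``censored`` marks censoring.
    causes
        Optional explicit cause label set; labels present in the data but
        not listed here raise :class:`DataError`.
    """
    if causes is None:
        causes = data.causes
    unknown = set(data.cause) - set(causes) - {CENSORED}
    if unknown:
        raise DataError(f"unknown cause labels: {sorted(unknown)}")

    order = np.argsort(data.time, kind="stable")
    t_sorted = data.time[order]
    c_sorted = data.cause[order]

    event_mask = c_sorted != CENSORED
    jump_times = np.unique(t_sorted[event_mask])

    cif = {k: np.zeros(jump_times.size) for k in causes}
    surv = np.ones(jump_times.size)

    s_prev = 1.0
    cif_run = {k: 0.0 for k in causes}
    n = len(data)
    i = 0  # pointer into the sorted sample
    for j, t in enumerate(jump_times):
        # remove subjects with time < t (event or censoring before t)
        while i < n and t_sorted[i] < t:
            i += 1
        at_risk = n - i
        # events at exactly t (censorings at t remain in the risk set: events first)
        d = {k: 0 for k in causes}
        m = i
        while m < n and t_sorted[m] == t:
            if c_sorted[m] != CENSORED:
                d[c_sorted[m]] += 1
            m += 1
        total_d = sum(d.values())
        for k in causes:
            if d[k]:
                cif_run[k] += s_prev * d[k] / at_risk
        s_prev *= 1.0 - total_d / at_risk
        for k in causes:
            cif[k][j] = cif_run[k]
        surv[j] = s_prev

    return CIFEstimate(jump_times=jump_times, cif=cif, event_free_survival=surv)


def cif_at(est: CIFEstimate, t: float) -> dict[str, float]:
    """Right-continuous evaluation of all CIFs and survival at time ``t``.

    Returns a dict with one entry per cause plus ``"event_free_survival"``.
    Before the first jump all CIFs are 0 and survival 1; beyond the last
    jump the last value is carried forward.
    """
    if t < 0:
        raise DomainError(f"t must be >= 0, got {t}")
    idx = int(np.searchsorted(est.jump_times, t, side="right")) - 1
    out: dict[str, float] = {}
    for k, v in est.cif.items():
        out[k] = float(v[idx]) if idx >= 0 else 0.0
    out["event_free_survival"] = (
        float(est.event_free_survival[idx]) if idx >= 0 else 1.0
    )
    return out


# --------------------------------------------------------------------------
# Combined-endpoint first-event codings
# --------------------------------------------------------------------------

EVENT = "event"
COMPETING = "competing"

OUTCOME_NAMES = ("any_krt", "any_cvd", "death", "death_without_krt",
                 "death_after_krt", "no_event")


def outcome_riskset(cohort: Cohort, outcome: str,
                    horizon: Optional[float] = None) -> FirstEventData:
    """First-event (event / competing / censored) coding for one combined
    endpoint.

    - ``any_krt``: event = KRT start; competing = death before KRT; CVD
      ignored; otherwise censored at end of follow-up.
    - ``any_cvd``: event = first CVD; competing = death before CVD.
    - ``death``: event = death, no competing cause.
    - ``death_without_krt``: event = death with no prior KRT; competing =
      KRT start (KRT precludes the outcome).
    - ``death_after_krt``: event = death with prior KRT; competing = death
      without prior KRT.
    - ``no_event``: composite — event = first of KRT/CVD/death. (Predicted
      event-free probability ranks inversely, so downstream concordance
      uses the negated prediction.)

    With ``horizon`` given, anything after it is recoded as censored at the
    horizon.
    """
    if outcome not in OUTCOME_NAMES:
        raise ConfigurationError(f"unknown outcome {outcome!r}; choose from {OUTCOME_NAMES}")
    cohort.require_nonempty()

    times, causes = [], []
    for r in cohort:
        end = r.followup_end
        death = r.death_time
        krt = r.krt_time
        cvd = r.cvd_time
        if outcome == "any_krt":
            if krt is not None:
                t, c = krt, EVENT
            elif death is not None:
                t, c = death, COMPETING
            else:
                t, c = end, CENSORED
        elif outcome == "any_cvd":
            if cvd is not None:
                t, c = cvd, EVENT
            elif death is not None:
                t, c = death, COMPETING
            else:
                t, c = end, CENSORED
        elif outcome == "death":
            if death is not None:
                t, c = death, EVENT
            else:
                t, c = end, CENSORED
        elif outcome == "death_without_krt":
            if krt is not None:
                t, c = krt, COMPETING
            elif death is not None:
                t, c = death, EVENT
            else:
                t, c = end, CENSORED
        elif outcome == "death_after_krt":
            if death is not None and krt is not None and krt <= death:
                t, c = death, EVENT
            elif death is not None:
                t, c = death, COMPETING
            else:
                t, c = end, CENSORED
        else:  # no_event composite
            evts = [t for t in (krt, cvd, death) if t is not None]
            if evts:
                t, c = min(evts), EVENT
            else:
                t, c = end, CENSORED
        times.append(t)
        causes.append(c)

    data = FirstEventData(time=np.array(times), cause=np.array(causes, dtype=object))
    return data.truncated(horizon) if horizon is not None else data


def stacked_incidence_table(cohort: Cohort):
    """Jump-time table of first-event CIFs (KRT / CVD / death) and survival,
    suitable for a stacked cumulative incidence plot."""
    import pandas as pd

    times, causes = [], []
    for r in cohort:
        evts = [(t, c) for t, c in ((r.death_time, "death"), (r.krt_time, "krt"),
                                    (r.cvd_time, "cvd")) if t is not None]
        if evts:
            t = min(e[0] for e in evts)
            c = next(cc for tt, cc in evts if tt == t)
        else:
            t, c = r.followup_end, CENSORED
        times.append(t)
        causes.append(c)
    est = aalen_johansen(
        FirstEventData(np.array(times), np.array(causes, dtype=object)),
        causes=("krt", "cvd", "death"),
    )
    return pd.DataFrame({
        "time": est.jump_times,
        "cif_krt": est.cif["krt"],
        "cif_cvd": est.cif["cvd"],
        "cif_death": est.cif["death"],
        "event_free_survival": est.event_free_survival,
    })
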