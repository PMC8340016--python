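"""Kaplan–Meier estimation and the Mantel–Haenszel (log-rank) comparison.

The two-group log-rank statistic is the classic Mantel–Haenszel form: at
each distinct event time t_j with d_j pooled events, n_j subjects at risk
and n_1j of them in group 1,

    O − E = Σ_j (d_1j − d_j · n_1j / n_j)
    V     = Σ_j d_j (n_1j/n_j)(1 − n_1j/n_j)(n_j − d_j)/(n_j − 1)

and χ² = (O − E)² / V is referred to the 1-df chi-square upper tail. Tied
event times are pooled at each distinct time (hypergeometric variance);
subjects censored exactly at an event time are counted at risk at that
time (standard convention).

The statistic is computed directly (vectorized over distinct event times)
because the resampling analyses evaluate it hundreds of thousands of
times; Kaplan–Meier curves go through :mod:`lifelines`. p-values are
never reported as exactly 0 — they are floored at the smallest normal
float with a flag, so downstream log10 summaries stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from grpsig.errors import DataValidationError, DegenerateInputError
from grpsig.expression import CohortData
from grpsig.stratification import median_split, pc1_scores

_P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class SurvivalCurve:
    """Product-limit estimate at the distinct observed event times."""

    times: np.ndarray       # ordered distinct event times
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


@dataclass
class AssociationResult:
    """Outcome of a two-group survival comparison."""

    statistic: float
    p_value: float
    group_sizes: dict[int, int]
    events_per_group: dict[int, int]
    p_floored: bool = False


def _check_times_events(times: np.ndarray, events: np.ndarray) -> None:
    if len(times) == 0:
        raise DataValidationError("no subjects")
    if np.any(times < 0):
        raise DataValidationError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise DataValidationError("event indicator outside {0, 1}")


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan–Meier estimate; censored subjects leave the risk set after
    their censoring time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    _check_times_events(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    mask = table["observed"] > 0
    ts = table.index[mask].to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ts, kmf.survival_function_.columns[0]].to_numpy()
    return SurvivalCurve(
        times=ts,
        survival=surv,
        at_risk=table.loc[mask, "at_risk"].to_numpy(dtype=int),
        events=table.loc[mask, "observed"].to_numpy(dtype=int),
    )


def logrank_test(times, events, groups) -> AssociationResult:
    """Two-group Mantel–Haenszel test on −1/+1 group labels."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=int)
    _check_times_events(times, events)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise DegenerateInputError(
            f"exactly two group labels required, got {labels.tolist()}"
        )
    if events.sum() == 0:
        raise DegenerateInputError("zero events: log-rank statistic undefined")

    in1 = groups == labels[0]
    event_times = np.unique(times[events == 1])
    # at-risk counts: subjects with time >= t (censoring at an event time
    # keeps the subject at risk there)
    order = np.argsort(times)
    ts, ev, g1 = times[order], events[order], in1[order].astype(int)
    n_total = len(ts)
    # index of first subject with time >= t for each event time
    first = np.searchsorted(ts, event_times, side="left")
    cum_g1 = np.concatenate(([0], np.cumsum(g1)))
    n_j = n_total - first
    n_1j = cum_g1[n_total] - cum_g1[first]
    # pooled events and group-1 events at each event time
    is_event = ev == 1
    ev_ts = ts[is_event]
    ev_g1 = g1[is_event]
    left = np.searchsorted(ev_ts, event_times, side="left")
    right = np.searchsorted(ev_ts, event_times, side="right")
    cum_ev_g1 = np.concatenate(([0], np.cumsum(ev_g1)))
    d_j = right - left
    d_1j = cum_ev_g1[right] - cum_ev_g1[left]

    frac = n_1j / n_j
    o_minus_e = float(np.sum(d_1j - d_j * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d_j * frac * (1.0 - frac) * (n_j - d_j) / (n_j - 1.0)
    var_terms = np.where(n_j > 1, var_terms, 0.0)
    v = float(np.sum(var_terms))
    if v == 0.0:
        if o_minus_e == 0.0:
            chi2 = 0.0
        else:
            raise DegenerateInputError("zero log-rank variance with non-zero O−E")
    else:
        chi2 = o_minus_e**2 / v
    p = float(stats.chi2.sf(chi2, df=1))
    floored = p == 0.0
    return AssociationResult(
        statistic=chi2,
        p_value=max(p, _P_FLOOR),
        group_sizes={int(l): int(np.sum(groups == l)) for l in labels},
        events_per_group={int(l): int(events[groups == l].sum()) for l in labels},
        p_floored=floored,
    )


def outcome_association(cohort: CohortData, gene_set, scale: bool = False) -> AssociationResult:
    """Survival association of a gene set: PC1 scores → median split →
    log-rank test. Deterministic given cohort and gene set."""
    scores = pc1_scores(cohort, gene_set, scale=scale)
    groups = median_split(scores)
    return logrank_test(
        cohort.time.to_numpy(), cohort.event.to_numpy(), groups.labels.to_numpy()
    )
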