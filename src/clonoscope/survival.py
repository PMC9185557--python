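"""Kaplan-Meier curves and log-rank comparison of clonotype-labelled groups.

Estimation and testing are delegated to lifelines (product-limit
estimator; log-rank with the standard multi-event hypergeometric
variance at tied event times — censored subjects at an event time are
counted at risk for that time, i.e. censoring is ordered after events).
The module adds the repertoire-specific surfaces: per-stratum
oligoclonal-vs-polyclonal comparisons filtered by HPV (p16) status or
smoking history, and the covariate table handed to external Cox tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger("clonoscope")


@dataclass
class SurvivalCurve:
    """Step-function survival estimate on the event-time grid."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function (S(0) = 1)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(grid).to_numpy(dtype=float)
    return SurvivalCurve(
        timeline=grid,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(times[~events]),
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic 1 df, p).

    The statistic is (sum O - E)^2 / sum V over distinct event times,
    with the hypergeometric variance; invariant under label swap and
    under any monotone transformation of the times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ValueError(f"log-rank comparison requires exactly 2 groups, got {uniq.size}")
    for g in uniq:
        mask = groups == g
        if not mask.any():
            raise ValueError(f"group {g!r} is empty")
        if not events[mask].any():
            raise ValueError(f"group {g!r} has no observed events")
    a = groups == uniq[0]
    res = _ll_logrank(times[a], times[~a], event_observed_A=events[a],
                      event_observed_B=events[~a])
    return float(res.test_statistic), float(res.p_value)


def stratified_survival_report(
    cohort: pd.DataFrame,
    labels: pd.Series | dict,
    stratify_by: str | None = None,
) -> dict:
    """KM curves + log-rank per stratum for labelled patients.

    ``cohort`` is the validated clinical table (os_time, os_event,
    p16_status, smoking, ...); ``labels`` maps patient_id -> patient
    clonotype label (e.g. OLIGOCLONAL/POLYCLONAL).  ``stratify_by``
    names a cohort column (``p16_status`` or ``smoking``); None runs the
    single unstratified comparison.  Strata with fewer than 2 patients
    in either label group are skipped with a warning.  The returned dict
    has one entry per stratum: {"curves": {label: SurvivalCurve},
    "statistic", "p_value", "n"}; plus "covariates": the table for
    external Cox fitting.
    """
    labels = pd.Series(labels)
    df = cohort[cohort["patient_id"].isin(labels.index)].copy()
    if df.empty:
        raise ValueError("no cohort patients carry a clonotype label")
    df["clonotype_label"] = df["patient_id"].map(labels)

    strata = {"ALL": df} if stratify_by is None else {
        str(value): sub for value, sub in df.groupby(stratify_by)
    }
    report: dict = {}
    for name, sub in strata.items():
        counts = sub["clonotype_label"].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            logger.warning("stratum %s: <2 patients in a label group, skipped", name)
            continue
        curves = {
            str(label): km_estimate(part["os_time"], part["os_event"])
            for label, part in sub.groupby("clonotype_label")
        }
        try:
            stat, p = logrank_test(sub["os_time"], sub["os_event"], sub["clonotype_label"])
        except ValueError as exc:  # e.g. a group with no events
            logger.warning("stratum %s: log-rank skipped (%s)", name, exc)
            stat, p = np.nan, np.nan
        report[name] = {"curves": curves, "statistic": stat, "p_value": p, "n": len(sub)}

    covariate_cols = [c for c in ("patient_id", "os_time", "os_event", "smoking",
                                  "p16_status", "age", "productive_templates") if c in df.columns]
    report["covariates"] = df[covariate_cols + ["clonotype_label"]].reset_index(drop=True)
    return report
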