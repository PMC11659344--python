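"""Prognosis analysis: Kaplan-Meier curves, log-rank test, Cox regression.

Thin, typed wrappers over lifelines (product-limit estimator, two-sided
log-rank with 1 df, Cox partial likelihood with Efron tie handling) that
return plain result objects and make degenerate inputs explicit: the KM
estimate is always returned even when the log-rank test is undefined, and
monotone partial likelihood (a covariate perfectly ordering the events) is
flagged instead of silently reporting runaway hazard ratios.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning
from lifelines.statistics import logrank_test


@dataclass
class KMCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray  # step values at `times`, starts from S(0)=1

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


@dataclass
class SurvivalFit:
    km: dict[str, KMCurve] = field(default_factory=dict)
    logrank_stat: float | None = None
    logrank_p: float | None = None
    hazard_ratios: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    hr_p_values: dict[str, float] = field(default_factory=dict)
    monotone_likelihood: bool = False
    notes: list[str] = field(default_factory=list)


def km_logrank(times, events, groups) -> SurvivalFit:
    """Per-group Kaplan-Meier estimates plus the two-group log-rank test.

    With zero events overall the test is undefined: the KM curves are still
    returned, with a note, and the statistic left as None.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    fit = SurvivalFit()
    for g in labels:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        fit.km[str(g)] = KMCurve(
            group=str(g),
            times=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
        )
    if len(labels) != 2:
        fit.notes.append("log-rank requires exactly 2 groups; test skipped")
        return fit
    if events.sum() == 0:
        fit.notes.append("no events; log-rank test undefined")
        return fit
    m0, m1 = groups == labels[0], groups == labels[1]
    res = logrank_test(times[m0], times[m1], events[m0], events[m1])
    fit.logrank_stat = float(res.test_statistic)
    fit.logrank_p = float(res.p_value)
    return fit


def logrank_p(times, events, groups) -> float:
    """Two-sided log-rank p-value only (no KM fitting); for permutation
    loops where the full :func:`km_logrank` output is not needed."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("log-rank requires exactly 2 groups")
    if events.sum() == 0:
        raise ValueError("no events; log-rank test undefined")
    m = groups == labels[0]
    res = logrank_test(times[m], times[~m], events[m], events[~m])
    return float(res.p_value)


def cox_fit(times, events, covariates: pd.DataFrame, min_events: int = 10) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron ties) with Wald 95 % CIs per
    covariate.  Monotone likelihood is flagged via `monotone_likelihood`."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    covariates = covariates.reset_index(drop=True).astype(float)
    if events.sum() < min_events:
        raise ValueError(f"need at least {min_events} events, got {int(events.sum())}")
    constant = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariates: {constant}")

    df = covariates.copy()
    df["_time"] = times
    df["_event"] = events
    fit = SurvivalFit()
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="_time", event_col="_event")
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                fit.monotone_likelihood = True
                fit.notes.append(str(w.message))
    if np.max(np.abs(cph.params_.to_numpy())) > 30:
        fit.monotone_likelihood = True
        fit.notes.append("runaway coefficient: likelihood appears monotone")
    summary = cph.summary
    for cov in covariates.columns:
        row = summary.loc[cov]
        fit.hazard_ratios[cov] = (
            float(row["exp(coef)"]),
            float(row["exp(coef) lower 95%"]),
            float(row["exp(coef) upper 95%"]),
        )
        fit.hr_p_values[cov] = float(row["p"])
    return fit
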