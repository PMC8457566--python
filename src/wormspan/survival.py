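"""Kaplan-Meier survival estimation, log-rank tests, and effect arithmetic.

Estimation delegates to ``lifelines`` (product-limit estimator,
Mantel-Cox log-rank) and ``statsmodels`` (Benjamini-Hochberg step-up);
this module adds the bookkeeping, the lifespan summaries, and the
percent-effect arithmetic used throughout the combinatorial analysis.

Conventions:

* mean lifespan = arithmetic mean of observed death days, censored
  worms excluded (printed effect columns recompute exactly under this
  estimator); the KM restricted mean (RMST) is reported alongside;
* the published "± SD" uncertainties at cohort sizes of hundreds of
  worms are standard errors; both SD and SEM are emitted;
* "maximum lifespan" defaults to the mean of the top decile of death
  days (alternatives: absolute maximum, 90th percentile);
* ties share one event time; censorings tied with deaths leave the
  risk set after the deaths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable
from .interventions import InterventionSet

PVALUE_FLOOR = 2.0e-16  # printed as "<2.0E-16"


@dataclass
class KMCurve:
    """Product-limit survival estimate with at-risk/event bookkeeping.

    ``times`` are the distinct observation days (events or
    censorings); ``survival`` the step value Ŝ(t) just after each time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    n_total: int

    @property
    def has_events(self) -> bool:
        return bool(self.events.sum() > 0)

    def survival_at(self, t: float) -> float:
        """Ŝ(t): right-continuous step function, 1 before the first time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def rmst(self, horizon: float | None = None) -> float:
        """Area under the curve up to ``horizon`` (default: last time)."""
        if horizon is None:
            horizon = float(self.times[-1]) if len(self.times) else 0.0
        grid = np.concatenate(([0.0], self.times[self.times <= horizon], [horizon]))
        grid = np.unique(grid)
        steps = np.array([self.survival_at(t) for t in grid[:-1]])
        return float(np.sum(steps * np.diff(grid)))


def km_curve(durations, event_observed) -> KMCurve:
    """Kaplan-Meier estimate from per-worm durations and death flags.

    All-censored input is allowed: the curve is defined (never drops)
    and ``has_events`` is False.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(event_observed, dtype=bool)
    if durations.shape != events.shape:
        raise ValueError("durations and event flags must have equal length")
    if len(durations) == 0:
        raise ValueError("empty sample")
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")

    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    table = kmf.event_table[kmf.event_table.index > 0]  # drop the entrance row
    times = table.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in times])
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        censored=table["censored"].to_numpy(dtype=int),
        n_total=len(durations),
    )


def km_mean(durations, event_observed) -> float:
    """KM mean: area under the survival curve up to the last observation."""
    return km_curve(durations, event_observed).rmst()


@dataclass
class SurvivalSummary:
    """Per-strain lifespan summary in the published table layout."""

    strain: InterventionSet | str
    n: int
    n_events: int
    n_censored: int
    mean_lifespan: float
    sd: float
    sem: float
    max_lifespan: float
    rmst: float


def summarize_survival(cohort: CohortTable, strain,
                       max_estimator: str = "top_decile",
                       horizon: float | None = None) -> SurvivalSummary:
    """Lifespan summary for one strain of a cohort.

    ``max_estimator``: ``top_decile`` (mean of the top 10% of death
    days, the default), ``max``, or ``p90``.
    """
    outcomes = cohort.worm_outcomes(strain)
    deaths = outcomes.loc[outcomes["event"], "duration"].to_numpy(dtype=float)
    if len(deaths) == 0:
        raise ValueError(f"strain {strain!r} has no observed deaths")
    sd = float(np.std(deaths, ddof=1)) if len(deaths) > 1 else 0.0
    if max_estimator == "top_decile":
        k = max(1, int(np.ceil(len(deaths) / 10)))
        max_ls = float(np.mean(np.sort(deaths)[-k:]))
    elif max_estimator == "max":
        max_ls = float(deaths.max())
    elif max_estimator == "p90":
        max_ls = float(np.quantile(deaths, 0.9))
    else:
        raise ValueError(f"unknown max_estimator {max_estimator!r}")
    curve = km_curve(outcomes["duration"], outcomes["event"])
    return SurvivalSummary(
        strain=strain,
        n=len(outcomes),
        n_events=len(deaths),
        n_censored=int((~outcomes["event"]).sum()),
        mean_lifespan=float(deaths.mean()),
        sd=sd,
        sem=sd / np.sqrt(len(deaths)),
        max_lifespan=max_ls,
        rmst=curve.rmst(horizon),
    )


def logrank_test(durations_a, events_a, durations_b, events_b) -> tuple[float, float]:
    """Mantel-Cox log-rank test; returns (chi-square, p-value), 1 df."""
    ea, eb = np.asarray(events_a, dtype=bool), np.asarray(events_b, dtype=bool)
    if len(ea) == 0 or len(eb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() == 0 and eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(durations_a, durations_b, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (adjusted p, significant flags)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def effect_percent(value_strain: float, value_control: float) -> float:
    """Signed percent change of an endpoint vs its control."""
    if value_control <= 0:
        raise ValueError("control value must be positive")
    return 100.0 * (value_strain - value_control) / value_control


def format_pvalue(p: float) -> str:
    """Report convention: values below 2.0E-16 print as '<2.0E-16'."""
    return "<2.0E-16" if p < PVALUE_FLOOR else f"{p:.1E}"


@dataclass
class EffectEstimate:
    """Percent change of one strain's endpoint vs its control."""

    strain: InterventionSet | str
    control: InterventionSet | str
    endpoint: str
    effect_percent: float
    p_value: float
    p_adjusted: float
    significant: bool


def survival_table(cohort: CohortTable, control, alpha: float = 0.05,
                   max_estimator: str = "top_decile") -> pd.DataFrame:
    """Published-style survival report: one row per strain vs the control.

    Columns: n, deaths, censored, mean ± SEM, SD, max, RMST, percent
    effect vs control, log-rank p, BH-adjusted p, significance flag.
    """
    control_label = control.label if isinstance(control, InterventionSet) else control
    labels = cohort.strains()
    if control_label not in labels:
        raise KeyError(f"control strain {control_label!r} not in cohort")
    summaries = {s: summarize_survival(cohort, s, max_estimator) for s in labels}
    ctrl = summaries[control_label]
    ctrl_out = cohort.worm_outcomes(control_label)

    rows = []
    pvals = []
    others = [s for s in labels if s != control_label]
    for s in others:
        out = cohort.worm_outcomes(s)
        _, p = logrank_test(out["duration"], out["event"],
                            ctrl_out["duration"], ctrl_out["event"])
        pvals.append(p)
    p_adj, reject = bh_adjust(pvals, alpha)

    for s, p, pa, sig in zip(others, pvals, p_adj, reject):
        sm = summaries[s]
        rows.append({
            "strain": s, "n": sm.n, "deaths": sm.n_events, "censored": sm.n_censored,
            "mean_lifespan": round(sm.mean_lifespan, 1), "sem": round(sm.sem, 2),
            "sd": round(sm.sd, 2), "max_lifespan": round(sm.max_lifespan, 1),
            "rmst": round(sm.rmst, 1),
            "effect_percent": round(effect_percent(sm.mean_lifespan, ctrl.mean_lifespan), 1),
            "p_value": format_pvalue(p), "p_adjusted": format_pvalue(pa),
            "significant": bool(sig),
        })
    ctrl_row = {
        "strain": control_label, "n": ctrl.n, "deaths": ctrl.n_events,
        "censored": ctrl.n_censored, "mean_lifespan": round(ctrl.mean_lifespan, 1),
        "sem": round(ctrl.sem, 2), "sd": round(ctrl.sd, 2),
        "max_lifespan": round(ctrl.max_lifespan, 1), "rmst": round(ctrl.rmst, 1),
        "effect_percent": 0.0, "p_value": "[control]", "p_adjusted": "[control]",
        "significant": False,
    }
    return pd.DataFrame([ctrl_row] + rows)
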