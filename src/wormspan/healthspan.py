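"""Motility-based healthspan: state transitions and occupancy decomposition.

Worms are scored daily into three progressive motility stages — A
(fully mobile, moves > 0.5 cm), B (impaired, responds to prodding but
moves < 0.5 cm), C (frail, only head/tail movement).  Treating the
first exit from a set of stages as a survival event gives two
Kaplan-Meier analyses: (i) exit from {A} (loss of full mobility) and
(ii) exit from {A, B} (onset of frailty).  Death while still inside
the stage set ends the sojourn and counts as an event (a composite
endpoint): under this convention — and only under it — the three mean
durations decompose the mean lifespan exactly,

    mean mobile + mean impaired + mean frail = mean lifespan,

with mean impaired = KM-mean(exit {A,B}) − KM-mean(exit {A}) and
mean frail = KM-mean(death) − KM-mean(exit {A,B}).

Censored worms contribute censored observations to the transition
analyses at their censoring day by default; ``censor_policy="exclude"``
drops them instead (the convention of the daily bar-chart tallies).
Occupancy fractions are stored at the 0.1 % report precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import CohortTable
from .interventions import InterventionSet
from .survival import km_curve, logrank_test

MOBILE = frozenset({"A"})
NOT_FRAIL = frozenset({"A", "B"})


@dataclass(frozen=True)
class TransitionSpec:
    """Which stage exit defines the event, and how censoring is handled."""

    from_states: frozenset = MOBILE
    censor_policy: str = "censor"  # or "exclude"

    def __post_init__(self) -> None:
        if self.from_states not in (MOBILE, NOT_FRAIL):
            raise ValueError("from_states must be {A} or {A, B}")
        if self.censor_policy not in ("censor", "exclude"):
            raise ValueError("censor_policy must be 'censor' or 'exclude'")


def extract_transition_times(cohort: CohortTable, strain,
                             spec: TransitionSpec = TransitionSpec()) -> pd.DataFrame:
    """Per-worm sojourn durations in ``spec.from_states``.

    The duration is the first day the worm is observed outside the
    stage set — by motility transition or by death (composite
    endpoint).  Worms censored while still inside are censored at the
    censoring day.  Returns columns ``worm_id, duration, event``.
    """
    df = cohort.strain_data(strain)
    rows = []
    for (rep, wid), g in df.groupby(["replicate", "worm_id"], sort=True):
        g = g.sort_values("day")
        alive = g[g["status"] == "alive"]
        unscored = alive["motility"].eq("not_scored")
        if unscored.any():
            raise ValueError(f"worm {wid!r} has unscored motility while alive")
        outside = alive[~alive["motility"].isin(spec.from_states)]
        terminal = g.iloc[-1]
        if len(outside):
            rows.append((wid, int(outside["day"].iloc[0]), True))
        elif terminal["status"] == "dead":
            rows.append((wid, int(terminal["day"]), True))
        elif spec.censor_policy == "censor":
            rows.append((wid, int(terminal["day"]), False))
    out = pd.DataFrame(rows, columns=["worm_id", "duration", "event"])
    if len(out) and (out["duration"] <= 0).any():
        raise ValueError("worm left the stage set on day 0; day-0 scoring must be inside")
    return out


@dataclass
class StateOccupancySummary:
    """Mean days and lifespan fractions in the mobile/impaired/frail stages."""

    strain: InterventionSet | str
    mean_mobile: float
    mean_impaired: float
    mean_frail: float
    mean_lifespan: float
    frac_mobile: float
    frac_impaired: float
    frac_frail: float

    @classmethod
    def from_durations(cls, strain, mean_mobile: float, mean_impaired: float,
                       mean_frail: float, mean_lifespan: float | None = None
                       ) -> "StateOccupancySummary":
        """Build a summary from mean stage durations (e.g. published ones)."""
        if mean_lifespan is None:
            mean_lifespan = mean_mobile + mean_impaired + mean_frail
        return cls(
            strain=strain,
            mean_mobile=mean_mobile, mean_impaired=mean_impaired,
            mean_frail=mean_frail, mean_lifespan=mean_lifespan,
            frac_mobile=round(100.0 * mean_mobile / mean_lifespan, 1),
            frac_impaired=round(100.0 * mean_impaired / mean_lifespan, 1),
            frac_frail=round(100.0 * mean_frail / mean_lifespan, 1),
        )

    def fraction(self, state: str) -> float:
        try:
            return {"mobile": self.frac_mobile, "impaired": self.frac_impaired,
                    "frail": self.frac_frail}[state]
        except KeyError:
            raise ValueError(f"unknown state {state!r}") from None


def state_mean_durations(cohort: CohortTable, strain,
                         censor_policy: str = "censor") -> StateOccupancySummary:
    """KM-mean occupancy decomposition for one strain.

    The mobile mean is the KM mean of the exit-{A} durations; the
    impaired mean the difference between the exit-{A,B} and exit-{A}
    KM means; the frail mean the difference between the KM mean
    lifespan and the exit-{A,B} KM mean.
    """
    t_mobile = extract_transition_times(cohort, strain, TransitionSpec(MOBILE, censor_policy))
    t_ab = extract_transition_times(cohort, strain, TransitionSpec(NOT_FRAIL, censor_policy))
    if not t_mobile["event"].any() or not t_ab["event"].any():
        raise ValueError(f"strain {strain!r} has no transition events")
    outcomes = cohort.worm_outcomes(strain)

    mean_mobile = km_curve(t_mobile["duration"], t_mobile["event"]).rmst()
    mean_not_frail = km_curve(t_ab["duration"], t_ab["event"]).rmst()
    mean_lifespan = km_curve(outcomes["duration"], outcomes["event"]).rmst()
    return StateOccupancySummary.from_durations(
        strain,
        mean_mobile=mean_mobile,
        mean_impaired=mean_not_frail - mean_mobile,
        mean_frail=mean_lifespan - mean_not_frail,
        mean_lifespan=mean_lifespan,
    )


def fraction_change(strain_summary: StateOccupancySummary,
                    control_summary: StateOccupancySummary, state: str) -> float:
    """Signed percent change of a lifespan fraction vs the control strain."""
    f_s = strain_summary.fraction(state)
    f_c = control_summary.fraction(state)
    if f_c <= 0:
        raise ValueError(f"control fraction for state {state!r} is zero")
    return 100.0 * (f_s - f_c) / f_c


def daily_state_distribution(cohort: CohortTable, strain) -> pd.DataFrame:
    """Per-day fractions of stages A/B/C among worms alive that day.

    Dead and censored worm-days are excluded; days with no alive worms
    are omitted.  Fractions sum to 1 on every emitted day.
    """
    df = cohort.strain_data(strain)
    alive = df[df["status"] == "alive"]
    counts = (alive.groupby(["day", "motility"]).size().unstack(fill_value=0)
              .reindex(columns=["A", "B", "C"], fill_value=0))
    totals = counts.sum(axis=1)
    frac = counts.div(totals, axis=0)
    frac.columns = ["frac_A", "frac_B", "frac_C"]
    frac.insert(0, "n_alive", totals)
    return frac.reset_index()


def motility_logrank(cohort: CohortTable, strain_a, strain_b,
                     spec: TransitionSpec = TransitionSpec()) -> tuple[float, float]:
    """Log-rank comparison of two strains' stage-exit curves."""
    ta = extract_transition_times(cohort, strain_a, spec)
    tb = extract_transition_times(cohort, strain_b, spec)
    return logrank_test(ta["duration"], ta["event"], tb["duration"], tb["event"])


def occupancy_table(cohort: CohortTable, control,
                    censor_policy: str = "censor") -> pd.DataFrame:
    """Occupancy decomposition for every strain, with changes vs control.

    Days are reported to 0.1 d and fractions to 0.1 %, the published
    precision.
    """
    control_label = control.label if isinstance(control, InterventionSet) else control
    summaries = {s: state_mean_durations(cohort, s, censor_policy)
                 for s in cohort.strains()}
    ctrl = summaries[control_label]
    rows = []
    for label, sm in summaries.items():
        row = {
            "strain": label,
            "mean_mobile": round(sm.mean_mobile, 1),
            "mean_impaired": round(sm.mean_impaired, 1),
            "mean_frail": round(sm.mean_frail, 1),
            "mean_lifespan": round(sm.mean_lifespan, 1),
            "frac_mobile": sm.frac_mobile,
            "frac_impaired": sm.frac_impaired,
            "frac_frail": sm.frac_frail,
        }
        for state in ("mobile", "impaired", "frail"):
            row[f"{state}_fraction_change"] = (
                0.0 if label == control_label
                else round(fraction_change(sm, ctrl, state), 1))
        rows.append(row)
    return pd.DataFrame(rows).sort_values("strain").reset_index(drop=True)
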