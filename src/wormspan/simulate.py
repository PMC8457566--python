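"""Synthetic cohort simulator.

Worm mortality follows a Gompertz hazard h(t) = a·exp(b·t) with
per-strain proportional effects on the log-hazard scale: a strain
carrying interventions I has multiplier exp(Σᵢ βᵢ + Σᵢⱼ γᵢⱼ), so
negative β is pro-longevity.  Motility declines through the progressive
stages A → B → C via two further Gompertz transition hazards; while a
worm is impaired or frail its death hazard is multiplied by a frailty
factor.  Continuous event times are rounded up to the next scoring day,
mirroring daily scoring; censoring is a per-day Bernoulli with the
FUdR-era cause mix (bagging, wall-crawling, organ extrusion).

Default parameters emulate a wild-type cohort at 20 °C with a recorded
mean lifespan near 20.6 days (SD ≈ 3.2 d), ~85 worms per replicate and
3 replicates, and pro-longevity effects sized for the odr-3 / ife-2 /
cku-70 intervention panel.  Every stream of randomness derives from the
master seed, with one named substream per strain, so adding a strain
does not perturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, EndpointTable, StrainInfo
from .interventions import InterventionSet

DEFAULT_EFFECTS = {"odr-3": -2.16, "ife-2": -1.48, "cku-70": -0.36}
DEFAULT_MOTILITY_EFFECTS = {"odr-3": -1.4, "ife-2": -1.5, "cku-70": 0.2}
DEFAULT_CENSOR_CAUSES = {"bagging": 0.4, "wall": 0.4, "extrusion": 0.2}


# -- Gompertz primitives ---------------------------------------------------

def gompertz_cumhaz(t, a: float, b: float):
    """Cumulative hazard Λ(t) = (a/b)(e^{bt} − 1); a·t in the b→0 limit."""
    t = np.asarray(t, dtype=float)
    if a <= 0 or b < 0:
        raise ValueError("require scale a > 0 and shape b >= 0")
    if b == 0:
        return a * t
    return (a / b) * np.expm1(b * t)


def gompertz_survival(t, a: float, b: float):
    """Survival S(t) = exp(−Λ(t)) of a Gompertz time-to-event."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = np.exp(-gompertz_cumhaz(t, a, b))
    return float(out) if out.ndim == 0 else out


def _gompertz_invert(e, a: float, b: float, t0=0.0):
    """Solve Λ(t) − Λ(t0) = e for t ≥ t0 (inverse-transform sampling)."""
    e = np.asarray(e, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    if b == 0:
        return t0 + e / a
    return np.log(np.exp(b * t0) + b * e / a) / b


def gompertz_mean_recorded(a: float, b: float, multiplier: float = 1.0,
                           horizon: int = 10_000) -> float:
    """Expected recorded death day E[⌈T⌉] = Σ_{d≥0} S(d) under daily scoring."""
    days = np.arange(horizon)
    with np.errstate(over="ignore"):  # Λ(d) overflow far in the tail -> S = 0
        s = np.exp(-multiplier * gompertz_cumhaz(days, a, b))
    return float(np.sum(s))


# -- configuration ---------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of the cohort simulator; see the module docstring.

    ``intervention_effects`` maps gene symbol → log-hazard effect β on
    mortality; ``interaction_terms`` maps a gene pair (frozenset) → γ;
    ``motility_effects`` maps gene symbol → log-hazard effect on the
    A→B and B→C transitions.  RNAi-diluted interventions (1:1 mixes
    with empty-vector bacteria) contribute ``dilution_factor``·β.
    """

    baseline_a: float = 7.0e-5          # per day
    baseline_b: float = 0.40            # per day
    intervention_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    interaction_terms: Mapping[frozenset, float] = field(default_factory=dict)
    motility_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTILITY_EFFECTS))
    motility_hazards: tuple[float, float, float, float] = (1.6e-4, 0.40, 3.5e-4, 0.40)
    frailty_mortality_multiplier: float = 2.0
    censor_daily_prob: float = 0.005
    censor_causes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CENSOR_CAUSES))
    dilution_factor: float = 0.5
    n_worms: int = 85
    n_replicates: int = 3
    horizon_days: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_a <= 0 or self.baseline_b < 0:
            raise ValueError("require baseline_a > 0 and baseline_b >= 0")
        if self.n_worms < 1 or self.n_replicates < 1:
            raise ValueError("need at least one worm and one replicate")
        if self.horizon_days < 1:
            raise ValueError("horizon must be at least 1 day")
        if not 0.0 <= self.censor_daily_prob <= 1.0:
            raise ValueError("censor_daily_prob must be a probability")
        if self.frailty_mortality_multiplier < 1.0:
            raise ValueError("frailty multiplier must be >= 1")

    def death_multiplier(self, strain: InterventionSet) -> float:
        """exp(Σβ + Σγ) for the strain, with RNAi-dilution attenuation."""
        log_m = 0.0
        genes = []
        for iv in strain:
            if iv.gene not in self.intervention_effects:
                raise KeyError(f"no intervention effect configured for gene {iv.gene!r}")
            scale = self.dilution_factor if iv.mode == "rnai_diluted" else 1.0
            log_m += scale * self.intervention_effects[iv.gene]
            genes.append(iv.gene)
        for i, g1 in enumerate(genes):
            for g2 in genes[i + 1:]:
                log_m += self.interaction_terms.get(frozenset((g1, g2)), 0.0)
        return float(np.exp(log_m))

    def motility_multiplier(self, strain: InterventionSet) -> float:
        log_m = 0.0
        for iv in strain:
            scale = self.dilution_factor if iv.mode == "rnai_diluted" else 1.0
            log_m += scale * self.motility_effects.get(iv.gene, 0.0)
        return float(np.exp(log_m))


def _strain_rng(seed: int, label: str) -> np.random.Generator:
    # stable per-strain stream: master seed + CRC32 of the label
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


# -- cohort simulation -----------------------------------------------------

def _simulate_strain_times(config: SimulationConfig, strain: InterventionSet,
                           n: int, rng: np.random.Generator):
    """Continuous death / A→B / B→C times for ``n`` worms of one strain."""
    a, b = config.baseline_a, config.baseline_b
    a_ab, b_ab, a_bc, b_bc = config.motility_hazards
    m_d = config.death_multiplier(strain)
    m_m = config.motility_multiplier(strain)
    f = config.frailty_mortality_multiplier

    e_ab, e_bc, e_d = rng.exponential(size=(3, n))
    t_ab = _gompertz_invert(e_ab, a_ab * m_m, b_ab)
    t_bc = _gompertz_invert(e_bc, a_bc * m_m, b_bc, t0=t_ab)

    # death hazard is baseline while mobile, ×f once impaired (state B or C)
    lam_at_ab = m_d * gompertz_cumhaz(t_ab, a, b)
    mobile_death = e_d < lam_at_ab
    t_death = np.where(
        mobile_death,
        _gompertz_invert(e_d / m_d, a, b),
        _gompertz_invert((e_d - lam_at_ab) / (f * m_d), a, b, t0=t_ab),
    )
    return t_death, t_ab, t_bc


def simulate_cohort(config: SimulationConfig, strains: Sequence[InterventionSet],
                    return_truth: bool = False, validate: bool = True):
    """Simulate daily observation records for the given strains.

    Returns a validated :class:`CohortTable`; with ``return_truth`` also
    a per-worm DataFrame of the continuous (pre-censoring) event times.
    Identical config + seed gives byte-identical output.  ``validate``
    may be switched off for large repeated-simulation studies; the
    generated records satisfy the invariants by construction.
    """
    frames = []
    truths = []
    metadata: dict[str, StrainInfo] = {}
    cause_names = list(config.censor_causes)
    cause_p = np.array([config.censor_causes[c] for c in cause_names], dtype=float)
    if cause_names:
        cause_p = cause_p / cause_p.sum()

    for strain in strains:
        rng = _strain_rng(config.seed, strain.label)
        metadata[strain.label] = StrainInfo(interventions=strain)
        for rep in range(config.n_replicates):
            n = config.n_worms
            t_death, t_ab, t_bc = _simulate_strain_times(config, strain, n, rng)
            death_day = np.maximum(np.ceil(t_death).astype(int), 1)

            if config.censor_daily_prob > 0:
                censor_day = rng.geometric(config.censor_daily_prob, size=n)
            else:
                censor_day = np.full(n, np.iinfo(np.int64).max)
            causes = (rng.choice(cause_names, size=n, p=cause_p)
                      if cause_names else np.full(n, "other"))

            end = np.minimum(np.minimum(death_day, censor_day), config.horizon_days)
            died = death_day <= np.minimum(censor_day, config.horizon_days)
            cause = np.where(died, "none",
                             np.where(censor_day <= config.horizon_days, causes, "other"))

            # expand to one row per worm-day without a per-worm python loop
            lengths = end + 1
            idx = np.repeat(np.arange(n), lengths)
            starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
            day = np.arange(lengths.sum()) - np.repeat(starts, lengths)
            terminal_rows = np.cumsum(lengths) - 1

            status = np.full(day.shape, "alive", dtype=object)
            status[terminal_rows] = np.where(died, "dead", "censored")
            censor_cause = np.full(day.shape, "none", dtype=object)
            censor_cause[terminal_rows] = cause
            motility = np.where(day < t_ab[idx], "A",
                                np.where(day < t_bc[idx], "B", "C")).astype(object)
            motility[terminal_rows] = "not_scored"
            worm_ids = np.array(
                [f"{strain.label}-r{rep}-w{i:04d}" for i in range(n)], dtype=object)
            frames.append(pd.DataFrame({
                "worm_id": worm_ids[idx],
                "strain": strain.label,
                "replicate": rep,
                "day": day,
                "status": status,
                "censor_cause": censor_cause,
                "motility": motility,
            }))
            if return_truth:
                truths.append(pd.DataFrame({
                    "worm_id": [f"{strain.label}-r{rep}-w{i:04d}" for i in range(n)],
                    "strain": strain.label,
                    "replicate": rep,
                    "t_death": t_death, "t_ab": t_ab, "t_bc": t_bc,
                    "death_day": death_day,
                }))

    cohort = CohortTable(pd.concat(frames, ignore_index=True), metadata)
    if validate:
        cohort.validate()
    if return_truth:
        return cohort, pd.concat(truths, ignore_index=True)
    return cohort


# -- endpoint simulators ---------------------------------------------------

@dataclass
class PumpingConfig:
    """Pharyngeal-pumping simulator: exponential decline with age.

    The mean rate at day d is rate_day1·exp(−decline_rate·(d−1)·s),
    where s is the product of per-intervention slowdown factors (<1
    slows the decline).  Counts get Gaussian noise, truncation at zero,
    and rounding.  Defaults emulate a wild-type decline from 250
    contractions/min at day 1 to ~30/min at day 15, sampling 14 worms
    at days 1, 5, 10 and 15.
    """

    rate_day1: float = 250.0
    decline_rate: float = 0.15           # per day
    intervention_rate_effects: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 25.0
    sample_days: tuple[int, ...] = (1, 5, 10, 15)
    n_sampled: int = 14
    dilution_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_day1 <= 0:
            raise ValueError("rate_day1 must be positive")
        if self.n_sampled < 1:
            raise ValueError("must sample at least one worm")

    def mean_rate(self, strain: InterventionSet, day: int) -> float:
        slowdown = 1.0
        for iv in strain:
            eff = self.intervention_rate_effects.get(iv.gene, 1.0)
            if iv.mode == "rnai_diluted":
                eff = 1.0 - self.dilution_factor * (1.0 - eff)
            slowdown *= eff
        return self.rate_day1 * float(np.exp(-self.decline_rate * slowdown * (day - 1)))


def simulate_pumping(config: PumpingConfig, strains: Sequence[InterventionSet]) -> EndpointTable:
    """Simulate per-worm pumping counts at the configured sample days."""
    rows = []
    for strain in strains:
        rng = _strain_rng(config.seed, "pumping:" + strain.label)
        for day in config.sample_days:
            mean = config.mean_rate(strain, day)
            vals = mean + config.noise_sd * rng.standard_normal(config.n_sampled)
            vals = np.clip(np.rint(vals), 0, None).astype(int)
            for i, v in enumerate(vals):
                rows.append((f"{strain.label}-d{day}-w{i:02d}", strain.label, 0, day, v))
    df = pd.DataFrame(rows, columns=["worm_id", "strain", "replicate", "condition", "value"])
    return EndpointTable("pumping", df)


def simulate_stress_assay(n: int, survival_prob: float, seed: int) -> tuple[int, int]:
    """Binomial survivor count for a stress exposure: (survivors, total)."""
    if n < 1:
        raise ValueError("need at least one animal")
    if not 0.0 <= survival_prob <= 1.0:
        raise ValueError("survival_prob must be a probability")
    rng = np.random.default_rng(seed)
    return int(rng.binomial(n, survival_prob)), n
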