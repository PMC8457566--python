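"""Published reference values for the odr-3 / ife-2 / cku-70 panel.

Curated summary statistics from the combinatorial longevity study of
the *odr-3(n1605)* mutation with *ife-2* and *cku-70* RNAi knock-downs
in *C. elegans* at 20 °C: mean lifespans (days ± SEM) of the wild-type
background strains, the mean days spent per motility stage, and the
day-15 pharyngeal-pumping effects.  These published group-level values
are the inputs of the replay analyses (effect arithmetic, occupancy
fractions, synergy classification); no per-worm data were deposited.

RNAi arms: full-dose clones versus 1:1 empty-vector (EV) mixes; the
double RNAi ``ife-2;cku-70`` co-feeds both clones, i.e. each at half
dose, so its matched singletons are the EV-mix arms.
"""

from __future__ import annotations

import pandas as pd

from .healthspan import StateOccupancySummary
from .interventions import Intervention, InterventionSet
from .synergy import EffectLattice, build_lattice

_ODR3 = Intervention("odr-3", "mutation")
_IFE2 = Intervention("ife-2", "rnai")
_IFE2_EV = Intervention("ife-2", "rnai_diluted")
_CKU70 = Intervention("cku-70", "rnai")
_CKU70_EV = Intervention("cku-70", "rnai_diluted")

WT_EV = InterventionSet.control("WT", label="WT(EV)")

STRAINS = {
    "WT(EV)": WT_EV,
    "odr-3": InterventionSet.of(_ODR3, label="odr-3"),
    "ife-2": InterventionSet.of(_IFE2, label="ife-2"),
    "cku-70": InterventionSet.of(_CKU70, label="cku-70"),
    "odr-3;ife-2": InterventionSet.of(_ODR3, _IFE2, label="odr-3;ife-2"),
    "odr-3;cku-70": InterventionSet.of(_ODR3, _CKU70, label="odr-3;cku-70"),
    "ife-2;EV": InterventionSet.of(_IFE2_EV, label="ife-2;EV"),
    "cku-70;EV": InterventionSet.of(_CKU70_EV, label="cku-70;EV"),
    "odr-3;ife-2;EV": InterventionSet.of(_ODR3, _IFE2_EV, label="odr-3;ife-2;EV"),
    "odr-3;cku-70;EV": InterventionSet.of(_ODR3, _CKU70_EV, label="odr-3;cku-70;EV"),
    "ife-2;cku-70": InterventionSet.of(_IFE2_EV, _CKU70_EV, label="ife-2;cku-70"),
    "odr-3;ife-2;cku-70": InterventionSet.of(_ODR3, _IFE2_EV, _CKU70_EV,
                                             label="odr-3;ife-2;cku-70"),
}

# label -> (mean lifespan d, SEM d, printed effect %, printed p-value)
_LIFESPAN = {
    "WT(EV)": (20.6, 0.2, 0.0, None),
    "odr-3": (26.0, 0.3, 26.2, "<2.0E-16"),
    "ife-2": (24.3, 0.2, 18.0, "<2.0E-16"),
    "cku-70": (21.5, 0.2, 4.4, "7.0E-03"),
    "odr-3;ife-2": (28.9, 0.4, 40.3, "<2.0E-16"),
    "odr-3;cku-70": (23.4, 0.5, 13.6, "4.0E-11"),
    "ife-2;EV": (22.9, 0.3, 11.2, "1.0E-10"),
    "cku-70;EV": (21.9, 0.2, 6.3, "1.0E-04"),
    "odr-3;ife-2;EV": (30.1, 0.5, 46.1, "<2.0E-16"),
    "odr-3;cku-70;EV": (26.5, 0.4, 28.6, "<2.0E-16"),
    "ife-2;cku-70": (23.7, 0.3, 15.0, "3.0E-16"),
    "odr-3;ife-2;cku-70": (27.9, 0.3, 35.4, "<2.0E-16"),
}

# label -> mean days (mobile, impaired, frail) and mean lifespan
_OCCUPANCY = {
    "WT(EV)": (17.3, 1.5, 1.8, 20.6),
    "odr-3": (20.8, 2.6, 2.6, 26.0),
    "ife-2": (21.0, 1.6, 1.7, 24.3),
    "odr-3;ife-2": (25.0, 2.2, 1.7, 28.9),
}

# day-15 pharyngeal pumping: control rate ~15 contractions/min and the
# published percent increases (66 %, 55 % singles; 187 % double)
PUMPING_DAY15_CONTROL_RATE = 15.0
_PUMPING_EFFECTS = {"WT": 0.0, "odr-3": 66.0, "ife-2": 55.0, "odr-3;ife-2": 187.0}


def lifespan_panel() -> pd.DataFrame:
    """The published lifespan table: one row per strain of the panel."""
    rows = [
        {"label": label, "mean_lifespan": m, "sem": sem,
         "effect_printed": eff, "p_printed": p}
        for label, (m, sem, eff, p) in _LIFESPAN.items()
    ]
    return pd.DataFrame(rows)


def lifespan_lattice() -> EffectLattice:
    """Effect lattice of the panel's mean lifespans (WT background)."""
    return build_lattice(
        [(STRAINS[label], m, sem) for label, (m, sem, _, _) in _LIFESPAN.items()],
        background="WT", endpoint="mean_lifespan",
    )


def occupancy_summaries() -> dict[str, StateOccupancySummary]:
    """Published motility-stage occupancy decompositions."""
    return {
        label: StateOccupancySummary.from_durations(
            STRAINS[label], mobile, impaired, frail, lifespan)
        for label, (mobile, impaired, frail, lifespan) in _OCCUPANCY.items()
    }


def pumping_day15_lattice() -> EffectLattice:
    """Day-15 pumping-rate lattice (mutation alleles; all subsets measured)."""
    odr3 = Intervention("odr-3", "mutation")
    ife2 = Intervention("ife-2", "mutation")
    strains = {
        "WT": InterventionSet.control("WT", label="WT"),
        "odr-3": InterventionSet.of(odr3, label="odr-3"),
        "ife-2": InterventionSet.of(ife2, label="ife-2"),
        "odr-3;ife-2": InterventionSet.of(odr3, ife2, label="odr-3;ife-2"),
    }
    base = PUMPING_DAY15_CONTROL_RATE
    return build_lattice(
        [(strains[label], base * (1.0 + eff / 100.0))
         for label, eff in _PUMPING_EFFECTS.items()],
        background="WT", endpoint="pumping_day15",
    )
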