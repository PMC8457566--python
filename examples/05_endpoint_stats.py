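"""Pharyngeal pumping endpoint: ANOVA, Dunnett, and day-15 synergy.

Two parts.  First, simulate per-worm pumping counts (exponential
decline from 250/min at day 1, slower decline for the intervention
strains, 14 filmed worms per group) and compare every strain to WT
with Dunnett's many-to-one test at day 15 — at this group size only
large differences clear the family-wise threshold.  Second, classify
the published day-15 rates (WT 15/min; singles +66 % and +55 %;
double +187 %) on the effect lattice.
"""

from wormspan import InterventionSet, Intervention, PumpingConfig, \
    classify_combination, endpoint_report, simulate_pumping
from wormspan.datasets import pumping_day15_lattice

odr3, ife2 = Intervention("odr-3"), Intervention("ife-2")
strains = [
    InterventionSet.control("WT", label="WT"),
    InterventionSet.of(odr3, label="odr-3"),
    InterventionSet.of(ife2, label="ife-2"),
    InterventionSet.of(odr3, ife2, label="odr-3;ife-2"),
]
cfg = PumpingConfig(seed=5, intervention_rate_effects={"odr-3": 0.82, "ife-2": 0.85})
table = simulate_pumping(cfg, strains)

report = endpoint_report(table, control="WT", by="condition", seed=5)
day15 = report[report["condition"] == 15]
print("simulated day-15 pumping (counts/min), Dunnett vs WT:")
print(day15[["strain", "n", "mean", "sem", "effect_percent",
             "dunnett_p"]].to_string(index=False))
print("\nwith n=14 per group only the double intervention's gain is")
print("family-wise significant; the singles' gains are not.\n")

lattice = pumping_day15_lattice()
target = next(s for s in lattice.strains() if len(s) == 2)
cls = classify_combination(lattice, target, tol_rel=0.10)
print(f"published day-15 rates classified: {cls.category}")
print("the 187 % combined increase exceeds the 121 % singleton sum by far")
print("more than the 10 % tolerance - a fully synergistic late-age effect.")
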