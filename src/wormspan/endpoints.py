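"""Endpoint statistics: group summaries, one-way ANOVA, Dunnett's test.

Used for the scalar assay endpoints — pharyngeal pumping rate, stress
survival fractions (heat, paraquat, NaN₃), and brood size — where each
mutant group is compared against the control group (many-to-one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import EndpointTable


@dataclass
class GroupSummary:
    group: tuple
    n: int
    mean: float
    sd: float
    sem: float


def summarize_groups(table: EndpointTable,
                     stratify_by: Sequence[str] = ("strain", "condition")) -> list[GroupSummary]:
    """Per-group mean, SD (ddof=1) and SEM of the endpoint values."""
    out = []
    for key, g in table.data.groupby(list(stratify_by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        vals = g["value"].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out.append(GroupSummary(group=key, n=len(vals), mean=float(vals.mean()),
                                sd=sd, sem=sd / np.sqrt(len(vals))))
    if not out:
        raise ValueError("endpoint table has no rows to summarize")
    return out


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA over ≥2 groups; returns (F, p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical: F is undefined (0/0)")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def dunnett_test(groups: Sequence[Sequence[float]], control_index: int = 0,
                 seed: int = 0, alternative: str = "two-sided") -> pd.DataFrame:
    """Dunnett many-to-one comparisons against the control group.

    Family-wise adjustment uses the joint null distribution of the
    comparisons (equal-correlation multivariate t, integrated by a
    seeded quasi-Monte-Carlo rule), so results are reproducible from
    the seed.  Returns one row per non-control group with the t
    statistic and the adjusted p-value (≥ the raw pooled-t p-value).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need a control and at least one treatment group")
    if not 0 <= control_index < len(arrays):
        raise IndexError("control_index out of range")
    control = arrays[control_index]
    if len(control) == 0:
        raise ValueError("control group is empty")
    treatments = [a for i, a in enumerate(arrays) if i != control_index]
    res = stats.dunnett(*treatments, control=control, alternative=alternative,
                        rng=np.random.default_rng(seed))
    return pd.DataFrame({
        "group_index": [i for i in range(len(arrays)) if i != control_index],
        "statistic": res.statistic,
        "p_adjusted": res.pvalue,
    })


def endpoint_report(table: EndpointTable, control: str, by: str = "condition",
                    seed: int = 0) -> pd.DataFrame:
    """Per-condition ANOVA + Dunnett report for an endpoint assay.

    For each level of ``by`` (e.g. observation day), runs a one-way
    ANOVA across strains and Dunnett's test of every strain against
    ``control``.  Returns a tidy frame of group means ± SEM with the
    adjusted p-values.
    """
    rows = []
    for cond, g in table.data.groupby(by, sort=True):
        strains = sorted(g["strain"].unique())
        if control not in strains:
            raise KeyError(f"control strain {control!r} absent for {by}={cond!r}")
        groups = [g.loc[g["strain"] == s, "value"].to_numpy(dtype=float) for s in strains]
        f, p_anova = one_way_anova(groups)
        dn = dunnett_test(groups, control_index=strains.index(control), seed=seed)
        padj = dict(zip(dn["group_index"], dn["p_adjusted"]))
        ctrl_mean = groups[strains.index(control)].mean()
        for i, s in enumerate(strains):
            vals = groups[i]
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows.append({
                by: cond, "strain": s, "n": len(vals),
                "mean": round(float(vals.mean()), 1),
                "sem": round(sd / np.sqrt(len(vals)), 2),
                "effect_percent": round(100.0 * (vals.mean() - ctrl_mean) / ctrl_mean, 1),
                "anova_F": round(f, 2), "anova_p": p_anova,
                "dunnett_p": padj.get(i, float("nan")),
            })
    return pd.DataFrame(rows)
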