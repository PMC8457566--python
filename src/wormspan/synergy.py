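"""Synergy/additivity classification over the intervention-subset lattice.

For N combined interventions with percent effects Δ (vs the common
control), the categories follow the SynergyAge-style definitions:

* **full synergism** — every proper subset strain is measured and the
  combined effect strictly exceeds Δ(S₁) + Δ(S₂) for *every*
  bipartition (S₁, S₂) of the target;
* **simple synergism** — all single-intervention strains are measured
  and the combined effect strictly exceeds the sum of the single
  effects (intermediate subsets need not be measured);
* **partially known synergism** — only an incrementally built chain of
  strains is measured and the effect strictly increases at every
  extension of the chain.

When the measured coverage is rich enough to *refute* synergism, the
point estimate falls through to: additive (within a relative tolerance
of the singleton sum, 10 % by default), intermediate (between the best
singleton and the sum), antagonistic (no better than the best
singleton), or deleterious (no better than the control).  The
partially-known rule is only reachable when coverage is insufficient
for the full and simple rules, which is what scopes the definitions.

A synergism verdict must clear the same relative tolerance that
defines the additive band: each excess over a partition sum has to be
larger than ``tol_rel`` of that sum, otherwise a sampling fluctuation
just above exact additivity would be promoted to synergism.
Classification uses point estimates of mean effects, with every margin
and threshold exposed in the evidence for uncertainty reasoning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import networkx as nx

from .interventions import InterventionSet
from .survival import effect_percent

CATEGORIES = ("full_synergism", "simple_synergism", "partially_known_synergism",
              "additive", "intermediate", "antagonistic", "deleterious")


class LatticeCoverageError(ValueError):
    """The lattice lacks the strains needed by every classification rule."""


@dataclass(frozen=True)
class LatticeEntry:
    value: float
    effect_percent: float
    sem: float = float("nan")
    p_adjusted: float = float("nan")


@dataclass
class EffectLattice:
    """Measured endpoint values over subsets of an intervention set."""

    background: str
    endpoint: str
    effects: dict[frozenset, LatticeEntry] = field(default_factory=dict)
    labels: dict[frozenset, str] = field(default_factory=dict)

    def get(self, strain: InterventionSet) -> LatticeEntry:
        return self.effects[strain.interventions]

    def __contains__(self, strain: InterventionSet) -> bool:
        return strain.interventions in self.effects

    def strains(self) -> list[InterventionSet]:
        return [InterventionSet(k, self.background, self.labels.get(k, ""))
                for k in self.effects]


def build_lattice(summaries, background: str = "WT",
                  endpoint: str = "mean_lifespan") -> EffectLattice:
    """Build an effect lattice from (strain, value[, sem[, p_adjusted]]) tuples.

    The empty intervention set (the control) must be present; every
    effect is the percent change of the value vs the control's value.
    """
    lattice = EffectLattice(background, endpoint)
    entries = []
    for item in summaries:
        strain, value, *rest = item
        sem = rest[0] if len(rest) > 0 else float("nan")
        p_adj = rest[1] if len(rest) > 1 else float("nan")
        if strain.background != background:
            raise ValueError(
                f"strain {strain.label!r} has background {strain.background!r}, "
                f"lattice requires {background!r}")
        if strain.interventions in {e[0].interventions for e in entries}:
            raise ValueError(f"duplicate strain {strain.label!r}")
        entries.append((strain, float(value), float(sem), float(p_adj)))
    controls = [e for e in entries if e[0].is_control]
    if not controls:
        raise ValueError("control strain (empty intervention set) missing")
    v_control = controls[0][1]
    for strain, value, sem, p_adj in entries:
        lattice.effects[strain.interventions] = LatticeEntry(
            value=value, effect_percent=effect_percent(value, v_control),
            sem=sem, p_adjusted=p_adj)
        lattice.labels[strain.interventions] = strain.label
    return lattice


@dataclass
class SynergyClassification:
    """Verdict for one combination, with every comparison that was run."""

    target: InterventionSet
    category: str
    evidence: list[dict]
    tolerance_used: float


def _bipartitions(items: frozenset):
    items = sorted(items)
    n = len(items)
    for mask in range(1, 2 ** (n - 1)):  # unordered, both blocks non-empty
        s1 = frozenset(x for i, x in enumerate(items) if mask >> i & 1)
        s2 = frozenset(items) - s1
        yield s1, s2


def classify_combination(lattice: EffectLattice, target: InterventionSet,
                         tol_rel: float = 0.10) -> SynergyClassification:
    """Classify an intervention combination on the measured lattice."""
    if len(target) < 2:
        raise ValueError("target must combine at least two interventions")
    if target not in lattice:
        raise LatticeCoverageError(f"target strain {target.label!r} not measured")
    delta = lattice.get(target).effect_percent
    evidence: list[dict] = []

    singles = [InterventionSet(frozenset({iv}), target.background) for iv in target]
    singles_known = all(s in lattice for s in singles)
    proper = [s for s in target.subsets(proper=True) if not s.is_control]
    all_known = all(s in lattice for s in proper)

    single_sum = (sum(lattice.get(s).effect_percent for s in singles)
                  if singles_known else None)
    if singles_known:
        evidence.append({"rule": "simple_synergism", "delta": delta,
                         "singleton_sum": single_sum,
                         "margin": delta - single_sum,
                         "threshold": tol_rel * abs(single_sum)})

    if all_known:
        margins = []
        for s1, s2 in _bipartitions(target.interventions):
            d1 = lattice.effects[s1].effect_percent
            d2 = lattice.effects[s2].effect_percent
            margins.append({"rule": "full_synergism",
                            "partition": (sorted(str(i) for i in s1),
                                          sorted(str(i) for i in s2)),
                            "delta": delta, "partition_sum": d1 + d2,
                            "margin": delta - (d1 + d2),
                            "threshold": tol_rel * abs(d1 + d2)})
        evidence.extend(margins)
        if all(m["margin"] > m["threshold"] for m in margins):
            return SynergyClassification(target, "full_synergism", evidence, tol_rel)

    if not singles_known:
        # coverage too thin for the subset-sum rules: look for a measured chain
        chain = _increasing_chain(lattice, target)
        if chain is not None:
            evidence.append({"rule": "partially_known_synergism", "chain": chain})
            return SynergyClassification(
                target, "partially_known_synergism", evidence, tol_rel)
        raise LatticeCoverageError(
            f"cannot classify {target.label!r}: singletons "
            f"{[s.label for s in singles if s not in lattice]} unmeasured and no "
            "increasing incremental chain is measured")

    if delta - single_sum > tol_rel * abs(single_sum):
        return SynergyClassification(target, "simple_synergism", evidence, tol_rel)

    # synergism refuted -> additive / intermediate / antagonistic / deleterious
    tol_abs = tol_rel * abs(single_sum)
    max_single = max(lattice.get(s).effect_percent for s in singles)
    evidence.append({"rule": "additive", "delta": delta, "singleton_sum": single_sum,
                     "tolerance": tol_abs, "deviation": abs(delta - single_sum)})
    if abs(delta - single_sum) <= tol_abs:
        category = "additive"
    elif max_single < delta < single_sum:
        category = "intermediate"
    elif delta > 0:
        category = "antagonistic"
    else:
        category = "deleterious"
    return SynergyClassification(target, category, evidence, tol_rel)


def _increasing_chain(lattice: EffectLattice, target: InterventionSet):
    """A measured incremental chain with strictly increasing effect, if any."""
    items = sorted(target.interventions)
    for order in permutations(items):
        chain = []
        prev = 0.0
        ok = True
        for k in range(1, len(order) + 1):
            sub = frozenset(order[:k])
            if sub not in lattice.effects:
                ok = False
                break
            eff = lattice.effects[sub].effect_percent
            if eff <= prev:
                ok = False
                break
            chain.append({"strain": sorted(str(i) for i in sub), "effect": eff})
            prev = eff
        if ok:
            return chain
    return None


# -- strain network (lattice graph) ---------------------------------------

_SHAPES = {0: "diamond", 1: "circle", 2: "square", 3: "hexagon", 4: "octagon"}


@dataclass
class LatticeGraph:
    """Directed strain network: edges add exactly one intervention."""

    graph: nx.DiGraph


def annotate_edges(lattice: EffectLattice, pairwise_tests: dict | None = None,
                   neutral_threshold: float = 5.0, alpha: float = 0.05) -> LatticeGraph:
    """Build the strain network with percent-change edge annotations.

    Nodes carry the mean endpoint value (their vertical coordinate),
    SEM, and a shape class by intervention count; each edge origin →
    destination (one added intervention) carries the signed percent
    change and a color class: *increase* / *decrease*, or *neutral*
    when the change is small (< ``neutral_threshold`` %) or
    non-significant (adjusted p ≥ ``alpha``).
    """
    g = nx.DiGraph(background=lattice.background, endpoint=lattice.endpoint)
    keys = list(lattice.effects)
    for k in keys:
        e = lattice.effects[k]
        label = lattice.labels.get(k) or ";".join(sorted(str(i) for i in k)) or lattice.background
        g.add_node(label, value=e.value, sem=e.sem,
                   n_interventions=len(k),
                   shape=_SHAPES.get(len(k), "octagon"),
                   effect_percent=e.effect_percent)
    for origin in keys:
        for dest in keys:
            if origin < dest and len(dest - origin) == 1:
                lo, ld = lattice.labels[origin], lattice.labels[dest]
                v_o, v_d = lattice.effects[origin].value, lattice.effects[dest].value
                change = effect_percent(v_d, v_o)
                p_adj = (pairwise_tests or {}).get((lo, ld),
                                                   lattice.effects[dest].p_adjusted)
                if (p_adj == p_adj and p_adj >= alpha) or abs(change) < neutral_threshold:
                    color = "neutral"
                else:
                    color = "increase" if change > 0 else "decrease"
                g.add_edge(lo, ld, percent_change=round(change, 1),
                           color=color, added=str(next(iter(dest - origin))))
    return LatticeGraph(g)


def export_graph(graph: LatticeGraph, path, fmt: str | None = None) -> None:
    """Write the strain network to GraphML or node-link JSON (lossless)."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "graphml")
    if fmt == "graphml":
        nx.write_graphml(graph.graph, path)
    elif fmt == "json":
        data = nx.node_link_data(graph.graph, edges="edges")
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'graphml' or 'json'")


def import_graph(path, fmt: str | None = None) -> LatticeGraph:
    """Round-trip counterpart of :func:`export_graph`."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "graphml")
    if fmt == "graphml":
        return LatticeGraph(nx.read_graphml(path))
    if fmt == "json":
        data = json.loads(path.read_text(encoding="utf-8"))
        return LatticeGraph(nx.node_link_graph(data, edges="edges"))
    raise ValueError(f"unknown format {fmt!r}; expected 'graphml' or 'json'")
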