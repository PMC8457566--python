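"""End-to-end orchestration: simulate/load → analyze → classify → report.

A run produces a deterministic bundle in the output directory:

* ``survival.tsv`` — per-strain lifespan table vs the control;
* ``occupancy.tsv`` — motility-stage occupancy decomposition;
* ``lattice.graphml`` + ``classifications.json`` — the strain network
  and the synergy verdict for every multi-intervention strain;
* ``manifest.json`` — seed, package version, input digest and SHA-256
  of every output; identical config + seed ⇒ identical digests.

:func:`table1_replay` is the zero-simulation demo: it re-derives the
percent effects, occupancy fractions and synergy verdicts purely from
the published group means of the odr-3/ife-2/cku-70 panel.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, datasets
from .cohort import CohortTable, read_cohort
from .healthspan import fraction_change, occupancy_table
from .interventions import Intervention, InterventionSet
from .simulate import SimulationConfig, simulate_cohort
from .survival import bh_adjust, effect_percent, logrank_test, survival_table
from .synergy import (LatticeCoverageError, annotate_edges, build_lattice,
                      classify_combination, export_graph)

log = logging.getLogger("wormspan")


@dataclass
class RunConfig:
    """One analysis run: exactly one of (cohort_path, simulation) is set."""

    control: str
    cohort_path: str | None = None
    simulation: SimulationConfig | None = None
    strains: list[InterventionSet] = field(default_factory=list)
    alpha: float = 0.05
    tol_rel: float = 0.10
    neutral_threshold: float = 5.0
    outdir: str = "report"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.simulation is None):
            raise ValueError("exactly one of cohort_path / simulation must be given")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a run configuration from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    sim = None
    strains: list[InterventionSet] = []
    if "simulation" in raw:
        spec = dict(raw["simulation"])
        for entry in spec.pop("strains", []):
            members = frozenset(Intervention(i["gene"], i.get("mode", "mutation"))
                                for i in entry.get("interventions", []))
            strains.append(InterventionSet(members, entry.get("background", "WT"),
                                           entry.get("label", "")))
        if "interaction_terms" in spec:
            spec["interaction_terms"] = {frozenset(k.split("+")): v
                                         for k, v in spec["interaction_terms"].items()}
        spec.setdefault("seed", raw.get("seed", 0))
        sim = SimulationConfig(**spec)
    return RunConfig(
        control=raw["control"],
        cohort_path=raw.get("cohort"),
        simulation=sim,
        strains=strains,
        alpha=raw.get("alpha", 0.05),
        tol_rel=raw.get("tol_rel", 0.10),
        neutral_threshold=raw.get("neutral_threshold", 5.0),
        outdir=raw.get("outdir", "report"),
        seed=raw.get("seed", 0),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_report(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Returns the manifest dictionary.  Raises ``KeyError`` naming the
    background when the configured control strain is absent.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        log.info("stage=simulate n_strains=%d seed=%d", len(config.strains), config.seed)
        cohort = simulate_cohort(config.simulation, config.strains)
        input_digest = f"simulated:seed={config.simulation.seed}"
    else:
        log.info("stage=load path=%s", config.cohort_path)
        cohort = read_cohort(config.cohort_path)
        input_digest = _sha256(Path(config.cohort_path))

    if config.control not in cohort.strains():
        background = "WT"
        info = cohort.metadata.get(config.control)
        if info is not None and info.interventions is not None:
            background = info.interventions.background
        raise KeyError(f"control strain {config.control!r} not present "
                       f"(background {background!r})")

    log.info("stage=survival n_worms=%d", cohort.n_worms())
    surv = survival_table(cohort, config.control, alpha=config.alpha)
    surv_path = outdir / "survival.tsv"
    surv.to_csv(surv_path, sep="\t", index=False, lineterminator="\n")

    log.info("stage=healthspan")
    occ = occupancy_table(cohort, config.control)
    occ_path = outdir / "occupancy.tsv"
    occ.to_csv(occ_path, sep="\t", index=False, lineterminator="\n")

    log.info("stage=synergy")
    outputs = [surv_path, occ_path]
    strain_sets = {label: info.interventions
                   for label, info in cohort.metadata.items()
                   if info.interventions is not None}
    if config.control in strain_sets and len(strain_sets) >= 2:
        background = strain_sets[config.control].background
        means = {r["strain"]: r["mean_lifespan"] for _, r in surv.iterrows()}
        sems = {r["strain"]: r["sem"] for _, r in surv.iterrows()}
        members = [(s, means[lbl], sems[lbl]) for lbl, s in sorted(strain_sets.items())
                   if lbl in means and s.background == background]
        lattice = build_lattice(members, background, "mean_lifespan")

        edge_p = _edge_pvalues(cohort, lattice, config.alpha)
        graph = annotate_edges(lattice, edge_p,
                               neutral_threshold=config.neutral_threshold,
                               alpha=config.alpha)
        graph_path = outdir / "lattice.graphml"
        export_graph(graph, graph_path)
        outputs.append(graph_path)

        verdicts = {}
        for lbl, s in sorted(strain_sets.items()):
            if len(s) >= 2 and s in lattice:
                try:
                    c = classify_combination(lattice, s, config.tol_rel)
                    verdicts[lbl] = {"category": c.category, "evidence": c.evidence,
                                     "tolerance_used": c.tolerance_used}
                except LatticeCoverageError as exc:
                    verdicts[lbl] = {"category": "unclassifiable", "reason": str(exc)}
        cls_path = outdir / "classifications.json"
        cls_path.write_text(json.dumps(verdicts, indent=2, sort_keys=True) + "\n",
                            encoding="utf-8")
        outputs.append(cls_path)

    manifest = {
        "package": "wormspan",
        "version": __version__,
        "seed": config.seed,
        "control": config.control,
        "alpha": config.alpha,
        "tol_rel": config.tol_rel,
        "input": input_digest,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                             encoding="utf-8")
    log.info("stage=done outdir=%s", outdir)
    return manifest


def _edge_pvalues(cohort: CohortTable, lattice, alpha: float) -> dict:
    """BH-adjusted log-rank p for every one-intervention edge of the lattice."""
    keys = list(lattice.effects)
    pairs = [(o, d) for o in keys for d in keys if o < d and len(d - o) == 1]
    pvals = []
    for o, d in pairs:
        lo, ld = lattice.labels[o], lattice.labels[d]
        a = cohort.worm_outcomes(lo)
        b = cohort.worm_outcomes(ld)
        _, p = logrank_test(a["duration"], a["event"], b["duration"], b["event"])
        pvals.append(p)
    p_adj, _ = bh_adjust(pvals, alpha)
    return {(lattice.labels[o], lattice.labels[d]): float(pa)
            for (o, d), pa in zip(pairs, p_adj)}


# -- the zero-simulation replay demo --------------------------------------

def table1_replay(tol_rel: float = 0.10) -> dict:
    """Re-derive the headline numbers from the published group means.

    Uses only the published mean lifespans, stage durations and day-15
    pumping effects of the odr-3/ife-2/cku-70 panel: percent effects vs
    control, occupancy fractions and their changes vs control, and the
    synergy classification of every measured combination.
    """
    panel = datasets.lifespan_panel().set_index("label")
    control_mean = panel.loc["WT(EV)", "mean_lifespan"]
    effects = {
        label: round(effect_percent(row["mean_lifespan"], control_mean), 1)
        for label, row in panel.iterrows() if label != "WT(EV)"
    }

    occ = datasets.occupancy_summaries()
    fractions = {label: {"mobile": s.frac_mobile, "impaired": s.frac_impaired,
                         "frail": s.frac_frail} for label, s in occ.items()}
    wt = occ["WT(EV)"]
    changes = {
        label: {state: round(fraction_change(s, wt, state), 1)
                for state in ("mobile", "impaired", "frail")}
        for label, s in occ.items() if label != "WT(EV)"
    }

    lattice = datasets.lifespan_lattice()
    verdicts = {}
    for strain in lattice.strains():
        if len(strain) >= 2:
            c = classify_combination(lattice, strain, tol_rel)
            verdicts[strain.label] = c.category
    pumping = datasets.pumping_day15_lattice()
    pump_target = next(s for s in pumping.strains() if len(s) == 2)
    pump_cls = classify_combination(pumping, pump_target, tol_rel)
    verdicts["pumping_day15:odr-3;ife-2"] = pump_cls.category

    return {"effects": effects, "fractions": fractions,
            "fraction_changes": changes, "classifications": verdicts}
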