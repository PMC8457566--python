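"""Tidy per-worm observation tables: data model, validation, and I/O.

The unit record is one worm on one scoring day: its vital status
(alive / dead / censored), the censoring cause when applicable
(bagging, wall-crawling, extrusion of internal organs, or other), and
its motility stage while alive (A fully mobile, B impaired, C frail).

Day coordinates are integer days post-L4 moult, day 0 = L4.  The
recorded death (or censoring) day is the first day the worm was scored
dead (censored); a worm dead on day *d* therefore has alive records on
days 0..d-1 and one terminal record on day *d*, and its lifespan is *d*.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .interventions import InterventionSet

STATUSES = ("alive", "dead", "censored")
CENSOR_CAUSES = ("none", "bagging", "wall", "extrusion", "other")
MOTILITY_STATES = ("A", "B", "C", "not_scored")

COLUMNS = ("worm_id", "strain", "replicate", "day", "status", "censor_cause", "motility")

_STAGE_ORDER = {"A": 0, "B": 1, "C": 2}


class SchemaError(ValueError):
    """The file/table does not have the expected columns or value domains."""


class CohortValidationError(ValueError):
    """One or more worms violate the per-worm record invariants."""

    def __init__(self, violations: Sequence[tuple[str, str]]):
        self.violations = list(violations)
        lines = "; ".join(f"worm {w!r}: {rule}" for w, rule in self.violations[:20])
        more = "" if len(self.violations) <= 20 else f" (+{len(self.violations) - 20} more)"
        super().__init__(f"invalid cohort: {lines}{more}")


@dataclass(frozen=True)
class StrainInfo:
    """Husbandry metadata for one strain label."""

    interventions: InterventionSet | None = None
    diet: str = "HT115"
    temperature: float = 20.0
    fudr: float = 15.0  # μM


@dataclass
class CohortTable:
    """A validated collection of worm-day observation records.

    ``data`` is a tidy DataFrame with columns ``worm_id, strain,
    replicate, day, status, censor_cause, motility``; ``metadata`` maps
    each strain label to its :class:`StrainInfo`.
    """

    data: pd.DataFrame
    metadata: dict[str, StrainInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _coerce(self.data)
        for strain in self.strains():
            self.metadata.setdefault(strain, StrainInfo())

    # -- accessors ---------------------------------------------------------
    def strains(self) -> list[str]:
        return sorted(self.data["strain"].unique())

    def n_worms(self, strain: str | None = None) -> int:
        df = self.data if strain is None else self.data[self.data["strain"] == strain]
        return df.groupby(["strain", "replicate", "worm_id"]).ngroups

    def strain_data(self, strain: str | InterventionSet) -> pd.DataFrame:
        label = strain.label if isinstance(strain, InterventionSet) else strain
        out = self.data[self.data["strain"] == label]
        if out.empty:
            raise KeyError(f"strain {label!r} not present in cohort")
        return out

    def worm_outcomes(self, strain: str | InterventionSet | None = None) -> pd.DataFrame:
        """One row per worm: terminal ``day``, ``event`` flag (died), cause.

        The terminal record carries the duration: the day the worm was
        first scored dead, or the day it was censored.
        """
        df = self.data if strain is None else self.strain_data(strain)
        term = df[df["status"] != "alive"]
        out = term[["worm_id", "strain", "replicate", "day", "status", "censor_cause"]].copy()
        out["event"] = out["status"].eq("dead")
        return out.rename(columns={"day": "duration"}).reset_index(drop=True)

    # -- validation --------------------------------------------------------
    def validate(self, permissive_motility: bool = False) -> "CohortTable":
        """Check schema, value domains, and the per-worm invariants.

        Raises :class:`SchemaError` or :class:`CohortValidationError`;
        returns ``self`` on success so calls can be chained.
        """
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        for col, domain in (("status", STATUSES), ("censor_cause", CENSOR_CAUSES),
                            ("motility", MOTILITY_STATES)):
            bad = set(df[col].unique()) - set(domain)
            if bad:
                raise SchemaError(f"column {col!r} contains unknown value(s) {sorted(bad)}")
        if (df["day"] < 0).any():
            raise SchemaError("column 'day' contains negative values")

        violations: list[tuple[str, str]] = []
        for (strain, rep, wid), g in df.groupby(["strain", "replicate", "worm_id"], sort=True):
            tag = f"{strain}/rep{rep}/{wid}"
            g = g.sort_values("day")
            days = g["day"].to_numpy()
            if not (days == range(days[0], days[0] + len(days))).all():
                violations.append((tag, "days must be consecutive integers"))
            if days[0] != 0:
                violations.append((tag, "records must start at day 0"))
            status = g["status"].to_numpy()
            terminal = status != "alive"
            if terminal.sum() != 1:
                violations.append((tag, "exactly one terminal (dead/censored) record required"))
            elif not terminal[-1]:
                violations.append((tag, "records found after the terminal record"))
            cause_ok = (g["censor_cause"].eq("none") ^ g["status"].eq("censored")).all()
            if not cause_ok:
                violations.append((tag, "censor_cause must be set iff status is censored"))
            mot = g["motility"].to_numpy()
            alive = status == "alive"
            if (mot[~alive] != "not_scored").any():
                violations.append((tag, "terminal records must have motility not_scored"))
            scored = [m for m, a in zip(mot, alive) if a]
            if not permissive_motility and "not_scored" in scored:
                violations.append((tag, "motility must be scored on every alive day"))
            ranks = [_STAGE_ORDER[m] for m in scored if m != "not_scored"]
            if any(b < a for a, b in zip(ranks, ranks[1:])):
                violations.append((tag, "motility must not improve over days (A→B→C only)"))
        if violations:
            raise CohortValidationError(violations)
        missing_meta = set(self.strains()) - set(self.metadata)
        if missing_meta:
            raise SchemaError(f"strains missing from metadata: {sorted(missing_meta)}")
        return self


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df = df[list(COLUMNS)]
    df["worm_id"] = df["worm_id"].astype(str)
    df["strain"] = df["strain"].astype(str)
    df["replicate"] = df["replicate"].astype(int)
    df["day"] = df["day"].astype(int)
    for col in ("status", "censor_cause", "motility"):
        df[col] = df[col].astype(str)
    return df.reset_index(drop=True)


ASSAYS = ("pumping", "heat", "paraquat", "nan3", "brood")


@dataclass
class EndpointTable:
    """Scalar endpoint assay values, one row per worm (or plate).

    Columns: ``worm_id, strain, replicate, condition, value``;
    ``condition`` is the observation day for pumping or the treatment
    label for stress assays.  Pumping values are counts per minute,
    stress values survival fractions in [0, 1], brood values egg counts.
    """

    assay: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise SchemaError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        required = ("worm_id", "strain", "replicate", "condition", "value")
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise SchemaError(f"endpoint table missing column(s): {', '.join(missing)}")
        vals = self.data["value"]
        if self.assay in ("pumping", "brood"):
            if (vals < 0).any():
                raise SchemaError(f"{self.assay} values must be non-negative")
            if (vals != vals.astype(int)).any():
                raise SchemaError(f"{self.assay} values must be integer counts")
        elif self.assay in ("heat", "paraquat", "nan3"):
            if ((vals < 0) | (vals > 1)).any():
                raise SchemaError("survival fractions must lie in [0, 1]")


# -- file I/O --------------------------------------------------------------

def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_cohort(path: str | Path, dialect: str | None = None,
                metadata: Mapping[str, StrainInfo] | None = None,
                permissive_motility: bool = False) -> CohortTable:
    """Read and validate a delimited observation file.

    The delimiter is auto-detected from the header line (tab or comma)
    unless ``dialect`` gives it explicitly.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise SchemaError(f"{path.name}: empty file (no header line)")
    sep = dialect or _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s): {', '.join(missing)}")
    try:
        df["replicate"] = df["replicate"].astype(int)
        df["day"] = df["day"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"{path.name}: non-integer replicate/day: {exc}") from None
    cohort = CohortTable(df, dict(metadata) if metadata else {})
    return cohort.validate(permissive_motility=permissive_motility)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort deterministically, sorted by (strain, worm_id, day).

    The delimiter follows the file extension: tab for ``.tsv``, comma
    otherwise.  Output is re-readable by :func:`read_cohort`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = cohort.data.sort_values(["strain", "replicate", "worm_id", "day"],
                                 kind="mergesort")
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")


def cohort_bytes(cohort: CohortTable) -> bytes:
    """Canonical serialized form (used for digests / determinism checks)."""
    buf = io.StringIO()
    df = cohort.data.sort_values(["strain", "replicate", "worm_id", "day"],
                                 kind="mergesort")
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    return buf.getvalue().encode("utf-8")


def read_strain_metadata(path: str | Path) -> dict[str, StrainInfo]:
    """Load strain metadata from a YAML mapping.

    Each entry maps a strain label to ``interventions`` (list of
    ``gene``/``mode`` pairs), ``background``, ``diet``, ``temperature``
    and ``fudr``.
    """
    from .interventions import Intervention

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, StrainInfo] = {}
    for label, entry in raw.items():
        entry = entry or {}
        ivs = None
        if "interventions" in entry:
            members = frozenset(
                Intervention(item["gene"], item.get("mode", "mutation"))
                for item in entry["interventions"]
            )
            ivs = InterventionSet(members, entry.get("background", "WT"), label)
        out[label] = StrainInfo(
            interventions=ivs,
            diet=entry.get("diet", "HT115"),
            temperature=float(entry.get("temperature", 20.0)),
            fudr=float(entry.get("fudr", 15.0)),
        )
    return out


# -- pooling ---------------------------------------------------------------

def pool_replicates(cohorts: Sequence[CohortTable]) -> CohortTable:
    """Pool independent experiments into one cohort.

    Replicate indices are offset so they stay distinct across input
    cohorts; worm ids are disambiguated when they collide.  Metadata for
    the same strain label must agree across cohorts.
    """
    if not cohorts:
        raise ValueError("no cohorts to pool")
    if len(cohorts) == 1:
        return cohorts[0]

    metadata: dict[str, StrainInfo] = {}
    for cohort in cohorts:
        for label, info in cohort.metadata.items():
            if label in metadata and metadata[label] != info:
                raise ValueError(f"conflicting metadata for strain {label!r}")
            metadata.setdefault(label, info)

    frames = []
    offset = 0
    seen_ids: set[str] = set()
    for i, cohort in enumerate(cohorts):
        df = cohort.data.copy()
        df["replicate"] = df["replicate"] + offset
        offset = int(df["replicate"].max()) + 1
        clash = set(df["worm_id"].unique()) & seen_ids
        if clash:
            mask = df["worm_id"].isin(clash)
            df.loc[mask, "worm_id"] = df.loc[mask, "worm_id"] + f"#c{i}"
        seen_ids |= set(df["worm_id"].unique())
        frames.append(df)
    pooled = CohortTable(pd.concat(frames, ignore_index=True), metadata)
    return pooled.validate()
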