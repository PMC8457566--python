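"""Strains as sets of genetic interventions.

A strain is modelled as an unordered set of single-gene interventions
(mutation, RNAi knock-down, or half-dose RNAi from a 1:1 mix with
empty-vector bacteria) applied on top of a genetic background (wild type
or e.g. a ``daf-16`` null).  The empty set denotes the control strain of
its background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

MODES = ("mutation", "rnai", "rnai_diluted")

_MODE_SUFFIX = {"mutation": "", "rnai": "(RNAi)", "rnai_diluted": "(RNAi;EV)"}


@dataclass(frozen=True, order=True)
class Intervention:
    """One genetic intervention: a gene symbol plus how it is perturbed."""

    gene: str
    mode: str = "mutation"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown intervention mode {self.mode!r}; expected one of {MODES}")
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")

    def __str__(self) -> str:
        return f"{self.gene}{_MODE_SUFFIX[self.mode]}"


@dataclass(frozen=True)
class InterventionSet:
    """A strain: a set of interventions on a genetic background.

    Equality and hashing are order-insensitive; the empty set is the
    control strain for its background.
    """

    interventions: frozenset[Intervention] = frozenset()
    background: str = "WT"
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        ivs = frozenset(self.interventions)
        object.__setattr__(self, "interventions", ivs)
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if not self.interventions:
            return self.background
        body = ";".join(str(iv) for iv in sorted(self.interventions))
        if self.background == "WT":
            return body
        return f"{self.background};{body}"

    # -- constructors ------------------------------------------------------
    @classmethod
    def control(cls, background: str = "WT", label: str = "") -> "InterventionSet":
        return cls(frozenset(), background, label)

    @classmethod
    def single(cls, gene: str, mode: str = "mutation", background: str = "WT",
               label: str = "") -> "InterventionSet":
        return cls(frozenset({Intervention(gene, mode)}), background, label)

    @classmethod
    def of(cls, *interventions: Intervention, background: str = "WT",
           label: str = "") -> "InterventionSet":
        return cls(frozenset(interventions), background, label)

    # -- set algebra -------------------------------------------------------
    def union(self, other: "InterventionSet", label: str = "") -> "InterventionSet":
        if other.background != self.background:
            raise ValueError(
                f"cannot combine strains from backgrounds {self.background!r} and {other.background!r}"
            )
        return InterventionSet(self.interventions | other.interventions, self.background, label)

    def issubset(self, other: "InterventionSet") -> bool:
        return (self.background == other.background
                and self.interventions <= other.interventions)

    def difference(self, other: "InterventionSet") -> frozenset[Intervention]:
        return self.interventions - other.interventions

    def subsets(self, proper: bool = True) -> Iterable["InterventionSet"]:
        """All (by default proper) subsets, as strains of the same background."""
        from itertools import combinations

        items = sorted(self.interventions)
        top = len(items) if not proper else len(items) - 1
        for k in range(0, top + 1):
            for combo in combinations(items, k):
                yield InterventionSet(frozenset(combo), self.background)

    def __len__(self) -> int:
        return len(self.interventions)

    def __iter__(self):
        return iter(sorted(self.interventions))

    def __str__(self) -> str:
        return self.label

    @property
    def is_control(self) -> bool:
        return not self.interventions
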