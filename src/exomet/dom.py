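"""Screening identified exometabolites against environmental DOM formula sets.

Environmental dissolved-organic-matter datasets are consumed as plain
formula lists (one Hill-notation formula per line); presence/absence is
decided by exact formula identity, never by intensity, since relative
FT-ICR-MS intensities are not comparable across instruments or
extraction protocols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .chem import MolecularFormula, parse_formula
from .metabolites import MetaboliteRecord

__all__ = [
    "DOMFormulaSet",
    "DOMOverlap",
    "load_dom_set",
    "overlap_report",
    "packaged_dom_set",
    "screen",
]

log = logging.getLogger(__name__)

PACKAGED_DOM_SETS = ("mesocosm", "north_sea")


@dataclass(frozen=True)
class DOMFormulaSet:
    name: str
    formulas: frozenset[MolecularFormula]

    def __contains__(self, formula: MolecularFormula) -> bool:
        return formula in self.formulas

    def __len__(self) -> int:
        return len(self.formulas)


def load_dom_set(path, name: str) -> DOMFormulaSet:
    """Read a DOM formula set: one formula per line, '#' comments allowed."""
    if hasattr(path, "read_text"):
        text = path.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    formulas = set()
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            formulas.add(parse_formula(line))
    log.info("DOM set %s: %d formulas", name, len(formulas))
    return DOMFormulaSet(name, frozenset(formulas))


def packaged_dom_set(name: str) -> DOMFormulaSet:
    if name not in PACKAGED_DOM_SETS:
        raise ValueError(f"unknown packaged DOM set {name!r}; have {PACKAGED_DOM_SETS}")
    return load_dom_set(resources.files("exomet").joinpath(f"data/dom_{name}.txt"), name)


def screen(
    identified: Sequence[MetaboliteRecord],
    dom: DOMFormulaSet,
) -> dict[str, bool]:
    """Presence map record name → formula found in the DOM set."""
    return {rec.name: rec.formula in dom.formulas for rec in identified}


@dataclass(frozen=True)
class DOMOverlap:
    """Counts of identified formulas also present in one DOM dataset."""

    dom_name: str
    n_total: int
    per_strain: Mapping[str, int]
    n_all_strains: int
    consistent: bool


def overlap_report(
    identified_by_strain: Mapping[str, Sequence[MetaboliteRecord]],
    dom: DOMFormulaSet,
) -> DOMOverlap:
    """Overlap of per-strain identified formula sets with a DOM set.

    Counts distinct formulas: overall (union over strains), per strain,
    and in every strain.  For two strains, inclusion-exclusion
    consistency is checked and reported — a violation is surfaced, not
    silently repaired.
    """
    per_strain_sets: dict[str, set[MolecularFormula]] = {
        strain: {r.formula for r in recs} & dom.formulas
        for strain, recs in identified_by_strain.items()
    }
    union: set[MolecularFormula] = set().union(*per_strain_sets.values()) if per_strain_sets else set()
    inter: set[MolecularFormula] = (
        set.intersection(*per_strain_sets.values()) if per_strain_sets else set()
    )
    per_strain = {s: len(v) for s, v in per_strain_sets.items()}
    consistent = True
    if len(per_strain) == 2:
        a, b = per_strain.values()
        consistent = len(union) == a + b - len(inter)
        if not consistent:
            log.warning(
                "DOM overlap inclusion-exclusion violated for %s: %d != %d + %d - %d",
                dom.name, len(union), a, b, len(inter),
            )
    return DOMOverlap(
        dom_name=dom.name,
        n_total=len(union),
        per_strain=per_strain,
        n_all_strains=len(inter),
        consistent=consistent,
    )
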