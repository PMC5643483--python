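"""Elemental chemistry primitives for exact-mass work.

Molecular formulas are immutable element→count maps over CHNOSP (plus
sodium), printed in Hill notation (carbon first, hydrogen second, the
remaining elements alphabetical).  Monoisotopic masses are computed from
IUPAC atomic masses pinned in a packaged text table, so that sub-ppm mass
arithmetic is reproducible bit-for-bit across installations.

The double-bond-equivalent convention is the standard one for neutral
CHNOSP molecules: trivalent N and P contribute +1/2 each, divalent O and
S contribute nothing::

    DBE = 1 + C - H/2 + (N + P)/2

A neutral even-electron molecule has an integer, non-negative DBE; a
half-integer value signals a radical or an ion composition written as if
it were neutral.
"""

from __future__ import annotations

import csv
import re
from collections.abc import Mapping
from dataclasses import dataclass, field
from importlib import resources
from types import MappingProxyType
from typing import Iterator

__all__ = [
    "ELECTRON_MASS",
    "DEFAULT_ELEMENTS",
    "ElementTable",
    "FormulaError",
    "MolecularFormula",
    "dbe",
    "is_subformula",
    "load_element_table",
    "monoisotopic_mass",
    "neutral_loss",
    "parse_formula",
]

#: Electron rest mass in Da (CODATA).
ELECTRON_MASS = 0.000548579909

#: Elements the DBE convention covers.
_DBE_ELEMENTS = frozenset("CHNOSP")


class FormulaError(ValueError):
    """Malformed formula string or unsupported element."""


@dataclass(frozen=True)
class ElementTable:
    """Immutable table of monoisotopic atomic masses.

    C, H, N, O, S and P are mandatory; Na is optional.  The proton mass
    is derived as atomic hydrogen minus one electron, which is what the
    [M+H]+/[M-H]- adduct arithmetic needs.
    """

    masses: Mapping[str, float]
    electron_mass: float = ELECTRON_MASS

    def __post_init__(self) -> None:
        frozen = MappingProxyType(dict(self.masses))
        object.__setattr__(self, "masses", frozen)
        for sym in ("C", "H", "N", "O", "S", "P"):
            if sym not in frozen:
                raise ValueError(f"element table is missing mandatory element {sym!r}")
        if frozen["C"] != 12.0:
            raise ValueError("monoisotopic mass of C must be exactly 12 by definition")
        for sym, m in frozen.items():
            if not m > 0:
                raise ValueError(f"non-positive mass for element {sym!r}")

    @property
    def proton_mass(self) -> float:
        return self.masses["H"] - self.electron_mass

    def mass(self, symbol: str) -> float:
        try:
            return self.masses[symbol]
        except KeyError:
            raise FormulaError(f"unknown element symbol {symbol!r}") from None


def load_element_table(path=None) -> ElementTable:
    """Load an element table from a two-column TSV (symbol, monoisotopic_mass)."""
    if path is None:
        source = resources.files("exomet").joinpath("data/elements.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    masses: dict[str, float] = {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        masses[row["symbol"].strip()] = float(row["monoisotopic_mass"])
    return ElementTable(masses)


DEFAULT_ELEMENTS = load_element_table()

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class MolecularFormula(Mapping):
    """An immutable, hashable element→count map.

    Zero counts are never stored; the empty formula (mass 0) is allowed
    and represents e.g. an empty neutral loss.  Equality, hashing and the
    canonical string form all go through the sorted (element, count)
    tuple, so two formulas compare equal iff they are elementwise equal.
    """

    __slots__ = ("_counts", "_key")

    def __init__(self, counts: Mapping[str, int], table: ElementTable = DEFAULT_ELEMENTS):
        clean: dict[str, int] = {}
        for sym, n in counts.items():
            if sym not in table.masses:
                raise FormulaError(f"unknown element symbol {sym!r}")
            if isinstance(n, bool) or not isinstance(n, (int,)):
                raise FormulaError(f"count for {sym!r} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for {sym!r}")
            if n:
                clean[sym] = int(n)
        object.__setattr__(self, "_counts", clean)
        object.__setattr__(self, "_key", tuple(sorted(clean.items())))

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, sym: str) -> int:
        return self._counts[sym]

    def get(self, sym: str, default: int = 0) -> int:
        return self._counts.get(sym, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    # identity ---------------------------------------------------------
    def __hash__(self) -> int:
        return hash(self._key)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, MolecularFormula):
            return self._key == other._key
        return NotImplemented

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("MolecularFormula is immutable")

    # arithmetic -------------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self._counts)
        for sym, n in other.items():
            merged[sym] = merged.get(sym, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = dict(self._counts)
        for sym, n in other.items():
            left = out.get(sym, 0) - n
            if left < 0:
                raise FormulaError(
                    f"cannot subtract {other.hill()} from {self.hill()}: "
                    f"{sym} count would be negative"
                )
            out[sym] = left
        return MolecularFormula(out)

    @property
    def is_empty(self) -> bool:
        return not self._counts

    def hill(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        parts = []
        if "C" in self._counts:
            order = ["C"] + (["H"] if "H" in self._counts else [])
            order += sorted(s for s in self._counts if s not in ("C", "H"))
        else:
            order = sorted(self._counts)
        for sym in order:
            n = self._counts[sym]
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"MolecularFormula({self.hill()!r})"


def parse_formula(text: str, table: ElementTable = DEFAULT_ELEMENTS) -> MolecularFormula:
    """Parse ``"C10H15N2O8P"``-style strings into a :class:`MolecularFormula`.

    Each element symbol may be followed by an optional positive integer
    count (implicit 1).  Unknown symbols and malformed counts raise
    :class:`FormulaError` naming the symbol or the offending position.
    """
    if not isinstance(text, str):
        raise FormulaError(f"formula must be a string, got {type(text).__name__}")
    s = text.strip()
    if not s:
        return MolecularFormula({}, table)
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in table.masses:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        if digits:
            n = int(digits)
            if n <= 0:
                raise FormulaError(
                    f"count for {sym!r} must be positive (position {m.start(2)} in {text!r})"
                )
        else:
            n = 1
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return MolecularFormula(counts, table)


def monoisotopic_mass(f: MolecularFormula, table: ElementTable = DEFAULT_ELEMENTS) -> float:
    """Neutral monoisotopic mass in Da (sum of count × atomic mass)."""
    return sum(n * table.mass(sym) for sym, n in f.items())


def dbe(f: MolecularFormula) -> float:
    """Double-bond equivalents (rings plus double bonds) of a CHNOSP formula.

    May be half-integer; see the module docstring for the convention.
    """
    for sym in f:
        if sym not in _DBE_ELEMENTS:
            raise FormulaError(f"DBE is undefined for element {sym!r} (CHNOSP only)")
    return (
        1.0
        + f.get("C")
        - f.get("H") / 2.0
        + (f.get("N") + f.get("P")) / 2.0
    )


def is_subformula(fragment: MolecularFormula, parent: MolecularFormula) -> bool:
    """True iff every element count of *fragment* is ≤ the parent's.

    Used to check that a proposed fragment composition is consistent
    with its precursor: the implied neutral loss ``parent - fragment``
    then has non-negative counts.
    """
    return all(parent.get(sym) >= n for sym, n in fragment.items())


def neutral_loss(parent: MolecularFormula, fragment: MolecularFormula) -> MolecularFormula:
    """The formula of the neutral loss ``parent - fragment``."""
    if not is_subformula(fragment, parent):
        raise FormulaError(
            f"{fragment.hill()} is not a subformula of {parent.hill()}"
        )
    return parent - fragment
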