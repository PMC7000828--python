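"""Molecular formulas and monoisotopic masses.

A :class:`ChemicalFormula` is an immutable element → count mapping with
elementwise addition/subtraction, a Hill-notation parser/formatter, and a
monoisotopic mass computed from the pinned table in :mod:`ugimem.elements`.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

from .elements import MONOISOTOPIC_MASS

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string, unknown element, or negative count."""


class ChemicalFormula(Mapping):
    """Immutable multiset of atoms.

    Parameters
    ----------
    counts
        Mapping of element symbol to a non-negative atom count. Zero
        counts are dropped; negative counts raise :class:`FormulaError`.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for elem, n in (counts or {}).items():
            if elem not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element {elem!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for {elem}: {n}")
            if n:
                clean[elem] = n
        self._counts = clean

    @classmethod
    def parse(cls, text: str) -> "ChemicalFormula":
        """Parse a Hill-notation string such as ``"C28H43N3O4"``."""
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        for match in _TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"malformed formula {text!r} at position {pos}")
            elem, digits = match.groups()
            if elem not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element {elem!r} in {text!r}")
            counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        return cls(counts)

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, elem: str) -> int:
        return self._counts[elem]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, elem: str, default: int = 0) -> int:
        return self._counts.get(elem, default)

    # -- algebra -----------------------------------------------------------
    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        counts = dict(self._counts)
        for elem, n in other.items():
            counts[elem] = counts.get(elem, 0) + n
        return ChemicalFormula(counts)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        counts = dict(self._counts)
        for elem, n in other.items():
            new = counts.get(elem, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction yields negative {elem} count ({new})"
                )
            counts[elem] = new
        return ChemicalFormula(counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ChemicalFormula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    # -- rendering ---------------------------------------------------------
    def hill(self) -> str:
        """Hill order: C first, then H, then other elements alphabetically."""
        parts = []
        for elem in ("C", "H"):
            n = self._counts.get(elem)
            if n:
                parts.append(elem + (str(n) if n > 1 else ""))
        for elem in sorted(self._counts):
            if elem in ("C", "H"):
                continue
            n = self._counts[elem]
            parts.append(elem + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ChemicalFormula({self.hill()!r})"

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str) -> ChemicalFormula:
    """Parse Hill notation; see :meth:`ChemicalFormula.parse`."""
    return ChemicalFormula.parse(text)


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Sum of per-element counts times most-abundant-isotope masses (Da)."""
    total = 0.0
    for elem, n in formula.items():
        try:
            total += n * MONOISOTOPIC_MASS[elem]
        except KeyError:
            raise FormulaError(f"no tabulated mass for element {elem!r}") from None
    return total
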