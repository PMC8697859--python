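"""Element and isotope reference data plus diatomic formula parsing.

The element table is vendored as a CSV inside the package (``data/elements.csv``)
so that the package works with no network access.  Sources: Slater's empirical
atomic radii, standard reference ionization potentials / electron affinities
(eV) and Pauling electronegativities (Allen-type values are substituted for the
noble gases, which have no Pauling value).  Groups follow the IUPAC 1–18
convention; lanthanides and actinides are assigned group 3.

The hydrogen isotopes D and T are first-class symbols: they share Z = 1,
group 1, period 1 with H but carry their own masses and mass numbers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Optional

__all__ = [
    "ElementRecord",
    "ElementTable",
    "FormulaError",
    "get_element_table",
    "parse_diatomic_formula",
    "format_diatomic_formula",
]


class FormulaError(ValueError):
    """Raised when a diatomic formula cannot be parsed."""


@dataclass(frozen=True)
class ElementRecord:
    """One element or isotope.

    Attributes
    ----------
    symbol:
        Chemical symbol ("H", "D", "T", "Fe", ...).
    Z:
        Atomic number.
    group, period:
        IUPAC group (1–18) and period (1–7).  f-block elements carry group 3.
    mass:
        Atomic mass in u (isotope mass for D/T, standard atomic weight else).
    radius:
        Empirical atomic radius in Å.
    IP, EA:
        Ionization potential and electron affinity in eV (EA = 0 where no
        stable anion exists).
    chi:
        Electronegativity (Pauling scale, dimensionless).
    mass_number:
        Mass number for the hydrogen isotopes D (2) and T (3); ``None``
        otherwise.
    """

    symbol: str
    Z: int
    group: int
    period: int
    mass: float
    radius: float
    IP: float
    EA: float
    chi: float
    mass_number: Optional[int] = None

    def __post_init__(self) -> None:
        if not (1 <= self.group <= 18):
            raise ValueError(f"{self.symbol}: group {self.group} outside 1..18")
        if not (1 <= self.period <= 7):
            raise ValueError(f"{self.symbol}: period {self.period} outside 1..7")
        if self.Z < 1 or self.mass <= 0 or self.radius <= 0:
            raise ValueError(f"{self.symbol}: invalid Z/mass/radius")


class ElementTable:
    """Symbol-indexed lookup over the vendored element table."""

    def __init__(self, records: list[ElementRecord]):
        self._by_symbol = {r.symbol: r for r in records}
        if len(self._by_symbol) != len(records):
            raise ValueError("duplicate symbols in element table")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __getitem__(self, symbol: str) -> ElementRecord:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise FormulaError(f"unknown element symbol {symbol!r}") from None

    def __iter__(self):
        return iter(self._by_symbol.values())

    def __len__(self) -> int:
        return len(self._by_symbol)

    @property
    def symbols(self) -> list[str]:
        return list(self._by_symbol)


_TABLE: Optional[ElementTable] = None


def _load_table() -> ElementTable:
    records = []
    path = resources.files("spectroml.data").joinpath("elements.csv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                ElementRecord(
                    symbol=row["symbol"],
                    Z=int(row["Z"]),
                    group=int(row["group"]),
                    period=int(row["period"]),
                    mass=float(row["mass"]),
                    radius=float(row["radius"]),
                    IP=float(row["IP"]),
                    EA=float(row["EA"]),
                    chi=float(row["chi"]),
                    mass_number=int(row["mass_number"]) if row["mass_number"] else None,
                )
            )
    return ElementTable(records)


def get_element_table() -> ElementTable:
    """Return the (cached) vendored element table."""
    global _TABLE
    if _TABLE is None:
        _TABLE = _load_table()
    return _TABLE


def parse_diatomic_formula(
    formula: str, table: Optional[ElementTable] = None
) -> tuple[ElementRecord, ElementRecord]:
    """Split a diatomic formula into its two constituent elements.

    The formula must be the concatenation of exactly two element/isotope
    symbols (e.g. ``"NaK"``, ``"DF"``).  When several splits are possible the
    split where both tokens are valid symbols wins; if both splits are valid,
    the one with a two-letter first token is preferred.  Written order is
    preserved.

    Raises
    ------
    FormulaError
        For unparseable strings, unknown symbols and homonuclear pairs
        (isotopes such as H/D count as distinct).
    """
    table = table or get_element_table()
    formula = formula.strip()
    if not (2 <= len(formula) <= 4):
        raise FormulaError(f"cannot parse diatomic formula {formula!r}")

    candidates = []
    for cut in (2, 1):  # two-letter first token preferred
        a, b = formula[:cut], formula[cut:]
        if 1 <= len(b) <= 2 and a in table and b in table:
            candidates.append((a, b))
    if not candidates:
        # diagnose the offending token for the error message
        for cut in (2, 1):
            a, b = formula[:cut], formula[cut:]
            if a in table and b and b not in table:
                raise FormulaError(f"unknown element symbol {b!r} in {formula!r}")
        raise FormulaError(f"unknown element symbol {formula[:1]!r} in {formula!r}")

    a, b = candidates[0]
    if a == b:
        raise FormulaError(f"homonuclear molecule {formula!r} is not supported")
    return table[a], table[b]


def format_diatomic_formula(atom1: ElementRecord, atom2: ElementRecord) -> str:
    """Inverse of :func:`parse_diatomic_formula` (written order preserved)."""
    return atom1.symbol + atom2.symbol
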