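"""Monoisotopic mass bookkeeping for Girard-P derivative ions.

Element masses are hard-coded to CODATA/NIST monoisotopic values in a single
table so that golden-value tests are hermetic.  Deuterium is written as the
isotope token ``[2H]`` (``D`` is accepted on input); carbon-13 substitutions
are handled as an isotopologue index rather than as formula entries, because
the :sup:`13`\\ C envelope of a derivative is a property of natural abundance,
not of the molecule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping


class FormulaError(ValueError):
    """Element bookkeeping went negative or a symbol is unknown."""


class InvalidIsotopologueError(ValueError):
    """Requested more 13C substitutions than there are carbons."""


@dataclass(frozen=True)
class ElementMassTable:
    """Monoisotopic isotope masses in unified atomic mass units."""

    entries: Mapping[str, float]
    electron_mass: float = 0.000548579909

    def mass(self, symbol: str) -> float:
        try:
            return self.entries[symbol]
        except KeyError:
            raise FormulaError(f"unknown isotope symbol: {symbol!r}") from None

    @property
    def c13_shift(self) -> float:
        return self.entries["13C"] - self.entries["C"]

    @property
    def deuterium_shift(self) -> float:
        return self.entries["2H"] - self.entries["H"]


#: NIST monoisotopic masses (u).  The only table the package uses.
DEFAULT_MASSES = ElementMassTable(
    entries={
        "H": 1.00782503207,
        "2H": 2.01410177785,
        "C": 12.0,
        "13C": 13.00335483778,
        "N": 14.0030740048,
        "O": 15.9949146196,
    }
)

_TOKEN = re.compile(r"\[(\d+)([A-Z][a-z]?)\]|([A-Z][a-z]?)|(\d+)")


@dataclass(frozen=True)
class MolecularFormula:
    """An isotope-resolved molecular formula with a signed charge.

    Counts are element-wise non-negative; addition and subtraction are
    element-wise and subtraction raises :class:`FormulaError` rather than
    produce a negative count.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {k: int(v) for k, v in self.counts.items() if v != 0}
        for sym, n in clean.items():
            if n < 0:
                raise FormulaError(f"negative count for {sym}: {n}")
        object.__setattr__(self, "counts", clean)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return MolecularFormula(counts, self.charge + other.charge)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            new = counts.get(sym, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction yields negative {sym} count ({new})"
                )
            counts[sym] = new
        return MolecularFormula(counts, self.charge - other.charge)

    def replace_charge(self, charge: int) -> "MolecularFormula":
        return MolecularFormula(dict(self.counts), charge)

    # -- queries ------------------------------------------------------------
    def count(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    @property
    def carbon_count(self) -> int:
        return self.count("C") + self.count("13C")

    @property
    def deuterium_count(self) -> int:
        return self.count("2H")

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self.counts.items()))

    # -- parsing / formatting ----------------------------------------------
    @classmethod
    def parse(cls, text: str, charge: int | None = None) -> "MolecularFormula":
        """Parse Hill-style notation with ``[2H]n`` or ``D`` deuterium tokens.

        A trailing ``+``/``-`` sets the charge (one sign per unit charge);
        an explicit ``charge=`` argument overrides it.
        """
        text = text.strip()
        sign_charge = 0
        while text and text[-1] in "+-":
            sign_charge += 1 if text[-1] == "+" else -1
            text = text[:-1]
        counts: Dict[str, int] = {}
        pos = 0
        last_sym: str | None = None
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if m is None:
                raise FormulaError(f"cannot parse formula at {text[pos:]!r}")
            iso_n, iso_sym, sym, digits = m.groups()
            if digits is not None:
                if last_sym is None:
                    raise FormulaError(f"dangling count in {text!r}")
                counts[last_sym] = counts.get(last_sym, 0) - 1 + int(digits)
                last_sym = None
            else:
                if iso_sym is not None:
                    key = f"{iso_n}{iso_sym}"
                elif sym == "D":
                    key = "2H"
                else:
                    key = sym
                counts[key] = counts.get(key, 0) + 1
                last_sym = key
            pos = m.end()
        return cls(counts, charge if charge is not None else sign_charge)

    def hill(self) -> str:
        """Hill notation; deuterium rendered as an explicit ``[2H]n`` token."""
        order = ["C", "13C", "H", "2H"]
        rest = sorted(k for k in self.counts if k not in order)
        parts = []
        for sym in order + rest:
            n = self.count(sym)
            if n == 0:
                continue
            token = f"[{sym}]" if sym[0].isdigit() else sym
            parts.append(token if n == 1 else f"{token}{n}")
        s = "".join(parts)
        if self.charge:
            s += ("+" if self.charge > 0 else "-") * abs(self.charge)
        return s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def neutral_mass(
    formula: MolecularFormula, table: ElementMassTable = DEFAULT_MASSES
) -> float:
    """Sum of isotope masses, ignoring charge and electrons."""
    return sum(table.mass(sym) * n for sym, n in formula.counts.items())


def monoisotopic_mz(
    formula: MolecularFormula,
    isotopologue_k: int = 0,
    table: ElementMassTable = DEFAULT_MASSES,
) -> float:
    """m/z of the *k*-th 13C isotopologue of a charged formula.

    m/z = (sum of isotope masses + k*(m13C - m12C) - charge*m_e) / |charge|.
    """
    if formula.charge == 0:
        raise FormulaError("m/z undefined for a neutral formula")
    if isotopologue_k < 0 or isotopologue_k > formula.count("C"):
        raise InvalidIsotopologueError(
            f"isotopologue k={isotopologue_k} outside 0..{formula.count('C')}"
        )
    m = neutral_mass(formula, table)
    m += isotopologue_k * table.c13_shift
    m -= formula.charge * table.electron_mass
    return m / abs(formula.charge)


# Small reusable neutral fragments.
H2 = MolecularFormula({"H": 2})
H2O = MolecularFormula({"H": 2, "O": 1})
PROTON = MolecularFormula({"H": 1}, charge=+1)
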