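"""Molecular-formula arithmetic for accurate-mass metabolite identification.

Everything downstream — candidate enumeration, precursor matching, neutral-loss
annotation — reduces to sums over a small table of monoisotopic atomic masses.
The table is embedded as constants so that theoretical m/z values, and hence
reported mass errors, are reproducible independent of any external isotope
database.

Conventions
-----------
* Masses are monoisotopic, in Da.
* Only singly charged positive adducts ([M+H]+, [M+Na]+, [M+K]+) are
  supported: every ion in the target application is a +1 cation.
* Cation m/z subtracts one electron mass from the neutral-atom mass, i.e.
  ``m/z = M + m(cation atom) - m(e-)``; for H this equals the proton mass.
* Mass errors are reported in mDa, sign preserved, rounded half away from
  zero to one decimal.
"""

from __future__ import annotations

import math
import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "FormulaError",
    "Formula",
    "Adduct",
    "ADDUCTS",
    "parse_formula",
    "parse_ion",
    "formula_mass",
    "ion_mz",
    "mass_error_mda",
    "reported_mda",
    "apply_formula_delta",
]

#: Monoisotopic atomic masses (Da), fixed CODATA/IUPAC values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.007825,
    "C": 12.000000,
    "N": 14.003074,
    "O": 15.994915,
    "Na": 22.989770,
    "K": 38.963707,
}

PROTON_MASS = 1.007276  # Da; = m(H) - m(e-)
ELECTRON_MASS = 0.000549  # Da


class FormulaError(ValueError):
    """Raised for malformed formula strings or infeasible element counts."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """An immutable element -> count mapping with canonical equality.

    Zero counts are dropped on construction, so two formulas are equal iff
    they describe the same composition regardless of input order or the
    presence of explicit zeros.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None) -> None:
        clean: dict[str, int] = {}
        for element, n in (counts or {}).items():
            if n != int(n):
                raise FormulaError(f"non-integer count {n!r} for element {element}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count {n} for element {element}")
            if n:
                clean[element] = n
        object.__setattr__(self, "_counts", clean)

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        # Hill order: C first, H second, then alphabetical.
        return iter(sorted(self._counts, key=lambda e: (e != "C", e != "H", e)))

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {e: n for e, n in other.items() if n}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:  # pragma: no cover - debugging sugar
        return f"Formula({str(self)!r})"

    def __str__(self) -> str:
        return "".join(
            f"{e}{self._counts[e] if self._counts[e] != 1 else ''}" for e in self
        )

    # -- chemistry ---------------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string.

        Accepts both the plain dialect (``"C15H22O5"``) and the
        underscore-subscript dialect (``"C_15_H_22_O_5_"``).
        """
        plain = text.replace("_", "").strip()
        counts: dict[str, int] = {}
        pos = 0
        while pos < len(plain):
            m = _TOKEN.match(plain, pos)
            if m is None or not m.group(1):
                raise FormulaError(
                    f"malformed formula {text!r}: unexpected character "
                    f"{plain[pos]!r} at position {pos}"
                )
            element, digits = m.group(1), m.group(2)
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = m.end()
        return cls(counts)

    def mass(self, masses: Mapping[str, float] | None = None) -> float:
        return formula_mass(self, masses)


@dataclass(frozen=True)
class Adduct:
    """A singly charged cationizing species, e.g. [M+Na]+."""

    label: str
    cation: str  # element symbol whose neutral atom attaches
    charge: int = 1

    def mz(self, neutral_mass: float, masses: Mapping[str, float] | None = None) -> float:
        table = MONOISOTOPIC_MASS if masses is None else masses
        if self.cation not in table:
            raise FormulaError(f"no mass for cation {self.cation!r}")
        return neutral_mass + table[self.cation] - ELECTRON_MASS


#: The closed default adduct set; extensible by constructing further Adducts.
ADDUCTS: dict[str, Adduct] = {
    "M+H": Adduct("M+H", "H"),
    "M+Na": Adduct("M+Na", "Na"),
    "M+K": Adduct("M+K", "K"),
}

_ADDUCT_SUFFIX = re.compile(r"\+\s*(H|Na|K)\s*(?:\^)?\+(?:\^)?\s*$")


def parse_formula(text: str) -> Formula:
    """Parse a formula string in either accepted dialect. See :meth:`Formula.parse`."""
    return Formula.parse(text)


def parse_ion(text: str) -> tuple[Formula, Adduct]:
    """Split an ion string such as ``"C_15_H_22_O_6_ + Na^+^"`` into
    (neutral formula, adduct).
    """
    m = _ADDUCT_SUFFIX.search(text)
    if m is None:
        raise FormulaError(
            f"no adduct suffix in {text!r}; expected one of "
            f"{sorted('M+' + a for a in ('H', 'Na', 'K'))}"
        )
    adduct = ADDUCTS[f"M+{m.group(1)}"]
    return Formula.parse(text[: m.start()].rstrip(" +")), adduct


def formula_mass(
    formula: Mapping[str, int], masses: Mapping[str, float] | None = None
) -> float:
    """Monoisotopic mass (Da) of a neutral formula: sum of count x atom mass."""
    table = MONOISOTOPIC_MASS if masses is None else masses
    total = 0.0
    for element, n in formula.items():
        if element not in table:
            raise FormulaError(f"no monoisotopic mass for element {element!r}")
        total += n * table[element]
    return total


def ion_mz(
    formula: Mapping[str, int],
    adduct: Adduct | str,
    masses: Mapping[str, float] | None = None,
) -> float:
    """Theoretical m/z of the +1 adduct ion of ``formula``.

    m/z = M + m(cation atom) - m(electron); for [M+H]+ this is M + 1.007276.
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise FormulaError(
                f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
            ) from None
    return adduct.mz(formula_mass(formula, masses), masses)


def mass_error_mda(observed: float, theoretical: float) -> float:
    """Signed mass error (observed - theoretical) in mDa, unrounded."""
    return (observed - theoretical) * 1000.0


def reported_mda(error_mda: float, decimals: int = 1) -> float:
    """Round a mDa error half away from zero, the sign-preserving style used
    for reporting (so -0.45 -> -0.5, not -0.4)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(error_mda) * factor + 0.5) / factor, error_mda)


def apply_formula_delta(
    formula: Mapping[str, int], delta: Mapping[str, int]
) -> Formula:
    """Apply a signed element-count delta (e.g. ``{"O": -1}``) to a formula.

    Raises :class:`FormulaError` if any resulting count would be negative —
    the transformation is infeasible for that composition.
    """
    counts = dict(formula)
    for element, change in delta.items():
        new = counts.get(element, 0) + change
        if new < 0:
            raise FormulaError(
                f"infeasible transformation: {element} count would be {new} "
                f"applying {dict(delta)} to {Formula(dict(formula))}"
            )
        counts[element] = new
    return Formula(counts)
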