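"""Elemental-formula algebra and monoisotopic mass arithmetic.

This is the numeric kernel of the package: an immutable element-count
formula type with Hill-notation parsing/rendering, monoisotopic mass,
proton-adduct m/z for multiply charged ions, and the signed ppm mass-error
metric used for identity assignment in high-resolution MS.

All masses are monoisotopic (lightest-isotope) atomic masses in daltons.
Charging is modelled as proton addition, i.e. the electron mass is *not*
included with the adduct hydrogen — at z = 2 the distinction already moves
the fourth decimal of m/z, so it matters for 4-dp report values.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "WATER",
    "FormulaError",
    "ElementalFormula",
    "ChargedIon",
    "MassError",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
]

#: Monoisotopic atomic masses (Da). 12C is exact by definition; the other
#: values are the CODATA/IUPAC lightest-isotope masses. Centralised here so
#: an alternative constants set is a one-place change.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Se": 78.9718499,
}

#: Mass of the proton (Da), used for [M + zH]z+ adducts.
PROTON_MASS: float = 1.007276466621

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid formula arithmetic."""


class ElementalFormula(Mapping):
    """Immutable map from element symbol to a non-negative integer count.

    Formulas form a commutative monoid under ``+``; ``-`` is partial
    (raising :class:`FormulaError` if any count would go negative) and
    ``*`` scales by a non-negative integer. Elements with count zero are
    dropped from the canonical representation, so ``str`` round-trips
    through :meth:`parse`.

    >>> f = ElementalFormula.parse("C76H108N20O25S3")
    >>> f["S"], str(f - ElementalFormula({"S": 3}) + ElementalFormula(H=6))
    (3, 'C76H114N20O25')
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for element, count in source.items():
                merged[element] = merged.get(element, 0) + int(count)
        for element, count in merged.items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if count != int(count) or count < 0:
                raise FormulaError(
                    f"count for {element} must be a non-negative integer, got {count!r}"
                )
        object.__setattr__(
            self, "_counts", {el: int(n) for el, n in merged.items() if n > 0}
        )

    # -- parsing / rendering -------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-notation formula string such as ``"C76H108N20O25S3"``.

        A missing count means 1 (``"CH4"``). Lowercase-led tokens, stray
        characters and the empty string are rejected.
        """
        if not isinstance(text, str) or not text.strip():
            raise FormulaError("empty formula string")
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if m is None or m.start() != pos or not m.group(1):
                raise FormulaError(f"malformed token at {text[pos:]!r} in {text!r}")
            element, digits = m.groups()
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = m.end()
        return cls(counts)

    def hill(self) -> str:
        """Canonical Hill-order rendering: C, H, then other elements A→Z.

        If no carbon is present all elements are ordered alphabetically.
        """
        if not self._counts:
            return ""
        symbols = sorted(self._counts)
        if "C" in self._counts:
            ordered = ["C"] + (["H"] if "H" in self._counts else [])
            ordered += [s for s in symbols if s not in ("C", "H")]
        else:
            ordered = symbols
        return "".join(
            f"{el}{self._counts[el] if self._counts[el] != 1 else ''}"
            for el in ordered
        )

    # -- Mapping protocol ----------------------------------------------------

    def __getitem__(self, element: str) -> int:
        # Absent elements count zero; iteration only visits present ones.
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element: object) -> bool:
        return element in self._counts

    # -- algebra ---------------------------------------------------------------

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        counts = dict(self._counts)
        for el, n in other._counts.items():
            counts[el] = counts.get(el, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        counts = dict(self._counts)
        for el, n in other._counts.items():
            counts[el] = counts.get(el, 0) - n
            if counts[el] < 0:
                raise FormulaError(
                    f"subtraction yields negative count for {el}: "
                    f"{self.hill()!r} - {other.hill()!r}"
                )
        return ElementalFormula(counts)

    def __mul__(self, n: int) -> "ElementalFormula":
        if not isinstance(n, int):
            return NotImplemented
        if n < 0:
            raise FormulaError("formula multiplier must be non-negative")
        return ElementalFormula({el: c * n for el, c in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"

    def __str__(self) -> str:
        return self.hill()

    @property
    def monoisotopic_mass(self) -> float:
        """Monoisotopic mass in daltons (0.0 for the empty formula)."""
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self._counts.items())

    @property
    def n_atoms(self) -> int:
        return sum(self._counts.values())


WATER = ElementalFormula(H=2, O=1)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass (Da) of a formula or Hill-notation string."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return formula.monoisotopic_mass


def ion_mz(formula: ElementalFormula | str, charge: int) -> float:
    """m/z of the [M + zH]z+ ion: (M + z·m_proton) / z, full precision.

    Report surfaces round half-even to 4 decimal places; use
    ``round(ion_mz(...), 4)`` for table values.
    """
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (monoisotopic_mass(formula) + charge * PROTON_MASS) / charge


def ppm_error(observed_mz: float, calculated_mz: float) -> float:
    """Signed relative mass error, (observed − calculated)/calculated × 1e6.

    The sign convention makes a heavy observation positive. Report surfaces
    round to 2 decimal places.
    """
    if calculated_mz <= 0:
        raise ValueError(f"calculated m/z must be positive, got {calculated_mz}")
    return (observed_mz - calculated_mz) / calculated_mz * 1e6


@dataclass(frozen=True)
class ChargedIon:
    """A (formula, charge) pair with its proton-adduct m/z."""

    formula: ElementalFormula
    charge: int
    mz: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", ion_mz(self.formula, self.charge))

    @property
    def mz_4dp(self) -> float:
        return round(self.mz, 4)


@dataclass(frozen=True)
class MassError:
    """An observed/calculated m/z pair and its signed ppm error."""

    observed_mz: float
    calculated_mz: float

    @property
    def ppm(self) -> float:
        return ppm_error(self.observed_mz, self.calculated_mz)

    @property
    def ppm_2dp(self) -> float:
        return round(self.ppm, 2)
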