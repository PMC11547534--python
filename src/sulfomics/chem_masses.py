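"""Molecular-formula parsing and monoisotopic mass / m/z arithmetic.

Negative-mode high-resolution MS of steroid sulfate conjugates rests on a
handful of exact-mass quantities: the monoisotopic masses of neutral losses
(SO3, H2SO4) and the m/z of small sulfur-oxide anions (SO3-., HSO3-, SO4-.,
HSO4-), plus the deprotonated molecule of each candidate conjugate.  This
module provides those computations and the ppm mass-deviation arithmetic
used everywhere downstream.

Conventions
-----------
* Monoisotopic element masses are NIST/CODATA values embedded as constants,
  so results are reproducible without any network resource.
* Anion m/z is electron-inclusive: the mass of the extra electron
  (~5.486e-4 Da) is added.  With this convention the printed reference
  values for HSO3- (80.9652), HSO4- (96.9601) and SO4-. (95.9523) are
  reproduced exactly at 4 decimal places.
* Formulas are rendered canonically in Hill order (C first, then H, then
  all other elements alphabetically).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Mapping

__all__ = [
    "ELEMENT_MASSES",
    "ELECTRON_MASS",
    "MolecularFormula",
    "IonKind",
    "IonSpecies",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_delta",
]

#: Monoisotopic masses (Da) of the elements needed for steroid sulfates and
#: common small-molecule chemistry.  12C defines the scale exactly.
ELEMENT_MASSES: Dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146,
    "S": 31.9720707,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885271,
    "F": 18.99840320,
}

#: Electron rest mass in Da.
ELECTRON_MASS: float = 0.0005485799

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formula strings."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count mapping with Hill-order canonical rendering."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}")
        # drop zero counts for a canonical representation
        object.__setattr__(
            self, "counts", {el: n for el, n in self.counts.items() if n > 0}
        )

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
        return MolecularFormula(merged)  # __post_init__ rejects negatives

    def hill(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical)."""
        parts = []
        rest = dict(self.counts)
        for el in ("C", "H"):
            if el in rest:
                n = rest.pop(el)
                parts.append(el + (str(n) if n != 1 else ""))
        for el in sorted(rest):
            n = rest[el]
            parts.append(el + (str(n) if n != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    def __hash__(self) -> int:
        return hash(self.hill())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)


def parse_formula(text: str) -> MolecularFormula:
    """Parse an element-count string such as ``"C18H22O5S"``.

    Counts default to 1 (``"H"`` -> one hydrogen).  Raises
    :class:`FormulaError` for empty input or unknown element symbols.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(
                f"unparseable formula {text!r} at position {pos}"
            )
        if not m.group(0):
            break
        el, digits = m.group(1), m.group(2)
        if el not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"unparseable formula {text!r} at position {pos}")
    if not counts:
        raise FormulaError(f"no elements found in {text!r}")
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass in Da; the empty formula has mass 0."""
    total = 0.0
    for el, n in f.counts.items():
        try:
            total += ELEMENT_MASSES[el] * n
        except KeyError:
            raise FormulaError(f"element {el!r} missing from mass table") from None
    return total


class IonKind(str, Enum):
    DEPROTONATED = "deprotonated-molecule"
    RADICAL_ANION = "radical-anion"
    ANION = "anion-with-explicit-formula"
    NEUTRAL_LOSS = "neutral-loss"


@dataclass(frozen=True)
class IonSpecies:
    """A charged (or neutral-loss) species derived from a molecular formula.

    * deprotonated-molecule: formula is the *neutral* molecule M; the ion is
      [M-H]- and its m/z is M - m(H) + m(e-).
    * radical-anion / anion-with-explicit-formula: formula is the ion's own
      composition; m/z is mass(formula) + m(e-).
    * neutral-loss: an uncharged mass difference; "m/z" is just its mass.
    """

    formula: MolecularFormula
    kind: IonKind
    charge: int = -1

    def __post_init__(self) -> None:
        if self.kind is IonKind.NEUTRAL_LOSS:
            if self.charge != 0:
                raise ValueError("neutral-loss species must have charge 0")
        else:
            if self.charge != -1:
                raise ValueError(
                    f"{self.kind.value} must carry charge -1, got {self.charge}"
                )


_H = MolecularFormula({"H": 1})


def ion_mz(ion: IonSpecies) -> float:
    """m/z of an :class:`IonSpecies` under the electron-inclusive convention."""
    m = monoisotopic_mass(ion.formula)
    if ion.kind is IonKind.NEUTRAL_LOSS:
        return m
    if ion.kind is IonKind.DEPROTONATED:
        return m - ELEMENT_MASSES["H"] + ELECTRON_MASS
    # radical anion or explicit-formula anion: add one electron
    return m + ELECTRON_MASS


def deprotonated_mz(formula: MolecularFormula | str) -> float:
    """Convenience: [M-H]- m/z for a neutral molecule formula."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return ion_mz(IonSpecies(formula, IonKind.DEPROTONATED))


def ppm_delta(observed: float, theoretical: float) -> float:
    """Signed mass deviation in parts-per-million.

    ``1e6 * (observed - theoretical) / theoretical``; raises ``ValueError``
    for a non-positive theoretical m/z.
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical
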