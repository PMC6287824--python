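"""Exact monoisotopic mass arithmetic for elemental formulas.

Everything downstream of the mass spectrometer — peak calibration,
mass-difference networks, formula propagation — reduces to arithmetic on
monoisotopic masses of small elemental formulas.  This module provides the
formula container, parsing/formatting, neutral and deprotonated-ion masses,
ppm errors, and the catalogue of mass-difference "building blocks"
(elemental composition changes such as CH2 or H2O that correspond to
common biochemical transformations).

Masses are in daltons (Da) throughout.  The atomic-mass table is pinned to
CODATA/IUPAC monoisotopic values (12C = 12 exactly); negative-mode
electrospray produces [M-H]- ions, so the ion mass is the neutral mass
minus a proton (hydrogen atom minus its electron).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "ATOMIC_MASSES",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "C13_SPACING",
    "ElementalFormula",
    "BuildingBlock",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "deprotonated_ion_mass",
    "ppm_error",
    "default_building_blocks",
    "load_building_blocks",
]

# Monoisotopic atomic masses (Da).  Extensible: pass extra elements via the
# ``masses`` argument of :func:`monoisotopic_mass` if ever needed; the
# default scope is CHNOPS, which covers the metabolite space handled here.
ATOMIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.007825032,
    "N": 14.003074005,
    "O": 15.994914620,
    "P": 30.973761998,
    "S": 31.972071174,
}

ELECTRON_MASS = 0.000548580
#: Mass removed from a neutral molecule upon deprotonation ([M-H]-).
PROTON_MASS = ATOMIC_MASSES["H"] - ELECTRON_MASS
#: 13C - 12C isotopologue spacing (Da).
C13_SPACING = 1.0033548

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid element counts."""


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable map element symbol -> non-negative integer count.

    Supports addition and subtraction (subtraction may produce negative
    counts via :meth:`shift`, which callers must validate with
    :meth:`is_valid` — formula propagation along a network edge can run in
    either direction).
    """

    counts: tuple[tuple[str, int], ...] = field(default=())

    @staticmethod
    def from_dict(d: Mapping[str, int]) -> "ElementalFormula":
        items = tuple(sorted((e, int(n)) for e, n in d.items() if n != 0))
        return ElementalFormula(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def is_valid(self) -> bool:
        """True iff every element count is non-negative."""
        return all(n >= 0 for _, n in self.counts)

    def shift(self, delta: "ElementalFormula", sign: int = 1) -> "ElementalFormula":
        """Return self + sign * delta (counts may go negative)."""
        d = self.as_dict()
        for e, n in delta.counts:
            d[e] = d.get(e, 0) + sign * n
        return ElementalFormula.from_dict(d)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return self.shift(other, +1)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return self.shift(other, -1)

    def __str__(self) -> str:
        return format_formula(self)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str, masses: Mapping[str, float] | None = None) -> ElementalFormula:
    """Parse a Hill-style formula string like ``"C5H7NO3"``.

    Grammar: element symbol (capital letter, optional lowercase letter)
    followed by an optional positive integer count.  Unknown element
    symbols and explicit zero counts are rejected.
    """
    masses = masses or ATOMIC_MASSES
    text = text.strip()
    if not text:
        return ElementalFormula()
    pos = 0
    counts: dict[str, int] = {}
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in masses:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"count for {element} must be positive in {text!r}")
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return ElementalFormula.from_dict(counts)


def format_formula(f: ElementalFormula) -> str:
    """Hill order: C, then H, then the rest alphabetically."""
    d = f.as_dict()
    parts = []
    for e in ["C", "H"] + sorted(k for k in d if k not in ("C", "H")):
        n = d.get(e, 0)
        if n == 1:
            parts.append(e)
        elif n > 1:
            parts.append(f"{e}{n}")
        elif n < 0:
            parts.append(f"{e}({n})")  # only reachable on unvalidated shifts
    return "".join(parts)


def monoisotopic_mass(f: ElementalFormula | Mapping[str, int],
                      masses: Mapping[str, float] | None = None) -> float:
    """Sum of monoisotopic atomic masses; the empty formula has mass 0."""
    masses = masses or ATOMIC_MASSES
    items = f.counts if isinstance(f, ElementalFormula) else tuple(f.items())
    total = 0.0
    for e, n in items:
        try:
            total += n * masses[e]
        except KeyError:
            raise FormulaError(f"no atomic mass for element {e!r}") from None
    return total


def deprotonated_ion_mass(f: ElementalFormula) -> float:
    """m/z of the [M-H]- ion at charge 1: neutral mass - m(H) + m(e-)."""
    if f["H"] < 1:
        raise FormulaError(f"cannot deprotonate {format_formula(f)!r}: no hydrogen")
    return monoisotopic_mass(f) - ATOMIC_MASSES["H"] + ELECTRON_MASS


def neutral_from_ion(mz: float) -> float:
    """Neutral monoisotopic mass of a singly charged [M-H]- ion."""
    return mz + PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class BuildingBlock:
    """A mass-difference building block: an elemental-composition delta.

    ``delta_formula`` holds non-negative counts; the sign of the mass
    difference is carried by the direction of a network edge, not by the
    block itself.
    """

    label: str
    delta_formula: ElementalFormula
    description: str = ""

    @property
    def delta_mass(self) -> float:
        return monoisotopic_mass(self.delta_formula)


# The default catalogue covers the elementary biochemical transformations
# used throughout (alkyl chain extension, (de)hydrogenation, oxidation,
# hydration, carboxylation, amination, sulfation, phosphorylation, ...).
# Users extend or replace it via a TSV file, see load_building_blocks().
_DEFAULT_BLOCKS: list[tuple[str, str, str]] = [
    ("CH2", "CH2", "methylene / alkyl chain extension"),
    ("H2", "H2", "hydrogenation / saturation"),
    ("O", "O", "oxidation / hydroxylation"),
    ("H2O", "H2O", "hydration / condensation"),
    ("CO", "CO", "carbonylation"),
    ("CO2", "CO2", "carboxylation / decarboxylation"),
    ("NH3", "NH3", "amination / deamination"),
    ("NH", "NH", "imine formation"),
    ("CH2O", "CH2O", "formaldehyde unit / hydroxymethylation"),
    ("C2H2O", "C2H2O", "acetylation (ketene unit)"),
    ("C2H4", "C2H4", "ethylene / double chain extension"),
    ("S", "S", "thiolation"),
    ("SO3", "SO3", "sulfation"),
    ("HPO3", "HPO3", "phosphorylation"),
]


def default_building_blocks(extra: Iterable[BuildingBlock] = ()) -> list[BuildingBlock]:
    """The packaged block catalogue, optionally extended by the caller.

    Labels must be unique across the merged catalogue.
    """
    blocks = [BuildingBlock(lbl, parse_formula(f), desc) for lbl, f, desc in _DEFAULT_BLOCKS]
    blocks.extend(extra)
    seen: set[str] = set()
    for b in blocks:
        if b.label in seen:
            raise FormulaError(f"duplicate building-block label {b.label!r}")
        seen.add(b.label)
    return blocks


def load_building_blocks(path) -> list[BuildingBlock]:
    """Read a block catalogue TSV with columns label, formula[, description]."""
    blocks: list[BuildingBlock] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "label":
                continue
            label, formula = parts[0], parts[1]
            desc = parts[2] if len(parts) > 2 else ""
            if label in seen:
                raise FormulaError(f"duplicate building-block label {label!r}")
            if formula.startswith("-"):
                raise FormulaError(
                    f"signed block formula {formula!r} not allowed; "
                    "edge direction carries the sign")
            seen.add(label)
            blocks.append(BuildingBlock(label, parse_formula(formula), desc))
    return blocks


def packaged_name_table() -> dict[str, list[str]]:
    """Offline formula -> candidate compound names lookup table."""
    table: dict[str, list[str]] = {}
    ref = resources.files("mdinet.data").joinpath("compound_names.tsv")
    with ref.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("formula\t"):
                continue
            formula, name = line.split("\t")[:2]
            key = format_formula(parse_formula(formula))
            table.setdefault(key, []).append(name)
    return table
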