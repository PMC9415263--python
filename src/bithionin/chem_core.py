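"""Elemental-formula arithmetic and ion mass bookkeeping.

This module is the numeric substrate for the rest of the package: exact
(monoisotopic) and nominal masses of elemental formulas, m/z of multiply
protonated positive ions, charge deconvolution, and ppm mass errors.

Conventions
-----------
* Monoisotopic mass is the sum over elements of count times the exact mass
  of the principal (most abundant) isotope; for C, H, N, O, P and S this is
  also the lightest isotope.
* Nominal mass is the integer sum of principal-isotope mass numbers
  (H=1, C=12, N=14, O=16, P=31, S=32).
* Positive-mode ions are modelled as ``M + z`` protons with the proton mass
  constant 1.007276466 Da (electron mass folded in); no other adducts.
* Formulas print in Hill order (C, H, then alphabetical).

Full precision is kept internally; rounding to 4 decimals is applied only
at presentation (CLI / reports).
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "PROTON_MASS",
    "WATER",
    "Isotope",
    "IsotopeTable",
    "DEFAULT_ISOTOPES",
    "FormulaError",
    "ElementalFormula",
    "parse_formula",
    "monoisotopic_mass",
    "nominal_mass",
    "IonSpec",
    "mz_of_ion",
    "deconvolute",
    "ppm_error",
    "ResidueSpec",
    "RESIDUES",
    "residue_formula",
    "residue_mass",
]

#: Mass of a proton in Da (positive-mode charge carrier).
PROTON_MASS = 1.007276466


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


@dataclass(frozen=True)
class Isotope:
    """One stable isotope of an element."""

    mass_number: int
    mass: float
    abundance: float


class IsotopeTable:
    """Per-element stable-isotope masses and abundances.

    Invariants enforced at construction: abundances of each element sum to
    1 within 1e-9, and exact masses increase strictly with mass number.
    """

    def __init__(self, isotopes: Mapping[str, list[Isotope]]):
        self._table: dict[str, tuple[Isotope, ...]] = {}
        for element, isos in isotopes.items():
            isos = tuple(sorted(isos, key=lambda i: i.mass_number))
            total = sum(i.abundance for i in isos)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"abundances for {element} sum to {total!r}, not 1"
                )
            masses = [i.mass for i in isos]
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"isotope masses for {element} not increasing")
            self._table[element] = isos

    def __getitem__(self, element: str) -> tuple[Isotope, ...]:
        try:
            return self._table[element]
        except KeyError:
            raise FormulaError(f"element {element!r} not in isotope table") from None

    def __contains__(self, element: str) -> bool:
        return element in self._table

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._table)

    def principal(self, element: str) -> Isotope:
        """Most abundant isotope of *element*."""
        return max(self[element], key=lambda i: i.abundance)

    @classmethod
    def from_tsv(cls, path) -> "IsotopeTable":
        """Load a table from TSV columns: element, mass_number, exact_mass, abundance."""
        table: dict[str, list[Isotope]] = {}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                element, mass_number, mass, abundance = line.split("\t")
                table.setdefault(element, []).append(
                    Isotope(int(mass_number), float(mass), float(abundance))
                )
        return cls(table)

    @classmethod
    def default(cls) -> "IsotopeTable":
        path = resources.files("bithionin").joinpath("data/isotopes.tsv")
        with resources.as_file(path) as p:
            return cls.from_tsv(p)


DEFAULT_ISOTOPES = IsotopeTable.default()

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula(Mapping):
    """Immutable element -> count map with exact-mass arithmetic.

    Counts are non-negative integers; element symbols must be present in the
    isotope table. Supports ``+``, ``-`` (raising on negative results) and
    multiplication by a non-negative integer.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kw:
            for element, n in source.items():
                merged[element] = merged.get(element, 0) + int(n)
        for element, n in list(merged.items()):
            if element not in DEFAULT_ISOTOPES:
                raise FormulaError(f"unknown element symbol {element!r}")
            if n < 0:
                raise FormulaError(f"negative count for {element}: {n}")
            if n == 0:
                del merged[element]
        self._counts = merged

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element) -> bool:
        return element in self._counts

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: Mapping[str, int]) -> "ElementalFormula":
        out = dict(self._counts)
        for element, n in other.items():
            out[element] = out.get(element, 0) + n
        return ElementalFormula(out)

    def __sub__(self, other: Mapping[str, int]) -> "ElementalFormula":
        out = dict(self._counts)
        for element, n in other.items():
            out[element] = out.get(element, 0) - n
        return ElementalFormula(out)

    def __mul__(self, factor: int) -> "ElementalFormula":
        return ElementalFormula({e: n * factor for e, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        return dict(self._counts) == dict(other) if isinstance(other, Mapping) else NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    # -- presentation -----------------------------------------------------
    def hill(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical)."""
        parts = []
        rest = dict(self._counts)
        for element in ("C", "H"):
            if element in rest:
                n = rest.pop(element)
                parts.append(element + (str(n) if n != 1 else ""))
        for element in sorted(rest):
            n = rest[element]
            parts.append(element + (str(n) if n != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"

    # -- masses -----------------------------------------------------------
    def monoisotopic_mass(self, table: IsotopeTable | None = None) -> float:
        table = table or DEFAULT_ISOTOPES
        return sum(n * table.principal(e).mass for e, n in self._counts.items())

    def nominal_mass(self, table: IsotopeTable | None = None) -> int:
        table = table or DEFAULT_ISOTOPES
        return sum(n * table.principal(e).mass_number for e, n in self._counts.items())

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        return parse_formula(text)


def parse_formula(text: str) -> ElementalFormula:
    """Parse an element-count string such as ``"C115H174N28O31S2"``.

    Implicit count is 1 (``"H2O"`` -> H:2, O:1). Raises :class:`FormulaError`
    naming the offending token for malformed input or unknown symbols.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if not match or match.start() != pos or not match.group(1):
            raise FormulaError(f"malformed token at {text[pos:]!r} in {text!r}")
        element, digits = match.groups()
        if element not in DEFAULT_ISOTOPES:
            raise FormulaError(f"unknown element {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula | Mapping[str, int] | str,
                      table: IsotopeTable | None = None) -> float:
    """Monoisotopic (principal-isotope) mass of *formula* in Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    elif not isinstance(formula, ElementalFormula):
        formula = ElementalFormula(formula)
    return formula.monoisotopic_mass(table)


def nominal_mass(formula: ElementalFormula | Mapping[str, int] | str,
                 table: IsotopeTable | None = None) -> int:
    """Integer nominal mass (principal mass numbers) of *formula*."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    elif not isinstance(formula, ElementalFormula):
        formula = ElementalFormula(formula)
    return formula.nominal_mass(table)


#: The formula of water, used throughout peptide bookkeeping.
WATER = ElementalFormula(H=2, O=1)


@dataclass(frozen=True)
class IonSpec:
    """A positive-mode, protonated ion: neutral species plus charge.

    ``neutral`` may be an :class:`ElementalFormula` or a neutral monoisotopic
    mass in Da. The adduct is ``charge`` protons.
    """

    neutral: ElementalFormula | float
    charge: int

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")

    @property
    def neutral_mass(self) -> float:
        if isinstance(self.neutral, ElementalFormula):
            return self.neutral.monoisotopic_mass()
        return float(self.neutral)

    @property
    def mz(self) -> float:
        return mz_of_ion(self.neutral_mass, self.charge)


def mz_of_ion(neutral_mass: float | ElementalFormula, charge: int) -> float:
    """m/z of ``[M + zH]z+``: ``(M + z * 1.007276466) / z``."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if isinstance(neutral_mass, (ElementalFormula, Mapping)):
        neutral_mass = monoisotopic_mass(neutral_mass)
    return (neutral_mass + charge * PROTON_MASS) / charge


def deconvolute(mz: float, charge: int) -> float:
    """Neutral monoisotopic mass from an observed m/z at charge z.

    Exact inverse of :func:`mz_of_ion`: ``mz * z - z * 1.007276466``.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    return mz * charge - charge * PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


# ---------------------------------------------------------------------------
# Residue table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueSpec:
    """An amino-acid residue (amino acid minus water) usable in peptides.

    ``isomer_group`` marks residues with identical elemental composition that
    MS alone cannot distinguish: dehydroalanine (Dha) and the beta-enamino
    acid 3-aminoacrylic acid (Aaa) share C3H3NO, as do dehydrobutyrine (Dhb)
    and methyl-Aaa (C4H5NO).
    """

    code: str
    name: str
    composition: ElementalFormula = field(hash=False)
    is_modified: bool = False
    isomer_group: str | None = None

    @property
    def mass(self) -> float:
        return self.composition.monoisotopic_mass()


def _r(code, name, formula, modified=False, group=None) -> ResidueSpec:
    return ResidueSpec(code, name, parse_formula(formula), modified, group)


#: Residue table: the 20 standard residues plus the modified residues of the
#: kin maturation pathway. d-Ala is compositionally identical to Ala; Dha/Aaa
#: and Dhb/mAaa are mass-isomer pairs.
RESIDUES: dict[str, ResidueSpec] = {
    spec.code: spec
    for spec in [
        _r("G", "glycine", "C2H3NO"),
        _r("A", "alanine", "C3H5NO"),
        _r("S", "serine", "C3H5NO2"),
        _r("P", "proline", "C5H7NO"),
        _r("V", "valine", "C5H9NO"),
        _r("T", "threonine", "C4H7NO2"),
        _r("C", "cysteine", "C3H5NOS"),
        _r("L", "leucine", "C6H11NO"),
        _r("I", "isoleucine", "C6H11NO"),
        _r("N", "asparagine", "C4H6N2O2"),
        _r("D", "aspartate", "C4H5NO3"),
        _r("Q", "glutamine", "C5H8N2O2"),
        _r("K", "lysine", "C6H12N2O"),
        _r("E", "glutamate", "C5H7NO3"),
        _r("M", "methionine", "C5H9NOS"),
        _r("H", "histidine", "C6H7N3O"),
        _r("F", "phenylalanine", "C9H9NO"),
        _r("R", "arginine", "C6H12N4O"),
        _r("Y", "tyrosine", "C9H9NO2"),
        _r("W", "tryptophan", "C11H10N2O"),
        # --- pathway-modified residues ---
        _r("Dha", "dehydroalanine", "C3H3NO", True, "C3H3NO"),
        _r("Aaa", "3-aminoacrylic acid", "C3H3NO", True, "C3H3NO"),
        _r("Dhb", "dehydrobutyrine", "C4H5NO", True, "C4H5NO"),
        _r("mAaa", "methyl-3-aminoacrylic acid", "C4H5NO", True, "C4H5NO"),
        _r("Abu", "2-aminobutyrate (ring Dhb + thioether)", "C4H5NO", True, "C4H5NO"),
        _r("dA", "d-alanine", "C3H5NO", True),
        _r("pS", "phosphoserine", "C3H6NO5P", True),
        _r("pT", "phosphothreonine", "C4H8NO5P", True),
    ]
}


def residue_formula(code: str) -> ElementalFormula:
    """Composition of residue *code*; raises ``KeyError`` for unknown codes."""
    return RESIDUES[code].composition


def residue_mass(code: str) -> float:
    """Monoisotopic residue mass in Da."""
    return RESIDUES[code].mass
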