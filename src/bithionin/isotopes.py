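"""Isotopologue fine structure of elemental formulas.

High-resolution FT-ICR spectra resolve the individual heavy-isotope
compositions (13C1, 15N1, 33S1, 34S1, 2H1, 18O1, ...) inside each nominal
M+k peak. This module enumerates those isotopologues exactly, by dynamic
programming over elements rather than FFT convolution, so that each
retained isotopologue keeps an identifiable composition label, and then
aggregates them into nominal M+k peaks (abundance-weighted centroids).

The enumeration is exact up to a pruning threshold on relative abundance
(default 1e-6); because per-element multinomial factors are <= 1, pruning
partial products below the threshold can never discard an isotopologue
whose final abundance would reach it. The truncation loss (total abundance
of pruned isotopologues) is reported on the pattern object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chem_core import (
    DEFAULT_ISOTOPES,
    ElementalFormula,
    IsotopeTable,
    PROTON_MASS,
    parse_formula,
)

__all__ = ["Isotopologue", "IsotopePattern", "fine_structure", "aggregate_pattern"]


@dataclass(frozen=True)
class Isotopologue:
    """One heavy-isotope composition of a formula.

    ``composition`` maps labels like ``"13C"`` to the number of atoms of
    that heavy isotope; the monoisotopic species has an empty composition.
    ``k`` is the total extra mass-number count relative to monoisotopic.
    ``mass`` is the neutral exact mass, or the per-isotopologue m/z when the
    pattern was generated with a charge.
    """

    composition: tuple[tuple[str, int], ...]
    mass: float
    abundance: float
    k: int

    def label(self) -> str:
        if not self.composition:
            return "monoisotopic"
        return " ".join(f"{iso}x{n}" if n > 1 else iso for iso, n in self.composition)


@dataclass
class IsotopePattern:
    """Fine structure of one formula: pruned isotopologues plus metadata."""

    formula: ElementalFormula
    charge: int
    threshold: float
    isotopologues: list[Isotopologue] = field(default_factory=list)

    @property
    def truncation_loss(self) -> float:
        """Total relative abundance lost to pruning (1 - retained sum)."""
        return 1.0 - sum(i.abundance for i in self.isotopologues)

    def aggregate(self) -> list[tuple[int, float, float]]:
        return aggregate_pattern(self)

    def monoisotopic(self) -> Isotopologue:
        return next(i for i in self.isotopologues if i.k == 0 and not i.composition)


def _element_terms(element: str, count: int, threshold: float,
                   table: IsotopeTable) -> list[tuple[tuple[tuple[str, int], ...], float, float, int]]:
    """Multinomial expansion for ``count`` atoms of one element.

    Returns (composition, mass, abundance, k) terms with abundance >=
    threshold, composition listing heavy isotopes only.
    """
    isotopes = table[element]
    principal = table.principal(element)
    heavies = [i for i in isotopes if i is not principal]
    terms: list[tuple[tuple[tuple[str, int], ...], float, float, int]] = []

    def recurse(idx: int, remaining: int, abundance: float, mass: float,
                k: int, comp: list[tuple[str, int]]):
        if abundance < threshold:
            return
        if idx == len(heavies):
            total = abundance * principal.abundance ** remaining
            if total >= threshold:
                terms.append(
                    (tuple(comp), mass + remaining * principal.mass, total, k)
                )
            return
        iso = heavies[idx]
        # n atoms of this heavy isotope; multinomial coefficient accumulates
        # as C(remaining, n) relative to the atoms still unassigned.
        term_abundance = 1.0
        for n in range(remaining + 1):
            if n > 0:
                term_abundance = term_abundance * iso.abundance * (remaining - n + 1) / n
                comp.append((f"{iso.mass_number}{element}", n))
            recurse(
                idx + 1,
                remaining - n,
                abundance * term_abundance,
                mass + n * iso.mass,
                k + n * (iso.mass_number - principal.mass_number),
                comp,
            )
            if n > 0:
                comp.pop()
        return

    recurse(0, count, 1.0, 0.0, 0, [])
    return terms


def fine_structure(formula: ElementalFormula | str, charge: int = 0,
                   threshold: float = 1e-6,
                   table: IsotopeTable | None = None) -> IsotopePattern:
    """Enumerate isotopologues of *formula* with abundance >= *threshold*.

    With ``charge >= 1`` each isotopologue mass is reported as m/z of the
    ``[M + zH]z+`` species; ``charge=0`` keeps neutral masses.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if len(formula) == 0:
        raise ValueError("empty formula has no isotope pattern")
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if charge < 0:
        raise ValueError("charge must be >= 0")
    table = table or DEFAULT_ISOTOPES

    # DP over elements: combine per-element multinomial terms, pruning
    # partial abundances below threshold (safe: remaining factors <= 1).
    states: list[tuple[tuple[tuple[str, int], ...], float, float, int]] = [
        ((), 0.0, 1.0, 0)
    ]
    for element in sorted(formula):
        element_terms = _element_terms(element, formula[element], threshold, table)
        new_states = []
        for comp_a, mass_a, ab_a, k_a in states:
            for comp_b, mass_b, ab_b, k_b in element_terms:
                abundance = ab_a * ab_b
                if abundance >= threshold:
                    new_states.append(
                        (comp_a + comp_b, mass_a + mass_b, abundance, k_a + k_b)
                    )
        states = new_states

    isotopologues = []
    for comp, mass, abundance, k in states:
        if charge >= 1:
            mass = (mass + charge * PROTON_MASS) / charge
        isotopologues.append(Isotopologue(comp, mass, abundance, k))
    isotopologues.sort(key=lambda i: (i.k, -i.abundance, i.mass))
    return IsotopePattern(formula, charge, threshold, isotopologues)


def aggregate_pattern(pattern: IsotopePattern) -> list[tuple[int, float, float]]:
    """Group isotopologues into nominal M+k peaks.

    Returns ``(k, centroid, abundance)`` triples ordered by k, where the
    centroid is the abundance-weighted mean mass (or m/z) and abundances
    are summed within each k.
    """
    if not pattern.isotopologues:
        raise ValueError("empty isotope pattern")
    peaks: dict[int, tuple[float, float]] = {}
    for iso in pattern.isotopologues:
        weighted, total = peaks.get(iso.k, (0.0, 0.0))
        peaks[iso.k] = (weighted + iso.mass * iso.abundance, total + iso.abundance)
    return [
        (k, weighted / total, total)
        for k, (weighted, total) in sorted(peaks.items())
        if total > 0 and math.isfinite(weighted)
    ]
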