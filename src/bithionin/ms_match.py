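"""Theoretical fragment ladders, ppm peak matching and sequence-tag inference.

Fragment ion conventions (positive mode, z protons as the charge carrier):

* ``b_i``  = sum of the first i residue masses + z protons
* ``y_j``  = sum of the last j residue masses + H2O + z protons
* ``c_i``  = ``b_i`` + NH3 and ``z_j`` = ``y_j`` - NH3 (ECD-type series)

For products carrying an intact bis-thioether macrocycle, backbone
cleavages strictly inside the crosslinked span do not yield separable
fragments; ``crosslink_mode="suppress"`` (the default) omits those ions,
while ``"labile"`` additionally emits them, modelling thioether C-S
scission accompanying the backbone cleavage. Suppress-mode ladders are
always a subset of labile-mode ladders.

Matching is intensity-blind: intensities are carried through and reported,
but every matching decision uses m/z alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chem_core import (
    PROTON_MASS,
    RESIDUES,
    WATER,
    monoisotopic_mass,
    ppm_error,
    residue_mass,
)
from .ptm_engine import ProductSpec

__all__ = [
    "FragmentIon",
    "PeakList",
    "Match",
    "MatchReport",
    "SequenceTag",
    "TagStep",
    "fragment_ladder",
    "match_peaks",
    "infer_sequence_tag",
]

_NH3 = monoisotopic_mass({"N": 1, "H": 3})
_H2O = WATER.monoisotopic_mass()


@dataclass(frozen=True)
class FragmentIon:
    series: str
    index: int
    charge: int
    mz: float
    observable: bool = True

    @property
    def name(self) -> str:
        return f"{self.series}{self.index}({self.charge}+)"


@dataclass
class PeakList:
    """(m/z, intensity) pairs, sorted ascending by m/z after load."""

    mz: np.ndarray
    intensity: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must be 1-D and equal length")
        if np.any(self.mz <= 0):
            raise ValueError("all m/z values must be positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    @classmethod
    def from_mgf(cls, path) -> "PeakList":
        """First spectrum of an MGF file (via pyteomics)."""
        from pyteomics import mgf

        with mgf.MGF(str(path)) as reader:
            spectrum = next(iter(reader))
        return cls(spectrum["m/z array"], spectrum["intensity array"], source=str(path))

    @classmethod
    def from_tsv(cls, path) -> "PeakList":
        """Two-column TSV: m/z, intensity (lines starting with # ignored)."""
        data = np.loadtxt(str(path), comments="#", ndmin=2)
        return cls(data[:, 0], data[:, 1], source=str(path))

    def to_tsv(self, path) -> None:
        np.savetxt(str(path), np.column_stack([self.mz, self.intensity]),
                   fmt="%.6f\t%.3f", header="mz\tintensity")


def _residue_masses(product: ProductSpec | str) -> tuple[list[float], list[tuple[int, int]]]:
    """Per-position effective residue masses and crosslink spans (0-based)."""
    if isinstance(product, str):
        return [residue_mass(a) for a in product], []
    positions = product.positions
    index = {p: i for i, p in enumerate(positions)}
    masses = [product.effective_composition(p)[1] for p in positions]
    spans = [(index[min(c)], index[max(c)]) for c in product.crosslinks]
    return masses, spans


def fragment_ladder(product: ProductSpec | str,
                    series: Iterable[str] = ("b", "y"),
                    charges: Sequence[int] = (1,),
                    crosslink_mode: str = "suppress") -> list[FragmentIon]:
    """Theoretical b/y (and c/z) ions for a product or plain sequence.

    Cleavage i separates residues 1..i from i+1..n (i = 1..n-1). With an
    intact crosslink spanning residues a..c, a cleavage with a <= i < c cuts
    through the macrocycle: suppressed by default, emitted in labile mode.
    """
    if crosslink_mode not in ("suppress", "labile"):
        raise ValueError(f"crosslink_mode must be 'suppress' or 'labile'")
    unknown = set(series) - {"b", "y", "c", "z"}
    if unknown:
        raise ValueError(f"unknown ion series {sorted(unknown)}")
    masses, spans = _residue_masses(product)
    n = len(masses)
    prefix = np.concatenate([[0.0], np.cumsum(masses)])
    ions = []
    for i in range(1, n):
        crossed = any(a <= i - 1 < b for a, b in spans)
        if crossed and crosslink_mode == "suppress":
            continue
        b_neutral = prefix[i]
        y_neutral = prefix[n] - prefix[i] + _H2O
        for z in charges:
            for name in series:
                if name == "b":
                    neutral = b_neutral
                elif name == "c":
                    neutral = b_neutral + _NH3
                elif name == "y":
                    neutral = y_neutral
                else:  # z
                    neutral = y_neutral - _NH3
                index = i if name in ("b", "c") else n - i
                ions.append(FragmentIon(name, index, z,
                                        (neutral + z * PROTON_MASS) / z,
                                        observable=not crossed))
    return ions


@dataclass(frozen=True)
class Match:
    ion: FragmentIon
    peak_mz: float
    peak_intensity: float
    ppm: float


@dataclass
class MatchReport:
    """Greedy one-to-one assignment of theoretical ions to observed peaks."""

    matches: list[Match]
    unmatched_peaks: np.ndarray
    tolerance_ppm: float
    n_theoretical: int
    coverage: dict[str, float] = field(default_factory=dict)

    @property
    def fraction_matched(self) -> float:
        return len(self.matches) / self.n_theoretical if self.n_theoretical else 0.0


def match_peaks(theoretical: Sequence[FragmentIon], observed: PeakList,
                tolerance_ppm: float = 5.0) -> MatchReport:
    """Match ions to peaks within a ppm tolerance.

    Greedy nearest matching: candidate pairs are ranked by absolute ppm
    error, ties broken toward lower charge; every ion and every observed
    peak is used at most once. An empty theoretical list yields an empty
    report rather than an error.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    candidates = []
    for ion_idx, ion in enumerate(theoretical):
        lo = np.searchsorted(observed.mz, ion.mz * (1 - tolerance_ppm * 1e-6))
        hi = np.searchsorted(observed.mz, ion.mz * (1 + tolerance_ppm * 1e-6), side="right")
        for peak_idx in range(lo, hi):
            delta = ppm_error(observed.mz[peak_idx], ion.mz)
            candidates.append((abs(delta), ion.charge, ion_idx, peak_idx, delta))
    candidates.sort()

    used_ions: set[int] = set()
    used_peaks: set[int] = set()
    matches = []
    for _, _, ion_idx, peak_idx, delta in candidates:
        if ion_idx in used_ions or peak_idx in used_peaks:
            continue
        used_ions.add(ion_idx)
        used_peaks.add(peak_idx)
        ion = theoretical[ion_idx]
        matches.append(Match(ion, float(observed.mz[peak_idx]),
                             float(observed.intensity[peak_idx]), delta))
    unmatched = np.array([mz for i, mz in enumerate(observed.mz) if i not in used_peaks])

    coverage: dict[str, float] = {}
    for name in sorted({ion.series for ion in theoretical}):
        total = sum(1 for ion in theoretical if ion.series == name)
        hit = sum(1 for m in matches if m.ion.series == name)
        coverage[name] = hit / total if total else 0.0
    return MatchReport(matches, unmatched, tolerance_ppm, len(theoretical), coverage)


# ---------------------------------------------------------------------------
# Sequence-tag inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TagStep:
    """One inter-peak mass delta with its residue candidates.

    ``isomeric`` is set when several candidates share one elemental
    composition (Dha vs Aaa; Dhb vs methyl-Aaa vs ring Abu) and MS alone
    cannot distinguish them.
    """

    delta: float
    candidates: tuple[str, ...]
    isomeric: bool


@dataclass
class SequenceTag:
    steps: list[TagStep]
    unassigned: list[float] = field(default_factory=list)

    @property
    def residues(self) -> list[tuple[str, ...]]:
        return [step.candidates for step in self.steps]

    def __len__(self) -> int:
        return len(self.steps)


def infer_sequence_tag(peaks: PeakList, tolerance_ppm: float = 5.0,
                       charge: int = 1) -> SequenceTag:
    """Read a residue sequence from consecutive single-series peak deltas.

    Peaks are assumed to form one fragment-ion ladder at the given charge;
    each consecutive delta (times charge) is looked up in the residue table
    (standard residues plus Dha/Dhb/Aaa/methyl-Aaa/Abu/phospho residues).
    Deltas matching no residue are reported in ``unassigned``; a tag with
    no assignable delta at all is returned empty with those diagnostics.
    """
    if len(peaks) < 2:
        raise ValueError("sequence-tag inference needs at least 2 peaks")
    steps = []
    unassigned = []
    for lighter, heavier in zip(peaks.mz, peaks.mz[1:]):
        delta = (heavier - lighter) * charge
        window = heavier * charge * tolerance_ppm * 1e-6
        hits = [spec for spec in RESIDUES.values() if abs(spec.mass - delta) <= window]
        if not hits:
            unassigned.append(float(delta))
            continue
        groups = {spec.composition.hill() for spec in hits}
        steps.append(TagStep(
            delta=float(delta),
            candidates=tuple(sorted(spec.code for spec in hits)),
            isomeric=len(hits) > 1 and len(groups) == 1,
        ))
    return SequenceTag(steps, unassigned)
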