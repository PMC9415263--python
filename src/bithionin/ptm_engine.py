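"""Rule engine for the kin (beta-bithionin) maturation pathway.

A kin-type precursor peptide (leader + core) is matured by a small set of
dedicated enzymes:

* **KinD** (Ser/Thr kinase) phosphorylates core Ser/Thr residues one at a
  time, N- to C-terminal, starting from the first dehydratable position.
* **KinC** (phospho-Ser/Thr lyase) eliminates the phosphate to leave
  dehydroalanine (Dha, from Ser) or dehydrobutyrine (Dhb, from Thr); at one
  special Ser the elimination proceeds through rearrangement to the
  beta-enamino acid 3-aminoacrylic acid (Aaa), a mass-isomer of Dha.
* **KinH + KinI** (kinase homologue + HFCD-like flavoprotein, acting as a
  pair) oxidatively decarboxylate the C-terminal Cys (-CO2 -H2, net
  -46.00548 Da) and cyclise the resulting thioenol with a ring Dhb and the
  internal thiol Cys into the bis-thioether MAbi crosslink (0 Da).
* **KinJ** (F420H2-dependent reductase) reduces specific Dha residues to
  d-Ala (+H2), compositionally identical to Ala.
* **KinE/F** (proteases) remove the leader peptide.
* **KinO** (methyltransferase) N,N-dimethylates the new N-terminus (+C2H4).

Every modification is a typed :class:`ModificationEvent` with a fixed
elemental delta, so product formulas and masses are exact bookkeeping:
``product = precursor segment + sum of event deltas``. Which events an
enzyme set triggers, and at which positions, is data (a YAML rule table)
rather than code, so kin-like pathways with a different enzyme complement
(e.g. clusters lacking the methyltransferase) are configurable.

Position numbering follows the leader/core convention: leader residues at
negative positions ..., -2, -1; core residues 1..n; there is no position 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .chem_core import (
    DEFAULT_ISOTOPES,
    ElementalFormula,
    WATER,
    mz_of_ion,
    residue_formula,
)

__all__ = [
    "PrecursorPeptide",
    "EnzymeSet",
    "ModificationEvent",
    "ProductSpec",
    "DigestFragment",
    "EVENT_DELTAS",
    "PathwayRules",
    "load_rules",
    "peptide_formula",
    "apply_events",
    "kin_maturation",
    "variant_predict",
    "gluc_digest",
    "processive_series",
]

_STANDARD = set("GASPVTCLINDQKEMHFRYW")

#: Fixed signed elemental deltas per event kind. Thioether crosslinking and
#: the Dha -> Aaa rearrangement are mass-neutral relative to the already
#: dehydrated residue.
EVENT_DELTAS: dict[str, dict[str, int]] = {
    "dehydration": {"H": -2, "O": -1},
    "rearrangement_to_aaa": {},
    "reduction_to_dala": {"H": 2},
    "phosphorylation": {"H": 1, "P": 1, "O": 3},
    "oxidative_decarboxylation": {"C": -1, "H": -2, "O": -2},
    "thioether_crosslink": {},
    "disulfide": {"H": -2},
    "n_dimethylation": {"C": 2, "H": 4},
    "proteolysis": {},
}


class MaturationError(ValueError):
    """Raised for illegal site/kind pairings or inconsistent enzyme sets."""


@dataclass(frozen=True)
class ModificationEvent:
    """A typed PTM applied at one or more positions."""

    kind: str
    sites: tuple[int, ...]

    def __post_init__(self):
        if self.kind not in EVENT_DELTAS:
            raise MaturationError(f"unknown modification kind {self.kind!r}")
        object.__setattr__(self, "sites", tuple(self.sites))

    @property
    def delta(self) -> dict[str, int]:
        return dict(EVENT_DELTAS[self.kind])


def _apply_delta(formula: ElementalFormula, delta: Mapping[str, int]) -> ElementalFormula:
    plus = {e: n for e, n in delta.items() if n > 0}
    minus = {e: -n for e, n in delta.items() if n < 0}
    return formula + plus - minus


@dataclass(frozen=True)
class PrecursorPeptide:
    """Leader + core residue sequence with gap-free leader/core numbering."""

    core: str
    leader: str = ""
    name: str = ""

    def __post_init__(self):
        if len(self.core) < 1:
            raise ValueError("core peptide must have at least one residue")
        for aa in self.leader + self.core:
            if aa not in _STANDARD:
                raise ValueError(f"unknown residue code {aa!r}")

    # -- numbering --------------------------------------------------------
    @property
    def n_core(self) -> int:
        return len(self.core)

    @property
    def first_position(self) -> int:
        return -len(self.leader) if self.leader else 1

    def positions(self, start: int | None = None, end: int | None = None) -> list[int]:
        """All positions from *start* to *end* inclusive, skipping 0."""
        start = self.first_position if start is None else start
        end = self.n_core if end is None else end
        return [p for p in range(start, end + 1) if p != 0]

    def residue(self, position: int) -> str:
        if position == 0:
            raise KeyError("position 0 does not exist (leader <0, core >=1)")
        if position >= 1:
            if position > self.n_core:
                raise KeyError(f"core position {position} beyond {self.n_core}")
            return self.core[position - 1]
        idx = len(self.leader) + position
        if idx < 0:
            raise KeyError(f"leader position {position} beyond -{len(self.leader)}")
        return self.leader[idx]

    def substitute(self, substitutions: Mapping[int, str]) -> "PrecursorPeptide":
        """Return a copy with core positions replaced (site-directed mutagenesis)."""
        core = list(self.core)
        for pos, aa in substitutions.items():
            if not (1 <= pos <= self.n_core):
                raise MaturationError(f"substitution target {pos} outside core 1..{self.n_core}")
            if aa not in _STANDARD:
                raise MaturationError(f"unknown substitution residue {aa!r}")
            core[pos - 1] = aa
        tag = ",".join(f"{self.core[p-1]}{p}{a}" for p, a in sorted(substitutions.items()))
        return replace(self, core="".join(core), name=f"{self.name}[{tag}]" if self.name else tag)

    # -- IO ---------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path) -> list["PrecursorPeptide"]:
        """Read precursors from protein FASTA; headers carry ``leader_len=K``."""
        from Bio import SeqIO

        out = []
        for record in SeqIO.parse(str(path), "fasta"):
            leader_len = 0
            for token in record.description.split():
                if token.startswith("leader_len="):
                    leader_len = int(token.split("=", 1)[1])
            seq = str(record.seq).upper()
            out.append(cls(core=seq[leader_len:], leader=seq[:leader_len], name=record.id))
        return out


@dataclass(frozen=True)
class EnzymeSet:
    """Which kin enzymes are present. KinC requires KinD (elimination needs
    prior phosphorylation); KinE and KinF act together and are one flag."""

    kinC: bool = False
    kinD: bool = False
    kinH: bool = False
    kinI: bool = False
    kinJ: bool = False
    kinEF: bool = False
    kinO: bool = False

    def __post_init__(self):
        if self.kinC and not self.kinD:
            raise MaturationError("inconsistent enzyme set: KinC requires KinD")

    @classmethod
    def from_codes(cls, codes: str | Iterable[str]) -> "EnzymeSet":
        """Build from codes like ``"C,D,H,I"`` or ``["C", "D", "E/F"]``."""
        if isinstance(codes, str):
            codes = codes.split(",")
        flags = dict.fromkeys(("C", "D", "H", "I", "J", "EF", "O"), False)
        for code in codes:
            code = code.strip().upper().replace("KIN", "").replace("E/F", "EF")
            if code in ("E", "F"):
                code = "EF"
            if code not in flags:
                raise MaturationError(f"unknown enzyme code {code!r}")
            flags[code] = True
        return cls(**{f"kin{k}": v for k, v in flags.items()})

    def has(self, code: str) -> bool:
        return getattr(self, f"kin{code}")


# ---------------------------------------------------------------------------
# Pathway rules
# ---------------------------------------------------------------------------

@dataclass
class PathwayRules:
    """Resolved positional roles for one precursor under one rule table."""

    aaa_site: int | None
    retained_ser: tuple[int, ...]
    reduce_sites: tuple[int, ...]
    crosslink: tuple[int, int, int] | None
    phospho_start: int | None
    dehydratable: tuple[int, ...]


def load_rules(path=None) -> dict:
    """Load a maturation rule table (defaults to the bundled kin table)."""
    if path is None:
        resource = resources.files("bithionin").joinpath("data/kin_rules.yaml")
        with resources.as_file(resource) as p:
            return yaml.safe_load(p.read_text())
    with open(path) as handle:
        return yaml.safe_load(handle)


def resolve_rules(precursor: PrecursorPeptide, table: dict | None = None,
                  require_motif: bool = True) -> PathwayRules:
    """Instantiate positional roles for *precursor* from a rule table.

    ``auto`` roles are derived from the precursor's signature-motif anchors;
    explicit 1-based core positions in the table override them.
    """
    from .mining import scan_motif  # local import; mining has no ptm dependency

    table = table if table is not None else load_rules()
    hits = scan_motif(precursor.core)
    anchors = hits[0].positions if hits else None
    if anchors is None and require_motif and any(
        table.get(key, "auto") == "auto"
        for key in ("aaa_site", "retained_ser", "reduce_sites", "crosslink")
    ):
        raise MaturationError(
            "precursor core lacks the S-[ST]-X-X-C-Xn-T-X4-C signature motif; "
            "supply explicit rule positions or a motif-valid core"
        )

    def auto(key, fallback):
        value = table.get(key, "auto")
        return fallback() if value == "auto" else value

    s1 = c1 = acc = c2 = None
    if anchors:
        s1, _s2, c1, acc, c2 = anchors

    aaa_site = auto("aaa_site", lambda: s1)
    retained = tuple(auto(
        "retained_ser",
        lambda: [p for p in range((acc or 0) + 1, (c2 or 0))
                 if precursor.residue(p) == "S"] if anchors else [],
    ))
    crosslink = auto("crosslink", lambda: (c1, acc, c2) if anchors else None)
    if crosslink is not None:
        crosslink = tuple(crosslink)
    dehydratable = tuple(
        p for p in range(1, precursor.n_core + 1)
        if precursor.residue(p) in "ST" and p not in retained
    )
    reduce_sites = tuple(auto(
        "reduce_sites",
        lambda: [p for p in range((c1 or 0) + 1, (acc or 0))
                 if precursor.residue(p) == "S"] if anchors else [],
    ))
    phospho_start = auto("phospho_start",
                         lambda: dehydratable[0] if dehydratable else None)
    return PathwayRules(aaa_site, retained, reduce_sites, crosslink,
                        phospho_start, dehydratable)


# ---------------------------------------------------------------------------
# Products
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProductSpec:
    """A (possibly partially) matured peptide: segment + events + residue map.

    The formula is pure bookkeeping: genetic residue compositions over the
    retained segment, plus water, plus the sum of event deltas.
    """

    label: str
    precursor: PrecursorPeptide
    segment: tuple[int, int]
    residues: Mapping[int, str]
    events: tuple[ModificationEvent, ...]
    crosslinks: tuple[tuple[int, int, int], ...] = ()
    ratio: float = 1.0

    @property
    def positions(self) -> list[int]:
        return self.precursor.positions(*self.segment)

    def genetic(self, position: int) -> str:
        return self.precursor.residue(position)

    def position_delta(self, position: int) -> dict[str, int]:
        """Summed signed delta of events attributed to *position*.

        Multi-site events (crosslink, disulfide) are attributed to their
        first site; both kinds are mass-neutral or small (-H2) and recorded
        on the fragment that carries the first site.
        """
        total: dict[str, int] = {}
        for event in self.events:
            if event.sites and event.sites[0] == position:
                for element, n in event.delta.items():
                    total[element] = total.get(element, 0) + n
        return total

    def effective_composition(self, position: int) -> tuple[dict[str, int], float]:
        """(signed counts, mass) of the residue at *position* after its events."""
        counts: dict[str, int] = dict(residue_formula(self.genetic(position)))
        for element, n in self.position_delta(position).items():
            counts[element] = counts.get(element, 0) + n
        mass = sum(_ELEMENT_MASS[e] * n for e, n in counts.items())
        return counts, mass

    @property
    def formula(self) -> ElementalFormula:
        total = peptide_formula(self.precursor, self.segment)
        for event in self.events:
            total = _apply_delta(total, event.delta)
        return total

    @property
    def mass(self) -> float:
        return self.formula.monoisotopic_mass()

    @property
    def nominal_mass(self) -> int:
        return self.formula.nominal_mass()

    def mz(self, charge: int) -> float:
        return mz_of_ion(self.mass, charge)

    # -- residue-level summaries ------------------------------------------
    @property
    def n_dehydrations(self) -> int:
        return sum(1 for e in self.events if e.kind == "dehydration")

    @property
    def dehydro_residues(self) -> tuple[int, ...]:
        """Positions currently carrying a dehydro residue (Dha/Dhb/Aaa/mAaa)."""
        return tuple(p for p in self.positions
                     if self.residues.get(p) in ("Dha", "Dhb", "Aaa", "mAaa"))

    @property
    def d_ala_sites(self) -> tuple[int, ...]:
        return tuple(p for p in self.positions if self.residues.get(p) == "dA")

    def charge_table(self, charges: Sequence[int] = (1, 2, 3)) -> dict[int, float]:
        return {z: self.mz(z) for z in charges}


_ELEMENT_MASS = {
    e: DEFAULT_ISOTOPES.principal(e).mass for e in ("C", "H", "N", "O", "P", "S")
}


def peptide_formula(precursor: PrecursorPeptide,
                    segment: tuple[int, int] | None = None) -> ElementalFormula:
    """Formula of the unmodified peptide over *segment*: residues + H2O."""
    positions = precursor.positions(*(segment or (None, None)))
    if not positions:
        raise ValueError(f"empty segment {segment}")
    total = ElementalFormula()
    for pos in positions:
        total = total + residue_formula(precursor.residue(pos))
    return total + WATER


def apply_events(precursor: PrecursorPeptide,
                 events: Sequence[ModificationEvent],
                 label: str = "product",
                 segment: tuple[int, int] | None = None,
                 ratio: float = 1.0) -> ProductSpec:
    """Apply an ordered event list, validating each site/kind pairing.

    Raises :class:`MaturationError` naming the position and kind for illegal
    pairings (dehydration off Ser/Thr, decarboxylation off the C-terminal
    Cys, crosslinking before decarboxylation, ...).
    """
    seg_start, seg_end = segment or (precursor.first_position, precursor.n_core)
    codes = {p: precursor.residue(p) for p in precursor.positions(seg_start, seg_end)}
    crosslinks: list[tuple[int, int, int]] = []
    applied: list[ModificationEvent] = []

    def fail(event, why):
        raise MaturationError(
            f"illegal {event.kind} at {event.sites}: {why}"
        )

    for event in events:
        kind, sites = event.kind, event.sites
        if kind == "proteolysis":
            (new_start,) = sites
            if new_start not in codes:
                fail(event, "cleavage start outside segment")
            for p in list(codes):
                if p < new_start:
                    del codes[p]
            seg_start = new_start
        elif kind == "dehydration":
            (p,) = sites
            if codes.get(p) not in ("S", "T"):
                fail(event, f"residue {codes.get(p)!r} is not Ser/Thr")
            codes[p] = "Dha" if codes[p] == "S" else "Dhb"
        elif kind == "rearrangement_to_aaa":
            (p,) = sites
            if codes.get(p) == "Dha":
                codes[p] = "Aaa"
            elif codes.get(p) == "Dhb":
                codes[p] = "mAaa"
            else:
                fail(event, "rearrangement requires a dehydrated Ser/Thr")
        elif kind == "reduction_to_dala":
            (p,) = sites
            if codes.get(p) != "Dha":
                fail(event, f"residue {codes.get(p)!r} is not Dha")
            codes[p] = "dA"
        elif kind == "phosphorylation":
            (p,) = sites
            if codes.get(p) not in ("S", "T"):
                fail(event, f"residue {codes.get(p)!r} is not Ser/Thr")
            codes[p] = "pS" if codes[p] == "S" else "pT"
        elif kind == "oxidative_decarboxylation":
            (p,) = sites
            if p != seg_end:
                fail(event, "decarboxylation only on the C-terminal residue")
            if codes.get(p) != "C":
                fail(event, f"residue {codes.get(p)!r} is not Cys")
            codes[p] = "AED"
        elif kind == "thioether_crosslink":
            thiol, acceptor, cterm = sites
            if codes.get(cterm) != "AED":
                fail(event, "crosslink requires prior decarboxylation (AED)")
            if codes.get(thiol) != "C":
                fail(event, f"thiol site is {codes.get(thiol)!r}, not Cys")
            if codes.get(acceptor) not in ("Dhb", "Dha"):
                fail(event, "acceptor site is not a dehydro residue")
            if codes[acceptor] == "Dhb":
                codes[acceptor] = "Abu"
            crosslinks.append((thiol, acceptor, cterm))
        elif kind == "disulfide":
            a, b = sites
            if codes.get(a) != "C" or codes.get(b) != "C":
                fail(event, "disulfide requires two Cys residues")
        elif kind == "n_dimethylation":
            (p,) = sites
            if p != seg_start:
                fail(event, "N,N-dimethylation only at the free N-terminus")
        applied.append(event)

    return ProductSpec(label, precursor, (seg_start, seg_end), dict(codes),
                       tuple(applied), tuple(crosslinks), ratio)


# ---------------------------------------------------------------------------
# Enzyme-set -> product mapping
# ---------------------------------------------------------------------------

def _maturation_events(precursor: PrecursorPeptide, enzymes: EnzymeSet,
                       rules: PathwayRules,
                       aaa_mode: str = "auto") -> tuple[list[ModificationEvent], str]:
    """Compile the event list for one precursor/enzyme-set combination.

    ``aaa_mode``: "auto" rearranges the aaa site if dehydratable; "skip"
    leaves it untouched (the partially dehydrated shunt of the TtoA variant).
    """
    events: list[ModificationEvent] = []
    label = "precursor"
    if not enzymes.kinD:
        return events, label

    if not enzymes.kinC:
        # kinase alone: processive phosphorylation is caught at the first
        # position; the observed species is the monophosphorylated peptide.
        if rules.phospho_start is not None:
            events.append(ModificationEvent("phosphorylation", (rules.phospho_start,)))
        return events, "10"

    dehydratable = [p for p in rules.dehydratable
                    if not (aaa_mode == "skip" and p == rules.aaa_site)]
    for p in dehydratable:
        events.append(ModificationEvent("dehydration", (p,)))
        if p == rules.aaa_site and aaa_mode != "plain":
            events.append(ModificationEvent("rearrangement_to_aaa", (p,)))
    label = "11"

    decarb = (enzymes.kinH and enzymes.kinI and rules.crosslink is not None
              and precursor.residue(rules.crosslink[0]) == "C"
              and precursor.residue(rules.crosslink[2]) == "C"
              and rules.crosslink[2] == precursor.n_core)
    if decarb:
        thiol, acceptor, cterm = rules.crosslink
        events.append(ModificationEvent("oxidative_decarboxylation", (cterm,)))
        events.append(ModificationEvent("thioether_crosslink", (thiol, acceptor, cterm)))
        label = "12"

    if enzymes.kinJ:
        for p in rules.reduce_sites:
            if p in dehydratable and precursor.residue(p) == "S" and p != rules.aaa_site:
                events.append(ModificationEvent("reduction_to_dala", (p,)))

    if enzymes.kinEF:
        events.append(ModificationEvent("proteolysis", (1,)))
        if enzymes.kinO:
            events.append(ModificationEvent("n_dimethylation", (1,)))

    if decarb:
        if enzymes.kinJ and enzymes.kinEF:
            label = "7" if enzymes.kinO else "8"
    elif enzymes.kinEF:
        label = "9"
    return events, label


def kin_maturation(precursor: PrecursorPeptide, enzymes: EnzymeSet,
                   rule_table: dict | None = None,
                   require_motif: bool = True) -> ProductSpec:
    """Predict the maturation product of *precursor* under *enzymes*.

    The enzyme-set -> product mapping follows the pathway logic established
    by heterologous co-expression: {D} gives the Thr-2 monophosphorylated
    species (compound 10 state); {C,D} the fully dehydrated linear peptide
    with 11 dehydrations and Aaa (compound 11); adding only one of KinH/KinI
    changes nothing; {C,D,H,I} adds decarboxylation and the MAbi crosslink
    (compound 12); KinJ adds d-Ala reductions, KinE/F leader removal, KinO
    N,N-dimethylation (compound 7; compound 9 is the KinI-less linear shunt).
    """
    rules = resolve_rules(precursor, rule_table, require_motif=require_motif)
    events, label = _maturation_events(precursor, enzymes, rules)
    return apply_events(precursor, events, label=label)


def variant_predict(precursor: PrecursorPeptide,
                    substitutions: Mapping[int, str],
                    enzymes: EnzymeSet,
                    rule_table: dict | None = None) -> list[ProductSpec]:
    """Predict products for a core-substituted precursor variant.

    Encodes the observed substitution logic: single Thr/Ser -> Ala sites are
    simply inert; substituting the Aaa-site Ser by Thr yields methyl-Aaa;
    removing the thiol Cys abolishes decarboxylation and cyclisation even
    with KinH + KinI present; removing every dehydratable Thr upstream of
    the Aaa site yields two co-eluting products (fully dehydrated, and
    Aaa-site-retained) in a 1:1 ratio.
    """
    parent_rules = resolve_rules(precursor, rule_table)
    variant = precursor.substitute(dict(substitutions))

    # Positional roles are inherited from the parent (anchors may be broken
    # by the substitution itself, e.g. C11A).
    retained = tuple(p for p in parent_rules.retained_ser if variant.residue(p) in "ST")
    dehydratable = tuple(p for p in range(1, variant.n_core + 1)
                         if variant.residue(p) in "ST" and p not in retained)
    crosslink = parent_rules.crosslink
    if crosslink is not None and (
        variant.residue(crosslink[0]) != "C" or variant.residue(crosslink[2]) != "C"
    ):
        crosslink = None  # e.g. C11A: no decarboxylation, no cyclisation
    aaa_site = parent_rules.aaa_site
    if aaa_site is not None and variant.residue(aaa_site) not in "ST":
        aaa_site = None
    rules = PathwayRules(
        aaa_site=aaa_site,
        retained_ser=retained,
        reduce_sites=tuple(p for p in parent_rules.reduce_sites
                           if variant.residue(p) == "S"),
        crosslink=crosslink,
        phospho_start=dehydratable[0] if dehydratable else None,
        dehydratable=dehydratable,
    )

    # Dual outcome when every dehydratable Thr upstream of the Aaa site was
    # substituted away: phosphorylation of the Aaa-site Ser becomes
    # inefficient and a partially dehydrated product co-accumulates.
    upstream_thr = [p for p in parent_rules.dehydratable
                    if precursor.residue(p) == "T"
                    and aaa_site is not None and p < aaa_site]
    dual = (bool(upstream_thr)
            and all(variant.residue(p) not in "ST" for p in upstream_thr)
            and enzymes.kinC)

    tag = variant.name
    products = []
    events, label = _maturation_events(variant, enzymes, rules)
    products.append(apply_events(
        variant, events, label=f"{label}[{tag}]", ratio=0.5 if dual else 1.0))
    if dual:
        events_partial, label_partial = _maturation_events(
            variant, enzymes, rules, aaa_mode="skip")
        products.append(apply_events(
            variant, events_partial, label=f"{label_partial}-partial[{tag}]", ratio=0.5))
    return products


# ---------------------------------------------------------------------------
# GluC digestion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DigestFragment:
    """A contiguous proteolytic fragment with intact termini chemistry."""

    start: int
    end: int
    formula: ElementalFormula
    mass: float

    def mz(self, charge: int = 2) -> float:
        return mz_of_ion(self.mass, charge)


def gluc_digest(product: ProductSpec,
                accessible_sites: Sequence[int] | None = None) -> list[DigestFragment]:
    """Cleave *product* C-terminal to Glu at the accessible sites.

    By default every Glu in the segment is accessible; callers mask sites
    blocked by modification (on the dehydrated core the Glu-9 site is
    inaccessible unless the downstream structure is disrupted). Each
    fragment formula is the sum of effective residue compositions plus
    water; per-fragment ``[M + 2H]2+`` is available via ``mz(2)``.
    """
    positions = product.positions
    seg_start, seg_end = product.segment
    if accessible_sites is None:
        accessible_sites = [p for p in positions[:-1] if product.genetic(p) == "E"]
    for site in accessible_sites:
        if product.genetic(site) != "E":
            raise MaturationError(
                f"cleavage site {site} is {product.genetic(site)!r}, not C-terminal to Glu")
        if site == seg_end:
            raise MaturationError(f"cleavage site {site} is the segment C-terminus")

    cuts = set(accessible_sites)
    chunks: list[list[int]] = [[]]
    for p in positions:
        chunks[-1].append(p)
        if p in cuts:
            chunks.append([])
    fragments = []
    for frag_positions in chunks:
        if not frag_positions:
            continue
        counts: dict[str, int] = dict(WATER)
        for p in frag_positions:
            comp, _ = product.effective_composition(p)
            for element, n in comp.items():
                counts[element] = counts.get(element, 0) + n
        formula = ElementalFormula({e: n for e, n in counts.items() if n})
        fragments.append(DigestFragment(frag_positions[0], frag_positions[-1],
                                        formula, formula.monoisotopic_mass()))
    return fragments


# ---------------------------------------------------------------------------
# Processive intermediate series
# ---------------------------------------------------------------------------

def processive_series(precursor: PrecursorPeptide,
                      rule_table: dict | None = None) -> list[ProductSpec]:
    """Phosphorylation/elimination intermediates in N- to C-terminal order.

    KinD/KinC act processively, one residue at a time from the first
    dehydratable position: each dehydratable site contributes a phospho
    intermediate (+HPO3) followed by the eliminated species (-H3PO4
    relative to it). The final entry is the fully dehydrated state of
    compound 11.
    """
    rules = resolve_rules(precursor, rule_table)
    series: list[ProductSpec] = []
    prior: list[ModificationEvent] = []
    for p in rules.dehydratable:
        phospho = prior + [ModificationEvent("phosphorylation", (p,))]
        series.append(apply_events(precursor, phospho, label=f"p{p}"))
        prior = prior + [ModificationEvent("dehydration", (p,))]
        if p == rules.aaa_site:
            prior.append(ModificationEvent("rearrangement_to_aaa", (p,)))
        series.append(apply_events(precursor, prior, label=f"dh{p}"))
    return series
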