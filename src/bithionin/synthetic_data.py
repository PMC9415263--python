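"""Deterministic generators for every input the pipeline consumes.

All generators are pure functions of a :class:`GeneratorConfig` (NumPy
``default_rng`` seeded from ``cfg.seed``), and each returns its ground
truth alongside the fixture, so downstream tests never re-derive it.

They emulate the study conditions of the kin pathway: 27-residue cores
carrying the S-[ST]-X-X-C-Xn-T-X4-C anchors with a Thr-rich N-terminus
(3-5 Thr among the first core positions), GC-rich actinobacterial genomes
with a planted precursor ORF and mutated enzyme-homologue genes in close
proximity, FT-ICR-like peak lists (ppm-scale jitter, uniform decoys, no
isotope envelopes), and Gaussian distance trajectories around planted
means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ms_match import FragmentIon, PeakList
from .noe_filter import NOEMonitor, StereoCandidate
from .ptm_engine import PrecursorPeptide

__all__ = [
    "GeneratorConfig",
    "kina_like_precursor",
    "gen_precursor",
    "gen_enzyme_refs",
    "gen_genome",
    "gen_spectrum",
    "gen_trajectories",
    "reverse_translate",
    "STREPTOMYCES_CODONS",
]

#: Most-frequent Streptomyces codon per amino acid (GC-rich), used for
#: reverse translation so planted genes have realistic composition.
STREPTOMYCES_CODONS = {
    "A": "GCC", "R": "CGC", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCG",
    "S": "TCC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTC",
    "*": "TGA",
}

#: Spacer with stop codons in all six frames; flanks every planted gene so
#: ORF calls recover exactly the planted coordinates.
_STOP_SPACER = "TTAATTAATTAA"

# Residues used to fill non-anchor positions (no S/T/C, which would blur
# the planted modification chemistry; no M, which would add start codons).
_FILLER = "AVLGFWYPDENQ"
_LEADER_ALPHABET = "ADLGVPQNFYW"


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed + size/noise parameters shared by all generators.

    Identical configs give bit-identical outputs (portable NumPy RNG).
    """

    seed: int = 0
    core_length: int = 27
    leader_length: int = 30
    # genome generation
    intergenic_bp: int = 300
    flank_bp: int = 2_000
    mutation_rate: float = 0.05
    # spectra
    ppm_sd: float = 3.0
    decoy_count: int = 25
    # trajectories
    n_frames: int = 200
    distance_sd: float = 0.1

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def kina_like_precursor() -> PrecursorPeptide:
    """Synthetic KinA-like demo precursor (NOT the deposited KinA sequence).

    A mass-consistent surrogate: every residue identity that the kin
    maturation chemistry constrains (the Ile-1 methylation site, the
    Thr-rich N-terminus Thr-2/3/4/6, the Aaa site Ser-7, Dha site Ser-8,
    the GluC sites Glu-(-6)/Glu-9, the MAbi anchors Cys-11/Thr-22/Cys-27,
    the d-Ala sites Ser-13/16/18, Leu-14, Dhb-20, Ala-21, the retained
    Ser-25) is in place, and the remaining positions carry a fixed
    arbitrary arrangement of the residue inventory that closes the mature
    product's molecular formula to C115H174N28O31S2. Mass- and
    motif-dependent predictions therefore reproduce the pathway's reported
    ions; the residue order at the unconstrained positions is synthetic.
    """
    return PrecursorPeptide(
        leader="MDLNQAQLAALGALDNLDVAGLDAESAPAD",
        core="ITTTVTSSEICVSLVSVSWTATGDSAC",
        name="kinA-like-synthetic",
    )


# ---------------------------------------------------------------------------
# Precursors
# ---------------------------------------------------------------------------

def gen_precursor(cfg: GeneratorConfig) -> PrecursorPeptide:
    """Random kin-like precursor: motif-valid core with Thr-rich N-terminus.

    The anchor layout mirrors the founding member: first S anchor at core
    position 7, thiol Cys at 11, Thr acceptor 5 before the C-terminal Cys,
    and the inner gap g = core_length - 17. Between the thiol and acceptor
    anchors 2-3 Ser are planted (reductase substrates) plus one retained
    Ser before the C-terminal Cys; N-terminal positions 2..6 carry 3-5 Thr
    in total across the first eight positions.
    """
    n = cfg.core_length
    gap = n - 17
    if gap < 1:
        raise ValueError(f"core_length {n} too short for the anchor template")
    rng = cfg.rng()
    core = [rng.choice(list(_FILLER)) for _ in range(n)]

    core[0] = "I"
    s2 = rng.choice(["S", "T"])
    core[6], core[7] = "S", s2                      # S7, S/T8
    core[10] = "C"                                  # thiol Cys
    acceptor, cterm = n - 5, n
    core[acceptor - 1], core[cterm - 1] = "T", "C"
    core[8] = "E"                                   # GluC site before the thiol
    core[acceptor + 2] = "S"                        # retained Ser (between T and C-term)
    # reductase-substrate Ser strictly between thiol and acceptor anchors
    interior = [p - 1 for p in range(13, acceptor - 1)]
    for idx in rng.choice(interior, size=min(3, len(interior)), replace=False):
        core[idx] = "S"
    # Thr-rich N-terminus: 3-5 Thr in the first eight positions
    n_thr = int(rng.integers(3, 5 if s2 == "T" else 6))
    thr_slots = rng.choice(range(1, 6), size=n_thr, replace=False)
    for pos in thr_slots:
        core[pos] = "T"

    leader = [rng.choice(list(_LEADER_ALPHABET)) for _ in range(cfg.leader_length)]
    leader[0] = "M"
    leader[-6], leader[-5] = "E", "S"               # GluC site, Ser-(-5)
    return PrecursorPeptide(core="".join(core), leader="".join(leader),
                            name=f"synthetic-precursor-{cfg.seed}")


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

_ROLE_LENGTHS = {"KinC": 323, "KinD": 300, "KinH": 280, "KinI": 180}


def gen_enzyme_refs(cfg: GeneratorConfig) -> dict[str, str]:
    """Random reference proteins at realistic kin enzyme lengths."""
    rng = np.random.default_rng(cfg.seed + 101)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    refs = {}
    for role, length in _ROLE_LENGTHS.items():
        refs[role] = "M" + "".join(rng.choice(alphabet, size=length - 1))
    return refs


def reverse_translate(protein: str,
                      table: Mapping[str, str] = STREPTOMYCES_CODONS) -> str:
    """Deterministic reverse translation with a fixed codon table (+ stop)."""
    return "".join(table[aa] for aa in protein) + table["*"]


def _mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    out = list(protein)
    for i in range(1, len(out)):  # keep the Met start
        if rng.random() < rate:
            out[i] = alphabet[int(rng.integers(len(alphabet)))]
    return "".join(out)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    # GC-biased filler, as in actinobacterial genomes
    return "".join(rng.choice(list("ACGT"), size=n, p=[0.14, 0.36, 0.36, 0.14]))


def gen_genome(cfg: GeneratorConfig, precursor: PrecursorPeptide,
               enzyme_refs: Mapping[str, str],
               include_roles: Sequence[str] | None = None,
               ) -> tuple[SeqRecord, dict]:
    """Plant a precursor ORF and mutated enzyme-homologue genes in a contig.

    Genes are laid out colinearly with stop-codon spacers and random
    GC-rich intergenic filler, all within a few kb of the precursor. The
    ground-truth sidecar records every planted span (0-based half-open,
    stop codon included) and the planted roles.
    """
    rng = np.random.default_rng(cfg.seed + 202)
    include_roles = list(enzyme_refs if include_roles is None else include_roles)
    truth: dict = {"roles": include_roles, "genes": {}}

    parts: list[str] = [_random_dna(cfg.flank_bp, rng)]
    offset = cfg.flank_bp

    def plant(name: str, protein: str):
        nonlocal offset
        parts.append(_STOP_SPACER)
        offset += len(_STOP_SPACER)
        gene = reverse_translate(protein)
        truth["genes"][name] = {"start": offset, "end": offset + len(gene),
                                "strand": "+", "protein": protein}
        parts.append(gene)
        offset += len(gene)
        parts.append(_STOP_SPACER)
        offset += len(_STOP_SPACER)
        filler = _random_dna(cfg.intergenic_bp, rng)
        parts.append(filler)
        offset += len(filler)

    plant("precursor", precursor.leader + precursor.core)
    for role in include_roles:
        plant(role, _mutate_protein(enzyme_refs[role], cfg.mutation_rate, rng))
    parts.append(_random_dna(cfg.flank_bp, rng))

    record = SeqRecord(Seq("".join(parts)), id=f"synthetic-contig-{cfg.seed}",
                       description="synthetic kin-like BGC fixture")
    truth["length"] = len(record.seq)
    return record, truth


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def gen_spectrum(cfg: GeneratorConfig, ions: Sequence[FragmentIon],
                 ) -> tuple[PeakList, dict]:
    """Noisy peak list from a theoretical ladder: ppm jitter + decoys.

    Each observable ion is jittered by Normal(0, ppm_sd) in relative mass;
    ``decoy_count`` uniform decoys span the ladder's m/z range. The ground
    truth maps each peak index (after m/z sorting) to its source ion name,
    or None for decoys.
    """
    rng = np.random.default_rng(cfg.seed + 303)
    real = [ion for ion in ions if ion.observable]
    mz = np.array([ion.mz for ion in real])
    jitter = rng.normal(0.0, cfg.ppm_sd * 1e-6, size=len(real))
    mz_obs = mz * (1.0 + jitter)
    intensity = rng.lognormal(mean=10.0, sigma=1.0, size=len(real))

    lo, hi = (mz.min() * 0.9, mz.max() * 1.1) if len(real) else (100.0, 2000.0)
    decoys = rng.uniform(lo, hi, size=cfg.decoy_count)
    decoy_intensity = rng.lognormal(mean=8.0, sigma=1.0, size=cfg.decoy_count)

    all_mz = np.concatenate([mz_obs, decoys])
    all_intensity = np.concatenate([intensity, decoy_intensity])
    labels = [ion.name for ion in real] + [None] * cfg.decoy_count
    order = np.argsort(all_mz, kind="stable")
    peaks = PeakList(all_mz[order], all_intensity[order],
                     source=f"synthetic seed={cfg.seed}")
    truth = {"peak_ions": [labels[i] for i in order],
             "n_real": len(real), "n_decoys": cfg.decoy_count}
    return peaks, truth


# ---------------------------------------------------------------------------
# Distance trajectories
# ---------------------------------------------------------------------------

def gen_trajectories(cfg: GeneratorConfig,
                     design: Mapping[str, Mapping[str, float]],
                     monitors: Sequence[NOEMonitor] | None = None,
                     ) -> tuple[list[StereoCandidate], dict]:
    """Gaussian distance trajectories around planted per-monitor means.

    ``design`` maps candidate id -> monitor label -> planted mean distance
    (A); frames are Normal(mean, cfg.distance_sd), clipped to stay
    positive. With *monitors* given, the ground truth also records which
    monitors each candidate's planted mean satisfies.
    """
    if cfg.distance_sd < 0:
        raise ValueError("distance sd must be non-negative")
    rng = np.random.default_rng(cfg.seed + 404)
    candidates = []
    truth: dict = {"satisfied": {}}
    bounds = {m.label: (m.lower, m.upper) for m in (monitors or [])}
    for cand_id in sorted(design):
        trajectories = {}
        satisfied = {}
        for label in sorted(design[cand_id]):
            mean = float(design[cand_id][label])
            if mean <= 0:
                raise ValueError(f"planted mean for {cand_id}/{label} must be positive")
            frames = rng.normal(mean, cfg.distance_sd, size=cfg.n_frames)
            trajectories[label] = np.clip(frames, 1e-3, None)
            if label in bounds:
                lo, hi = bounds[label]
                satisfied[label] = bool(lo <= mean <= hi)
        candidates.append(StereoCandidate(cand_id, centres={}, trajectories=trajectories))
        truth["satisfied"][cand_id] = satisfied
    return candidates, truth
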