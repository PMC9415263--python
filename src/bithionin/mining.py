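"""Conserved-genomics survey for kin-like biosynthetic gene clusters.

kin-like precursor peptides are short ORFs whose core carries the signature
anchor motif ``S-[ST]-X-X-C-Xn-T-X4-C`` (S7-S8-C11-T22-C27 in the founding
member) and whose genomic neighbourhood encodes homologues of the four
essential maturation enzymes (the dehydratase pair KinC/KinD and the
cyclisation pair KinH/KinI). The survey therefore has three stages:

1. six-frame short-ORF detection (:func:`find_orfs`),
2. anchor-motif scanning of the translated ORFs (:func:`scan_motif`),
3. windowed co-occurrence calls for enzyme homologues by Smith-Waterman
   local alignment against reference proteins (:func:`survey_bgc`).

Coordinates are 0-based half-open on the forward strand internally;
motif-hit anchor positions are 1-based within the protein, matching the
field's residue-numbering convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "ORF",
    "MotifPattern",
    "MotifHit",
    "AlignmentResult",
    "BGCHit",
    "find_orfs",
    "scan_motif",
    "sw_align",
    "survey_bgc",
]

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = {"TAA", "TAG", "TGA"}
_VALID_NT = set("ACGTN")


@dataclass(frozen=True)
class ORF:
    """An open reading frame; span is 0-based half-open on the forward
    strand and includes the stop codon (so length = 3 * (aa + 1))."""

    contig: str
    strand: str
    frame: int
    start: int
    end: int
    protein: str

    @property
    def length_aa(self) -> int:
        return len(self.protein)

    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def _orfs_one_strand(seq: str, contig: str, strand: str, length: int,
                     min_aa: int, max_aa: int,
                     start_codons: Sequence[str]) -> list[ORF]:
    out = []
    for frame in range(3):
        starts: list[int] = []
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                # longest in-bounds ORF for this stop
                for start in starts:
                    aa = (pos - start) // 3
                    if aa > max_aa:
                        continue
                    if aa >= min_aa:
                        protein = "M" + str(Seq(seq[start + 3:pos]).translate())
                        begin, stop_end = start, pos + 3
                        if strand == "-":
                            begin, stop_end = length - stop_end, length - start
                        out.append(ORF(contig, strand, frame, begin, stop_end, protein))
                    break
                starts = []
            elif codon in start_codons:
                starts.append(pos)
    return out


def find_orfs(genome, min_aa: int = 30, max_aa: int = 120,
              start_codons: Sequence[str] = START_CODONS) -> list[ORF]:
    """Six-frame ORF scan of a nucleotide sequence or SeqRecord.

    For each in-frame stop, the longest upstream start codon giving an ORF
    within ``[min_aa, max_aa]`` is reported (one ORF per stop). ``N`` is
    tolerated in the alphabet but never inside a reported start/stop codon.
    """
    contig = getattr(genome, "id", "seq")
    seq = str(getattr(genome, "seq", genome)).upper()
    if set(seq) - _VALID_NT:
        bad = sorted(set(seq) - _VALID_NT)
        raise ValueError(f"invalid nucleotide characters {bad} in {contig}")
    if min_aa > max_aa:
        raise ValueError(f"min_aa {min_aa} > max_aa {max_aa}")
    orfs = _orfs_one_strand(seq, contig, "+", len(seq), min_aa, max_aa, start_codons)
    rc = str(Seq(seq).reverse_complement())
    orfs += _orfs_one_strand(rc, contig, "-", len(seq), min_aa, max_aa, start_codons)
    return sorted(orfs, key=lambda o: (o.start, o.end, o.strand))


# ---------------------------------------------------------------------------
# Signature motif
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifPattern:
    """The kin anchor template ``S-[ST]-X-X-C-X{g}-T-X{4}-C``.

    The inner gap g between the first Cys anchor and the Thr anchor varies
    among homologues; the default range [6, 16] brackets the founding
    member's g = 10.
    """

    g_min: int = 6
    g_max: int = 16

    def __post_init__(self):
        if self.g_min > self.g_max or self.g_min < 0:
            raise ValueError(f"invalid gap range [{self.g_min}, {self.g_max}]")

    def regex(self, g: int) -> re.Pattern:
        return re.compile(rf"(?=(S[ST]..C.{{{g}}}T.{{4}}C))")


@dataclass(frozen=True)
class MotifHit:
    """Anchor positions (1-based) of one motif match."""

    seq_id: str
    positions: tuple[int, int, int, int, int]  # S, S/T, C, T, C
    gap: int


def scan_motif(protein: str, pattern: MotifPattern | None = None,
               seq_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) anchor-motif matches in *protein*."""
    if not protein:
        raise ValueError("empty protein sequence")
    pattern = pattern or MotifPattern()
    hits = []
    for g in range(pattern.g_min, pattern.g_max + 1):
        for m in pattern.regex(g).finditer(protein):
            s1 = m.start() + 1
            hits.append(MotifHit(seq_id, (s1, s1 + 1, s1 + 4, s1 + 5 + g, s1 + 10 + g), g))
    return sorted(hits, key=lambda h: (h.positions[0], h.gap))


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentResult:
    score: float
    query_span: tuple[int, int] | None = None
    ref_span: tuple[int, int] | None = None


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def sw_align(query: str, ref: str, matrix: str = "BLOSUM62",
             gap_open: float = 10.0, gap_extend: float = 1.0,
             spans: bool = True) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment score (and spans).

    Affine gaps: a gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    Either sequence empty gives score 0. Residues absent from the
    substitution matrix raise ``ValueError``.
    """
    if not query or not ref:
        return AlignmentResult(0.0)
    aligner = _aligner(matrix, gap_open, gap_extend)
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    for name, seq in (("query", query), ("ref", ref)):
        missing = set(seq) - alphabet
        if missing:
            raise ValueError(f"{name} residues {sorted(missing)} absent from {matrix}")
    if not spans:
        return AlignmentResult(float(aligner.score(query, ref)))
    alignment = next(iter(aligner.align(query, ref)))
    q_blocks, r_blocks = alignment.aligned
    return AlignmentResult(
        float(alignment.score),
        (int(q_blocks[0][0]), int(q_blocks[-1][1])),
        (int(r_blocks[0][0]), int(r_blocks[-1][1])),
    )


# ---------------------------------------------------------------------------
# Co-occurrence survey
# ---------------------------------------------------------------------------

@dataclass
class BGCHit:
    """A motif-bearing short ORF with per-role enzyme co-occurrence calls."""

    precursor: ORF
    motif: MotifHit
    best: dict[str, tuple[float, ORF | None]] = field(default_factory=dict)
    verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def total_score(self) -> float:
        return sum(score for score, _ in self.best.values())

    @property
    def all_roles_present(self) -> bool:
        return all(self.verdicts.values())


def survey_bgc(genome, refs: Mapping[str, str],
               window_bp: int = 10_000, score_min: float = 100.0,
               precursor_bounds: tuple[int, int] = (30, 120),
               enzyme_bounds: tuple[int, int] = (100, 600),
               pattern: MotifPattern | None = None,
               matrix: str = "BLOSUM62",
               required_roles: Sequence[str] = ("KinC", "KinD", "KinH", "KinI"),
               ) -> list[BGCHit]:
    """Call kin-like BGCs: motif-bearing short ORFs with nearby enzyme genes.

    For every short ORF whose translation carries the signature motif, all
    ORFs within ``window_bp`` of it are aligned against each reference
    protein; a role verdict is true when the best local-alignment score
    reaches ``score_min``. The default of 100 sits well above the best
    local scores of unrelated proteins at these lengths (about 65 for
    random 300-residue pairs under BLOSUM62 with gap 10/1) and far below
    genuine homologue scores. Hits are sorted by total alignment score.
    """
    for role in required_roles:
        if role not in refs:
            raise KeyError(f"missing reference protein for role {role!r}")
    pattern = pattern or MotifPattern()
    precursors = find_orfs(genome, *precursor_bounds)
    enzymes = find_orfs(genome, *enzyme_bounds)
    aligner = _aligner(matrix, 10.0, 1.0)

    hits: list[BGCHit] = []
    for orf in precursors:
        motif_hits = scan_motif(orf.protein, pattern, seq_id=orf.contig)
        if not motif_hits:
            continue
        lo, hi = orf.start - window_bp, orf.end + window_bp
        neighbours = [e for e in enzymes
                      if e.start < hi and e.end > lo
                      and (e.start, e.end, e.strand) != (orf.start, orf.end, orf.strand)]
        hit = BGCHit(orf, motif_hits[0])
        for role in refs:
            best_score, best_orf = 0.0, None
            for neighbour in neighbours:
                score = float(aligner.score(neighbour.protein, refs[role]))
                if score > best_score:
                    best_score, best_orf = score, neighbour
            hit.best[role] = (best_score, best_orf)
            hit.verdicts[role] = best_score >= score_min
        hits.append(hit)
    return sorted(hits, key=lambda h: -h.total_score)
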