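"""NOE distance-restraint filtering of stereoisomer candidates.

The relative configuration of a crosslinked peptide's stereocentres can be
narrowed down by comparing long-range NOE-derived inter-proton distance
bounds with distances monitored along molecular-dynamics trajectories of
each candidate diastereomer. This module implements only that
post-processing: the MD engine itself is external, and trajectories arrive
as per-frame distance series.

The effective distance of a trajectory is the NOE-appropriate ensemble
average ``<r^-6>^(-1/6)`` over post-burn-in frames (NOE intensity scales
with r^-6, so transiently short distances dominate, and the effective
distance never exceeds the arithmetic mean). An alternative
fraction-of-frames-in-bounds criterion is available.

Default bounds follow NOE practice: 1.8-5.0 A for general monitors and
4.0-5.0 A for weak long-range monitors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "NOEMonitor",
    "DistanceTrajectory",
    "StereoCandidate",
    "MonitorResult",
    "CandidateEvaluation",
    "effective_distance",
    "evaluate_candidate",
    "rank_candidates",
    "load_trajectories_tsv",
]

GENERAL_BOUNDS = (1.8, 5.0)
LONG_RANGE_BOUNDS = (4.0, 5.0)


@dataclass(frozen=True)
class NOEMonitor:
    """One NOE-derived distance restraint between an atom pair."""

    label: str
    atom_pair: tuple[str, str]
    lower: float = GENERAL_BOUNDS[0]
    upper: float = GENERAL_BOUNDS[1]
    long_range: bool = False

    def __post_init__(self):
        if not (0 < self.lower < self.upper):
            raise ValueError(
                f"monitor {self.label!r}: need 0 < lower < upper, "
                f"got [{self.lower}, {self.upper}]")

    @classmethod
    def long_range_monitor(cls, label: str, atom_pair: tuple[str, str]) -> "NOEMonitor":
        return cls(label, atom_pair, *LONG_RANGE_BOUNDS, long_range=True)


@dataclass
class DistanceTrajectory:
    """Per-frame distances (A) for one candidate/monitor pair."""

    candidate_id: str
    monitor: str
    distances: np.ndarray

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 1 or len(self.distances) < 1:
            raise ValueError("trajectory needs at least one frame")
        if np.any(self.distances <= 0):
            raise ValueError("distances must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.distances)


@dataclass
class StereoCandidate:
    """A candidate stereoisomer: configuration labels + monitor trajectories."""

    candidate_id: str
    centres: Mapping[str, str]
    trajectories: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class MonitorResult:
    monitor: str
    effective: float
    lower: float
    upper: float
    satisfied: bool
    violation: float


@dataclass
class CandidateEvaluation:
    candidate_id: str
    results: list[MonitorResult]
    rank: int | None = None

    @property
    def n_satisfied(self) -> int:
        return sum(r.satisfied for r in self.results)

    @property
    def fully_consistent(self) -> bool:
        return all(r.satisfied for r in self.results)

    @property
    def total_violation(self) -> float:
        return sum(r.violation for r in self.results)


def effective_distance(distances, burn_in: float = 0.1) -> float:
    """``<r^-6>^(-1/6)`` over frames after discarding a burn-in fraction."""
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 1 or distances.size == 0:
        raise ValueError("empty trajectory")
    if not (0.0 <= burn_in < 1.0):
        raise ValueError(f"burn-in fraction must be in [0, 1), got {burn_in}")
    kept = distances[int(np.floor(burn_in * distances.size)):]
    if kept.size == 0:
        raise ValueError("no frames left after burn-in")
    return float(np.mean(kept ** -6.0) ** (-1.0 / 6.0))


def _monitor_result(monitor: NOEMonitor, distances, burn_in: float,
                    criterion: str, min_fraction: float) -> MonitorResult:
    if criterion == "r6":
        eff = effective_distance(distances, burn_in)
        ok = monitor.lower <= eff <= monitor.upper
        violation = max(0.0, monitor.lower - eff, eff - monitor.upper)
    elif criterion == "fraction":
        distances = np.asarray(distances, dtype=float)
        kept = distances[int(np.floor(burn_in * distances.size)):]
        inside = np.mean((kept >= monitor.lower) & (kept <= monitor.upper))
        eff = effective_distance(distances, burn_in)
        ok = inside >= min_fraction
        violation = max(0.0, min_fraction - float(inside))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return MonitorResult(monitor.label, eff, monitor.lower, monitor.upper,
                         bool(ok), float(violation))


def evaluate_candidate(candidate: StereoCandidate,
                       monitors: Sequence[NOEMonitor],
                       burn_in: float = 0.1,
                       criterion: str = "r6",
                       min_fraction: float = 0.8) -> CandidateEvaluation:
    """Per-monitor satisfaction for one candidate.

    A candidate is "fully consistent" iff every monitor's effective
    distance sits inside its bounds. A missing trajectory raises a
    ``KeyError`` naming the monitor.
    """
    results = []
    for monitor in monitors:
        if monitor.label not in candidate.trajectories:
            raise KeyError(
                f"candidate {candidate.candidate_id!r} has no trajectory "
                f"for monitor {monitor.label!r}")
        results.append(_monitor_result(monitor, candidate.trajectories[monitor.label],
                                       burn_in, criterion, min_fraction))
    return CandidateEvaluation(candidate.candidate_id, results)


def rank_candidates(candidates: Sequence[StereoCandidate],
                    monitors: Sequence[NOEMonitor],
                    burn_in: float = 0.1,
                    criterion: str = "r6",
                    min_fraction: float = 0.8) -> list[CandidateEvaluation]:
    """Rank candidates by (satisfied monitors desc, total violation asc, id).

    The deterministic id tie-break makes the ordering reproducible for
    identical trajectories.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    evaluations = [evaluate_candidate(c, monitors, burn_in, criterion, min_fraction)
                   for c in candidates]
    evaluations.sort(key=lambda e: (-e.n_satisfied, e.total_violation, e.candidate_id))
    for rank, evaluation in enumerate(evaluations, start=1):
        evaluation.rank = rank
    return evaluations


def load_trajectories_tsv(path) -> list[DistanceTrajectory]:
    """Read distance trajectories from TSV: candidate, monitor, frame, distance_A."""
    series: dict[tuple[str, str], list[tuple[int, float]]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            candidate, monitor, frame, distance = line.split("\t")
            series.setdefault((candidate, monitor), []).append(
                (int(frame), float(distance)))
    out = []
    for (candidate, monitor), frames in sorted(series.items()):
        frames.sort()
        out.append(DistanceTrajectory(candidate, monitor,
                                      np.array([d for _, d in frames])))
    return out
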