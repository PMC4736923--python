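"""Feature grading rules and the per-iris characterization record.

Grade scales (1-based):

* crypts 1-4: 1 none; 2 only small crypts; 3 at least one large crypt in
  fewer than three quadrants; 4 at least three large crypts spread over
  three or more quadrants. Grade 4 requires BOTH clauses (>=3 large crypts
  AND >=3 distinct quadrants holding large crypts); anything else with a
  large crypt is grade 3.
* furrows / nodules 1-3: 1 absent; 2 extends <=180 degrees; 3 extends
  strictly more than 180 degrees.
* spots raw 1-4: none / 1-2 / 3-5 / >5; the collapsed 1-3 scale merges the
  top two raw grades.
* melanosis: presence (1) or absence (0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotation import (
    FeatureGrades,
    FeatureObservation,
    IrisAnnotation,
    ParticipantRecord,
    Population,
)
from .errors import ExclusionError, IristexError, ValidationError
from .geometry import CryptSize, classify_crypt, iris_width, quadrant_of_point

__all__ = [
    "grade_crypts",
    "grade_extension",
    "grade_spots_raw",
    "grade_spots",
    "characterize",
    "Characterization",
    "filter_cohort",
    "ExclusionLog",
]


def grade_crypts(classified: Sequence[tuple[CryptSize, int]]) -> int:
    """Crypt grade from (size, quadrant) pairs."""
    for _, quad in classified:
        if quad not in (1, 2, 3, 4):
            raise ValidationError(f"quadrant must be 1..4, got {quad}")
    if not classified:
        return 1
    large = [(s, q) for s, q in classified if s is CryptSize.LARGE]
    if not large:
        return 2
    n_large = len(large)
    n_quadrants = len({q for _, q in large})
    if n_large >= 3 and n_quadrants >= 3:
        return 4
    return 3


def grade_extension(obs: FeatureObservation) -> int:
    """Extension grade shared by contraction furrows and Wolfflin nodules."""
    if not obs.present:
        return 1
    return 3 if obs.over_180 else 2


def grade_spots_raw(n_spots: int) -> int:
    if n_spots < 0:
        raise ValidationError(f"spot count must be >= 0, got {n_spots}")
    if n_spots == 0:
        return 1
    if n_spots <= 2:
        return 2
    if n_spots <= 5:
        return 3
    return 4


def grade_spots(n_spots: int) -> int:
    """Collapsed 3-grade spot scale (raw grades 3 and 4 merged)."""
    return min(grade_spots_raw(n_spots), 3)


@dataclass(frozen=True)
class Characterization:
    """What the original program exported per iris."""

    grades: FeatureGrades
    quadrant_profile: dict[str, tuple[bool, bool, bool, bool]]
    iris_width_px: float


def _quadrant_flags(quadrants: Iterable[int]) -> tuple[bool, bool, bool, bool]:
    qs = set(quadrants)
    return tuple(q in qs for q in (1, 2, 3, 4))


def characterize(a: IrisAnnotation) -> Characterization:
    """Produce the full per-iris record from a validated annotation.

    Crypt quadrant tallies count large crypts only (matching the reported
    per-quadrant prevalence semantics); spot tallies count all spots.
    Obstructed annotations cannot be characterized and raise
    :class:`ExclusionError`.
    """
    if a.obstructed:
        raise ExclusionError(
            f"annotation {a.id!r} is obstructed and cannot be characterized",
            reason="obstructed",
        )
    classified = [
        (classify_crypt(a, c), quadrant_of_point(a, c.tip)) for c in a.crypts
    ]
    crypt_grade = grade_crypts(classified)
    large_quadrants = [q for s, q in classified if s is CryptSize.LARGE]
    spot_quadrants = [quadrant_of_point(a, p) for p in a.spots]
    spot_raw = grade_spots_raw(len(a.spots))
    grades = FeatureGrades(
        crypt=crypt_grade,
        furrow=grade_extension(a.furrows),
        nodule=grade_extension(a.nodules),
        spot=min(spot_raw, 3),
        spot_raw=spot_raw,
        melanosis=int(a.melanosis),
        colour=a.self_colour,
    )
    profile = {
        "crypt": _quadrant_flags(large_quadrants),
        "furrow": a.furrows.quadrants,
        "nodule": a.nodules.quadrants,
        "spot": _quadrant_flags(spot_quadrants),
    }
    return Characterization(grades, profile, iris_width(a))


@dataclass
class ExclusionLog:
    """Counts of excluded records by reason and by population."""

    by_reason: dict[str, int] = field(default_factory=dict)
    by_population: dict[str, dict[str, int]] = field(default_factory=dict)
    total_excluded: int = 0

    def record(self, reason: str, population: Population) -> None:
        self.by_reason[reason] = self.by_reason.get(reason, 0) + 1
        pop = self.by_population.setdefault(population.value, {})
        pop[reason] = pop.get(reason, 0) + 1
        self.total_excluded += 1


def filter_cohort(
    records: Iterable[ParticipantRecord],
) -> tuple[list[ParticipantRecord], ExclusionLog]:
    """Drop excluded (obstructed / disorder-flagged) records, logging counts."""
    log = ExclusionLog()
    included = []
    for r in records:
        if r.excluded:
            if not r.exclusion_reason:
                raise IristexError(f"record {r.id} flagged excluded without a reason")
            log.record(r.exclusion_reason, r.population)
        else:
            included.append(r)
    return included, log
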