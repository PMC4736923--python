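"""Seeded generators: cohort-level genotype-phenotype simulation and
annotation-level geometry fixtures.

Determinism: a single root seed spawns named substreams through
``numpy.random.SeedSequence(seed).spawn``; the substream order is fixed
(one per population, in config order, then one for annotations), so a
component can be regenerated in isolation by reusing its substream index.

The crypt-grade/genotype link is a cumulative-logit model whose baseline
thresholds reproduce the configured marginal category probabilities at
odds ratio 1, so the association machinery has a well-defined truth to
recover. Because the published odds ratios were covariate-adjusted, the
generator's marginal odds ratios are approximations of them, not
reproductions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import (
    ArcInterval,
    Circle,
    CohortTable,
    CryptMark,
    FeatureGrades,
    FeatureObservation,
    IrisAnnotation,
    ParticipantRecord,
    Point,
    Population,
    Sex,
)
from .errors import ValidationError
from .fixtures import ALLELE_FREQUENCIES, TABLE1, TABLE3_COUNTS
from .geometry import anatomical_to_image_angle, ray_circle_distance

__all__ = [
    "SimulationConfig",
    "IrisGeometry",
    "simulate_cohort",
    "simulate_annotation",
    "simulate_rater",
    "place_crypt_tip",
    "default_config",
]

_DEFAULT_MARKER = "rs10235789"


def _table3_probs(trait: str) -> dict[str, tuple[float, ...]]:
    out = {}
    for pop in ("EastAsian", "European", "SouthAsian"):
        counts = np.asarray(TABLE3_COUNTS[trait][pop], dtype=float)
        out[pop] = tuple(counts / counts.sum())
    return out


# Table 2 crypt odds ratios per derived-genotype class (het, hom). The East
# Asian derived-homozygote class was dropped in the source analysis; its
# default here is the additive (log-scale) extrapolation of the het effect.
_DEFAULT_GENOTYPE_OR = {
    "EastAsian": (1.679, 1.679**2),
    "European": (1.507, 2.203),
    "SouthAsian": (2.206, 2.721),
}

_FEATURES = ("crypt", "furrow", "nodule", "spot", "melanosis", "colour")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort simulation parameters; every default comes from the packaged
    tables (category frequencies, allele frequencies, odds ratios, widths)."""

    seed: int
    n: dict[str, int] = field(
        default_factory=lambda: {"EastAsian": 467, "European": 619, "SouthAsian": 364}
    )
    category_probs: dict[str, dict[str, tuple[float, ...]]] = field(
        default_factory=lambda: {t: _table3_probs(t) for t in _FEATURES}
    )
    allele_freq: dict[str, float] = field(
        default_factory=lambda: {
            p: ALLELE_FREQUENCIES[_DEFAULT_MARKER][p]
            for p in ("EastAsian", "European", "SouthAsian")
        }
    )
    genotype_odds_ratios: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_GENOTYPE_OR)
    )
    marker: str = _DEFAULT_MARKER
    iris_width_mean: dict[str, float] = field(
        default_factory=lambda: {
            p: TABLE1[p]["mean_iris_width"]
            for p in ("EastAsian", "European", "SouthAsian")
        }
    )
    iris_width_sd: float = 20.0
    female_share: dict[str, float] = field(
        default_factory=lambda: {
            p: TABLE1[p]["females"] / TABLE1[p]["irises_included"]
            for p in ("EastAsian", "European", "SouthAsian")
        }
    )
    mean_age: dict[str, float] = field(
        default_factory=lambda: {
            p: TABLE1[p]["mean_age"] for p in ("EastAsian", "European", "SouthAsian")
        }
    )

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValidationError("seed is mandatory and must be an integer")
        for pop, count in self.n.items():
            if count < 0:
                raise ValidationError(f"n for {pop} must be >= 0")
            if pop not in self.category_probs["crypt"]:
                raise ValidationError(f"no category probabilities for {pop}")
        for trait, per_pop in self.category_probs.items():
            for pop, probs in per_pop.items():
                arr = np.asarray(probs, dtype=float)
                if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                    raise ValidationError(
                        f"category probabilities for {trait}/{pop} must be a "
                        f"distribution summing to 1 (got sum {arr.sum()!r})"
                    )
        for pop, freq in self.allele_freq.items():
            if not 0.0 <= freq <= 1.0:
                raise ValidationError(f"allele frequency for {pop} out of [0,1]")
        for pop, ors in self.genotype_odds_ratios.items():
            if any(o <= 0 for o in ors):
                raise ValidationError(f"odds ratios for {pop} must be > 0")


def default_config(seed: int, **overrides) -> SimulationConfig:
    return replace(SimulationConfig(seed=seed), **overrides)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _draw_cumulative_logit(
    rng: np.random.Generator, probs: np.ndarray, eta: np.ndarray
) -> np.ndarray:
    """Draw 1-based ordinal outcomes from P(Y<=j) = sigmoid(theta_j - eta),
    with thresholds set so eta = 0 reproduces `probs` exactly."""
    theta = _logit(np.cumsum(probs)[:-1])
    cum = 1.0 / (1.0 + np.exp(-(theta[None, :] - eta[:, None])))
    u = rng.random(len(eta))
    return 1 + (u[:, None] > cum).sum(axis=1)


def _draw_categorical(
    rng: np.random.Generator, probs: tuple[float, ...], size: int
) -> np.ndarray:
    """1-based categorical draws."""
    cum = np.cumsum(np.asarray(probs, dtype=float))
    u = rng.random(size)
    return 1 + (u[:, None] > cum[None, :-1]).sum(axis=1)


def _quadrant_flags_for_grade(
    rng: np.random.Generator, feature: str, grade: int
) -> tuple[bool, bool, bool, bool]:
    if grade <= 1:
        return (False, False, False, False)
    if feature == "crypt" and grade == 2:
        # crypt flags track large crypts only; grade 2 has none
        return (False, False, False, False)
    n_quads = int(rng.integers(1, 5))
    if feature == "crypt" and grade == 4:
        n_quads = max(n_quads, 3)
    quads = rng.choice(4, size=n_quads, replace=False)
    return tuple(q in quads for q in range(4))


def simulate_cohort(cfg: SimulationConfig) -> CohortTable:
    """Simulate a multi-population cohort.

    Genotypes are drawn under Hardy-Weinberg proportions at the configured
    derived-allele frequencies; the crypt grade responds to genotype through
    the cumulative-logit model; the other features are independent
    categorical draws from their configured probabilities.
    """
    root = np.random.SeedSequence(cfg.seed)
    pops = list(cfg.n)
    streams = root.spawn(len(pops) + 1)
    records = []
    for pop, stream in zip(pops, streams):
        rng = np.random.default_rng(stream)
        n = cfg.n[pop]
        if n == 0:
            continue
        freq = cfg.allele_freq[pop]
        genotypes = rng.binomial(2, freq, size=n)
        or_het, or_hom = cfg.genotype_odds_ratios[pop]
        eta = np.where(
            genotypes == 1, math.log(or_het), np.where(genotypes == 2, math.log(or_hom), 0.0)
        )
        crypt = _draw_cumulative_logit(
            rng, np.asarray(cfg.category_probs["crypt"][pop]), eta
        )
        furrow = _draw_categorical(rng, cfg.category_probs["furrow"][pop], n)
        nodule = _draw_categorical(rng, cfg.category_probs["nodule"][pop], n)
        spot = _draw_categorical(rng, cfg.category_probs["spot"][pop], n)
        melanosis = _draw_categorical(rng, cfg.category_probs["melanosis"][pop], n) - 1
        colour = _draw_categorical(rng, cfg.category_probs["colour"][pop], n)
        widths = rng.normal(cfg.iris_width_mean[pop], cfg.iris_width_sd, size=n)
        widths = np.clip(widths, 50.0, None)
        sexes = rng.random(n) < cfg.female_share[pop]
        ages = np.clip(rng.normal(cfg.mean_age[pop], 2.5, size=n), 18.0, 35.0)
        for i in range(n):
            grades = FeatureGrades(
                crypt=int(crypt[i]),
                furrow=int(furrow[i]),
                nodule=int(nodule[i]),
                spot=int(spot[i]),
                spot_raw=int(spot[i]) if spot[i] < 3 else int(rng.integers(3, 5)),
                melanosis=int(melanosis[i]),
                colour=int(colour[i]),
            )
            profile = {
                feat: _quadrant_flags_for_grade(rng, feat, getattr(grades, feat))
                for feat in ("crypt", "furrow", "nodule", "spot")
            }
            records.append(
                ParticipantRecord(
                    id=f"{pop}-{i + 1:05d}",
                    population=Population(pop),
                    sex=Sex.female if sexes[i] else Sex.male,
                    age=round(float(ages[i]), 1),
                    iris_width=round(float(widths[i]), 2),
                    grades=grades,
                    quadrant_profile=profile,
                    genotypes={cfg.marker: int(genotypes[i])},
                )
            )
    return CohortTable(records)


# ---------------------------------------------------------------------------
# Annotation-level geometry fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IrisGeometry:
    """Circle layout for a synthetic annotation.

    Defaults are mildly non-concentric (offsets up to ~5% of the sclera
    radius) so downstream geometry exercises its general ray-intersection
    path rather than the concentric shortcut.
    """

    iris_centre: Point = Point(600.0, 400.0)
    sclera: Circle = Circle(Point(601.0, 399.0), 195.0)
    collarette: Circle = Circle(Point(596.0, 404.0), 95.0)
    pupil: Circle = Circle(Point(603.0, 398.0), 45.0)


def place_crypt_tip(
    geometry: IrisGeometry,
    eye_side: str,
    mirrored: bool,
    quadrant: int,
    fraction: float,
    rng: np.random.Generator,
    jitter_deg: float = 25.0,
) -> Point:
    """A point at ciliary-extension `fraction` in the given quadrant.

    The anatomical angle is drawn in the quadrant's sector (away from the
    boundaries by a margin wider than the jitter).
    """
    sector_start = {1: 0.0, 4: 90.0, 3: 180.0, 2: 270.0}[quadrant]
    phi = sector_start + 45.0 + float(rng.uniform(-jitter_deg, jitter_deg))
    # build a throwaway annotation shell to reuse the frame conversion
    shell = _bare_annotation(geometry, eye_side, mirrored)
    img_angle = anatomical_to_image_angle(shell, phi)
    dc = ray_circle_distance(geometry.iris_centre, img_angle, geometry.collarette)
    ds = ray_circle_distance(geometry.iris_centre, img_angle, geometry.sclera)
    dist = dc + fraction * (ds - dc)
    theta = math.radians(img_angle)
    return Point(
        geometry.iris_centre.x + dist * math.cos(theta),
        geometry.iris_centre.y + dist * math.sin(theta),
    )


def _bare_annotation(
    geometry: IrisGeometry, eye_side: str, mirrored: bool
) -> IrisAnnotation:
    return IrisAnnotation(
        id="shell",
        eye_side=eye_side,
        mirrored=mirrored,
        iris_centre=geometry.iris_centre,
        pupil_centre=geometry.pupil.centre,
        pupil_circle=geometry.pupil,
        collarette_circle=geometry.collarette,
        sclera_circle=geometry.sclera,
    )


def _observation_for_grade(grade: int) -> FeatureObservation:
    if grade == 1:
        return FeatureObservation.absent()
    if grade == 2:
        return FeatureObservation(True, False, (False, False, True, False))
    return FeatureObservation(True, True, (True, True, True, True))


_SPOT_COUNT_FOR_RAW = {1: 0, 2: 2, 3: 4, 4: 6}

LARGE_FRACTION_RANGE = (0.6, 0.9)
SMALL_FRACTION_RANGE = (0.1, 0.4)


def simulate_annotation(
    target: FeatureGrades,
    geometry: IrisGeometry | None = None,
    seed: int = 0,
    eye_side: str = "right",
    mirrored: bool = False,
    annotation_id: str | None = None,
) -> IrisAnnotation:
    """Construct an annotation that characterizes back to exactly `target`.

    Crypt tips are placed at ciliary-extension fractions strictly inside the
    intended class band (LARGE in [0.6, 0.9], SMALL in [0.1, 0.4]) and
    quadrants are distributed to satisfy the crypt-grade clauses.
    """
    geometry = geometry or IrisGeometry()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    crypts: list[CryptMark] = []

    def add_crypt(quadrant: int, large: bool, from_collarette: bool = True) -> None:
        lo, hi = LARGE_FRACTION_RANGE if large else SMALL_FRACTION_RANGE
        f = float(rng.uniform(lo, hi))
        tip = place_crypt_tip(geometry, eye_side, mirrored, quadrant, f, rng)
        crypts.append(CryptMark(tip, from_collarette))

    if target.crypt == 2:
        for q in (1, 2):
            add_crypt(q, large=False)
    elif target.crypt == 3:
        add_crypt(2, large=True)
        add_crypt(2, large=False)
    elif target.crypt == 4:
        for q in (1, 2, 3):
            add_crypt(q, large=True)

    n_spots = _SPOT_COUNT_FOR_RAW[target.spot_raw]
    spots = [
        place_crypt_tip(
            geometry, eye_side, mirrored, 1 + int(rng.integers(0, 4)), 0.3, rng
        )
        for _ in range(n_spots)
    ]

    return IrisAnnotation(
        id=annotation_id or f"sim-{target.crypt}{target.furrow}{target.nodule}{target.spot}{target.melanosis}",
        eye_side=eye_side,
        mirrored=mirrored,
        iris_centre=geometry.iris_centre,
        pupil_centre=geometry.pupil.centre,
        pupil_circle=geometry.pupil,
        collarette_circle=geometry.collarette,
        sclera_circle=geometry.sclera,
        crypts=tuple(crypts),
        spots=tuple(spots),
        furrows=_observation_for_grade(target.furrow),
        nodules=_observation_for_grade(target.nodule),
        melanosis=bool(target.melanosis),
        self_colour=target.colour,
    )


def simulate_rater(
    grades: np.ndarray | list[int],
    misgrade_prob: float,
    seed: int,
    n_categories: int,
) -> np.ndarray:
    """Re-rate a grade vector with independent one-step confusions.

    Each grade moves one step up or down (direction 50/50) with probability
    `misgrade_prob`, clamped to the 1..n_categories range.
    """
    if not 0.0 <= misgrade_prob < 1.0:
        raise ValidationError("misgrade_prob must be in [0, 1)")
    g = np.asarray(grades, dtype=int)
    if g.size and (g.min() < 1 or g.max() > n_categories):
        raise ValidationError(f"grades must lie in 1..{n_categories}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    flip = rng.random(g.shape) < misgrade_prob
    step = np.where(rng.random(g.shape) < 0.5, -1, 1)
    out = np.where(flip, g + step, g)
    return np.clip(out, 1, n_categories)


def simulate_annotations_for_all_grades(
    geometry: IrisGeometry | None = None, seed: int = 0
) -> list[tuple[FeatureGrades, IrisAnnotation]]:
    """The exhaustive 216-vector grade cross-product with one annotation each."""
    out = []
    i = 0
    for crypt in (1, 2, 3, 4):
        for furrow in (1, 2, 3):
            for nodule in (1, 2, 3):
                for spot in (1, 2, 3):
                    for melanosis in (0, 1):
                        target = FeatureGrades(
                            crypt=crypt,
                            furrow=furrow,
                            nodule=nodule,
                            spot=spot,
                            spot_raw=spot,
                            melanosis=melanosis,
                            colour=None,
                        )
                        out.append(
                            (
                                target,
                                simulate_annotation(
                                    target,
                                    geometry=geometry,
                                    seed=seed + i,
                                    annotation_id=f"grid-{i:03d}",
                                ),
                            )
                        )
                        i += 1
    return out
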