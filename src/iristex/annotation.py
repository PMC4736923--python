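"""Domain types for iris annotations and cohorts plus JSON/CSV interchange.

Coordinate frame
----------------
All coordinates are image pixel coordinates with the origin at the top-left
corner and y increasing downward (raster convention). The anatomical frame
used for quadrant assignment is derived from ``eye_side`` and ``mirrored``:
for an unmirrored right-eye photograph, nasal is +x (image right) and
superior is -y (image up).

Grades are canonically 1-based; the 0-based export used by the tabulated
category labels is an explicit conversion, never implicit.
"""

from __future__ import annotations

import csv
import io
import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import FormatError, ValidationError

__all__ = [
    "Point",
    "Circle",
    "CryptMark",
    "ArcInterval",
    "FeatureObservation",
    "IrisAnnotation",
    "FeatureGrades",
    "Population",
    "Sex",
    "ParticipantRecord",
    "CohortTable",
    "ContingencyTable",
    "read_annotation",
    "write_annotation",
    "read_annotations_jsonl",
    "write_annotations_jsonl",
    "read_cohort",
    "write_cohort",
    "COHORT_FIXED_COLUMNS",
]


def _require_finite(name: str, value: float) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise FormatError("not a number", field=name)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class Point:
    """A pixel location in image coordinates."""

    x: float
    y: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", _require_finite("x", self.x))
        object.__setattr__(self, "y", _require_finite("y", self.y))

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Circle:
    """A best-fit circle (centre + radius, pixels)."""

    centre: Point
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "radius", _require_finite("radius", self.radius))
        if self.radius <= 0:
            raise ValidationError(f"circle radius must be > 0, got {self.radius}")

    def contains(self, p: Point) -> bool:
        """Strict interior test."""
        return self.centre.distance_to(p) < self.radius


@dataclass(frozen=True)
class CryptMark:
    """A clicked crypt tip (outermost edge of the crypt)."""

    tip: Point
    from_collarette: bool


@dataclass(frozen=True)
class ArcInterval:
    """Half-open angular interval [start, end) in degrees.

    Sweeps in the positive anatomical angular direction; wraparound is
    expressed by ``end < start``.
    """

    start_deg: float
    end_deg: float

    def __post_init__(self) -> None:
        s = _require_finite("start_deg", self.start_deg)
        e = _require_finite("end_deg", self.end_deg)
        if not (0.0 <= s < 360.0) or not (0.0 <= e < 360.0):
            raise ValidationError(
                f"arc endpoints must lie in [0, 360): got ({s}, {e})"
            )
        if s == e:
            raise ValidationError("degenerate arc: start == end")
        object.__setattr__(self, "start_deg", s)
        object.__setattr__(self, "end_deg", e)

    @property
    def length_deg(self) -> float:
        d = self.end_deg - self.start_deg
        return d if d > 0 else d + 360.0


@dataclass(frozen=True)
class FeatureObservation:
    """Presence/extension record for furrows or nodules.

    ``over_180`` means the feature extends over strictly more than half the
    iris circumference. ``quadrants`` flags Q1..Q4 occupancy.
    """

    present: bool
    over_180: bool
    quadrants: tuple[bool, bool, bool, bool]

    def __post_init__(self) -> None:
        q = tuple(bool(v) for v in self.quadrants)
        if len(q) != 4:
            raise ValidationError("quadrants must have exactly 4 flags")
        object.__setattr__(self, "quadrants", q)
        if self.over_180 and not self.present:
            raise ValidationError("over_180 requires present")
        if self.present and not any(q):
            raise ValidationError("present feature must occupy >=1 quadrant")
        if not self.present and (any(q) or self.over_180):
            raise ValidationError("absent feature cannot have quadrant flags")

    @classmethod
    def absent(cls) -> "FeatureObservation":
        return cls(False, False, (False, False, False, False))


class EyeSide(str, Enum):
    right = "right"
    left = "left"


_NESTING_RAYS = 360  # one-degree sampling of the nested-circle invariant


@dataclass(frozen=True)
class IrisAnnotation:
    """One photographed iris's raw annotation record."""

    id: str
    iris_centre: Point
    pupil_centre: Point
    pupil_circle: Circle
    collarette_circle: Circle
    sclera_circle: Circle
    crypts: tuple[CryptMark, ...] = ()
    spots: tuple[Point, ...] = ()
    furrows: FeatureObservation = field(default_factory=FeatureObservation.absent)
    nodules: FeatureObservation = field(default_factory=FeatureObservation.absent)
    melanosis: bool = False
    self_colour: int | None = None
    eye_side: EyeSide = EyeSide.right
    mirrored: bool = False
    obstructed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "crypts", tuple(self.crypts))
        object.__setattr__(self, "spots", tuple(self.spots))
        object.__setattr__(self, "eye_side", EyeSide(self.eye_side))
        if self.self_colour is not None:
            if not isinstance(self.self_colour, int) or not 1 <= self.self_colour <= 5:
                raise ValidationError(
                    f"self_colour must be 1..5 or missing, got {self.self_colour!r}"
                )
        self._check_nesting()

    def _check_nesting(self) -> None:
        # deferred import: geometry depends on these types
        from .geometry import ray_circle_distance

        c = self.iris_centre
        for circ, name in (
            (self.pupil_circle, "pupil_circle"),
            (self.collarette_circle, "collarette_circle"),
            (self.sclera_circle, "sclera_circle"),
        ):
            if not circ.contains(c):
                raise ValidationError(
                    f"iris_centre must lie strictly inside {name}"
                )
        angles = np.linspace(0.0, 360.0, _NESTING_RAYS, endpoint=False)
        for ang in angles:
            dp = ray_circle_distance(c, ang, self.pupil_circle)
            dc = ray_circle_distance(c, ang, self.collarette_circle)
            ds = ray_circle_distance(c, ang, self.sclera_circle)
            if not (dp < dc < ds):
                raise ValidationError(
                    "circles are not nested pupil < collarette < sclera "
                    f"along the ray at {ang:.1f} deg "
                    f"(distances {dp:.3f}, {dc:.3f}, {ds:.3f})"
                )


def _collapse_spot(raw: int) -> int:
    return min(raw, 3)


@dataclass(frozen=True)
class FeatureGrades:
    """The five feature grades (1-based) plus self-described colour.

    ``spot`` is the collapsed 3-grade scale (raw grades 3 and 4 merged);
    ``spot_raw`` keeps the original 4-grade scale.
    """

    crypt: int
    furrow: int
    nodule: int
    spot: int
    spot_raw: int
    melanosis: int
    colour: int | None = None

    def __post_init__(self) -> None:
        ranges = {
            "crypt": (self.crypt, 1, 4),
            "furrow": (self.furrow, 1, 3),
            "nodule": (self.nodule, 1, 3),
            "spot": (self.spot, 1, 3),
            "spot_raw": (self.spot_raw, 1, 4),
            "melanosis": (self.melanosis, 0, 1),
        }
        for name, (v, lo, hi) in ranges.items():
            if not isinstance(v, (int, np.integer)) or not lo <= v <= hi:
                raise ValidationError(f"{name} grade must be in {lo}..{hi}, got {v!r}")
        if self.spot != _collapse_spot(self.spot_raw):
            raise ValidationError(
                f"spot={self.spot} is not the collapse of spot_raw={self.spot_raw}"
            )
        if self.colour is not None and not 1 <= int(self.colour) <= 5:
            raise ValidationError(f"colour must be 1..5 or missing, got {self.colour!r}")

    def as_zero_based(self) -> dict[str, int | None]:
        """Export with the 0-based category labels used in the printed tables."""
        return {
            "crypt": self.crypt - 1,
            "furrow": self.furrow - 1,
            "nodule": self.nodule - 1,
            "spot": self.spot - 1,
            "melanosis": self.melanosis,
            "colour": None if self.colour is None else self.colour - 1,
        }


class Population(str, Enum):
    EastAsian = "EastAsian"
    European = "European"
    SouthAsian = "SouthAsian"
    Other = "Other"


class Sex(str, Enum):
    female = "female"
    male = "male"
    unknown = "unknown"


FEATURES_WITH_QUADRANTS = ("crypt", "furrow", "nodule", "spot")


@dataclass(frozen=True)
class ParticipantRecord:
    """Per-subject phenotype, covariates and genotypes — the analysis unit."""

    id: str
    population: Population
    sex: Sex
    age: float | None
    iris_width: float
    grades: FeatureGrades
    quadrant_profile: Mapping[str, tuple[bool, bool, bool, bool]]
    genotypes: Mapping[str, int | None] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "population", Population(self.population))
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.iris_width <= 0:
            raise ValidationError(f"iris_width must be > 0, got {self.iris_width}")
        qp = {}
        for feat in FEATURES_WITH_QUADRANTS:
            flags = tuple(bool(v) for v in self.quadrant_profile.get(feat, (False,) * 4))
            if len(flags) != 4:
                raise ValidationError(f"quadrant profile for {feat} must have 4 flags")
            qp[feat] = flags
        object.__setattr__(self, "quadrant_profile", qp)
        gt = {}
        for marker, val in self.genotypes.items():
            if val is not None and val not in (0, 1, 2):
                raise ValidationError(
                    f"genotype for {marker} must be 0/1/2 or missing, got {val!r}"
                )
            gt[str(marker)] = None if val is None else int(val)
        object.__setattr__(self, "genotypes", gt)
        if self.excluded and not self.exclusion_reason:
            raise ValidationError("excluded record must carry an exclusion reason")


class CohortTable:
    """An ordered collection of :class:`ParticipantRecord`."""

    def __init__(self, records: Iterable[ParticipantRecord]):
        self.records: list[ParticipantRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortTable) and self.records == other.records

    @property
    def markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            for m in r.genotypes:
                seen.setdefault(m)
        return list(seen)

    def included(self) -> "CohortTable":
        return CohortTable(r for r in self.records if not r.excluded)

    def by_population(self) -> dict[Population, list[ParticipantRecord]]:
        out: dict[Population, list[ParticipantRecord]] = {}
        for r in self.records:
            out.setdefault(r.population, []).append(r)
        return out


@dataclass(frozen=True)
class ContingencyTable:
    """Population-by-category counts."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match labels "
                f"({len(self.row_labels)}, {len(self.col_labels)})"
            )
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# JSON interchange for annotations
# ---------------------------------------------------------------------------

def _point_to_json(p: Point) -> dict:
    return {"x": p.x, "y": p.y}


def _point_from_json(obj, fieldname: str) -> Point:
    if not isinstance(obj, dict) or "x" not in obj or "y" not in obj:
        raise FormatError("expected an object with 'x' and 'y'", field=fieldname)
    return Point(obj["x"], obj["y"])


def _circle_from_json(obj, fieldname: str) -> Circle:
    if not isinstance(obj, dict) or "centre" not in obj or "radius" not in obj:
        raise FormatError("expected an object with 'centre' and 'radius'", field=fieldname)
    return Circle(_point_from_json(obj["centre"], fieldname + ".centre"), obj["radius"])


def _observation_from_json(obj, fieldname: str) -> FeatureObservation:
    if not isinstance(obj, dict):
        raise FormatError("expected an object", field=fieldname)
    for key in ("present", "over_180", "quadrants"):
        if key not in obj:
            raise FormatError(f"missing '{key}'", field=fieldname)
    quads = obj["quadrants"]
    if not isinstance(quads, (list, tuple)) or len(quads) != 4:
        raise FormatError("'quadrants' must be a 4-element array", field=fieldname)
    return FeatureObservation(bool(obj["present"]), bool(obj["over_180"]), tuple(quads))


_REQUIRED_ANNOTATION_KEYS = (
    "id",
    "iris_centre",
    "pupil_centre",
    "pupil_circle",
    "collarette_circle",
    "sclera_circle",
)


def annotation_to_dict(a: IrisAnnotation) -> dict:
    return {
        "id": a.id,
        "eye_side": a.eye_side.value,
        "mirrored": a.mirrored,
        "obstructed": a.obstructed,
        "iris_centre": _point_to_json(a.iris_centre),
        "pupil_centre": _point_to_json(a.pupil_centre),
        "pupil_circle": {"centre": _point_to_json(a.pupil_circle.centre), "radius": a.pupil_circle.radius},
        "collarette_circle": {"centre": _point_to_json(a.collarette_circle.centre), "radius": a.collarette_circle.radius},
        "sclera_circle": {"centre": _point_to_json(a.sclera_circle.centre), "radius": a.sclera_circle.radius},
        "crypts": [
            {"tip": _point_to_json(c.tip), "from_collarette": c.from_collarette}
            for c in a.crypts
        ],
        "spots": [_point_to_json(p) for p in a.spots],
        "furrows": {
            "present": a.furrows.present,
            "over_180": a.furrows.over_180,
            "quadrants": list(a.furrows.quadrants),
        },
        "nodules": {
            "present": a.nodules.present,
            "over_180": a.nodules.over_180,
            "quadrants": list(a.nodules.quadrants),
        },
        "melanosis": a.melanosis,
        "self_colour": a.self_colour,
    }


def annotation_from_dict(obj: dict) -> IrisAnnotation:
    if not isinstance(obj, dict):
        raise FormatError("annotation must be a JSON object")
    for key in _REQUIRED_ANNOTATION_KEYS:
        if key not in obj:
            raise FormatError("missing required field", field=key)
    self_colour = obj.get("self_colour")
    if self_colour is not None:
        if not isinstance(self_colour, int) or isinstance(self_colour, bool):
            raise FormatError("must be an integer or null", field="self_colour")
    crypts = []
    for i, c in enumerate(obj.get("crypts", [])):
        if not isinstance(c, dict) or "tip" not in c or "from_collarette" not in c:
            raise FormatError("expected {'tip', 'from_collarette'}", field=f"crypts[{i}]")
        crypts.append(CryptMark(_point_from_json(c["tip"], f"crypts[{i}].tip"), bool(c["from_collarette"])))
    spots = [
        _point_from_json(p, f"spots[{i}]") for i, p in enumerate(obj.get("spots", []))
    ]
    furrows = (
        _observation_from_json(obj["furrows"], "furrows")
        if "furrows" in obj
        else FeatureObservation.absent()
    )
    nodules = (
        _observation_from_json(obj["nodules"], "nodules")
        if "nodules" in obj
        else FeatureObservation.absent()
    )
    try:
        eye_side = EyeSide(obj.get("eye_side", "right"))
    except ValueError:
        raise FormatError(f"unknown eye_side {obj.get('eye_side')!r}", field="eye_side")
    return IrisAnnotation(
        id=str(obj["id"]),
        eye_side=eye_side,
        mirrored=bool(obj.get("mirrored", False)),
        obstructed=bool(obj.get("obstructed", False)),
        iris_centre=_point_from_json(obj["iris_centre"], "iris_centre"),
        pupil_centre=_point_from_json(obj["pupil_centre"], "pupil_centre"),
        pupil_circle=_circle_from_json(obj["pupil_circle"], "pupil_circle"),
        collarette_circle=_circle_from_json(obj["collarette_circle"], "collarette_circle"),
        sclera_circle=_circle_from_json(obj["sclera_circle"], "sclera_circle"),
        crypts=tuple(crypts),
        spots=tuple(spots),
        furrows=furrows,
        nodules=nodules,
        melanosis=bool(obj.get("melanosis", False)),
        self_colour=self_colour,
    )


def read_annotation(stream: str | io.TextIOBase) -> IrisAnnotation:
    """Parse a single-annotation JSON document."""
    text = stream.read() if hasattr(stream, "read") else stream
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON: {exc}") from exc
    return annotation_from_dict(obj)


def write_annotation(a: IrisAnnotation) -> str:
    return json.dumps(annotation_to_dict(a), sort_keys=True)


def read_annotations_jsonl(stream: str | io.TextIOBase) -> list[IrisAnnotation]:
    """Parse a JSON-lines batch of annotations."""
    text = stream.read() if hasattr(stream, "read") else stream
    out = []
    for i, line in enumerate(text.splitlines()):
        if not line.strip():
            continue
        try:
            out.append(read_annotation(line))
        except (FormatError, ValidationError) as exc:
            raise type(exc)(f"line {i + 1}: {exc}") from exc
    return out


def write_annotations_jsonl(annotations: Sequence[IrisAnnotation]) -> str:
    return "".join(write_annotation(a) + "\n" for a in annotations)


# ---------------------------------------------------------------------------
# CSV interchange for cohorts
# ---------------------------------------------------------------------------

COHORT_FIXED_COLUMNS = (
    "id",
    "population",
    "sex",
    "age_years",
    "iris_width_px",
    "crypt_grade",
    "furrow_grade",
    "nodule_grade",
    "spot_grade",
    "spot_raw_grade",
    "melanosis",
    "colour",
    *[f"{feat}_q{q}" for feat in FEATURES_WITH_QUADRANTS for q in range(1, 5)],
    "excluded",
    "exclusion_reason",
)

_GRADE_COLUMNS = {
    "crypt_grade": (1, 4),
    "furrow_grade": (1, 3),
    "nodule_grade": (1, 3),
    "spot_grade": (1, 3),
    "spot_raw_grade": (1, 4),
    "melanosis": (0, 1),
}


def _parse_int(value: str, lo: int, hi: int, column: str, row: int) -> int:
    try:
        v = int(value)
    except ValueError:
        raise FormatError(f"non-integer value {value!r}", field=column, row=row)
    if not lo <= v <= hi:
        raise FormatError(f"value {v} out of range {lo}..{hi}", field=column, row=row)
    return v


def _parse_bool(value: str, column: str, row: int) -> bool:
    v = value.strip().lower()
    if v in ("1", "true"):
        return True
    if v in ("0", "false", ""):
        return False
    raise FormatError(f"expected a boolean, got {value!r}", field=column, row=row)


def read_cohort(stream: str | io.TextIOBase) -> CohortTable:
    """Read the cohort CSV.

    Columns beyond the fixed header are treated as genotype markers with
    values 0/1/2 (derived-allele copies) or empty for missing. Unknown
    population labels map to ``Other`` with a warning.
    """
    text = stream.read() if hasattr(stream, "read") else stream
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise FormatError("empty CSV: no header row")
    missing = [c for c in COHORT_FIXED_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    marker_cols = [c for c in reader.fieldnames if c not in COHORT_FIXED_COLUMNS]
    records = []
    for idx, row in enumerate(reader, start=1):
        pop_raw = row["population"].strip()
        try:
            population = Population(pop_raw)
        except ValueError:
            warnings.warn(
                f"row {idx}: unknown population {pop_raw!r} mapped to Other",
                stacklevel=2,
            )
            population = Population.Other
        try:
            sex = Sex(row["sex"].strip() or "unknown")
        except ValueError:
            raise FormatError(f"unknown sex {row['sex']!r}", field="sex", row=idx)
        age = float(row["age_years"]) if row["age_years"].strip() else None
        try:
            iris_width = float(row["iris_width_px"])
        except ValueError:
            raise FormatError(
                f"non-numeric iris width {row['iris_width_px']!r}",
                field="iris_width_px",
                row=idx,
            )
        grade_vals = {
            col: _parse_int(row[col], lo, hi, col, idx)
            for col, (lo, hi) in _GRADE_COLUMNS.items()
        }
        colour = (
            _parse_int(row["colour"], 1, 5, "colour", idx)
            if row["colour"].strip()
            else None
        )
        try:
            grades = FeatureGrades(
                crypt=grade_vals["crypt_grade"],
                furrow=grade_vals["furrow_grade"],
                nodule=grade_vals["nodule_grade"],
                spot=grade_vals["spot_grade"],
                spot_raw=grade_vals["spot_raw_grade"],
                melanosis=grade_vals["melanosis"],
                colour=colour,
            )
        except ValidationError as exc:
            raise FormatError(str(exc), row=idx) from exc
        profile = {
            feat: tuple(
                _parse_bool(row[f"{feat}_q{q}"], f"{feat}_q{q}", idx)
                for q in range(1, 5)
            )
            for feat in FEATURES_WITH_QUADRANTS
        }
        genotypes: dict[str, int | None] = {}
        for m in marker_cols:
            raw = row[m].strip()
            if raw == "":
                genotypes[m] = None
            else:
                genotypes[m] = _parse_int(raw, 0, 2, m, idx)
        excluded = _parse_bool(row["excluded"], "excluded", idx)
        reason = row["exclusion_reason"].strip() or None
        try:
            records.append(
                ParticipantRecord(
                    id=row["id"],
                    population=population,
                    sex=sex,
                    age=age,
                    iris_width=iris_width,
                    grades=grades,
                    quadrant_profile=profile,
                    genotypes=genotypes,
                    excluded=excluded,
                    exclusion_reason=reason,
                )
            )
        except ValidationError as exc:
            raise FormatError(str(exc), row=idx) from exc
    return CohortTable(records)


def write_cohort(cohort: CohortTable) -> str:
    markers = cohort.markers
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(list(COHORT_FIXED_COLUMNS) + markers)
    for r in cohort:
        row = [
            r.id,
            r.population.value,
            r.sex.value,
            "" if r.age is None else repr(float(r.age)),
            repr(float(r.iris_width)),
            r.grades.crypt,
            r.grades.furrow,
            r.grades.nodule,
            r.grades.spot,
            r.grades.spot_raw,
            r.grades.melanosis,
            "" if r.grades.colour is None else r.grades.colour,
        ]
        for feat in FEATURES_WITH_QUADRANTS:
            row.extend(int(v) for v in r.quadrant_profile[feat])
        row.append(int(r.excluded))
        row.append(r.exclusion_reason or "")
        for m in markers:
            v = r.genotypes.get(m)
            row.append("" if v is None else v)
        writer.writerow(row)
    return buf.getvalue()
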