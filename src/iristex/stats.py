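"""Descriptive and inferential statistics for graded cohorts.

All statistics here are computed from first principles (concordant pair
counts, Pearson residual sums, pooled variances, ...); only the reference
distributions (normal, t, F, chi-square) come from :mod:`scipy.stats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as spstats

from ._util import round_half_up
from .annotation import CohortTable, ContingencyTable, ParticipantRecord, Population
from .errors import IristexError, UndefinedStatisticError, ValidationError

__all__ = [
    "GammaResult",
    "TestResult",
    "gk_gamma",
    "weighted_kappa",
    "chi2_homogeneity",
    "grouped_grade_ttest",
    "bonferroni_alpha",
    "anova_oneway",
    "tabulate",
    "quadrant_prevalence",
    "FEATURE_CATEGORIES",
]


@dataclass(frozen=True)
class GammaResult:
    """Goodman-Kruskal gamma with its independence z-test."""

    C: int
    D: int
    G: float
    se: float
    z: float
    p: float
    n: int


@dataclass(frozen=True)
class TestResult:
    """Generic test output (chi-square, t, F or kappa)."""

    statistic: float
    df: float | tuple[float, float] | None
    p: float | None
    method: str

    def __post_init__(self) -> None:
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p-value out of [0,1]: {self.p}")


def _crosstab(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    table = np.zeros((len(xv), len(yv)), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)
    return table


def concordant_discordant(table: np.ndarray) -> tuple[int, int]:
    """Concordant and discordant pair counts from an ordered cross-tab."""
    r, c = table.shape
    C = D = 0
    # cum[i, j] = count with row < i and col < j
    cum = np.zeros((r + 1, c + 1), dtype=np.int64)
    cum[1:, 1:] = table.cumsum(axis=0).cumsum(axis=1)
    total = cum[r, c]
    for i in range(r):
        for j in range(c):
            nij = table[i, j]
            if nij == 0:
                continue
            lower_left = cum[i, j]
            upper_right = total - cum[i + 1, c] - cum[r, j + 1] + cum[i + 1, j + 1]
            lower_right = cum[i, c] - cum[i, j + 1]
            upper_left = cum[r, j] - cum[i + 1, j]
            C += nij * (lower_left + upper_right)
            D += nij * (lower_right + upper_left)
    return int(C // 2), int(D // 2)


def _null_variance_S(table: np.ndarray) -> float:
    """Null (independence) variance of S = C - D with tie correction.

    The classical tie-corrected formula for Kendall-type statistics; S is
    shared by gamma and tau, so the same variance calibrates gamma's
    independence test. (The often-quoted shortcut
    z = G*sqrt((C+D)/(n(1-G^2))) is badly conservative under heavy ties and
    fails nominal-level calibration; see the decisions ledger.)
    """
    n = float(table.sum())
    ti = table.sum(axis=1).astype(float)
    uj = table.sum(axis=0).astype(float)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float((ti * (ti - 1) * (2 * ti + 5)).sum())
    vu = float((uj * (uj - 1) * (2 * uj + 5)).sum())
    v1 = float((ti * (ti - 1)).sum() * (uj * (uj - 1)).sum()) / (2 * n * (n - 1))
    v2 = 0.0
    if n > 2:
        v2 = float(
            (ti * (ti - 1) * (ti - 2)).sum() * (uj * (uj - 1) * (uj - 2)).sum()
        ) / (9 * n * (n - 1) * (n - 2))
    return (v0 - vt - vu) / 18.0 + v1 + v2


def gk_gamma(x: Sequence[float], y: Sequence[float]) -> GammaResult:
    """Goodman-Kruskal gamma between two equally long ordinal vectors.

    Ties contribute to neither the concordant nor the discordant count. The
    two-sided p-value tests independence using the exact tie-corrected null
    variance of S = C - D (the same test commercial packages report for
    Kendall-type statistics), giving nominal type-I calibration.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 2:
        raise ValidationError("need at least 2 observations")
    table = _crosstab(x, y)
    C, D = concordant_discordant(table)
    if C + D == 0:
        raise UndefinedStatisticError("gamma undefined: all pairs are tied")
    G = (C - D) / (C + D)
    var_s = _null_variance_S(table)
    if var_s <= 0:
        se, z, p = 0.0, math.copysign(math.inf, G) if G else 0.0, 0.0 if G else 1.0
    else:
        z = (C - D) / math.sqrt(var_s)
        se = math.sqrt(var_s) / (C + D)  # scale such that z == G / se
        p = 2.0 * float(spstats.norm.sf(abs(z)))
    return GammaResult(C=C, D=D, G=G, se=se, z=z, p=p, n=n)


def weighted_kappa(
    r1: Sequence[int], r2: Sequence[int], k: int
) -> TestResult:
    """Linear weighted kappa between two raters on a 1..k ordinal scale.

    Uses agreement weights ``w_ij = 1 - |i - j| / (k - 1)``; chance-expected
    agreement comes from the marginal products. With k = 2 this reduces to
    unweighted Cohen's kappa.
    """
    if k < 2:
        raise ValidationError("need at least 2 categories")
    r1 = np.asarray(r1, dtype=int)
    r2 = np.asarray(r2, dtype=int)
    if r1.shape != r2.shape or r1.ndim != 1 or len(r1) == 0:
        raise ValidationError("ratings must be equal-length non-empty vectors")
    if r1.min() < 1 or r1.max() > k or r2.min() < 1 or r2.max() > k:
        raise ValidationError(f"ratings must lie in 1..{k}")
    n = len(r1)
    obs = np.zeros((k, k), dtype=float)
    np.add.at(obs, (r1 - 1, r2 - 1), 1.0)
    obs /= n
    marg1 = obs.sum(axis=1)
    marg2 = obs.sum(axis=0)
    exp = np.outer(marg1, marg2)
    idx = np.arange(k)
    w = 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    po = float((w * obs).sum())
    pe = float((w * exp).sum())
    if pe >= 1.0:
        raise UndefinedStatisticError(
            "kappa undefined: chance-expected weighted agreement is 1"
        )
    kappa = (po - pe) / (1.0 - pe)
    return TestResult(statistic=kappa, df=None, p=None, method="linear weighted kappa")


def chi2_homogeneity(t: ContingencyTable) -> TestResult:
    """Pearson chi-square test of homogeneity across the table's rows."""
    counts = t.counts.astype(float)
    if np.any(t.row_totals == 0) or np.any(t.col_totals == 0):
        raise ValidationError("all row and column totals must be positive")
    expected = np.outer(t.row_totals, t.col_totals) / t.total
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(spstats.chi2.sf(chi2, df))
    return TestResult(statistic=chi2, df=df, p=p, method="pearson chi2 homogeneity")


def _grouped_moments(counts: np.ndarray, scores: np.ndarray) -> tuple[int, float, float]:
    n = int(counts.sum())
    mean = float((scores * counts).sum() / n)
    ss = float(((scores - mean) ** 2 * counts).sum())
    return n, mean, ss / (n - 1)


def grouped_grade_ttest(
    countsA: Sequence[int],
    countsB: Sequence[int],
    variant: str = "pooled",
) -> TestResult:
    """Independent two-sample t-test on grouped ordinal counts.

    Categories are given equally spaced scores; the result is identical to
    expanding the counts into per-individual score vectors, and invariant to
    affine recoding of the scale. The statistic is signed B minus A.
    """
    countsA = np.asarray(countsA, dtype=np.int64)
    countsB = np.asarray(countsB, dtype=np.int64)
    if countsA.shape != countsB.shape or countsA.ndim != 1 or len(countsA) < 2:
        raise ValidationError("count vectors must be equal length >= 2")
    if countsA.sum() < 2 or countsB.sum() < 2:
        raise ValidationError("each group needs at least 2 individuals")
    scores = np.arange(len(countsA), dtype=float)
    na, ma, va = _grouped_moments(countsA, scores)
    nb, mb, vb = _grouped_moments(countsB, scores)
    if va == 0.0 and vb == 0.0:
        raise UndefinedStatisticError("t undefined: zero variance in both groups")
    if variant == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df: float = na + nb - 2
    elif variant == "welch":
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    else:
        raise ValidationError(f"unknown variant {variant!r}; use 'pooled' or 'welch'")
    tstat = (mb - ma) / se
    p = 2.0 * float(spstats.t.sf(abs(tstat), df))
    return TestResult(statistic=tstat, df=df, p=p, method=f"grouped t ({variant})")


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison threshold alpha/m, reported to 4 decimals (half-up)."""
    if m < 1:
        raise ValidationError("number of comparisons must be >= 1")
    return round_half_up(alpha / m, 4)


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA from per-group value vectors."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValidationError("each group needs at least 2 values")
    allv = np.concatenate(arrays)
    if np.all(allv == allv[0]):
        raise UndefinedStatisticError("F undefined: all values identical")
    grand = allv.mean()
    k = len(arrays)
    N = len(allv)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df = (k - 1, N - k)
    if ssw == 0.0:
        return TestResult(statistic=math.inf, df=df, p=0.0, method="one-way anova")
    F = (ssb / df[0]) / (ssw / df[1])
    p = float(spstats.f.sf(F, *df))
    return TestResult(statistic=float(F), df=df, p=p, method="one-way anova")


# category count per tabulated feature (1-based grades except melanosis 0/1)
FEATURE_CATEGORIES: dict[str, list[int]] = {
    "crypt": [1, 2, 3, 4],
    "furrow": [1, 2, 3],
    "nodule": [1, 2, 3],
    "spot": [1, 2, 3],
    "spot_raw": [1, 2, 3, 4],
    "melanosis": [0, 1],
    "colour": [1, 2, 3, 4, 5],
}

_POP_ORDER = [Population.EastAsian, Population.European, Population.SouthAsian, Population.Other]


def _records(cohort: CohortTable | Iterable[ParticipantRecord]) -> list[ParticipantRecord]:
    return list(cohort)


def tabulate(cohort: CohortTable | Iterable[ParticipantRecord], feature: str) -> ContingencyTable:
    """Population-by-category counts for one feature over included records."""
    if feature not in FEATURE_CATEGORIES:
        raise IristexError(
            f"unknown feature {feature!r}; expected one of {sorted(FEATURE_CATEGORIES)}"
        )
    records = [r for r in _records(cohort) if not r.excluded]
    if not records:
        raise IristexError("empty cohort: nothing to tabulate")
    cats = FEATURE_CATEGORIES[feature]
    pops = [p for p in _POP_ORDER if any(r.population is p for r in records)]
    counts = np.zeros((len(pops), len(cats)), dtype=np.int64)
    pop_index = {p: i for i, p in enumerate(pops)}
    cat_index = {c: j for j, c in enumerate(cats)}
    for r in records:
        value = getattr(r.grades, feature)
        if value is None:
            continue
        counts[pop_index[r.population], cat_index[value]] += 1
    return ContingencyTable(
        row_labels=tuple(p.value for p in pops),
        col_labels=tuple(str(c) for c in cats),
        counts=counts,
    )


def quadrant_prevalence(
    cohort: CohortTable | Iterable[ParticipantRecord], feature: str
) -> dict[str, dict[int, float]]:
    """Per-population share (%) of irises with `feature` in each quadrant.

    Percentages are rounded half-up to one decimal, matching the printed
    tables. Crypt flags refer to large crypts only.
    """
    records = [r for r in _records(cohort) if not r.excluded]
    if not records:
        raise IristexError("empty cohort")
    if feature not in ("crypt", "furrow", "nodule", "spot"):
        raise IristexError(f"feature {feature!r} has no quadrant profile")
    out: dict[str, dict[int, float]] = {}
    for pop in _POP_ORDER:
        group = [r for r in records if r.population is pop]
        if not group:
            continue
        n = len(group)
        out[pop.value] = {
            q: round_half_up(
                100.0 * sum(r.quadrant_profile[feature][q - 1] for r in group) / n, 1
            )
            for q in (1, 2, 3, 4)
        }
    return out
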