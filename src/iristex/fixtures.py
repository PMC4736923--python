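"""Packaged reference tables transcribed from the published study.

Every value carries a provenance string (table or section plus row label)
so reports can surface where each number came from. Category labels follow
the published tables' 0-based convention; :func:`counts_matrix` returns the
counts in that category order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import ContingencyTable

__all__ = [
    "POPULATIONS",
    "TABLE1",
    "TABLE2_ODDS_RATIOS",
    "TABLE3_COUNTS",
    "TABLE4_QUADRANT_COUNTS",
    "ALLELE_FREQUENCIES",
    "PRINTED_STATISTICS",
    "fixtures",
    "counts_matrix",
    "contingency_table",
]

POPULATIONS = ("EastAsian", "European", "SouthAsian")


@dataclass(frozen=True)
class Sourced:
    """A fixture value with its provenance string."""

    value: object
    source: str


# --- Table 1: cohort descriptives -----------------------------------------

TABLE1 = {
    "EastAsian": {
        "irises_included": 467,
        "females": 320,
        "males": 147,
        "mean_age": 21.61,
        "mean_iris_width": 376.72,
    },
    "European": {
        "irises_included": 619,
        "females": 376,
        "males": 243,
        "mean_age": 22.65,
        "mean_iris_width": 394.45,
    },
    "SouthAsian": {
        "irises_included": 364,
        "females": 246,
        "males": 118,
        "mean_age": 20.67,
        "mean_iris_width": 384.92,
    },
    "source": "Table 1 (descriptive statistics per population)",
}

# recruitment totals before exclusions, and the exclusion tallies
RECRUITED = {
    "EastAsian": 475,
    "European": 623,
    "SouthAsian": 367,
    "source": "Results: irises evaluated per population",
}
EXCLUSIONS = {
    "obscured": {"EastAsian": 8, "European": 4, "SouthAsian": 2},
    "disorder": {"EastAsian": 0, "European": 0, "SouthAsian": 1},
    "source": "Results: 14 obscured/blurry irises; one albinism case",
}

# --- Table 3: category counts per trait and population --------------------
# Categories use the published 0-based labels; counts are the parenthesized
# numbers, which sum to each population's included n.

TABLE3_COUNTS: dict[str, dict[str, tuple[int, ...]]] = {
    "crypt": {
        "EastAsian": (95, 233, 92, 47),
        "European": (57, 235, 191, 136),
        "SouthAsian": (55, 151, 91, 67),
        "source": "Table 3, Fuchs' crypts rows (categories 0-3)",
    },
    "furrow": {
        "EastAsian": (71, 176, 220),
        "European": (41, 69, 509),
        "SouthAsian": (14, 56, 294),
        "source": "Table 3, contraction furrows rows (categories 0-2)",
    },
    "spot": {
        "EastAsian": (364, 96, 7),
        "European": (260, 238, 121),
        "SouthAsian": (303, 54, 7),
        "source": "Table 3, pigment spots rows (categories 0-2)",
    },
    "nodule": {
        "EastAsian": (467, 0, 0),
        "European": (388, 74, 157),
        "SouthAsian": (359, 2, 3),
        "source": "Table 3, Wolfflin nodules rows (categories 0-2)",
    },
    "melanosis": {
        "EastAsian": (358, 109),
        "European": (606, 13),
        "SouthAsian": (200, 164),
        "source": "Table 3, melanosis rows (absent/present)",
    },
    "colour": {
        "EastAsian": (0, 0, 21, 212, 234),
        "European": (73, 279, 143, 118, 6),
        "SouthAsian": (0, 6, 30, 189, 139),
        "source": "Table 3, eye colour rows (categories 0-4)",
    },
}

# --- Table 4: per-quadrant prevalence counts ------------------------------

TABLE4_QUADRANT_COUNTS: dict[str, dict[str, tuple[int, ...]]] = {
    "large_crypts": {
        "EastAsian": (51, 74, 67, 86),
        "European": (195, 220, 160, 181),
        "SouthAsian": (86, 109, 82, 81),
        "source": "Table 4, large crypts rows (Q1..Q4)",
    },
    "furrows": {
        "EastAsian": (125, 329, 385, 285),
        "European": (508, 525, 552, 522),
        "SouthAsian": (257, 332, 346, 306),
        "source": "Table 4, furrows rows (Q1..Q4)",
    },
    "pigment_spots": {
        "EastAsian": (13, 24, 48, 38),
        "European": (107, 115, 196, 193),
        "SouthAsian": (10, 18, 23, 24),
        "source": "Table 4, pigment spots rows (Q1..Q4)",
    },
    "nodules": {
        "EastAsian": (0, 0, 0, 0),
        "European": (147, 177, 216, 193),
        "SouthAsian": (3, 4, 5, 5),
        "source": "Table 4, nodules rows (Q1..Q4)",
    },
}

# --- Table 2: genetic ordinal regression ----------------------------------
# rows: (marker, trait, population, genotype, p, odds ratio); None means the
# class was dropped (fewer than five individuals).

TABLE2_ODDS_RATIOS: list[dict] = [
    {"marker": "rs10235789", "trait": "crypt", "population": "EastAsian", "genotype": "CC", "p": None, "odds_ratio": None},
    {"marker": "rs10235789", "trait": "crypt", "population": "EastAsian", "genotype": "CT", "p": 0.018, "odds_ratio": 1.679},
    {"marker": "rs10235789", "trait": "crypt", "population": "European", "genotype": "CC", "p": 0.001, "odds_ratio": 2.203},
    {"marker": "rs10235789", "trait": "crypt", "population": "European", "genotype": "CT", "p": 0.023, "odds_ratio": 1.507},
    {"marker": "rs10235789", "trait": "crypt", "population": "SouthAsian", "genotype": "CC", "p": 0.011, "odds_ratio": 2.721},
    {"marker": "rs10235789", "trait": "crypt", "population": "SouthAsian", "genotype": "CT", "p": 0.001, "odds_ratio": 2.206},
    {"marker": "rs3739070", "trait": "furrow", "population": "EastAsian", "genotype": "AA", "p": None, "odds_ratio": None},
    {"marker": "rs3739070", "trait": "furrow", "population": "EastAsian", "genotype": "CA", "p": 0.956, "odds_ratio": 0.980},
    {"marker": "rs3739070", "trait": "furrow", "population": "European", "genotype": "AA", "p": 0.051, "odds_ratio": 6.385},
    {"marker": "rs3739070", "trait": "furrow", "population": "European", "genotype": "CA", "p": 0.333, "odds_ratio": 2.601},
    {"marker": "rs3739070", "trait": "furrow", "population": "SouthAsian", "genotype": "CA", "p": 0.168, "odds_ratio": 0.360},
    {"marker": "rs11630290", "trait": "spot", "population": "EastAsian", "genotype": "CT", "p": 0.173, "odds_ratio": 0.241},
    {"marker": "rs11630290", "trait": "spot", "population": "European", "genotype": "TT", "p": 0.187, "odds_ratio": 1.685},
    {"marker": "rs11630290", "trait": "spot", "population": "European", "genotype": "CT", "p": 0.998, "odds_ratio": 1.000},
    {"marker": "rs11630290", "trait": "spot", "population": "SouthAsian", "genotype": "CT", "p": 0.136, "odds_ratio": 0.536},
    {"marker": "rs7277820", "trait": "nodule", "population": "European", "genotype": "AA", "p": 0.375, "odds_ratio": 0.758},
    {"marker": "rs7277820", "trait": "nodule", "population": "European", "genotype": "GA", "p": 0.345, "odds_ratio": 0.794},
]
TABLE2_SOURCE = "Table 2 (genetic ordinal regression odds ratios)"

# --- Discussion 4.1: derived-allele frequencies for rs10235789 ------------

ALLELE_FREQUENCIES = {
    "rs10235789": {
        "European": 0.48,
        "EastAsian": 0.08,
        "SouthAsian": 0.28,
        "source": "Discussion 4.1 (derived C allele frequencies)",
    }
}

# --- Printed inferential statistics (reproduction targets) ----------------

PRINTED_STATISTICS = {
    "chi2": {
        "crypt": 67.388,
        "furrow": 186.819,
        "spot": 260.587,
        "nodule": 350.627,
        "melanosis": 273.177,
        "colour": 892.674,
        "source": "Results: between-population chi-square statistics",
    },
    "t_crypt_EA_vs_EU": Sourced(8.333, "Results: pairwise t, crypts, European vs East Asian"),
    "anova_iris_width_F": Sourced(200.161, "Results: one-way ANOVA on iris width"),
    "pct_crypt_ciliary_EastAsian": Sourced(29.8, "Discussion 4.1: East Asians with crypts into the ciliary zone"),
    "pct_crypt_ciliary_European": Sourced(52.9, "Discussion 4.1: Europeans with crypts into the ciliary zone"),
    "pct_crypt_ciliary_SouthAsian": Sourced(43.4, "Discussion 4.1: South Asians with crypts into the ciliary zone"),
    "pct_melanosis_EastAsian": Sourced(23.3, "Discussion 4.5: East Asians with conjunctival melanosis"),
}


def counts_matrix(trait: str) -> np.ndarray:
    """Table 3 counts for `trait` as a (3, n_categories) array, rows in
    (EastAsian, European, SouthAsian) order."""
    rows = TABLE3_COUNTS[trait]
    return np.array([rows[p] for p in POPULATIONS], dtype=np.int64)


def contingency_table(trait: str) -> ContingencyTable:
    """Table 3 counts for `trait` as a :class:`ContingencyTable`."""
    if trait not in TABLE3_COUNTS:
        raise KeyError(f"unknown trait {trait!r}")
    m = counts_matrix(trait)
    return ContingencyTable(
        row_labels=POPULATIONS,
        col_labels=tuple(str(j) for j in range(m.shape[1])),
        counts=m,
    )


def fixtures() -> dict:
    """Bundle of every packaged table, each tagged with its source."""
    return {
        "table1": TABLE1,
        "recruited": RECRUITED,
        "exclusions": EXCLUSIONS,
        "table2_odds_ratios": {"rows": TABLE2_ODDS_RATIOS, "source": TABLE2_SOURCE},
        "table3_counts": TABLE3_COUNTS,
        "table4_quadrant_counts": TABLE4_QUADRANT_COUNTS,
        "allele_frequencies": ALLELE_FREQUENCIES,
        "printed_statistics": PRINTED_STATISTICS,
    }
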