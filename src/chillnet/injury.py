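"""Ordinal chilling-injury grading and the cohort CI index.

Seedlings exposed to low-temperature stress develop necrotic lesions on
the cotyledons. Damage is scored on two ordinal scales: a per-cotyledon
grade 0-6 driven by the necrotic-area fraction X of a single cotyledon,
and a per-seedling grade 0-7 driven by the whole-seedling necrotic-area
fraction Y. A variety's chilling-injury (CI) index is the grade-weighted
cohort mean

    CI = 100 * sum_i(i * S_i) / (8 * N),

where S_i counts seedlings at grade i and N is the cohort size. Lower CI
means more cold-tolerant. Because the maximum grade is 7 over a
denominator of 8, CI lies in [0, 87.5] on the percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

__all__ = [
    "GradeCounts",
    "CIResult",
    "grade_cotyledon",
    "grade_seedling",
    "ci_index",
    "survival_rate",
]

N_SEEDLING_GRADES = 8  # grades 0..7


def grade_cotyledon(x: float, yellowish: bool = False, healthy: bool = False) -> int:
    """Grade a single cotyledon from its necrotic-area fraction.

    Bins: 0 healthy; 1 yellowish (no necrosis); 2 if 0 < X < 1/8;
    3 if 1/8 <= X < 1/4; 4 if 1/4 <= X < 1/2; 5 if 1/2 <= X < 3/4;
    6 if X >= 3/4. ``yellowish`` is an explicit flag because grade 1 is a
    colour symptom, not an area bin; area-only callers with 0 < X < 1/8
    get grade 2.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"necrotic-area fraction X must be in [0, 1], got {x}")
    if healthy and x == 0.0:
        return 0
    if yellowish and x == 0.0:
        return 1
    if x == 0.0:
        return 0
    if x < Fraction(1, 8):
        return 2
    if x < Fraction(1, 4):
        return 3
    if x < Fraction(1, 2):
        return 4
    if x < Fraction(3, 4):
        return 5
    return 6


def grade_seedling(y: float) -> int:
    """Grade a whole seedling from its necrotic-area fraction Y.

    Bins: 0 if Y = 0; 1 if 0 < Y < 1/16; 2 if 1/16 <= Y <= 1/8;
    3 if 1/8 < Y <= 1/4; 4 if 1/4 < Y <= 3/8; 5 if 3/8 < Y <= 1/2;
    6 if 1/2 < Y <= 3/4; 7 if Y > 3/4. The boundary Y = 1/16 is assigned
    to grade 2 (each interval left-closed where the published scheme is
    silent).
    """
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"necrotic-area fraction Y must be in [0, 1], got {y}")
    if y == 0.0:
        return 0
    if y < Fraction(1, 16):
        return 1
    if y <= Fraction(1, 8):
        return 2
    if y <= Fraction(1, 4):
        return 3
    if y <= Fraction(3, 8):
        return 4
    if y <= Fraction(1, 2):
        return 5
    if y <= Fraction(3, 4):
        return 6
    return 7


@dataclass(frozen=True)
class GradeCounts:
    """Per-variety counts of seedlings at grades 0-7."""

    variety: str
    counts: tuple[int, ...]  # S0..S7

    def __post_init__(self):
        if len(self.counts) != N_SEEDLING_GRADES:
            raise ValueError(f"expected 8 grade counts S0..S7, got {len(self.counts)}")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise ValueError(f"grade counts must be nonnegative integers: {self.counts}")
        if self.n == 0:
            raise ValueError("empty cohort: total seedling count is zero")

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @classmethod
    def from_grades(cls, variety: str, grades: Sequence[int]) -> "GradeCounts":
        counts = [0] * N_SEEDLING_GRADES
        for g in grades:
            counts[int(g)] += 1
        return cls(variety, tuple(counts))


@dataclass(frozen=True)
class CIResult:
    variety: str
    ci: float  # percent scale, in [0, 87.5]


def ci_index(counts: GradeCounts) -> CIResult:
    """Chilling-injury index of a cohort, exact before the final float.

    CI = 100 * sum(i * S_i) / (8 * N). Computed in rational arithmetic so
    the result is bit-stable regardless of count order.
    """
    weighted = sum(i * s for i, s in enumerate(counts.counts))
    ci = Fraction(100 * weighted, 8 * counts.n)
    return CIResult(counts.variety, float(ci))


def ci_table(cohorts: Sequence[GradeCounts]) -> pd.DataFrame:
    """CI index for several varieties as a tidy table."""
    rows = [
        {"variety": c.variety, "N": c.n, "ci": ci_index(c).ci}
        for c in cohorts
    ]
    return pd.DataFrame(rows)


def survival_rate(survivors: int, total: int) -> float:
    """Percent of seedlings surviving the stress episode."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= survivors <= total:
        raise ValueError(f"survivors {survivors} outside [0, {total}]")
    return 100.0 * survivors / total


def read_grade_counts(path) -> list[GradeCounts]:
    """Read a grade-count TSV (columns: variety, S0..S7)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [f"S{i}" for i in range(N_SEEDLING_GRADES)]
    missing = [c for c in ["variety", *cols] if c not in df.columns]
    if missing:
        raise ValueError(f"grade-count table missing columns: {missing}")
    return [
        GradeCounts(str(row["variety"]), tuple(int(row[c]) for c in cols))
        for _, row in df.iterrows()
    ]


def write_grade_counts(cohorts: Sequence[GradeCounts], path) -> None:
    cols = [f"S{i}" for i in range(N_SEEDLING_GRADES)]
    df = pd.DataFrame(
        [{"variety": c.variety, **dict(zip(cols, c.counts))} for c in cohorts]
    )
    df.to_csv(path, sep="\t", index=False)
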