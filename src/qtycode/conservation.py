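"""Entropy-based per-column conservation grading from an MSA.

This is an explicit stand-in for phylogeny-aware Bayesian conservation
servers: the per-column statistic is the Shannon entropy of residue
frequencies normalized by log(20), and grades 1-9 (9 = most conserved) are
assigned by equal-frequency binning of the entropies, mirroring the common
1-to-9 conservation-grade convention (1 = variable, 5 = average,
9 = conserved).  It captures column variability only, not evolutionary
rates, and conservation grades attached to curated variant tables should
come from their original source rather than be recomputed here.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from Bio import AlignIO

from .sequences import STANDARD_AAS

PathLike = Union[str, Path]

GAP_CHARS = frozenset("-.")
_ALPHABET = frozenset(STANDARD_AAS)


@dataclass
class Alignment:
    """>= 2 equal-length gapped sequences; columns 1-based."""

    rows: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        self.rows = [r.upper() for r in self.rows]
        length = len(self.rows[0])
        if any(len(r) != length for r in self.rows):
            raise ValueError("alignment rows differ in length")
        for r in self.rows:
            bad = set(r) - _ALPHABET - GAP_CHARS
            if bad:
                raise ValueError(f"illegal alignment character(s) {sorted(bad)}")
        if not self.ids:
            self.ids = [f"seq{i+1}" for i in range(len(self.rows))]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, column: int) -> str:
        if not 1 <= column <= self.length:
            raise IndexError(f"column {column} outside 1..{self.length}")
        return "".join(r[column - 1] for r in self.rows)


def read_alignment(path: PathLike) -> Alignment:
    """Read an aligned FASTA file."""
    msa = AlignIO.read(str(path), "fasta")
    return Alignment(rows=[str(rec.seq) for rec in msa], ids=[rec.id for rec in msa])


def column_entropy(alignment: Alignment, column: int, *, gap_policy: str = "exclude") -> float:
    """Normalized Shannon entropy of one column (0 = invariant, 1 = uniform).

    Gaps are excluded from the frequencies by default (``gap_policy
    "exclude"``) or counted as a 21st symbol (``"count"``).  An effectively
    all-gap column is undefined and returns NaN.
    """
    col = alignment.column(column)
    if gap_policy == "exclude":
        symbols = [c for c in col if c not in GAP_CHARS]
    elif gap_policy == "count":
        symbols = list(col)
    else:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    if not symbols:
        warnings.warn(f"column {column} is all-gap; entropy undefined")
        return float("nan")
    counts = Counter(symbols)
    n = len(symbols)
    h = -sum((c / n) * math.log(c / n) for c in counts.values())
    return h / math.log(20.0)


@dataclass
class ConservationProfile:
    scores: np.ndarray     # per-column normalized entropy
    grades: np.ndarray     # per-column grade 1-9, 9 most conserved
    low_confidence: np.ndarray  # columns with > 50% gaps


def grades_from_scores(scores: list[float] | np.ndarray) -> np.ndarray:
    """Map entropy scores to conservation grades 1-9 (9 = lowest entropy).

    Equal-frequency binning over the 9 grades; ties between equal scores
    are broken by column index (stable), so lower entropy never earns a
    lower grade than higher entropy.  All-equal scores map to grade 5
    ("average"); fewer than 9 columns fall back to a linear min-max mapping
    with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n == 0:
        return np.zeros(0, dtype=int)
    finite = np.isfinite(scores)
    if not np.any(finite) or np.ptp(scores[finite]) == 0:
        return np.full(n, 5, dtype=int)
    if n < 9:
        warnings.warn("fewer than 9 columns; using linear score-to-grade mapping")
        lo, hi = scores[finite].min(), scores[finite].max()
        grades = np.full(n, 5, dtype=int)
        grades[finite] = np.round(9 - 8 * (scores[finite] - lo) / (hi - lo)).astype(int)
        return grades
    order = np.lexsort((np.arange(n), scores))  # ascending entropy, stable
    grades = np.empty(n, dtype=int)
    for rank, col in enumerate(order):
        grades[col] = 9 - (rank * 9) // n
    # columns with identical scores share their group's best grade, so e.g.
    # every invariant (entropy-0) column lands in grade 9 however many tie
    for value in np.unique(scores[np.isfinite(scores)]):
        tie = np.isfinite(scores) & (scores == value)
        grades[tie] = grades[tie].max()
    return grades


def profile_alignment(alignment: Alignment, *, gap_policy: str = "exclude") -> ConservationProfile:
    """Per-column entropy, grade and gap-confidence flag for a whole MSA."""
    scores = np.array(
        [column_entropy(alignment, c, gap_policy=gap_policy) for c in range(1, alignment.length + 1)]
    )
    gap_fracs = np.array(
        [
            sum(ch in GAP_CHARS for ch in alignment.column(c)) / len(alignment.rows)
            for c in range(1, alignment.length + 1)
        ]
    )
    return ConservationProfile(
        scores=scores,
        grades=grades_from_scores(scores),
        low_confidence=gap_fracs > 0.5,
    )


def conserved_fraction(profile: ConservationProfile, threshold: int = 5) -> tuple[int, float]:
    """Count and fraction of columns graded strictly above the threshold.

    The default threshold 5 is the "average" grade, so the fraction counts
    columns that are more than averagely conserved.
    """
    count = int(np.sum(profile.grades > threshold))
    total = len(profile.grades)
    return count, (count / total if total else 0.0)
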