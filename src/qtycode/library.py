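"""Saturation mutation libraries with a pluggable effect scorer.

A site library enumerates all 19 amino-acid alternatives at one position.
Libraries are built either for a single site or for every L/I/V/F residue
inside the transmembrane helices of a protein.  Substitutions are grouped
for comparison into:

* ``QTY_COGNATE`` — the paired polar twin of a hydrophobic wild residue
  (L->Q, I->T, V->T, F->Y) or the paired hydrophobic twin of a polar wild
  residue (Q->L, T->I and T->V, Y->F);
* ``OTHER_POLAR`` — the remaining polar alternatives
  (D, E, R, K, H, N, S, T, Q, Y minus the cognates);
* ``OTHER_NONPOLAR`` — the remaining nonpolar alternatives
  (A, C, G, I, L, M, F, P, W, V minus the cognates).

Effect scores live in [0, 1] (probability-like damage scores, the scale
used by common missense-impact predictors).  Real predictors are external
web tools; the package ships a deterministic stand-in scorer built from
hydropathy distance, burial and conservation so the aggregation machinery
is fully testable offline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .sequences import (
    STANDARD_AAS,
    ProteinRecord,
    SegmentKind,
    Topology,
)
from .qty import DEFAULT_TARGET_KINDS

POLAR_SET = frozenset("DERKHNSTQY")
NONPOLAR_SET = frozenset("ACGILMFPWV")

#: Cognate substitution targets per wild residue (QTY pairs and inverses).
COGNATES: dict[str, frozenset[str]] = {
    "L": frozenset("Q"),
    "I": frozenset("T"),
    "V": frozenset("T"),
    "F": frozenset("Y"),
    "Q": frozenset("L"),
    "T": frozenset("IV"),
    "Y": frozenset("F"),
}

DEFAULT_TARGET_AAS = frozenset("LIVF")


@dataclass(frozen=True)
class SiteLibrary:
    """All 19 substitutions at one site."""

    protein_id: str
    position: int
    wild_aa: str

    @property
    def alternatives(self) -> frozenset[str]:
        return frozenset(STANDARD_AAS) - {self.wild_aa}


class SubstitutionClass:
    QTY_COGNATE = "QTY_COGNATE"
    OTHER_POLAR = "OTHER_POLAR"
    OTHER_NONPOLAR = "OTHER_NONPOLAR"
    ALL = "ALL"


def classify_substitution(wild_aa: str, alt_aa: str) -> str:
    """Class of one substitution relative to its wild residue."""
    if wild_aa == alt_aa:
        raise ValueError("substitution to the wild residue itself")
    if alt_aa in COGNATES.get(wild_aa, frozenset()):
        return SubstitutionClass.QTY_COGNATE
    if alt_aa in POLAR_SET:
        return SubstitutionClass.OTHER_POLAR
    return SubstitutionClass.OTHER_NONPOLAR


def build_site_library(record: ProteinRecord, position: int) -> SiteLibrary:
    if not 1 <= position <= len(record):
        raise IndexError(f"position {position} outside 1..{len(record)}")
    return SiteLibrary(
        protein_id=record.id, position=position, wild_aa=record.residue(position)
    )


def build_tm_library(
    record: ProteinRecord,
    topology: Topology,
    target_aas: Iterable[str] = DEFAULT_TARGET_AAS,
    target_kinds: Iterable[SegmentKind] = DEFAULT_TARGET_KINDS,
) -> list[SiteLibrary]:
    """One site library per matching residue inside the target segments.

    Defaults enumerate the classic design surface: every L, I, V, F in a
    transmembrane helix, 19 candidates per site.
    """
    targets = set(target_aas)
    sites = [
        build_site_library(record, pos)
        for pos in sorted(topology.positions_of_kind(target_kinds))
        if record.residue(pos) in targets
    ]
    return sites


def library_size(sites: Iterable[SiteLibrary]) -> int:
    return 19 * sum(1 for _ in sites)


Scorer = Callable[[SiteLibrary, str], float]


def standin_scorer(
    record: ProteinRecord,
    topology: Topology | None = None,
    conservation_grade_per_site: Mapping[int, int] | None = None,
    burial_per_site: Mapping[int, bool] | None = None,
) -> Scorer:
    """Deterministic effect-score stand-in.

    score = clamp01( (|KD(wild) - KD(alt)| / 9.0)
                     * (0.5 + 0.5 * buried)
                     * (grade / 9) )

    with the conservation grade defaulting to 5 (average) when absent and
    burial defaulting to exposed.  The 9.0 divisor is the KD range
    (R = -4.5 to I = +4.5).  This is a documented stand-in for external
    missense-impact predictors: it preserves the qualitative property that
    chemically conservative substitutions score lower, nothing more.
    """
    grades = conservation_grade_per_site or {}
    burials = burial_per_site or {}

    def score(site: SiteLibrary, alt_aa: str) -> float:
        dkd = abs(KYTE_DOOLITTLE[site.wild_aa] - KYTE_DOOLITTLE[alt_aa])
        buried = 1.0 if burials.get(site.position, False) else 0.0
        grade = grades.get(site.position, 5)
        value = (dkd / 9.0) * (0.5 + 0.5 * buried) * (grade / 9.0)
        return min(1.0, max(0.0, value))

    return score


def score_library(sites: Iterable[SiteLibrary], scorer: Scorer) -> dict[tuple[int, str], float]:
    """Score every (site, alternative) pair of a library."""
    return {
        (site.position, alt): scorer(site, alt)
        for site in sites
        for alt in sorted(site.alternatives)
    }


def aggregate_by_class(
    scores: Mapping[tuple[int, str], float],
    wild_aa_per_site: Mapping[int, str],
) -> dict[str, tuple[float, int]]:
    """Per-class mean score and count over a scored library.

    Returns a dict mapping class name to (mean, n); classes with no members
    report (nan, 0).  Entries whose site has no recorded wild residue are
    excluded with a warning.
    """
    sums: dict[str, float] = {c: 0.0 for c in (
        SubstitutionClass.QTY_COGNATE,
        SubstitutionClass.OTHER_POLAR,
        SubstitutionClass.OTHER_NONPOLAR,
        SubstitutionClass.ALL,
    )}
    counts: dict[str, int] = {c: 0 for c in sums}
    skipped = []
    for (position, alt), value in scores.items():
        wild = wild_aa_per_site.get(position)
        if wild is None:
            skipped.append((position, alt))
            continue
        cls = classify_substitution(wild, alt)
        for key in (cls, SubstitutionClass.ALL):
            sums[key] += value
            counts[key] += 1
    if skipped:
        warnings.warn(f"{len(skipped)} scored entries without a wild residue were excluded")
    return {
        c: ((sums[c] / counts[c]) if counts[c] else (float("nan")), counts[c])
        for c in sums
    }
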