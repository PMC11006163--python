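"""Classification and cross-tabulation of natural missense variants.

A :class:`VariantRecord` holds one ref->alt amino-acid substitution at the
protein-consequence level (HGVS short form like "I59T") together with its
topological location, secondary structure, residue exposure, conservation
grade (1-9, 9 most conserved), predicted phenotypic effect and clinical
significance.  Variants are classified as QTY (hydrophobic -> polar twin:
L->Q, I->T, V->T, F->Y), reverse-QTY (the inverse pairs) or OTHER, and
summarized by direction x location x effect x secondary-structure class.

A reference table of 95 natural QTY/rQTY variants of the eight human
glutamate transporters (EAAT1-4, VGLUT1-3, YLAT2), compiled from
population-sequencing and clinical databases, ships with the package and
loads via :func:`load_reference_variants`.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .codons import single_change_paths
from .sequences import STANDARD_AAS

PathLike = Union[str, Path]

QTY_DIRECTION_PAIRS = frozenset({("L", "Q"), ("I", "T"), ("V", "T"), ("F", "Y")})
RQTY_DIRECTION_PAIRS = frozenset({(b, a) for a, b in QTY_DIRECTION_PAIRS})


class Direction(Enum):
    QTY = "QTY"
    RQTY = "RQTY"
    OTHER = "OTHER"


class Location(Enum):
    TM = "TM"
    ECL = "ECL"
    ICL = "ICL"
    IM = "IM"
    INTRACELLULAR = "INTRACELLULAR"
    EXTRACELLULAR = "EXTRACELLULAR"
    UNKNOWN = "UNKNOWN"


class StructureClass(Enum):
    ALPHA_HELIX = "ALPHA_HELIX"
    THREE_TEN_HELIX = "THREE_TEN_HELIX"
    BETA_STRAND = "BETA_STRAND"
    LOOP = "LOOP"
    COIL = "COIL"
    UNKNOWN = "UNKNOWN"


#: Helical secondary structure = canonical alpha helix or the tighter 3/10 helix.
HELICAL_CLASSES = frozenset({StructureClass.ALPHA_HELIX, StructureClass.THREE_TEN_HELIX})


class Exposure(Enum):
    EXPOSED = "EXPOSED"
    BURIED = "BURIED"
    UNKNOWN = "UNKNOWN"


class Effect(Enum):
    BENIGN = "BENIGN"
    POSSIBLY_DAMAGING = "POSSIBLY_DAMAGING"
    PROBABLY_DAMAGING = "PROBABLY_DAMAGING"
    UNKNOWN = "UNKNOWN"


class ResidueRole(Enum):
    FUNCTIONAL = "FUNCTIONAL"   # exposed and highly conserved
    STRUCTURAL = "STRUCTURAL"   # buried and highly conserved
    NEITHER = "NEITHER"


_VARIANT_RE = re.compile(rf"^([{STANDARD_AAS}])(\d+)([{STANDARD_AAS}])$")


def parse_variant(token: str) -> tuple[str, int, str]:
    """Parse an HGVS-style short token like ``I59T`` -> (ref, position, alt)."""
    m = _VARIANT_RE.match(token.strip())
    if not m:
        raise ValueError(f"malformed variant token {token!r} (expected e.g. I59T)")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if pos < 1:
        raise ValueError(f"variant position must be >= 1 in {token!r}")
    return ref, pos, alt


@dataclass
class VariantRecord:
    """One annotated protein missense variant."""

    protein_id: str
    ref_aa: str
    position: int
    alt_aa: str
    location: Location = Location.UNKNOWN
    location_label: str = ""
    structure: StructureClass = StructureClass.UNKNOWN
    exposure: Exposure = Exposure.UNKNOWN
    conservation_grade: int | None = None
    predicted_effect: Effect = Effect.UNKNOWN
    clinical_significance: str | None = None
    residue_flag: str | None = None  # ConSurf-style F (functional) / S (structural)

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"ref and alt identical in {self.mutation}")
        if self.conservation_grade is not None and not 1 <= self.conservation_grade <= 9:
            raise ValueError(f"conservation grade {self.conservation_grade} outside 1..9")

    @property
    def mutation(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


def classify_direction(v: VariantRecord) -> Direction:
    pair = (v.ref_aa, v.alt_aa)
    if pair in QTY_DIRECTION_PAIRS:
        return Direction.QTY
    if pair in RQTY_DIRECTION_PAIRS:
        return Direction.RQTY
    return Direction.OTHER


def second_base_reachable(v: VariantRecord) -> bool:
    """True iff the substitution is a pure second-position single-base change.

    Requires at least one single-nucleotide codon path between ref and alt
    and that *every* such path changes codon position 2.  L->I, for example,
    has single-base paths but at positions 1 and 3, so it is not
    second-base reachable; V->T has no single-base path at all.
    """
    paths = single_change_paths(v.ref_aa, v.alt_aa)
    return bool(paths) and all(p.position == 2 for p in paths)


def functional_structural_flags(v: VariantRecord, grade_threshold: int = 8) -> ResidueRole:
    """Classify the mutated residue as functional/structural/neither.

    Functional = exposed and highly conserved (grade >= threshold);
    structural = buried and highly conserved.  Missing exposure or grade
    yields NEITHER with a warning.
    """
    if v.exposure is Exposure.UNKNOWN or v.conservation_grade is None:
        warnings.warn(f"{v.protein_id} {v.mutation}: exposure or grade missing; NEITHER")
        return ResidueRole.NEITHER
    if v.conservation_grade >= grade_threshold:
        if v.exposure is Exposure.EXPOSED:
            return ResidueRole.FUNCTIONAL
        if v.exposure is Exposure.BURIED:
            return ResidueRole.STRUCTURAL
    return ResidueRole.NEITHER


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class DirectionSummary:
    """Counts for one substitution direction (QTY, rQTY or other)."""

    n: int = 0
    tm: int = 0                      # located in a membrane-spanning helix
    non_tm: int = 0                  # everything else, incl. intramembrane hairpins
    by_location: Counter = field(default_factory=Counter)
    by_effect: Counter = field(default_factory=Counter)
    tm_by_effect: Counter = field(default_factory=Counter)
    non_tm_by_effect: Counter = field(default_factory=Counter)
    helical: int = 0
    helical_by_effect: Counter = field(default_factory=Counter)
    second_base_reachable: int = 0

    def pct_tm(self) -> float:
        return round(100.0 * self.tm / self.n, 1) if self.n else 0.0

    def pct_non_tm(self) -> float:
        return round(100.0 * self.non_tm / self.n, 1) if self.n else 0.0


@dataclass
class SummaryCounts:
    n_total: int
    n_qty: int
    n_rqty: int
    n_other: int
    directions: dict[Direction, DirectionSummary]

    def as_dict(self) -> dict:
        out = {
            "n_total": self.n_total,
            "n_qty": self.n_qty,
            "n_rqty": self.n_rqty,
            "n_other": self.n_other,
        }
        for d, s in self.directions.items():
            out[d.value] = {
                "n": s.n,
                "tm": s.tm,
                "non_tm": s.non_tm,
                "pct_tm": s.pct_tm(),
                "pct_non_tm": s.pct_non_tm(),
                "by_location": {k.value: c for k, c in sorted(s.by_location.items(), key=lambda kv: kv[0].value)},
                "by_effect": {k.value: c for k, c in sorted(s.by_effect.items(), key=lambda kv: kv[0].value)},
                "tm_by_effect": {k.value: c for k, c in sorted(s.tm_by_effect.items(), key=lambda kv: kv[0].value)},
                "non_tm_by_effect": {k.value: c for k, c in sorted(s.non_tm_by_effect.items(), key=lambda kv: kv[0].value)},
                "helical": s.helical,
                "helical_by_effect": {k.value: c for k, c in sorted(s.helical_by_effect.items(), key=lambda kv: kv[0].value)},
                "second_base_reachable": s.second_base_reachable,
            }
        return out


def summarize(table: Iterable[VariantRecord]) -> SummaryCounts:
    """Cross-tabulate a variant table by direction, location, effect, structure.

    The TM/non-TM split counts only membrane-*spanning* helix locations as
    TM; intramembrane hairpin segments (IM) sit in the membrane but do not
    span it and are counted non-TM, consistent with the transporter
    architecture convention used for the reference table.
    """
    directions = {d: DirectionSummary() for d in Direction}
    for v in table:
        d = classify_direction(v)
        s = directions[d]
        s.n += 1
        is_tm = v.location is Location.TM
        if is_tm:
            s.tm += 1
            s.tm_by_effect[v.predicted_effect] += 1
        else:
            s.non_tm += 1
            s.non_tm_by_effect[v.predicted_effect] += 1
        s.by_location[v.location] += 1
        s.by_effect[v.predicted_effect] += 1
        if v.structure in HELICAL_CLASSES:
            s.helical += 1
            s.helical_by_effect[v.predicted_effect] += 1
        if second_base_reachable(v):
            s.second_base_reachable += 1
    return SummaryCounts(
        n_total=sum(s.n for s in directions.values()),
        n_qty=directions[Direction.QTY].n,
        n_rqty=directions[Direction.RQTY].n,
        n_other=directions[Direction.OTHER].n,
        directions=directions,
    )


# ---------------------------------------------------------------------------
# Table I/O — TSV with columns protein_id, mutation, second_base, location,
# structure, exposure, conservation_grade, predicted_effect,
# clinical_significance
# ---------------------------------------------------------------------------

_STRUCTURE_TOKENS = {
    "a-helix": StructureClass.ALPHA_HELIX,
    "alpha-helix": StructureClass.ALPHA_HELIX,
    "3/10-helix": StructureClass.THREE_TEN_HELIX,
    "b-strand": StructureClass.BETA_STRAND,
    "beta-strand": StructureClass.BETA_STRAND,
    "loop": StructureClass.LOOP,
    "n-coil": StructureClass.COIL,
    "c-coil": StructureClass.COIL,
    "coil": StructureClass.COIL,
    # enum-value tokens, so written tables read back identically
    "alpha_helix": StructureClass.ALPHA_HELIX,
    "three_ten_helix": StructureClass.THREE_TEN_HELIX,
    "beta_strand": StructureClass.BETA_STRAND,
    "unknown": StructureClass.UNKNOWN,
    "-": StructureClass.UNKNOWN,
    "": StructureClass.UNKNOWN,
}

_LOCATION_PREFIXES = [
    ("TM", Location.TM),
    ("ECL", Location.ECL),
    ("ICL", Location.ICL),
    ("IM", Location.IM),
]


def parse_location(token: str) -> tuple[Location, str]:
    """Map a location label like ``TM6``/``ECL2``/``Intracellular`` to its class."""
    t = token.strip()
    low = t.lower()
    if not t or t == "-":
        return Location.UNKNOWN, ""
    if low.startswith("intracellular") or low.startswith("cytoplasm"):
        return Location.INTRACELLULAR, t
    if low.startswith("extracellular"):
        return Location.EXTRACELLULAR, t
    for prefix, loc in _LOCATION_PREFIXES:
        if t.upper().startswith(prefix):
            return loc, t
    return Location.UNKNOWN, t


def _parse_exposure(token: str) -> tuple[Exposure, str | None]:
    t = token.strip()
    flag = None
    m = re.search(r"\(([FS])\)\s*$", t)
    if m:
        flag = m.group(1)
        t = t[: m.start()].strip()
    low = t.lower()
    if low.startswith("exposed"):
        return Exposure.EXPOSED, flag
    if low.startswith("buried"):
        return Exposure.BURIED, flag
    return Exposure.UNKNOWN, flag


def _parse_effect(token: str) -> Effect:
    t = token.strip().lower().replace("?damaging", "? damaging")
    if t == "benign":
        return Effect.BENIGN
    if t in {"? damaging", "possibly damaging", "possibly_damaging"}:
        return Effect.POSSIBLY_DAMAGING
    if t in {"damaging", "probably damaging", "probably_damaging"}:
        return Effect.PROBABLY_DAMAGING
    return Effect.UNKNOWN


def read_variant_table(path: PathLike) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein_id", "mutation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing column(s) {sorted(missing)}")
    records: list[VariantRecord] = []
    for _, row in df.iterrows():
        ref, pos, alt = parse_variant(row["mutation"])
        loc, label = parse_location(row.get("location", ""))
        exposure, flag = _parse_exposure(row.get("exposure", ""))
        grade_tok = str(row.get("conservation_grade", "")).strip()
        grade = int(grade_tok) if grade_tok.isdigit() else None
        structure = _STRUCTURE_TOKENS.get(
            str(row.get("structure", "")).strip().lower(), StructureClass.UNKNOWN
        )
        clin = str(row.get("clinical_significance", "")).strip()
        records.append(
            VariantRecord(
                protein_id=row["protein_id"],
                ref_aa=ref,
                position=pos,
                alt_aa=alt,
                location=loc,
                location_label=label,
                structure=structure,
                exposure=exposure,
                conservation_grade=grade,
                predicted_effect=_parse_effect(str(row.get("predicted_effect", ""))),
                clinical_significance=None if clin in {"", "-"} else clin,
                residue_flag=flag,
            )
        )
    return records


def write_variant_table(records: Sequence[VariantRecord], path: PathLike, *, with_direction: bool = True) -> None:
    rows = []
    for v in records:
        row = {
            "protein_id": v.protein_id,
            "mutation": v.mutation,
            "location": v.location_label or v.location.value,
            "structure": v.structure.value,
            "exposure": v.exposure.value,
            "conservation_grade": "" if v.conservation_grade is None else v.conservation_grade,
            "predicted_effect": v.predicted_effect.value,
            "clinical_significance": v.clinical_significance or "-",
        }
        if with_direction:
            row["direction"] = classify_direction(v).value
            row["second_base_reachable"] = second_base_reachable(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_reference_variants() -> list[VariantRecord]:
    """The packaged table of 95 natural QTY/rQTY glutamate-transporter variants."""
    ref = resources.files("qtycode.data").joinpath("glutamate_variants.tsv")
    with resources.as_file(ref) as p:
        return read_variant_table(p)
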