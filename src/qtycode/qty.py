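"""The QTY code engine.

The QTY code renders transmembrane helices water-soluble by replacing the
four dominant hydrophobic residues with structurally analogous neutral polar
ones: leucine -> glutamine (L->Q), isoleucine and valine -> threonine
(I->T, V->T), phenylalanine -> tyrosine (F->Y).  Each pair shares a very
similar side-chain shape, so the substitution changes surface chemistry
without changing the helical fold.  This module applies the transform inside
designated topology segments and reports the sequence-level accounting that
accompanies a design: percent variation in the targeted segments and
overall, molecular weight and isoelectric point of native and variant.

MW and pI follow the Expasy conventions (average isotopic masses; the
Bjellqvist pK set with residue-specific N-terminal pKs), delegated to
Biopython's ProtParam machinery; the pI root-find is a bisection on the
net-charge curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

from .sequences import (
    ProteinRecord,
    SegmentKind,
    SequenceError,
    Topology,
    validate_sequence,
)

#: The QTY substitution table. Residues outside the table are never touched.
QTY_MAP: dict[str, str] = {"L": "Q", "I": "T", "V": "T", "F": "Y"}

#: Valid (from, to) pairs, and their inverses for reverse-QTY work.
QTY_PAIRS = frozenset(QTY_MAP.items())
RQTY_PAIRS = frozenset((b, a) for a, b in QTY_MAP.items())

DEFAULT_TARGET_KINDS = frozenset({SegmentKind.TM_HELIX})

# mean water mass added on peptide-bond hydrolysis accounting (Expasy)
WATER_MASS = 18.01524


def qty_map(aa: str) -> str | None:
    """QTY target of a residue, or None if it is outside the code's domain."""
    aa = validate_sequence(aa)
    if len(aa) != 1:
        raise SequenceError("qty_map expects a single residue")
    return QTY_MAP.get(aa)


@dataclass(frozen=True)
class QTYSubstitution:
    """One positional substitution produced by the transform."""

    position: int  # 1-based
    from_aa: str
    to_aa: str

    def __post_init__(self) -> None:
        if (self.from_aa, self.to_aa) not in QTY_PAIRS:
            raise ValueError(f"{self.from_aa}->{self.to_aa} is not a QTY substitution")

    def __str__(self) -> str:  # HGVS-like short form, e.g. L92Q
        return f"{self.from_aa}{self.position}{self.to_aa}"


@dataclass
class QTYResult:
    """Variant sequence plus the bookkeeping of a QTY design."""

    record: ProteinRecord
    variant_sequence: str
    substitutions: list[QTYSubstitution] = field(default_factory=list)
    tm_variation_pct: float = 0.0
    overall_variation_pct: float = 0.0
    native_mw: float = 0.0
    variant_mw: float = 0.0
    native_pI: float = 0.0
    variant_pI: float = 0.0

    @property
    def variant_record(self) -> ProteinRecord:
        return ProteinRecord(
            id=f"{self.record.id}_QTY",
            sequence=self.variant_sequence,
            name=(self.record.name + " QTY variant").strip(),
        )


def variation_stats(
    native: ProteinRecord,
    variant_sequence: str,
    topology: Topology,
    target_kinds: Iterable[SegmentKind] = DEFAULT_TARGET_KINDS,
) -> tuple[float, float]:
    """Percent changed positions inside target segments, and overall.

    The targeted-segment percentage is normalized by the number of residues
    *inside* target-kind segments (the convention that reproduces the
    reported 41-54% TM variation range); overall by full sequence length.
    A protein with zero residues in target segments reports 0 with a warning.
    """
    if len(native.sequence) != len(variant_sequence):
        raise ValueError("native and variant sequences differ in length")
    changed = [
        i + 1
        for i, (a, b) in enumerate(zip(native.sequence, variant_sequence))
        if a != b
    ]
    target_positions = set(topology.positions_of_kind(target_kinds))
    n_target = len(target_positions)
    changed_in_target = sum(1 for p in changed if p in target_positions)
    if n_target == 0:
        warnings.warn(
            f"{native.id}: no residues in target segments; TM variation reported as 0"
        )
        tm_pct = 0.0
    else:
        tm_pct = 100.0 * changed_in_target / n_target
    overall_pct = 100.0 * len(changed) / len(native.sequence)
    return tm_pct, overall_pct


def apply_qty(
    record: ProteinRecord,
    topology: Topology,
    target_kinds: Iterable[SegmentKind] = DEFAULT_TARGET_KINDS,
) -> QTYResult:
    """Apply the QTY code to every L/I/V/F inside the target segments.

    Defaults to transmembrane helices only; intramembrane hairpins (HP1/HP2
    in the EAAT fold) can be included by passing
    ``{SegmentKind.TM_HELIX, SegmentKind.INTRAMEMBRANE}``.
    """
    if topology.max_end > len(record):
        raise ValueError(
            f"topology extends to {topology.max_end} but {record.id} has "
            f"{len(record)} residues"
        )
    target_positions = topology.positions_of_kind(target_kinds)
    seq = list(record.sequence)
    subs: list[QTYSubstitution] = []
    for pos in sorted(target_positions):
        aa = seq[pos - 1]
        to = QTY_MAP.get(aa)
        if to is not None:
            seq[pos - 1] = to
            subs.append(QTYSubstitution(position=pos, from_aa=aa, to_aa=to))
    variant = "".join(seq)
    tm_pct, overall_pct = variation_stats(record, variant, topology, target_kinds)
    return QTYResult(
        record=record,
        variant_sequence=variant,
        substitutions=subs,
        tm_variation_pct=tm_pct,
        overall_variation_pct=overall_pct,
        native_mw=molecular_weight(record.sequence),
        variant_mw=molecular_weight(variant),
        native_pI=isoelectric_point(record.sequence),
        variant_pI=isoelectric_point(variant),
    )


def molecular_weight(sequence: str) -> float:
    """Average-isotopic molecular weight in Da (residue masses + one water)."""
    seq = validate_sequence(sequence)
    return float(ProteinAnalysis(seq).molecular_weight())


def charge_at_pH(sequence: str, pH: float) -> float:
    """Net charge (elementary charges) from the Bjellqvist pK set.

    Henderson-Hasselbalch sum over D, E, C, Y, H, K, R side chains plus the
    free termini, with Expasy's residue-specific N-terminal pKs.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside 0..14")
    seq = validate_sequence(sequence)
    return float(IsoelectricPoint(seq).charge_at_pH(pH))


def isoelectric_point(sequence: str, *, tol: float = 0.005) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge curve is strictly decreasing in pH (every group deprotonates
    with rising pH), so the zero crossing is unique.  Result reported to two
    decimals, Expasy-style.
    """
    seq = validate_sequence(sequence)
    lo, hi = 0.0, 14.0
    c_lo = charge_at_pH(seq, lo)
    c_hi = charge_at_pH(seq, hi)
    if c_lo < 0 or c_hi > 0:
        raise ValueError("charge curve has no zero crossing in [0, 14]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if charge_at_pH(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return round(0.5 * (lo + hi), 2)
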