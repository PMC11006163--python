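"""Protein sequence and membrane-topology data model.

Positions are 1-based inclusive throughout, matching UniProt feature tables
and the HGVS-style variant numbering used elsewhere in the package (e.g.
"I59T" refers to the 59th residue of the mature sequence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

#: The 20 standard one-letter amino-acid codes. B/Z/X/U/O are rejected by
#: default because the QTY transform and the downstream physicochemical
#: computations are undefined on them.
STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AAS)

PathLike = Union[str, Path]


class SequenceError(ValueError):
    """Malformed sequence input (illegal residue, empty record, ...)."""


class TopologyError(ValueError):
    """Invalid topology annotation (overlap, bad range, unknown kind)."""


class SegmentKind(Enum):
    """Vocabulary of membrane-topology segment kinds.

    ECL/ICL (extracellular/intracellular *loops*) are deliberately distinct
    from the generic EXTRACELLULAR/INTRACELLULAR domains so that variant
    tables can reproduce the location labels of transporter architecture
    (TM6, ECL2, ICL4, IM, "Intracellular") exactly.  INTRAMEMBRANE covers
    membrane-embedded hairpin helices (HP1/HP2 in EAATs) that do not span
    the bilayer and are therefore not TM helices.
    """

    TM_HELIX = "TM_HELIX"
    INTRAMEMBRANE = "INTRAMEMBRANE"
    EXTRACELLULAR = "EXTRACELLULAR"
    INTRACELLULAR = "INTRACELLULAR"
    ECL = "ECL"
    ICL = "ICL"
    OTHER = "OTHER"


def validate_sequence(sequence: str, *, context: str = "") -> str:
    """Uppercase and validate a protein sequence.

    Raises :class:`SequenceError` if the sequence is empty or contains a
    character outside the 20-letter alphabet.
    """
    seq = sequence.upper()
    if not seq:
        raise SequenceError(f"empty sequence{' in ' + context if context else ''}")
    bad = sorted(set(seq) - _STANDARD_SET)
    if bad:
        raise SequenceError(
            f"illegal residue(s) {','.join(bad)}"
            f"{' in ' + context if context else ''}: only {STANDARD_AAS} allowed"
        )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence, 1-based positions."""

    id: str
    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("protein record requires a non-empty id")
        object.__setattr__(self, "sequence", validate_sequence(self.sequence, context=self.id))

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class TopologySegment:
    """One labelled topology segment, 1-based inclusive coordinates."""

    kind: SegmentKind
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.kind, SegmentKind):
            raise TopologyError(f"unknown segment kind {self.kind!r}")
        if self.start < 1 or self.end < self.start:
            raise TopologyError(
                f"segment {self.label or self.kind.value}: bad range {self.start}..{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class Topology:
    """Ordered, non-overlapping labelled segments for one protein.

    The annotation may be sparse: positions not covered by any segment are
    reported as :attr:`SegmentKind.OTHER`.
    """

    protein_id: str
    segments: list[TopologySegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start <= a.end:
                raise TopologyError(
                    f"overlapping segments {a.label or a.kind.value} "
                    f"({a.start}-{a.end}) and {b.label or b.kind.value} ({b.start}-{b.end})"
                )

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def max_end(self) -> int:
        return max((s.end for s in self.segments), default=0)

    def segments_of_kind(self, kinds: Iterable[SegmentKind]) -> list[TopologySegment]:
        kindset = set(kinds)
        return [s for s in self.segments if s.kind in kindset]

    def positions_of_kind(self, kinds: Iterable[SegmentKind]) -> list[int]:
        """All 1-based positions covered by segments of the given kinds."""
        out: list[int] = []
        for seg in self.segments_of_kind(kinds):
            out.extend(range(seg.start, seg.end + 1))
        return out


def segment_kind_at(topology: Topology, position: int, *, sequence_length: int | None = None) -> SegmentKind:
    """Kind of the segment covering ``position`` (OTHER if uncovered).

    ``sequence_length``, when given, bounds the valid range; otherwise any
    position >= 1 is accepted (topologies may be sparse).
    """
    upper = sequence_length if sequence_length is not None else max(topology.max_end, position)
    if not 1 <= position <= upper:
        raise IndexError(f"position {position} outside 1..{upper}")
    for seg in topology.segments:
        if position in seg:
            return seg.kind
        if seg.start > position:
            break
    return SegmentKind.OTHER


# ---------------------------------------------------------------------------
# FASTA I/O (via Biopython, with residue validation on read)
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike, *, allow_nonstandard: bool = False) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    With ``allow_nonstandard`` the residues outside the 20-letter alphabet
    are kept (callers that only need bookkeeping may opt in); by default
    they raise :class:`SequenceError` naming the offending record.
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise SequenceError(f"malformed FASTA header in {path}")
        seq = str(rec.seq).upper()
        if allow_nonstandard:
            obj = object.__new__(ProteinRecord)
            object.__setattr__(obj, "id", rec.id)
            object.__setattr__(obj, "sequence", seq)
            object.__setattr__(obj, "name", rec.description)
            records.append(obj)
        else:
            records.append(ProteinRecord(id=rec.id, sequence=seq, name=rec.description))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: PathLike) -> None:
    """Write records as FASTA, 60-column wrapped."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.name or "") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


# ---------------------------------------------------------------------------
# Topology I/O — JSON {"protein_id", "segments": [{label, kind, start, end}]}
# or TSV with header  label<TAB>kind<TAB>start<TAB>end
# ---------------------------------------------------------------------------

def _segment_from_fields(label: str, kind: str, start: str | int, end: str | int) -> TopologySegment:
    try:
        kind_enum = SegmentKind(kind)
    except ValueError as exc:
        raise TopologyError(f"segment {label!r}: unknown kind {kind!r}") from exc
    try:
        s, e = int(start), int(end)
    except (TypeError, ValueError) as exc:
        raise TopologyError(f"segment {label!r}: non-integer bounds {start!r}..{end!r}") from exc
    return TopologySegment(kind=kind_enum, start=s, end=e, label=label)


def read_topology(path: PathLike, *, protein_id: str | None = None) -> Topology:
    """Read a topology annotation from JSON or TSV (sniffed by content)."""
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        data = json.loads(text)
        segs = [
            _segment_from_fields(s.get("label", ""), s["kind"], s["start"], s["end"])
            for s in data.get("segments", [])
        ]
        return Topology(protein_id=protein_id or data.get("protein_id", ""), segments=segs)
    segs = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return Topology(protein_id=protein_id or "", segments=[])
    start_idx = 1 if lines[0].lower().startswith("label") else 0
    for ln in lines[start_idx:]:
        fields = ln.rstrip("\n").split("\t")
        if len(fields) != 4:
            raise TopologyError(f"topology TSV row needs 4 tab-separated fields: {ln!r}")
        segs.append(_segment_from_fields(fields[0], fields[1], fields[2], fields[3]))
    return Topology(protein_id=protein_id or "", segments=segs)


def write_topology(topology: Topology, path: PathLike, *, fmt: str = "json") -> None:
    if fmt == "json":
        data = {
            "protein_id": topology.protein_id,
            "segments": [
                {"label": s.label, "kind": s.kind.value, "start": s.start, "end": s.end}
                for s in topology.segments
            ],
        }
        Path(path).write_text(json.dumps(data, indent=1) + "\n")
    elif fmt == "tsv":
        rows = ["label\tkind\tstart\tend"]
        rows += [f"{s.label}\t{s.kind.value}\t{s.start}\t{s.end}" for s in topology.segments]
        Path(path).write_text("\n".join(rows) + "\n")
    else:
        raise ValueError(f"unknown topology format {fmt!r}")
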