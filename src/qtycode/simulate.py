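"""Seeded generators for every input the pipeline consumes.

The generators emulate the shape of the real study inputs without any
download: transporter-like proteins (8-12 TM helices of hydrophobic-biased
composition separated by polar loops, total length in the 400-560 residue
range typical of glutamate transporters), variant tables with a planted
QTY/rQTY/other composition, ideal-geometry helix-bundle CA traces, and
alignments with a planted fraction of invariant columns.

Determinism: a single integer seed spans all generators; each generator
derives its own independent stream from the seed via a fixed spawn key, so
adding a generator never perturbs the output of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import ProteinRecord, SegmentKind, Topology, TopologySegment
from .structure import StructureModel
from .conservation import Alignment
from .variants import (
    Effect,
    Exposure,
    Location,
    StructureClass,
    VariantRecord,
)

_STREAM_KEYS = {"transporter": 1, "variants": 2, "bundle": 3, "msa": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_KEYS[stream],)))


def _normalized(weights: dict[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}

#: TM composition: strongly hydrophobic-biased (~70% mass on L,I,V,F,A,M,G),
#: echoing the residue usage of membrane-spanning helices.
DEFAULT_TM_COMPOSITION = _normalized({
    "L": 0.16, "I": 0.12, "V": 0.12, "F": 0.09, "A": 0.11, "M": 0.04, "G": 0.07,
    "S": 0.06, "T": 0.06, "W": 0.02, "Y": 0.03, "C": 0.02, "P": 0.02,
    "N": 0.02, "Q": 0.01, "E": 0.01, "D": 0.01, "K": 0.01, "R": 0.01, "H": 0.01,
})

#: Loop composition: polar/charged-biased.
DEFAULT_LOOP_COMPOSITION = _normalized({
    "S": 0.09, "T": 0.07, "N": 0.06, "Q": 0.06, "D": 0.07, "E": 0.08,
    "K": 0.08, "R": 0.07, "H": 0.03, "G": 0.09, "P": 0.07, "A": 0.07,
    "L": 0.05, "I": 0.03, "V": 0.04, "F": 0.02, "Y": 0.03, "M": 0.02,
    "W": 0.01, "C": 0.01,
})


@dataclass
class GeneratorConfig:
    """Parameters of the transporter-like sequence generator."""

    seed: int = 0
    n_tm: int = 8
    tm_length: tuple[int, int] = (18, 25)
    loop_length: tuple[int, int] = (15, 45)
    tm_composition: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TM_COMPOSITION))
    loop_composition: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOOP_COMPOSITION))

    def __post_init__(self) -> None:
        for name, comp in (("tm", self.tm_composition), ("loop", self.loop_composition)):
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} composition probabilities must sum to 1")
        for name, rng in (("tm_length", self.tm_length), ("loop_length", self.loop_length)):
            if rng[0] < 1 or rng[1] < rng[0]:
                raise ValueError(f"bad {name} range {rng}")
        if self.n_tm < 1:
            raise ValueError("n_tm must be >= 1")


def _draw_segment(rng: np.random.Generator, length: int, composition: dict[str, float]) -> str:
    aas = sorted(composition)
    probs = np.array([composition[a] for a in aas])
    return "".join(rng.choice(list(aas), size=length, p=probs))


def generate_transporter(config: GeneratorConfig) -> tuple[ProteinRecord, Topology]:
    """A transporter-like protein: alternating loops and TM helices.

    Loops alternate between the intracellular and extracellular side
    (N-terminus intracellular, as in the glutamate-transporter fold);
    TM helices are labelled TM1..TMn.
    """
    rng = _rng(config.seed, "transporter")
    pieces: list[str] = []
    segments: list[TopologySegment] = []
    pos = 1
    inside = True  # N-terminus intracellular
    for i in range(config.n_tm):
        loop_len = int(rng.integers(config.loop_length[0], config.loop_length[1] + 1))
        pieces.append(_draw_segment(rng, loop_len, config.loop_composition))
        kind = SegmentKind.ICL if inside else SegmentKind.ECL
        label = ("N-term" if i == 0 else f"{'ICL' if inside else 'ECL'}{(i + 1) // 2}")
        segments.append(TopologySegment(kind=SegmentKind.INTRACELLULAR if i == 0 else kind,
                                        start=pos, end=pos + loop_len - 1, label=label))
        pos += loop_len
        tm_len = int(rng.integers(config.tm_length[0], config.tm_length[1] + 1))
        pieces.append(_draw_segment(rng, tm_len, config.tm_composition))
        segments.append(TopologySegment(kind=SegmentKind.TM_HELIX, start=pos,
                                        end=pos + tm_len - 1, label=f"TM{i + 1}"))
        pos += tm_len
        inside = not inside
    tail_len = int(rng.integers(config.loop_length[0], config.loop_length[1] + 1))
    pieces.append(_draw_segment(rng, tail_len, config.loop_composition))
    segments.append(TopologySegment(
        kind=SegmentKind.INTRACELLULAR if inside else SegmentKind.EXTRACELLULAR,
        start=pos, end=pos + tail_len - 1, label="C-term"))
    sequence = "".join(pieces)
    record = ProteinRecord(id=f"SYN{config.seed:04d}", sequence=sequence,
                           name=f"synthetic {config.n_tm}-TM transporter")
    return record, Topology(protein_id=record.id, segments=segments)


# ---------------------------------------------------------------------------
# Variant tables with planted composition
# ---------------------------------------------------------------------------

QTY_PAIRS_NO_VT = [("L", "Q"), ("I", "T"), ("F", "Y")]
RQTY_PAIRS_NO_TV = [("Q", "L"), ("T", "I"), ("Y", "F")]
_OTHER_PAIRS = [("A", "G"), ("S", "P"), ("R", "W"), ("D", "N"), ("K", "E"), ("M", "V")]

DEFAULT_LOCATION_MIX = {Location.TM: 0.54, Location.ECL: 0.12, Location.ICL: 0.14,
                        Location.IM: 0.05, Location.INTRACELLULAR: 0.15}
DEFAULT_EFFECT_MIX = {Effect.BENIGN: 0.54, Effect.POSSIBLY_DAMAGING: 0.22,
                      Effect.PROBABLY_DAMAGING: 0.24}


def generate_variant_table(
    seed: int,
    n_qty: int,
    n_rqty: int,
    n_other: int = 0,
    location_mix: dict[Location, float] | None = None,
    effect_mix: dict[Effect, float] | None = None,
    allow_vt: bool = False,
) -> list[VariantRecord]:
    """Variant table with exactly the planted direction composition.

    QTY rows draw from {L->Q, I->T, F->Y} (V->T only with ``allow_vt``,
    off by default to mirror the two-nucleotide barrier that keeps V->T out
    of natural single-base variation); rQTY rows are the inverses.
    """
    rng = _rng(seed, "variants")
    loc_mix = location_mix or DEFAULT_LOCATION_MIX
    eff_mix = effect_mix or DEFAULT_EFFECT_MIX
    locs, loc_p = zip(*sorted(loc_mix.items(), key=lambda kv: kv[0].value))
    effs, eff_p = zip(*sorted(eff_mix.items(), key=lambda kv: kv[0].value))
    loc_p = np.array(loc_p) / sum(loc_p)
    eff_p = np.array(eff_p) / sum(eff_p)

    qty_pairs = QTY_PAIRS_NO_VT + ([("V", "T")] if allow_vt else [])
    rqty_pairs = RQTY_PAIRS_NO_TV + ([("T", "V")] if allow_vt else [])

    records: list[VariantRecord] = []
    used_positions: set[int] = set()

    def draw(pairs: list[tuple[str, str]], count: int) -> None:
        for _ in range(count):
            ref, alt = pairs[int(rng.integers(len(pairs)))]
            position = int(rng.integers(1, 560))
            while position in used_positions:
                position = int(rng.integers(1, 560))
            used_positions.add(position)
            loc = locs[int(rng.choice(len(locs), p=loc_p))]
            label = f"{loc.value}{int(rng.integers(1, 13))}" if loc in {
                Location.TM, Location.ECL, Location.ICL} else loc.value
            structure = (StructureClass.ALPHA_HELIX if rng.random() < 0.8
                         else StructureClass.LOOP)
            records.append(VariantRecord(
                protein_id="SYNPROT",
                ref_aa=ref,
                position=position,
                alt_aa=alt,
                location=loc,
                location_label=label,
                structure=structure,
                exposure=Exposure.EXPOSED if rng.random() < 0.6 else Exposure.BURIED,
                conservation_grade=int(rng.integers(1, 10)),
                predicted_effect=effs[int(rng.choice(len(effs), p=eff_p))],
            ))

    draw(qty_pairs, n_qty)
    draw(rqty_pairs, n_rqty)
    draw(_OTHER_PAIRS, n_other)
    return records


# ---------------------------------------------------------------------------
# Helix-bundle CA coordinates (ideal alpha-helix geometry)
# ---------------------------------------------------------------------------

HELIX_RISE = 1.5        # Angstrom per residue along the axis
HELIX_TURN = 100.0      # degrees per residue
HELIX_RADIUS = 2.3      # CA distance from the helix axis

_HYDROPHOBICS = "LIVFAM"


def generate_helix_bundle(seed: int, n_helices: int = 4, residues_per_helix: int = 20) -> StructureModel:
    """CA trace of parallel ideal helices arranged on a circle (~10 A apart)."""
    if n_helices < 1 or residues_per_helix < 1:
        raise ValueError("counts must be >= 1")
    rng = _rng(seed, "bundle")
    if n_helices == 1:
        centres = np.zeros((1, 2))
    else:
        bundle_radius = 10.0 / (2.0 * np.sin(np.pi / n_helices))
        angles = 2 * np.pi * np.arange(n_helices) / n_helices
        centres = bundle_radius * np.column_stack([np.cos(angles), np.sin(angles)])
    coords = []
    residues = []
    indices = []
    idx = 1
    for h in range(n_helices):
        phase = float(rng.uniform(0, 2 * np.pi))
        for r in range(residues_per_helix):
            theta = phase + np.deg2rad(HELIX_TURN) * r
            coords.append([
                centres[h, 0] + HELIX_RADIUS * np.cos(theta),
                centres[h, 1] + HELIX_RADIUS * np.sin(theta),
                HELIX_RISE * r,
            ])
            residues.append(_HYDROPHOBICS[int(rng.integers(len(_HYDROPHOBICS)))])
            indices.append(idx)
            idx += 1
    return StructureModel(indices=np.array(indices), residues=residues, coords=np.array(coords))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random proper rotation matrix (QR of a Gaussian matrix)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def perturb_structure(model: StructureModel, sigma: float, seed: int) -> StructureModel:
    """Add isotropic Gaussian noise (sigma in Angstrom) to every CA."""
    rng = _rng(seed, "bundle")
    noise = rng.normal(0.0, sigma, size=model.coords.shape) if sigma > 0 else 0.0
    return StructureModel(
        indices=model.indices.copy(),
        residues=list(model.residues),
        coords=model.coords + noise,
    )


# ---------------------------------------------------------------------------
# Alignments with planted conservation
# ---------------------------------------------------------------------------

def generate_alignment(seed: int, n_rows: int = 20, length: int = 100,
                       conserved_fraction: float = 0.5) -> Alignment:
    """MSA with a planted fraction of invariant columns, the rest i.i.d. uniform."""
    if not 0.0 <= conserved_fraction <= 1.0:
        raise ValueError("conserved_fraction must be in [0, 1]")
    rng = _rng(seed, "msa")
    from .sequences import STANDARD_AAS
    aas = np.array(list(STANDARD_AAS))
    n_conserved = int(round(length * conserved_fraction))
    conserved_cols = set(rng.choice(length, size=n_conserved, replace=False).tolist())
    cols = []
    for c in range(length):
        if c in conserved_cols:
            cols.append(np.repeat(rng.choice(aas), n_rows))
        else:
            cols.append(rng.choice(aas, size=n_rows))
    matrix = np.column_stack(cols)
    rows = ["".join(row) for row in matrix]
    return Alignment(rows=rows, ids=[f"seq{i+1}" for i in range(n_rows)])
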