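"""Standard-genetic-code machinery for single-nucleotide mutation paths.

Works in the RNA alphabet (U, C, A, G); DNA input is transliterated on
entry.  The central objects are codon sets per amino acid, minimum
nucleotide-change distances between amino acids, and the exhaustive list of
single-nucleotide codon paths between two amino acids, each annotated with
the changed position (1-3) and its transition/transversion class.

These primitives explain why the natural QTY substitutions (L->Q, I->T,
F->Y and their reverses) are each one second-position base change away,
while V<->T needs at least two nucleotide changes and is accordingly never
observed among the natural variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

RNA_BASES = "UCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")

STOP_SYMBOL = "*"

_STANDARD_RNA = CodonTable.unambiguous_rna_by_id[1]


class ChangeClass(Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"


class SecondBaseClass(Enum):
    """Chemistry conferred by the second codon base (the codon's chemical axis)."""

    HYDROPHOBIC = "hydrophobic"                      # second base U
    LESS_HYDROPHOBIC_OR_OH = "less_hydrophobic_or_OH"  # second base C
    HYDROPHILIC = "hydrophilic"                      # second base A
    MIXED = "mixed"                                  # second base G


_SECOND_BASE_CLASS = {
    "U": SecondBaseClass.HYDROPHOBIC,
    "C": SecondBaseClass.LESS_HYDROPHOBIC_OR_OH,
    "A": SecondBaseClass.HYDROPHILIC,
    "G": SecondBaseClass.MIXED,
}


def _normalize_codon(codon: str) -> str:
    c = codon.upper().replace("T", "U")
    if len(c) != 3 or any(b not in RNA_BASES for b in c):
        raise ValueError(f"not a codon: {codon!r}")
    return c


@dataclass(frozen=True)
class CodonPath:
    """A single-nucleotide codon change, annotated."""

    codon_from: str
    codon_to: str
    position: int  # 1-3
    base_from: str
    base_to: str
    change_class: ChangeClass

    def reversed(self) -> "CodonPath":
        return CodonPath(
            codon_from=self.codon_to,
            codon_to=self.codon_from,
            position=self.position,
            base_from=self.base_to,
            base_to=self.base_from,
            change_class=self.change_class,
        )


@lru_cache(maxsize=None)
def codons_of(aa: str) -> frozenset[str]:
    """Standard-genetic-code codon set of a residue (or '*' for stop)."""
    aa = aa.upper()
    if aa == STOP_SYMBOL:
        return frozenset(_STANDARD_RNA.stop_codons)
    codons = frozenset(c for c, a in _STANDARD_RNA.forward_table.items() if a == aa)
    if not codons:
        raise ValueError(f"unknown amino-acid symbol {aa!r}")
    return codons


def classify_base_change(b1: str, b2: str) -> ChangeClass:
    """Transition (within purines or within pyrimidines) or transversion."""
    b1, b2 = b1.upper().replace("T", "U"), b2.upper().replace("T", "U")
    for b in (b1, b2):
        if b not in RNA_BASES:
            raise ValueError(f"not an RNA base: {b!r}")
    if b1 == b2:
        raise ValueError("bases are identical; no change to classify")
    if (b1 in PURINES) == (b2 in PURINES):
        return ChangeClass.TRANSITION
    return ChangeClass.TRANSVERSION


def hamming(codon1: str, codon2: str) -> int:
    c1, c2 = _normalize_codon(codon1), _normalize_codon(codon2)
    return sum(a != b for a, b in zip(c1, c2))


@lru_cache(maxsize=None)
def min_nt_changes(aa1: str, aa2: str) -> int:
    """Minimum nucleotide Hamming distance over all codon pairs (0-3)."""
    return min(hamming(c1, c2) for c1, c2 in product(codons_of(aa1), codons_of(aa2)))


def single_change_paths(aa1: str, aa2: str) -> list[CodonPath]:
    """All codon pairs of (aa1, aa2) differing at exactly one position.

    Empty exactly when ``min_nt_changes(aa1, aa2) != 1``.  Paths are sorted
    by (codon_from, codon_to) for reproducible output.
    """
    if aa1.upper() == aa2.upper():
        raise ValueError("amino acids are identical")
    paths: list[CodonPath] = []
    for c1, c2 in product(sorted(codons_of(aa1)), sorted(codons_of(aa2))):
        diff = [i for i in range(3) if c1[i] != c2[i]]
        if len(diff) == 1:
            i = diff[0]
            paths.append(
                CodonPath(
                    codon_from=c1,
                    codon_to=c2,
                    position=i + 1,
                    base_from=c1[i],
                    base_to=c2[i],
                    change_class=classify_base_change(c1[i], c2[i]),
                )
            )
    return paths


def second_position_profile(aa: str) -> dict[SecondBaseClass, int]:
    """Chemistry classes of a residue's codons, keyed by class with codon counts.

    Most residues have a single second base and hence one class; serine and
    arginine span two (UCx vs AGy, CGx vs AGy).
    """
    profile: dict[SecondBaseClass, int] = {}
    for codon in sorted(codons_of(aa)):
        cls = _SECOND_BASE_CLASS[codon[1]]
        profile[cls] = profile.get(cls, 0) + 1
    return profile


def distance_matrix() -> dict[tuple[str, str], int]:
    """20x20 matrix of minimum nucleotide changes between standard residues."""
    aas = sorted(set(_STANDARD_RNA.forward_table.values()))
    return {(a, b): min_nt_changes(a, b) for a in aas for b in aas}
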