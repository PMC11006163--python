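"""CA-trace structure model: superposition, burial proxy, hydropathy.

Superposition uses the Kabsch algorithm (SVD of the cross-covariance of
centered coordinate sets, with the reflection corrected so the rotation is
proper) and reports the RMSD over the paired CA atoms.  Pairing is by
residue index, which is the natural choice when comparing a native model
with a same-numbering designed variant; a caller may restrict the pairing
to a subset of indices (e.g. to drop flexible loops).

Residue burial is approximated by a CA coordination number: a residue is
BURIED when it has at least ``cutoff`` other CA atoms within ``radius``.
This is a deliberately simple stand-in for solvent-accessibility
algorithms, adequate for synthetic-geometry tests but not a replacement for
a real accessibility computation on experimental structures.

Hydropathy uses the Kyte-Doolittle scale; the per-position profile is a
sliding-window mean with truncated windows at the chain ends, and the
sequence mean (GRAVY) quantifies overall hydrophobicity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from Bio.SeqUtils import seq1
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .sequences import validate_sequence
from .variants import Exposure

PathLike = Union[str, Path]


@dataclass
class StructureModel:
    """Per-residue CA coordinates in Angstrom, indexed 1-based."""

    indices: np.ndarray           # (n,) int, strictly increasing
    residues: list[str]           # one-letter codes ("X" when unknown)
    coords: np.ndarray            # (n, 3) float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.indices), 3):
            raise ValueError("coords must be (n, 3) matching indices")
        if len(self.residues) != len(self.indices):
            raise ValueError("residues must match indices")
        if len(self.indices) and np.any(np.diff(self.indices) <= 0):
            raise ValueError("residue indices must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.indices)

    def subset(self, indices: Sequence[int]) -> "StructureModel":
        mask = np.isin(self.indices, np.asarray(list(indices), dtype=int))
        return StructureModel(
            indices=self.indices[mask],
            residues=[r for r, m in zip(self.residues, mask) if m],
            coords=self.coords[mask],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        return StructureModel(
            indices=self.indices.copy(),
            residues=list(self.residues),
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
        )


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # (3, 3) proper rotation
    translation: np.ndarray   # (3,) in Angstrom
    rmsd: float
    n_pairs: int
    degenerate: bool = False  # collinear/rank-deficient pairing


def read_pdb_ca(path: PathLike, chain: str | None = None) -> StructureModel:
    """Read one CA per residue from a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties alphabetical).  HETATM records are ignored; a file with no CA
    atoms, or a duplicate residue index surviving altLoc resolution, is an
    error.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    mask = (atoms.atom_name == "CA") & (atoms.element == "C") & ~atoms.hetero
    if chain is not None:
        mask &= atoms.chain_id == chain
    ca = atoms[mask]
    if ca.array_length() == 0:
        raise ValueError(f"no CA atoms found in {path}" + (f" chain {chain}" if chain else ""))
    res_ids = ca.res_id
    uniq, counts = np.unique(res_ids, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1]
        raise ValueError(f"duplicate CA for residue index(es) {dup.tolist()} in {path}")
    order = np.argsort(res_ids, kind="stable")
    letters = []
    for name in ca.res_name[order]:
        try:
            one = seq1(name.capitalize())
        except Exception:
            one = "X"
        letters.append(one if one.isalpha() else "X")
    return StructureModel(
        indices=res_ids[order],
        residues=letters,
        coords=ca.coord[order],
    )


def write_pdb_ca(model: StructureModel, path: PathLike, *, chain: str = "A") -> None:
    """Write a CA-only PDB (plain text, one ATOM record per residue)."""
    lines = []
    for i, (idx, aa, xyz) in enumerate(zip(model.indices, model.residues, model.coords), start=1):
        resname = _one_to_three(aa)
        lines.append(
            f"ATOM  {i:5d}  CA  {resname:>3s} {chain}{idx:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


_ONE_TO_THREE_CACHE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def _one_to_three(aa: str) -> str:
    return _ONE_TO_THREE_CACHE.get(aa.upper(), "UNK")


def kabsch_superpose(
    mobile: StructureModel,
    reference: StructureModel,
    pairing: Sequence[int] | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of mobile onto reference.

    Pairs residues by common residue index (optionally restricted to
    ``pairing``); requires at least 3 pairs.  The optimal rotation comes
    from the SVD of the cross-covariance matrix with the determinant sign
    corrected to +1, so reflections are never returned.  A rank-deficient
    (e.g. collinear) pairing is solved anyway but flagged ``degenerate``.
    """
    common = np.intersect1d(mobile.indices, reference.indices)
    if pairing is not None:
        common = np.intersect1d(common, np.asarray(list(pairing), dtype=int))
    if len(common) < 3:
        raise ValueError(f"need >= 3 paired residues, got {len(common)}")
    P = mobile.subset(common).coords           # mobile
    Q = reference.subset(common).coords        # reference
    cP, cQ = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cP, Q - cQ
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    # rank deficiency of the centered point cloud (collinear or planar-degenerate)
    degenerate = np.linalg.matrix_rank(P0, tol=1e-8) < 2
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=len(common), degenerate=degenerate)


def burial_classes(
    model: StructureModel, radius: float = 10.0, cutoff: int = 14
) -> dict[int, Exposure]:
    """CA coordination-number burial proxy: BURIED iff >= cutoff neighbours within radius."""
    if len(model) == 0:
        raise ValueError("empty structure model")
    tree = cKDTree(model.coords)
    neighbour_counts = np.array([len(tree.query_ball_point(p, radius)) - 1 for p in model.coords])
    return {
        int(idx): (Exposure.BURIED if c >= cutoff else Exposure.EXPOSED)
        for idx, c in zip(model.indices, neighbour_counts)
    }


def hydropathy_profile(sequence: str, window: int = 9) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy, truncated at the ends.

    Position i (0-based output) averages the KD values over
    [i - w//2, i + w//2] intersected with the sequence.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    seq = validate_sequence(sequence)
    if window > len(seq):
        raise ValueError("window longer than sequence")
    values = np.array([KYTE_DOOLITTLE[aa] for aa in seq])
    half = window // 2
    out = np.empty(len(seq))
    for i in range(len(seq)):
        lo, hi = max(0, i - half), min(len(seq), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean KD value over the whole sequence."""
    seq = validate_sequence(sequence)
    return float(np.mean([KYTE_DOOLITTLE[aa] for aa in seq]))
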