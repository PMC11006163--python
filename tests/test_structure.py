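"""CA structures: PDB reading, Kabsch superposition, burial, hydropathy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qtycode as q
from qtycode.variants import Exposure

# ---------------------------------------------------------------------------
# quaternion-method oracle (Horn 1987), independent of the SVD route
# ---------------------------------------------------------------------------

def quaternion_superpose_rmsd(P, Q):
    """Optimal-rotation RMSD via the eigenvector of Horn's 4x4 K matrix."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    Sxx, Sxy, Sxz = (P0[:, 0] @ Q0[:, 0], P0[:, 0] @ Q0[:, 1], P0[:, 0] @ Q0[:, 2])
    Syx, Syy, Syz = (P0[:, 1] @ Q0[:, 0], P0[:, 1] @ Q0[:, 1], P0[:, 1] @ Q0[:, 2])
    Szx, Szy, Szz = (P0[:, 2] @ Q0[:, 0], P0[:, 2] @ Q0[:, 1], P0[:, 2] @ Q0[:, 2])
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    w, v = np.linalg.eigh(K)
    qw, qx, qy, qz = v[:, np.argmax(w)]
    R = np.array([
        [1 - 2 * (qy**2 + qz**2), 2 * (qx * qy - qz * qw), 2 * (qx * qz + qy * qw)],
        [2 * (qx * qy + qz * qw), 1 - 2 * (qx**2 + qz**2), 2 * (qy * qz - qx * qw)],
        [2 * (qx * qz - qy * qw), 2 * (qy * qz + qx * qw), 1 - 2 * (qx**2 + qy**2)],
    ])
    moved = P0 @ R.T
    return float(np.sqrt(np.mean(np.sum((moved - Q0) ** 2, axis=1))))


def model_from_coords(coords, start_index=1):
    n = len(coords)
    return q.StructureModel(
        indices=np.arange(start_index, start_index + n),
        residues=["A"] * n,
        coords=np.asarray(coords, dtype=float),
    )


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       2.000   3.800   0.000  1.00  0.00           C
ATOM      4  CA  LEU A   3       3.100   7.400   1.000  1.00  0.00           C
END
"""

PDB_HETATM_ONLY = """\
HETATM    1  CA  CA  A 101       0.000   0.000   0.000  1.00  0.00          CA
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       2.000   3.800   0.000  1.00  0.00           C
ATOM      4  CA  LEU A   3       3.100   7.400   1.000  1.00  0.00           C
END
"""


def test_read_pdb_ca_basic(tmp_path):
    f = tmp_path / "three.pdb"
    f.write_text(PDB_3RES)
    model = q.read_pdb_ca(f)
    assert len(model) == 3
    assert model.residues == ["A", "G", "L"]
    assert model.indices.tolist() == [1, 2, 3]
    np.testing.assert_allclose(model.coords[0], [1.458, 0.0, 0.0])


def test_read_pdb_ca_hetatm_only_errors(tmp_path):
    f = tmp_path / "het.pdb"
    f.write_text(PDB_HETATM_ONLY)
    with pytest.raises(ValueError, match="no CA"):
        q.read_pdb_ca(f)


def test_read_pdb_ca_altloc_highest_occupancy(tmp_path):
    f = tmp_path / "alt.pdb"
    f.write_text(PDB_ALTLOC)
    model = q.read_pdb_ca(f)
    assert len(model) == 3
    assert model.coords[0][0] == pytest.approx(1.0)  # occ 0.60 conformer kept


def test_pdb_round_trip(tmp_path):
    bundle = q.generate_helix_bundle(seed=5, n_helices=2, residues_per_helix=8)
    path = tmp_path / "bundle.pdb"
    q.write_pdb_ca(bundle, path)
    back = q.read_pdb_ca(path)
    assert back.indices.tolist() == bundle.indices.tolist()
    assert back.residues == bundle.residues
    np.testing.assert_allclose(back.coords, bundle.coords, atol=1e-3)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def test_superpose_self_is_identity():
    model = q.generate_helix_bundle(seed=0, n_helices=2, residues_per_helix=10)
    res = q.kabsch_superpose(model, model)
    assert res.rmsd == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)
    assert res.n_pairs == 20


def test_superpose_recovers_rigid_motion():
    model = q.generate_helix_bundle(seed=0, n_helices=3, residues_per_helix=12)
    theta = np.deg2rad(37.0)
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0],
                  [0, 0, 1]])
    moved = model.transformed(R, np.array([5.0, -2.0, 9.0]))
    res = q.kabsch_superpose(moved, model)
    assert res.rmsd < 1e-6
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


@settings(max_examples=25)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_rigid_motion_invariance_randomized(seed):
    rng = np.random.default_rng(seed)
    model = model_from_coords(rng.normal(size=(30, 3)) * 8)
    moved = model.transformed(q.random_rotation(rng), rng.normal(size=3) * 20)
    assert q.kabsch_superpose(moved, model).rmsd < 1e-6
    # and applying a rigid motion to BOTH leaves any rmsd unchanged
    noisy = model_from_coords(model.coords + rng.normal(scale=0.3, size=(30, 3)))
    base = q.kabsch_superpose(noisy, model).rmsd
    R2, t2 = q.random_rotation(rng), rng.normal(size=3) * 10
    again = q.kabsch_superpose(noisy.transformed(R2, t2), model.transformed(R2, t2)).rmsd
    assert again == pytest.approx(base, abs=1e-6)


@settings(max_examples=25)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_kabsch_agrees_with_quaternion_oracle(seed):
    rng = np.random.default_rng(seed)
    P = rng.normal(size=(10, 3)) * 5
    Q = rng.normal(size=(10, 3)) * 5
    ours = q.kabsch_superpose(model_from_coords(P), model_from_coords(Q)).rmsd
    oracle = quaternion_superpose_rmsd(P, Q)
    assert ours == pytest.approx(oracle, abs=1e-8)
    # fitted rmsd never exceeds the unfitted one
    unfitted = float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
    assert ours <= unfitted + 1e-12


def test_gaussian_noise_rmsd_matches_expectation():
    """sigma = 0.5 A isotropic noise on 200 CAs: rmsd near sigma * sqrt(3)."""
    model = q.generate_helix_bundle(seed=3, n_helices=10, residues_per_helix=20)
    noisy = q.perturb_structure(model, sigma=0.5, seed=77)
    res = q.kabsch_superpose(noisy, model)
    assert res.n_pairs == 200
    assert 0.6 <= res.rmsd <= 1.1


def test_superpose_requires_three_pairs():
    a = model_from_coords([[0, 0, 0], [1, 0, 0]])
    with pytest.raises(ValueError, match="3"):
        q.kabsch_superpose(a, a)


def test_superpose_flags_collinear_input():
    line = model_from_coords([[float(i), 0.0, 0.0] for i in range(5)])
    res = q.kabsch_superpose(line, line)
    assert res.degenerate


def test_superpose_pairing_subset():
    model = q.generate_helix_bundle(seed=9, n_helices=2, residues_per_helix=10)
    res = q.kabsch_superpose(model, model, pairing=range(1, 6))
    assert res.n_pairs == 5


# ---------------------------------------------------------------------------
# burial proxy
# ---------------------------------------------------------------------------

def test_single_residue_is_exposed():
    model = model_from_coords([[0.0, 0.0, 0.0]])
    assert q.burial_classes(model)[1] is Exposure.EXPOSED


def test_dense_cluster_centre_is_buried(rng):
    # 30 points inside a 5 A ball around the origin plus the centre itself
    pts = rng.normal(scale=2.0, size=(30, 3))
    coords = np.vstack([[0.0, 0.0, 0.0], pts])
    model = model_from_coords(coords)
    classes = q.burial_classes(model, radius=10.0, cutoff=14)
    assert classes[1] is Exposure.BURIED


def test_burial_is_deterministic_and_rigid_motion_invariant(rng):
    coords = rng.normal(scale=6.0, size=(40, 3))
    m1 = model_from_coords(coords)
    first = q.burial_classes(m1)
    assert q.burial_classes(m1) == first  # deterministic
    moved = m1.transformed(q.random_rotation(rng), rng.normal(size=3) * 30)
    assert q.burial_classes(moved) == first  # neighbour counts are metric


def test_helix_bundle_surface_vs_core():
    """In a wide ring of helices, residues are less buried than in a tight cluster."""
    sparse = q.generate_helix_bundle(seed=1, n_helices=2, residues_per_helix=10)
    classes = q.burial_classes(sparse, radius=8.0, cutoff=14)
    assert all(v is Exposure.EXPOSED for v in classes.values())


# ---------------------------------------------------------------------------
# hydropathy
# ---------------------------------------------------------------------------

def test_gravy_hand_sums():
    assert q.gravy("LIVF") == pytest.approx(3.825)       # (3.8+4.5+4.2+2.8)/4
    assert q.gravy("QTTY") == pytest.approx(-1.55)       # (-3.5-0.7-0.7-1.3)/4


def test_hydropathy_profile_all_glycine():
    prof = q.hydropathy_profile("G" * 15, window=5)
    np.testing.assert_allclose(prof, -0.4)


def test_hydropathy_profile_window_validation():
    with pytest.raises(ValueError):
        q.hydropathy_profile("GGGG", window=2)
    with pytest.raises(ValueError):
        q.hydropathy_profile("GG", window=5)


@settings(max_examples=20)
@given(st.integers(min_value=0, max_value=999))
def test_qty_transform_always_lowers_tm_hydropathy(seed):
    """Mean TM-segment hydropathy strictly decreases whenever residues change."""
    rec, topo = q.generate_transporter(q.GeneratorConfig(seed=seed, n_tm=4))
    tm_positions = topo.positions_of_kind({q.SegmentKind.TM_HELIX})
    variant = "".join(
        q.QTY_MAP.get(aa, aa) if pos in set(tm_positions) else aa
        for pos, aa in enumerate(rec.sequence, start=1)
    )
    if variant == rec.sequence:
        return
    native_tm = "".join(rec.sequence[p - 1] for p in tm_positions)
    variant_tm = "".join(variant[p - 1] for p in tm_positions)
    assert q.gravy(variant_tm) < q.gravy(native_tm)
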