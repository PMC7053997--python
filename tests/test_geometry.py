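"""Geometric kernels against independent oracles, and PDB round trips."""

import numpy as np
import pytest

from gpcrdyn import geometry as geo
from gpcrdyn.errors import ConfigurationError, FormatError, GeometryError
from gpcrdyn.geometry import (FeatureSeries, Topology, Trajectory,
                              kabsch_superpose, pairwise_rmsd_matrix,
                              read_multimodel_pdb, select_atoms,
                              superposed_rmsd, write_multimodel_pdb)


def _toy_traj(coords, frame_interval_ns=1.0, elements=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    elements = elements or ["C"] * n
    top = Topology(tuple(f"A{i}" for i in range(n)), tuple(range(1, n + 1)),
                   tuple(["ALA"] * n), tuple(["A"] * n), tuple(elements))
    return Trajectory(top, coords, frame_interval_ns)


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def quaternion_rmsd(a, b):
    """Independent minimal-RMSD oracle via the quaternion (key-matrix) method."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key).max()
    msd = (np.sum(a**2) + np.sum(b**2) - 2.0 * lam) / a.shape[0]
    return np.sqrt(max(msd, 0.0))


# --------------------------------------------------------------------- I/O

def test_pdb_round_trip_preserves_coordinates(tmp_path, rng):
    coords = np.round(rng.uniform(-40, 40, size=(5, 12, 3)), 3)
    traj = _toy_traj(coords)
    path = tmp_path / "traj.pdb"
    write_multimodel_pdb(traj, path)
    back = read_multimodel_pdb(path)
    assert back.n_frames == 5
    np.testing.assert_allclose(back.coords, coords, atol=1.5e-3)
    assert back.topology.atom_names == traj.topology.atom_names


def test_single_model_pdb_gives_one_frame(tmp_path, rng):
    traj = _toy_traj(rng.normal(size=(1, 6, 3)))
    path = tmp_path / "one.pdb"
    write_multimodel_pdb(traj, path)
    assert read_multimodel_pdb(path).n_frames == 1


def test_inconsistent_models_raise_format_error(tmp_path):
    lines = [
        "MODEL        1",
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
        "ATOM      2  CB  ALA A   1       1.000   0.000   0.000  1.00  0.00           C",
        "ENDMDL",
        "MODEL        2",
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
        "ENDMDL",
        "END",
    ]
    path = tmp_path / "bad.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(FormatError):
        read_multimodel_pdb(path)


# --------------------------------------------------------------- distances

def test_distance_examples(rng):
    traj = _toy_traj([[[0, 0, 0], [3, 4, 0], [0, 0, 0]]])
    d = geo.interatomic_distance(traj, [0], [1])
    assert d.values[0] == pytest.approx(5.0)
    assert geo.interatomic_distance(traj, [0], [2]).values[0] == 0.0


def test_distance_matches_direct_formula(rng):
    coords = rng.normal(size=(10, 5, 3))
    traj = _toy_traj(coords)
    d = geo.interatomic_distance(traj, [1], [3]).values
    expected = np.sqrt(((coords[:, 1] - coords[:, 3]) ** 2).sum(axis=1))
    np.testing.assert_allclose(d, expected, atol=1e-9)


def test_distance_requires_single_atoms(small_dataset):
    with pytest.raises(ConfigurationError):
        geo.interatomic_distance(small_dataset.trajectory, [0, 1], [2])


# --------------------------------------------------------------- dihedrals

def test_dihedral_planar_cis_and_trans():
    cis = _toy_traj([[[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]]])
    assert geo.dihedral(cis, [0], [1], [2], [3]).values[0] == pytest.approx(0.0, abs=1e-9)
    trans = _toy_traj([[[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]]])
    assert geo.dihedral(trans, [0], [1], [2], [3]).values[0] == pytest.approx(180.0)


def test_dihedral_matches_atan2_oracle(rng):
    def oracle(p):
        b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
        return np.degrees(np.arctan2(y, np.dot(n1, n2)))

    coords = rng.normal(size=(25, 4, 3))
    traj = _toy_traj(coords)
    got = geo.dihedral(traj, [0], [1], [2], [3]).values
    expected = np.array([oracle(p) for p in coords])
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_dihedral_sign_flips_under_mirror(rng):
    coords = rng.normal(size=(8, 4, 3))
    mirrored = coords * np.array([1.0, 1.0, -1.0])
    a = geo.dihedral(_toy_traj(coords), [0], [1], [2], [3]).values
    b = geo.dihedral(_toy_traj(mirrored), [0], [1], [2], [3]).values
    np.testing.assert_allclose(b, -a, atol=1e-9)


def test_collinear_dihedral_is_geometry_error():
    traj = _toy_traj([[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]]])
    with pytest.raises(GeometryError):
        geo.dihedral(traj, [0], [1], [2], [3])


# ------------------------------------------------------------- centers of mass

def test_com_distance_examples():
    traj = _toy_traj([[[0, 0, 0], [0, 0, 2], [1, 0, 0], [1, 0, 2]]])
    d = geo.com_distance(traj, [0, 1], [2, 3])
    assert d.values[0] == pytest.approx(1.0)
    assert geo.com_distance(traj, [0, 1], [0, 1]).values[0] == 0.0


def test_com_mass_weighting_matches_hand_computation(rng):
    coords = rng.normal(size=(3, 4, 3))
    traj = _toy_traj(coords, elements=["C", "N", "O", "S"])
    masses = np.array([12.011, 14.007, 15.999, 32.06])
    got = geo.com_distance(traj, [0, 1], [2, 3]).values
    ca = (coords[:, :2] * masses[:2, None]).sum(axis=1) / masses[:2].sum()
    cb = (coords[:, 2:] * masses[2:, None]).sum(axis=1) / masses[2:].sum()
    np.testing.assert_allclose(got, np.linalg.norm(ca - cb, axis=1), atol=1e-9)


# ------------------------------------------------------------- superposition

def test_kabsch_identical_sets(rng):
    x = rng.normal(size=(7, 3))
    rot, trans, rmsd = kabsch_superpose(x, x)
    assert rmsd == pytest.approx(0.0, abs=1e-6)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-8)


def test_kabsch_recovers_rigid_motion(rng):
    x = rng.normal(size=(10, 3))
    r90 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
    y = x @ r90.T + np.array([3.0, -2.0, 7.0])
    _, _, rmsd = kabsch_superpose(x, y)
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_kabsch_agrees_with_quaternion_oracle(rng):
    for _ in range(30):
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        assert superposed_rmsd(a, b) == pytest.approx(quaternion_rmsd(a, b), abs=1e-9)


def test_kabsch_rotation_is_proper(rng):
    a = rng.normal(size=(5, 3))
    b = -a  # mirror image tempts an improper rotation
    rot, _, _ = kabsch_superpose(a, b)
    assert np.linalg.det(rot) == pytest.approx(1.0)


def test_kabsch_degenerate_inputs():
    with pytest.raises(GeometryError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
    with pytest.raises(GeometryError):
        kabsch_superpose(line, line)


def test_superposed_rmsd_rigid_motion_invariance(rng):
    a = rng.normal(size=(8, 3))
    b = rng.normal(size=(8, 3))
    base = superposed_rmsd(a, b)
    rot = _random_rotation(rng)
    assert superposed_rmsd(a @ rot.T + 5.0, b) == pytest.approx(base, abs=1e-8)
    assert superposed_rmsd(a, b @ rot.T - 2.0) == pytest.approx(base, abs=1e-8)


# ----------------------------------------------------------- pairwise RMSD

def test_pairwise_rmsd_duplicated_frames(rng):
    frame = rng.normal(size=(1, 6, 3))
    traj = _toy_traj(np.repeat(frame, 4, axis=0))
    mat = pairwise_rmsd_matrix(traj, np.arange(6))
    np.testing.assert_allclose(mat.values, 0.0, atol=1e-9)


def test_pairwise_rmsd_rigid_motion_frame(rng):
    a = rng.normal(size=(6, 3))
    b = rng.normal(size=(6, 3))
    rot = _random_rotation(rng)
    c = b @ rot.T + np.array([1.0, 2.0, 3.0])
    mat = pairwise_rmsd_matrix(_toy_traj(np.stack([a, b, c])), np.arange(6))
    assert mat.values[1, 2] == pytest.approx(0.0, abs=1e-6)
    assert mat.values[0, 1] == pytest.approx(mat.values[0, 2], abs=1e-8)


def test_pairwise_rmsd_matches_elementwise_kabsch(rng):
    coords = rng.normal(size=(10, 5, 3))
    traj = _toy_traj(coords)
    mat = pairwise_rmsd_matrix(traj, np.arange(5)).values
    for i in range(10):
        for j in range(10):
            expected = 0.0 if i == j else superposed_rmsd(coords[i], coords[j])
            assert mat[i, j] == pytest.approx(expected, abs=1e-9)


def test_pairwise_rmsd_cross_checked_against_mdtraj(rng):
    mdtraj = pytest.importorskip("mdtraj")
    import pandas as pd

    n = 8
    coords = rng.normal(size=(6, n, 3))
    traj = _toy_traj(coords)
    df = pd.DataFrame({
        "serial": np.arange(1, n + 1), "name": [f"A{i}" for i in range(n)],
        "element": ["C"] * n, "resSeq": np.arange(1, n + 1),
        "resName": ["ALA"] * n, "chainID": [0] * n, "segmentID": [""] * n,
    })
    mtop = mdtraj.Topology.from_dataframe(df, bonds=np.zeros((0, 2), dtype=int))
    mt = mdtraj.Trajectory(coords / 10.0, mtop)  # mdtraj uses nm
    ours = pairwise_rmsd_matrix(traj, np.arange(n)).values
    for ref in range(6):
        theirs = mdtraj.rmsd(mt, mt, frame=ref) * 10.0
        np.testing.assert_allclose(ours[ref], theirs, atol=1e-4)


# -------------------------------------------------------------- selections

def test_select_atoms_classes(toy_spec):
    top = toy_spec.topology
    ca = select_atoms(top, atom_class="CA")
    assert all(top.atom_names[i] == "CA" for i in ca)
    bb = select_atoms(top, residues=[183], atom_class="backbone-heavy")
    assert {top.atom_names[i] for i in bb} == {"N", "CA", "C", "O"}
    sc = select_atoms(top, residues=[100], atom_class="sidechain-heavy")
    assert {top.atom_names[i] for i in sc} == {"CB", "CG", "CD1", "CD2"}
    with pytest.raises(ConfigurationError):
        select_atoms(top, residues=[9999])


def test_feature_series_tsv(tmp_path):
    fs = FeatureSeries(np.array([1.0, 2.0]), np.array([0.0, 0.6]), "d")
    out = tmp_path / "f.tsv"
    fs.to_tsv(out)
    import pandas as pd
    df = pd.read_csv(out, sep="\t")
    assert list(df.columns) == ["frame", "time_ns", "value"]
    assert df.value.tolist() == [1.0, 2.0]
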