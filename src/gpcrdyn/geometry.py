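"""Structure/trajectory containers and geometric kernels.

The in-memory trajectory is a thin, array-backed container: an immutable
topology (atom metadata shared by all frames) plus a ``(n_frames, n_atoms, 3)``
coordinate array in Angstrom.  On-disk exchange uses multi-model PDB through
biotite; all kernels (distances, dihedrals, mass-weighted centers, Kabsch
superposition, pairwise RMSD matrices) operate directly on the coordinate
arrays so they can be vectorized over frames and frame pairs.

Conventions
-----------
* Coordinates are Angstrom throughout; frame times derive from
  ``frame_interval_ns``.
* Dihedrals are signed IUPAC torsions in degrees, range (-180, 180].
* Centers of mass are mass-weighted with standard atomic masses by default;
  an unweighted geometric centroid is available via ``weights="geometric"``.
* Pairwise RMSD uses a per-pair optimal (Kabsch) superposition on the same
  atom selection used for the RMSD itself; no common reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .errors import ConfigurationError, FormatError, GeometryError

__all__ = [
    "Topology",
    "Trajectory",
    "FeatureSeries",
    "RmsdMatrix",
    "select_atoms",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "interatomic_distance",
    "dihedral",
    "com_distance",
    "kabsch_superpose",
    "superposed_rmsd",
    "pairwise_rmsd_matrix",
    "cross_rmsd",
]

# Standard atomic masses (u) for the elements that occur in protein/ligand
# heavy-atom models; hydrogens included for completeness.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078,
    "ZN": 65.38, "FE": 55.845,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Topology:
    """Ordered per-atom metadata shared by all frames of a trajectory."""

    atom_names: tuple[str, ...]
    residue_seq: tuple[int, ...]
    residue_names: tuple[str, ...]
    chains: tuple[str, ...]
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for f in (self.residue_seq, self.residue_names, self.chains, self.elements):
            if len(f) != n:
                raise ConfigurationError("topology fields must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASSES[e.upper()] for e in self.elements])
        except KeyError as exc:  # pragma: no cover - guarded by construction
            raise ConfigurationError(f"unknown element {exc} in topology") from exc


@dataclass
class Trajectory:
    """Frames of coordinates over a fixed topology.

    Parameters
    ----------
    topology : Topology
    coords : ndarray, shape (n_frames, n_atoms, 3), Angstrom
    frame_interval_ns : float
        Time between successive frames, ns. Frame times are
        ``frame_index * frame_interval_ns``.
    """

    topology: Topology
    coords: np.ndarray
    frame_interval_ns: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ConfigurationError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ConfigurationError("trajectory needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ConfigurationError("coords incongruent with topology")
        if not np.all(np.isfinite(self.coords)):
            raise ConfigurationError("coordinates must be finite")
        if self.frame_interval_ns <= 0:
            raise ConfigurationError("frame_interval_ns must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ns

    def slice_frames(self, index) -> "Trajectory":
        return Trajectory(self.topology, self.coords[index], self.frame_interval_ns)


@dataclass
class FeatureSeries:
    """A scalar geometric feature evaluated per frame."""

    values: np.ndarray
    times_ns: np.ndarray
    name: str = "feature"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.values.shape != self.times_ns.shape:
            raise ConfigurationError("values and times must align")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self.values)), "time_ns": self.times_ns,
             "value": self.values}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class RmsdMatrix:
    """Symmetric frame-by-frame RMSD matrix with per-frame stratum labels.

    ``frame_labels`` carries one row per frame with at least the columns
    ``condition`` (e.g. ligand complex) and ``el2_state`` (helical/extended);
    it is what the stratified clustering operates on.
    """

    values: np.ndarray
    frame_labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ConfigurationError("RMSD matrix must be square")
        if len(self.frame_labels) != n:
            raise ConfigurationError("frame_labels must have one row per frame")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ConfigurationError("RMSD matrix must be symmetric")
        if np.any(self.values < -1e-12):
            raise ConfigurationError("RMSD entries must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_csv(self, matrix_path, labels_path) -> None:
        pd.DataFrame(self.values).to_csv(matrix_path, index=False, header=False)
        self.frame_labels.to_csv(labels_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def select_atoms(
    topology: Topology,
    residues: Iterable[int] | None = None,
    atom_class: str = "any",
    names: Iterable[str] | None = None,
) -> np.ndarray:
    """Resolve a deterministic, ordered atom-index list on a topology.

    Parameters
    ----------
    residues : iterable of int, optional
        Residue sequence numbers to keep (all residues if omitted).
    atom_class : {"any", "CA", "backbone-heavy", "sidechain-heavy"}
    names : iterable of str, optional
        Explicit atom names to keep (applied after ``atom_class``).

    Returns the selected atom indices in topology order. Raises
    :class:`ConfigurationError` if the selection is empty.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    if residues is not None:
        residues = set(int(r) for r in residues)
        mask &= np.array([r in residues for r in topology.residue_seq])
    anames = np.array(topology.atom_names)
    elems = np.array([e.upper() for e in topology.elements])
    if atom_class == "CA":
        mask &= anames == "CA"
    elif atom_class == "backbone-heavy":
        mask &= np.isin(anames, BACKBONE_ATOMS) & (elems != "H")
    elif atom_class == "sidechain-heavy":
        mask &= ~np.isin(anames, BACKBONE_ATOMS) & (elems != "H")
    elif atom_class != "any":
        raise ConfigurationError(f"unknown atom_class {atom_class!r}")
    if names is not None:
        mask &= np.isin(anames, list(names))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ConfigurationError("atom selection resolved to zero atoms")
    return idx


def _single_atom(topology: Topology, sel) -> int:
    idx = np.atleast_1d(np.asarray(sel, dtype=int))
    if idx.size != 1:
        raise ConfigurationError(f"selection must resolve to exactly one atom, got {idx.size}")
    return int(idx[0])


# ---------------------------------------------------------------------------
# Multi-model PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def _stack_to_trajectory(stack: struc.AtomArrayStack, frame_interval_ns: float) -> Trajectory:
    top = Topology(
        atom_names=tuple(stack.atom_name),
        residue_seq=tuple(int(r) for r in stack.res_id),
        residue_names=tuple(stack.res_name),
        chains=tuple(stack.chain_id),
        elements=tuple(stack.element),
    )
    return Trajectory(top, np.array(stack.coord, dtype=float), frame_interval_ns)


def read_multimodel_pdb(path, frame_interval_ns: float = 1.0) -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file into a :class:`Trajectory`.

    All models must share the same atom ordering and count; a file whose
    models disagree raises :class:`FormatError`.
    """
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        raise FormatError(f"cannot parse multi-model PDB {path}: {exc}") from exc
    if stack.stack_depth() != n_models:  # pragma: no cover
        raise FormatError("inconsistent model count")
    return _stack_to_trajectory(stack, frame_interval_ns)


def write_multimodel_pdb(trajectory: Trajectory, path) -> None:
    """Write a trajectory as MODEL/ENDMDL records (0.001 A precision)."""
    top = trajectory.topology
    n = top.n_atoms
    atoms = struc.AtomArray(n)
    atoms.atom_name = np.array(top.atom_names)
    atoms.res_id = np.array(top.residue_seq)
    atoms.res_name = np.array(top.residue_names)
    atoms.chain_id = np.array(top.chains)
    atoms.element = np.array(top.elements)
    atoms.coord = trajectory.coords[0]
    stack = struc.stack([atoms] * trajectory.n_frames)
    stack.coord = np.array(trajectory.coords, dtype=np.float32)
    out = pdb.PDBFile()
    out.set_structure(stack)
    out.write(str(path))


# ---------------------------------------------------------------------------
# Geometric kernels
# ---------------------------------------------------------------------------

def interatomic_distance(traj: Trajectory, sel_a, sel_b, name: str = "distance") -> FeatureSeries:
    """Per-frame Euclidean distance (A) between two single atoms."""
    ia = _single_atom(traj.topology, sel_a)
    ib = _single_atom(traj.topology, sel_b)
    d = np.linalg.norm(traj.coords[:, ia] - traj.coords[:, ib], axis=-1)
    return FeatureSeries(d, traj.times_ns, name)


def dihedral(traj: Trajectory, sel_a, sel_b, sel_c, sel_d, name: str = "dihedral") -> FeatureSeries:
    """Signed IUPAC torsion (degrees, (-180, 180]) over four atoms per frame."""
    idx = [_single_atom(traj.topology, s) for s in (sel_a, sel_b, sel_c, sel_d)]
    if len(set(idx)) != 4:
        raise ConfigurationError("dihedral requires four distinct atoms")
    p = traj.coords[:, idx]  # (n_frames, 4, 3)
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-9) or np.any(np.linalg.norm(n2, axis=-1) < 1e-9):
        raise GeometryError("collinear atom triple: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 into the half-open convention (-180, 180]
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return FeatureSeries(ang, traj.times_ns, name)


def center_of_mass(traj: Trajectory, sel, weights: str = "mass") -> np.ndarray:
    """Per-frame centroid of a group, mass-weighted ("mass") or unweighted
    ("geometric"). Returns shape (n_frames, 3)."""
    idx = np.asarray(sel, dtype=int)
    if idx.size == 0:
        raise ConfigurationError("empty group for center of mass")
    if weights == "mass":
        w = traj.topology.masses()[idx]
    elif weights == "geometric":
        w = np.ones(idx.size)
    else:
        raise ConfigurationError(f"unknown weighting {weights!r}")
    w = w / w.sum()
    return np.einsum("fij,i->fj", traj.coords[:, idx], w)


def com_distance(traj: Trajectory, group_a, group_b, weights: str = "mass",
                 name: str = "com_distance") -> FeatureSeries:
    """Per-frame distance between the (mass-weighted) centroids of two groups."""
    ca = center_of_mass(traj, group_a, weights)
    cb = center_of_mass(traj, group_b, weights)
    return FeatureSeries(np.linalg.norm(ca - cb, axis=-1), traj.times_ns, name)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to ``reference``.
    The rotation is proper (det +1).

    Raises :class:`GeometryError` for fewer than 3 atoms or a rank-deficient
    (collinear/degenerate) configuration.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("coordinate sets must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition requires at least 3 atoms")
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    if min(np.linalg.matrix_rank(mc, tol=1e-9), np.linalg.matrix_rank(rc, tol=1e-9)) < 2:
        raise GeometryError("rank-deficient configuration: superposition not unique")
    h = mc.T @ rc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(diag) @ u.T
    msd = (np.sum(mc**2) + np.sum(rc**2) - 2.0 * np.sum(s * diag)) / n
    rmsd = float(np.sqrt(max(msd, 0.0)))
    trans = reference.mean(axis=0) - mobile.mean(axis=0) @ rot.T
    return rot, trans, rmsd


def superposed_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets over rigid transforms."""
    return kabsch_superpose(coords_a, coords_b)[2]


def _batch_pair_rmsd(x: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """Kabsch RMSD for frame pairs (ii, jj) of pre-centered coords x (f, m, 3)."""
    m = x.shape[1]
    sq = np.einsum("fij,fij->f", x, x)
    h = np.einsum("pim,pin->pmn", x[ii], x[jj])  # (n_pairs, 3, 3)
    s = np.linalg.svd(h, compute_uv=False)
    det = np.linalg.det(h)
    # det(H) < 0 implies the optimal rotation flips the sign of the smallest
    # singular value (reflection correction)
    corr = np.where(det < 0, s[:, 0] + s[:, 1] - s[:, 2], s.sum(axis=1))
    msd = (sq[ii] + sq[jj] - 2.0 * corr) / m
    return np.sqrt(np.maximum(msd, 0.0))


def pairwise_rmsd_matrix(
    traj: Trajectory,
    sel,
    frame_labels: pd.DataFrame | None = None,
) -> RmsdMatrix:
    """All-against-all superposed RMSD over an atom selection.

    Each entry (i, j) is the Kabsch-minimal RMSD between frames i and j on the
    selected atoms; each unordered pair is computed once and mirrored. The
    pair computation is batched (3x3 SVDs) so thousands of frames stay cheap.
    """
    idx = np.asarray(sel, dtype=int)
    nf = traj.n_frames
    if nf < 2:
        raise ConfigurationError("pairwise RMSD needs at least 2 frames")
    if idx.size < 3:
        raise GeometryError("selection too small for superposition (need >= 3 atoms)")
    x = traj.coords[:, idx]
    x = x - x.mean(axis=1, keepdims=True)
    ii, jj = np.triu_indices(nf, k=1)
    vals = _batch_pair_rmsd(x, ii, jj)
    mat = np.zeros((nf, nf))
    mat[ii, jj] = vals
    mat[jj, ii] = vals
    if frame_labels is None:
        frame_labels = pd.DataFrame(
            {"condition": ["all"] * nf, "el2_state": ["unknown"] * nf}
        )
    return RmsdMatrix(mat, frame_labels.reset_index(drop=True))


def cross_rmsd(
    traj_a: Trajectory, sel_a, traj_b: Trajectory, sel_b,
    frame_a: int = 0, frame_b: int = 0,
) -> float:
    """Superposed RMSD between one frame of each of two structures.

    The two selections must resolve to equal atom counts in matched order
    (e.g. backbone heavy atoms of aligned binding-site residues of two
    receptors). This is the comparison used to relate two crystal structures'
    binding-site conformations.
    """
    ia = np.asarray(sel_a, dtype=int)
    ib = np.asarray(sel_b, dtype=int)
    if ia.size != ib.size:
        raise ConfigurationError("selections must match atom-for-atom")
    return superposed_rmsd(traj_a.coords[frame_a, ia], traj_b.coords[frame_b, ib])
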