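"""Pairwise-distance difference maps between conformational ensembles.

Compares two simulation ensembles (e.g. a receptor bound to two different
antagonists) by the change in time-averaged pairwise distances, at two
granularities:

* subsegment level — distances between the unweighted Calpha centroids of
  helix subsegments (e.g. the extracellular thirds TM1e..TM7e);
* residue level — distances between the Calpha atoms of the ligand-binding
  residues.

The difference map is (mean distance in ensemble A) - (mean distance in
ensemble B): a negative entry means the pair moved closer in A.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .geometry import Trajectory, select_atoms

__all__ = [
    "D2R_SUBSEGMENTS",
    "D2R_BINDING_SITE",
    "D3R_BINDING_SITE",
    "DiffMap",
    "ensemble_distance_profile",
    "diff_map",
]

# Extracellular subsegments of the D2 receptor's transmembrane helices
# (sequence residue ranges, inclusive).
D2R_SUBSEGMENTS: dict[str, tuple[int, int]] = {
    "TM1e": (31, 38), "TM2e": (92, 96), "TM3e": (104, 113), "TM4e": (166, 172),
    "TM5e": (187, 195), "TM6e": (364, 369), "TM7e": (376, 382),
}

# Ligand-binding residues of D2R and the aligned residues of D3R.
D2R_BINDING_SITE: tuple[int, ...] = (
    91, 94, 95, 100, 110, 111, 114, 115, 118, 119, 122, 167, 184, 189, 190,
    193, 194, 197, 198, 353, 357, 360, 361, 364, 365, 367, 368, 376, 379,
    380, 383, 384, 386, 387,
)
D3R_BINDING_SITE: tuple[int, ...] = (
    86, 89, 90, 96, 106, 107, 110, 111, 114, 115, 118, 165, 183, 188, 189,
    192, 193, 196, 197, 338, 342, 345, 346, 349, 350, 352, 353, 362, 365,
    366, 369, 370, 372, 373,
)


@dataclass
class DiffMap:
    """Mean-distance differences (A) between two ensembles, A - B."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ConfigurationError("diff map must be square over its labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _group_positions(traj: Trajectory, groups) -> tuple[list[str], np.ndarray]:
    """Per-frame representative point of each group: Calpha centroid for a
    residue-range subsegment, the single Calpha for an individual residue."""
    labels, pos = [], []
    if isinstance(groups, dict):  # subsegment map: name -> (first, last) residues
        for name, (a, b) in groups.items():
            idx = select_atoms(traj.topology, residues=range(a, b + 1), atom_class="CA")
            labels.append(name)
            pos.append(traj.coords[:, idx].mean(axis=1))
    else:  # binding-site residue list
        for r in groups:
            idx = select_atoms(traj.topology, residues=[r], atom_class="CA")
            if idx.size != 1:
                raise DataError(f"residue {r} does not resolve to a single Calpha")
            labels.append(str(r))
            pos.append(traj.coords[:, idx[0]])
    return labels, np.stack(pos, axis=1)  # (n_frames, n_groups, 3)


def ensemble_distance_profile(traj: Trajectory, groups,
                              frames: slice | None = None) -> pd.DataFrame:
    """Symmetric matrix of time-averaged pairwise distances (A).

    ``groups`` is either a subsegment map (name -> inclusive residue range;
    the group position is the unweighted Calpha centroid) or an iterable of
    binding-site residue numbers (single Calpha atoms). ``frames`` restricts
    the averaging window (e.g. the final stretch of a trajectory).
    """
    if frames is not None:
        traj = traj.slice_frames(frames)
    labels, pos = _group_positions(traj, groups)
    diff = pos[:, :, None, :] - pos[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1).mean(axis=0)
    return pd.DataFrame(dist, index=labels, columns=labels)


def diff_map(profile_a: pd.DataFrame, profile_b: pd.DataFrame) -> DiffMap:
    """Element-wise difference of two distance profiles (A - B).

    Negative entries: the pair is closer in ensemble A. Swapping the
    arguments negates the map exactly.
    """
    if list(profile_a.index) != list(profile_b.index):
        raise DataError("profiles must share an identical label set")
    return DiffMap(tuple(profile_a.index), profile_a.to_numpy() - profile_b.to_numpy())


def load_groups_json(path):
    """Load a subsegment map or binding-site list from JSON."""
    obj = json.loads(Path(path).read_text())
    if isinstance(obj, dict):
        return {k: (int(v[0]), int(v[1])) for k, v in obj.items()}
    return [int(r) for r in obj]
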