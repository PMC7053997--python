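"""Discrete conformational-state classification of geometric features.

Three discretizations used throughout the analyses:

* EL2 secondary-structure proxy: the Ile183(C=O)-Asn186(N-H) backbone
  hydrogen bond of the second extracellular loop, measured as the heavy-atom
  N-O distance. Below 4 A the loop's C-terminal stretch is helical; above it
  the helix has unwound to an extended conformation.
* Sidechain chi rotamer bins: gauche-, gauche+ and trans thirds of the
  torsion circle.
* Ile3.40 sub-pocket occupancy: whether a ligand probe atom sits inside the
  small cavity enclosed by the Calpha atoms of residues 3.40, 5.47 and 6.44.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .geometry import FeatureSeries, Trajectory, center_of_mass

__all__ = [
    "StateSeries",
    "classify_el2",
    "classify_rotamer",
    "subpocket_occupancy",
    "EL2_CUTOFF_ANGSTROM",
    "SUBPOCKET_CUTOFF_ANGSTROM",
]

EL2_CUTOFF_ANGSTROM = 4.0
# The sub-pocket occupancy criterion is a convention of this implementation:
# no numeric cutoff exists in the literature for this cavity.
SUBPOCKET_CUTOFF_ANGSTROM = 4.5


@dataclass
class StateSeries:
    """Per-frame categorical labels aligned to a trajectory."""

    labels: np.ndarray
    categories: tuple[str, ...]
    source_feature: str = ""
    threshold_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(self.categories)
        if bad:
            raise DataError(f"labels outside declared categories: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.categories}

    def fractions(self) -> dict[str, float]:
        n = len(self.labels)
        return {c: v / n for c, v in self.counts().items()}

    def to_tsv(self, path) -> None:
        pd.DataFrame({"frame": np.arange(len(self.labels)), "label": self.labels}).to_csv(
            path, sep="\t", index=False)

    def manifest(self) -> str:
        return json.dumps(
            {"source_feature": self.source_feature,
             "categories": list(self.categories),
             "thresholds": self.threshold_record}, indent=2)


def classify_el2(distance_series: FeatureSeries,
                 cutoff: float = EL2_CUTOFF_ANGSTROM) -> StateSeries:
    """Two-state EL2 classification from the Ile183-Asn186 N-O distance.

    ``helical`` iff distance < cutoff (default 4 A), else ``extended``.
    """
    d = np.asarray(distance_series.values)
    if np.any(d <= 0):
        raise DataError("distances must be positive")
    labels = np.where(d < cutoff, "helical", "extended")
    return StateSeries(labels, ("helical", "extended"),
                       source_feature=distance_series.name,
                       threshold_record={"cutoff_angstrom": cutoff})


def classify_rotamer(chi_series: FeatureSeries) -> StateSeries:
    """Three-state chi rotamer classification.

    Bins on (-180, 180]: gauche- for chi in (-120, 0), gauche+ for chi in
    [0, 120), trans otherwise — each boundary belongs to exactly one bin
    (-120 and 120 are trans, 0 is gauche+).
    """
    chi = np.asarray(chi_series.values)
    if np.any(chi <= -180.0) or np.any(chi > 180.0):
        raise DataError("angles must lie in (-180, 180]")
    labels = np.full(chi.shape, "trans", dtype=object)
    labels[(chi > -120.0) & (chi < 0.0)] = "gauche-"
    labels[(chi >= 0.0) & (chi < 120.0)] = "gauche+"
    return StateSeries(labels, ("gauche-", "gauche+", "trans"),
                       source_feature=chi_series.name,
                       threshold_record={"bins": "gauche-: (-120,0), gauche+: [0,120), trans: rest"})


def subpocket_occupancy(
    traj: Trajectory,
    probe,
    pocket,
    cutoff: float = SUBPOCKET_CUTOFF_ANGSTROM,
) -> StateSeries:
    """Per-frame occupancy of the Ile3.40 sub-pocket by a ligand probe atom.

    ``occupied`` iff the probe-to-pocket-centroid distance is below ``cutoff``;
    the pocket is the unweighted centroid of exactly three Calpha atoms
    (residues 3.40, 5.47, 6.44).
    """
    pocket = np.asarray(pocket, dtype=int)
    if pocket.size != 3:
        raise ConfigurationError(
            f"pocket selection must resolve to exactly 3 atoms, got {pocket.size}")
    probe = np.atleast_1d(np.asarray(probe, dtype=int))
    if probe.size != 1:
        raise ConfigurationError("probe must be a single atom")
    centroid = center_of_mass(traj, pocket, weights="geometric")
    d = np.linalg.norm(traj.coords[:, probe[0]] - centroid, axis=-1)
    labels = np.where(d < cutoff, "occupied", "vacant")
    return StateSeries(labels, ("occupied", "vacant"),
                       source_feature="probe-to-subpocket-centroid distance",
                       threshold_record={"cutoff_angstrom": cutoff})
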