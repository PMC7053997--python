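"""Binding-site conformation clustering with average-pairwise-RMSD statistics.

The procedure: draw a stratified sample of frames (equal numbers per
condition x EL2-state stratum), compute the frame-pairwise RMSD matrix over
the binding-site backbone heavy atoms, k-means-cluster the frames using the
rows of that matrix as feature vectors, and summarize each cluster by

* apRMSD — the mean pairwise RMSD over all frame pairs within a cluster
  (diagonal) or across two clusters (off-diagonal), and
* composition — the percentage of each cluster's frames belonging to each
  condition and to each EL2 state, normalized per stratification axis.

The selection + clustering is repeated ``n_repeats`` times with fresh frame
draws; clusters are matched across repeats by Hungarian assignment on their
condition-composition profiles, and composition means and standard
deviations over the repeats are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .errors import ConfigurationError, DataError, EstimationError
from .geometry import RmsdMatrix

__all__ = [
    "ClusterConfig",
    "ClusterResult",
    "stratified_sample",
    "kmeans_cluster",
    "summarize_clusters",
    "repeat_and_average",
    "centroid_frames",
]


@dataclass(frozen=True)
class ClusterConfig:
    """Knobs of the clustering protocol (defaults follow the study design:
    4 clusters, 20 random k-means starts, 20 repeat runs, 1000 frames per
    condition x EL2-state stratum)."""

    k: int = 4
    n_starts: int = 20
    n_repeats: int = 20
    n_per_stratum: int = 1000
    seed: int = 0
    embedding: str = "rows"  # "rows": RMSD-matrix rows as features; "mds": classical MDS

    def __post_init__(self) -> None:
        for name in ("k", "n_starts", "n_repeats", "n_per_stratum"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.embedding not in ("rows", "mds"):
            raise ConfigurationError(f"unknown embedding {self.embedding!r}")


@dataclass
class ClusterResult:
    """Assignments, apRMSD matrix, composition table and centroid frames.

    ``composition`` has one row per (cluster, axis, category) with mean and
    sd percentage over repeats; percentages within one (cluster, axis) sum
    to 100.
    """

    assignments: np.ndarray          # (n_repeats, n_frames) cluster ids, aligned across repeats
    apRMSD: np.ndarray               # (k, k), from the first repeat
    composition: pd.DataFrame
    centroids: np.ndarray            # frame ids (into the sampled frames of repeat 0)
    frame_ids: np.ndarray | None = None   # sampled original frame ids per repeat


def stratified_sample(
    frame_table: pd.DataFrame,
    n_per_stratum: int,
    seed: int | None = None,
    strata: tuple[str, str] = ("condition", "el2_state"),
) -> np.ndarray:
    """Sample exactly ``n_per_stratum`` frames per (condition, EL2-state)
    stratum, without replacement, deterministically under ``seed``.

    ``frame_table`` needs one row per frame with the stratum columns; the
    returned array holds the selected row indices in sorted order. A stratum
    smaller than the request raises :class:`DataError` naming the stratum.
    """
    rng = np.random.default_rng(seed)
    picked = []
    for key, group in frame_table.groupby(list(strata), sort=True):
        if len(group) < n_per_stratum:
            raise DataError(
                f"stratum {key} has only {len(group)} frames (< {n_per_stratum})")
        picked.append(rng.choice(group.index.to_numpy(), size=n_per_stratum, replace=False))
    return np.sort(np.concatenate(picked))


def _features(matrix: np.ndarray, mode: str, k: int) -> np.ndarray:
    if mode == "rows":
        return matrix
    # classical MDS (Torgerson) on squared distances
    n = matrix.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (matrix**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    ncomp = min(max(k, 2), n)
    w, v = np.clip(w[order[:ncomp]], 0, None), v[:, order[:ncomp]]
    return v * np.sqrt(w)


def kmeans_cluster(matrix: RmsdMatrix | np.ndarray, config: ClusterConfig) -> np.ndarray:
    """K-means over the pairwise-RMSD matrix; returns per-frame cluster ids.

    Rows of the matrix serve as feature vectors (``embedding="rows"``), or a
    classical-MDS embedding (``embedding="mds"``). Best of ``n_starts``
    random initializations by within-cluster sum of squares; deterministic
    under ``config.seed``.
    """
    values = matrix.values if isinstance(matrix, RmsdMatrix) else np.asarray(matrix)
    if not np.all(np.isfinite(values)):
        raise DataError("RMSD matrix must be finite")
    if config.k > values.shape[0]:
        raise ConfigurationError("k exceeds the number of frames")
    feats = _features(values, config.embedding, config.k)
    km = KMeans(n_clusters=config.k, n_init=config.n_starts,
                random_state=config.seed % (2**31), init="random")
    return km.fit_predict(feats)


def summarize_clusters(
    matrix: RmsdMatrix | np.ndarray,
    assignments: np.ndarray,
    frame_labels: pd.DataFrame | None = None,
) -> ClusterResult:
    """apRMSD and composition statistics for one clustering run.

    apRMSD diagonal entries average all unordered frame pairs within a
    cluster; off-diagonal entries average all cross pairs between two
    clusters. Compositions are percentages per cluster, normalized
    separately along each stratification axis.
    """
    if isinstance(matrix, RmsdMatrix):
        values = matrix.values
        if frame_labels is None:
            frame_labels = matrix.frame_labels
    else:
        values = np.asarray(matrix)
    assignments = np.asarray(assignments, dtype=int)
    if assignments.shape[0] != values.shape[0]:
        raise DataError("assignments must cover all frames")
    ids = np.unique(assignments)
    k = len(ids)
    ap = np.zeros((k, k))
    members = [np.flatnonzero(assignments == c) for c in ids]
    for a in range(k):
        ma = members[a]
        if len(ma) > 1:
            sub = values[np.ix_(ma, ma)]
            iu = np.triu_indices(len(ma), k=1)
            ap[a, a] = sub[iu].mean()
        for b in range(a + 1, k):
            ap[a, b] = ap[b, a] = values[np.ix_(ma, members[b])].mean()

    comp_rows = []
    if frame_labels is not None:
        for axis in ("condition", "el2_state"):
            if axis not in frame_labels.columns:
                continue
            col = frame_labels[axis].to_numpy()
            cats = sorted(set(col))
            for a, c in enumerate(ids):
                sub = col[members[a]]
                for cat in cats:
                    pct = 100.0 * np.mean(sub == cat)
                    comp_rows.append({"cluster": int(c), "axis": axis,
                                      "category": cat, "mean": pct, "sd": 0.0})
    composition = pd.DataFrame(comp_rows)
    cents = centroid_frames(values, assignments)
    return ClusterResult(assignments[None, :], ap, composition, cents)


def centroid_frames(matrix: RmsdMatrix | np.ndarray, assignments: np.ndarray) -> np.ndarray:
    """Per cluster, the frame minimizing the mean RMSD to its co-members
    (ties broken by lowest frame id). A singleton cluster's centroid is its
    only frame."""
    values = matrix.values if isinstance(matrix, RmsdMatrix) else np.asarray(matrix)
    assignments = np.asarray(assignments, dtype=int)
    out = []
    for c in np.unique(assignments):
        m = np.flatnonzero(assignments == c)
        if m.size == 0:
            raise EstimationError(f"cluster {c} is empty")
        if m.size == 1:
            out.append(int(m[0]))
            continue
        sub = values[np.ix_(m, m)]
        mean_to_others = sub.sum(axis=1) / (m.size - 1)
        out.append(int(m[np.argmin(mean_to_others)]))  # argmin takes lowest id on ties
    return np.array(out)


def _match_clusters(ref_profile: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Permutation aligning ``profile`` rows onto ``ref_profile`` rows by
    Hungarian assignment on squared profile distance."""
    cost = ((ref_profile[:, None, :] - profile[None, :, :]) ** 2).sum(axis=2)
    _, perm = linear_sum_assignment(cost)
    return perm


def repeat_and_average(
    frame_table: pd.DataFrame,
    matrix_builder,
    config: ClusterConfig,
) -> ClusterResult:
    """Full repeated-clustering protocol with averaged compositions.

    ``matrix_builder(frame_ids)`` must return the RMSD matrix (RmsdMatrix or
    ndarray) over the sampled frames, in sampled-frame order. Each repeat
    draws a fresh stratified sample, clusters it, and computes compositions;
    clusters are aligned across repeats by Hungarian matching on their
    condition-composition profiles, then means and sds over repeats are
    reported. apRMSD and centroid frames come from the first repeat.
    """
    rng = np.random.default_rng(config.seed)
    per_repeat = []
    all_assign, all_frames = [], []
    first_ap, first_cent = None, None
    for r in range(config.n_repeats):
        sub_seed = int(rng.integers(2**31))
        frame_ids = stratified_sample(frame_table, config.n_per_stratum, seed=sub_seed)
        labels = frame_table.loc[frame_ids].reset_index(drop=True)
        mat = matrix_builder(frame_ids)
        assign = kmeans_cluster(mat, replace(config, seed=sub_seed))
        res = summarize_clusters(mat, assign, labels)
        per_repeat.append(res.composition)
        all_assign.append(assign)
        all_frames.append(frame_ids)
        if r == 0:
            first_ap, first_cent = res.apRMSD, res.centroids

    # align clusters across repeats on their full composition profiles
    # (condition alone is ambiguous when two clusters are pure in the same
    # condition and differ only in EL2-state composition)
    def profile(comp: pd.DataFrame) -> np.ndarray:
        return comp.pivot_table(index="cluster", columns=["axis", "category"],
                                values="mean", sort=True).to_numpy()

    ref = profile(per_repeat[0])
    aligned = [per_repeat[0]]
    aligned_assign = [all_assign[0]]
    for comp, assign in zip(per_repeat[1:], all_assign[1:]):
        perm = _match_clusters(ref, profile(comp))
        remap = {int(old): new for new, old in enumerate(perm)}
        comp = comp.assign(cluster=comp.cluster.map(remap))
        aligned.append(comp)
        aligned_assign.append(np.array([remap[a] for a in assign]))

    pooled = pd.concat(aligned, ignore_index=True)
    agg = (pooled.groupby(["cluster", "axis", "category"])["mean"]
           .agg(["mean", "std"]).reset_index()
           .rename(columns={"std": "sd"}))
    agg["sd"] = agg["sd"].fillna(0.0)
    return ClusterResult(np.array(aligned_assign), first_ap, agg, first_cent,
                         frame_ids=np.array(all_frames))
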