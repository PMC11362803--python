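"""Consensus pose selection.

The selection core of consensus (meta-)docking: pool the top-k ranked
poses of every engine, cluster the pooled ensemble hierarchically on
the pairwise heavy-atom RMSD matrix, pick the number of clusters at the
minimum of the Kelley penalty, and report the member of the most
populated cluster nearest its centroid (realised as the
squared-dissimilarity medoid) as the final model.

The Kelley penalty at a cut into k clusters is

    penalty(k) = norm_spread(k) + k,        k = 1 .. N-1

where av_spread(k) is the mean, over clusters of size >= 2, of the mean
within-cluster pairwise dissimilarity, and norm_spread rescales
av_spread linearly across the N-1 levels onto [1, N-1].  The +k term
penalises fragmentation; the minimum balances tight clusters against
their number.  The k = 1 level (everything in one cluster) always
carries the maximum spread and so is never itself the minimum, but its
inclusion in the rescaling is what lets the penalty resolve a genuine
two-cluster structure: without it the k = 2 level would by construction
sit at the top of the normalised scale.  The selected cluster count is
the argmin over k >= 2.  When all levels have equal spread (e.g. an
all-zero matrix) norm_spread is defined as 1 everywhere and the
selection falls to k = 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .geometry import RMSDMatrix
from .structmodel import Pose, ProteinStructure

logger = logging.getLogger(__name__)

LINKAGE_METHODS = ("average", "single", "complete", "ward")


def pool_top_k(ensemble: Sequence[Pose], k: int) -> list[Pose]:
    """Keep each engine's top-k poses by ascending rank.

    Output order is stable: engines in first-appearance order, then
    rank.  An engine with fewer than k poses contributes all of them
    (with a warning).
    """
    if not ensemble:
        raise ValidationError("cannot pool an empty ensemble")
    if k < 1:
        raise ValidationError("k must be >= 1")
    by_engine: dict[str, list[Pose]] = {}
    for pose in ensemble:
        by_engine.setdefault(pose.engine, []).append(pose)
    pooled: list[Pose] = []
    for engine, poses in by_engine.items():
        poses = sorted(poses, key=lambda p: p.rank)
        if len(poses) < k:
            logger.warning("engine %r has only %d poses (< top_k=%d); taking all",
                           engine, len(poses), k)
        pooled.extend(poses[:k])
    return pooled


@dataclass
class Dendrogram:
    """Agglomerative merge tree over an ensemble."""

    pose_ids: list[str]
    linkage_matrix: np.ndarray   # scipy (N-1, 4) linkage encoding
    linkage_method: str

    @property
    def n(self) -> int:
        return len(self.pose_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Integer labels (0-based, arbitrary) of the k-cluster partition."""
        if k < 1 or k > self.n:
            raise ValidationError(f"cannot cut {self.n} poses into {k} clusters")
        return hierarchy.cut_tree(self.linkage_matrix, n_clusters=k).ravel()


def hierarchical_cluster(matrix: RMSDMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of the pose dissimilarity matrix."""
    if linkage not in LINKAGE_METHODS:
        raise ValidationError(f"unknown linkage {linkage!r}; expected one of {LINKAGE_METHODS}")
    if matrix.n < 3:
        raise ValidationError("clustering needs at least 3 poses")
    condensed = squareform(matrix.values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(list(matrix.pose_ids), Z, linkage)


@dataclass
class KelleyProfile:
    """Per-level records (k, av_spread, norm_spread, penalty), k = 1..N-1."""

    levels: np.ndarray
    av_spread: np.ndarray
    norm_spread: np.ndarray
    penalty: np.ndarray
    norm_min: float = 1.0

    @property
    def best_k(self) -> int:
        """Penalty argmin over the non-trivial levels k >= 2.

        Ties resolve to the smallest k because levels are ascending.
        """
        sel = self.levels >= 2
        return int(self.levels[sel][int(np.argmin(self.penalty[sel]))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.levels,
            "av_spread": self.av_spread,
            "norm_spread": self.norm_spread,
            "penalty": self.penalty,
        })


def _cluster_spread(values: np.ndarray, members: np.ndarray) -> float:
    """Mean pairwise dissimilarity within one cluster (size >= 2)."""
    sub = values[np.ix_(members, members)]
    m = len(members)
    return float(np.sum(np.triu(sub, k=1)) / (m * (m - 1) / 2))


def _average_spread(values: np.ndarray, labels: np.ndarray) -> float:
    spreads = []
    for label in np.unique(labels):
        members = np.flatnonzero(labels == label)
        if len(members) >= 2:
            spreads.append(_cluster_spread(values, members))
    return float(np.mean(spreads)) if spreads else 0.0


def kelley_profile(dendrogram: Dendrogram, matrix: RMSDMatrix,
                   norm_min: float = 1.0) -> KelleyProfile:
    """Kelley penalty across every dendrogram level k = 1..N-1.

    norm_spread maps av_spread linearly onto [norm_min, N-1] — one unit
    per level, so the rescaled spread and the +k term are commensurate.
    When all spreads are equal the map is degenerate and
    norm_spread := norm_min at every level, so the penalty reduces to
    norm_min + k (selection then falls to the smallest non-trivial
    level, k = 2).
    """
    n = dendrogram.n
    if n < 4:
        raise ValidationError("Kelley profile needs at least 4 poses (>= 2 levels)")
    if dendrogram.pose_ids != matrix.pose_ids:
        raise ValidationError("dendrogram and matrix pose ids differ")
    levels = np.arange(1, n)
    av = np.array([
        _average_spread(matrix.values, dendrogram.cut(int(k))) for k in levels
    ])
    lo, hi = float(av.min()), float(av.max())
    norm_max = norm_min + float(len(levels) - 1)
    if hi - lo < 1e-12:
        norm = np.full_like(av, norm_min)
    else:
        norm = norm_min + (norm_max - norm_min) * (av - lo) / (hi - lo)
    penalty = norm + levels
    return KelleyProfile(levels, av, norm, penalty, norm_min)


@dataclass
class ConsensusResult:
    """Chosen partition and the final-model pose."""

    chosen_k: int
    partition: dict[str, int]
    top_cluster: int
    representative: str
    cluster_sizes: dict[int, int]
    cluster_spreads: dict[int, float]

    def to_frame(self, poses: Optional[Sequence[Pose]] = None) -> pd.DataFrame:
        meta = {p.pose_id: p for p in poses} if poses else {}
        rows = []
        for pose_id, label in self.partition.items():
            row = {"pose_id": pose_id, "cluster": label,
                   "is_representative": pose_id == self.representative}
            if pose_id in meta:
                row["engine"] = meta[pose_id].engine
                row["rank"] = meta[pose_id].rank
            rows.append(row)
        cols = ["pose_id", "engine", "rank", "cluster", "is_representative"] \
            if meta else ["pose_id", "cluster", "is_representative"]
        return pd.DataFrame(rows)[cols]


def select_consensus(profile: KelleyProfile, dendrogram: Dendrogram,
                     matrix: RMSDMatrix) -> ConsensusResult:
    """Pick k at the penalty minimum and the final-model pose.

    Ties are deterministic: smallest k; most populated cluster, then
    smaller mean spread, then smallest member pose_id; representative is
    the member minimising the mean squared dissimilarity to the other
    members of the top cluster, ties to the smallest pose_id.
    """
    chosen_k = profile.best_k
    labels = dendrogram.cut(chosen_k)
    pose_ids = dendrogram.pose_ids
    ids = np.array(pose_ids)

    sizes: dict[int, int] = {}
    spreads: dict[int, float] = {}
    min_member: dict[int, str] = {}
    for label in np.unique(labels):
        members = np.flatnonzero(labels == label)
        sizes[int(label)] = len(members)
        spreads[int(label)] = (_cluster_spread(matrix.values, members)
                               if len(members) >= 2 else 0.0)
        min_member[int(label)] = min(ids[members])

    top_cluster = min(sizes, key=lambda c: (-sizes[c], spreads[c], min_member[c]))

    members = np.flatnonzero(labels == top_cluster)
    sub = matrix.submatrix(members) ** 2
    if len(members) == 1:
        representative = str(ids[members[0]])
    else:
        cost = sub.sum(axis=1) / (len(members) - 1)
        best = cost.min()
        tied = members[np.flatnonzero(cost <= best + 1e-12)]
        representative = min(ids[tied])

    return ConsensusResult(
        chosen_k=chosen_k,
        partition={pid: int(lab) for pid, lab in zip(pose_ids, labels)},
        top_cluster=int(top_cluster),
        representative=str(representative),
        cluster_sizes=sizes,
        cluster_spreads=spreads,
    )


# ---------------------------------------------------------------------------
# Trajectory subsampling
# ---------------------------------------------------------------------------

def subsample_frames(frames: Sequence[ProteinStructure], times: Sequence[float],
                     interval: float, duration: float) -> list[ProteinStructure]:
    """Snapshots at t = interval, 2*interval, ... <= duration.

    Each target time is matched to the nearest frame within a tolerance
    of interval/2 (unmatched targets are skipped with a warning); t = 0
    is never selected as a target.
    """
    if len(frames) == 0:
        raise ValidationError("empty trajectory")
    if len(frames) != len(times):
        raise ValidationError("frames and timestamps differ in length")
    if interval <= 0:
        raise ValidationError("interval must be positive")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValidationError("timestamps must be sorted")
    n_targets = int(np.floor(duration / interval + 1e-9))
    selected: list[ProteinStructure] = []
    for m in range(1, n_targets + 1):
        target = m * interval
        i = int(np.argmin(np.abs(t - target)))
        if abs(t[i] - target) <= interval / 2 + 1e-9:
            selected.append(frames[i])
        else:
            logger.warning("no frame within %g of target time %g; skipped",
                           interval / 2, target)
    return selected
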