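"""Consensus-docking pose analysis: pool top poses from several engines,
cluster by pairwise heavy-atom RMSD, pick the cluster count with the
Kelley–Gardner–Sutcliffe penalty, and select the medoid of the largest
cluster as the representative complex.

The Kelley penalty at K clusters is the average within-cluster spread
(mean pairwise distance over clusters with ≥2 members), min–max normalised
to [1, n−1] across the candidate K range, plus K itself; the optimal K
minimises the penalty.  The "centroid-closest" representative is the medoid
— the member with minimal mean distance to its cluster — since only a
distance matrix is available in general.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform

from .structures import Frame, Trajectory, read_structure
from .geometry import rmsd

logger = logging.getLogger(__name__)


class HarmonizationError(Exception):
    pass


class DegenerateClusteringError(Exception):
    pass


@dataclass
class PoseEnsemble:
    """Docked two-chain complexes sharing one harmonised heavy-atom set."""

    poses: list[Frame]
    source_engine: list[str]

    def __post_init__(self):
        if len(self.poses) < 2:
            raise ValueError("an ensemble needs at least 2 poses")
        ref = self.poses[0].identity_tuples()
        for k, p in enumerate(self.poses[1:], 1):
            if p.identity_tuples() != ref:
                raise HarmonizationError(f"pose {k} atom identities differ")

    def __len__(self):
        return len(self.poses)


def harmonize(poses: list[Frame], engines: list[str]) -> PoseEnsemble:
    """Reduce poses to the shared heavy-atom identity set, preserving order."""
    heavy = [p.subset(p.element != "H") for p in poses]
    common = set(heavy[0].identity_tuples())
    for p in heavy[1:]:
        common &= set(p.identity_tuples())
    if len(common) < 3:
        raise HarmonizationError("no usable common atom set across poses")
    dropped = max(len(p) for p in heavy) - len(common)
    if dropped:
        logger.warning("harmonization dropped up to %d atoms per pose", dropped)
    out = []
    for p in heavy:
        ids = p.identity_tuples()
        keep = np.array([t in common for t in ids])
        sub = p.subset(keep)
        # impose one canonical order so coordinates align positionally
        order = np.argsort([repr(t) for t in sub.identity_tuples()], kind="stable")
        out.append(sub.subset(order))
    return PoseEnsemble(poses=out, source_engine=list(engines))


def pool_poses(paths, engine_labels, cap_per_engine: int = 10) -> PoseEnsemble:
    """Pool ≤ cap poses per engine file (multi-model PDB), file order kept."""
    poses, engines = [], []
    for path, label in zip(paths, engine_labels):
        traj = read_structure(path)
        for frame in traj.frames[:cap_per_engine]:
            poses.append(frame)
            engines.append(label)
    if len(poses) < 2:
        raise ValueError("pooled fewer than 2 poses")
    return harmonize(poses, engines)


def pairwise_pose_rmsd(ensemble: PoseEnsemble, superpose: bool = True) -> np.ndarray:
    """Symmetric heavy-atom RMSD matrix (Kabsch-superposed by default)."""
    n = len(ensemble)
    d = np.zeros((n, n))
    coords = [p.coords for p in ensemble.poses]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = rmsd(coords[i], coords[j], superpose=superpose)
    return d


def hierarchical_cluster(distance_matrix: np.ndarray,
                         linkage_method: str = "average") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) from a distance matrix."""
    if linkage_method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 2:
        raise ValueError("need a square distance matrix with n >= 2")
    if not np.allclose(d, d.T, atol=1e-8) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return linkage(squareform(d, checks=False), method=linkage_method)


def cluster_labels(merge_tree: np.ndarray, k: int) -> np.ndarray:
    """Flat labels in 1..k from the merge tree."""
    return fcluster(merge_tree, t=k, criterion="maxclust")


def _avg_within_spread(labels: np.ndarray, d: np.ndarray) -> float | None:
    """Mean over multi-member clusters of their mean pairwise distance."""
    spreads = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if len(members) < 2:
            continue
        sub = d[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        spreads.append(float(sub[iu].mean()))
    return float(np.mean(spreads)) if spreads else None


def kelley_select(merge_tree: np.ndarray, distance_matrix: np.ndarray,
                  k_range=None):
    """Kelley-penalty cluster-count selection.

    Returns (selected_k, penalties dict K -> penalty, labels dict K -> labels).
    Spreads are min–max normalised to [1, n−1] across the K range; ties in
    the penalty resolve to the smaller K.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if k_range is None:
        k_range = range(2, n)
    k_range = [int(k) for k in k_range if 2 <= k <= n - 1]
    if not k_range and n == 2:
        k_range = [2]
    spreads, labels_by_k = {}, {}
    for k in k_range:
        labels = cluster_labels(merge_tree, k)
        labels_by_k[k] = labels
        s = _avg_within_spread(labels, d)
        if s is not None:
            spreads[k] = s
    if not spreads:
        raise DegenerateClusteringError(
            "all candidate partitions are singletons-only")
    vals = np.array(list(spreads.values()))
    lo, hi = vals.min(), vals.max()
    penalties = {}
    for k, s in spreads.items():
        norm = 1.0 if hi == lo else 1.0 + (s - lo) * (n - 2) / (hi - lo)
        penalties[k] = norm + k
    selected = min(sorted(penalties), key=lambda k: (penalties[k], k))
    return selected, penalties, labels_by_k


def representatives(labels: np.ndarray, distance_matrix: np.ndarray):
    """Medoid per cluster and the largest cluster's pick.

    Returns (dict cluster -> medoid index, largest-cluster medoid index).
    Cluster-size ties go to the cluster containing the lowest pose index.
    """
    labels = np.asarray(labels)
    d = np.asarray(distance_matrix, dtype=float)
    reps: dict[int, int] = {}
    best_cluster, best_size, best_first = None, -1, None
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        mean_d = d[np.ix_(members, members)].mean(axis=1)
        reps[int(c)] = int(members[int(np.argmin(mean_d))])
        first = int(members[0])
        if len(members) > best_size or (len(members) == best_size
                                        and first < best_first):
            best_cluster, best_size, best_first = int(c), len(members), first
    return reps, reps[best_cluster]


@dataclass
class ClusteringResult:
    distance_matrix: np.ndarray
    merge_tree: np.ndarray
    penalties: dict
    selected_k: int
    labels: np.ndarray
    representatives: dict
    largest_cluster_representative: int

    def penalty_curve(self):
        import pandas as pd
        return pd.DataFrame(
            {"k": sorted(self.penalties),
             "penalty": [self.penalties[k] for k in sorted(self.penalties)]})

    def labels_table(self, engines=None):
        import pandas as pd
        df = pd.DataFrame({"pose": np.arange(len(self.labels)),
                           "cluster": self.labels})
        if engines is not None:
            df["engine"] = list(engines)
        return df


def cluster_ensemble(ensemble: PoseEnsemble, linkage_method: str = "average",
                     superpose: bool = True, k_range=None) -> ClusteringResult:
    """Full consensus stage: RMSD matrix → tree → Kelley K → medoids."""
    d = pairwise_pose_rmsd(ensemble, superpose=superpose)
    tree = hierarchical_cluster(d, linkage_method)
    k, penalties, labels_by_k = kelley_select(tree, d, k_range)
    labels = labels_by_k[k]
    reps, top = representatives(labels, d)
    return ClusteringResult(
        distance_matrix=d, merge_tree=tree, penalties=penalties,
        selected_k=k, labels=labels, representatives=reps,
        largest_cluster_representative=top,
    )
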