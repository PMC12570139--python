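"""Grouping of top paths into distinct allosteric routes.

Two paths overlap where their residues come spatially close: the overlap
count is the number of residue pairs (one from each path) whose minimum
heavy-atom distance is within a cutoff (12 A by default).  Normalizing by
|p|*|q| and subtracting from 1 gives a dissimilarity in [0, 1] that is free
of path-length bias.  Agglomerative (average-linkage) clustering on this
precomputed dissimilarity is cut at each candidate cluster count and the
silhouette score picks the winner.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .path_graph import Path, PathSet
from .trajectory_io import DistanceMatrix

logger = logging.getLogger(__name__)

DEFAULT_OVERLAP_CUTOFF = 12.0  # A


@dataclass
class PathDissimilarity:
    matrix: np.ndarray      # (n_paths, n_paths) in [0, 1], zero diagonal
    overlap_cutoff: float


@dataclass
class ClusterAssignment:
    labels: np.ndarray              # per-path cluster label in 1..k_star
    k_star: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def cluster_sizes(self) -> dict[int, int]:
        u, c = np.unique(self.labels, return_counts=True)
        return {int(k): int(n) for k, n in zip(u, c)}

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "labels": [int(x) for x in self.labels],
                    "k_star": self.k_star,
                    "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k.items()},
                },
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("path_id\tcluster\n")
            for i, l in enumerate(self.labels):
                fh.write(f"{i}\t{int(l)}\n")
            fh.write("# silhouette_by_k\n")
            for k in sorted(self.silhouette_by_k):
                fh.write(f"# {k}\t{self.silhouette_by_k[k]:.6f}\n")


def path_overlap(
    p: Path, q: Path, dist: DistanceMatrix, overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF
) -> int:
    """Number of cross-path residue pairs within the overlap cutoff."""
    d = dist.distances[np.ix_(list(p.residues), list(q.residues))]
    return int((d <= overlap_cutoff).sum())


def dissimilarity_matrix(
    paths: PathSet, dist: DistanceMatrix, overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF
) -> PathDissimilarity:
    """d(p,q) = 1 - overlap(p,q)/(|p|*|q|), clamped to [0, 1], zero diagonal."""
    n = len(paths)
    if n < 2:
        raise ValueError("need at least 2 paths for a dissimilarity matrix")
    m = np.zeros((n, n))
    plist = paths.paths
    for i in range(n):
        for j in range(i + 1, n):
            ov = path_overlap(plist[i], plist[j], dist, overlap_cutoff)
            d = 1.0 - ov / (len(plist[i].residues) * len(plist[j].residues))
            m[i, j] = m[j, i] = min(1.0, max(0.0, d))
    return PathDissimilarity(matrix=m, overlap_cutoff=overlap_cutoff)


def cluster_paths(
    d: PathDissimilarity,
    k_range: range | list[int] | None = None,
    linkage: str = "average",
) -> ClusterAssignment:
    """Cut an average-linkage tree at each candidate k; keep the silhouette argmax.

    Fewer than 3 paths, or all-identical paths (zero dissimilarity
    everywhere), collapse to a single cluster with a warning.
    """
    n = d.matrix.shape[0]
    if n < 3:
        logger.warning("only %d path(s): returning a single cluster", n)
        return ClusterAssignment(labels=np.ones(n, dtype=int), k_star=1)
    if d.matrix.max() == 0.0:
        logger.warning("all paths identical under the overlap metric; single cluster")
        return ClusterAssignment(labels=np.ones(n, dtype=int), k_star=1)
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    ks = sorted(int(k) for k in k_range if 2 <= int(k) <= n - 1) or [2]

    sil: dict[int, float] = {}
    lab: dict[int, np.ndarray] = {}
    for k in ks:
        model = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage=linkage)
        labels = model.fit_predict(d.matrix)
        lab[k] = labels
        if len(ks) > 1:
            sil[k] = float(silhouette_score(d.matrix, labels, metric="precomputed"))
    k_star = ks[0] if len(ks) == 1 else max(sil, key=lambda k: (sil[k], -k))
    labels = _relabel_by_first_occurrence(lab[k_star])
    return ClusterAssignment(labels=labels, k_star=k_star, silhouette_by_k=sil)


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    """Deterministic labels 1..k in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, l in enumerate(labels):
        mapping.setdefault(int(l), len(mapping) + 1)
        out[i] = mapping[int(l)]
    return out


def cluster_summary(
    assignment: ClusterAssignment, paths: PathSet
) -> dict[int, dict[tuple[int, int], int]]:
    """Per cluster, how many member paths traverse each consecutive residue pair.

    These traversal counts drive the visualization radii (frequent
    connections are drawn thicker).
    """
    out: dict[int, dict[tuple[int, int], int]] = {
        int(c): {} for c in np.unique(assignment.labels)
    }
    for label, path in zip(assignment.labels, paths.paths):
        counts = out[int(label)]
        for a, b in path.edges:
            key = (a, b) if a < b else (b, a)
            counts[key] = counts.get(key, 0) + 1
    return out
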