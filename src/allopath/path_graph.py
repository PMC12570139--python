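"""NMI-weighted residue-contact graph and maximum-cumulative-NMI path tracing.

Residues are nodes; an undirected edge joins residues whose minimum
heavy-atom distance is within the contact cutoff (5 A by default), weighted
by the NMI of their phi motions.  Between every pair of spatially distant
residues (>= 12 A by default) the best communication route is the path
maximizing cumulative NMI.  Dijkstra minimizes nonnegative costs, so each
edge carries cost (1 - NMI) in [0, 1] and the minimum-cost route is reported
with its NMI sum as the score; top-k ranking across all pairs keeps the 500
strongest routes by default.

Nodes are integer residue ordinals into the topology's residue list, which
makes tie-breaking (lexicographic on the ordinal sequence) and canonical
path orientation (lower endpoint first) exact and bit-reproducible.
"""

from __future__ import annotations

import heapq
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

from .mutual_information import NMIMatrix
from .trajectory_io import DistanceMatrix

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 5.0   # A, "within": inclusive
DEFAULT_MIN_SEPARATION = 12.0  # A, "at least": inclusive
DEFAULT_TOP_K = 500

#: edge-cost transforms turning NMI maximization into cost minimization
TRANSFORMS: dict[str, Callable[[float], float]] = {
    "one_minus": lambda w: 1.0 - w,
    "inverse": lambda w: np.inf if w <= 0 else 1.0 / w,
    "neglog": lambda w: np.inf if w <= 0 else -float(np.log(w)),
}


@dataclass(frozen=True)
class Path:
    """A simple path through the contact graph, canonically oriented."""

    residues: tuple[int, ...]   # ordinals; residues[0] < residues[-1]
    score: float                # sum of edge NMI weights

    def __post_init__(self):
        if len(self.residues) < 2:
            raise ValueError("a path needs at least 2 residues")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("path revisits a residue")

    @property
    def edges(self) -> list[tuple[int, int]]:
        return list(zip(self.residues[:-1], self.residues[1:]))

    def labels(self, residue_labels: Sequence[str]) -> list[str]:
        return [residue_labels[i] for i in self.residues]


def canonical(residues: Sequence[int]) -> tuple[int, ...]:
    r = tuple(int(x) for x in residues)
    return r if r[0] <= r[-1] else r[::-1]


@dataclass
class PathSet:
    """Ranked top-k paths (descending score, lexicographic tie-break)."""

    paths: list[Path]
    k: int
    provenance: list[tuple[int, int]] = field(default_factory=list)  # (source, target) per path
    n_unreachable: int = 0

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)

    def path_keys(self) -> set[tuple[int, ...]]:
        return {p.residues for p in self.paths}

    def to_json(self, path: str, residue_labels: Sequence[str] | None = None) -> None:
        payload = {
            "k": self.k,
            "n_unreachable_pairs": self.n_unreachable,
            "paths": [
                {
                    "residues": list(p.residues),
                    "labels": p.labels(residue_labels) if residue_labels else None,
                    "score": p.score,
                    "source": s,
                    "target": t,
                }
                for p, (s, t) in zip(self.paths, self.provenance)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path: str, residue_labels: Sequence[str] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tscore\tsource\ttarget\tresidues\n")
            for rank, (p, (s, t)) in enumerate(zip(self.paths, self.provenance), 1):
                res = p.labels(residue_labels) if residue_labels else [str(i) for i in p.residues]
                fh.write(f"{rank}\t{p.score:.10g}\t{s}\t{t}\t{'-'.join(map(str, res))}\n")


@dataclass
class MotifReport:
    """Occurrence of named residue motifs within top-path sets.

    occurrence = maximum, over the motif's member residues, of the number of
    paths containing that residue summed over replicas; per-replica counts
    are retained alongside.
    """

    motifs: dict[str, dict]  # name -> {members, per_residue_total, per_residue_by_replica, occurrence}

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.motifs, fh, indent=1, sort_keys=True)
            fh.write("\n")


def build_graph(
    nmi: NMIMatrix, dist: DistanceMatrix, contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> nx.Graph:
    """Contact graph: edge iff min heavy-atom distance <= cutoff, weight = NMI."""
    g = nx.Graph(contact_cutoff=contact_cutoff)
    ords = [int(o) for o in nmi.residue_ordinals]
    g.add_nodes_from(ords)
    d = dist.distances
    for a in range(len(ords)):
        for b in range(a + 1, len(ords)):
            i, j = ords[a], ords[b]
            if d[i, j] <= contact_cutoff:
                g.add_edge(i, j, weight=float(nmi.values[a, b]))
    if g.number_of_edges() == 0:
        raise ValueError(
            f"contact graph is empty: no residue pair within {contact_cutoff} A "
            f"(closest off-diagonal distance {np.min(d[d > 0]) if (d > 0).any() else 'n/a'})"
        )
    return g


def select_distant_pairs(
    dist: DistanceMatrix,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    nodes: Iterable[int] | None = None,
) -> list[tuple[int, int]]:
    """All unordered residue pairs at least ``min_separation`` apart (inclusive)."""
    idx = sorted(int(n) for n in nodes) if nodes is not None else list(range(len(dist.distances)))
    pairs = [
        (i, j)
        for a, i in enumerate(idx)
        for j in idx[a + 1:]
        if dist.distances[i, j] >= min_separation
    ]
    if not pairs:
        logger.warning(
            "no residue pair separated by >= %.1f A; no paths will be traced", min_separation
        )
    return pairs


def max_nmi_path(
    graph: nx.Graph, source: int, target: int, transform: str = "one_minus"
) -> Path | None:
    """Best-communication path between two residues, or None if disconnected.

    Dijkstra on edge cost = transform(NMI) with lexicographic tie-breaking:
    among equal-cost routes the lexicographically smallest ordinal sequence
    wins, making reruns bit-identical.  The returned score is the plain sum
    of edge NMI weights.
    """
    if source == target:
        raise ValueError("source and target must differ")
    if source not in graph or target not in graph:
        raise ValueError("source/target not in graph")
    cost_fn = TRANSFORMS[transform]
    # uniform-cost search carrying the path: the heap order (cost, path) is
    # exactly "min cost, then lexicographically smallest route"
    heap: list[tuple[float, tuple[int, ...]]] = [(0.0, (source,))]
    done: set[int] = set()
    while heap:
        cost, route = heapq.heappop(heap)
        node = route[-1]
        if node in done:
            continue
        done.add(node)
        if node == target:
            score = sum(graph[a][b]["weight"] for a, b in zip(route[:-1], route[1:]))
            return Path(residues=canonical(route), score=float(score))
        for nbr in graph[node]:
            if nbr in done:
                continue
            c = cost_fn(graph[node][nbr]["weight"])
            if np.isfinite(c):
                heapq.heappush(heap, (cost + c, route + (nbr,)))
    return None


def trace_all(
    graph: nx.Graph,
    pairs: Sequence[tuple[int, int]],
    k: int = DEFAULT_TOP_K,
    transform: str = "one_minus",
) -> PathSet:
    """One best path per reachable pair, then keep the top-k by NMI score."""
    found: list[tuple[Path, tuple[int, int]]] = []
    unreachable = 0
    for s, t in pairs:
        if s not in graph or t not in graph:
            unreachable += 1
            continue
        p = max_nmi_path(graph, s, t, transform=transform)
        if p is None:
            unreachable += 1
        else:
            found.append((p, (s, t)))
    if not found:
        raise ValueError(
            f"no reachable distant residue pair ({len(pairs)} candidate pairs, "
            f"{unreachable} unreachable)"
        )
    found.sort(key=lambda pt: (-pt[0].score, pt[0].residues))
    found = found[:k]
    return PathSet(
        paths=[p for p, _ in found],
        k=k,
        provenance=[pt for _, pt in found],
        n_unreachable=unreachable,
    )


def filter_by_residues(
    pairs_or_paths, restriction: Iterable[int], mode: str = "endpoint", graph: nx.Graph | None = None
):
    """Restrict tracing to ligand-contact residues.

    mode="endpoint" filters candidate (source, target) pairs to those with at
    least one endpoint in the restriction set (apply before trace_all);
    mode="contains" keeps already-traced paths touching the set.
    """
    restriction = {int(r) for r in restriction}
    if not restriction:
        raise ValueError("restriction residue set is empty")
    if graph is not None:
        missing = sorted(restriction - set(graph.nodes))
        if missing:
            raise ValueError(f"restriction residues not in the residue graph: {missing}")
    if mode == "endpoint":
        return [(s, t) for s, t in pairs_or_paths if s in restriction or t in restriction]
    if mode == "contains":
        ps: PathSet = pairs_or_paths
        keep = [
            (p, prov)
            for p, prov in zip(ps.paths, ps.provenance)
            if restriction.intersection(p.residues)
        ]
        return PathSet(
            paths=[p for p, _ in keep],
            k=ps.k,
            provenance=[prov for _, prov in keep],
            n_unreachable=ps.n_unreachable,
        )
    raise ValueError(f"unknown restriction mode {mode!r}")


def motif_occurrence(
    path_sets: Sequence[PathSet], motifs: dict[str, Iterable[int]]
) -> MotifReport:
    """Count motif-residue hits in the top paths of one or more replicas."""
    if not path_sets:
        raise ValueError("need at least one replica PathSet")
    report: dict[str, dict] = {}
    for name, members in motifs.items():
        members = [int(m) for m in members]
        by_rep = []
        for ps in path_sets:
            by_rep.append(
                {str(m): sum(1 for p in ps.paths if m in p.residues) for m in members}
            )
        total = {str(m): sum(rep[str(m)] for rep in by_rep) for m in members}
        report[name] = {
            "members": members,
            "per_residue_by_replica": by_rep,
            "per_residue_total": total,
            "occurrence": max(total.values()) if total else 0,
        }
    return MotifReport(motifs=report)
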