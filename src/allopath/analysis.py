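"""Shared single-shot analysis core: dihedrals -> NMI -> graph -> top paths.

Both the main pipeline and the bootstrap resampler run exactly this routine,
so a bootstrap replicate is "the same analysis on resampled frames" by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from . import mutual_information as mi
from . import path_graph as pg
from .trajectory_io import DihedralMatrix, DistanceMatrix


@dataclass
class AnalysisConfig:
    """Knobs of the tracing stage (defaults are the published standard settings)."""

    contact_cutoff: float = pg.DEFAULT_CONTACT_CUTOFF    # A, graph edges
    min_separation: float = pg.DEFAULT_MIN_SEPARATION    # A, traced pairs
    top_k: int = pg.DEFAULT_TOP_K
    bins: int = mi.DEFAULT_BINS
    transform: str = "one_minus"
    restriction: list[int] = field(default_factory=list)  # residue ordinals; empty = no filter
    restriction_mode: str = "endpoint"

    def to_dict(self) -> dict:
        return asdict(self)


def trace_from_dihedrals(
    dihedrals: DihedralMatrix, dist: DistanceMatrix, config: AnalysisConfig | None = None
) -> pg.PathSet:
    """NMI matrix, contact graph and top-k path tracing in one call."""
    config = config or AnalysisConfig()
    nmi_mat = mi.nmi_matrix(dihedrals, bins=config.bins)
    graph = pg.build_graph(nmi_mat, dist, contact_cutoff=config.contact_cutoff)
    pairs = pg.select_distant_pairs(dist, config.min_separation, nodes=graph.nodes)
    if config.restriction and config.restriction_mode == "endpoint":
        pairs = pg.filter_by_residues(pairs, config.restriction, "endpoint", graph=graph)
    paths = pg.trace_all(graph, pairs, k=config.top_k, transform=config.transform)
    if config.restriction and config.restriction_mode == "contains":
        paths = pg.filter_by_residues(paths, config.restriction, "contains", graph=graph)
    return paths
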