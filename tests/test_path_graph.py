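"""Contact-graph construction, Dijkstra tracing, ranking, filters, motifs."""

import itertools

import networkx as nx
import numpy as np
import pytest

from allopath.mutual_information import NMIMatrix
from allopath.path_graph import (
    Path, PathSet, build_graph, canonical, filter_by_residues, max_nmi_path,
    motif_occurrence, select_distant_pairs, trace_all,
)
from allopath.trajectory_io import DistanceMatrix


def _nmi(values):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return NMIMatrix(
        values=values,
        entropies=np.ones(n),
        residue_labels=[f"A:{i + 1}" for i in range(n)],
        residue_ordinals=np.arange(n),
        bins=36,
    )


def _dist(values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(
        distances=values, residue_labels=[f"A:{i + 1}" for i in range(len(values))]
    )


def _graph_from_edges(n, edges):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    return g


class TestBuildGraph:
    def test_contact_cutoff_is_inclusive(self):
        d = _dist([[0, 4.9, 5.0], [4.9, 0, 5.1], [5.0, 5.1, 0]])
        w = np.full((3, 3), 0.5)
        g = build_graph(_nmi(w), d, contact_cutoff=5.0)
        assert g.has_edge(0, 1) and g.has_edge(0, 2)
        assert not g.has_edge(1, 2)

    def test_edge_set_matches_exhaustive_pair_scan(self, chain_coupled):
        _, _, _, dihedrals, dist = chain_coupled
        from allopath.mutual_information import nmi_matrix

        m = nmi_matrix(dihedrals)
        g = build_graph(m, dist)
        ords = list(m.residue_ordinals)
        expected = {
            (min(i, j), max(i, j))
            for i, j in itertools.combinations(ords, 2)
            if dist.distances[i, j] <= 5.0
        }
        assert {tuple(sorted(e)) for e in g.edges} == expected
        # the line fixture only touches sequence neighbors: a path graph
        assert expected == {(i, i + 1) for i in range(1, 9)}

    def test_no_contacts_is_fatal(self):
        d = _dist(np.array([[0.0, 30.0], [30.0, 0.0]]))
        with pytest.raises(ValueError, match="empty"):
            build_graph(_nmi(np.eye(2)), d, contact_cutoff=5.0)


class TestDistantPairs:
    def test_separation_threshold_inclusive(self):
        d = _dist([[0, 15.0, 10.0], [15.0, 0, 12.0], [10.0, 12.0, 0]])
        assert select_distant_pairs(d, 12.0) == [(0, 1), (1, 2)]

    def test_chain_fixture_pairs(self, chain_coupled):
        _, _, _, _, dist = chain_coupled
        pairs = select_distant_pairs(dist, 12.0)
        assert (0, 4) in pairs       # ~15 A along the chain
        assert (0, 2) not in pairs   # well inside 12 A
        assert pairs == sorted(pairs)

    def test_all_close_yields_empty_with_warning(self, caplog):
        d = _dist(np.full((3, 3), 3.0) - 3.0 * np.eye(3))
        with caplog.at_level("WARNING"):
            assert select_distant_pairs(d, 12.0) == []
        assert "no residue pair" in caplog.text


class TestMaxNmiPath:
    def test_highest_cumulative_nmi_route_wins(self):
        g = _graph_from_edges(4, [(0, 1, 0.9), (1, 3, 0.9), (0, 2, 0.8), (2, 3, 0.8)])
        p = max_nmi_path(g, 0, 3)
        assert p.residues == (0, 1, 3)
        assert p.score == pytest.approx(1.8)

    def test_single_edge(self):
        g = _graph_from_edges(2, [(0, 1, 0.5)])
        p = max_nmi_path(g, 0, 1)
        assert p.residues == (0, 1) and p.score == pytest.approx(0.5)

    def test_disconnected_pair_returns_none(self):
        g = _graph_from_edges(4, [(0, 1, 0.5), (2, 3, 0.5)])
        assert max_nmi_path(g, 0, 3) is None

    def test_optimal_on_random_graphs_vs_enumeration(self):
        """Dijkstra under the (1 - NMI) cost equals exhaustive enumeration."""
        rng = np.random.default_rng(42)
        for trial in range(200):
            n = int(rng.integers(4, 11))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(0, 2**31)))
            for a, b in g.edges:
                g[a][b]["weight"] = float(np.round(rng.random(), 3))
            nodes = list(g.nodes)
            s, t = rng.choice(nodes, size=2, replace=False)
            got = max_nmi_path(g, int(s), int(t))
            best = None
            for route in nx.all_simple_paths(g, int(s), int(t)):
                cost = sum(1 - g[a][b]["weight"] for a, b in zip(route, route[1:]))
                if best is None or cost < best - 1e-12:
                    best = cost
            if best is None:
                assert got is None
            else:
                got_cost = sum(
                    1 - g[a][b]["weight"] for a, b in zip(got.residues, got.residues[1:])
                )
                assert got_cost == pytest.approx(best, abs=1e-9)

    def test_path_reversal_canonicalization(self):
        g = _graph_from_edges(5, [(0, 1, 0.4), (1, 2, 0.6), (2, 3, 0.4), (3, 4, 0.9)])
        forward = max_nmi_path(g, 0, 4)
        backward = max_nmi_path(g, 4, 0)
        assert forward == backward
        assert forward.residues[0] < forward.residues[-1]

    def test_raising_contact_cutoff_only_adds_edges_and_lowers_route_cost(self, chain_coupled):
        # a larger cutoff yields a superset of edges, so the optimal
        # (1 - NMI) route cost between any fixed pair cannot increase
        _, _, _, dihedrals, dist = chain_coupled
        from allopath.mutual_information import nmi_matrix

        m = nmi_matrix(dihedrals)
        prev_edges: set = set()
        prev_cost = np.inf
        for cutoff in (4.0, 5.0, 8.0):
            g = build_graph(m, dist, contact_cutoff=cutoff)
            edges = {tuple(sorted(e)) for e in g.edges}
            assert prev_edges <= edges
            p = max_nmi_path(g, 1, 9)
            cost = sum(1 - g[a][b]["weight"] for a, b in zip(p.residues, p.residues[1:]))
            assert cost <= prev_cost + 1e-12
            prev_edges, prev_cost = edges, cost


class TestTraceAll:
    def test_k_larger_than_supply_keeps_everything(self):
        g = _graph_from_edges(5, [(i, i + 1, 0.5) for i in range(4)])
        d = np.abs(np.subtract.outer(np.arange(5), np.arange(5))) * 4.0
        pairs = select_distant_pairs(_dist(d), 12.0)
        ps = trace_all(g, pairs, k=500)
        assert len(ps) == len(pairs) == 3
        assert ps.k == 500

    def test_ranking_descending_with_lexicographic_ties(self):
        g = _graph_from_edges(6, [(0, 1, 0.5), (1, 2, 0.5), (3, 4, 0.5), (4, 5, 0.5)])
        ps = trace_all(g, [(3, 5), (0, 2)], k=10)
        scores = [p.score for p in ps]
        assert scores == sorted(scores, reverse=True)
        # equal scores: canonical residue sequence decides
        assert ps.paths[0].residues == (0, 1, 2)
        assert ps.paths[1].residues == (3, 4, 5)

    def test_zero_reachable_pairs_is_fatal(self):
        g = _graph_from_edges(4, [(0, 1, 0.5), (2, 3, 0.5)])
        with pytest.raises(ValueError, match="reachable"):
            trace_all(g, [(0, 3), (1, 2)], k=5)

    def test_deterministic_rerun(self, chain_coupled):
        _, _, _, dihedrals, dist = chain_coupled
        from allopath.analysis import AnalysisConfig, trace_from_dihedrals

        a = trace_from_dihedrals(dihedrals, dist, AnalysisConfig())
        b = trace_from_dihedrals(dihedrals, dist, AnalysisConfig())
        assert [p.residues for p in a] == [p.residues for p in b]
        assert [p.score for p in a] == [p.score for p in b]


class TestRestriction:
    def test_endpoint_mode_filters_pairs(self):
        pairs = [(10, 40), (5, 40)]
        assert filter_by_residues(pairs, {10}, "endpoint") == [(10, 40)]

    def test_full_restriction_is_identity(self):
        pairs = [(1, 5), (2, 6)]
        assert filter_by_residues(pairs, {1, 2, 5, 6}, "endpoint") == pairs

    def test_restricted_paths_subset_of_unrestricted_with_equal_scores(self, chain_coupled):
        _, _, _, dihedrals, dist = chain_coupled
        from allopath.analysis import AnalysisConfig, trace_from_dihedrals

        full = trace_from_dihedrals(dihedrals, dist, AnalysisConfig())
        restricted = trace_from_dihedrals(
            dihedrals, dist, AnalysisConfig(restriction=[1], restriction_mode="endpoint")
        )
        full_scores = {p.residues: p.score for p in full}
        assert len(restricted) > 0
        for p in restricted:
            assert p.residues in full_scores
            assert p.score == full_scores[p.residues]

    def test_unknown_restriction_residue_is_fatal(self):
        g = _graph_from_edges(3, [(0, 1, 0.5), (1, 2, 0.5)])
        with pytest.raises(ValueError, match="99"):
            filter_by_residues([(0, 2)], {99}, "endpoint", graph=g)


class TestMotifOccurrence:
    @staticmethod
    def _path_set(paths):
        ps = [Path(residues=canonical(r), score=1.0) for r in paths]
        return PathSet(paths=ps, k=len(ps), provenance=[(p.residues[0], p.residues[-1]) for p in ps])

    def test_occurrence_is_max_member_frequency(self):
        ps = self._path_set([(10, 11, 40), (10, 12, 41), (12, 40, 50)])
        rep = motif_occurrence([ps], {"m": [10, 12]})
        assert rep.motifs["m"]["per_residue_total"] == {"10": 2, "12": 2}
        assert rep.motifs["m"]["occurrence"] == 2

    def test_absent_motif_residues_count_zero(self):
        ps = self._path_set([(1, 2, 3)])
        assert motif_occurrence([ps], {"m": [7, 8]}).motifs["m"]["occurrence"] == 0

    def test_replica_frequencies_are_summed_and_reported_per_replica(self):
        reps = [
            self._path_set([(1, 2)] * n_paths) for n_paths in (10, 12, 8)
        ]
        rep = motif_occurrence(reps, {"m": [1]})
        assert rep.motifs["m"]["occurrence"] == 30
        assert [r["1"] for r in rep.motifs["m"]["per_residue_by_replica"]] == [10, 12, 8]
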