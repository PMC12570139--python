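"""Spline geometry, viewer script, cluster JSON and STL mesh export."""

import json

import numpy as np
import pytest
import trimesh

from allopath.path_clustering import ClusterAssignment, cluster_summary
from allopath.path_graph import Path, PathSet
from allopath.synthetic_fixtures import make_chain_structure
from allopath.visualization_export import (
    PathSpline, catmull_rom, make_splines, write_cluster_json, write_stl,
    write_viewer_script,
)


def _toy_clustered_paths():
    """Two chain paths in one cluster sharing a middle edge, plus a singleton cluster."""
    structure = make_chain_structure(8)
    paths = PathSet(
        paths=[
            Path(residues=(1, 2, 3, 4), score=2.0),
            Path(residues=(2, 3, 4, 5), score=1.9),
            Path(residues=(4, 5, 6, 7), score=1.5),
        ],
        k=3,
        provenance=[(1, 4), (2, 5), (4, 7)],
    )
    assignment = ClusterAssignment(labels=np.array([1, 1, 2]), k_star=2)
    summary = cluster_summary(assignment, paths)
    return structure, paths, assignment, summary


class TestSplines:
    def test_curve_passes_through_every_control_point(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-10, 10, size=(6, 3))
        curve = catmull_rom(pts, samples_per_segment=10)
        assert curve.shape == (51, 3)
        np.testing.assert_allclose(curve[::10], pts, atol=1e-6)

    def test_two_point_path_degenerates_to_straight_segment(self):
        pts = np.array([[0.0, 0, 0], [3.8, 0, 0]])
        curve = catmull_rom(pts, samples_per_segment=5)
        # all samples on the segment between the two anchors
        assert np.allclose(curve[:, 1:], 0.0, atol=1e-9)
        assert np.all(np.diff(curve[:, 0]) > 0)

    def test_radii_scale_with_traversal_counts(self):
        structure, paths, assignment, summary = _toy_clustered_paths()
        splines = make_splines(assignment, summary, paths, structure)
        # cluster 1: shared edges (2,3),(3,4) traversed twice -> r_max, rest r_min
        sp = splines[0]
        assert sp.control_points.shape == (4, 3)
        assert np.all(sp.segment_radii > 0)
        assert sp.segment_radii[1] > sp.segment_radii[0]
        # singleton cluster: uniform counts collapse to r_min
        assert np.allclose(splines[2].segment_radii, 0.1)

    def test_missing_ca_is_fatal(self):
        structure, paths, assignment, summary = _toy_clustered_paths()
        structure.atom_names[structure.atom_names == "CA"] = "CB"
        with pytest.raises(ValueError, match="CA"):
            make_splines(assignment, summary, paths, structure)


class TestViewerScript:
    def test_empty_input_writes_header_only(self, tmp_path):
        out = tmp_path / "empty.pml"
        write_viewer_script([], str(out))
        text = out.read_text()
        assert "CYLINDER" in text.splitlines()[1]  # import line only
        assert "load_cgo" not in text

    def test_single_path_has_one_object_block(self, tmp_path):
        structure, paths, assignment, summary = _toy_clustered_paths()
        splines = make_splines(assignment, summary, paths, structure)[:1]
        out = tmp_path / "one.pml"
        write_viewer_script(splines, str(out))
        text = out.read_text()
        assert text.count("load_cgo") == 1
        assert "allopath_cluster_1" in text

    def test_regeneration_is_byte_identical(self, tmp_path):
        structure, paths, assignment, summary = _toy_clustered_paths()
        splines = make_splines(assignment, summary, paths, structure)
        a, b = tmp_path / "a.pml", tmp_path / "b.pml"
        write_viewer_script(splines, str(a))
        write_viewer_script(splines, str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_toy_fixture_golden_lines(self, tmp_path):
        """Frozen reference: first cylinder of the toy fixture's cluster 1."""
        structure, paths, assignment, summary = _toy_clustered_paths()
        splines = make_splines(assignment, summary, paths, structure)
        out = tmp_path / "golden.pml"
        write_viewer_script(splines, str(out))
        lines = out.read_text().splitlines()
        assert lines[4] == "cluster_1 = ["
        # first cylinder: straight-chain fixture, first sub-segment of the
        # (1,2,3,4) path starting at residue 2's CA (x = 3.8 A), radius r_min
        assert lines[5] == (
            "    CYLINDER, 3.800, 0.000, 0.000, 4.180, 0.000, 0.000, "
            "0.100, 0.894, 0.102, 0.110, 0.894, 0.102, 0.110,"
        )


class TestClusterJson:
    def test_round_trip_and_schema(self, tmp_path):
        structure, paths, assignment, summary = _toy_clustered_paths()
        splines = make_splines(assignment, summary, paths, structure)
        out = tmp_path / "viz.json"
        payload = write_cluster_json(assignment, summary, paths, splines, str(out))
        back = json.loads(out.read_text())
        assert back == payload
        assert {c["id"] for c in back["clusters"]} == {1, 2}
        for c in back["clusters"]:
            for e in c["edges"]:
                assert set(e) == {"r1", "r2", "count", "radius"}
            for p in c["paths"]:
                assert set(p) == {"residues", "score"}

    def test_empty_input(self, tmp_path):
        a = ClusterAssignment(labels=np.array([], dtype=int), k_star=0)
        ps = PathSet(paths=[], k=0, provenance=[])
        out = tmp_path / "empty.json"
        payload = write_cluster_json(a, {}, ps, [], str(out))
        assert payload == {"clusters": []}
        assert json.loads(out.read_text()) == {"clusters": []}


def _line_spline(n_samples, radius=0.3):
    pts = np.stack([np.linspace(0, 5, n_samples), np.zeros(n_samples), np.zeros(n_samples)], axis=1)
    return PathSpline(
        cluster_id=1, residues=(0, 1), score=1.0,
        control_points=pts[[0, -1]], samples=pts,
        segment_radii=np.array([radius]), sample_radii=np.full(n_samples, radius),
    )


class TestStl:
    def test_single_segment_tube_triangle_count(self, tmp_path):
        out = tmp_path / "one.stl"
        n = write_stl([_line_spline(2)], str(out), sides=8)
        assert n == 2 * 1 * 8 + 2 * (8 - 2)  # 28
        mesh = trimesh.load(str(out))
        assert len(mesh.faces) == 28
        assert np.isfinite(mesh.vertices).all()

    @pytest.mark.parametrize("s,c", [(4, 8), (10, 6)])
    def test_triangle_count_formula(self, tmp_path, s, c):
        out = tmp_path / "tube.stl"
        n = write_stl([_line_spline(s + 1)], str(out), sides=c)
        assert n == 2 * s * c + 2 * (c - 2)
        assert len(trimesh.load(str(out)).faces) == n

    def test_empty_spline_list_is_valid_stl(self, tmp_path):
        import struct

        out = tmp_path / "empty.stl"
        assert write_stl([], str(out)) == 0
        raw = out.read_bytes()
        assert len(raw) == 84  # header + zero-count, nothing else
        assert struct.unpack_from("<I", raw, 80)[0] == 0

    def test_facet_normals_are_unit_length(self, tmp_path):
        import struct

        out = tmp_path / "norm.stl"
        n = write_stl([_line_spline(6)], str(out), sides=8)
        raw = out.read_bytes()
        for i in range(n):
            nx, ny, nz = struct.unpack_from("<3f", raw, 84 + 50 * i)
            assert np.hypot(np.hypot(nx, ny), nz) == pytest.approx(1.0, abs=1e-6)

    def test_tube_is_watertight(self, tmp_path):
        structure, paths, assignment, summary = _toy_clustered_paths()
        splines = make_splines(assignment, summary, paths, structure)
        out = tmp_path / "paths.stl"
        write_stl(splines[:1], str(out))
        mesh = trimesh.load(str(out))
        assert mesh.is_watertight
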