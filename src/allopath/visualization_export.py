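"""Viewer-ready geometry for clustered paths.

Each path becomes a Catmull-Rom spline anchored at the C-alpha atoms of its
residues; the spline interpolates (passes through every anchor).  Segment
radii scale linearly with how many paths of the cluster traverse that
residue-residue connection, so heavily used connections render thicker.
Exports: a PyMOL-style CGO script, a JSON payload for notebook viewers,
and a binary STL tube mesh for 3D modeling tools.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .path_clustering import ClusterAssignment
from .path_graph import Path, PathSet
from .trajectory_io import Structure

DEFAULT_SAMPLES_PER_SEGMENT = 10
DEFAULT_R_MIN = 0.1  # A
DEFAULT_R_MAX = 0.6  # A
DEFAULT_SIDES = 8    # tube cross-section

# fixed cluster palette (RGB in [0,1]); cycles if more clusters than entries
PALETTE: list[tuple[float, float, float]] = [
    (0.894, 0.102, 0.110), (0.216, 0.494, 0.722), (0.302, 0.686, 0.290),
    (0.596, 0.306, 0.639), (1.000, 0.498, 0.000), (1.000, 1.000, 0.200),
    (0.651, 0.337, 0.157), (0.969, 0.506, 0.749), (0.600, 0.600, 0.600),
    (0.121, 0.471, 0.706),
]


@dataclass
class PathSpline:
    """Sampled interpolating spline for one path, with per-segment radii."""

    cluster_id: int
    residues: tuple[int, ...]
    score: float
    control_points: np.ndarray    # (L, 3) C-alpha anchors, Angstrom
    samples: np.ndarray           # (S, 3) polyline through all anchors
    segment_radii: np.ndarray     # (L-1,) Angstrom
    sample_radii: np.ndarray      # (S,) radius at each sampled point


def catmull_rom(points: np.ndarray, samples_per_segment: int = DEFAULT_SAMPLES_PER_SEGMENT) -> np.ndarray:
    """Uniform Catmull-Rom curve through ``points`` (natural end tangents).

    Returns (n_segments * samples_per_segment + 1) points; every control
    point is hit exactly at segment boundaries.
    """
    P = np.asarray(points, dtype=np.float64)
    if P.shape[0] < 2:
        raise ValueError("need at least 2 control points")
    pad = np.vstack([2 * P[0] - P[1], P, 2 * P[-1] - P[-2]])
    out = []
    t = np.arange(samples_per_segment) / samples_per_segment
    t2, t3 = t * t, t * t * t
    for i in range(P.shape[0] - 1):
        p0, p1, p2, p3 = pad[i], pad[i + 1], pad[i + 2], pad[i + 3]
        seg = 0.5 * (
            (2 * p1)[None, :]
            + np.outer(t, -p0 + p2)
            + np.outer(t2, 2 * p0 - 5 * p1 + 4 * p2 - p3)
            + np.outer(t3, -p0 + 3 * p1 - 3 * p2 + p3)
        )
        out.append(seg)
    out.append(P[-1][None, :])
    return np.vstack(out)


def _ca_coordinates(structure: Structure, residues: Sequence[int], coords: np.ndarray) -> np.ndarray:
    pts = np.empty((len(residues), 3))
    for n, r in enumerate(residues):
        hits = np.where((structure.atom_residue == r) & (structure.atom_names == "CA"))[0]
        if hits.size == 0:
            raise ValueError(f"residue {structure.residue_labels()[r]} has no CA atom")
        pts[n] = coords[hits[0]]
    return pts


def make_splines(
    assignment: ClusterAssignment,
    summary: dict[int, dict[tuple[int, int], int]],
    paths: PathSet,
    structure: Structure,
    coords: np.ndarray | None = None,
    samples_per_segment: int = DEFAULT_SAMPLES_PER_SEGMENT,
    r_min: float = DEFAULT_R_MIN,
    r_max: float = DEFAULT_R_MAX,
) -> list[PathSpline]:
    """One spline per path, radii from the cluster's traversal counts.

    ``coords`` defaults to the structure's reference coordinates (typically
    the first trajectory frame).  With a uniform traversal count (max = 1 or
    all equal to the max observed once) radii collapse to r_min.
    """
    if coords is None:
        coords = structure.ref_coords
    splines: list[PathSpline] = []
    for label, path in zip(assignment.labels, paths.paths):
        counts = summary[int(label)]
        max_count = max(counts.values()) if counts else 1
        seg_r = np.empty(len(path.residues) - 1)
        for s, (a, b) in enumerate(path.edges):
            key = (a, b) if a < b else (b, a)
            c = counts.get(key, 1)
            if max_count > 1:
                seg_r[s] = r_min + (r_max - r_min) * (c - 1) / (max_count - 1)
            else:
                seg_r[s] = r_min
        control = _ca_coordinates(structure, path.residues, coords)
        samples = catmull_rom(control, samples_per_segment)
        spp = (samples.shape[0] - 1) // len(seg_r)
        sample_r = seg_r[np.minimum(np.arange(samples.shape[0]) // spp, len(seg_r) - 1)]
        splines.append(
            PathSpline(
                cluster_id=int(label),
                residues=path.residues,
                score=path.score,
                control_points=control,
                samples=samples,
                segment_radii=seg_r,
                sample_radii=sample_r,
            )
        )
    return splines


def write_viewer_script(splines: Sequence[PathSpline], out: str) -> None:
    """PyMOL script drawing each spline as CGO cylinders, grouped per cluster."""
    lines = [
        "# allopath cluster path geometry",
        "from pymol.cgo import CYLINDER",
        "from pymol import cmd",
        "",
    ]
    by_cluster: dict[int, list[PathSpline]] = {}
    for sp in splines:
        by_cluster.setdefault(sp.cluster_id, []).append(sp)
    for cid in sorted(by_cluster):
        r, g, b = PALETTE[(cid - 1) % len(PALETTE)]
        parts: list[str] = []
        for sp in by_cluster[cid]:
            for i in range(sp.samples.shape[0] - 1):
                x1, y1, z1 = sp.samples[i]
                x2, y2, z2 = sp.samples[i + 1]
                rad = sp.sample_radii[i + 1]
                parts.append(
                    f"CYLINDER, {x1:.3f}, {y1:.3f}, {z1:.3f}, {x2:.3f}, {y2:.3f}, {z2:.3f}, "
                    f"{rad:.3f}, {r:.3f}, {g:.3f}, {b:.3f}, {r:.3f}, {g:.3f}, {b:.3f},"
                )
        lines.append(f"cluster_{cid} = [")
        lines.extend("    " + p for p in parts)
        lines.append("]")
        lines.append(f'cmd.load_cgo(cluster_{cid}, "allopath_cluster_{cid}")')
        lines.append("")
    with open(out, "w") as fh:
        fh.write("\n".join(lines).rstrip("\n") + "\n")


def write_cluster_json(
    assignment: ClusterAssignment,
    summary: dict[int, dict[tuple[int, int], int]],
    paths: PathSet,
    splines: Sequence[PathSpline],
    out: str,
    r_min: float = DEFAULT_R_MIN,
    r_max: float = DEFAULT_R_MAX,
) -> dict:
    """Data payload a notebook viewer consumes; round-trips losslessly."""
    clusters = []
    for cid in sorted({int(l) for l in assignment.labels} if len(assignment.labels) else []):
        counts = summary[cid]
        max_count = max(counts.values()) if counts else 1
        edges = []
        for (a, b), c in sorted(counts.items()):
            radius = r_min if max_count <= 1 else r_min + (r_max - r_min) * (c - 1) / (max_count - 1)
            edges.append({"r1": a, "r2": b, "count": c, "radius": radius})
        member_paths = [
            {"residues": list(p.residues), "score": p.score}
            for l, p in zip(assignment.labels, paths.paths)
            if int(l) == cid
        ]
        clusters.append({"id": cid, "paths": member_paths, "edges": edges})
    payload = {"clusters": clusters}
    with open(out, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return payload


def _tube_mesh(samples: np.ndarray, radii: np.ndarray, sides: int) -> tuple[np.ndarray, np.ndarray]:
    """Vertices and triangle index array for an open tube with fan caps."""
    S = samples.shape[0]
    tangents = np.empty_like(samples)
    tangents[1:-1] = samples[2:] - samples[:-2]
    tangents[0] = samples[1] - samples[0]
    tangents[-1] = samples[-1] - samples[-2]
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangents /= norms

    # parallel-transported frame avoids tube twist
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, tangents[0])) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    normal = ref - np.dot(ref, tangents[0]) * tangents[0]
    normal /= np.linalg.norm(normal)
    theta = 2 * np.pi * np.arange(sides) / sides
    rings = np.empty((S, sides, 3))
    for i in range(S):
        if i:
            normal = normal - np.dot(normal, tangents[i]) * tangents[i]
            n = np.linalg.norm(normal)
            normal = normal / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])
        binormal = np.cross(tangents[i], normal)
        rings[i] = (
            samples[i][None, :]
            + radii[i] * (np.outer(np.cos(theta), normal) + np.outer(np.sin(theta), binormal))
        )
    verts = rings.reshape(-1, 3)

    tris: list[tuple[int, int, int]] = []
    for i in range(S - 1):
        base, nxt = i * sides, (i + 1) * sides
        for j in range(sides):
            j2 = (j + 1) % sides
            tris.append((base + j, nxt + j, nxt + j2))
            tris.append((base + j, nxt + j2, base + j2))
    for j in range(1, sides - 1):  # start cap fan
        tris.append((0, j + 1, j))
    last = (S - 1) * sides
    for j in range(1, sides - 1):  # end cap fan
        tris.append((last, last + j, last + j + 1))
    return verts, np.asarray(tris, dtype=np.int64)


def write_stl(splines: Sequence[PathSpline], out: str, sides: int = DEFAULT_SIDES) -> int:
    """Binary STL of all spline tubes; returns the triangle count written.

    An open tube of s sampled segments and c cross-section sides carries
    2*s*c wall triangles plus two (c-2)-triangle cap fans.
    """
    facets: list[bytes] = []
    for sp in splines:
        verts, tris = _tube_mesh(sp.samples, sp.sample_radii, sides)
        for a, b, c in tris:
            v1, v2, v3 = verts[a], verts[b], verts[c]
            n = np.cross(v2 - v1, v3 - v1)
            ln = np.linalg.norm(n)
            n = n / ln if ln > 1e-12 else np.array([0.0, 0.0, 1.0])
            facets.append(
                struct.pack("<12fH", *n, *v1, *v2, *v3, 0)
            )
    with open(out, "wb") as fh:
        fh.write(b"allopath spline tubes".ljust(80, b"\0"))
        fh.write(struct.pack("<I", len(facets)))
        fh.writelines(facets)
    return len(facets)
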