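"""Shared fixtures: synthetic chains/rings with planted dihedral coupling.

The expensive 5000-frame trajectories are session-scoped; everything is
generated programmatically, no data files are shipped.
"""

from __future__ import annotations

import numpy as np
import pytest

from allopath.synthetic_fixtures import (
    CouplingSpec, make_chain_structure, make_coupled_trajectory,
)
from allopath.trajectory_io import compute_phi, residue_min_distances

CHAIN_N = 10
FRAMES = 5000


def _chain_bundle(kappa: float, frames: int = FRAMES, seed: int = 0):
    structure = make_chain_structure(CHAIN_N)
    spec = CouplingSpec(
        coupled_residues=list(range(CHAIN_N)), kappa=kappa, m=4, frames=frames, seed=seed
    )
    trajectory, target = make_coupled_trajectory(structure, spec)
    dihedrals = compute_phi(structure, trajectory)
    distances = residue_min_distances(structure, trajectory)
    return structure, trajectory, target, dihedrals, distances


@pytest.fixture(scope="session")
def chain_coupled():
    """10-residue line chain, kappa=0.9, 5000 frames, seed 0."""
    return _chain_bundle(kappa=0.9)


@pytest.fixture(scope="session")
def chain_noise():
    """Same chain with kappa=0: independent residues."""
    return _chain_bundle(kappa=0.0)


@pytest.fixture(scope="session")
def ring_structure():
    """21-residue ring fixture: 20 phi-defined residues on a cycle."""
    return make_chain_structure(21, geometry="ring")


def dihedral_oracle(p0, p1, p2, p3) -> float:
    """Independent signed-dihedral computation: arccos of plane normals,
    sign from the triple product (distinct from the package's atan2 route)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b1) < 0:
        ang = -ang
    return float(ang)


def mi_oracle_bits(table: np.ndarray) -> float:
    """Literal term-by-term MI summation over a contingency table, bits."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    p = table / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                mi += p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
    return mi


def entropy_oracle_bits(counts: np.ndarray) -> float:
    p = np.asarray(counts, dtype=float)
    p = p / p.sum()
    return float(-sum(q * np.log2(q) for q in p if q > 0))


def silhouette_oracle(d: np.ndarray, labels: np.ndarray) -> float:
    """From-scratch mean silhouette on a precomputed dissimilarity."""
    n = len(labels)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a = np.mean([d[i, j] for j in same]) if same else 0.0
        bs = []
        for lab in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == lab]
            bs.append(np.mean([d[i, j] for j in other]))
        b = min(bs)
        scores.append(0.0 if not same else (b - a) / max(a, b))
    return float(np.mean(scores))
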