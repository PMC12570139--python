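"""Synthetic structures and trajectories with planted dihedral correlations.

The generator builds minimal poly-alanine backbones (N, CA, C per residue)
in two geometries:

* ``line`` — residues along an axis with 3.8 A CA spacing, so that sequence
  neighbors are contact-graph edges (within 5 A) while residues four or
  more apart exceed the 12 A tracing separation; the contact graph is a
  path graph.
* ``ring`` — residues on a circle, closing the chain spatially so that two
  competing arcs connect any pair of far-apart residues; used to probe
  whether path choices are signal-driven or noise-driven.

Dihedral coupling follows a latent-state sector model: a hidden categorical
state with m symbols is drawn per frame, and each coupled residue's phi
falls inside the state's angular sector with probability kappa (otherwise a
uniformly random sector), uniformly within the sector.  Discretized at m
sector-aligned bins, two coupled residues at kappa = 1 share exactly
H = log2(m) bits, so their NMI is 1; at kappa = 0 residues are independent.
This closed form is what makes the model a usable oracle.  Backbone carbonyl
carbons are re-placed each frame (fixed 1.52 A bond, 111 deg N-CA-C angle)
so that the production dihedral reader recovers the planted phi angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .path_graph import Path, PathSet
from .trajectory_io import DistanceMatrix, Structure, Trajectory, wrap_degrees

CA_C_BOND = 1.52   # A
N_CA_C_ANGLE = 111.0  # deg
N_OFFSET = 1.45    # A, N placed this far behind CA along the chain direction


@dataclass
class CouplingSpec:
    """Planted-correlation recipe for :func:`make_coupled_trajectory`."""

    coupled_residues: list[int] = field(default_factory=list)  # residue ordinals
    kappa: float = 0.9          # coupling strength in [0, 1]
    m: int = 4                  # latent angular sectors
    frames: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if self.m < 2 or self.frames < 1:
            raise ValueError("need m >= 2 sectors and at least 1 frame")


def _backbone_positions(n_residues: int, ca_spacing: float, geometry: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Static N and CA positions plus per-residue chain tangent unit vectors."""
    if geometry == "line":
        t = np.tile(np.array([1.0, 0.0, 0.0]), (n_residues, 1))
        ca = np.zeros((n_residues, 3))
        ca[:, 0] = ca_spacing * np.arange(n_residues)
        n = ca - N_OFFSET * t
    elif geometry == "ring":
        # ordinals 1..n-1 sit on a circle; ordinal 0 is an off-ring stub whose
        # carbonyl C gives residue 1 a defined phi, so that every ring residue
        # enters the NMI matrix and the contact graph closes into a cycle
        n_ring = n_residues - 1
        radius = n_ring * ca_spacing / (2 * np.pi)
        ang = 2 * np.pi * np.arange(n_ring) / n_ring
        ca = np.zeros((n_residues, 3))
        t = np.zeros((n_residues, 3))
        ca[1:] = np.stack(
            [radius * np.cos(ang), radius * np.sin(ang), np.zeros(n_ring)], axis=1
        )
        t[1:] = np.stack([-np.sin(ang), np.cos(ang), np.zeros(n_ring)], axis=1)
        radial = np.array([1.0, 0.0, 0.0])  # outward at residue 1 (angle 0)
        ca[0] = ca[1] + 2 * ca_spacing * radial
        t[0] = -radial
        n = ca - N_OFFSET * t
        # stub carbonyl just outside residue 1's N, off the N-CA axis
        n[0] = ca[0] - N_OFFSET * t[0]
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return n, ca, t


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D at given bond length |CD|, angle B-C-D and dihedral A-B-C-D."""
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:  # collinear support; pick any perpendicular
        n = np.cross(bc, [0.0, 0.0, 1.0])
        nn = np.linalg.norm(n)
        if nn < 1e-10:
            n = np.cross(bc, [0.0, 1.0, 0.0])
            nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(phi),
        bond * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_chain_structure(
    n_residues: int,
    ca_spacing: float = 3.8,
    geometry: str = "line",
    pdb_path: str | None = None,
    chain_id: str = "A",
) -> Structure:
    """Poly-alanine backbone chain (N, CA, C per residue); optionally writes a PDB.

    ``geometry="line"`` lays all residues along x.  ``geometry="ring"``
    places residues 2..n on a circle with residue 1 as an off-ring stub
    predecessor, so the n-1 ring residues all carry a phi angle and their
    contact graph is a cycle (two competing arcs between any distant pair).
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    npos, ca, t = _backbone_positions(n_residues, ca_spacing, geometry)
    coords = np.empty((3 * n_residues, 3))
    names, elements, res_of = [], [], []
    for i in range(n_residues):
        coords[3 * i] = npos[i]
        coords[3 * i + 1] = ca[i]
        if i == 0:
            coords[3 * i + 2] = _nerf(npos[0] - t[0], npos[0], ca[0], CA_C_BOND, N_CA_C_ANGLE, -60.0)
        else:
            coords[3 * i + 2] = _nerf(coords[3 * (i - 1) + 2], npos[i], ca[i], CA_C_BOND, N_CA_C_ANGLE, -60.0)
        names += ["N", "CA", "C"]
        elements += ["N", "C", "C"]
        res_of += [i, i, i]
    structure = Structure(
        atom_names=np.array(names),
        atom_elements=np.array(elements),
        atom_residue=np.array(res_of, dtype=np.int64),
        atom_is_heavy=np.ones(3 * n_residues, dtype=bool),
        residue_keys=[(chain_id, i + 1) for i in range(n_residues)],
        residue_names=["ALA"] * n_residues,
        ref_coords=coords,
    )
    if pdb_path is not None:
        write_pdb(structure, pdb_path)
    return structure


def write_pdb(structure: Structure, path: str, coords: np.ndarray | None = None) -> None:
    """Minimal fixed-format PDB writer (fixtures only; reading is MDAnalysis's job)."""
    if coords is None:
        coords = structure.ref_coords
    lines = []
    for a in range(structure.n_atoms):
        r = int(structure.atom_residue[a])
        chain, resid = structure.residue_keys[r]
        name = structure.atom_names[a]
        pdb_name = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = coords[a]
        lines.append(
            f"ATOM  {a + 1:5d} {pdb_name}{'':1s}{structure.residue_names[r]:>3s} "
            f"{chain[:1]}{resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {structure.atom_elements[a]:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_dcd(structure: Structure, trajectory: Trajectory, path: str) -> None:
    """Write trajectory frames to DCD via MDAnalysis."""
    import warnings
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(structure.n_atoms, trajectory=True)
        u.load_new(trajectory.coords.astype(np.float32))
        with mda.Writer(path, n_atoms=structure.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def sample_phi_series(spec: CouplingSpec, n_defined: int, coupled_mask: np.ndarray) -> np.ndarray:
    """Planted phi series (frames x defined residues, degrees in [-180, 180))."""
    rng = np.random.default_rng(spec.seed)
    F, m = spec.frames, spec.m
    width = 360.0 / m
    latent = rng.integers(0, m, size=F)
    sectors = rng.integers(0, m, size=(F, n_defined))
    follow = rng.random((F, n_defined)) < spec.kappa
    sectors[:, coupled_mask] = np.where(
        follow[:, coupled_mask], latent[:, None], sectors[:, coupled_mask]
    )
    within = rng.random((F, n_defined))
    return -180.0 + (sectors + within) * width


def make_coupled_trajectory(
    structure: Structure,
    spec: CouplingSpec,
    dcd_path: str | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Trajectory whose recovered phi angles equal a planted coupled series.

    Returns the trajectory and the planted angles as a (frames, n_residues)
    array (NaN in the phi-undefined first column).  N and CA atoms stay
    fixed; each residue's carbonyl C is re-placed per frame (in chain order,
    since residue i's phi pivots on residue i-1's C) to realize the target
    dihedral.  Optionally writes a DCD file.
    """
    n_res = structure.n_residues
    defined = np.where(structure.phi_defined)[0]
    coupled_mask = np.isin(defined, np.asarray(spec.coupled_residues, dtype=np.int64))
    phi = sample_phi_series(spec, defined.size, coupled_mask)

    target = np.full((spec.frames, n_res), np.nan)
    target[:, defined] = phi

    coords = np.tile(structure.ref_coords, (spec.frames, 1, 1))
    atom_of = {  # (residue ordinal, name) -> atom index; fixture atoms are N/CA/C triplets
        (int(r), str(n)): a
        for a, (r, n) in enumerate(zip(structure.atom_residue, structure.atom_names))
    }
    for f in range(spec.frames):
        c = coords[f]
        for i in range(1, n_res):
            if np.isnan(target[f, i]):
                continue
            c[atom_of[(i, "C")]] = _nerf(
                c[atom_of[(i - 1, "C")]],
                c[atom_of[(i, "N")]],
                c[atom_of[(i, "CA")]],
                CA_C_BOND, N_CA_C_ANGLE, target[f, i],
            )
    trajectory = Trajectory(coords=coords)
    if dcd_path is not None:
        write_dcd(structure, trajectory, dcd_path)
    return trajectory, target


def make_planted_bundles(
    n_bundles: int = 2,
    paths_per_bundle: int = 10,
    bundle_size: int = 10,
    path_length: int = 8,
    residue_spacing: float = 3.0,
    bundle_gap: float = 100.0,
    seed: int = 0,
) -> tuple[PathSet, DistanceMatrix, np.ndarray]:
    """Spatially separated path bundles plus matching residue distances.

    Bundle b owns ``bundle_size`` pseudo-residues along a line at y-offset
    b * bundle_gap; its paths are overlapping sub-chains of that line.
    Cross-bundle residue distances far exceed any overlap cutoff, so the
    dissimilarity matrix is block-structured with blocks of planted labels
    (returned as the third element).
    """
    rng = np.random.default_rng(seed)
    n_res = n_bundles * bundle_size
    pts = np.zeros((n_res, 3))
    for b in range(n_bundles):
        sl = slice(b * bundle_size, (b + 1) * bundle_size)
        pts[sl, 0] = residue_spacing * np.arange(bundle_size)
        pts[sl, 1] = bundle_gap * b
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    dist = DistanceMatrix(
        distances=d,
        residue_labels=[f"A:{i + 1}" for i in range(n_res)],
        frame_selection="synthetic",
    )
    paths: list[Path] = []
    truth: list[int] = []
    max_start = bundle_size - path_length
    for b in range(n_bundles):
        base = b * bundle_size
        for j in range(paths_per_bundle):
            start = int(rng.integers(0, max_start + 1)) if max_start > 0 else 0
            residues = tuple(range(base + start, base + start + path_length))
            paths.append(Path(residues=residues, score=float(path_length - 1 - 0.001 * len(paths))))
            truth.append(b)
    order = sorted(range(len(paths)), key=lambda i: (-paths[i].score, paths[i].residues))
    path_set = PathSet(
        paths=[paths[i] for i in order],
        k=len(paths),
        provenance=[(paths[i].residues[0], paths[i].residues[-1]) for i in order],
    )
    return path_set, dist, np.array([truth[i] for i in order])
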