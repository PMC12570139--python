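"""Topology/trajectory reading, backbone dihedral extraction, residue distances.

The raw observable of the whole analysis is the backbone phi torsion
C(i-1)-N(i)-CA(i)-C(i), computed per frame for every residue that has a
sequence predecessor in the same chain.  Angles are kept in degrees, wrapped
to [-180, 180), so that downstream histogramming can use fixed bin edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import MDAnalysis as mda

logger = logging.getLogger(__name__)

_BACKBONE = ("N", "CA", "C")


@dataclass
class Structure:
    """Static topology: atoms grouped into ordered residues.

    Residue identity is the pair (chain_id, resid); PDB numbering is kept
    as-is.  ``phi_defined[i]`` is True when residue i has N/CA/C atoms and a
    sequence predecessor (resid - 1, same chain) carrying a carbonyl C.
    """

    atom_names: np.ndarray          # (n_atoms,) str
    atom_elements: np.ndarray       # (n_atoms,) str
    atom_residue: np.ndarray        # (n_atoms,) int, ordinal into residue list
    atom_is_heavy: np.ndarray       # (n_atoms,) bool
    residue_keys: list[tuple[str, int]]   # (chain_id, resid), file order
    residue_names: list[str]
    ref_coords: np.ndarray          # (n_atoms, 3) Angstrom
    phi_defined: np.ndarray = field(init=False)     # (n_residues,) bool
    phi_atoms: np.ndarray = field(init=False)       # (n_residues, 4) atom idx, -1 rows undefined

    def __post_init__(self) -> None:
        n_res = len(self.residue_keys)
        self.phi_defined = np.zeros(n_res, dtype=bool)
        self.phi_atoms = np.full((n_res, 4), -1, dtype=np.int64)
        by_res: dict[int, dict[str, int]] = {i: {} for i in range(n_res)}
        for a, r in enumerate(self.atom_residue):
            by_res[int(r)].setdefault(str(self.atom_names[a]), a)
        key_to_ordinal = {k: i for i, k in enumerate(self.residue_keys)}
        for i, (chain, resid) in enumerate(self.residue_keys):
            prev = key_to_ordinal.get((chain, resid - 1))
            if prev is None:
                continue  # first residue of a chain carries no phi
            if "C" not in by_res[prev]:
                logger.warning(
                    "residue %s:%d: predecessor lacks carbonyl C; phi undefined", chain, resid
                )
                continue
            missing = [n for n in _BACKBONE if n not in by_res[i]]
            if missing:
                logger.warning(
                    "residue %s:%d missing backbone atom(s) %s; phi undefined",
                    chain, resid, ",".join(missing),
                )
                continue
            self.phi_atoms[i] = (
                by_res[prev]["C"], by_res[i]["N"], by_res[i]["CA"], by_res[i]["C"]
            )
            self.phi_defined[i] = True

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)

    def residue_labels(self) -> list[str]:
        return [f"{c}:{r}" for c, r in self.residue_keys]

    def ordinal_of(self, label: str) -> int:
        """Ordinal of a residue given a 'CHAIN:RESID' label (chain optional if unique)."""
        labels = self.residue_labels()
        if label in labels:
            return labels.index(label)
        hits = [i for i, (_, resid) in enumerate(self.residue_keys) if str(resid) == str(label)]
        if len(hits) == 1:
            return hits[0]
        raise KeyError(f"residue {label!r} not found (or ambiguous) in topology")


@dataclass
class Trajectory:
    """Per-frame coordinates (Angstrom) for every atom of a Structure."""

    coords: np.ndarray  # (frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")

    @property
    def frame_count(self) -> int:
        return self.coords.shape[0]


@dataclass
class DihedralMatrix:
    """frames x residues phi angles in degrees, wrapped to [-180, 180).

    Undefined entries (first residue of a chain, missing atoms, collinear
    geometry in a frame) are NaN; ``defined`` marks residues with a usable
    phi column.
    """

    angles: np.ndarray      # (frames, n_residues), NaN where undefined
    defined: np.ndarray     # (n_residues,) bool
    residue_labels: list[str]

    @property
    def frame_count(self) -> int:
        return self.angles.shape[0]


@dataclass
class DistanceMatrix:
    """Symmetric residues x residues minimum heavy-atom distance (Angstrom)."""

    distances: np.ndarray
    residue_labels: list[str]
    frame_selection: str = "first"


def _element_of(atom) -> str:
    el = getattr(atom, "element", "") or ""
    if not el:
        name = atom.name.strip()
        el = "H" if name[:1] in "123456789" or name[:1] == "H" else name[:1]
    return el.strip().capitalize()


def load_topology(path: str) -> Structure:
    """Read a PDB topology into a :class:`Structure`.

    Highest-occupancy altloc is kept (MDAnalysis default keeps altloc A).
    Hydrogens are flagged non-heavy from the element column or atom name.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path)
    except Exception as exc:  # unparseable file is fatal
        raise ValueError(f"cannot parse topology {path!r}: {exc}") from exc
    atoms = u.atoms
    if atoms.n_atoms == 0:
        raise ValueError(f"topology {path!r} contains no atoms")

    residue_keys: list[tuple[str, int]] = []
    residue_names: list[str] = []
    res_ordinal: dict[tuple[str, int], int] = {}
    atom_residue = np.empty(atoms.n_atoms, dtype=np.int64)
    names, elements, heavy = [], [], []
    for a in atoms:
        chain = str(getattr(a, "chainID", "") or getattr(a.residue, "segid", "") or "A").strip() or "A"
        key = (chain, int(a.residue.resid))
        if key not in res_ordinal:
            res_ordinal[key] = len(residue_keys)
            residue_keys.append(key)
            residue_names.append(str(a.residue.resname))
        atom_residue[len(names)] = res_ordinal[key]
        names.append(str(a.name))
        el = _element_of(a)
        elements.append(el)
        heavy.append(el != "H")

    return Structure(
        atom_names=np.array(names),
        atom_elements=np.array(elements),
        atom_residue=atom_residue,
        atom_is_heavy=np.array(heavy, dtype=bool),
        residue_keys=residue_keys,
        residue_names=residue_names,
        ref_coords=atoms.positions.astype(np.float64).copy(),
    )


def load_trajectory(structure: Structure, path: str, topology_path: str | None = None) -> Trajectory:
    """Read a DCD trajectory matching ``structure`` into memory (Angstrom)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if topology_path is not None:
                u = mda.Universe(topology_path, path)
            else:
                u = mda.Universe.empty(structure.n_atoms, trajectory=True)
                u.load_new(path)
            traj_atoms = u.atoms.n_atoms
        except Exception as exc:
            from MDAnalysis.coordinates.DCD import DCDFile

            try:
                with DCDFile(path) as dcd:
                    traj_atoms = int(dcd.header["natoms"])
            except Exception:
                raise ValueError(f"cannot read trajectory {path!r}: {exc}") from exc
            if traj_atoms != structure.n_atoms:
                raise ValueError(
                    f"atom count mismatch: topology has {structure.n_atoms} atoms, "
                    f"trajectory {path!r} has {traj_atoms}"
                ) from None
            raise
    if traj_atoms != structure.n_atoms:
        raise ValueError(
            f"atom count mismatch: topology has {structure.n_atoms} atoms, "
            f"trajectory {path!r} has {traj_atoms}"
        )
    n_frames = len(u.trajectory)
    if n_frames < 1:
        raise ValueError(f"trajectory {path!r} contains zero frames")
    coords = np.empty((n_frames, structure.n_atoms, 3), dtype=np.float64)
    for f, _ in enumerate(u.trajectory):
        coords[f] = u.atoms.positions
    return Trajectory(coords=coords)


def wrap_degrees(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles in degrees onto [-180, 180)."""
    return (np.asarray(x) + 180.0) % 360.0 - 180.0


def compute_phi(structure: Structure, trajectory: Trajectory) -> DihedralMatrix:
    """Per-frame phi dihedrals for every phi-defined residue.

    Uses the standard signed-dihedral convention (IUPAC): 0 for cis,
    +/-180 for trans (reported as -180 after wrapping).  Frames where the
    four defining atoms are collinear yield NaN for that entry.
    """
    F = trajectory.frame_count
    R = structure.n_residues
    angles = np.full((F, R), np.nan)
    idx = np.where(structure.phi_defined)[0]
    if idx.size:
        quads = structure.phi_atoms[idx]  # (m, 4)
        # double precision throughout so rigid-body invariance holds to ~1e-7 deg
        p = trajectory.coords[:, quads, :]          # (F, m, 4, 3)
        b0 = p[..., 1, :] - p[..., 0, :]
        b1 = p[..., 2, :] - p[..., 1, :]
        b2 = p[..., 3, :] - p[..., 2, :]
        n1 = np.cross(b0, b1)
        n2 = np.cross(b1, b2)
        b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
        x = np.einsum("...i,...i->...", n1, n2)
        y = np.einsum("...i,...i->...", np.cross(b1n, n1), n2)
        rad = np.arctan2(y, x)
        bad = (np.linalg.norm(n1, axis=-1) < 1e-9) | (np.linalg.norm(n2, axis=-1) < 1e-9)
        rad[bad] = np.nan
        angles[:, idx] = wrap_degrees(np.degrees(rad))
        if bad.any():
            logger.warning("%d phi entries undefined (collinear atoms)", int(bad.sum()))
    return DihedralMatrix(
        angles=angles,
        defined=structure.phi_defined & ~np.all(np.isnan(angles), axis=0),
        residue_labels=structure.residue_labels(),
    )


def _resolve_frames(selection, frame_count: int) -> tuple[np.ndarray, str]:
    if selection is None or selection == "first":
        return np.array([0]), "first"
    if selection == "all":
        return np.arange(frame_count), "all"
    if isinstance(selection, int):
        return np.arange(0, frame_count, selection), f"every-{selection}"
    frames = np.asarray(list(selection), dtype=np.int64)
    if frames.size == 0:
        raise ValueError("frame selection is empty")
    return frames, f"explicit({frames.size})"


def residue_min_distances(
    structure: Structure, trajectory: Trajectory, frames="first"
) -> DistanceMatrix:
    """Minimum heavy-atom distance between every residue pair (Angstrom).

    Entry (i, j) is the minimum over the selected frames and over all heavy
    atom pairs of residues i and j.  Default selection is the first frame;
    "all" or an integer stride take the minimum over more frames.
    """
    frame_idx, descriptor = _resolve_frames(frames, trajectory.frame_count)
    heavy = structure.atom_is_heavy
    res_of_heavy = structure.atom_residue[heavy]
    R = structure.n_residues
    out = np.full((R, R), np.inf)
    from scipy.spatial.distance import cdist

    for f in frame_idx:
        pts = trajectory.coords[f][heavy]
        d = cdist(pts, pts)
        # reduce atom-pair distances to residue-pair minima
        order = np.argsort(res_of_heavy, kind="stable")
        r_sorted = res_of_heavy[order]
        bounds = np.searchsorted(r_sorted, np.arange(R + 1))
        d_sorted = d[np.ix_(order, order)]
        for i in range(R):
            si = slice(bounds[i], bounds[i + 1])
            if bounds[i] == bounds[i + 1]:
                continue
            block = d_sorted[si]
            for j in range(i, R):
                sj = slice(bounds[j], bounds[j + 1])
                if bounds[j] == bounds[j + 1]:
                    continue
                m = block[:, sj].min()
                if m < out[i, j]:
                    out[i, j] = out[j, i] = m
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(
        distances=out, residue_labels=structure.residue_labels(), frame_selection=descriptor
    )
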