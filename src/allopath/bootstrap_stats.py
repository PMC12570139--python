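"""Path-stability statistics by bootstrap resampling of trajectory frames.

Frames of the dihedral time series are drawn with replacement (one shared
index vector for all residues, preserving per-frame cross-residue coupling)
and the full analysis is repeated on each replicate.  Stability is the
number of original top-k paths recovered in each replicate's top-k, matched
by canonical residue sequence; the standard error of that count over B
replicates is sd / sqrt(B).  Contact distances come from atom positions,
which frame resampling does not move, so the graph topology is held fixed
and only the NMI edge weights change per replicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .analysis import AnalysisConfig, trace_from_dihedrals
from .path_graph import PathSet
from .trajectory_io import DihedralMatrix, DistanceMatrix

DEFAULT_B = 500


@dataclass
class BootstrapResult:
    B: int
    k: int                      # size of the original top-k set
    overlap_counts: np.ndarray  # (B,) n_b = |top-k(b) ∩ top-k(original)|
    seed: int

    def __post_init__(self) -> None:
        self.overlap_counts = np.asarray(self.overlap_counts, dtype=np.int64)
        if np.any(self.overlap_counts < 0) or np.any(self.overlap_counts > self.k):
            raise ValueError("replicate overlap counts must lie in [0, k]")

    @property
    def standard_error(self) -> float:
        return standard_error(self)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "B": self.B,
                    "k": self.k,
                    "seed": self.seed,
                    "overlap_counts": [int(x) for x in self.overlap_counts],
                    "standard_error": self.standard_error,
                    "mean_overlap_fraction": float(self.overlap_counts.mean() / self.k),
                },
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")

    def counts_to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("replicate,n_b\n")
            for b, n in enumerate(self.overlap_counts):
                fh.write(f"{b},{int(n)}\n")


def resample_frames(dihedrals: DihedralMatrix, seed: int) -> DihedralMatrix:
    """Draw frames with replacement; all residues share one index vector."""
    F = dihedrals.frame_count
    if F < 2:
        raise ValueError("need at least 2 frames to resample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, F, size=F)
    return DihedralMatrix(
        angles=dihedrals.angles[idx],
        defined=dihedrals.defined.copy(),
        residue_labels=list(dihedrals.residue_labels),
    )


def bootstrap_analysis(
    dihedrals: DihedralMatrix,
    dist: DistanceMatrix,
    config: AnalysisConfig | None = None,
    B: int = DEFAULT_B,
    seed: int = 0,
    original: PathSet | None = None,
    resampler: Callable[[DihedralMatrix, int], DihedralMatrix] = resample_frames,
) -> BootstrapResult:
    """Repeat the full tracing analysis on B frame-resampled replicates.

    ``resampler`` is pluggable for testing (e.g. the identity, which must
    recover every original path and give SE = 0).  Per-replicate seeds are
    spawned deterministically from ``seed``.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap samples")
    config = config or AnalysisConfig()
    if original is None:
        original = trace_from_dihedrals(dihedrals, dist, config)
    original_keys = original.path_keys()
    k = len(original)

    child_seeds = np.random.SeedSequence(seed).generate_state(B) % (2**31)
    counts = np.empty(B, dtype=np.int64)
    for b in range(B):
        replicate = resampler(dihedrals, int(child_seeds[b]))
        ps = trace_from_dihedrals(replicate, dist, config)
        counts[b] = len(original_keys & ps.path_keys())
    return BootstrapResult(B=B, k=k, overlap_counts=counts, seed=seed)


def standard_error(result: BootstrapResult) -> float:
    """SE = sample standard deviation (ddof=1) of the overlap counts / sqrt(B)."""
    return float(np.std(result.overlap_counts, ddof=1) / np.sqrt(result.B))
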