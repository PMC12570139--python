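"""Quantify path stability by bootstrap resampling of trajectory frames.

Uses a ring-shaped fixture where two competing arcs connect distant
residues: when dihedral coupling is planted along one arc the traced routes
are stable under frame resampling; with no coupling the route choice is
noise-driven and the bootstrap recovers fewer of the original paths.
"""

from allopath.analysis import AnalysisConfig
from allopath.bootstrap_stats import bootstrap_analysis
from allopath.synthetic_fixtures import CouplingSpec, make_chain_structure, make_coupled_trajectory
from allopath.trajectory_io import compute_phi, residue_min_distances

ring = make_chain_structure(21, geometry="ring")
for name, kappa in (("planted coupling", 0.9), ("pure noise", 0.0)):
    spec = CouplingSpec(coupled_residues=list(range(1, 16)), kappa=kappa,
                        m=4, frames=2000, seed=3)
    trajectory, _ = make_coupled_trajectory(ring, spec)
    dihedrals = compute_phi(ring, trajectory)
    distances = residue_min_distances(ring, trajectory)
    res = bootstrap_analysis(dihedrals, distances, AnalysisConfig(top_k=20), B=20, seed=7)
    print(f"{name}: mean top-path recovery {res.overlap_counts.mean() / res.k:.2f}, "
          f"SE {res.standard_error:.3f} (B={res.B}, k={res.k})")
print("Recovery near 1 with a small standard error marks reproducible,")
print("signal-driven paths; noise-driven paths churn between replicates.")
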