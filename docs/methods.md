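# Methods

## Model and procedure

The package treats allosteric communication as statistical dependence
between backbone torsion motions, propagated through physical contacts.
The pipeline is:

1. **Dihedral extraction.** The φ torsion C(i−1)–N(i)–CA(i)–C(i) is
   computed per frame for every residue with a sequence predecessor in the
   same chain, in double precision, wrapped to [−180°, 180°). φ is used
   because every amino acid has one (unlike side-chain χ angles) and
   internal coordinates avoid the spurious correlations that Cartesian
   coordinates pick up from rigid-body motion. The first residue of each
   chain, and residues missing N/CA/C or a predecessor carbonyl C, are
   masked out with a warning rather than failing the run.
2. **NMI estimation.** Marginal and joint distributions are equal-width
   histograms on the fixed support [−180°, 180°), so bin edges are
   identical for every residue and trajectory length. MI is computed from
   the joint contingency table (via scikit-learn's `mutual_info_score`,
   converted from nats to bits), entropies via SciPy, and
   NMI = MI/√(H(X)·H(Y)), clamped to [0, 1]. Each unordered pair is
   evaluated once; frames where either series is undefined are dropped
   pairwise.
3. **Graph and tracing.** Edges join residues whose minimum heavy-atom
   distance is ≤ the contact cutoff; weights are NMI values. Dijkstra
   minimizes the edge cost 1 − NMI, and the minimizing route is reported
   with score Σ NMI. One best path is traced per residue pair separated by
   ≥ the tracing cutoff; the top k paths by score are kept.
4. **Clustering.** Paths p, q overlap wherever a residue of p lies within
   the overlap cutoff of a residue of q; the dissimilarity is
   d(p,q) = 1 − overlap/(|p|·|q|), clamped to [0, 1]. Average-linkage
   agglomerative clustering on this precomputed matrix is cut at each
   candidate k and the silhouette score (on the same matrix) picks k*.
5. **Bootstrap stability.** Frame indices are drawn with replacement —
   one shared index vector for all residues, preserving per-frame
   cross-residue coupling — and the full analysis (steps 2–3) is repeated
   per replicate. The statistic is n_b, the number of original top-k paths
   recovered in replicate b (matched by canonical residue sequence), and
   SE = sd(n_b)/√B. Atom positions do not move under frame resampling, so
   distances and graph topology are held fixed; only NMI weights change.
6. **Export.** Each path becomes a uniform Catmull-Rom spline through its
   C-alpha anchors (the curve interpolates every anchor), sampled at 10
   points per segment; segment radii grow linearly with the number of
   cluster members traversing that connection. Writers emit a PyMOL CGO
   script, a JSON payload for notebook viewers, and binary STL tube
   meshes (8-sided cross-section, fan caps; an open tube of s segments
   and c sides has 2sc + 2(c−2) triangles).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `contact_cutoff` | 5.0 Å | max heavy-atom distance for a graph edge (inclusive) |
| `min_separation` | 12.0 Å | min heavy-atom distance between traced endpoints (inclusive) |
| `top_k` | 500 | paths kept after ranking across all pairs |
| `bins` | 36 | histogram bins (10° each) on the fixed support |
| `overlap_cutoff` | 12.0 Å | residue-proximity cutoff in the path-overlap metric |
| `transform` | `one_minus` | NMI→cost map for Dijkstra (`inverse`, `neglog` available) |
| `distance_frames` | `first` | frames defining residue distances (`all` or a stride) |
| `bootstrap` (B) | 500 | bootstrap replicates (0 skips the stage) |
| `seed` | 0 | the single source of randomness; runs are bit-reproducible |

The 5 Å/12 Å/500-path/500-replicate defaults are the method's standard
settings; bin count and the cost transform are free choices documented
below.

## Design choices

- **Histogram bins.** 36 equal-width bins on a fixed support make results
  independent of per-trajectory ranges and keep bin edges reproducible.
  No smoothing or finite-sample bias correction is applied; with N frames
  and B bins the independence noise floor is ≈ (B−1)²/(2N ln 2) bits of
  MI, i.e. NMI ≈ 0.036 at N = 5000, B = 36. Reported NMI values should be
  read relative to that floor, not as absolute zero-signal.
- **Cost transform.** Dijkstra needs nonnegative costs; 1 − NMI ∈ [0, 1]
  is bounded, penalizes long low-NMI detours, and keeps ties exact in
  floating point. Because cost = path length − score, the minimum-cost
  route is not always the maximum-score route when alternatives differ in
  length; `neglog` (multiplicative NMI) and `inverse` are available where
  that trade-off matters. Consequently the returned score is *not*
  monotone in the contact cutoff (denser graphs favor shorter, cheaper
  routes with fewer summed edges); the optimal cost is.
- **Determinism.** Dijkstra is implemented as uniform-cost search over
  (cost, residue-sequence) pairs, so equal-cost ties resolve to the
  lexicographically smallest route; top-k ties resolve the same way;
  paths are stored with the lower-ordinal endpoint first. Reruns are
  byte-identical.
- **Degenerate entropies.** NMI := 0 when either marginal entropy is 0: a
  motionless residue carries no communicable signal, and the convention
  avoids 0/0.
- **Clustering linkage.** Average linkage is robust on the non-Euclidean
  overlap dissimilarity; complete/single are accepted. The normalization
  by |p|·|q| bounds d in [0, 1] and removes path-length bias. Fewer than
  3 paths, or an all-zero dissimilarity (identical paths), collapse to a
  single cluster with a warning; the silhouette scan covers
  k = 2 … min(10, n−1).
- **Bootstrap statistic.** The per-replicate top-k overlap count gives one
  stability number per system. A per-path occurrence-frequency variant
  would weight hubs differently; the resampler and the statistic are
  pluggable (`resampler=` hook), and the identity resampler is the exact
  degeneracy check (SE = 0).
- **Distance frames.** Contact distances default to the first frame:
  cheap and deterministic. `all` (minimum over frames) widens the graph
  for mobile systems and is the conservative choice when contacts break
  and reform.
- **Splines.** Catmull-Rom interpolates its control points, so tubes pass
  exactly through the C-alpha anchors; radius mapping is linear between
  r_min = 0.1 Å and r_max = 0.6 Å in traversal count, collapsing to r_min
  when all counts are equal.

## Synthetic fixtures: what they emulate and what they do not

The generator plants correlated dihedral motion with a latent-state sector
model: per frame a hidden categorical state s ∈ {1…m} is drawn; each
coupled residue's φ lands in sector s with probability κ (else a uniform
random sector), uniformly within the sector; uncoupled residues are
uniform on the circle. At κ = 1 and m sector-aligned bins two coupled
residues share exactly log₂ m bits, so NMI = 1 — a closed form that makes
the model an analytic oracle. Backbone carbonyl carbons are re-placed per
frame (1.52 Å bond, 111° N–CA–C angle) so the production reader recovers
the planted angles to < 10⁻³ °.

Two geometries: a **line** chain (3.8 Å CA spacing; neighbors within 5 Å,
residues ≥ 4 apart beyond 12 Å; contact graph is a path) and a **ring**
(residues on a circle plus an off-ring stub predecessor so every ring
residue carries φ; the graph is a cycle with two competing arcs between
distant residues — the fixture that distinguishes signal-driven from
noise-driven route choice). `make_planted_bundles` fabricates spatially
separated path bundles for the clustering stage.

These fixtures emulate the *statistical* structure the method detects, not
real protein physics: no side chains, no force-field dynamics, no
autocorrelation in time (frames are i.i.d. given the latent state), no
conformational substates entangled with contact changes. Passing tests
therefore certify the estimators, the tracing/clustering machinery and the
exports — not that any particular biological system shows a given pathway.

## Problem sizes

Tests and the acceptance script run on 10-residue chains and 21-residue
rings, 1000–5000 frames, B = 20–30 bootstrap replicates, and 200 random
graphs for the optimality check; these sizes keep every planted effect
several times larger than its sampling noise while the full suite runs in
well under a minute. Real systems (hundreds of residues, 10⁴–10⁵ frames,
B = 500) use the same code paths; NMI estimation is O(R²·N) and is the
dominant cost, with the bootstrap multiplying it by B.

## Known limitations

- φ only; ψ/χ dihedrals and side-chain information are not used.
- Plain frame bootstrap ignores autocorrelation; for strongly correlated
  trajectories the SE is optimistic (no block bootstrap).
- Histogram MI is biased upward at finite N; comparisons are meaningful
  within a run (same N, same bins), absolute values less so.
- The additive score favors longer routes among equals; interpret
  rankings per endpoint-separation class when comparing across pairs.
- Trajectory alignment/centering is assumed done upstream (dihedrals are
  invariant to it; the first-frame distance matrix is not, for PBC-broken
  inputs).
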