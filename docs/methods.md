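# Methods

This note records the models implemented in `allopath`, the assumptions
behind them, the defaults that matter, and the choices made where the
design was genuinely open.

## Sites and superposition

All analyses operate on one 3-dimensional site per residue.  The default
representative atom is Cα for amino acids and C1′ for nucleotides; when
the representative atom is missing the heavy-atom center of geometry is
used (with a logged warning), and a center-of-geometry rule is available
throughout — which atoms best represent residue fluctuations is a
modelling choice, so the rule is a parameter rather than a fixed
convention.  Frames are superposed by rigid-body least squares (Kabsch)
onto the mean structure, iterating fit → recompute mean → refit until the
mean stops moving; this makes superposition idempotent and
pose-invariant, the standard essential-dynamics convention.  Coordinates
are Å throughout; XTC input (nm) is converted on read.  Synthetic
ensembles are generated as fluctuations about a fixed reference and
therefore need no superposition.

## Generalized correlations

The coupling of sites i and j is their mutual information
I_ij = H[x_i] + H[x_j] − H[x_i, x_j], estimated with the Kraskov
k-nearest-neighbour estimator (algorithm 1): for each frame, the max-norm
distance ε to the k-th neighbour in the joint 6-D space is found, and the
marginal neighbour counts strictly inside ε enter
I = ψ(k) + ψ(N) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩.  Defaults: k = 6 (exposed as a
flag; small k lowers bias at the price of variance), natural logarithms
(nats) throughout.  Choices near the estimator's edges:

* Slightly negative raw estimates — ordinary noise near independence —
  are clamped to 0, with the raw value retained and clamping counted.
* Duplicate-heavy input (zero neighbour distances, e.g. discretized
  coordinates) receives a tiny seeded jitter, with a warning.
* The diagonal GC is defined as 1 (self-MI diverges).

MI maps to GC_ij = √(1 − exp(−2 I_ij / d)) with d = 3.  For jointly
Gaussian variables this has a closed form via
I = ½ ln(det Σ_i · det Σ_j / det Σ_ij); in one dimension GC = |r|, and
for isotropic 3-D coupling with per-axis correlation ρ, GC = |ρ|.  These
closed forms are the oracles the estimator is tested against.  Replica
matrices (the analogue of averaging independent simulations) are averaged
entrywise after checking that site lists and estimator settings match.

### Scores

The per-residue correlation score is Σ_{j≠i} GC_ij over pairs passing an
intensity cutoff (default 0.6, chosen to isolate the strong couplings
from the pervasive weak background of a compact structure) and an
optional intra-/inter-domain filter.  The contribution score of a residue
*type* is AS_i − ES_i where AS_i sums GC over unordered pairs involving
at least one residue of the type (a pair with both members of the type is
counted once — "involving at least one" is read as set membership) and
ES_i = TS·N_i/N is the share expected from abundance alone.  The
identities Σ_i ES_i = TS and Σ_i N_i = N hold exactly and are asserted.

## Weighted network and communication analyses

Residue pairs are connected when any heavy-atom pair between them lies
within 5.5 Å in at least 75 % of frames; both cutoffs are parameters, and
the CRD scan (below) is the tool for checking that conclusions do not
depend on them.  Edge lengths are w_ij = −log(GC_ij); the log base is a
parameter but immaterial, because a uniform scaling of all lengths
changes neither path orderings nor any relative tolerance — asserted by
recomputation under ln vs log10.  Contacts with GC = 0 would have
infinite length and are dropped with a warning; GC = 1 contacts give
zero-length edges, kept but flagged since they can make shortest paths
degenerate (ties are retrievable via the sub-optimal enumeration at
tolerance 0).

* **Shortest pathways**: Floyd–Warshall over the dense length matrix with
  predecessor reconstruction; unreachable pairs yield an explicit
  unreachable status, never an exception.
* **Sub-optimal pathways**: all simple paths with length ≤ (1+t)·L_min,
  default t = 0.02, enumerated by depth-first search pruned with exact
  shortest-distance-to-target lower bounds; results are sorted by
  (length, node sequence) and truncation at `max_paths` always warns.
* **Edge betweenness**: all-pairs shortest-path counts with fractional
  splitting among equal-length ties (the standard convention); an integer
  "census" mode counts one reconstructed path per pair instead, for
  reporting whole-path counts.
* **Communities**: Girvan–Newman — iteratively remove the
  highest-betweenness edge (betweenness over edge lengths; ties broken by
  lexicographically smallest edge, so the procedure is seedless and
  deterministic), record a candidate partition at every component split,
  and return the partition maximizing modularity evaluated on the
  original graph.  Modularity Q = Σ_c (e_cc − a_c²) uses the GC edge
  weight as strength; a single community gives Q = 0 identically and is
  returned when no split improves on it.
* **CRD**: the fraction of unordered node pairs whose co-membership
  differs between two partitions.  The normalization (total unordered
  pairs N(N−1)/2) and pair convention are parameters
  (`denominator="pairs"|"ordered"`) since more than one reading is
  defensible; the unordered/total-pairs default is used everywhere.
  CRD is a pseudometric (non-negative, symmetric, zero on identical
  partitions; the triangle inequality is checked on random triples).
  The cutoff scan rebuilds network and partition over a grid of
  (distance, frame) cutoffs and reports CRD between neighbouring grid
  points; a run of values below the tolerance (default 0.02) is the
  convergence plateau, and grid points with empty networks are recorded
  as missing rather than aborting the scan.

## Essential dynamics and free-energy landscapes

PCA diagonalizes the mass-unweighted 3N×3N covariance of superposed
positions, using the time-average (1/N) normalization so that the trace
equals the summed squared RMSF exactly.  Modes are sorted by decreasing
eigenvalue; projections q_t = (x_t − ⟨x⟩)·v have variance equal to the
eigenvalue by construction.  Free-energy profiles are
F(q) = −k_B·T·ln(P(q)/P_MAX(q)) from histograms (default 50 bins per
axis), in k_B·T units by default or kcal/mol on request.  The most
probable bin has F = 0 exactly; empty bins are reported as NaN — a
plotting layer may cap them for display, but the numeric output never
fabricates a finite value.  The 2-D landscape over two projection series
is the joint histogram of the pair (its marginals recover the 1-D
surfaces at matching binning).

## Synthetic ensembles and what passing tests show

`GaussianEnsembleSpec` derives a site–site covariance from an
elastic-network (Kirchhoff) topology: C = (T/γ)·Γ⁺ per Cartesian axis,
isotropic 3-D blocks, sampled i.i.d. about a fixed reference geometry.
This emulates the stationary fluctuation statistics of a folded
biomolecule — nontrivial short- and long-range correlations with fully
known Gaussian structure — which is exactly what the GC, network and PCA
stages consume.  It deliberately does **not** emulate anharmonicity,
multi-basin kinetics, solvent effects or time correlation; passing tests
therefore demonstrate the correctness of the estimators and graph
algorithms, not the physics of any particular molecular system.

The two-domain fixture has 2×10 sites on antiparallel chains (3.8 Å
spacing, 4.5 Å apart), nearest-neighbour springs within each chain, one
strong designed cross-domain spring (sites 4–15, analytic GC 0.793) and
one weak one (8–11, GC 0.563); the next-largest inter-domain GC is ≈ 0.41,
so the designed couplings are unambiguously the top inter-domain signal.
The spring stiffness (covariance scale 1/24) puts site RMSF at
0.3–0.7 Å, typical of a stable fold at Cα resolution, and makes the
contact set identical across 5.0–6.0 Å so that the community structure is
convergent under the CRD scan by construction.

Planted-partition graphs draw edges with probability p_in within and
p_out between communities; edge weights use the same distribution in both
classes by default, so the planted signal is purely topological.

## Problem sizes and numerical choices

Validation runs use 10,000–20,000 frames for estimator-accuracy checks
(the KSG bias and variance at these sizes keep GC errors below the stated
0.02–0.05 tolerances), 100 random ≤8-node graphs for exact path oracles,
20 seeds for planted-partition recovery, and the 20-site fixture for
end-to-end runs — sizes at which every oracle is exact or analytic.
Ties in Girvan–Newman are broken lexicographically; all randomness flows
from explicit seeds; pipeline outputs are formatted with fixed precision
(`%.10g`) so identical configurations reproduce byte-identical files.

## Known limitations

* The KSG estimator's bias grows for very strong couplings (GC → 1) and
  small frame counts; clamping statistics are reported so such regimes
  are visible.
* Girvan–Newman recomputes betweenness after every edge removal
  (O(E²V)); it is intended for residue networks up to a few thousand
  edges, not large graphs.
* Sub-optimal path enumeration is exponential in the worst case; the
  `max_paths` guard truncates with a warning rather than running
  unbounded.
* The synthetic generator is Gaussian and frame-i.i.d.; it cannot probe
  estimator behaviour under anharmonic or kinetically correlated data.
* DCD/XTC reading delegates to MDAnalysis and inherits its format
  coverage; the fixture text dialect is the only hand-rolled reader.
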