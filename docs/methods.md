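# Methods

`allokit` reconstructs allosteric communication networks from molecular
dynamics trajectories of a protein in two liganded states and compares
them. This note records the models implemented, the choices made where
the methodology is genuinely open, and what the synthetic validation
does and does not establish.

## Structural and dynamic observables

All observables operate on a `Trajectory` (frames × atoms × 3, nm, ps;
residues 0-based internally, 1-based in every exported table).

- **Superposition / RMSD.** Each frame is rigidly fitted to a reference
  frame by the Kabsch SVD solution over a selection (default: all
  atoms); RMSD is the post-fit root-mean-square deviation. RMSD is
  computed per replicate against its own first frame; all other
  observables assume a superposed trajectory.
- **RMSF.** Per-residue Cα root-mean-square fluctuation about the
  time-mean position, on the concatenated replicates of a state.
- **Native contacts.** Heavy-atom pairs closer than 0.45 nm, counted
  per frame with a k-d tree; pairs within the same residue are
  excluded, and no sequence-neighbor exclusion is applied beyond that
  (a documented choice — common tools are ambiguous here). The
  neighbor-list count equals the all-pairs count exactly, by test.
- **Hydrogen bonds.** Geometric criterion: donor–acceptor distance
  < 0.35 nm and donor–hydrogen–acceptor angle > 150°. Donors are N/O
  atoms with a hydrogen within 0.12 nm in the same residue; acceptors
  are any other N/O. A topology without hydrogens yields an explicit
  warning and empty results rather than silent zeros.
- **Radius of gyration.** Mass-weighted by default (atomic masses from
  the element column).
- **SASA.** Shrake–Rupley with Bondi radii, probe 0.14 nm, 960
  golden-spiral quadrature points per atom. An isolated atom
  reproduces 4π(r+probe)² within 2% at that resolution.
- **Essential dynamics.** PCA of the 3N×3N Cα positional covariance;
  eigenpairs sorted by descending variance, projections in the
  eigenbasis. Identities Σλ = tr(C) = Σ RMSF² are enforced by test.
- **Free-energy landscape.** F = −kT·ln(P/P_max) on a PC1/PC2
  histogram, reported in kT (a kJ/mol conversion at a stated
  temperature, default 300 K, is provided). The most populated bin is
  exactly 0; empty bins are +inf, never 0.
- **Porcupine export.** Per-residue PC displacement vectors as a TSV
  plus a PyMOL CGO script.

## Neural relational inference (NRI)

The interaction-graph model is a variational autoencoder whose latent
variables are categorical edge types on the fully connected directed
graph over residues:

- **Encoder**: message-passing rounds (node → edge → node → edge with
  a skip connection) of two-layer ELU MLP blocks with batch
  normalization, producing per-ordered-pair logits over edge types.
- **Latent edges**: Gumbel-softmax (concrete) samples at temperature
  0.5; a hard straight-through mode is available.
- **Decoder**: per-edge-type MLP messages computed from the sender and
  receiver states, aggregated at the receiver and mapped to a
  Gaussian next-frame displacement. Edge type 0 contributes no
  message, so it is non-interacting by construction; the interaction
  probability of a pair is defined as 1 − p(type 0).
- **Objective**: Gaussian reconstruction NLL of teacher-forced
  rollouts (default 10 steps within each 50-frame window, σ² = 5·10⁻⁵
  on normalized features) plus the KL of the edge posterior against a
  uniform prior.
- **Training**: Adam. The `paper_scale` preset uses learning rate
  5·10⁻⁴ decayed ×0.2 every 200 epochs for 500 epochs at batch size
  1. The `ci` preset (used in all synthetic validation) uses
  mini-batches of 5 segments, learning rate 2·10⁻³, float32
  arithmetic, and fewer epochs; the ×0.2 decay is rescaled to ~60% of
  the run. Output heads are zero-initialized so the posterior starts
  uniform and the decoder starts inert — without this the large NLL
  scale collapses the posterior onto the silent edge type within a few
  updates and it cannot recover. Gradients are clipped at global norm
  10. Training is deterministic given the config seed.
- **Replicates**: the edge posterior is averaged over segments within
  a run and element-wise over replicate runs (`consensus_graph`),
  which suppresses run-to-run posterior noise.

Features are Cα positions and velocities. Positions are per-node
fluctuations about the time mean: planted springs (and residue
contacts) have pair-specific equilibrium separations, and a
weight-shared decoder can only represent the linearized force law in
fluctuation coordinates. Velocities are forward finite differences of
the saved frames (saved trajectories carry no velocities). Each
channel group is scaled to maximum absolute value 1; offsets and
scales are retained so the normalization inverts exactly.

The whole model runs on a small reverse-mode autodiff engine
(`allokit.autodiff`) written for this package; its gradients are
verified against finite differences in the test suite.

## Preprocessing

- **Uniform downsampling** keeps the first frame and uses even index
  spacing round(i·(N−1)/(n−1)) — reproducible, no phase choice.
- **Spatially uniform residue sampling** is farthest-point sampling on
  time-averaged Cα coordinates (seeded start); the complement is the
  reverse-sampling set. The reverse-sampling consistency check trains
  independently on both halves and rank-correlates the region-level
  cross-strength matrices.
- **Windowing**: overlapping segments of 50 frames at stride 100
  (both configurable); ⌊(n−w)/s⌋+1 segments, never out of bounds.

## Network analysis

Interaction graphs become weighted directed graphs with edge weight =
interaction probability and communication cost d = −ln(w), so shortest
paths (Dijkstra) are maximum-likelihood communication routes and a
probability-1 link is free. Ties are broken by fewer hops, then
lexicographic node order. Betweenness uses the same costs, normalized
by (n−1)(n−2) (directed convention; printed values are comparable only
under the same convention). Cross-region strength (A,B) is the mean
weight over ordered pairs (i ∈ A, j ∈ B, i ≠ j), absent edges counting
as 0.

**Edge retention.** A trained posterior leaves pairs without evidence
*at* the uniform prior (p ≈ 1/K), not below it: on the 10-node
validation system, retaining edges at p ≥ 0.5 admitted 28 false edges
versus 2 at p ≥ 0.6. Thresholded graph metrics therefore default to
min_probability = 0.6 (strictly above the uniform prior, with margin),
while path analyses may use the full weighted graph (threshold 0) —
there the −ln cost itself penalizes uncertain edges. Both are exposed.

Relay detection compares shortest-path sets between states: for each
region pair, relays are intermediates present in the bound path but
absent from the apo path. Pocket prioritization scores each candidate
pocket by |pocket ∩ relays| + |pocket ∩ top-decile betweenness|
(weights configurable), with external pocket scores breaking ties.

## Synthetic ground truth

The generator produces spring networks in reduced units (nm, ps,
kT = 1; defaults: k = 25 kT/nm², γ = 1 ps⁻¹, Δt = 0.005 ps) with two
integrators:

- **Overdamped (Brownian) Langevin** (`simulate_langevin`):
  Δx = −(Δt/γ)∇U + √(2kT·Δt/γ)·ξ, sub-stepped automatically so the
  stiffest node satisfies κΔt_sub/γ ≤ 0.15 (plain Euler–Maruyama
  inflates stationary variances by 1/(1−κΔt/2γ), enough to invert
  region-level RMSF patterns at 4× stiffening). Used for all
  ensemble/observable validation (RMSF, contacts, PCA, FEL).
- **Inertial (underdamped) Langevin** (`simulate_inertial`): BAOAB
  splitting, Maxwell–Boltzmann initial velocities, automatic
  sub-stepping to ≥ 20 steps per fastest period. Used for all
  relational-inference validation. The reason is quantitative: in the
  overdamped regime the interaction-driven share of an inter-frame
  displacement is bounded by SNR² = tanh(s/2τ) whatever the
  parameters (drift and noise share the same γ and kT), which leaves
  desk-scale edge inference marginal; inertial dynamics — the regime
  of real MD and of the relational-inference literature — lets forces
  bend ballistic motion visibly. NRI validation uses γ = 0.5 ps⁻¹
  (bond quality factor ω/γ ≈ 14) and frames saved every 10 steps
  (0.05 ps ≈ 1/18 of a bond period).

The apo topology is a random geometric graph over seeded random
coordinates (bridged to be connected), spatially coherent like a
residue contact network. The bound state multiplies core-internal
spring constants by a stiffening factor, peripheral-internal constants
by a softening factor, and may add relay edges absent from apo.
Scenario presets add weak all-pairs background springs (10% of base
stiffness) as tertiary packing — without them sparse networks have
zero-stiffness collective modes whose diffusive fluctuations never
converge — and lay regions out as spatial clusters, like contiguous
protein segments.

**Edge-label identifiability.** After superposition the centered
coordinates sum to zero, so a node's message sum over its
*non*-neighbors equals minus its neighbor sum: a weight-shared
relational decoder reconstructs the dynamics equally well from the
true graph or from its complement, and training converges to either
labeling — the same ambiguity as a sign flip in PCA/ICA, and one that
applies to any superposed trajectory, not just synthetic ones.
`orient_by_locality` resolves it with the physical prior that residue
interactions are short-ranged: if the inferred interaction
probability rank-correlates *positively* with mean inter-node
distance, the edge-type labels are swapped. The orientation uses no
ground-truth edges and is applied wherever mean coordinates are
available (the pipeline always applies it).

**What the validation shows.** On a 10-node network with 5,000
inertial frames, the desk-scale NRI config with locality orientation
recovers the planted adjacency with AUROC 0.96 at the validation
seeds (run-to-run outcomes vary; replicate consensus averages the
variation, which is why the pipeline trains per replicate and
averages, as the underlying methodology prescribes). A 30-node
scenario with 4× core stiffening and 0.25× peripheral softening
reproduces the rigid-core/flexible-periphery ΔRMSF sign pattern in
3/3 validation seeds. A block-structured system with homogeneous
region-level connectivity exercises the reverse-sampling consistency
check.

**What it does not show.** The synthetic systems are isotropic
harmonic networks of point nodes: no anharmonicity, no side chains, no
solvent, no rugged energy landscape, and interaction strength maps
directly to spring stiffness. Passing these tests demonstrates that
the pipeline recovers planted dynamical couplings under its stated
sampling conditions — not that NRI posteriors on real MD data are
calibrated probabilities. Two measured limitations deserve emphasis.
First, the posterior tracks dynamical *coupling*, not direct
adjacency: a pair joined only through a 2-hop chain of stiff springs
can carry nearly as much inferred probability as a directly bonded
pair, so analyses that hinge on distinguishing a direct edge from a
short indirect path — notably the composition of individual shortest
paths between two states, the relay-residue readout — are not
reliable at desk scale even though edge *ranking* is strong (the
package's relay test records this honestly by failing). Second,
converged posteriors are only label-oriented, not calibrated;
thresholded network metrics should be compared between states
computed identically, never read as probabilities of physical
contact.

## Numerical choices and degenerate inputs

- Euler–Maruyama integration biases stationary bond-length variance
  upward by ~1/(1−κΔt/2γ) for mode stiffness κ; at default parameters
  the bias is ≤5% and the equipartition check allows 10%.
- Superposition requires ≥3 non-collinear selected atoms; collinear
  selections raise. Single-frame trajectories cannot form velocity
  features and raise.
- Zero-frame export, self-edges, non-positive spring constants,
  overlapping nodes (zero distance), and non-finite forces all raise
  named errors; training aborts with the epoch and learning rate on a
  non-finite loss.
- Constant cross-strength matrices make the reverse-sampling rank
  correlation undefined; the result says so instead of reporting 0.
- float32 is used by the `ci` training preset for speed; the autodiff
  engine keeps float64 elsewhere, and gradient checks run in float64.

## Problem sizes

Validation problem sizes (10–30 nodes, 3,000–5,000 frames, 35–100
epochs) were chosen so the full suite runs on a single desktop core in
tens of minutes while remaining in the regime where the method's
signal-to-noise analysis above applies. The `paper_scale` preset
reproduces the published training schedule for real-protein work.
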