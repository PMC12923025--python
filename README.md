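# allokit

Allosteric communication analysis of molecular-dynamics trajectories.

Ligand binding often rigidifies the region around the binding site
while releasing distal regions — and the functional question is how
those spatially separated changes are coordinated. `allokit` takes MD
trajectories of a protein in two liganded states (apo and bound) and

1. quantifies the structural/dynamic changes: RMSD, per-residue RMSF,
   native contacts, hydrogen bonds, radius of gyration, solvent
   accessible surface area, essential dynamics (Cα PCA) and
   Boltzmann free-energy landscapes over PC1/PC2;
2. infers a **residue interaction network** from the dynamics with
   **neural relational inference (NRI)** — a variational autoencoder
   whose latent variables are per-residue-pair edge types: the encoder
   maps trajectory segments to edge-type probabilities, and an MLP
   decoder must predict the next-frame displacements using messages
   that flow only along inferred edges;
3. analyzes the resulting weighted directed communication network:
   total edge weight, betweenness centrality, cross-region interaction
   strengths, Dijkstra shortest paths on d = −ln(p) (maximum-likelihood
   communication routes), **relay residues** (new path intermediates
   appearing upon binding), and ranking of externally detected pockets
   by overlap with relays and centrality hubs.

Because public trajectory data for a given system is rarely available
and never carries ground truth, the package ships a first-class
synthetic generator: spring networks with a *planted* interaction
graph, integrated with overdamped Langevin dynamics, including
apo/bound scenario pairs with core stiffening, peripheral softening
and added relay edges. Every stage of the pipeline is validated
against this ground truth.

NRI training runs on a small numpy reverse-mode autodiff engine
included in the package (gradients are verified against finite
differences in the tests); no deep-learning framework is required.

## Worked example

Generate a synthetic apo/bound scenario, train the relational model on
one trajectory, and inspect the network:

```python
from allokit import (make_scenario, simulate_inertial, superpose,
                     compute_features, NRIConfig, train_nri,
                     build_graph, total_edge_weight, shortest_path)

# 10-node spring network; bound state stiffens the core 4x
sc = make_scenario(n_nodes=10, core_region={0, 1, 2},
                   peripheral_regions={"P1": {7, 8, 9}}, seed=0)
sc.apo.friction = 0.5  # underdamped regime for interaction inference
traj = superpose(simulate_inertial(sc.apo, n_frames=5000,
                                   save_stride=10, seed=1))

segments = compute_features(traj).windows(window=50, stride=100)
model, graph, history = train_nri(
    segments, NRIConfig.ci(seed=0, lr_decay_every=60),
    node_positions=traj.ca_coords().mean(axis=0))

m = graph.interaction_matrix()          # 10x10 interaction probabilities
adj = sc.apo.adjacency()                # planted ground truth
from sklearn.metrics import roc_auc_score
pairs = [(i, j) for i in range(10) for j in range(10) if i != j]
print("edge-recovery AUROC:",
      round(roc_auc_score([adj[i, j] for i, j in pairs],
                          [m[i, j] for i, j in pairs]), 3))

g = build_graph(graph, min_probability=0.6)
print("retained edges:", g.number_of_edges(),
      "total weight:", round(total_edge_weight(g), 2))
p = shortest_path(build_graph(graph, 0.0), 0, 8)
print("path 1->9 (1-based):", [r + 1 for r in p.residues],
      "distance:", round(p.distance, 3))
```

Output (fixed seeds; train time a few minutes on one core):

```
edge-recovery AUROC: 0.96
retained edges: 3 total weight: 2.02
path 1->9 (1-based): [1, 9] distance: 1.342
```

An AUROC of 0.96 means the inferred interaction probabilities rank the
planted spring-network edges almost perfectly above non-edges. The
absolute probabilities are conservative (few pairs clear the 0.6
retention threshold here) — rankings are reliable, calibration is not,
which is why comparative analyses in the pipeline always compute both
states identically (see `docs/methods.md`). The path lists the
maximum-likelihood communication route on the full weighted graph,
whose summed −ln(probability) cost is the printed distance.

The full two-state comparison — observables, per-replicate training,
consensus networks, ΔRMSF by region, path tables and the relay
report — runs from a YAML config:

```bash
allokit fixtures --preset relay-demo --out demo --seed 7
allokit run -c demo/config.yaml
```

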