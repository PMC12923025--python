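"""Synthetic spring-network dynamics with a known (planted) interaction graph.

Every downstream stage of the package — flexibility profiles, relational
inference, communication-path analysis — is exercised on these systems,
because they provide what real MD data cannot: ground truth. A
:class:`PlantedSystem` is a set of point nodes joined by harmonic
springs, integrated with overdamped (Brownian) Langevin dynamics. A
:class:`ScenarioPair` mimics a ligand-binding event: the *bound* system
copies the *apo* one, stiffens springs inside a core region, softens
springs inside peripheral regions, and adds relay edges absent from the
apo graph — the "rigid core / flexible periphery with new relays"
organization that allosteric activation produces in proteins.

Units: nm, ps, kT = 1. PDB export scales to Å per format convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = ["PlantedSystem", "ScenarioPair", "simulate_langevin",
           "make_scenario", "export_trajectory", "spring_energy"]

Edge = tuple[int, int]


def _norm_edge(e) -> Edge:
    i, j = int(e[0]), int(e[1])
    if i == j:
        raise ValueError(f"self-edge ({i},{j}) not allowed")
    return (i, j) if i < j else (j, i)


@dataclass
class PlantedSystem:
    """Harmonic spring network: nodes, edges, per-edge stiffness.

    ``spring_constant`` and ``rest_length`` map each unordered edge to
    its stiffness (kT·nm⁻²) and equilibrium distance (nm).
    """

    n_nodes: int
    initial_coords: np.ndarray
    edges: list[Edge]
    spring_constant: dict[Edge, float]
    rest_length: dict[Edge, float]
    friction: float = 1.0
    temperature: float = 1.0
    timestep: float = 0.005
    # optional weak all-pairs restraints (elastic-network-style tertiary
    # packing): suppress floppy collective modes of sparse graphs while
    # staying far below the planted-edge stiffness; rest lengths are the
    # initial pair distances. The planted graph (edges/adjacency) is
    # unaffected.
    background_spring_constant: float = 0.0

    def __post_init__(self):
        self.initial_coords = np.asarray(self.initial_coords,
                                         dtype=np.float64)
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.initial_coords.shape != (self.n_nodes, 3):
            raise ValueError("initial_coords must be (n_nodes, 3)")
        self.edges = sorted(_norm_edge(e) for e in self.edges)
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        for e in self.edges:
            if not (0 <= e[0] < self.n_nodes and 0 <= e[1] < self.n_nodes):
                raise ValueError(f"edge {e} out of range")
            if self.spring_constant[e] <= 0:
                raise ValueError(f"spring constant of {e} must be > 0")
            if self.rest_length[e] < 0:
                raise ValueError(f"rest length of {e} must be ≥ 0")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be ≥ 0")
        if self.background_spring_constant < 0:
            raise ValueError("background_spring_constant must be ≥ 0")

    # convenience arrays for vectorized force evaluation
    def _edge_arrays(self):
        if not self.edges:
            z = np.zeros(0)
            return np.zeros((0,), dtype=np.int64), np.zeros((0,),
                                                            dtype=np.int64), z, z
        ij = np.asarray(self.edges, dtype=np.int64)
        k = np.array([self.spring_constant[e] for e in self.edges])
        r0 = np.array([self.rest_length[e] for e in self.edges])
        return ij[:, 0], ij[:, 1], k, r0

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j in self.edges:
            a[i, j] = a[j, i] = True
        return a

    def copy(self) -> "PlantedSystem":
        return PlantedSystem(self.n_nodes, self.initial_coords.copy(),
                             list(self.edges), dict(self.spring_constant),
                             dict(self.rest_length), self.friction,
                             self.temperature, self.timestep,
                             self.background_spring_constant)


def spring_energy(system: PlantedSystem, coords: np.ndarray) -> float:
    """Total harmonic energy U = Σ ½k(d − r₀)² of one configuration."""
    i, j, k, r0 = system._edge_arrays()
    if len(i) == 0:
        return 0.0
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    return float(0.5 * np.sum(k * (d - r0) ** 2))


class IntegrationFailure(RuntimeError):
    pass


def simulate_langevin(system: PlantedSystem, n_frames: int,
                      save_stride: int = 5, seed: int = 0) -> Trajectory:
    """Overdamped Langevin (Brownian) dynamics of a planted spring network.

    Per step, Δx = −(Δt/γ)·∇U + ξ with ξ ~ N(0, 2kT·Δt/γ) per
    coordinate. Frame 0 is the initial configuration; each subsequent
    frame advances ``save_stride`` steps. Deterministic given the seed.

    The default saving interval (5 steps = 0.025 ps at the default
    timestep) is comparable to the relaxation time of a default-
    stiffness bond (γ/2k = 0.02 ps): as in saved MD trajectories, a
    frame interval near the fastest relevant relaxation maximizes the
    deterministic (interaction-driven) share of inter-frame
    displacements relative to diffusive noise.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be ≥ 2")
    if save_stride < 1:
        raise ValueError("save_stride must be ≥ 1")
    rng = np.random.default_rng(seed)
    i, j, k, r0 = system._edge_arrays()
    dt, gamma, kt = system.timestep, system.friction, system.temperature
    k_bg = system.background_spring_constant
    # Euler–Maruyama inflates stationary variances by 1/(1 − κΔt/2γ)
    # for mode stiffness κ; sub-step so the stiffest node stays in the
    # accurate regime (κΔt_sub/γ ≤ 0.15, bias ≤ 8%)
    node_k = np.zeros(system.n_nodes)
    if len(i):
        np.add.at(node_k, i, k)
        np.add.at(node_k, j, k)
    kappa_max = float(node_k.max()) + system.n_nodes * k_bg
    n_sub = max(1, int(np.ceil(dt * kappa_max / (0.15 * gamma)))) \
        if kappa_max > 0 else 1
    dt_sub = dt / n_sub
    mobility = dt_sub / gamma
    noise_sd = np.sqrt(2.0 * kt * dt_sub / gamma)
    if k_bg > 0:
        x0 = system.initial_coords
        bg_r0 = np.linalg.norm(x0[:, None] - x0[None, :], axis=-1)
        np.fill_diagonal(bg_r0, 1.0)  # self-pairs masked below

    x = system.initial_coords.copy()
    frames = np.empty((n_frames, system.n_nodes, 3))
    frames[0] = x
    for f in range(1, n_frames):
        for _ in range(save_stride * n_sub):
            if len(i):
                dvec = x[i] - x[j]
                d = np.linalg.norm(dvec, axis=1)
                if np.any(d < 1e-12):
                    raise IntegrationFailure(
                        f"overlapping nodes (zero distance) at frame {f}")
                fmag = -k * (d - r0) / d  # force per unit dvec on node i
                fvec = fmag[:, None] * dvec
                force = np.zeros_like(x)
                np.add.at(force, i, fvec)
                np.add.at(force, j, -fvec)
            else:
                force = np.zeros_like(x)
            if k_bg > 0:
                dmat = x[:, None] - x[None, :]
                dist = np.linalg.norm(dmat, axis=-1)
                np.fill_diagonal(dist, 1.0)
                if np.any(dist < 1e-12):
                    raise IntegrationFailure(
                        f"overlapping nodes (zero distance) at frame {f}")
                coeff = -k_bg * (dist - bg_r0) / dist
                np.fill_diagonal(coeff, 0.0)
                force = force + np.einsum("ab,abd->ad", coeff, dmat)
            if not np.all(np.isfinite(force)):
                raise IntegrationFailure(f"non-finite forces at frame {f}")
            x = x + mobility * force
            if kt > 0:
                x = x + noise_sd * rng.standard_normal(x.shape)
        frames[f] = x

    meta = pd.DataFrame({
        "name": ["CA"] * system.n_nodes,
        "element": ["C"] * system.n_nodes,
        "heavy": [True] * system.n_nodes,
        "resid": np.arange(system.n_nodes, dtype=np.int64),
        "resname": ["GLY"] * system.n_nodes,
        "chain": ["A"] * system.n_nodes,
    })
    times = np.arange(n_frames, dtype=np.float64) * dt * save_stride
    return Trajectory(frames, meta, times)


def simulate_inertial(system: PlantedSystem, n_frames: int,
                      save_stride: int = 10, seed: int = 0,
                      mass: float = 1.0) -> Trajectory:
    """Underdamped Langevin dynamics (BAOAB splitting) of a planted
    spring network.

    Molecular dynamics is inertial: atoms move ballistically between
    collisions, so interatomic forces bend trajectories visibly and
    saved frames carry a large deterministic (interaction-driven)
    component. Overdamped (Brownian) dynamics, by contrast, buries the
    force signal in diffusive noise — the per-frame drift-to-noise
    ratio is bounded by tanh(s/2τ) whatever the parameters. This
    integrator therefore provides the regime in which
    trajectory-based interaction inference is well-posed, and is the
    one the relational-inference validation scenarios use.

    Friction is taken from ``system.friction`` (per ps); with the
    default spring constants the bond quality factor ω/γ ≈ 14, i.e.
    clearly underdamped. The timestep sub-divides automatically so the
    stiffest mode is integrated at ≥ 20 steps per period. Velocities
    start from the Maxwell–Boltzmann distribution; deterministic given
    the seed.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be ≥ 2")
    if save_stride < 1:
        raise ValueError("save_stride must be ≥ 1")
    rng = np.random.default_rng(seed)
    i, j, k, r0 = system._edge_arrays()
    dt, gamma, kt = system.timestep, system.friction, system.temperature
    k_bg = system.background_spring_constant
    node_k = np.zeros(system.n_nodes)
    if len(i):
        np.add.at(node_k, i, k)
        np.add.at(node_k, j, k)
    kappa_max = float(node_k.max()) + system.n_nodes * k_bg
    omega_max = np.sqrt(max(kappa_max, 1e-12) / mass)
    n_sub = max(1, int(np.ceil(dt * omega_max / 0.3)))
    dt_sub = dt / n_sub
    if k_bg > 0:
        x0 = system.initial_coords
        bg_r0 = np.linalg.norm(x0[:, None] - x0[None, :], axis=-1)
        np.fill_diagonal(bg_r0, 1.0)

    def forces(x):
        force = np.zeros_like(x)
        if len(i):
            dvec = x[i] - x[j]
            d = np.linalg.norm(dvec, axis=1)
            if np.any(d < 1e-12):
                raise IntegrationFailure("overlapping nodes")
            fvec = (-k * (d - r0) / d)[:, None] * dvec
            np.add.at(force, i, fvec)
            np.add.at(force, j, -fvec)
        if k_bg > 0:
            dmat = x[:, None] - x[None, :]
            dist = np.linalg.norm(dmat, axis=-1)
            np.fill_diagonal(dist, 1.0)
            coeff = -k_bg * (dist - bg_r0) / dist
            np.fill_diagonal(coeff, 0.0)
            force = force + np.einsum("ab,abd->ad", coeff, dmat)
        return force

    x = system.initial_coords.copy()
    v = rng.standard_normal(x.shape) * np.sqrt(kt / mass)
    f = forces(x)
    # BAOAB constants
    c1 = np.exp(-gamma * dt_sub)
    c2 = np.sqrt(kt / mass * (1.0 - c1 * c1)) if kt > 0 else 0.0
    frames = np.empty((n_frames, system.n_nodes, 3))
    frames[0] = x
    for fr in range(1, n_frames):
        for _ in range(save_stride * n_sub):
            v = v + 0.5 * dt_sub * f / mass
            x = x + 0.5 * dt_sub * v
            v = c1 * v + c2 * rng.standard_normal(v.shape)
            x = x + 0.5 * dt_sub * v
            f = forces(x)
            if not np.all(np.isfinite(f)):
                raise IntegrationFailure(f"non-finite forces at frame {fr}")
            v = v + 0.5 * dt_sub * f / mass
        frames[fr] = x

    meta = pd.DataFrame({
        "name": ["CA"] * system.n_nodes,
        "element": ["C"] * system.n_nodes,
        "heavy": [True] * system.n_nodes,
        "resid": np.arange(system.n_nodes, dtype=np.int64),
        "resname": ["GLY"] * system.n_nodes,
        "chain": ["A"] * system.n_nodes,
    })
    times = np.arange(n_frames, dtype=np.float64) * dt * save_stride
    return Trajectory(frames, meta, times)


# --------------------------------------------------------------------
# scenario construction

@dataclass
class ScenarioPair:
    """Apo/bound system pair with planted perturbations and ground truth."""

    apo: PlantedSystem
    bound: PlantedSystem
    core_region: set[int]
    peripheral_regions: dict[str, set[int]]
    relay_nodes: set[int]
    relay_edges: set[Edge]
    stiffening_factor: float = 1.0
    softening_factor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.apo.n_nodes != self.bound.n_nodes:
            raise ValueError("apo and bound must have identical n_nodes")
        for e in self.relay_edges:
            if e in self.apo.spring_constant:
                raise ValueError(f"relay edge {e} already present in apo")
            if e not in self.bound.spring_constant:
                raise ValueError(f"relay edge {e} missing from bound")
        for e in self.apo.edges:
            if e[0] in self.core_region and e[1] in self.core_region:
                if self.bound.spring_constant[e] < self.apo.spring_constant[e]:
                    raise ValueError(
                        f"bound core spring {e} weaker than apo")
        regions = [set(self.core_region)] + \
            [set(v) for v in self.peripheral_regions.values()]
        for a in range(len(regions)):
            for b in range(a + 1, len(regions)):
                if regions[a] & regions[b]:
                    raise ValueError("region sets overlap")

    @property
    def regions(self) -> dict[str, set[int]]:
        out = {"core": set(self.core_region)}
        out.update({k: set(v) for k, v in self.peripheral_regions.items()})
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "n_nodes": self.apo.n_nodes,
            "apo_edges": [list(e) for e in self.apo.edges],
            "bound_edges": [list(e) for e in self.bound.edges],
            "core_region": sorted(self.core_region),
            "peripheral_regions": {k: sorted(v) for k, v
                                   in self.peripheral_regions.items()},
            "relay_nodes": sorted(self.relay_nodes),
            "relay_edges": [list(e) for e in sorted(self.relay_edges)],
            "stiffening_factor": self.stiffening_factor,
            "softening_factor": self.softening_factor,
            "seed": self.seed,
            "indexing": "0-based node ids",
        }, indent=1))


def _bridge_components(edges: set[Edge], n: int,
                       d: np.ndarray) -> set[Edge]:
    """Connect graph components through their nearest inter-component
    node pairs (keeps the graph spatially coherent)."""
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        parent[find(i)] = find(j)
    while True:
        roots = {find(v) for v in range(n)}
        if len(roots) == 1:
            break
        groups = [[v for v in range(n) if find(v) == r] for r in roots]
        best, pair = np.inf, None
        base = groups[0]
        for other in groups[1:]:
            for a in base:
                for b in other:
                    if d[a, b] < best:
                        best, pair = d[a, b], (min(a, b), max(a, b))
        edges.add(pair)
        parent[find(pair[0])] = find(pair[1])
    return edges


def _random_geometric_graph(coords: np.ndarray, radius: float) -> list[Edge]:
    """Edges between node pairs within ``radius``; components bridged
    so the graph is connected."""
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    edges = {(i, j) for i in range(n) for j in range(i + 1, n)
             if d[i, j] <= radius}
    return sorted(_bridge_components(edges, n, d))


def make_block_system(region_sizes: dict[str, int],
                      density: dict[tuple[str, str], float],
                      seed: int = 0,
                      base_spring_constant: float = 25.0,
                      box_size: float | None = None
                      ) -> tuple[PlantedSystem, dict[str, set[int]]]:
    """Spring network with block-structured (region-level) connectivity.

    An edge between regions A and B is present with probability
    ``density[(A, B)]`` (order-insensitive, default 0). Region labels
    are assigned by cycling through the regions along a spatial sort
    of the node coordinates, so every spatial neighborhood contains
    all regions: a spatially uniform residue split (and its
    complement) then samples every region, and both halves see the
    same region-level structure in expectation — the property the
    reverse-sampling consistency check relies on. Rest lengths equal
    initial distances; the graph is bridged to be connected.
    """
    rng = np.random.default_rng(seed)
    names = list(region_sizes)
    n = sum(region_sizes.values())
    if box_size is None:
        box_size = 1.2 * n ** (1 / 3)
    coords = rng.uniform(0, box_size, size=(n, 3))
    # interleave region labels along the dominant spatial axis
    order = np.argsort(coords[:, 0], kind="stable")
    cycle: list[str] = []
    remaining = dict(region_sizes)
    while any(v > 0 for v in remaining.values()):
        for name in names:
            if remaining[name] > 0:
                cycle.append(name)
                remaining[name] -= 1
    regions: dict[str, set[int]] = {name: set() for name in names}
    for node, name in zip(order, cycle):
        regions[name].add(int(node))
    label = {v: name for name, nodes in regions.items() for v in nodes}
    edges: set[Edge] = set()
    for i in range(n):
        for j in range(i + 1, n):
            key = (label[i], label[j])
            p = density.get(key, density.get((key[1], key[0]), 0.0))
            if rng.random() < p:
                edges.add((i, j))
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    edges = _bridge_components(edges, n, d)
    k = {e: base_spring_constant for e in edges}
    r0 = {e: float(d[e[0], e[1]]) for e in edges}
    return PlantedSystem(n, coords, sorted(edges), k, r0), regions


def make_scenario(n_nodes: int = 30,
                  core_region: set[int] | None = None,
                  peripheral_regions: dict[str, set[int]] | None = None,
                  relay_spec: list[Edge] | None = None,
                  stiffening_factor: float = 4.0,
                  softening_factor: float = 0.25,
                  seed: int = 0,
                  base_spring_constant: float = 25.0,
                  connect_radius: float | None = None,
                  box_size: float | None = None,
                  background_spring_factor: float = 0.0,
                  initial_coords: np.ndarray | None = None) -> ScenarioPair:
    """Build an apo/bound pair emulating cofactor-induced remodeling.

    The apo interaction graph is a random geometric graph over seeded
    random coordinates (spatially coherent, like a protein contact
    network). The bound system multiplies spring constants of edges
    internal to the core region by ``stiffening_factor`` (≥ 1,
    rigidification), edges internal to each peripheral region by
    ``softening_factor`` (≤ 1, flexibilization), and adds the
    ``relay_spec`` edges, which must be absent from apo.
    """
    if stiffening_factor < 1:
        raise ValueError("stiffening_factor must be ≥ 1")
    if not 0 < softening_factor <= 1:
        raise ValueError("softening_factor must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if box_size is None:
        # ~constant node density as n grows
        box_size = 1.2 * n_nodes ** (1 / 3)
    if initial_coords is not None:
        coords = np.asarray(initial_coords, dtype=np.float64)
        if coords.shape != (n_nodes, 3):
            raise ValueError("initial_coords must be (n_nodes, 3)")
    else:
        coords = rng.uniform(0, box_size, size=(n_nodes, 3))
    if connect_radius is None:
        connect_radius = 0.55 * box_size
    for region in [core_region or set()] + \
            list((peripheral_regions or {}).values()):
        for v in region:
            if not 0 <= v < n_nodes:
                raise ValueError(f"region node {v} out of range")

    edges = _random_geometric_graph(coords, connect_radius)
    k = {e: base_spring_constant for e in edges}
    r0 = {e: float(np.linalg.norm(coords[e[0]] - coords[e[1]]))
          for e in edges}
    apo = PlantedSystem(
        n_nodes, coords, edges, k, r0,
        background_spring_constant=background_spring_factor
        * base_spring_constant)

    core = set(core_region or set())
    periph = {name: set(v) for name, v
              in (peripheral_regions or {}).items()}
    bound = apo.copy()
    for e in bound.edges:
        if e[0] in core and e[1] in core:
            bound.spring_constant[e] *= stiffening_factor
        else:
            for reg in periph.values():
                if e[0] in reg and e[1] in reg:
                    bound.spring_constant[e] *= softening_factor
                    break
    relay_edges = set()
    relay_nodes = set()
    for e in (relay_spec or []):
        e = _norm_edge(e)
        if e in apo.spring_constant:
            raise ValueError(
                f"relay edge {e} is already an apo edge; relay edges must "
                "be new in the bound state")
        relay_edges.add(e)
        relay_nodes.update(e)
        bound.edges.append(e)
        bound.spring_constant[e] = base_spring_constant
        bound.rest_length[e] = float(
            np.linalg.norm(coords[e[0]] - coords[e[1]]))
    bound.edges = sorted(bound.edges)
    # relay nodes = nodes incident to relay edges that sit between regions
    return ScenarioPair(apo, bound, core, periph, relay_nodes, relay_edges,
                        stiffening_factor, softening_factor, seed)


# --------------------------------------------------------------------
# export

def export_trajectory(traj: Trajectory, topology_path: str | Path,
                      coords_path: str | Path) -> None:
    """Write a minimal PDB topology and an XTC/DCD coordinate file.

    One CA pseudo-atom per node with sequential 1-based residue
    numbering; nm → Å conversion applied. Round-trips through
    :func:`allokit.trajectory.load_trajectory` to XTC precision.
    """
    import MDAnalysis as mda

    if traj.n_frames == 0:
        raise ValueError("cannot export an empty (0-frame) trajectory")
    topology_path, coords_path = Path(topology_path), Path(coords_path)
    if topology_path.suffix.lower() != ".pdb":
        raise ValueError("topology must be written as .pdb")
    if coords_path.suffix.lower() not in {".xtc", ".dcd"}:
        raise ValueError(
            f"unsupported coordinate format {coords_path.suffix!r}; "
            "supported: .xtc, .dcd")

    n = traj.n_atoms
    u = mda.Universe.empty(n, n_residues=n,
                           atom_resindex=np.arange(n),
                           residue_segindex=np.zeros(n, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", list(traj.atom_meta["name"]))
    u.add_TopologyAttr("resnames", list(traj.atom_meta["resname"]))
    u.add_TopologyAttr("resids", np.arange(1, n + 1))
    u.add_TopologyAttr("elements", list(traj.atom_meta["element"]))
    u.atoms.positions = traj.coords[0] * 10.0  # nm → Å
    with mda.Writer(str(topology_path), n_atoms=n) as w:
        w.write(u.atoms)
    dt = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 1.0
    with mda.Writer(str(coords_path), n_atoms=n) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coords[f] * 10.0
            u.trajectory.ts.frame = f
            u.trajectory.ts.time = f * dt
            w.write(u.atoms)
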