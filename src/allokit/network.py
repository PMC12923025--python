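"""Communication-network analysis of inferred interaction graphs.

Latent interaction graphs become weighted directed graphs (edge weight
= interaction probability); communication cost along an edge is
d = −ln(w), so a probability-1 link is free and shortest paths are
maximum-likelihood communication routes. On top sit the comparative
analyses: total edge weight, betweenness centrality, cross-region
strengths, shortest paths between region centers, relay-residue
detection between two states, and pocket prioritization by overlap
with relays and high-centrality hubs.

Residue numbering is 0-based internally, 1-based in every exported
table.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .nri import LatentInteractionGraph

__all__ = [
    "RegionSet", "CommunicationPath", "PocketDefinition", "build_graph",
    "total_edge_weight", "betweenness", "cross_region_strength",
    "region_center_residue", "shortest_path", "shortest_paths_to_regions",
    "detect_relays", "prioritize_pockets", "parse_fpocket_info",
    "export_edge_tsv", "export_graphml", "DEFAULT_REGIONS_1BASED",
]

# SIR2 region definitions (1-based inclusive residue ranges): the
# catalytic β1–α2 loop and the five distal flexibility hotspots S1–S5.
# S2 and S3 share residue 160; the overlap is deliberate and preserved.
DEFAULT_REGIONS_1BASED: dict[str, tuple[int, int]] = {
    "beta1_alpha2": (35, 63),
    "S1": (80, 100),
    "S2": (140, 160),
    "S3": (160, 190),
    "S4": (210, 220),
    "S5": (250, 265),
}


@dataclass
class RegionSet:
    """Named residue ranges (0-based internal indices)."""

    regions: dict[str, set[int]]
    declared_overlaps: set[frozenset] = field(default_factory=set)

    def __post_init__(self):
        names = list(self.regions)
        for name in names:
            if not self.regions[name]:
                raise ValueError(f"region {name!r} is empty")
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                shared = self.regions[names[a]] & self.regions[names[b]]
                pair = frozenset((names[a], names[b]))
                if shared and pair not in self.declared_overlaps:
                    raise ValueError(
                        f"regions {names[a]!r} and {names[b]!r} overlap "
                        f"({sorted(shared)}); declare the overlap "
                        "explicitly if intended")

    @classmethod
    def from_ranges_1based(cls, ranges: dict[str, tuple[int, int]]
                           | None = None,
                           declared_overlaps=None) -> "RegionSet":
        """Inclusive 1-based ranges → internal 0-based sets.

        With no argument, the SIR2 defaults are used (S2/S3 share
        residue 160, a declared overlap).
        """
        if ranges is None:
            ranges = DEFAULT_REGIONS_1BASED
            declared_overlaps = {frozenset(("S2", "S3"))}
        regions = {name: set(range(lo - 1, hi)) for name, (lo, hi)
                   in ranges.items()}
        return cls(regions, set(declared_overlaps or ()))

    def __getitem__(self, name: str) -> set[int]:
        return self.regions[name]

    def __iter__(self):
        return iter(self.regions)

    def items(self):
        return self.regions.items()

    def restrict(self, n_residues: int) -> "RegionSet":
        """Clip all regions to residues < n_residues."""
        return RegionSet({k: {r for r in v if r < n_residues}
                          for k, v in self.regions.items()},
                         self.declared_overlaps)


@dataclass
class CommunicationPath:
    """A shortest communication route between two residues.

    ``distance`` is the summed −ln(edge probability); by duality
    exp(−distance) is the product of per-edge probabilities.
    """

    source: int
    target: int
    residues: list[int]
    distance: float
    edge_probabilities: list[float]
    reachable: bool = True

    def __post_init__(self):
        if self.reachable:
            if self.residues[0] != self.source \
                    or self.residues[-1] != self.target:
                raise ValueError("path must run from source to target")
            expected = float(np.sum(-np.log(self.edge_probabilities))) \
                if self.edge_probabilities else 0.0
            if abs(expected - self.distance) > 1e-9 * max(1.0, abs(expected)):
                raise ValueError("distance inconsistent with edge "
                                 "probabilities")

    @property
    def intermediates(self) -> list[int]:
        return self.residues[1:-1] if self.reachable else []

    def as_record(self) -> dict:
        return {
            "source_1based": self.source + 1,
            "target_1based": self.target + 1,
            "path_1based": [r + 1 for r in self.residues],
            "distance": self.distance,
            "edge_probabilities": self.edge_probabilities,
            "reachable": self.reachable,
        }


@dataclass
class PocketDefinition:
    """A candidate pocket: id, member residues, optional external score."""

    pocket_id: int
    residues: set[int]
    score: float | None = None
    volume: float | None = None

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"pocket {self.pocket_id} has no residues")


# --------------------------------------------------------------------
# graph construction and global metrics

def build_graph(latent: LatentInteractionGraph,
                min_probability: float = 0.5) -> nx.DiGraph:
    """Weighted directed graph from interaction probabilities.

    Edge i→j has weight = interaction probability (1 − p(type 0)) and
    is kept iff weight ≥ ``min_probability``. All residues remain as
    nodes. The default threshold is the uniform-prior level
    1/n_edge_types.
    """
    if not 0 <= min_probability < 1:
        raise ValueError("min_probability must be in [0, 1)")
    g = nx.DiGraph()
    g.add_nodes_from(range(latent.n_nodes))
    p_int = 1.0 - latent.edge_probs[:, 0]
    for (i, j), w in zip(latent.pairs, p_int):
        if w >= min_probability:
            g.add_edge(i, j, weight=float(w),
                       distance=float(-np.log(w)) if w > 0 else np.inf)
    return g


def total_edge_weight(graph: nx.DiGraph) -> float:
    """Σ weights over retained directed edges."""
    return float(sum(d["weight"] for _, _, d in graph.edges(data=True)))


def betweenness(graph: nx.DiGraph) -> dict[int, float]:
    """Weighted betweenness centrality on distances d = −ln(w).

    Normalized by (n−1)(n−2) (directed convention); ties between
    equal-length shortest paths are split fractionally.
    """
    for _, _, d in graph.edges(data=True):
        if d["weight"] <= 0:
            raise ValueError("betweenness needs strictly positive weights "
                             "(distance −ln(w) undefined at w ≤ 0)")
    return nx.betweenness_centrality(graph, weight="distance",
                                     normalized=True)


def cross_region_strength(graph: nx.DiGraph, regions: RegionSet
                          ) -> tuple[np.ndarray, list[str]]:
    """Directed region × region mean edge weight.

    Entry (A, B) averages w(i→j) over all ordered pairs i ∈ A, j ∈ B,
    i ≠ j, counting absent edges as 0; the diagonal is the
    within-region mean over non-self pairs.
    """
    names = list(regions)
    nodes = set(graph.nodes)
    for name in names:
        if not (set(regions[name]) & nodes):
            raise ValueError(f"region {name!r} has no nodes in the graph")
    mat = np.zeros((len(names), len(names)))
    for a, na in enumerate(names):
        ia = sorted(set(regions[na]) & nodes)
        for b, nb in enumerate(names):
            ib = sorted(set(regions[nb]) & nodes)
            pairs = [(i, j) for i in ia for j in ib if i != j]
            if not pairs:
                mat[a, b] = 0.0
                continue
            w = [graph.edges[i, j]["weight"] if graph.has_edge(i, j) else 0.0
                 for i, j in pairs]
            mat[a, b] = float(np.mean(w))
    return mat, names


# --------------------------------------------------------------------
# paths

def region_center_residue(mean_ca_coords: np.ndarray, region) -> int:
    """Region residue whose mean Cα position is nearest the region
    centroid; ties broken by lowest residue index."""
    members = np.asarray(sorted(region), dtype=np.int64)
    if members.size == 0:
        raise ValueError("empty region")
    pts = mean_ca_coords[members]
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1)
    return int(members[np.argmin(d)])  # argmin returns first on ties


def shortest_path(graph: nx.DiGraph, source: int,
                  target: int) -> CommunicationPath:
    """Dijkstra shortest path on d = −ln(w) between two residues.

    Among equal-distance paths the one with fewer hops, then
    lexicographically smallest node sequence, is returned. An
    unreachable target yields a ``reachable=False`` result rather than
    an exception.
    """
    if source == target:
        raise ValueError("source and target must differ")
    if source not in graph or target not in graph:
        raise ValueError("source/target not in graph")
    try:
        dist = nx.dijkstra_path_length(graph, source, target,
                                       weight="distance")
    except nx.NetworkXNoPath:
        return CommunicationPath(source, target, [], np.inf, [],
                                 reachable=False)
    candidates = [tuple(p) for p in nx.all_shortest_paths(
        graph, source, target, weight="distance")]
    best = min(candidates, key=lambda p: (len(p), p))
    probs = [graph.edges[a, b]["weight"]
             for a, b in zip(best[:-1], best[1:])]
    # recompute distance from the chosen path (exact duality)
    dist = float(np.sum(-np.log(probs)))
    return CommunicationPath(source, target, list(best), dist, probs)


def shortest_paths_to_regions(graph: nx.DiGraph, regions: RegionSet,
                              mean_ca_coords: np.ndarray,
                              source_region: str = "beta1_alpha2",
                              endpoint_overrides: dict[str, int]
                              | None = None) -> dict[str, CommunicationPath]:
    """Shortest paths from the source-region center to each other
    region's center residue.

    ``endpoint_overrides`` maps region names to explicit residues
    (0-based), replacing the geometric-center choice.
    """
    overrides = endpoint_overrides or {}
    centers = {name: overrides.get(
        name, region_center_residue(mean_ca_coords, regions[name]))
        for name in regions}
    src = centers[source_region]
    out = {}
    for name in regions:
        if name == source_region:
            continue
        out[name] = shortest_path(graph, src, centers[name])
    return out


def detect_relays(paths_state_a: dict[str, CommunicationPath],
                  paths_state_b: dict[str, CommunicationPath]) -> dict:
    """Intermediates new in state b, lost from state a, per region pair.

    A relay residue is an intermediate present in the state-b path but
    absent from the state-a path for the same (source, target) pair.
    """
    if set(paths_state_a) != set(paths_state_b):
        missing = set(paths_state_a) ^ set(paths_state_b)
        raise ValueError(f"path sets disagree on region pairs: "
                         f"{sorted(missing)}")
    report = {}
    for key in paths_state_a:
        a, b = paths_state_a[key], paths_state_b[key]
        ia, ib = set(a.intermediates), set(b.intermediates)
        report[key] = {
            "relays": sorted(ib - ia),
            "lost": sorted(ia - ib),
            "unchanged": a.residues == b.residues,
            "path_a": a.residues,
            "path_b": b.residues,
        }
    return report


def all_relay_residues(report: dict) -> set[int]:
    return set().union(*(set(v["relays"]) for v in report.values())) \
        if report else set()


# --------------------------------------------------------------------
# pockets

def prioritize_pockets(pockets: list[PocketDefinition],
                       centrality: dict[int, float],
                       relays: set[int],
                       top_decile: float = 0.9,
                       relay_weight: float = 1.0,
                       hub_weight: float = 1.0) -> list[dict]:
    """Rank pockets by overlap with relays and high-centrality hubs.

    score = relay_weight·|pocket ∩ relays| +
    hub_weight·|pocket ∩ top-decile-centrality residues|; descending,
    ties broken by external pocket score (higher first) then pocket id.
    """
    if not pockets:
        raise ValueError("no pockets given")
    vals = np.array(list(centrality.values()))
    thr = np.quantile(vals, top_decile) if vals.size else np.inf
    hubs = {r for r, c in centrality.items() if c >= thr and c > 0}
    rows = []
    for p in pockets:
        r_overlap = p.residues & relays
        h_overlap = p.residues & hubs
        rows.append({
            "pocket_id": p.pocket_id,
            "score": relay_weight * len(r_overlap)
            + hub_weight * len(h_overlap),
            "relay_overlap_1based": sorted(r + 1 for r in r_overlap),
            "hub_overlap_1based": sorted(r + 1 for r in h_overlap),
            "external_score": p.score,
        })
    rows.sort(key=lambda r: (-r["score"],
                             -(r["external_score"]
                               if r["external_score"] is not None
                               else -np.inf),
                             r["pocket_id"]))
    return rows


def parse_fpocket_info(path: str | Path) -> list[PocketDefinition]:
    """Parse pocket residue lists from an fpocket ``*_info.txt``-style
    file or a plain TSV (pocket_id <tab> residue list).

    Residues in the file are 1-based; returned sets are 0-based.
    """
    text = Path(path).read_text()
    pockets: list[PocketDefinition] = []
    blocks = re.split(r"(?im)^pocket\s+(\d+)", text)
    if len(blocks) > 1:
        it = iter(blocks[1:])
        for pid, body in zip(it, it):
            score = None
            m = re.search(r"(?i)score\s*:\s*(-?[\d.]+)", body)
            if m:
                score = float(m.group(1))
            vol = None
            m = re.search(r"(?i)volume\s*:\s*(-?[\d.]+)", body)
            if m:
                vol = float(m.group(1))
            m = re.search(r"(?i)residues?\s*:\s*([\d,\s]+)", body)
            if not m:
                continue
            res = {int(tok) - 1 for tok in re.findall(r"\d+", m.group(1))}
            pockets.append(PocketDefinition(int(pid), res, score, vol))
    else:
        for line in text.strip().splitlines():
            if line.startswith("#") or not line.strip():
                continue
            pid, rest = line.split("\t", 1)
            res = {int(tok) - 1 for tok in re.findall(r"\d+", rest)}
            pockets.append(PocketDefinition(int(pid), res))
    if not pockets:
        raise ValueError(f"no pockets parsed from {path}")
    return pockets


# --------------------------------------------------------------------
# export

def export_edge_tsv(graph: nx.DiGraph, path: str | Path) -> None:
    """Cytoscape-compatible edge list (source, target, weight), 1-based."""
    lines = ["source\ttarget\tweight"]
    lines += [f"{i + 1}\t{j + 1}\t{d['weight']:.6f}"
              for i, j, d in graph.edges(data=True)]
    Path(path).write_text("\n".join(lines) + "\n")


def export_graphml(graph: nx.DiGraph, path: str | Path) -> None:
    g = nx.relabel_nodes(graph, {n: n + 1 for n in graph.nodes}, copy=True)
    nx.write_graphml(g, str(path))


def paths_to_json(paths: dict[str, CommunicationPath],
                  path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {k: v.as_record() for k, v in paths.items()}, indent=1))
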