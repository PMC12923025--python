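"""Structural and dynamic observables of a trajectory.

RMSD, per-residue RMSF, radius of gyration, heavy-atom contact counts,
geometric hydrogen bonds, Shrake–Rupley solvent-accessible surface
area, essential dynamics (PCA of Cα positional covariance), Boltzmann
free-energy landscapes over principal components, and porcupine-plot
export. Conventions follow the common MD-analysis tool defaults:
contacts are heavy-atom pairs within 0.45 nm (same-residue pairs
excluded), hydrogen bonds use donor–acceptor distance < 0.35 nm and
donor–hydrogen–acceptor angle > 150°.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import (Trajectory, _resolve_atom_mask,
                         _check_not_collinear, kabsch)

__all__ = [
    "FlexibilityProfile", "EssentialDynamics", "FreeEnergySurface",
    "HydrogenBond", "rmsd_series", "rmsf_profile", "count_contacts",
    "hydrogen_bonds", "radius_of_gyration", "sasa", "essential_dynamics",
    "free_energy_surface", "porcupine_export",
]

KB_KJ_PER_MOL_K = 0.00831446261815324

# Bondi van der Waals radii (nm)
_VDW_RADII = {"H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180,
              "P": 0.180, "SE": 0.190, "F": 0.147, "CL": 0.175}
_ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845,
                "ZN": 65.38, "MG": 24.305}


@dataclass
class FlexibilityProfile:
    """Per-residue root-mean-square fluctuation (nm)."""

    residues: np.ndarray
    rmsf: np.ndarray
    state: str = ""

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype=np.int64)
        self.rmsf = np.asarray(self.rmsf, dtype=np.float64)
        if np.any(self.rmsf < 0):
            raise ValueError("rmsf must be ≥ 0")
        if len(self.residues) != len(self.rmsf):
            raise ValueError("residues and rmsf length mismatch")

    def region_mean(self, region) -> float:
        mask = np.isin(self.residues, np.fromiter(region, dtype=np.int64))
        return float(self.rmsf[mask].mean())

    def to_tsv(self, path: str | Path) -> None:
        lines = ["# per-residue Cα RMSF; residue numbering 1-based; units nm",
                 "residue\trmsf_nm"]
        lines += [f"{r + 1}\t{v:.6f}"
                  for r, v in zip(self.residues, self.rmsf)]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EssentialDynamics:
    """PCA of the Cα positional covariance matrix."""

    mean_coords: np.ndarray       # (3N,)
    eigenvalues: np.ndarray       # descending, nm²
    eigenvectors: np.ndarray      # columns, orthonormal, (3N, 3N)
    projections: np.ndarray       # (frames, 3N) nm
    residues: np.ndarray

    def variance_fraction(self, n_components: int = 2) -> float:
        tot = self.eigenvalues.sum()
        return float(self.eigenvalues[:n_components].sum() / tot) \
            if tot > 0 else 0.0

    def reconstruct(self, n_components: int | None = None) -> np.ndarray:
        """Centered coordinates rebuilt from the leading components."""
        k = self.eigenvectors.shape[1] if n_components is None \
            else n_components
        return self.projections[:, :k] @ self.eigenvectors[:, :k].T


@dataclass
class FreeEnergySurface:
    """−kT·ln occupancy over a PC1/PC2 grid, zeroed at the deepest bin.

    Empty bins carry +inf (unbounded), never 0.
    """

    edges_pc1: np.ndarray
    edges_pc2: np.ndarray
    free_energy: np.ndarray   # kT units
    counts: np.ndarray
    temperature: float = 300.0

    def in_kj_per_mol(self) -> np.ndarray:
        return self.free_energy * KB_KJ_PER_MOL_K * self.temperature


@dataclass
class HydrogenBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float
    angle: float


# --------------------------------------------------------------------

def rmsd_series(traj: Trajectory, reference_frame: int = 0,
                selection=None) -> np.ndarray:
    """Per-frame RMSD (nm) to a reference frame after per-frame Kabsch fit."""
    mask = _resolve_atom_mask(traj, selection)
    if mask.sum() < 3:
        raise ValueError("RMSD needs at least 3 selected atoms")
    ref = traj.coords[reference_frame][mask]
    _check_not_collinear(ref)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.coords[f][mask]
        rot, cm, cr = kabsch(mob, ref)
        fitted = (mob - cm) @ rot.T + cr
        out[f] = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1)))
    return out


def rmsf_profile(traj: Trajectory, residues=None,
                 state: str = "") -> FlexibilityProfile:
    """Per-residue Cα RMSF about the time-mean position.

    The trajectory is assumed already superposed (same alignment
    protocol as the RMSD analysis).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    ca = traj.ca_coords()
    if residues is not None:
        residues = np.asarray(sorted(residues), dtype=np.int64)
        ca = ca[:, residues, :]
    else:
        residues = np.arange(ca.shape[1])
    mean = ca.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((ca - mean) ** 2, axis=2), axis=0))
    return FlexibilityProfile(residues, rmsf, state)


def count_contacts(traj: Trajectory, cutoff: float = 0.45) -> np.ndarray:
    """Per-frame count of heavy-atom pairs closer than ``cutoff`` nm.

    Pairs within the same residue are excluded. Uses a k-d tree
    neighbor list; the count equals the all-pairs result exactly.
    """
    heavy = np.flatnonzero(traj.atom_meta["heavy"].values)
    if heavy.size == 0:
        raise ValueError("no heavy atoms flagged in trajectory metadata")
    resid = traj.atom_meta["resid"].values[heavy]
    out = np.empty(traj.n_frames, dtype=np.int64)
    for f in range(traj.n_frames):
        tree = cKDTree(traj.coords[f][heavy])
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            # strict inequality per the contact definition
            d = np.linalg.norm(traj.coords[f][heavy][pairs[:, 0]]
                               - traj.coords[f][heavy][pairs[:, 1]], axis=1)
            keep = (d < cutoff) & (resid[pairs[:, 0]] != resid[pairs[:, 1]])
            out[f] = int(keep.sum())
        else:
            out[f] = 0
    return out


def hydrogen_bonds(traj: Trajectory, d_cut: float = 0.35,
                   angle_cut: float = 150.0,
                   covalent_cut: float = 0.12) -> list[list[HydrogenBond]]:
    """Geometric hydrogen bonds per frame.

    Donors are N/O atoms with a hydrogen within ``covalent_cut`` nm in
    the same residue; acceptors are any other N/O. A bond is recorded
    iff donor–acceptor distance < ``d_cut`` and the
    donor–hydrogen–acceptor angle > ``angle_cut`` degrees.
    """
    elems = traj.atom_meta["element"].values
    resid = traj.atom_meta["resid"].values
    no_idx = np.flatnonzero(np.isin(elems, ["N", "O"]))
    h_idx = np.flatnonzero(elems == "H")
    if h_idx.size == 0:
        import warnings
        warnings.warn("topology contains no hydrogens; hydrogen-bond "
                      "analysis returns empty results", stacklevel=2)
        return [[] for _ in range(traj.n_frames)]

    results: list[list[HydrogenBond]] = []
    for f in range(traj.n_frames):
        x = traj.coords[f]
        # donor-hydrogen pairing by covalent distance, same residue
        dh: list[tuple[int, int]] = []
        for h in h_idx:
            cand = no_idx[resid[no_idx] == resid[h]]
            if cand.size == 0:
                continue
            d = np.linalg.norm(x[cand] - x[h], axis=1)
            j = int(np.argmin(d))
            if d[j] < covalent_cut:
                dh.append((int(cand[j]), int(h)))
        bonds: list[HydrogenBond] = []
        for donor, h in dh:
            d_acc = np.linalg.norm(x[no_idx] - x[donor], axis=1)
            for acc, dda in zip(no_idx, d_acc):
                if acc == donor or dda >= d_cut:
                    continue
                v1 = x[donor] - x[h]
                v2 = x[acc] - x[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1)
                                           * np.linalg.norm(v2))
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if ang > angle_cut:
                    bonds.append(HydrogenBond(donor, h, int(acc),
                                              float(dda), ang))
        results.append(bonds)
    return results


def radius_of_gyration(traj: Trajectory,
                       mass_weighted: bool = True) -> np.ndarray:
    """Per-frame radius of gyration (nm)."""
    if mass_weighted:
        m = np.array([_ATOMIC_MASS.get(e, 12.011)
                      for e in traj.atom_meta["element"]])
    else:
        m = np.ones(traj.n_atoms)
    if m.sum() <= 0:
        raise ValueError("zero total mass")
    w = m / m.sum()
    com = np.einsum("a,fad->fd", w, traj.coords)
    dev = traj.coords - com[:, None, :]
    return np.sqrt(np.einsum("a,fad,fad->f", w, dev, dev))


# --------------------------------------------------------------------
# SASA

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere
    (golden-spiral quadrature)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 0.14,
         n_sphere_points: int = 960) -> tuple[np.ndarray, float]:
    """Shrake–Rupley solvent-accessible surface area of one frame.

    Each atom's sphere is expanded by the probe radius and covered
    with quadrature points; the accessible fraction (points outside
    every other expanded sphere) times 4π(r+probe)² is the per-atom
    area. Returns (per-atom areas, total) in nm².
    """
    coords = np.asarray(coords, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    n = coords.shape[0]
    expanded = radii + probe
    pts = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.empty(n)
    for a in range(n):
        sphere = coords[a] + expanded[a] * pts
        neighbors = [b for b in tree.query_ball_point(coords[a],
                                                      expanded[a] + max_r)
                     if b != a]
        if neighbors:
            nb = np.asarray(neighbors)
            d = np.linalg.norm(sphere[:, None, :] - coords[nb][None, :, :],
                               axis=2)
            buried = (d < expanded[nb][None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[a] = frac * 4.0 * np.pi * expanded[a] ** 2
    return areas, float(areas.sum())


def sasa_series(traj: Trajectory, probe: float = 0.14,
                n_sphere_points: int = 960) -> np.ndarray:
    """Per-frame total SASA (nm²) with Bondi radii by element."""
    radii = np.array([_VDW_RADII.get(e, 0.170)
                      for e in traj.atom_meta["element"]])
    return np.array([sasa(traj.coords[f], radii, probe, n_sphere_points)[1]
                     for f in range(traj.n_frames)])


# --------------------------------------------------------------------
# essential dynamics / FEL

def essential_dynamics(traj: Trajectory, residues=None) -> EssentialDynamics:
    """Diagonalize the 3N×3N Cα positional covariance (PCA).

    The trajectory must already be superposed. Eigenpairs are sorted
    by descending variance; projections are the centered coordinates
    in the eigenbasis.
    """
    if traj.n_frames < 2:
        raise ValueError("essential dynamics needs at least 2 frames")
    ca = traj.ca_coords()
    if residues is not None:
        residues = np.asarray(sorted(residues), dtype=np.int64)
        ca = ca[:, residues, :]
    else:
        residues = np.arange(ca.shape[1])
    flat = ca.reshape(traj.n_frames, -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.where(np.abs(evals) < 1e-12, np.maximum(evals, 0.0), evals)
    proj = centered @ evecs
    return EssentialDynamics(mean, evals, evecs, proj, residues)


def free_energy_surface(projections: np.ndarray, bins: int = 32,
                        temperature: float = 300.0) -> FreeEnergySurface:
    """F(bin) = −kT·ln(P/P_max) over the PC1/PC2 histogram.

    The most populated bin has F = 0 exactly; empty bins are +inf.
    Free energies are in kT units.
    """
    projections = np.asarray(projections)
    if projections.ndim != 2 or projections.shape[1] < 2:
        raise ValueError("projections must be (frames, ≥2)")
    if bins < 2:
        raise ValueError("bins must be ≥ 2")
    counts, e1, e2 = np.histogram2d(projections[:, 0], projections[:, 1],
                                    bins=bins)
    pmax = counts.max()
    with np.errstate(divide="ignore"):
        fe = -np.log(counts / pmax)
    fe[counts == 0] = np.inf
    return FreeEnergySurface(e1, e2, fe, counts.astype(np.int64),
                             temperature)


def porcupine_export(ed: EssentialDynamics, component: int, scale: float,
                     out_path: str | Path) -> Path:
    """Write PC displacement vectors as a PyMOL-style script plus TSV.

    One arrow per Cα; vector = eigenvector slice × scale. Returns the
    TSV path (script path is the same with a .pml suffix).
    """
    if component >= ed.eigenvectors.shape[1]:
        raise ValueError("component index out of range")
    out_path = Path(out_path)
    vecs = ed.eigenvectors[:, component].reshape(-1, 3) * scale
    mean = ed.mean_coords.reshape(-1, 3)
    lines = ["# porcupine vectors; residue numbering 1-based; units nm",
             "residue\tdx\tdy\tdz"]
    lines += [f"{r + 1}\t{v[0]:.6f}\t{v[1]:.6f}\t{v[2]:.6f}"
              for r, v in zip(ed.residues, vecs)]
    out_path.write_text("\n".join(lines) + "\n")
    pml = out_path.with_suffix(".pml")
    cgo = ["# PyMOL CGO arrows for principal-component displacements",
           "from pymol.cgo import CYLINDER", "obj = []"]
    for a, v in zip(mean, vecs):
        b = a + v
        cgo.append(
            "obj += [CYLINDER, {:.3f},{:.3f},{:.3f}, {:.3f},{:.3f},{:.3f},"
            " 0.2, 1,0,0, 1,0.6,0]".format(*(a * 10.0), *(b * 10.0)))
    cgo.append(f'cmd.load_cgo(obj, "pc{component + 1}_porcupine")')
    pml.write_text("\n".join(cgo) + "\n")
    return out_path
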