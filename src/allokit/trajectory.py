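"""Trajectory container, I/O and preprocessing for interaction inference.

Coordinates are stored in nm and times in ps throughout the package;
file formats that use Å (PDB, XTC via MDAnalysis) are converted on the
way in and out. Residue indices are 0-based internally and 1-based in
all user-facing output, following PDB convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory", "ResidueSelection", "FeatureTensor",
    "load_trajectory", "superpose", "kabsch", "downsample_uniform",
    "sparse_sample", "window_segments", "compute_features",
]

_HEAVY = {"C", "N", "O", "S", "P", "SE", "FE", "ZN", "MG", "CA", "MN"}


@dataclass
class Trajectory:
    """frames × atoms × 3 coordinates (nm) with per-atom metadata.

    ``atom_meta`` is a DataFrame with columns ``name``, ``element``,
    ``heavy`` (bool), ``resid`` (0-based), ``resname``, ``chain``.
    """

    coords: np.ndarray
    atom_meta: pd.DataFrame
    times: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if len(self.atom_meta) != self.coords.shape[1]:
            raise ValueError("atom_meta length does not match atom count")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length does not match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return int(self.atom_meta["resid"].nunique())

    def ca_indices(self) -> np.ndarray:
        """Atom indices of Cα (or sole-per-residue pseudo-)atoms."""
        mask = self.atom_meta["name"].values == "CA"
        if not mask.any():
            raise ValueError("trajectory has no CA-like atoms")
        return np.flatnonzero(mask)

    def ca_coords(self) -> np.ndarray:
        """frames × residues × 3 Cα coordinates, residue-sorted."""
        idx = self.ca_indices()
        order = np.argsort(self.atom_meta["resid"].values[idx], kind="stable")
        return self.coords[:, idx[order], :]

    def copy(self) -> "Trajectory":
        return Trajectory(self.coords.copy(), self.atom_meta.copy(),
                          self.times.copy())


@dataclass
class ResidueSelection:
    """A partition of residues into a selected half and its complement."""

    selected: np.ndarray
    complement: np.ndarray
    mode: str = "uniform"
    fraction: float = 0.5

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=np.int64)
        self.complement = np.asarray(self.complement, dtype=np.int64)
        if np.intersect1d(self.selected, self.complement).size:
            raise ValueError("selected and complement overlap")
        if len(set(self.selected.tolist())) != len(self.selected):
            raise ValueError("duplicate residue indices in selection")

    def reverse(self) -> "ResidueSelection":
        """The complementary (reverse-sampling) selection."""
        return ResidueSelection(self.complement.copy(), self.selected.copy(),
                                mode="reverse", fraction=1.0 - self.fraction)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "selected_1based": (self.selected + 1).tolist(),
            "complement_1based": (self.complement + 1).tolist(),
            "mode": self.mode, "fraction": self.fraction,
            "indexing": "1-based (PDB convention)",
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ResidueSelection":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["selected_1based"]) - 1,
                   np.array(d["complement_1based"]) - 1,
                   d["mode"], d["fraction"])


@dataclass
class FeatureTensor:
    """Per-frame node features: 3 position + 3 velocity channels.

    ``values`` has shape (frames, nodes, 6), scaled so the maximum
    absolute value within each channel group (positions, velocities)
    is 1 for nonzero input. Position channels are fluctuations about
    each node's time-mean position (the mean is kept in
    ``norm_constants["position_offset"]``), so that the same learned
    pairwise force law applies to every residue pair regardless of its
    equilibrium separation. ``norm_constants`` holds everything needed
    to undo the normalization.
    """

    values: np.ndarray
    norm_constants: dict = field(default_factory=dict)
    residue_ids: np.ndarray | None = None

    def denormalize(self) -> np.ndarray:
        out = self.values.copy()
        out[..., :3] *= self.norm_constants["position"]
        out[..., :3] += self.norm_constants["position_offset"]
        out[..., 3:] *= self.norm_constants["velocity"]
        return out

    def windows(self, window: int, stride: int) -> np.ndarray:
        """Stack :func:`window_segments` output: (segments, window, nodes, 6)."""
        return np.stack(window_segments(self.values, window, stride))


# --------------------------------------------------------------------
# I/O

def load_trajectory(topology_path: str | Path,
                    coords_path: str | Path | None = None) -> Trajectory:
    """Read PDB/GRO topology plus optional XTC/DCD coordinates.

    MDAnalysis does the format work; coordinates come back in nm.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if topology_path.suffix.lower() not in {".pdb", ".gro"}:
        raise ValueError(
            f"unsupported topology format {topology_path.suffix!r}; "
            "supported: .pdb, .gro")
    if coords_path is not None:
        coords_path = Path(coords_path)
        if coords_path.suffix.lower() not in {".xtc", ".dcd"}:
            raise ValueError(
                f"unsupported coordinate format {coords_path.suffix!r}; "
                "supported: .xtc, .dcd")
        try:
            u = mda.Universe(str(topology_path), str(coords_path))
        except Exception as err:  # MDAnalysis raises several types here
            raise ValueError(
                f"failed to combine {topology_path.name} with "
                f"{coords_path.name}: {err}") from err
    else:
        u = mda.Universe(str(topology_path))

    n_atoms = len(u.atoms)
    frames, times = [], []
    for ts in u.trajectory:
        if ts.positions.shape[0] != n_atoms:
            raise ValueError(
                f"atom-count mismatch: topology has {n_atoms}, "
                f"frame {ts.frame} has {ts.positions.shape[0]}")
        frames.append(ts.positions.astype(np.float64) / 10.0)  # Å → nm
        times.append(float(ts.time))
    times = np.asarray(times)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(times), dtype=np.float64)

    names = u.atoms.names
    try:
        elements = np.array([e.upper() for e in u.atoms.elements])
    except Exception:
        elements = np.array([_guess_element(n) for n in names])
    try:
        chains = u.atoms.segids
    except Exception:
        chains = np.array(["A"] * n_atoms)
    resids = u.atoms.resids
    # compact to 0-based in first-appearance order
    _, inverse = np.unique(resids, return_inverse=True)
    meta = pd.DataFrame({
        "name": names,
        "element": elements,
        "heavy": [e in _HEAVY and e != "H" for e in elements],
        "resid": inverse.astype(np.int64),
        "resname": u.atoms.resnames,
        "chain": chains,
    })
    return Trajectory(np.stack(frames), meta, times)


def _guess_element(name: str) -> str:
    n = name.strip().lstrip("0123456789")
    if not n:
        return "X"
    if n[:2].upper() in {"CL", "BR", "FE", "ZN", "MG", "SE", "NA", "MN"}:
        return n[:2].upper()
    return n[0].upper()


# --------------------------------------------------------------------
# superposition

def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns (rotation, mobile_centroid, reference_centroid) so that
    ``(x - mobile_centroid) @ rotation.T + reference_centroid`` is the
    superposed configuration.
    """
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, cm, cr


def _resolve_atom_mask(traj: Trajectory, selection) -> np.ndarray:
    if selection is None:
        return np.ones(traj.n_atoms, dtype=bool)
    if callable(selection):
        mask = np.asarray(selection(traj.atom_meta), dtype=bool)
    else:
        mask = np.asarray(selection)
        if mask.dtype != bool:
            full = np.zeros(traj.n_atoms, dtype=bool)
            full[mask] = True
            mask = full
    if mask.shape != (traj.n_atoms,):
        raise ValueError("selection mask has wrong length")
    return mask


def _check_not_collinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError("degenerate superposition: selected atoms are "
                         "collinear or coincident")


def superpose(traj: Trajectory, reference_frame: int = 0,
              selection=None) -> Trajectory:
    """Rigidly fit every frame onto ``reference_frame`` (Kabsch).

    The fit is computed on the selected atoms and applied to all atoms.
    Returns a new trajectory; the input is untouched.
    """
    mask = _resolve_atom_mask(traj, selection)
    if mask.sum() < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    ref = traj.coords[reference_frame][mask]
    _check_not_collinear(ref)
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        rot, cm, cr = kabsch(traj.coords[f][mask], ref)
        out[f] = (traj.coords[f] - cm) @ rot.T + cr
    return Trajectory(out, traj.atom_meta.copy(), traj.times.copy())


# --------------------------------------------------------------------
# sampling / windowing / features

def downsample_uniform(traj: Trajectory, target_frames: int) -> Trajectory:
    """Keep ``target_frames`` frames at even index spacing, first included.

    Frame i of the output is input frame round(i·(N−1)/(n−1)). A target
    at or above the frame count returns the trajectory unchanged.
    """
    if target_frames < 2:
        raise ValueError("target_frames must be ≥ 2")
    n = traj.n_frames
    if target_frames >= n:
        return traj
    idx = np.round(np.arange(target_frames) * (n - 1)
                   / (target_frames - 1)).astype(np.int64)
    return Trajectory(traj.coords[idx], traj.atom_meta.copy(),
                      traj.times[idx])


def sparse_sample(traj: Trajectory, fraction: float,
                  seed: int = 0) -> ResidueSelection:
    """Spatially uniform residue subset by farthest-point sampling.

    Operates on time-averaged Cα coordinates; the seed picks the
    starting residue. ceil(fraction·n) residues are selected and the
    rest stored as the reverse-sampling complement.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    mean_ca = traj.ca_coords().mean(axis=0)
    n = mean_ca.shape[0]
    k = int(np.ceil(fraction * n))
    if k >= n:
        return ResidueSelection(np.arange(n), np.array([], dtype=np.int64),
                                mode="uniform", fraction=fraction)
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n))
    selected = [start]
    dist = np.linalg.norm(mean_ca - mean_ca[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(dist))  # argmax is deterministic on ties
        selected.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(mean_ca - mean_ca[nxt], axis=1))
    sel = np.sort(np.array(selected, dtype=np.int64))
    comp = np.setdiff1d(np.arange(n), sel)
    return ResidueSelection(sel, comp, mode="uniform", fraction=fraction)


def window_segments(features: np.ndarray, window: int,
                    stride: int) -> list[np.ndarray]:
    """Cut a frames-leading array into windows of fixed length.

    Segments start at 0, stride, 2·stride, …; each has exactly
    ``window`` frames, giving ⌊(n_frames − window)/stride⌋ + 1 segments.
    """
    features = np.asarray(features)
    n = features.shape[0]
    if window < 2:
        raise ValueError("window must be ≥ 2")
    if stride < 1:
        raise ValueError("stride must be ≥ 1")
    if n < window:
        raise ValueError(f"need at least {window} frames, got {n}")
    starts = range(0, n - window + 1, stride)
    return [features[s:s + window] for s in starts]


def compute_features(traj: Trajectory,
                     selection: ResidueSelection | None = None
                     ) -> FeatureTensor:
    """Cα fluctuations + finite-difference velocities, max-|value|
    normalized.

    Position channels are each node's displacement from its time-mean
    position: a spring force linearized about equilibrium is then a
    shared function of the two nodes' channel values, which is what a
    weight-shared relational decoder can represent. Velocities are
    v_t = (x_{t+1} − x_t)/Δt with the last frame repeating the
    previous velocity (saved trajectories carry no velocities, so
    finite differences are the only self-consistent choice). Each
    channel group is scaled so its maximum absolute value is 1; scale
    factors and position offsets are kept for de-normalization.
    """
    if traj.n_frames < 2:
        raise ValueError("cannot form velocities from a single frame")
    ca = traj.ca_coords()
    if selection is not None:
        if len(selection.selected) == 0:
            raise ValueError("empty residue selection")
        ca = ca[:, selection.selected, :]
        resids = selection.selected.copy()
    else:
        resids = np.arange(ca.shape[1])
    dt = np.diff(traj.times)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    offset = ca.mean(axis=0)
    ca = ca - offset
    vel = np.empty_like(ca)
    vel[:-1] = (ca[1:] - ca[:-1]) / dt[:, None, None]
    vel[-1] = vel[-2]
    pos_scale = float(np.abs(ca).max())
    vel_scale = float(np.abs(vel).max())
    pos_scale = pos_scale if pos_scale > 0 else 1.0
    vel_scale = vel_scale if vel_scale > 0 else 1.0
    values = np.concatenate([ca / pos_scale, vel / vel_scale], axis=-1)
    return FeatureTensor(values,
                         {"position": pos_scale, "velocity": vel_scale,
                          "position_offset": offset},
                         residue_ids=resids)
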