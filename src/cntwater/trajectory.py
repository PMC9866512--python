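"""Trajectory containers, file I/O and cylindrical-channel geometry.

Coordinates are in Å, times in ps throughout.  A water molecule is
represented by its oxygen atom everywhere in the analysis chain; hydrogens
enter only through molecule grouping and hydrogen-bond geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class TrajectoryParseError(ValueError):
    """A trajectory file is malformed (e.g. atom count changes mid-file)."""


class GroupingError(ValueError):
    """Water-molecule grouping failed (an O without exactly two H)."""


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinate block with uniform frame spacing.

    Parameters
    ----------
    positions : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Å.
    dt : float
        Frame spacing in ps.
    labels : sequence of str
        Element symbol per atom ("O", "H", "C", ...).
    metadata : dict
        Free-form provenance record.
    """

    positions: np.ndarray
    dt: float
    labels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape[0] != self.positions.shape[1]:
            raise ValueError("labels length must equal atom count")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps (frame index × dt)."""
        return np.arange(self.n_frames) * self.dt


@dataclass
class TubeGeometry:
    """Cylindrical channel: a point on the axis, unit axis direction, radius
    and an axial interval delimiting the open channel."""

    axis_point: np.ndarray
    axis_dir: np.ndarray
    radius: float
    z_range: tuple

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        self.axis_dir = np.asarray(self.axis_dir, dtype=float)
        norm = np.linalg.norm(self.axis_dir)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("axis_dir must be nonzero")
            self.axis_dir = self.axis_dir / norm
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        z0, z1 = self.z_range
        if not z1 > z0:
            raise ValueError("z_range must be a nonempty interval")
        self.z_range = (float(z0), float(z1))

    @property
    def length(self) -> float:
        return self.z_range[1] - self.z_range[0]

    def basis(self) -> tuple:
        """Deterministic right-handed orthonormal basis (e1, e2, axis_dir)."""
        u = self.axis_dir
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, u)) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        e1 = trial - np.dot(trial, u) * u
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        return e1, e2, u


@dataclass
class WaterSystem:
    """Water molecules as (O index, H index, H index) atom triples."""

    molecules: list
    unpaired: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for mol in self.molecules:
            for idx in mol:
                if idx in seen:
                    raise ValueError(f"atom {idx} appears in more than one molecule")
                seen.add(idx)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def o_indices(self) -> np.ndarray:
        return np.array([m[0] for m in self.molecules], dtype=int)


@dataclass
class ResidencyTable:
    """Per-molecule sorted half-open frame intervals of in-channel residence."""

    intervals: list  # list (per molecule) of [(f0, f1), ...]
    n_frames: int

    def __post_init__(self) -> None:
        for mol_iv in self.intervals:
            prev_end = -1
            for f0, f1 in mol_iv:
                if not (0 <= f0 < f1 <= self.n_frames):
                    raise ValueError(f"interval ({f0}, {f1}) out of range")
                if f0 <= prev_end:
                    raise ValueError("intervals must be sorted and disjoint")
                prev_end = f1

    def mask(self) -> np.ndarray:
        """Boolean (n_frames, n_molecules) in-channel indicator."""
        out = np.zeros((self.n_frames, len(self.intervals)), dtype=bool)
        for j, mol_iv in enumerate(self.intervals):
            for f0, f1 in mol_iv:
                out[f0:f1, j] = True
        return out


@dataclass
class CylindricalCoords:
    """Per-frame per-molecule cylindrical coordinates about the tube axis."""

    r: np.ndarray      # (n_frames, n_molecules), Å
    theta: np.ndarray  # radians in (-pi, pi]
    z: np.ndarray      # Å along axis_dir from axis_point


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("xyz", "pdb", "dcd"):
        return suffix
    raise ValueError(f"cannot infer trajectory format from suffix {path.suffix!r}")


def read_trajectory(path, format: str | None = None, dt: float | None = None,
                    topology=None) -> Trajectory:
    """Read an XYZ, multi-MODEL PDB or DCD trajectory.

    XYZ and PDB carry no time metadata, so ``dt`` must be supplied for them.
    DCD requires ``topology``: a one-column text file listing the element
    symbol of each atom in order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "xyz":
        return _read_xyz(path, dt)
    if fmt == "pdb":
        return _read_pdb(path, dt)
    if fmt == "dcd":
        return _read_dcd(path, topology, dt)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def _require_dt(dt, fmt: str) -> float:
    if dt is None:
        raise ValueError(
            f"{fmt} files carry no time metadata; dt (ps) must be given explicitly"
        )
    return float(dt)


def _read_xyz(path: Path, dt) -> Trajectory:
    dt = _require_dt(dt, "XYZ")
    lines = path.read_text().splitlines()
    frames = []
    labels0 = None
    i = 0
    fidx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryParseError(
                f"frame {fidx}: expected atom-count line, got {lines[i]!r}")
        block = lines[i + 2:i + 2 + nat]
        if len(block) < nat:
            raise TrajectoryParseError(f"frame {fidx}: truncated frame "
                                       f"({len(block)} of {nat} atom lines)")
        labels = []
        coords = np.empty((nat, 3))
        for k, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise TrajectoryParseError(f"frame {fidx}: bad atom line {ln!r}")
            labels.append(parts[0])
            coords[k] = [float(v) for v in parts[1:4]]
        if labels0 is None:
            labels0 = labels
        elif len(labels) != len(labels0):
            raise TrajectoryParseError(
                f"frame {fidx}: atom count changed from {len(labels0)} to {len(labels)}")
        frames.append(coords)
        i += 2 + nat
        fidx += 1
    if not frames:
        raise TrajectoryParseError("no frames found")
    return Trajectory(np.stack(frames), dt, np.asarray(labels0, dtype=object),
                      {"source": str(path), "format": "xyz"})


def write_xyz(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\nframe {f}\n")
            for lab, (x, y, z) in zip(traj.labels, traj.positions[f]):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def _scan_pdb_models(path: Path) -> list:
    """Atom count per MODEL block (whole file = one model if no MODEL records)."""
    counts = []
    current = 0
    in_model = False
    saw_model = False
    for ln in path.read_text().splitlines():
        rec = ln[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if not saw_model:
        counts = [current]
    elif in_model:
        counts.append(current)
    return counts


def _read_pdb(path: Path, dt) -> Trajectory:
    dt = _require_dt(dt, "PDB")
    counts = _scan_pdb_models(path)
    if not counts or counts[0] == 0:
        raise TrajectoryParseError("no ATOM records found")
    for midx, c in enumerate(counts):
        if c != counts[0]:
            raise TrajectoryParseError(
                f"frame {midx}: MODEL atom count {c} differs from first model "
                f"({counts[0]})")
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        try:
            labels = [str(e) for e in u.atoms.elements]
        except Exception:
            labels = [name.strip("0123456789") or name for name in u.atoms.names]
        frames = np.stack([u.atoms.positions.copy().astype(float)
                           for _ in u.trajectory])
    return Trajectory(frames, dt, np.asarray(labels, dtype=object),
                      {"source": str(path), "format": "pdb"})


def write_pdb(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, (lab, (x, y, z)) in enumerate(zip(traj.labels, traj.positions[f])):
                serial = (i + 1) % 100000
                fh.write(
                    f"ATOM  {serial:5d}  {lab:<3s} HOH A{(i // 3 + 1) % 10000:4d}"
                    f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"          {lab:>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _read_dcd(path: Path, topology, dt) -> Trajectory:
    if topology is None:
        raise ValueError("DCD requires a companion text topology "
                         "(one element symbol per line)")
    labels = [ln.strip() for ln in Path(topology).read_text().splitlines()
              if ln.strip()]
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(len(labels), trajectory=True)
        try:
            u.load_new(str(path))
        except Exception as exc:  # atom-count mismatch surfaces here
            raise TrajectoryParseError(
                f"DCD/topology mismatch or malformed DCD: {exc}") from exc
        if dt is None:
            dt = float(u.trajectory.dt)
        frames = np.stack([u.atoms.positions.copy().astype(float)
                           for _ in u.trajectory])
    return Trajectory(frames, float(dt), np.asarray(labels, dtype=object),
                      {"source": str(path), "format": "dcd"})


def write_dcd(traj: Trajectory, path, topology_path) -> None:
    """Write a DCD plus its one-column element topology sidecar."""
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        with mda.coordinates.DCD.DCDWriter(str(path), traj.n_atoms,
                                           dt=traj.dt) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.positions[f].astype(np.float32)
                w.write(u.atoms)
    Path(topology_path).write_text("\n".join(str(l) for l in traj.labels) + "\n")


# ---------------------------------------------------------------------------
# molecule grouping and geometry
# ---------------------------------------------------------------------------

OH_CUTOFF = 1.2  # Å; intramolecular O-H upper bound


def build_water_system(traj: Trajectory, cutoff: float = OH_CUTOFF) -> WaterSystem:
    """Group O and H atoms into water molecules using frame 0.

    Each H is assigned to its nearest O; every O must end up with exactly
    two H within ``cutoff``.  Atoms that are neither O nor H, and H atoms
    farther than ``cutoff`` from every O, are reported as unpaired.
    """
    from scipy.spatial import cKDTree

    labels = np.asarray([str(l).upper() for l in traj.labels])
    o_idx = np.flatnonzero(labels == "O")
    h_idx = np.flatnonzero(labels == "H")
    if o_idx.size == 0:
        raise GroupingError("no oxygen atoms in trajectory")
    frame0 = traj.positions[0].astype(float)
    unpaired = [int(i) for i in np.flatnonzero(~np.isin(labels, ("O", "H")))]
    assigned: dict = {int(i): [] for i in o_idx}
    if h_idx.size:
        tree = cKDTree(frame0[o_idx])
        dist, nearest = tree.query(frame0[h_idx])
        for h, d, oi in zip(h_idx, dist, nearest):
            if d <= cutoff:
                assigned[int(o_idx[oi])].append(int(h))
            else:
                unpaired.append(int(h))
    bad = {o: hs for o, hs in assigned.items() if len(hs) != 2}
    if bad:
        desc = "; ".join(f"O atom {o} has {len(hs)} H within {cutoff} Å"
                         for o, hs in sorted(bad.items()))
        raise GroupingError(f"water grouping failed: {desc}")
    molecules = [(o, hs[0], hs[1]) for o, hs in sorted(assigned.items())]
    return WaterSystem(molecules=molecules, unpaired=sorted(unpaired))


def cylindrical_transform(traj: Trajectory, ws: WaterSystem,
                          tube: TubeGeometry) -> CylindricalCoords:
    """Cylindrical (r, θ, z) of each molecule's O atom about the tube axis.

    r = 0 is the channel centre; z is measured along ``axis_dir`` from
    ``axis_point``.  The transform is invariant under rigid motions applied
    jointly to the system and the tube.
    """
    e1, e2, u = tube.basis()
    pos = traj.positions[:, ws.o_indices, :].astype(float) - tube.axis_point
    z = pos @ u
    x = pos @ e1
    y = pos @ e2
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    return CylindricalCoords(r=r, theta=theta, z=z)


def inside_mask(coords: CylindricalCoords, tube: TubeGeometry) -> np.ndarray:
    """Boolean (frames, molecules): strict r < radius, inclusive z bounds."""
    z0, z1 = tube.z_range
    return (coords.r < tube.radius) & (coords.z >= z0) & (coords.z <= z1)


def residency(traj: Trajectory, ws: WaterSystem, tube: TubeGeometry,
              coords: CylindricalCoords | None = None) -> ResidencyTable:
    """Maximal in-channel frame intervals per molecule."""
    if coords is None:
        coords = cylindrical_transform(traj, ws, tube)
    mask = inside_mask(coords, tube)
    n_frames = mask.shape[0]
    intervals = []
    for j in range(mask.shape[1]):
        col = mask[:, j]
        edges = np.flatnonzero(np.diff(np.concatenate(([0], col.view(np.int8), [0]))))
        mol_iv = [(int(edges[k]), int(edges[k + 1]))
                  for k in range(0, len(edges), 2)]
        intervals.append(mol_iv)
    return ResidencyTable(intervals=intervals, n_frames=n_frames)


def fit_axis(traj: Trajectory, element: str = "C") -> tuple:
    """Optional helper: axis as the principal axis of the given element
    (default: the carbon wall) in frame 0.  Returns (axis_point, axis_dir)."""
    labels = np.asarray([str(l).upper() for l in traj.labels])
    sel = np.flatnonzero(labels == element.upper())
    if sel.size < 3:
        raise ValueError(f"need at least 3 {element} atoms to fit an axis")
    pts = traj.positions[0, sel, :].astype(float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    direction = vt[0]
    if direction[np.argmax(np.abs(direction))] < 0:
        direction = -direction
    return centroid, direction
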