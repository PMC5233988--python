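"""Lightweight trajectory container and multi-model PDB I/O.

A :class:`Trajectory` holds time-ordered coordinate frames for a labelled
particle set (bound ions, water oxygens, protein atoms).  Frames are a
single ``(n_frames, n_particles, 3)`` array in Å; particle roles are
resolved once at load time from configurable residue/atom name sets, so
the analysis code never touches topology objects.

Multi-model PDB files (MODEL/ENDMDL records) are read and written through
MDAnalysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .states import ResidueKey

__all__ = [
    "Particle",
    "Trajectory",
    "MetricWindow",
    "TrajectoryError",
    "InsufficientDataError",
    "WATER_RESNAMES",
    "ION_NAMES",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
]

#: Residue names recognised as water.
WATER_RESNAMES = frozenset({"HOH", "TIP3", "SOL", "WAT", "TIP"})
#: Residue or atom names recognised as a sodium ion.
ION_NAMES = frozenset({"NA", "SOD", "NA+"})


class TrajectoryError(ValueError):
    """Malformed trajectory or window."""


class InsufficientDataError(TrajectoryError):
    """Too few frames in the requested window."""


@dataclass(frozen=True)
class Particle:
    id: str
    role: str  # ion | water_oxygen | protein_atom | other
    residue: Optional[ResidueKey] = None


@dataclass
class Trajectory:
    """Time-ordered frames of labelled particles.

    coords : (n_frames, n_particles, 3) float array, Å
    times  : (n_frames,) strictly increasing, ps
    box    : optional (3,) orthorhombic box lengths, Å
    """

    coords: np.ndarray
    times: np.ndarray
    particles: tuple[Particle, ...]
    box: Optional[np.ndarray] = None

    _ion_idx: np.ndarray = field(init=False, repr=False)
    _water_idx: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError(f"coords must be (F, P, 3); got {self.coords.shape}")
        if self.coords.shape[0] < 2:
            raise TrajectoryError("a trajectory needs at least 2 frames")
        if self.coords.shape[:2] != (len(self.times), len(self.particles)):
            raise TrajectoryError("coords shape disagrees with times/particles")
        if not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise TrajectoryError("box must be 3 positive lengths")
        roles = np.array([p.role for p in self.particles])
        object.__setattr__(self, "_ion_idx", np.flatnonzero(roles == "ion"))
        object.__setattr__(self, "_water_idx", np.flatnonzero(roles == "water_oxygen"))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def ion_indices(self) -> np.ndarray:
        return self._ion_idx

    @property
    def water_indices(self) -> np.ndarray:
        return self._water_idx

    @property
    def sampling_interval(self) -> float:
        """Median inter-frame spacing in ps."""
        return float(np.median(np.diff(self.times)))

    def ion_coords(self) -> np.ndarray:
        return self.coords[:, self._ion_idx, :]

    def water_coords(self) -> np.ndarray:
        return self.coords[:, self._water_idx, :]


@dataclass(frozen=True)
class MetricWindow:
    """Averaging window [start_time, end_time] in ps."""

    start_time: float
    end_time: float

    def __post_init__(self) -> None:
        if not self.start_time < self.end_time:
            raise TrajectoryError(
                f"window start {self.start_time} must precede end {self.end_time}")

    def frame_mask(self, traj: Trajectory) -> np.ndarray:
        if self.start_time < traj.times[0] - 1e-9 or self.end_time > traj.times[-1] + 1e-9:
            raise TrajectoryError("window lies outside the trajectory time span")
        return (traj.times >= self.start_time - 1e-9) & (traj.times <= self.end_time + 1e-9)


def default_window(traj: Trajectory, tail_ps: float = 10_000.0,
                   tail_fraction: float = 0.2) -> MetricWindow:
    """Default averaging window: the last 10 ns of the trajectory.

    When the trajectory is shorter than ``tail_ps``, the final
    ``tail_fraction`` of frames is used instead.
    """
    t0, t1 = float(traj.times[0]), float(traj.times[-1])
    if t1 - t0 > tail_ps:
        return MetricWindow(t1 - tail_ps, t1)
    k = max(2, int(np.ceil(traj.n_frames * tail_fraction)))
    return MetricWindow(float(traj.times[-k]), t1)


# ---------------------------------------------------------------------------
# PDB I/O (MDAnalysis)

def _classify(resname: str, atom_name: str, water_resnames, ion_names) -> str:
    rn = resname.strip().upper()
    an = atom_name.strip().upper()
    if rn in ion_names or an in ion_names:
        return "ion"
    if rn in water_resnames:
        return "water_oxygen" if an.startswith("O") else "other"
    return "protein_atom"


def read_multimodel_pdb(path, water_resnames=WATER_RESNAMES,
                        ion_names=ION_NAMES) -> Trajectory:
    """Load a multi-model PDB as a :class:`Trajectory`.

    Waters are identified by residue name (HOH/TIP3/SOL by default) and
    only their oxygen is tracked; ions by residue or atom name (NA/SOD).
    MODEL blocks are taken as frames; times are reconstructed from the
    ``REMARK 250 SAMPLING INTERVAL`` header when present, else 1 ps/frame.
    """
    import MDAnalysis as mda

    interval = 1.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK 250 SAMPLING INTERVAL PS"):
                interval = float(line.split()[-1])
            if line.startswith(("MODEL", "ATOM", "HETATM")):
                break
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        particles = []
        for atom in u.atoms:
            role = _classify(atom.resname, atom.name, water_resnames, ion_names)
            res = None
            if role == "protein_atom":
                chain = getattr(atom, "chainID", "") or getattr(atom, "segid", "A") or "A"
                res = ResidueKey(str(chain), int(atom.resid), str(atom.resname).upper())
            particles.append(Particle(id=f"{atom.resname}:{atom.resid}:{atom.name}",
                                      role=role, residue=res))
        keep = [i for i, p in enumerate(particles) if p.role != "other"]
        coords = np.stack([u.atoms.positions[keep].copy()
                           for _ in u.trajectory])
        box = None
        dims = u.dimensions
        if dims is not None and np.all(dims[:3] > 0):
            box = np.array(dims[:3], dtype=float)
    times = interval * np.arange(coords.shape[0])
    return Trajectory(coords=coords, times=times,
                      particles=tuple(particles[i] for i in keep), box=box)


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as an uncompressed multi-model PDB."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n = len(traj.particles)
    names, resnames, resids = [], [], []
    for i, p in enumerate(traj.particles):
        if p.role == "ion":
            names.append("NA")
            resnames.append("SOD")
        elif p.role == "water_oxygen":
            names.append("OH2")
            resnames.append("HOH")
        else:
            names.append("CA")
            resnames.append(p.residue.residue_name if p.residue else "GLY")
        resids.append(p.residue.residue_number if p.residue else i + 1)

    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.load_new(np.ascontiguousarray(traj.coords, dtype=np.float32),
               format=MemoryReader)
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    # prepend the sampling interval so reads round-trip the time axis
    text = path.read_text()
    header = f"REMARK 250 SAMPLING INTERVAL PS {traj.sampling_interval:.6g}\n"
    path.write_text(header + text)
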