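"""Core domain types: topology, frames, trajectories and membrane reference geometry.

Conventions used throughout the package: coordinates in Å, times in ns, the
membrane normal along z, and generated membrane patches centred at z = 0.
"Heavy atom" means any non-hydrogen atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .roles import MEMBRANE_ROLES, ROLES, LIPID_HEAD, LIPID_GLYCEROL


class LdbindError(Exception):
    """Base class for package errors."""


class ParseError(LdbindError):
    """A structure or trajectory file could not be parsed."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    ``residue_index`` is 1-based within its chain/molecule numbering (PDB
    resSeq); ``molecule_id`` numbers whole molecules (a protein chain, a
    single lipid, one core neutral lipid).
    """

    atom_id: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    molecule_id: int
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")

    @property
    def is_heavy(self) -> bool:
        return self.element.strip().upper() != "H"


class Topology:
    """Ordered collection of :class:`AtomRecord` with cached numpy views."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms = list(atoms)
        n = len(self.atoms)
        self.role = np.array([a.role for a in self.atoms], dtype=object)
        self.residue_index = np.array([a.residue_index for a in self.atoms], dtype=int)
        self.residue_name = np.array([a.residue_name for a in self.atoms], dtype=object)
        self.molecule_id = np.array([a.molecule_id for a in self.atoms], dtype=int)
        self.atom_name = np.array([a.atom_name for a in self.atoms], dtype=object)
        self.atom_id = np.array([a.atom_id for a in self.atoms], dtype=int)
        self.is_heavy = np.array([a.is_heavy for a in self.atoms], dtype=bool)
        self._n = n

    def __len__(self) -> int:
        return self._n

    def __iter__(self):
        return iter(self.atoms)

    def __getitem__(self, i: int) -> AtomRecord:
        return self.atoms[i]

    @property
    def n_atoms(self) -> int:
        return self._n

    def protein_residue_ids(self) -> np.ndarray:
        """Sorted unique residue indices of protein atoms."""
        mask = self.role == "protein"
        return np.unique(self.residue_index[mask])


@dataclass
class Frame:
    """Coordinates of every topology atom at one time point.

    ``box`` holds orthorhombic x, y, z edge lengths in Å; periodicity is
    applied in x and y only (the membrane normal is not periodic in analysis).
    """

    frame_index: int
    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")


@dataclass
class Trajectory:
    """A topology plus an ordered list of frames sharing it."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for f in self.frames:
            if f.coords.shape[0] != n:
                raise ValueError(
                    f"frame {f.frame_index}: {f.coords.shape[0]} coordinates "
                    f"for a {n}-atom topology"
                )
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass
class MembraneGeometry:
    """Per-frame membrane reference planes (all arrays of length n_frames, Å).

    ``center_z`` is the mean z of all lipid heavy atoms (core neutral lipids
    included for filled-monolayer systems); the head and glycerol planes are
    leaflet means of the designated headgroup / glycerol-region atoms.
    """

    center_z: np.ndarray
    head_plane_upper: np.ndarray
    head_plane_lower: np.ndarray
    glycerol_plane_upper: np.ndarray
    glycerol_plane_lower: np.ndarray


def select_atoms(
    topology: Topology,
    role: str | Iterable[str] | None = None,
    residue_index: int | Iterable[int] | None = None,
    is_heavy: bool | None = None,
    predicate: Callable[[AtomRecord], bool] | None = None,
) -> np.ndarray:
    """Return the sorted array of atom indices matching every given criterion.

    An empty selection is valid and returns an empty array.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    if role is not None:
        roles = {role} if isinstance(role, str) else set(role)
        mask &= np.isin(topology.role, list(roles))
    if residue_index is not None:
        if isinstance(residue_index, (int, np.integer)):
            residue_index = [int(residue_index)]
        mask &= np.isin(topology.residue_index, list(residue_index))
    if is_heavy is not None:
        mask &= topology.is_heavy == is_heavy
    idx = np.flatnonzero(mask)
    if predicate is not None:
        idx = np.array([i for i in idx if predicate(topology[i])], dtype=int)
    return idx


def membrane_geometry(
    traj: Trajectory, lipid_selection: np.ndarray | None = None
) -> MembraneGeometry:
    """Compute per-frame membrane centre and leaflet reference planes.

    The membrane centre is the mean z of all lipid heavy atoms (solvent
    excluded; core neutral lipids included).  Leaflets are assigned per frame
    by the sign of each headgroup atom's z relative to the lipid centroid.
    """
    top = traj.topology
    if lipid_selection is None:
        lipid_selection = select_atoms(top, role=MEMBRANE_ROLES, is_heavy=True)
    lipid_selection = np.asarray(lipid_selection, dtype=int)
    if lipid_selection.size == 0:
        raise ValueError("empty lipid selection")

    head_idx = lipid_selection[top.role[lipid_selection] == LIPID_HEAD]
    gly_idx = lipid_selection[top.role[lipid_selection] == LIPID_GLYCEROL]
    if head_idx.size == 0:
        raise ValueError("lipid selection contains no headgroup atoms")

    n = traj.n_frames
    center = np.empty(n)
    hp_u = np.empty(n)
    hp_l = np.empty(n)
    gp_u = np.full(n, np.nan)
    gp_l = np.full(n, np.nan)
    for k, frame in enumerate(traj.frames):
        z = frame.coords[:, 2]
        center[k] = z[lipid_selection].mean()
        zh = z[head_idx]
        upper = zh >= center[k]
        if not upper.any() or upper.all():
            raise ValueError(f"frame {k}: a leaflet has zero lipid headgroups")
        hp_u[k] = zh[upper].mean()
        hp_l[k] = zh[~upper].mean()
        if gly_idx.size:
            zg = z[gly_idx]
            gu = zg >= center[k]
            if gu.any():
                gp_u[k] = zg[gu].mean()
            if (~gu).any():
                gp_l[k] = zg[~gu].mean()
    return MembraneGeometry(center, hp_u, hp_l, gp_u, gp_l)


def minimum_image_xy(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention in x and y to displacement vectors."""
    d = np.array(d, dtype=float, copy=True)
    for axis in (0, 1):
        L = box[axis]
        d[..., axis] -= L * np.round(d[..., axis] / L)
    return d
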