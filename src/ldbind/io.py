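"""Structure and trajectory I/O.

Formats: fixed-column PDB (ATOM/HETATM) for single structures and multi-model
trajectories, and a multi-frame XYZ container (atom-count line, comment line
carrying ``t=<ns>``, then ``name x y z`` records) with a JSON topology
sidecar as the package-native trajectory format.  Binary formats (DCD etc.)
are delegated to MDAnalysis when it is installed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .model import AtomRecord, Frame, ParseError, Topology, Trajectory
from .roles import RoleMap

_DEFAULT_BOX = np.array([1000.0, 1000.0, 1000.0])


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    return name[:1].upper() if name else "C"


def _records_from_model(model, role_map: RoleMap) -> tuple[list[AtomRecord], np.ndarray]:
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    mol_id = 0
    atom_id = 0
    for chain in model:
        prev_key = None
        for residue in chain:
            resname = residue.get_resname().strip()
            resseq = residue.get_id()[1]
            key = (chain.id, resseq, resname)
            if key != prev_key:
                mol_id += 1
                prev_key = key
            for atom in residue:
                atom_id += 1
                name = atom.get_name()
                element = (atom.element or "").strip() or _guess_element(name)
                records.append(
                    AtomRecord(
                        atom_id=atom_id,
                        atom_name=name,
                        element=element,
                        residue_index=max(int(resseq), 1),
                        residue_name=resname,
                        molecule_id=mol_id,
                        role=role_map.assign(resname, name),
                    )
                )
                coords.append(np.asarray(atom.get_coord(), dtype=float))
    return records, np.array(coords, dtype=float).reshape(-1, 3)


def read_structure(
    path: str | Path,
    role_map: RoleMap | None = None,
    box: np.ndarray | None = None,
) -> tuple[Topology, Frame]:
    """Read a PDB file into a topology and a single frame.

    Roles are assigned from residue/atom names via ``role_map`` (default
    mapping if omitted); unknown residue names become solvent with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    role_map = role_map or RoleMap.default()
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("s", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    records, coords = _records_from_model(models[0], role_map)
    if not records:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    frame = Frame(frame_index=0, time=0.0,
                  box=_DEFAULT_BOX if box is None else box, coords=coords)
    return Topology(records), frame


def write_structure(path: str | Path, topology: Topology, frame: Frame) -> None:
    """Write a topology + frame as fixed-column PDB ATOM records."""
    lines = []
    for a, xyz in zip(topology.atoms, frame.coords):
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"ATOM  {a.atom_id % 100000:5d} {name:<4.4s} {a.residue_name:<4.4s}A"
            f"{a.residue_index % 10000:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2.2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory_pdb(
    topology: Topology, path: str | Path, dt: float = 1.0,
    box: np.ndarray | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a trajectory over an existing topology."""
    path = Path(path)
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("t", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    role_map = RoleMap.default()
    frames = []
    for k, model in enumerate(structure):
        _, coords = _records_from_model(model, role_map)
        if coords.shape[0] != topology.n_atoms:
            raise ParseError(
                f"{path}: frame {k} has {coords.shape[0]} atoms, "
                f"topology has {topology.n_atoms}"
            )
        frames.append(Frame(k, k * dt, _DEFAULT_BOX if box is None else box, coords))
    if not frames:
        raise ParseError(f"{path}: no models found")
    return Trajectory(topology, frames)


# -- multi-frame XYZ ---------------------------------------------------------

def write_trajectory_xyz(path: str | Path, traj: Trajectory) -> None:
    """Write a trajectory as multi-frame XYZ (comment carries t and box)."""
    with open(path, "w") as fh:
        names = [a.atom_name for a in traj.topology.atoms]
        for frame in traj.frames:
            fh.write(f"{traj.topology.n_atoms}\n")
            bx, by, bz = frame.box
            fh.write(f"t={frame.time:.6f} box={bx:.3f},{by:.3f},{bz:.3f}\n")
            for name, (x, y, z) in zip(names, frame.coords):
                fh.write(f"{name} {x:.3f} {y:.3f} {z:.3f}\n")


def read_trajectory_xyz(
    topology: Topology, path: str | Path, dt: float = 1.0
) -> Trajectory:
    """Read a multi-frame XYZ file against an existing topology.

    Times come from ``t=<ns>`` in the comment line when present, otherwise
    frame_index * dt.  A frame whose atom count disagrees with the topology,
    or a truncated final frame, raises :class:`ParseError` naming the frame.
    """
    n_top = topology.n_atoms
    frames: list[Frame] = []
    lines = Path(path).read_text().splitlines()
    pos = 0
    k = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ParseError(f"{path}: bad atom-count line at frame {k}") from exc
        if n != n_top:
            raise ParseError(f"{path}: frame {k} declares {n} atoms, topology has {n_top}")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        time = k * dt
        box = _DEFAULT_BOX
        for token in comment.split():
            if token.startswith("t="):
                time = float(token[2:])
            elif token.startswith("box="):
                box = np.array([float(v) for v in token[4:].split(",")])
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise ParseError(f"{path}: frame {k} truncated ({len(body)}/{n} atom lines)")
        try:
            coords = np.array(
                [[float(v) for v in ln.split()[1:4]] for ln in body], dtype=float
            )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: unparseable coordinates in frame {k}") from exc
        if coords.shape != (n, 3):
            raise ParseError(f"{path}: unparseable coordinates in frame {k}")
        frames.append(Frame(k, time, box, coords))
        pos += 2 + n
        k += 1
    if not frames:
        raise ParseError(f"{path}: empty trajectory")
    return Trajectory(topology, frames)


def read_trajectory(
    topology: Topology, path: str | Path, dt: float = 1.0
) -> Trajectory:
    """Dispatch on extension: ``.xyz`` multi-frame XYZ, ``.pdb`` multi-model PDB."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        return read_trajectory_pdb(topology, path, dt=dt)
    return read_trajectory_xyz(topology, path, dt=dt)


# -- JSON topology sidecar ---------------------------------------------------

def write_topology_json(path: str | Path, topology: Topology) -> None:
    payload = [
        {
            "atom_id": a.atom_id, "atom_name": a.atom_name, "element": a.element,
            "residue_index": a.residue_index, "residue_name": a.residue_name,
            "molecule_id": a.molecule_id, "role": a.role,
        }
        for a in topology.atoms
    ]
    Path(path).write_text(json.dumps(payload))


def read_topology_json(path: str | Path) -> Topology:
    payload = json.loads(Path(path).read_text())
    return Topology([AtomRecord(**entry) for entry in payload])
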