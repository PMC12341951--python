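"""Synthetic membrane patches, pseudo-proteins and scripted binding trajectories.

This module replaces microsecond all-atom MD with scripted, seeded ground
truth so that every downstream analysis (contacts, penetration depth, packing
defects) can be tested against known parameters.  It emulates:

* a planar membrane patch — a standard two-leaflet bilayer, or a bilayer
  bisected by a slab of core neutral lipids (wax esters or TAG) that turns
  each leaflet into a lipid-droplet-like monolayer over a hydrophobic core;
* a rigid pseudo-protein placed at a configurable height above the membrane
  centre in one of 6 canonical starting orientations (rotations of 0, 90,
  180, 270 degrees about x and +/-90 about y);
* approach / binding / insertion kinematics: a mean-reverting vertical
  approach, steering of designated binding residues to a set depth below the
  proximal headgroup plane over a short ramp, an optional reversible
  "bounce" (contact then retreat by >= 20 A), thermal jitter on all beads,
  and stochastic surfacing of core neutral lipids that clears a disc of
  phospholipids and creates a packing defect.

Lipids are bead-resolution pseudo-molecules (one headgroup bead, one
glycerol bead, two acyl tails of chain beads); the analyses only consume
heavy-atom positions and role tags, so no chemistry is represented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3

from .composition import allocate_counts, get_table
from .model import AtomRecord, Frame, Topology, Trajectory, select_atoms
from .roles import CORE_NEUTRAL, LIPID_CHAIN, LIPID_GLYCEROL, LIPID_HEAD, PROTEIN

# bead-scale geometry constants (A)
CHAIN_SPACING = 1.5          # z spacing of successive tail beads
HEAD_ABOVE_GLYCEROL = 2.5    # headgroup bead height above the glycerol bead
GLYCEROL_CLEARANCE = 1.5     # glycerol bead height above the first tail bead
SLAB_MARGIN = 0.5            # core beads stay this far inside the core slab
TAIL_OFFSET = 0.8            # +/- x offset of the two tails
INSERTION_RAMP_FRAMES = 5
BOUNCE_RETREAT = 25.0        # centroid retreat distance after a bounce (>= 20)

MEMBRANE_KINDS = ("bilayer", "we_monolayer", "tag_monolayer")


@dataclass
class ScenarioConfig:
    """Full parameterisation of one synthetic binding scenario.

    Heights and depths in A, times in ns.  ``placement_height`` is the
    protein-centroid height above the membrane centre at frame 0 (50 for the
    filled-monolayer systems, 40 for plain bilayers, matching the simulated
    set-ups this generator emulates).  ``surfacing_rate`` is the Poisson rate
    (events/ns) at which core neutral-lipid molecules transiently surface,
    displacing phospholipids in a disc and exposing the core.
    """

    membrane_kind: str = "we_monolayer"
    composition: str = "jojoba"
    patch_dims: tuple[float, float] = (60.0, 60.0)
    core_gap: float = 30.0
    orientation_index: int = 1
    placement_height: float = 50.0
    binding_residues: frozenset[int] = frozenset(range(40, 46))
    bind_time: float = 80.0
    insertion_depth: float = 6.0
    bounce: bool = False
    surfacing_rate: float = 0.2
    jitter_sigma: float = 0.4
    n_frames: int = 200
    dt: float = 1.0
    seed: int = 0
    protein: str = "pseudo"
    # generator internals (defaults chosen once; see docs/methods.md)
    n_lipids_per_leaflet: int = 100
    n_core_molecules: int = 40
    chain_beads: int = 10
    n_protein_residues: int = 60
    beads_per_residue: int = 6
    surfacing_disc_radius: float = 5.0
    surfacing_dwell_mean: float = 10.0
    approach_tau_fraction: float = 3.0

    def __post_init__(self) -> None:
        if self.membrane_kind not in MEMBRANE_KINDS:
            raise ValueError(f"membrane_kind must be one of {MEMBRANE_KINDS}")
        if not 1 <= self.orientation_index <= 6:
            raise ValueError("orientation_index must be in 1..6")
        if self.placement_height <= 0:
            raise ValueError("placement_height must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.surfacing_rate < 0:
            raise ValueError("surfacing_rate must be >= 0")
        self.binding_residues = frozenset(int(r) for r in self.binding_residues)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["binding_residues"] = sorted(self.binding_residues)
        d["patch_dims"] = list(self.patch_dims)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown ScenarioConfig key(s): {sorted(unknown)}")
        data = dict(data)
        if "patch_dims" in data:
            data["patch_dims"] = tuple(data["patch_dims"])
        if "binding_residues" in data:
            data["binding_residues"] = frozenset(data["binding_residues"])
        return cls(**data)


# ---------------------------------------------------------------------------
# membrane patch

def _leaflet_lipid(code: str, x: float, y: float, zoff: float, sign: int,
                   chain_beads: int, mol_id: int, res_index: int,
                   atom_id0: int) -> tuple[list[AtomRecord], list[list[float]]]:
    """One bead lipid: head, glycerol, two tails pointing toward the centre."""
    gly_z = zoff + GLYCEROL_CLEARANCE + chain_beads * CHAIN_SPACING
    head_z = gly_z + HEAD_ABOVE_GLYCEROL
    records, coords = [], []
    aid = atom_id0

    def add(name, element, role, cx, cy, cz):
        nonlocal aid
        aid += 1
        records.append(AtomRecord(aid, name, element, res_index, code, mol_id, role))
        coords.append([cx, cy, sign * cz])

    add("PH", "P", LIPID_HEAD, x, y, head_z)
    add("GL", "C", LIPID_GLYCEROL, x, y, gly_z)
    for tail, dx in enumerate((-TAIL_OFFSET, TAIL_OFFSET)):
        for k in range(chain_beads):
            add(f"C{tail + 1}{k + 1:d}", "C", LIPID_CHAIN,
                x + dx, y, gly_z - GLYCEROL_CLEARANCE - k * CHAIN_SPACING)
    return records, coords


def _core_molecule(kind: str, x: float, y: float, core_gap: float,
                   mol_id: int, res_index: int, atom_id0: int,
                   rng: np.random.Generator) -> tuple[list[AtomRecord], list[list[float]]]:
    """A wax-ester (two acyl arms + ester bead) or TAG (glycerol bead + three
    arms) spanning the core slab between the leaflets."""
    lo = -core_gap / 2 + SLAB_MARGIN
    hi = core_gap / 2 - SLAB_MARGIN
    records, coords = [], []
    aid = atom_id0
    resname = "WE" if kind == "we_monolayer" else "TAG"

    def add(name, cx, cy, cz):
        nonlocal aid
        aid += 1
        records.append(AtomRecord(aid, name, "C", res_index, resname, mol_id, CORE_NEUTRAL))
        coords.append([cx, cy, cz])

    if resname == "WE":
        # two vertical arms joined by an ester bead at mid-height
        n_arm = 5
        zs = np.linspace(lo, hi, 2 * n_arm + 1)
        for k, z in enumerate(zs):
            dx = -1.0 if k < n_arm else (0.0 if k == n_arm else 1.0)
            name = "ES" if k == n_arm else f"W{k + 1}"
            add(name, x + dx + rng.uniform(-0.3, 0.3), y + rng.uniform(-0.3, 0.3), z)
    else:
        add("GL", x, y, hi)
        n_arm = 4
        for arm in range(3):
            ang = 2 * math.pi * arm / 3
            dx, dy = 1.0 * math.cos(ang), 1.0 * math.sin(ang)
            for k, z in enumerate(np.linspace(hi - 1.0, lo, n_arm)):
                add(f"T{arm + 1}{k + 1}", x + dx + rng.uniform(-0.3, 0.3),
                    y + dy + rng.uniform(-0.3, 0.3), z)
    return records, coords


def build_membrane_patch(
    kind: str,
    composition: str = "jojoba",
    patch_dims: tuple[float, float] = (60.0, 60.0),
    core_gap: float = 30.0,
    seed: int = 0,
    n_lipids_per_leaflet: int = 100,
    n_core_molecules: int = 40,
    chain_beads: int = 10,
) -> tuple[Topology, Frame]:
    """Build a planar bead-resolution membrane patch centred at z = 0.

    Phospholipids sit on a jittered lattice in two leaflets whose per-leaflet
    headgroup counts follow largest-remainder allocation of ``composition``.
    For ``we_monolayer`` / ``tag_monolayer`` the leaflets are separated by a
    ``core_gap`` slab filled with core neutral-lipid bead molecules.
    """
    if kind not in MEMBRANE_KINDS:
        raise ValueError(f"membrane kind must be one of {MEMBRANE_KINDS}")
    if not 8 <= chain_beads <= 12:
        raise ValueError("chain_beads must be in 8..12")
    table = get_table(composition)
    counts = allocate_counts(table, n_lipids_per_leaflet)
    lx, ly = patch_dims
    nx = math.ceil(math.sqrt(n_lipids_per_leaflet))
    ny = math.ceil(n_lipids_per_leaflet / nx)
    sx, sy = lx / nx, ly / ny
    if min(sx, sy) < 2.0:
        raise ValueError("patch too small for the requested lipid count")

    rng = np.random.default_rng(seed)
    zoff = core_gap / 2 if kind != "bilayer" else 0.0

    # per-leaflet species sequence, shuffled over lattice sites
    species = [code for code, n in counts.items() for _ in range(n)]

    records: list[AtomRecord] = []
    coords: list[list[float]] = []
    mol_id = 0
    for sign in (1, -1):
        order = rng.permutation(n_lipids_per_leaflet)
        for site, sp_idx in enumerate(order):
            code = species[sp_idx]
            ix, iy = site % nx, site // nx
            x = (ix + 0.5) * sx + rng.uniform(-0.5, 0.5)
            y = (iy + 0.5) * sy + rng.uniform(-0.5, 0.5)
            mol_id += 1
            recs, crds = _leaflet_lipid(code, x, y, zoff, sign, chain_beads,
                                        mol_id, mol_id, len(records))
            records.extend(recs)
            coords.extend(crds)

    if kind != "bilayer":
        for _ in range(n_core_molecules):
            x = rng.uniform(0, lx)
            y = rng.uniform(0, ly)
            mol_id += 1
            recs, crds = _core_molecule(kind, x, y, core_gap, mol_id, mol_id,
                                        len(records), rng)
            records.extend(recs)
            coords.extend(crds)

    z_span = 2 * (zoff + GLYCEROL_CLEARANCE + chain_beads * CHAIN_SPACING
                  + HEAD_ABOVE_GLYCEROL)
    box = np.array([lx, ly, z_span + 120.0])
    return Topology(records), Frame(0, 0.0, box, np.array(coords))


# ---------------------------------------------------------------------------
# pseudo-protein and placement

def build_pseudo_protein(
    n_residues: int = 60,
    beads_per_residue: int = 6,
    sequence: str | None = None,
) -> tuple[Topology, Frame]:
    """Compact rigid pseudo-protein: residues on a Fibonacci-sphere shell,
    each a small cluster of heavy beads.  Deterministic (no randomness)."""
    if sequence is not None and len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    radius = math.sqrt(n_residues * 25.0 / (4 * math.pi))  # ~5 A residue spacing
    golden = math.pi * (3.0 - math.sqrt(5.0))
    offsets = np.array([
        [0, 0, 0], [1.2, 0, 0], [-1.2, 0, 0],
        [0, 1.2, 0], [0, -1.2, 0], [0, 0, 1.2], [0, 0, -1.2],
    ])[:beads_per_residue]
    records, coords = [], []
    aid = 0
    for i in range(n_residues):
        zu = 1.0 - 2.0 * (i + 0.5) / n_residues
        r_xy = math.sqrt(max(0.0, 1.0 - zu * zu))
        theta = golden * i
        center = radius * np.array([r_xy * math.cos(theta), r_xy * math.sin(theta), zu])
        resname = (protein_letters_1to3[sequence[i]].upper()
                   if sequence else "ALA")
        for b, off in enumerate(offsets):
            aid += 1
            records.append(AtomRecord(aid, f"B{b + 1}", "C", i + 1, resname, 1, PROTEIN))
            coords.append(center + off)
    return Topology(records), Frame(0, 0.0, np.array([1000.0, 1000.0, 1000.0]),
                                    np.array(coords))


#: canonical starting orientations: rotations about x by 0/90/180/270 deg
#: (indices 1-4) and about y by +90/-90 deg (indices 5-6)
def orientation_matrix(orientation_index: int) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    if not 1 <= orientation_index <= 6:
        raise ValueError("orientation_index must be in 1..6")
    if orientation_index <= 4:
        return Rotation.from_euler("x", 90.0 * (orientation_index - 1), degrees=True).as_matrix()
    sign = 1.0 if orientation_index == 5 else -1.0
    return Rotation.from_euler("y", sign * 90.0, degrees=True).as_matrix()


def place_protein(
    protein_coords: np.ndarray,
    orientation_index: int,
    placement_height: float,
    center_z: float,
    box: np.ndarray,
) -> np.ndarray:
    """Rotate the rigid protein into a canonical orientation and translate its
    centroid to ``placement_height`` above the membrane centre, centred in x,y."""
    R = orientation_matrix(orientation_index)
    centroid = protein_coords.mean(axis=0)
    rotated = (protein_coords - centroid) @ R.T
    target = np.array([box[0] / 2, box[1] / 2, center_z + placement_height])
    return rotated + target


def combine_systems(parts: list[tuple[Topology, np.ndarray]]) -> tuple[Topology, np.ndarray]:
    """Concatenate (topology, coords) parts, renumbering atom and molecule ids."""
    records: list[AtomRecord] = []
    coords = []
    aid = 0
    mol_off = 0
    for top, crd in parts:
        max_mol = 0
        for a in top.atoms:
            aid += 1
            max_mol = max(max_mol, a.molecule_id)
            records.append(AtomRecord(aid, a.atom_name, a.element, a.residue_index,
                                      a.residue_name, a.molecule_id + mol_off, a.role))
        mol_off += max_mol
        coords.append(crd)
    return Topology(records), np.concatenate(coords, axis=0)


# ---------------------------------------------------------------------------
# trajectory generation

def _surfacing_events(cfg: ScenarioConfig, n_core: int, rng: np.random.Generator):
    """Poisson surfacing schedule: list of (frame_start, frame_end, molecule)."""
    events = []
    for f in range(cfg.n_frames):
        for _ in range(rng.poisson(cfg.surfacing_rate * cfg.dt)):
            mol = int(rng.integers(n_core))
            dwell = rng.exponential(cfg.surfacing_dwell_mean)
            events.append((f, f + max(1, math.ceil(dwell / cfg.dt)), mol))
    return events


def generate_trajectory(cfg: ScenarioConfig) -> Trajectory:
    """Generate a scripted binding trajectory for one scenario.

    All randomness derives from ``cfg.seed`` through fixed sub-streams (patch
    construction; kinematics; surfacing schedule; per-frame bead jitter), so
    identical configs are bit-reproducible and adding frames does not
    reshuffle earlier jitter.
    """
    mem_top, mem_frame = build_membrane_patch(
        cfg.membrane_kind, cfg.composition, cfg.patch_dims, cfg.core_gap,
        seed=np.random.default_rng([cfg.seed, 0]).integers(2**31),
        n_lipids_per_leaflet=cfg.n_lipids_per_leaflet,
        n_core_molecules=cfg.n_core_molecules, chain_beads=cfg.chain_beads,
    )
    prot_top, prot_frame = build_pseudo_protein(
        cfg.n_protein_residues, cfg.beads_per_residue)
    missing = set(cfg.binding_residues) - set(prot_top.protein_residue_ids().tolist())
    if missing:
        raise ValueError(f"binding residues not in the protein: {sorted(missing)}")

    box = mem_frame.box
    lipid_heavy = select_atoms(mem_top, role={LIPID_HEAD, LIPID_GLYCEROL,
                                              LIPID_CHAIN, CORE_NEUTRAL}, is_heavy=True)
    center_z = float(mem_frame.coords[lipid_heavy, 2].mean())
    head_sel = select_atoms(mem_top, role=LIPID_HEAD)
    head_z = mem_frame.coords[head_sel, 2]
    head_plane = float(head_z[head_z >= center_z].mean())

    placed = place_protein(prot_frame.coords, cfg.orientation_index,
                           cfg.placement_height, center_z, box)
    topology, base = combine_systems([(mem_top, mem_frame.coords),
                                      (prot_top, placed)])
    n_mem = mem_top.n_atoms
    prot_slice = slice(n_mem, n_mem + prot_top.n_atoms)
    prot_res = topology.residue_index[prot_slice]
    is_binding = np.isin(prot_res, sorted(cfg.binding_residues))
    near_binding = np.array([
        any(abs(r - b) <= 3 for b in cfg.binding_residues) for r in prot_res
    ]) & ~is_binding
    far_nonbind = ~is_binding & ~near_binding

    centroid_z0 = placed[:, 2].mean()
    min_off = placed[:, 2].min() - centroid_z0  # lowest bead relative to centroid
    clearance = 1.0 if cfg.bounce else 6.0
    z_contact = head_plane + clearance - min_off  # centroid height at contact
    tau = max(cfg.bind_time / cfg.approach_tau_fraction, cfg.dt)

    rng_kin = np.random.default_rng([cfg.seed, 1])
    rng_ev = np.random.default_rng([cfg.seed, 2])
    events = _surfacing_events(cfg, cfg.n_core_molecules, rng_ev) \
        if cfg.membrane_kind != "bilayer" else []

    # core molecule atom indices and per-molecule top bead
    core_mols: list[np.ndarray] = []
    if cfg.membrane_kind != "bilayer":
        core_idx = select_atoms(mem_top, role=CORE_NEUTRAL)
        for mid in np.unique(mem_top.molecule_id[core_idx]):
            core_mols.append(core_idx[mem_top.molecule_id[core_idx] == mid])
    lipid_mols: list[np.ndarray] = []
    lipid_head_of_mol: list[int] = []
    upper_lipid = head_sel[head_z >= center_z]
    for h in upper_lipid:
        mid = mem_top.molecule_id[h]
        lipid_mols.append(np.flatnonzero(mem_top.molecule_id == mid))
        lipid_head_of_mol.append(h)
    head_xy0 = mem_frame.coords[lipid_head_of_mol, :2] if lipid_head_of_mol else np.empty((0, 2))

    bind_frame = int(round(cfg.bind_time / cfg.dt))
    frames: list[Frame] = []
    z_c = centroid_z0
    contact_frame = None
    retreating = False

    for f in range(cfg.n_frames):
        coords = base.copy()
        rng_jit = np.random.default_rng([cfg.seed, 3, f])

        # membrane jitter
        coords[:n_mem] += rng_jit.normal(0.0, cfg.jitter_sigma, size=(n_mem, 3))

        # surfacing events: clear a phospholipid disc and expose the core bead
        for (f0, f1, mol) in events:
            if not (f0 <= f < f1) or mol >= len(core_mols):
                continue
            atoms = core_mols[mol]
            top_bead = atoms[np.argmax(base[atoms, 2])]
            cx, cy = base[top_bead, :2]
            coords[top_bead, 2] = head_plane - 0.5
            if head_xy0.shape[0]:
                d = head_xy0 - np.array([cx, cy])
                d -= box[:2] * np.round(d / box[:2])
                r = np.hypot(d[:, 0], d[:, 1])
                hit = np.flatnonzero((r < cfg.surfacing_disc_radius) & (r > 1e-9))
                for li in hit:
                    push = (cfg.surfacing_disc_radius + 1.0 - r[li])
                    coords[lipid_mols[li], :2] += push * d[li] / r[li]

        # protein vertical kinematics (mean-reverting approach); frame 0 is
        # the initial placement itself
        if f == 0:
            pass
        elif retreating:
            z_c = min(z_c + 2.5, centroid_z0)
        else:
            drift = (cfg.dt / tau) * (z_contact - z_c)
            z_c = max(z_c + drift + 0.6 * math.sqrt(cfg.dt) * rng_kin.normal(), z_contact)
            if cfg.bounce and contact_frame is None and z_c <= z_contact + 0.5:
                contact_frame = f
            if cfg.bounce and contact_frame is not None and f >= contact_frame + 5:
                retreating = True
        rng_pj = np.random.default_rng([cfg.seed, 4, f])
        pcoords = placed + np.array([0.0, 0.0, z_c - centroid_z0])
        pcoords = pcoords + rng_pj.normal(0.0, 0.2, size=pcoords.shape)

        # insertion steering of the scripted binding residues
        if not cfg.bounce and f >= bind_frame:
            ramp = min(1.0, (f - bind_frame + 1) / INSERTION_RAMP_FRAMES)
            target_z = head_plane - cfg.insertion_depth
            idx = np.flatnonzero(is_binding)
            rel = placed[idx, 2] - placed[idx, 2].mean()
            goal = target_z + 0.3 * rel
            pcoords[idx, 2] = (1 - ramp) * pcoords[idx, 2] + ramp * goal
        # keep non-binding residues above the head plane
        lim_far = head_plane + 6.0
        lim_near = head_plane + 1.0
        pcoords[far_nonbind, 2] = np.maximum(pcoords[far_nonbind, 2], lim_far)
        pcoords[near_binding, 2] = np.maximum(pcoords[near_binding, 2], lim_near)
        coords[prot_slice] = pcoords

        frames.append(Frame(f, f * cfg.dt, box.copy(), coords))

    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# ideal helix builder

_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from (a, b, c) with given c-d bond, b-c-d angle and
    a-b-c-d torsion (natural extension reference frame)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def generate_ideal_helix(
    sequence: str, phi: float = -57.0, psi: float = -47.0, omega: float = 180.0
) -> tuple[Topology, Frame]:
    """Build backbone (N, CA, C, O) coordinates of an ideal alpha-helix by
    sequential internal-coordinate placement with phi = -57, psi = -47 deg."""
    sequence = sequence.strip().upper()
    if len(sequence) < 4:
        raise ValueError("sequence must have length >= 4")
    bad = [c for c in sequence if c not in protein_letters_1to3]
    if bad:
        raise ValueError(f"unknown amino-acid letter(s): {sorted(set(bad))}")

    n_res = len(sequence)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [_B_N_CA, 0.0, 0.0]
    ang = math.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi)
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, omega)
        C[i] = _nerf(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi)
    O = np.zeros((n_res, 3))
    for i in range(n_res):
        O[i] = _nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)

    records, coords = [], []
    aid = 0
    for i, letter in enumerate(sequence):
        resname = protein_letters_1to3[letter].upper()
        for name, element, xyz in (("N", "N", N[i]), ("CA", "C", CA[i]),
                                   ("C", "C", C[i]), ("O", "O", O[i])):
            aid += 1
            records.append(AtomRecord(aid, name, element, i + 1, resname, 1, PROTEIN))
            coords.append(xyz)
    return Topology(records), Frame(0, 0.0, np.array([1000.0, 1000.0, 1000.0]),
                                    np.array(coords))
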