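import numpy as np
import pytest

from ldbind.model import AtomRecord, Frame, Topology, Trajectory
from ldbind.synthetic import ScenarioConfig, generate_trajectory


def make_toy_system(protein_atoms, membrane_atoms, box=(100.0, 100.0, 400.0)):
    """Tiny hand-built system: ``protein_atoms`` is a list of
    (residue_index, (x, y, z)); ``membrane_atoms`` a list of (x, y, z)
    acyl-chain beads.  Returns a one-frame Trajectory."""
    records, coords = [], []
    aid = 0
    for res, xyz in protein_atoms:
        aid += 1
        records.append(AtomRecord(aid, "CA", "C", res, "ALA", 1, "protein"))
        coords.append(xyz)
    for i, xyz in enumerate(membrane_atoms):
        aid += 1
        records.append(AtomRecord(aid, f"C{i}", "C", i + 1, "PC", 100 + i,
                                  "lipid_chain"))
        coords.append(xyz)
    top = Topology(records)
    frame = Frame(0, 0.0, np.array(box, dtype=float), np.array(coords, float))
    return Trajectory(top, [frame])


def mirror_patch(n_side=4, spacing=5.0, head_z=19.0, gly_z=16.5, chain_z=10.0):
    """Exactly mirror-symmetric bead bilayer centred at z = 0."""
    records, coords = [], []
    aid = 0
    mol = 0
    for sign in (1, -1):
        for i in range(n_side):
            for j in range(n_side):
                mol += 1
                x, y = (i + 0.5) * spacing, (j + 0.5) * spacing
                for name, el, role, z in (("PH", "P", "lipid_head", head_z),
                                          ("GL", "C", "lipid_glycerol", gly_z),
                                          ("C11", "C", "lipid_chain", chain_z)):
                    aid += 1
                    records.append(AtomRecord(aid, name, el, mol, "PC", mol, role))
                    coords.append([x, y, sign * z])
    top = Topology(records)
    box = np.array([n_side * spacing, n_side * spacing, 200.0])
    return top, Frame(0, 0.0, box, np.array(coords))


RECOVERY_CONFIG = dict(
    membrane_kind="we_monolayer",
    n_frames=100,
    bind_time=30.0,
    binding_residues=frozenset(range(40, 46)),
    seed=7,
)


@pytest.fixture(scope="session")
def recovery_trajectory():
    """Scripted binding scenario: residues 40-45 inserted after 30 ns."""
    return generate_trajectory(ScenarioConfig(**RECOVERY_CONFIG))


@pytest.fixture(scope="session")
def recovery_config():
    return ScenarioConfig(**RECOVERY_CONFIG)
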