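"""Core model types, atom selection, membrane geometry, and file round-trips."""

import numpy as np
import pytest

from ldbind.io import (read_structure, read_trajectory, write_structure,
                       write_topology_json, read_topology_json,
                       write_trajectory_xyz)
from ldbind.model import (AtomRecord, Frame, ParseError, Topology, Trajectory,
                          membrane_geometry, select_atoms)
from ldbind.synthetic import build_membrane_patch

from conftest import mirror_patch


class TestStructureIO:
    def test_pdb_round_trip_preserves_atoms_and_coords(self, tmp_path):
        top, frame = build_membrane_patch("we_monolayer", n_lipids_per_leaflet=9,
                                          patch_dims=(20, 20), n_core_molecules=2)
        path = tmp_path / "patch.pdb"
        write_structure(path, top, frame)
        top2, frame2 = read_structure(path)
        assert top2.n_atoms == top.n_atoms
        assert [a.atom_name for a in top2] == [a.atom_name for a in top]
        assert [a.role for a in top2] == [a.role for a in top]
        assert np.abs(frame2.coords - frame.coords).max() < 1e-3

    def test_hydrogen_atom_is_not_heavy(self, tmp_path):
        records = [AtomRecord(1, "CA", "C", 1, "ALA", 1, "protein"),
                   AtomRecord(2, "H1", "H", 1, "ALA", 1, "protein")]
        frame = Frame(0, 0.0, np.array([10.0, 10, 10]), np.zeros((2, 3)))
        path = tmp_path / "h.pdb"
        write_structure(path, Topology(records), frame)
        top, _ = read_structure(path)
        assert [a.is_heavy for a in top] == [True, False]

    def test_empty_file_raises_parse_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ParseError):
            read_structure(path)

    def test_unknown_residue_becomes_solvent(self, tmp_path):
        records = [AtomRecord(1, "X1", "C", 1, "QQQ", 1, "solvent")]
        frame = Frame(0, 0.0, np.array([10.0, 10, 10]), np.zeros((1, 3)))
        path = tmp_path / "u.pdb"
        write_structure(path, Topology(records), frame)
        top, _ = read_structure(path)
        assert top[0].role == "solvent"


class TestTrajectoryIO:
    def _static_traj(self, n_frames=3):
        top, frame = build_membrane_patch("bilayer", n_lipids_per_leaflet=4,
                                          patch_dims=(12, 12))
        frames = [Frame(k, float(k), frame.box, frame.coords.copy())
                  for k in range(n_frames)]
        return Trajectory(top, frames)

    def test_three_identical_frames_round_trip(self, tmp_path):
        traj = self._static_traj()
        path = tmp_path / "t.xyz"
        write_trajectory_xyz(path, traj)
        traj2 = read_trajectory(traj.topology, path)
        assert traj2.n_frames == 3
        for f1, f2 in zip(traj.frames, traj2.frames):
            assert np.abs(f1.coords - f2.coords).max() < 1e-3
            assert f1.time == pytest.approx(f2.time)

    def test_truncated_last_frame_names_the_frame(self, tmp_path):
        traj = self._static_traj()
        path = tmp_path / "t.xyz"
        write_trajectory_xyz(path, traj)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-5]) + "\n")
        with pytest.raises(ParseError, match="frame 2"):
            read_trajectory(traj.topology, path)

    def test_mismatched_atom_count_raises(self, tmp_path):
        traj = self._static_traj()
        path = tmp_path / "t.xyz"
        write_trajectory_xyz(path, traj)
        other, _ = build_membrane_patch("bilayer", n_lipids_per_leaflet=6,
                                        patch_dims=(14, 14))
        with pytest.raises(ParseError, match="frame 0"):
            read_trajectory(other, path)

    def test_topology_json_round_trip(self, tmp_path):
        top, _ = build_membrane_patch("bilayer", n_lipids_per_leaflet=4,
                                      patch_dims=(12, 12))
        path = tmp_path / "top.json"
        write_topology_json(path, top)
        top2 = read_topology_json(path)
        assert [a for a in top2.atoms] == [a for a in top.atoms]


class TestSelectAtoms:
    def test_protein_on_lipid_only_patch_is_empty(self):
        top, _ = build_membrane_patch("bilayer", n_lipids_per_leaflet=4,
                                      patch_dims=(12, 12))
        assert select_atoms(top, role="protein").size == 0

    def test_heavy_atom_count(self):
        records = ([AtomRecord(i + 1, f"H{i}", "H", 1, "ALA", 1, "protein")
                    for i in range(3)]
                   + [AtomRecord(i + 4, f"C{i}", "C", 1, "ALA", 1, "protein")
                      for i in range(5)])
        assert select_atoms(Topology(records), is_heavy=True).size == 5

    def test_union_of_complementary_predicates_is_everything(self):
        top, _ = build_membrane_patch("we_monolayer", n_lipids_per_leaflet=4,
                                      patch_dims=(12, 12), n_core_molecules=2)
        heavy = select_atoms(top, is_heavy=True)
        light = select_atoms(top, is_heavy=False)
        union = np.union1d(heavy, light)
        assert np.array_equal(union, np.arange(top.n_atoms))

    def test_selection_sorted_and_idempotent(self):
        top, _ = build_membrane_patch("we_monolayer", n_lipids_per_leaflet=6,
                                      patch_dims=(14, 14), n_core_molecules=2)
        sel = select_atoms(top, role="core_neutral")
        assert np.array_equal(sel, np.sort(sel))
        assert np.array_equal(sel, select_atoms(top, role="core_neutral"))


class TestMembraneGeometry:
    def test_symmetric_patch_centres_at_zero(self):
        top, frame = mirror_patch()
        geo = membrane_geometry(Trajectory(top, [frame]))
        assert geo.center_z[0] == pytest.approx(0.0, abs=1e-9)

    def test_translation_equivariance_in_z(self):
        top, frame = mirror_patch()
        traj = Trajectory(top, [frame])
        geo = membrane_geometry(traj)
        shifted = Frame(0, 0.0, frame.box, frame.coords + np.array([0, 0, 7.0]))
        geo2 = membrane_geometry(Trajectory(top, [shifted]))
        assert geo2.center_z[0] == pytest.approx(geo.center_z[0] + 7.0)
        assert geo2.head_plane_upper[0] == pytest.approx(geo.head_plane_upper[0] + 7.0)

    def test_inplane_translation_invariance(self):
        top, frame = mirror_patch()
        geo = membrane_geometry(Trajectory(top, [frame]))
        shifted = Frame(0, 0.0, frame.box, frame.coords + np.array([3.0, -2.0, 0]))
        geo2 = membrane_geometry(Trajectory(top, [shifted]))
        assert geo2.center_z[0] == pytest.approx(geo.center_z[0])

    def test_head_plane_mean_equals_center_for_mirror_patch(self):
        top, frame = mirror_patch()
        geo = membrane_geometry(Trajectory(top, [frame]))
        mid = 0.5 * (geo.head_plane_upper[0] + geo.head_plane_lower[0])
        assert mid == pytest.approx(geo.center_z[0], abs=1e-9)

    def test_empty_leaflet_raises(self):
        top, frame = mirror_patch()
        # push every head into the upper half-space
        coords = frame.coords.copy()
        coords[:, 2] = np.abs(coords[:, 2]) + 50.0
        bad = Frame(0, 0.0, frame.box, coords)
        with pytest.raises(ValueError):
            membrane_geometry(Trajectory(top, [bad]))


class TestInvariants:
    def test_frame_times_strictly_increasing_enforced(self):
        top, frame = mirror_patch()
        f2 = Frame(1, 0.0, frame.box, frame.coords)
        with pytest.raises(ValueError):
            Trajectory(top, [frame, f2])

    def test_frame_atom_count_must_match_topology(self):
        top, frame = mirror_patch()
        short = Frame(0, 0.0, frame.box, frame.coords[:-1])
        with pytest.raises(ValueError):
            Trajectory(top, [short])
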