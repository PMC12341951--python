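"""Synthetic membrane patches, protein placement, trajectories, ideal helices."""

import numpy as np
import pytest

from ldbind.composition import allocate_counts
from ldbind.model import select_atoms
from ldbind.synthetic import (ScenarioConfig, build_membrane_patch,
                              build_pseudo_protein, generate_ideal_helix,
                              generate_trajectory, place_protein)


class TestMembranePatch:
    def test_jojoba_leaflet_has_45_pc_per_100_lipids(self):
        top, _ = build_membrane_patch("bilayer", "jojoba",
                                      n_lipids_per_leaflet=100)
        heads = select_atoms(top, role="lipid_head")
        names = top.residue_name[heads]
        # two leaflets of 100 lipids each
        assert (names == "PC").sum() == 2 * 45
        assert (names == "PG").sum() == 2 * 7

    def test_per_leaflet_counts_match_allocation_exactly(self):
        top, frame = build_membrane_patch("bilayer", "tabacum",
                                          n_lipids_per_leaflet=50)
        expected = allocate_counts("tabacum", 50)
        heads = select_atoms(top, role="lipid_head")
        upper = heads[frame.coords[heads, 2] > 0]
        lower = heads[frame.coords[heads, 2] < 0]
        for leaflet in (upper, lower):
            names = top.residue_name[leaflet]
            counts = {c: int((names == c).sum()) for c in expected}
            assert counts == expected

    def test_core_slab_spans_the_gap(self):
        top, frame = build_membrane_patch("we_monolayer", core_gap=30.0)
        core = select_atoms(top, role="core_neutral")
        span = frame.coords[core, 2].max() - frame.coords[core, 2].min()
        assert span == pytest.approx(30.0, abs=1.5)

    def test_same_seed_is_bit_identical(self):
        _, f1 = build_membrane_patch("we_monolayer", seed=42)
        _, f2 = build_membrane_patch("we_monolayer", seed=42)
        assert np.array_equal(f1.coords, f2.coords)

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError):
            build_membrane_patch("bilayer", patch_dims=(8, 8),
                                 n_lipids_per_leaflet=100)

    def test_bilayer_has_no_core_atoms(self):
        top, _ = build_membrane_patch("bilayer")
        assert select_atoms(top, role="core_neutral").size == 0


class TestPlacement:
    def test_centroid_offset_is_placement_height(self):
        _, pf = build_pseudo_protein(30)
        box = np.array([60.0, 60.0, 200.0])
        placed = place_protein(pf.coords, 1, 50.0, center_z=0.0, box=box)
        assert placed[:, 2].mean() == pytest.approx(50.0, abs=1e-9)
        assert placed[:, 0].mean() == pytest.approx(30.0, abs=1e-9)

    def test_orientations_1_and_3_mirror_z_about_centroid(self):
        _, pf = build_pseudo_protein(30)
        box = np.array([60.0, 60.0, 200.0])
        p1 = place_protein(pf.coords, 1, 50.0, 0.0, box)
        p3 = place_protein(pf.coords, 3, 50.0, 0.0, box)
        z1 = p1[:, 2] - p1[:, 2].mean()
        z3 = p3[:, 2] - p3[:, 2].mean()
        assert np.allclose(z1, -z3, atol=1e-9)

    def test_all_six_orientations_pairwise_distinct(self):
        _, pf = build_pseudo_protein(30)
        box = np.array([60.0, 60.0, 200.0])
        placed = [place_protein(pf.coords, k, 50.0, 0.0, box)
                  for k in range(1, 7)]
        for i in range(6):
            for j in range(i + 1, 6):
                a = placed[i] - placed[i].mean(axis=0)
                b = placed[j] - placed[j].mean(axis=0)
                rmsd = np.sqrt(((a - b) ** 2).sum(axis=1).mean())
                assert rmsd > 1.0, (i + 1, j + 1)

    def test_invalid_orientation_rejected(self):
        _, pf = build_pseudo_protein(10)
        with pytest.raises(ValueError):
            place_protein(pf.coords, 7, 50.0, 0.0, np.array([60.0, 60, 200]))


class TestTrajectoryGeneration:
    def test_same_config_and_seed_identical(self):
        cfg = ScenarioConfig(n_frames=10, seed=5)
        t1 = generate_trajectory(cfg)
        t2 = generate_trajectory(cfg)
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.array_equal(f1.coords, f2.coords)

    def test_different_seed_differs(self):
        t1 = generate_trajectory(ScenarioConfig(n_frames=10, seed=5))
        t2 = generate_trajectory(ScenarioConfig(n_frames=10, seed=6))
        assert not np.array_equal(t1.frames[0].coords, t2.frames[0].coords)

    def test_zero_surfacing_keeps_core_below_glycerol_plane(self):
        cfg = ScenarioConfig(n_frames=20, surfacing_rate=0.0, seed=2)
        traj = generate_trajectory(cfg)
        top = traj.topology
        core = select_atoms(top, role="core_neutral")
        gly = select_atoms(top, role="lipid_glycerol")
        for frame in traj.frames:
            gly_upper = frame.coords[gly, 2]
            plane = gly_upper[gly_upper > 0].mean()
            assert frame.coords[core, 2].max() < plane

    def test_unknown_binding_residue_rejected(self):
        cfg = ScenarioConfig(n_frames=5, n_protein_residues=20,
                             binding_residues={40, 41})
        with pytest.raises(ValueError, match="binding residues"):
            generate_trajectory(cfg)

    def test_invalid_config_values_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(orientation_index=0)
        with pytest.raises(ValueError):
            ScenarioConfig(n_frames=1)
        with pytest.raises(ValueError):
            ScenarioConfig(surfacing_rate=-1.0)
        with pytest.raises(ValueError):
            ScenarioConfig(membrane_kind="vesicle")

    def test_config_dict_round_trip(self):
        cfg = ScenarioConfig(n_frames=10, binding_residues={3, 4})
        assert ScenarioConfig.from_dict(cfg.to_dict()) == cfg
        with pytest.raises(ValueError, match="unknown"):
            ScenarioConfig.from_dict({"n_frame": 10})


class TestIdealHelix:
    def test_rise_per_residue_near_1_5(self):
        _, frame = generate_ideal_helix("A" * 18)
        ca = frame.coords[1::4]
        c = ca - ca.mean(axis=0)
        axis = np.linalg.svd(c)[2][0]
        rise = abs(np.polyfit(np.arange(18), c @ axis, 1)[0])
        assert rise == pytest.approx(1.5, abs=0.15)

    def test_18_residues_span_five_full_turns(self):
        from ldbind.helix import wheel_angles

        angles = wheel_angles(19)
        assert angles[18] == pytest.approx(angles[0])

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError, match="[XZ]"):
            generate_ideal_helix("AAXZAA")

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            generate_ideal_helix("AAA")
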