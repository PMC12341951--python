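"""Wimley-White sums, mutations, hydrophobic moment, dihedrals, helicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldbind.helix import (MutationSpec, WW_INTERFACE, annotate_helix,
                          apply_mutations, backbone_dihedrals, dihedral,
                          face_partition, helicity_classify, hydrophobic_moment,
                          wheel_angles, ww_sum)
from ldbind.synthetic import generate_ideal_helix

AA = "".join(sorted(WW_INTERFACE))
seq_strategy = st.text(alphabet=AA, min_size=0, max_size=30)


class TestWWSum:
    def test_ile_met_window(self):
        assert ww_sum("IM") == pytest.approx(-0.54)

    def test_empty_window_is_zero(self):
        assert ww_sum("") == 0.0

    @given(seq_strategy, seq_strategy)
    @settings(max_examples=100, deadline=None)
    def test_additivity(self, s1, s2):
        assert ww_sum(s1 + s2) == pytest.approx(ww_sum(s1) + ww_sum(s2))

    def test_nonstandard_letter_named_in_error(self):
        with pytest.raises(ValueError, match="X"):
            ww_sum("AXA")


class TestMutations:
    def test_substitution_at_full_protein_positions(self):
        seq = "GGGIGGMGG"  # I at 158, M at 161 with offset 155
        out = apply_mutations(seq, ["I158F", "M161L"], offset=155)
        assert out == "GGGFGGLGG"

    def test_involution(self):
        seq = "AICM"
        spec = MutationSpec.parse("I2V")
        back = apply_mutations(apply_mutations(seq, [spec]), [spec.inverse()])
        assert back == seq

    def test_wild_type_mismatch_names_position(self):
        with pytest.raises(ValueError, match="158"):
            apply_mutations("GGGG", ["I158F"], offset=155)

    def test_unparseable_spec_rejected(self):
        with pytest.raises(ValueError):
            MutationSpec.parse("F159")

    def test_ww_delta_independent_of_context(self):
        delta = (MutationSpec.parse("I158F").ww_delta
                 + MutationSpec.parse("M161L").ww_delta)
        assert delta == pytest.approx(-1.15)
        for ctx in ("GGGIGGMGG", "WWWIWWMWW"):
            mutated = apply_mutations(ctx, ["I158F", "M161L"], offset=155)
            assert ww_sum(mutated) - ww_sum(ctx) == pytest.approx(delta)

    def test_mutant_panel_hydrophobicity_ordering(self):
        # printed regional sums as inputs: the jojoba-like helix and the
        # double-swapped Arabidopsis helix are both more hydrophobic
        # (more negative) than the Arabidopsis wild type
        at_wt = 0.31
        sc_wt = -0.99
        at_double = at_wt + (MutationSpec.parse("I158F").ww_delta
                             + MutationSpec.parse("M161L").ww_delta)
        assert sc_wt < at_wt
        assert at_double < at_wt
        assert at_double == pytest.approx(-0.84)


class TestHydrophobicMoment:
    def test_homopolymer_over_whole_turns_cancels(self):
        mag, _ = hydrophobic_moment("L" * 18)
        assert mag == pytest.approx(0.0, abs=1e-9)

    def test_perfect_amphipathic_toy_points_at_90_degrees(self):
        # hydrophobicity +1 for wheel angles in (0, 180), -1 elsewhere,
        # over 18 residues (exact five turns)
        angles = wheel_angles(18)
        upper = (angles > 0) & (angles < 180)
        seq = "".join("A" if u else "B" for u in upper)
        scale = {"A": 1.0, "B": -1.0}
        mag, direction = hydrophobic_moment(seq, scale=scale)
        # independent oracle: direct vector summation
        h = np.where(upper, 1.0, -1.0)
        vx = (h * np.cos(np.deg2rad(angles))).sum()
        vy = (h * np.sin(np.deg2rad(angles))).sum()
        assert direction == pytest.approx(90.0, abs=1.0)
        assert mag == pytest.approx(np.hypot(vx, vy), rel=1e-9)
        assert direction == pytest.approx(
            np.degrees(np.arctan2(vy, vx)) % 360, abs=1e-9)

    def test_cyclic_rotation_preserves_magnitude_and_shifts_direction(self):
        # a full-turn (18-residue) window: rotating the start residue is a
        # pure 100-degree rotation of the wheel
        seq = "LKWIDEFAGHLKWIDEFA"
        mag0, dir0 = hydrophobic_moment(seq)
        mag1, dir1 = hydrophobic_moment(seq[1:] + seq[0])
        assert mag1 == pytest.approx(mag0, rel=1e-9)
        assert (dir0 - dir1) % 360 == pytest.approx(100.0, abs=1e-6)

    def test_minimum_window_enforced(self):
        with pytest.raises(ValueError):
            hydrophobic_moment("LK")

    def test_wheel_angle_formula(self):
        angles = wheel_angles(5)
        assert angles.tolist() == [0.0, 100.0, 200.0, 300.0, 40.0]


class TestDihedrals:
    def test_trans_planar_is_180(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == \
            pytest.approx(180.0)

    def test_cis_planar_is_zero(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == \
            pytest.approx(0.0)

    def test_ideal_helix_round_trip_within_one_degree(self):
        top, frame = generate_ideal_helix("ACDEFGHIKLMN")
        table = backbone_dihedrals(top, frame)
        interior = table.iloc[1:-1]
        assert np.allclose(interior["phi"], -57.0, atol=1.0)
        assert np.allclose(interior["psi"], -47.0, atol=1.0)

    def test_terminal_residues_have_undefined_angles(self):
        top, frame = generate_ideal_helix("ACDEFG")
        table = backbone_dihedrals(top, frame)
        assert np.isnan(table["phi"].iloc[0])
        assert np.isnan(table["psi"].iloc[-1])


class TestHelicity:
    @pytest.mark.parametrize("phi,psi,helical,region", [
        (-57.0, -47.0, True, "allowed"),
        (-57.0, 120.0, False, "outside"),
        (-87.0, -47.0, True, "allowed"),   # boundary inclusive at tol 30
        (-110.0, -90.0, False, "marginal"),
    ])
    def test_classification(self, phi, psi, helical, region):
        got_helical, got_region = helicity_classify(phi, psi, tolerance=30.0)
        assert got_helical == helical
        assert got_region == region

    def test_undefined_angles(self):
        helical, region = helicity_classify(np.nan, -47.0)
        assert not helical and region == "undefined"


class TestAnnotation:
    def test_window_report_and_structure_calls(self):
        seq = "LDKLIGFLSETWSNLKQM"
        top, frame = generate_ideal_helix(seq)
        ann = annotate_helix(seq, 2, 17, structure=(top, frame))
        assert ann.sequence == seq[1:17]
        assert ann.ww_sum == pytest.approx(ww_sum(seq[1:17]))
        assert ann.helical.all()
        df = ann.to_frame()
        assert list(df.index) == list(range(2, 18))

    def test_face_partition_by_scale_sign(self):
        assert face_partition("LK") == ["hydrophobic", "hydrophilic"]

    def test_mutations_applied_before_scoring(self):
        seq = "GGGIGGMGG"
        ann = annotate_helix(seq, 156, 164, mutations=["I159F", "M162L"],
                             seq_offset=156)
        assert ann.sequence == "GGGFGGLGG"
        assert ann.ww_sum == pytest.approx(ww_sum("GGGFGGLGG"))
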