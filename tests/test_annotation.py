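"""Backbone torsions, secondary structure, H-bonds and environment codes."""

import itertools

import numpy as np
import pytest

from conftest import make_residue
from varstruct.annotate import (
    AnnotationConfig,
    StructuralEnvironment,
    assign_secondary_structure,
    backbone_torsions,
    classify_environment,
    env_decode,
    sidechain_hbonds,
)
from varstruct.geometry import dihedral
from varstruct.synthetic import ChainRecipe, Segment, build_ideal_structure


class TestTorsions:
    def test_ideal_helix_recovers_construction_angles(self, helix_chain):
        torsions = backbone_torsions(helix_chain)
        for phi, psi in torsions[1:-1]:
            assert abs(phi - (-57.0)) < 0.5
            assert abs(psi - (-47.0)) < 0.5

    def test_termini_undefined(self, helix_chain):
        torsions = backbone_torsions(helix_chain)
        assert torsions[0][0] is None          # no phi at N-terminus
        assert torsions[-1][1] is None         # no psi at C-terminus
        assert torsions[0][1] is not None

    def test_planar_cis_arrangement_gives_zero(self):
        # four coplanar points with both outer atoms on the same side
        p = [(1, 1, 0), (0, 0, 0), (2, 0, 0), (1.5, 1, 0)]
        assert abs(dihedral(*p)) < 1e-9

    def test_right_angle_arrangement(self):
        p = [(1, 1, 0), (0, 0, 0), (2, 0, 0), (1.5, 0, 1)]
        assert abs(abs(dihedral(*p)) - 90.0) < 1e-9

    def test_chain_break_undefines_flanking_torsions(self, helix_chain):
        import copy

        broken = copy.deepcopy(helix_chain)
        for res in broken[6:]:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + np.array([50.0, 0, 0])
        torsions = backbone_torsions(broken)
        assert torsions[5][1] is None and torsions[6][0] is None
        assert torsions[4][1] is not None and torsions[7][0] is not None


class TestSecondaryStructure:
    def test_ideal_segments_labelled_as_constructed(self, mixed_annotation):
        ss = "".join(rec["ss"] for rec in mixed_annotation.values())
        # helix(12) coil(4) strand(8) coil(4) pos-phi(4) coil(4) helix(12)
        assert ss == ("C" + "H" * 11 + "C" * 4 + "E" * 8 + "C" * 4
                      + "P" * 4 + "C" * 4 + "H" * 11 + "C")

    def test_positive_phi_inside_helix_run_is_P(self):
        torsions = [(-57.0, -47.0)] * 6
        torsions[3] = (60.0, -47.0)
        ss = assign_secondary_structure(torsions)
        assert ss[3] == "P"

    def test_short_fragments_are_coil(self):
        ss = assign_secondary_structure([(-57.0, -47.0)] * 2)
        assert ss == ["C", "C"]
        ss = assign_secondary_structure([(-57.0, -47.0)] * 3)
        assert ss == ["C"] * 3  # helix needs runs of >= 4
        ss = assign_secondary_structure([(-139.0, 135.0)] * 3)
        assert ss == ["E"] * 3  # strand needs only 3

    def test_undefined_torsions_are_coil(self):
        assert assign_secondary_structure([(None, None)]) == ["C"]

    def test_classes_partition_residues(self, bundle_annotation):
        counts = {s: 0 for s in "HECP"}
        for rec in bundle_annotation.values():
            counts[rec["ss"]] += 1
        assert sum(counts.values()) == len(bundle_annotation)


class TestEnvironmentCode:
    def test_full_enumeration_is_bijective(self):
        codes = {classify_environment(ss, acc, nh, co, sc)
                 for ss in "HECP"
                 for acc, nh, co, sc in itertools.product([False, True],
                                                          repeat=4)}
        assert codes == set(range(64))

    def test_decode_round_trip(self):
        for code in range(64):
            assert classify_environment(*env_decode(code)) == code

    def test_burial_distinguishes_codes(self):
        a = StructuralEnvironment("H", True, False, False, False)
        b = StructuralEnvironment("H", False, False, False, False)
        assert a.code != b.code

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_environment("X", True, False, False, False)
        with pytest.raises(ValueError):
            env_decode(64)


def _pair(donor_res, acceptor_res):
    return {"A": [donor_res, acceptor_res]}


class TestHydrogenBonds:
    def ser_residue(self, number, og):
        return make_residue("A", number, "S", "SER", {
            "N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2.2, 1.3, 0),
            "O": (1.8, 2.4, 0), "CB": (2.0, -1.2, 1.0), "OG": og})

    def gly_residue(self, number, origin):
        ox, oy, oz = origin
        return make_residue("A", number, "G", "GLY", {
            "N": (ox, oy, oz), "CA": (ox + 1.5, oy, oz),
            "C": (ox + 2.2, oy + 1.3, oz), "O": (ox + 1.8, oy + 2.4, oz)})

    @pytest.mark.parametrize("distance,expected", [
        (3.4, True), (3.5, True), (3.6, False)])
    def test_hydroxyl_to_carbonyl_boundary(self, distance, expected):
        gly = self.gly_residue(2, (20.0, 0.0, 0.0))
        og = gly.atoms["O"] + np.array([0.0, distance, 0.0])
        ser = self.ser_residue(1, tuple(og))
        flags = sidechain_hbonds(_pair(ser, gly))
        assert flags[ser.key]["hb_co"] is expected
        assert flags[gly.key]["hb_co"] is False

    @pytest.mark.parametrize("distance,expected", [
        (3.8, True), (4.0, True), (4.05, False)])
    def test_sulphur_pairs_use_longer_cutoff(self, distance, expected):
        met = make_residue("A", 1, "M", "MET", {
            "N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2.2, 1.3, 0),
            "O": (1.8, 2.4, 0), "SD": (5.0, 0.0, 0.0)})
        lys = make_residue("A", 2, "K", "LYS", {
            "N": (30, 0, 0), "CA": (31.5, 0, 0), "C": (32.2, 1.3, 0),
            "O": (31.8, 2.4, 0), "NZ": (5.0 + distance, 0.0, 0.0)})
        flags = sidechain_hbonds(_pair(met, lys))
        assert flags[met.key]["hb_sc"] is expected
        assert flags[lys.key]["hb_sc"] is expected

    def test_sidechain_to_amide_needs_acceptor(self):
        gly = self.gly_residue(2, (20.0, 0.0, 0.0))
        og = gly.atoms["N"] + np.array([0.0, 3.0, 0.0])
        ser = self.ser_residue(1, tuple(og))
        flags = sidechain_hbonds(_pair(ser, gly))
        assert flags[ser.key]["hb_nh"] is True
        # Lys NZ is a pure donor: no bond to a main-chain amide
        nz = gly.atoms["N"] + np.array([0.0, -3.0, 0.0])
        lys = make_residue("A", 1, "K", "LYS", {
            "N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2.2, 1.3, 0),
            "O": (1.8, 2.4, 0), "NZ": tuple(nz)})
        flags = sidechain_hbonds(_pair(lys, gly))
        assert flags[lys.key]["hb_nh"] is False
        assert flags[lys.key]["hb_co"] is False  # carbonyl out of range

    def test_same_residue_pairs_excluded(self):
        ser = self.ser_residue(1, (2.5, 2.6, 0.0))  # OG close to own O
        flags = sidechain_hbonds({"A": [ser]})
        assert flags[ser.key] == {"hb_nh": False, "hb_co": False,
                                  "hb_sc": False}

    def test_flags_monotone_in_cutoff(self, bundle_structure):
        base = sidechain_hbonds(bundle_structure, AnnotationConfig())
        wide = sidechain_hbonds(bundle_structure,
                                AnnotationConfig(hb_dist=4.5,
                                                 hb_dist_sulphur=5.0))
        for key, flags in base.items():
            for name, value in flags.items():
                assert wide[key][name] or not value

    def test_poly_ala_helix_has_no_sidechain_bonds(self, helix_chain):
        flags = sidechain_hbonds({"A": helix_chain})
        assert not any(any(f.values()) for f in flags.values())
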