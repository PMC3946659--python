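"""Ring geometry, stacking, cation-π, hydrogen bonds and d_W-W."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nlsgeom.errors import ContractError, GeometryError
from nlsgeom.interactions import (classify_stacking, compute_dww,
                                  detect_cation_pi, detect_hbonds, trp_rings)
from nlsgeom.structure import AtomRecord, ComplexStructure, Residue
from nlsgeom.superpose import RigidTransform
from nlsgeom.synthetic import make_stacked_indoles, random_rigid_transform


def indole_pair(distance, angle=0.0, offset=0.0):
    st_ = make_stacked_indoles(distance, angle, offset)
    a, b = st_.residues
    return a, b


class TestTrpRings:
    def test_ideal_indole_is_planar(self):
        a, _ = indole_pair(10.0)
        six, five = trp_rings(a)
        assert six.planarity_residual < 1e-6
        assert five.planarity_residual < 1e-6
        assert six.atom_names == ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")

    def test_missing_ring_atom_is_named_in_error(self):
        a, _ = indole_pair(10.0)
        del a.atoms["CZ3"]
        with pytest.raises(GeometryError, match="CZ3"):
            trp_rings(a)

    def test_non_trp_rejected(self):
        res = Residue("A", 1, "", "ALA",
                      {"CA": AtomRecord("CA", "C", np.zeros(3))})
        with pytest.raises(ContractError):
            trp_rings(res)

    def test_normal_rotates_with_the_ring(self, rng):
        a, _ = indole_pair(10.0)
        T = random_rigid_transform(rng)
        moved = Residue(a.chain_id, a.res_seq, a.icode, a.res_name,
                        {n: AtomRecord(n, at.element, T.apply(at.coords))
                         for n, at in a.atoms.items()})
        n0 = trp_rings(a)[0].normal
        n1 = trp_rings(moved)[0].normal
        rotated = T.rotation @ n0
        # sign of the normal is arbitrary
        assert min(np.linalg.norm(n1 - rotated),
                   np.linalg.norm(n1 + rotated)) < 1e-6


class TestStacking:
    def test_coaxial_parallel_rings_are_sandwich(self):
        a, b = indole_pair(3.8, 0.0, 0.0)
        call = classify_stacking(trp_rings(a)[0], trp_rings(b)[0])
        assert call.category == "sandwich"
        assert call.angle == pytest.approx(0.0, abs=0.1)
        assert call.centroid_distance == pytest.approx(3.8, abs=1e-3)

    def test_perpendicular_rings_are_t_shaped(self):
        a, b = indole_pair(5.0, 90.0, 0.0)
        call = classify_stacking(trp_rings(a)[0], trp_rings(b)[0])
        assert call.category == "t_shaped"
        assert call.angle == pytest.approx(90.0, abs=0.1)

    def test_offset_parallel_rings_are_parallel_displaced(self):
        a, b = indole_pair(5.0, 0.0, 3.0)
        call = classify_stacking(trp_rings(a)[0], trp_rings(b)[0])
        assert call.category == "parallel_displaced"
        assert call.offset == pytest.approx(3.0, abs=1e-3)

    def test_beyond_contact_gate_is_none(self):
        a, b = indole_pair(9.0, 0.0, 0.0)
        call = classify_stacking(trp_rings(a)[0], trp_rings(b)[0])
        assert call.category == "none"

    def test_intermediate_angle_reported_as_none(self):
        a, b = indole_pair(4.5, 45.0, 0.0)
        call = classify_stacking(trp_rings(a)[0], trp_rings(b)[0])
        assert call.category == "none"
        assert 30.0 < call.angle < 60.0

    @given(distance=st.floats(3.5, 8.5), angle=st.floats(0, 90),
           offset_frac=st.floats(0, 0.8))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetric_in_arguments(self, distance, angle, offset_frac):
        a, b = indole_pair(distance, angle, offset_frac * distance)
        ra, rb = trp_rings(a)[0], trp_rings(b)[0]
        ab, ba = classify_stacking(ra, rb), classify_stacking(rb, ra)
        assert ab.category == ba.category
        assert ab.angle == pytest.approx(ba.angle, abs=1e-9)
        assert ab.offset == pytest.approx(ba.offset, abs=1e-9)

    def test_invariant_under_rigid_transform(self, rng):
        a, b = indole_pair(4.2, 20.0, 1.0)
        T = random_rigid_transform(rng)
        moved = [Residue(r.chain_id, r.res_seq, r.icode, r.res_name,
                         {n: AtomRecord(n, at.element, T.apply(at.coords))
                          for n, at in r.atoms.items()}) for r in (a, b)]
        before = classify_stacking(trp_rings(a)[0], trp_rings(b)[0])
        after = classify_stacking(trp_rings(moved[0])[0],
                                  trp_rings(moved[1])[0])
        assert before.category == after.category
        assert before.angle == pytest.approx(after.angle, abs=1e-6)


class TestCationPi:
    def _ring(self):
        a, _ = indole_pair(20.0)
        return trp_rings(a)[0]  # six-ring at origin, normal +z

    def test_cation_on_ring_axis_is_detected(self):
        ring = self._ring()
        call = detect_cation_pi(ring, ring.centroid + 4.0 * ring.normal)
        assert call.found
        assert call.distance == pytest.approx(4.0, abs=1e-9)

    def test_cation_in_ring_plane_fails_angle_gate(self):
        ring = self._ring()
        in_plane = np.array([1.0, 0.3, 0.0])
        in_plane -= np.dot(in_plane, ring.normal) * ring.normal
        in_plane /= np.linalg.norm(in_plane)
        call = detect_cation_pi(ring, ring.centroid + 4.0 * in_plane)
        assert not call.found
        assert call.angle > 45.0

    def test_distance_gate_at_7A(self):
        ring = self._ring()
        call = detect_cation_pi(ring, ring.centroid + 7.0 * ring.normal)
        assert not call.found

    def test_lysine_charge_center_is_nz(self):
        lys = Residue("B", 1, "", "LYS",
                      {"NZ": AtomRecord("NZ", "N", np.array([0.0, 0, 4.0]))})
        ring = self._ring()
        call = detect_cation_pi(ring, lys)
        assert call.found

    def test_unsupported_residue_rejected(self):
        ala = Residue("B", 1, "", "ALA",
                      {"CB": AtomRecord("CB", "C", np.zeros(3))})
        with pytest.raises(ContractError):
            detect_cation_pi(self._ring(), ala)


class TestHBonds:
    def _two_residues(self, separation):
        donor = Residue("B", 1, "", "GLY", {
            "N": AtomRecord("N", "N", np.zeros(3)),
            "CA": AtomRecord("CA", "C", np.array([1.4, 0.0, 0.0])),
        })
        acceptor = Residue("A", 1, "", "GLY", {
            "CA": AtomRecord("CA", "C",
                             np.array([-1.4, separation, 0.0])),
            "O": AtomRecord("O", "O", np.array([0.0, separation, 0.0])),
        })
        st_ = ComplexStructure("hb", [acceptor, donor],
                               {"A": "receptor", "B": "peptide"})
        return st_

    def test_amide_to_carbonyl_at_2p9(self):
        st_ = self._two_residues(2.9)
        bonds = detect_hbonds(st_, [("B", 1, "")], [("A", 1, "")])
        assert len(bonds) == 1
        assert bonds[0].donor_atom == "N" and bonds[0].acceptor_atom == "O"
        assert bonds[0].distance == pytest.approx(2.9)

    def test_beyond_cutoff_is_empty(self):
        st_ = self._two_residues(3.6)
        assert detect_hbonds(st_, [("B", 1, "")], [("A", 1, "")]) == []

    def test_carbon_contacts_fail_typing_gate(self):
        # CA-CA at 2.9 A but carbons are neither donors nor acceptors
        donor = Residue("B", 1, "", "ALA",
                        {"CA": AtomRecord("CA", "C", np.zeros(3)),
                         "CB": AtomRecord("CB", "C",
                                          np.array([0.0, 1.5, 0.0]))})
        other = Residue("A", 1, "", "ALA",
                        {"CA": AtomRecord("CA", "C",
                                          np.array([2.9, 0.0, 0.0]))})
        st_ = ComplexStructure("cc", [other, donor],
                               {"A": "receptor", "B": "peptide"})
        assert detect_hbonds(st_, [("B", 1, "")], [("A", 1, "")]) == []

    def test_sidechain_chemistry_table(self):
        lys = Residue("B", 1, "", "LYS",
                      {"NZ": AtomRecord("NZ", "N", np.zeros(3))})
        asp = Residue("A", 1, "", "ASP",
                      {"OD1": AtomRecord("OD1", "O",
                                         np.array([2.8, 0.0, 0.0])),
                       "CB": AtomRecord("CB", "C",
                                        np.array([3.9, 1.0, 0.0]))})
        st_ = ComplexStructure("sc", [asp, lys],
                               {"A": "receptor", "B": "peptide"})
        bonds = detect_hbonds(st_, [("B", 1, "")], [("A", 1, "")])
        assert [(b.donor_atom, b.acceptor_atom) for b in bonds] == \
            [("NZ", "OD1")]


class TestDww:
    def test_self_distance_is_zero(self):
        a, _ = indole_pair(10.0)
        result = compute_dww(a, a)
        assert result.d6 == 0.0 and result.d5 == 0.0 and result.d_ww == 0.0

    def test_translated_copy_gives_twice_the_shift(self):
        a, _ = indole_pair(10.0)
        t = 5.0
        shift = RigidTransform(np.eye(3), np.array([0.0, t, 0.0]))
        b = Residue(a.chain_id, 357, a.icode, a.res_name,
                    {n: AtomRecord(n, at.element, shift.apply(at.coords))
                     for n, at in a.atoms.items()})
        result = compute_dww(a, b)
        assert result.d6 == pytest.approx(t, abs=1e-12)
        assert result.d5 == pytest.approx(t, abs=1e-12)
        assert result.d_ww == pytest.approx(2 * t, abs=1e-12)

    def test_constructed_separations_sum_like_a_host_pair(self):
        # d6 = 7.2 and d5 = 7.3 -> d_W-W = 14.5 (the scale of a K guest
        # sandwiched between two host indoles)
        a, _ = indole_pair(10.0)
        b_atoms = {n: AtomRecord(n, at.element,
                                 at.coords + np.array([7.2, 0.0, 0.0]))
                   for n, at in a.atoms.items()}
        # push the three non-shared five-ring atoms to stretch d5 to 7.3
        for name in ("CG", "CD1", "NE1"):
            b_atoms[name].coords = b_atoms[name].coords + \
                np.array([0.1 * 5 / 3, 0.0, 0.0])
        b = Residue("A", 357, "", "TRP", b_atoms)
        result = compute_dww(a, b)
        assert result.d6 == pytest.approx(7.2, abs=1e-9)
        assert result.d5 == pytest.approx(7.3, abs=1e-9)
        assert result.d_ww == pytest.approx(14.5, abs=1e-9)

    def test_symmetry_and_triangle_bound(self, rng):
        a, _ = indole_pair(10.0)

        def moved(seed):
            T = random_rigid_transform(np.random.default_rng(seed))
            return Residue("A", 400 + seed, "", "TRP",
                           {n: AtomRecord(n, at.element, T.apply(at.coords))
                            for n, at in a.atoms.items()})

        for seed in range(5):
            x, y, z = moved(3 * seed), moved(3 * seed + 1), moved(3 * seed + 2)
            assert compute_dww(x, y).d_ww == \
                pytest.approx(compute_dww(y, x).d_ww, abs=1e-12)
            assert compute_dww(x, z).d_ww <= \
                compute_dww(x, y).d_ww + compute_dww(y, z).d_ww + 1e-12
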