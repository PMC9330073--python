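import math

import numpy as np
import pytest

from complexqa.interface import (
    buried_interface_area,
    cad_from_maps,
    cad_score_iface,
    classify_interface,
    residue_contact_areas,
    sasa,
    sasa_points,
)
from complexqa.model_io import AtomRecord, ComplexSpec, ResidueView, StructureModel
from complexqa.superpose import RigidTransform, transform_model
from complexqa.synthetic_data import ToyComplexSpec, default_complex_spec, make_toy_complex


def displaced_ligand(model, shift):
    out = model.copy()
    for r in out.residues({"B"}):
        for a in r.atoms:
            a.coords = a.coords + np.asarray(shift, float)
    return out


class TestSasa:
    def test_isolated_atom_matches_closed_form(self):
        r, w = 1.7, 1.4
        area = sasa_points(np.zeros((1, 3)), np.array([r]), probe_radius=w, n_points=960)
        assert area[0] == pytest.approx(4 * math.pi * (r + w) ** 2, rel=0.02)

    def test_far_apart_atoms_are_independent(self):
        coords = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        radii = np.array([1.7, 1.52])
        areas = sasa_points(coords, radii)
        singles = [sasa_points(coords[i:i + 1], radii[i:i + 1])[0] for i in range(2)]
        np.testing.assert_allclose(areas, singles, rtol=1e-12)

    def test_occlusion_reduces_area_and_refines_with_quadrature(self):
        # duplicate atom fully overlapping: each sphere loses exactly the
        # points inside the other; total must not exceed one isolated sphere
        coords = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
        radii = np.array([1.7, 1.7])
        coarse = sasa_points(coords, radii, n_points=960)
        fine = sasa_points(coords, radii, n_points=10000)
        isolated = sasa_points(coords[:1], radii[:1], n_points=10000)[0]
        assert coarse.sum() < 2 * isolated
        np.testing.assert_allclose(coarse.sum(), fine.sum(), rtol=0.02)

    def test_deterministic_for_fixed_n_points(self, toy):
        a1 = sasa(toy, n_points=480)
        a2 = sasa(toy, n_points=480)
        np.testing.assert_array_equal(a1, a2)

    def test_unknown_element_falls_back_with_warning(self):
        res = ResidueView("A", 1, "UNK", [AtomRecord(1, "XX", "XX", np.zeros(3))])
        model = StructureModel("m", {"A": [res]})
        with pytest.warns(UserWarning, match="unknown element"):
            sasa(model)


class TestBuriedArea:
    def test_separated_chains_bury_nothing(self, toy, cspec):
        far = displaced_ligand(toy, [0.0, -60.0, 0.0])
        assert buried_interface_area(far, cspec, n_points=480) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_receptor_ligand_labels(self, toy, cspec):
        swapped = ComplexSpec(cspec.ligand_chains, cspec.receptor_chains)
        a = buried_interface_area(toy, cspec)
        b = buried_interface_area(toy, swapped)
        assert a == pytest.approx(b, abs=1e-9)
        assert a > 0

    def test_invariant_under_rigid_transform(self, toy, cspec):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        tr = RigidTransform(Q, np.array([3.0, -2.0, 8.0]))
        a = buried_interface_area(toy, cspec, n_points=480)
        b = buried_interface_area(transform_model(toy, tr), cspec, n_points=480)
        # the quadrature lattice is fixed in space, so rotation changes which
        # points are occluded; agreement is to quadrature resolution
        assert b == pytest.approx(a, rel=0.05)

    def test_matches_high_density_quadrature_oracle(self, toy, cspec):
        coarse = buried_interface_area(toy, cspec, n_points=960)
        fine = buried_interface_area(toy, cspec, n_points=10000)
        assert coarse == pytest.approx(fine, rel=0.03)

    def test_empty_chain_group_errors(self, toy):
        spec = ComplexSpec(frozenset("A"), frozenset("Z"))
        with pytest.raises(ValueError, match="lacks"):
            buried_interface_area(toy, spec)


class TestContactAreas:
    def test_non_contacting_chains_give_empty_map(self, toy, cspec):
        far = displaced_ligand(toy, [0.0, -60.0, 0.0])
        assert residue_contact_areas(far, cspec, n_points=480).entries == {}

    def test_total_area_conserves_buried_area(self, toy, cspec):
        cm = residue_contact_areas(toy, cspec)
        buried = buried_interface_area(toy, cspec)
        assert cm.total_area == pytest.approx(2.0 * buried, rel=0.05)

    def test_receptor_residue_stored_first(self, toy, cspec):
        cm = residue_contact_areas(toy, cspec)
        assert cm.entries
        for (rk, lk), area in cm.entries.items():
            assert rk[0] == "A" and lk[0] == "B" and area > 0

    def test_single_residue_pair_collects_total_burial(self):
        # one-residue chains, only mutual burial possible
        a = ResidueView("A", 1, "ALA", [AtomRecord(1, "CB", "C", np.zeros(3))])
        b = ResidueView("B", 1, "ALA", [AtomRecord(2, "CB", "C", np.array([3.6, 0.0, 0.0]))])
        model = StructureModel("pair", {"A": [a], "B": [b]})
        spec = ComplexSpec(frozenset("A"), frozenset("B"))
        cm = residue_contact_areas(model, spec, n_points=2000)
        buried = buried_interface_area(model, spec, n_points=2000)
        assert set(cm.entries) == {(("A", 1), ("B", 1))}
        assert cm.total_area == pytest.approx(2.0 * buried, rel=1e-6)


class TestCadScore:
    def test_self_comparison_is_exactly_one(self, toy, cspec):
        comp = cad_score_iface(toy, toy, cspec)
        assert comp.score == 1.0

    def test_displaced_ligand_scores_zero(self, toy, cspec):
        far = displaced_ligand(toy, [0.0, -60.0, 0.0])
        comp = cad_score_iface(toy, far, cspec)
        assert comp.score == 0.0

    def test_empty_target_interface_is_an_error(self, toy, cspec):
        far = displaced_ligand(toy, [0.0, -60.0, 0.0])
        with pytest.raises(ValueError, match="empty"):
            cad_score_iface(far, toy, cspec)

    def test_hand_computed_three_residue_maps(self):
        T = {(("A", 1), ("B", 1)): 10.0,
             (("A", 2), ("B", 1)): 20.0,
             (("A", 3), ("B", 2)): 30.0}
        M = {(("A", 1), ("B", 1)): 5.0,    # |10-5| = 5
             (("A", 2), ("B", 1)): 50.0,   # capped at 2T=40 -> |20-40| = 20
             (("A", 9), ("B", 9)): 99.0}   # not in target: ignored
        # missing (A,3),(B,2): |30-0| = 30; total diff 55, total T 60
        comp = cad_from_maps(T, M)
        assert comp.total_abs_diff == pytest.approx(55.0)
        assert comp.score == pytest.approx(1.0 - 55.0 / 60.0)
        assert comp.n_target_contacts == 3

    def test_monotone_non_increasing_with_pose_error(self, toy, cspec):
        scores = []
        for shift in (0.0, 1.0, 2.0, 4.0, 8.0):
            model = displaced_ligand(toy, [0.0, -shift, 0.0])
            scores.append(cad_score_iface(toy, model, cspec, n_points=480).score)
        assert scores[0] == 1.0
        assert all(b <= a + 1e-9 for a, b in zip(scores, scores[1:]))
        assert all(0.0 <= s <= 1.0 for s in scores)


class TestClassification:
    def test_planted_salt_bridge_detected(self, toy, cspec):
        rep = classify_interface(toy, cspec)
        salt = {(k, n) for k, n, side, cls in rep.interface_residues if "salt_bridge" in cls}
        names = {n for _, n in salt}
        assert {"GLU", "ARG"} <= names

    def test_hydrophobic_leu_phe_pair(self):
        # Leu side-chain carbon packed 4.0 A from a Phe ring carbon
        leu = ResidueView("A", 1, "LEU", [
            AtomRecord(1, "CA", "C", np.array([0.0, 0.0, 0.0])),
            AtomRecord(2, "CB", "C", np.array([1.5, 0.0, 0.0])),
            AtomRecord(3, "CD1", "C", np.array([3.0, 0.0, 0.0])),
        ])
        phe = ResidueView("B", 1, "PHE", [
            AtomRecord(4, "CA", "C", np.array([10.0, 0.0, 0.0])),
            AtomRecord(5, "CB", "C", np.array([8.5, 0.0, 0.0])),
            AtomRecord(6, "CZ", "C", np.array([7.0, 0.0, 0.0])),
        ])
        model = StructureModel("lp", {"A": [leu], "B": [phe]})
        spec = ComplexSpec(frozenset("A"), frozenset("B"))
        rep = classify_interface(model, spec, n_points=480)
        classes = {n: cls for _, n, _, cls in rep.interface_residues}
        assert "hydrophobic" in classes["LEU"] and "hydrophobic" in classes["PHE"]
        assert "salt_bridge" not in classes["LEU"]

    def test_interface_residue_count_matches_brute_force_scan(self, toy, cspec):
        rep = classify_interface(toy, cspec)
        classified = {(k, side) for k, _, side, cls in rep.interface_residues if cls}
        # O(n^2) oracle: recompute every class by direct all-pairs distances
        from complexqa.interface import (_ACIDIC_O, _APOLAR_RES, _BACKBONE, _BASIC_N,
                                         _TYR_RING, HBOND_CUTOFF, HYDROPHOBIC_CUTOFF,
                                         SALT_BRIDGE_CUTOFF)
        expected = set()
        rec_atoms = toy.all_atoms({"A"})
        lig_atoms = toy.all_atoms({"B"})

        def props(r, a):
            el = a.element.upper()
            basic = a.name in _BASIC_N.get(r.res_name, ())
            acidic = a.name in _ACIDIC_O.get(r.res_name, ())
            polar = el in ("N", "O")
            apolar = el == "C" and a.name not in _BACKBONE and (
                r.res_name in _APOLAR_RES or (r.res_name == "TYR" and a.name in _TYR_RING))
            return basic, acidic, polar, apolar

        for ra, aa in rec_atoms:
            for rb, ab in lig_atoms:
                d = np.linalg.norm(aa.coords - ab.coords)
                if d > HYDROPHOBIC_CUTOFF:
                    continue
                b1, a1, p1, h1 = props(ra, aa)
                b2, a2, p2, h2 = props(rb, ab)
                hit = False
                if d <= SALT_BRIDGE_CUTOFF and ((b1 and a2) or (a1 and b2)):
                    hit = True
                if d <= HBOND_CUTOFF and p1 and p2:
                    hit = True
                if h1 and h2:
                    hit = True
                if hit:
                    expected.add(((ra.chain_id, ra.seq_id), "receptor"))
                    expected.add(((rb.chain_id, rb.seq_id), "ligand"))
        # brute force ignores chain-terminal amine/carboxylate special cases;
        # classified may therefore be a superset, never miss a brute-force hit
        assert expected <= classified
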