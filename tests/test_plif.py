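import numpy as np
import pytest

from pocketsim.plif import (
    InteractionConfig,
    InteractionFingerprint,
    annotate_pharmacophores,
    detect_interactions,
    fingerprint_tanimoto,
    summarize_interactions,
)
from pocketsim.structures import BindingSiteComplex

from conftest import identity_map, make_atom, random_rigid_transform, transform_complex


def _complex(protein, ligand):
    return BindingSiteComplex("c1", "t", "cofactor", protein, ligand)


def _gly_backbone(resnum=1, resname="GLY", origin=(0.0, 0.0, 0.0)):
    ox, oy, oz = origin
    return [
        make_atom("N", "N", (ox, oy, oz), resnum=resnum, resname=resname, is_backbone=True),
        make_atom("CA", "C", (ox + 1.46, oy, oz), resnum=resnum, resname=resname, is_backbone=True),
        make_atom("C", "C", (ox + 2.0, oy + 1.42, oz), resnum=resnum, resname=resname, is_backbone=True),
        make_atom("O", "O", (ox + 3.23, oy + 1.58, oz), resnum=resnum, resname=resname, is_backbone=True),
    ]


class TestAnnotatePharmacophores:
    def test_backbone_carbonyl_acceptor(self):
        protein = _gly_backbone()
        ligand = [make_atom("C1", "C", (50, 0, 0), resnum=9, resname="LIG", is_ligand=True)]
        cplx = _complex(protein, ligand)
        annot = annotate_pharmacophores(cplx)
        o_index = next(i for i, a in enumerate(protein) if a.name == "O")
        n_index = next(i for i, a in enumerate(protein) if a.name == "N")
        assert o_index in annot.acceptor
        assert n_index in annot.donor

    def test_lysine_nz_donor_and_cation(self):
        protein = _gly_backbone(resname="LYS") + [
            make_atom("NZ", "N", (0, 5, 0), resname="LYS"),
        ]
        ligand = [make_atom("C1", "C", (50, 0, 0), resnum=9, resname="LIG", is_ligand=True)]
        annot = annotate_pharmacophores(_complex(protein, ligand))
        nz = next(i for i, a in enumerate(protein) if a.name == "NZ")
        assert nz in annot.donor and nz in annot.cation

    def test_proline_n_not_donor(self):
        protein = _gly_backbone(resname="PRO")
        ligand = [make_atom("C1", "C", (50, 0, 0), resnum=9, resname="LIG", is_ligand=True)]
        annot = annotate_pharmacophores(_complex(protein, ligand))
        assert 0 not in annot.donor

    def test_ligand_carboxylate(self):
        # C bonded to two terminal O at ~1.25 A -> both anion + acceptor
        protein = _gly_backbone()
        ligand = [
            make_atom("C1", "C", (50.0, 0.0, 0.0), resnum=9, resname="LIG", is_ligand=True),
            make_atom("O1", "O", (51.25, 0.0, 0.0), resnum=9, resname="LIG", is_ligand=True),
            make_atom("O2", "O", (49.4, 1.05, 0.0), resnum=9, resname="LIG", is_ligand=True),
        ]
        cplx = _complex(protein, ligand)
        annot = annotate_pharmacophores(cplx)
        n_prot = len(protein)
        for off in (1, 2):  # the two oxygens
            assert n_prot + off in annot.anion
            assert n_prot + off in annot.acceptor
            assert n_prot + off not in annot.donor

    def test_ligand_hydroxyl_donor(self):
        protein = _gly_backbone()
        ligand = [
            make_atom("C1", "C", (50.0, 0.0, 0.0), resnum=9, resname="LIG", is_ligand=True),
            make_atom("O1", "O", (51.43, 0.0, 0.0), resnum=9, resname="LIG", is_ligand=True),
        ]
        annot = annotate_pharmacophores(_complex(protein, ligand))
        n_prot = len(protein)
        assert n_prot + 1 in annot.donor and n_prot + 1 in annot.acceptor

    def test_ligand_aromatic_ring_detected(self):
        protein = _gly_backbone()
        ring = []
        for k in range(6):  # benzene-like hexagon, bond length 1.39
            ang = np.pi / 3 * k
            ring.append(make_atom(f"C{k}", "C",
                                  (50 + 1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0),
                                  resnum=9, resname="LIG", is_ligand=True))
        annot = annotate_pharmacophores(_complex(protein, ring))
        assert len(annot.ligand_rings) == 1
        assert len(annot.ligand_rings[0]) == 6

    def test_unknown_element_warns(self):
        protein = _gly_backbone()
        ligand = [make_atom("FE", "FE", (50, 0, 0), resnum=9, resname="LIG", is_ligand=True)]
        with pytest.warns(UserWarning, match="unknown ligand element"):
            annotate_pharmacophores(_complex(protein, ligand))


class TestDetectInteractions:
    def test_ligand_donor_good_angle(self):
        # ligand N donor 2.9 A from backbone O, antecedent at 150 degrees
        protein = _gly_backbone(origin=(-3.23, -1.58, 0.0))  # puts O at origin
        n_xyz = np.array([2.9, 0.0, 0.0])
        c_xyz = n_xyz + 1.45 * np.array([np.cos(np.radians(30)), np.sin(np.radians(30)), 0.0])
        ligand = [
            make_atom("N1", "N", tuple(n_xyz), resnum=9, resname="LIG", is_ligand=True),
            make_atom("C1", "C", tuple(c_xyz), resnum=9, resname="LIG", is_ligand=True),
        ]
        cplx = _complex(protein, ligand)
        fp = detect_interactions(cplx, annotate_pharmacophores(cplx), identity_map(cplx))
        assert (0, "HBD") in fp.bits

    def test_ligand_donor_bad_angle(self):
        protein = _gly_backbone(origin=(-3.23, -1.58, 0.0))
        n_xyz = np.array([2.9, 0.0, 0.0])
        # antecedent at 60 degrees from the acceptor: angle proxy fails
        c_xyz = n_xyz - 1.45 * np.array([np.cos(np.radians(60)), np.sin(np.radians(60)), 0.0])
        ligand = [
            make_atom("N1", "N", tuple(n_xyz), resnum=9, resname="LIG", is_ligand=True),
            make_atom("C1", "C", tuple(c_xyz), resnum=9, resname="LIG", is_ligand=True),
        ]
        cplx = _complex(protein, ligand)
        fp = detect_interactions(cplx, annotate_pharmacophores(cplx), identity_map(cplx))
        assert (0, "HBD") not in fp.bits

    def test_counted_once_per_residue(self):
        # two acceptor atoms of the same residue within H-bond range of a
        # lone ligand donor -> still exactly one HBD bit
        protein = _gly_backbone(resname="SER", origin=(-3.23, -1.58, 0.0)) + [
            make_atom("OG", "O", (0.0, 3.0, 0.0), resname="SER"),
        ]
        ligand = [make_atom("N1", "N", (2.9, 0.0, 0.0), resnum=9, resname="LIG",
                            is_ligand=True)]
        cplx = _complex(protein, ligand)
        fp = detect_interactions(cplx, annotate_pharmacophores(cplx), identity_map(cplx))
        hbd_bits = [b for b in fp.bits if b[1] == "HBD"]
        assert hbd_bits == [(0, "HBD")]

    def test_far_ligand_empty_fingerprint(self):
        protein = _gly_backbone()
        ligand = [make_atom("N1", "N", (50, 0, 0), resnum=9, resname="LIG", is_ligand=True)]
        cplx = _complex(protein, ligand)
        fp = detect_interactions(cplx, annotate_pharmacophores(cplx), identity_map(cplx))
        assert fp.bits == frozenset()

    def test_ionic_contact(self):
        protein = _gly_backbone(resname="ASP") + [
            make_atom("CG", "C", (0.0, 4.5, 0.0), resname="ASP"),
            make_atom("OD1", "O", (1.2, 5.0, 0.0), resname="ASP"),
        ]
        # quaternary-like ligand N (degree 4) -> cation
        center = np.array([1.2, 8.4, 0.0])
        ligand = [make_atom("N1", "N", tuple(center), resnum=9, resname="LIG", is_ligand=True)]
        for k, d in enumerate([(1.5, 0, 0), (-1.5, 0, 0), (0, 1.5, 0), (0, 0, 1.5)]):
            ligand.append(make_atom(f"C{k}", "C", tuple(center + np.array(d)),
                                    resnum=9, resname="LIG", is_ligand=True))
        cplx = _complex(protein, ligand)
        fp = detect_interactions(cplx, annotate_pharmacophores(cplx), identity_map(cplx))
        assert (0, "IONIC") in fp.bits

    def test_arene_attraction(self):
        protein = _gly_backbone(resname="PHE", origin=(-20, 0, 0)) + [
            make_atom(name, "C",
                      (1.39 * np.cos(np.pi / 3 * k), 1.39 * np.sin(np.pi / 3 * k), 0.0),
                      resname="PHE")
            for k, name in enumerate(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"])
        ]
        ligand = [
            make_atom(f"C{k}", "C",
                      (1.39 * np.cos(np.pi / 3 * k), 1.39 * np.sin(np.pi / 3 * k), 3.6),
                      resnum=9, resname="LIG", is_ligand=True)
            for k in range(6)
        ]
        cplx = _complex(protein, ligand)
        fp = detect_interactions(cplx, annotate_pharmacophores(cplx), identity_map(cplx))
        assert (0, "ARENE") in fp.bits

    def test_surface_contact(self):
        protein = _gly_backbone()
        ca = protein[1]
        ligand = [make_atom("C1", "C", (ca.coords[0], ca.coords[1], 4.0),
                            resnum=9, resname="LIG", is_ligand=True)]
        cplx = _complex(protein, ligand)
        fp = detect_interactions(cplx, annotate_pharmacophores(cplx), identity_map(cplx))
        assert (0, "SURFACE") in fp.bits

    def test_unmapped_residue_dropped(self, caplog):
        protein = _gly_backbone()
        ligand = [make_atom("N1", "N", (3.23 + 2.9, 1.58, 0.0), resnum=9,
                            resname="LIG", is_ligand=True)]
        cplx = _complex(protein, ligand)
        amap = identity_map(cplx)
        amap.mapping.clear()
        with caplog.at_level("INFO"):
            fp = detect_interactions(cplx, annotate_pharmacophores(cplx), amap)
        assert fp.bits == frozenset()
        assert "dropped" in caplog.text

    def test_rigid_motion_invariance(self, toy_complex):
        rng = np.random.default_rng(5)
        amap = identity_map(toy_complex)
        base = detect_interactions(toy_complex, annotate_pharmacophores(toy_complex), amap)
        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            moved = transform_complex(toy_complex, rot, trans)
            fp = detect_interactions(moved, annotate_pharmacophores(moved), identity_map(moved))
            assert fp.bits == base.bits


def _fp(cid, bits, site="cofactor"):
    return InteractionFingerprint(cid, site, frozenset(bits))


class TestTanimoto:
    def test_identity(self):
        f = _fp("a", {(1, "HBD"), (2, "HBA")})
        assert fingerprint_tanimoto(f, f) == 1.0

    def test_disjoint(self):
        assert fingerprint_tanimoto(
            _fp("a", {(1, "HBD")}), _fp("b", {(2, "HBD")})
        ) == 0.0

    def test_half_overlap(self):
        f1 = _fp("a", {(1, "HBD"), (2, "HBA"), (3, "SURFACE")})
        f2 = _fp("b", {(2, "HBA"), (3, "SURFACE"), (4, "HBD")})
        assert fingerprint_tanimoto(f1, f2) == pytest.approx(0.5)

    def test_both_empty_warns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert fingerprint_tanimoto(_fp("a", set()), _fp("b", set())) == 0.0

    def test_site_mismatch(self):
        with pytest.raises(ValueError, match="site mismatch"):
            fingerprint_tanimoto(_fp("a", {(1, "HBD")}),
                                 _fp("b", {(1, "HBD")}, site="substrate"))

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(2)
        fps = [
            _fp(f"c{i}", {(int(rng.integers(0, 6)), "HBD") for _ in range(3)})
            for i in range(6)
        ]
        for f1 in fps:
            for f2 in fps:
                t = fingerprint_tanimoto(f1, f2)
                assert 0.0 <= t <= 1.0
                assert t == fingerprint_tanimoto(f2, f1)
                if f1.bits == f2.bits and f1.bits:
                    assert t == 1.0

    def test_one_iff_equal_nonempty(self):
        f1 = _fp("a", {(1, "HBD"), (2, "HBA")})
        f2 = _fp("b", {(1, "HBD")})
        assert fingerprint_tanimoto(f1, f2) < 1.0


class TestSummarize:
    def test_bit_percentage(self):
        fps = [
            _fp("c1", {(10, "HBD")}),
            _fp("c2", {(10, "HBD")}),
            _fp("c3", {(11, "HBA")}),
            _fp("c4", set()),
        ]
        tables = summarize_interactions(fps)
        per_bit = tables["per_bit"].set_index(["column", "type"])
        assert per_bit.loc[(10, "HBD"), "percent"] == pytest.approx(50.0)

    def test_type_shares_sum_to_100(self):
        fps = [
            _fp("c1", {(1, "HBD"), (2, "HBD"), (3, "HBD"), (4, "SURFACE")}),
        ]
        per_type = summarize_interactions(fps)["per_type"]
        shares = dict(zip(per_type["type"], per_type["percent"]))
        assert shares["HBD"] == pytest.approx(75.0)
        assert shares["SURFACE"] == pytest.approx(25.0)
        assert per_type["percent"].sum() == pytest.approx(100.0)

    def test_interacting_columns(self):
        fps = [_fp("c1", {(5, "HBD")}), _fp("c2", {(7, "SURFACE")})]
        cols = summarize_interactions(fps)["interacting_columns"]["column"].tolist()
        assert cols == [5, 7]

    def test_per_target_grouping(self):
        fps = [
            _fp("c1", {(10, "HBD")}),
            _fp("c2", {(10, "HBD")}),
            _fp("c3", set()),
            _fp("c4", set()),
        ]
        grouping = {"c1": "T1", "c2": "T1", "c3": "T2", "c4": "T3"}
        per_bit = summarize_interactions(fps, grouping=grouping)["per_bit"]
        row = per_bit.set_index(["column", "type"]).loc[(10, "HBD")]
        assert row["percent"] == pytest.approx(100.0 / 3.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            summarize_interactions([])
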