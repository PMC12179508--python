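"""Geometric feature detection on 3D models: hydrogen bonds, contacts,
secondary structure, and per-variant feature summaries."""

import numpy as np
import pytest

from indelstruct.structure import (
    ACIDIC_ATOMS,
    BACKBONE_NAMES,
    BASIC_ATOMS,
    HYDROPHOBIC,
    DisruptionLevel,
    IonicChange,
    Residue,
    SsSummary,
    StructureModel,
    assign_secondary_structure,
    backbone_hbonds,
    hydrophobic_contacts,
    polar_contacts,
    read_structure,
    salt_bridges,
    variant_structural_features,
    write_pdb,
)
from indelstruct.synthetic import (
    make_extended_chain,
    make_ideal_helix,
    make_random_contact_structure,
)
from indelstruct.variants import parse_hgvs_p


def two_residue_model(aa1, atoms1, aa2, atoms2) -> StructureModel:
    def mk(num, aa, spec):
        atoms = {"N": np.zeros(3), "CA": np.zeros(3), "C": np.zeros(3), "O": np.zeros(3)}
        atoms.update({k: np.asarray(v, dtype=float) for k, v in spec.items()})
        # place backbone far from the interaction site to keep it inert
        for name in ("N", "CA", "C", "O"):
            atoms[name] = atoms[name] + np.array([50.0 * num, 50.0, 50.0])
        return Residue(number=num, aa=aa, atoms=atoms, elements={k: k[:1] for k in atoms})

    return StructureModel(chain_id="A", residues=[mk(1, aa1, atoms1), mk(5, aa2, atoms2)])


class TestReadWritePdb:
    def test_helix_round_trip(self, helix20, tmp_path):
        p = tmp_path / "helix.pdb"
        write_pdb(helix20, p)
        again = read_structure(p)
        assert len(again.residues) == 20
        assert all(r.has_backbone() and "O" in r.atoms for r in again.residues)
        for a, b in zip(helix20.residues, again.residues):
            np.testing.assert_allclose(a.atoms["CA"], b.atoms["CA"], atol=1e-2)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        pdb = (
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40 10.00           N\n"
            "ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.60 10.00           N\n"
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C\n"
            "ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C\n"
            "END\n"
        )
        p = tmp_path / "altloc.pdb"
        p.write_text(pdb)
        model = read_structure(p)
        assert len(model.residues) == 1
        np.testing.assert_allclose(model.residues[0].atoms["N"], [9.0, 0.0, 0.0])

    def test_ca_only_file_warns_and_ss_refuses(self, tmp_path):
        lines = [
            f"ATOM  {i+1:5d}  CA  ALA A{i+1:4d}    {3.8*i:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 10.00           C"
            for i in range(5)
        ]
        p = tmp_path / "ca.pdb"
        p.write_text("\n".join(lines) + "\nEND\n")
        model = read_structure(p)
        assert len(model.warnings) == 5
        with pytest.raises(ValueError, match="backbone"):
            assign_secondary_structure(model)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ValueError):
            read_structure(p)


class TestBackboneHbonds:
    def test_ideal_helix_has_the_i_i4_ladder(self, helix20):
        bonds = backbone_hbonds(helix20)
        i_i4 = [(d, a) for d, a, _ in bonds if d - a == 4]
        assert len(i_i4) >= 12

    def test_extended_chain_has_no_bonds(self, extended20):
        assert backbone_hbonds(extended20) == []

    def test_distant_residues_never_bond(self):
        helix = make_ideal_helix(5)
        far = make_ideal_helix(5, start_number=6)
        for r in far.residues:
            for k in r.atoms:
                r.atoms[k] = r.atoms[k] + np.array([30.0, 0.0, 0.0])
        model = StructureModel(chain_id="A", residues=helix.residues + far.residues)
        assert all(
            {d, a} <= {1, 2, 3, 4, 5} or {d, a} <= {6, 7, 8, 9, 10}
            for d, a, _ in backbone_hbonds(model)
        )

    def test_energies_are_negative_at_report(self, helix20):
        assert all(e < -0.5 for _, _, e in backbone_hbonds(helix20))


class TestContactDetectors:
    def test_polar_contact_by_construction(self):
        m = two_residue_model("N", {"ND2": [0, 0, 0]}, "Q", {"OE1": [2.9, 0, 0]})
        contacts = polar_contacts(m)
        assert len(contacts) == 1
        assert contacts[0][:4] == (1, "ND2", 5, "OE1")

    def test_polar_contact_beyond_cutoff(self):
        m = two_residue_model("N", {"ND2": [0, 0, 0]}, "Q", {"OE1": [5.0, 0, 0]})
        assert polar_contacts(m) == []

    def test_salt_bridge_by_construction(self):
        m = two_residue_model("K", {"NZ": [0, 0, 0]}, "E", {"OE1": [3.5, 0, 0]})
        assert salt_bridges(m) == [(1, 5, pytest.approx(3.5))]
        m_far = two_residue_model("K", {"NZ": [0, 0, 0]}, "E", {"OE1": [4.5, 0, 0]})
        assert salt_bridges(m_far) == []

    def test_hydrophobic_pair_and_nonhydrophobic_partner(self):
        m = two_residue_model("L", {"CD1": [0, 0, 0]}, "L", {"CD1": [4.0, 0, 0]})
        assert [(i, j) for i, j, _ in hydrophobic_contacts(m)] == [(1, 5)]
        m2 = two_residue_model("L", {"CD1": [0, 0, 0]}, "S", {"OG": [4.0, 0, 0]})
        assert hydrophobic_contacts(m2) == []

    def test_sequence_neighbours_excluded_from_hydrophobic(self):
        m = two_residue_model("L", {"CD1": [0, 0, 0]}, "L", {"CD1": [4.0, 0, 0]})
        m.residues[1].number = 2  # adjacent in sequence
        assert hydrophobic_contacts(m) == []

    @pytest.mark.parametrize("seed", range(50))
    def test_detectors_equal_brute_force_scan(self, seed):
        """KD-tree detectors reproduce an O(n^2) all-pairs oracle."""
        model = make_random_contact_structure(n_residues=25, seed=seed)

        got_salt = {(b, a) for b, a, _ in salt_bridges(model)}
        expect_salt = set()
        for rb in model.residues:
            for ra in model.residues:
                if rb.aa not in BASIC_ATOMS or ra.aa not in ACIDIC_ATOMS:
                    continue
                if rb.number == ra.number:
                    continue
                dmin = min(
                    (
                        np.linalg.norm(rb.atoms[x] - ra.atoms[y])
                        for x in BASIC_ATOMS[rb.aa] if x in rb.atoms
                        for y in ACIDIC_ATOMS[ra.aa] if y in ra.atoms
                    ),
                    default=np.inf,
                )
                if dmin <= 4.0:
                    expect_salt.add((rb.number, ra.number))
        assert got_salt == expect_salt

        got_hyd = {(i, j) for i, j, _ in hydrophobic_contacts(model)}
        expect_hyd = set()
        for r1 in model.residues:
            for r2 in model.residues:
                if r1.number >= r2.number or abs(r1.number - r2.number) < 2:
                    continue
                if r1.aa not in HYDROPHOBIC or r2.aa not in HYDROPHOBIC:
                    continue
                for n1, x1 in r1.sidechain_atoms():
                    if r1.elements[n1] != "C":
                        continue
                    for n2, x2 in r2.sidechain_atoms():
                        if r2.elements[n2] != "C":
                            continue
                        if np.linalg.norm(x1 - x2) <= 4.5:
                            expect_hyd.add((r1.number, r2.number))
        assert got_hyd == expect_hyd

        got_polar = {(ri, ai, rj, aj) for ri, ai, rj, aj, _ in polar_contacts(model)}
        expect_polar = set()
        for r1 in model.residues:
            for n1, x1 in r1.atoms.items():
                if r1.elements[n1] not in "NO":
                    continue
                for r2 in model.residues:
                    if r2.number == r1.number:
                        continue
                    for n2, x2 in r2.atoms.items():
                        if r2.elements[n2] not in "NO":
                            continue
                        if n1 in BACKBONE_NAMES and n2 in BACKBONE_NAMES:
                            continue
                        if np.linalg.norm(x1 - x2) <= 3.5:
                            key = tuple(sorted([(r1.number, n1), (r2.number, n2)]))
                            expect_polar.add((key[0][0], key[0][1], key[1][0], key[1][1]))
        assert got_polar == expect_polar


class TestSecondaryStructure:
    def test_ideal_helix_mostly_h(self, helix20):
        ss = assign_secondary_structure(helix20)
        assert sum(1 for s in ss.values() if s == "H") >= 16

    def test_extended_chain_all_l(self, extended20):
        ss = assign_secondary_structure(extended20)
        assert set(ss.values()) == {"L"}

    def test_three_residue_fragment_all_l(self):
        frag = make_ideal_helix(6)
        frag3 = StructureModel(chain_id="A", residues=frag.residues[:3])
        assert set(assign_secondary_structure(frag3).values()) == {"L"}

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, helix20, seed):
        rng = np.random.default_rng(seed)
        # random rotation via QR decomposition, plus a translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.uniform(-50, 50, size=3)
        moved = StructureModel(
            chain_id="A",
            residues=[
                Residue(
                    number=r.number, aa=r.aa,
                    atoms={k: q @ v + t for k, v in r.atoms.items()},
                    elements=dict(r.elements),
                )
                for r in helix20.residues
            ],
        )
        assert assign_secondary_structure(moved) == assign_secondary_structure(helix20)


class TestVariantFeatures:
    def test_mid_helix_deletion_is_helical_with_hbond_loss(self):
        helix = make_ideal_helix(20, sequence="A" * 20)
        v = parse_hgvs_p("p.(Ala10_Ala11del)")
        f = variant_structural_features(helix, v)
        assert f.ss_summary is SsSummary.alpha_helix
        assert f.hbond_level in (DisruptionLevel.likely, DisruptionLevel.possibly)
        assert len(f.hbonds_lost) >= 1

    def test_loop_deletion_with_one_polar_contact(self):
        chain = make_extended_chain(12, sequence="ANAAAAAAQAAA")
        # place a single side-chain polar pair between Asn2 and Gln9
        chain.residues[1].atoms["ND2"] = np.array([0.0, 20.0, 0.0])
        chain.residues[1].elements["ND2"] = "N"
        chain.residues[8].atoms["OE1"] = np.array([2.9, 20.0, 0.0])
        chain.residues[8].elements["OE1"] = "O"
        f = variant_structural_features(chain, parse_hgvs_p("p.(Asn2del)"))
        assert f.ss_summary is SsSummary.loop
        assert f.hbond_level is DisruptionLevel.possibly

    def test_variant_outside_model_is_not_assessable(self, helix20):
        assert variant_structural_features(helix20, parse_hgvs_p("p.(Ala30del)")) is None

    def test_salt_bridge_loss_flagged(self):
        helix = make_ideal_helix(12, sequence="AKAAEAAAAAAA")
        helix.residues[1].atoms["NZ"] = np.array([0.0, 30.0, 0.0])
        helix.residues[1].elements["NZ"] = "N"
        helix.residues[4].atoms["OE1"] = np.array([3.0, 30.0, 0.0])
        helix.residues[4].elements["OE1"] = "O"
        f = variant_structural_features(helix, parse_hgvs_p("p.(Lys2del)"))
        assert f.ionic is IonicChange.possibly_lost

    def test_delins_gaining_charge_near_counter_charge(self):
        helix = make_ideal_helix(12, sequence="AAAAEAAAAAAA")
        helix.residues[4].atoms["OE1"] = helix.residues[2].atoms["CB"] + np.array(
            [0.0, 0.0, 2.0]
        )
        helix.residues[4].elements["OE1"] = "O"
        v = parse_hgvs_p("p.(Ala3delinsLys)")
        f = variant_structural_features(helix, v)
        assert f.ionic is IonicChange.possibly_created
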