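import numpy as np
import pytest
from dataclasses import replace

from conftest import make_atom
from halosite import synthetic as syn
from halosite.conformation import rotation_matrix
from halosite.ionsites import (
    LigandClass,
    analyze_mg,
    census,
    classify_context,
    classify_ligand,
    cluster_equivalent_sites,
    detect_sites,
    find_bridges,
    match_sites,
)
from halosite.structio import StructureModel


class TestClassifyLigand:
    @pytest.mark.parametrize(
        "res,name,expected",
        [
            ("GLU", "O", LigandClass.MAIN_CHAIN_CARBONYL),
            ("GLY", "O", LigandClass.MAIN_CHAIN_CARBONYL),
            ("ASP", "OD2", LigandClass.CARBOXYLATE_O),
            ("GLU", "OE1", LigandClass.CARBOXYLATE_O),
            ("ALA", "OXT", LigandClass.CARBOXYLATE_O),
            ("SER", "OG", LigandClass.HYDROXYL_O),
            ("THR", "OG1", LigandClass.HYDROXYL_O),
            ("TYR", "OH", LigandClass.HYDROXYL_O),
            ("ASN", "OD1", LigandClass.AMIDE_O),
            ("GLN", "OE1", LigandClass.AMIDE_O),
            ("HOH", "O", LigandClass.WATER_O),
        ],
    )
    def test_lookup_table(self, res, name, expected):
        atom = make_atom(1, name, "O", residue_name=res, is_hetero=False)
        assert classify_ligand(atom) is expected

    def test_cofactor_oxygen_is_hetero(self):
        # pyrophosphate oxygen of a bound dinucleotide
        atom = make_atom(1, "O1N", "O", residue_name="NAP", is_hetero=True)
        assert classify_ligand(atom) is LigandClass.HETERO_O

    def test_non_oxygen_is_other(self):
        atom = make_atom(1, "NZ", "N", residue_name="LYS")
        assert classify_ligand(atom) is LigandClass.OTHER

    def test_unknown_pair_warns(self):
        atom = make_atom(1, "OQ9", "O", residue_name="ALA")
        with pytest.warns(UserWarning, match="unrecognised"):
            assert classify_ligand(atom) is LigandClass.OTHER


class TestDetectSites:
    def test_planted_shell_recovered(self, planted_k_site):
        model, truth = planted_k_site
        sites = detect_sites(model, ["K"])
        assert len(sites) == 1
        s = sites[0]
        assert s.coordination_number == 7
        counts = {k.value: v for k, v in s.class_counts().items()}
        assert counts == {"main_chain_carbonyl": 4, "water_O": 3}
        # contacts sorted by distance
        dists = [c.distance for c in s.contacts]
        assert dists == sorted(dists)
        # distances match the planted truth as multisets
        assert sorted(round(d, 3) for d in dists) == sorted(
            round(d, 3) for d in truth.sites[0].ligand_distances
        )

    def test_under_coordinated_flagged(self):
        # K+ whose nearest O sits beyond the 3.5-A cutoff
        atoms = [
            make_atom(1, "O", "O", residue_name="HOH", residue_seq=1, chain_id="W",
                      position=(3.8, 0, 0)),
            make_atom(2, "K", "K", residue_name="K", residue_seq=1, chain_id="I",
                      position=(0, 0, 0), is_hetero=True),
        ]
        model = StructureModel(atoms=atoms)
        (site,) = detect_sites(model, ["K"])
        assert site.coordination_number == 0
        assert site.under_coordinated

    def test_absent_species_empty(self, helix10):
        assert detect_sites(helix10, ["NA"]) == []

    def test_unphysical_cutoff_rejected(self, planted_k_site):
        model, _ = planted_k_site
        with pytest.raises(ValueError, match="first-shell"):
            detect_sites(model, ["K"], cutoffs={"K": 6.5})

    def test_cutoff_monotonicity(self, planted_k_site):
        """Shrinking the cutoff never adds contacts."""
        model, _ = planted_k_site
        prev = None
        for cutoff in (3.5, 3.2, 2.9, 2.75, 2.5):
            (site,) = detect_sites(model, ["K"], cutoffs={"K": cutoff})
            keys = {c.atom_key for c in site.contacts}
            if prev is not None:
                assert keys <= prev
            prev = keys

    def test_other_ions_recorded_as_neighbors_not_ligands(self):
        atoms = [
            make_atom(1, "K", "K", residue_name="K", residue_seq=1, chain_id="I",
                      position=(0, 0, 0), is_hetero=True),
            make_atom(2, "MG", "MG", residue_name="MG", residue_seq=2, chain_id="I",
                      position=(3.0, 0, 0), is_hetero=True),
            make_atom(3, "O", "O", residue_name="HOH", residue_seq=3, chain_id="W",
                      position=(0, 2.8, 0)),
        ]
        model = StructureModel(atoms=atoms)
        (site,) = detect_sites(model, ["K"])
        assert site.coordination_number == 1
        assert [n[0].residue_name for n in site.ion_neighbors] == ["MG"]


class TestCensus:
    def test_empty_is_all_zero(self):
        c = census([])
        assert c.ion_count == 0
        assert c.protein_ligand_count == 0
        assert c.class_counts == {}

    def test_composite_census(self, composite_crystal):
        model, truth = composite_crystal
        sites = detect_sites(model, ["K"], include_symmetry=True)
        c = census(sites)
        assert c.ion_count == 4
        assert c.protein_ligand_count == 16
        assert c.protein_class_counts[LigandClass.MAIN_CHAIN_CARBONYL] == 16
        assert c.water_ligand_count == 12
        # invariant: protein class counts sum to the protein ligand count
        assert sum(c.protein_class_counts.values()) == c.protein_ligand_count

    def test_additivity(self, composite_crystal):
        model, _ = composite_crystal
        sites = detect_sites(model, ["K"])
        c_all = census(sites)
        c_sum = census(sites[:2]) + census(sites[2:])
        assert c_sum.ion_count == c_all.ion_count
        assert c_sum.protein_ligand_count == c_all.protein_ligand_count
        assert c_sum.class_counts == c_all.class_counts
        assert c_sum.water_ligand_count == c_all.water_ligand_count


class TestBridges:
    def test_planted_bridge_found(self, helix10):
        model, truth = syn.plant_bridged_pair(helix10, separation=3.9, seed=5)
        sites = detect_sites(model, ["K"])
        bridges = find_bridges(sites)
        assert len(bridges) == 1
        b = bridges[0]
        assert b["distance"] == pytest.approx(3.9, abs=1e-6)
        assert len(b["shared_contacts"]) == 3
        assert len(b["shared_protein_residues"]) == 2  # the two carbonyls

    def test_distant_sites_not_bridged(self, composite_crystal):
        model, _ = composite_crystal
        sites = detect_sites(model, ["K"])
        assert find_bridges(sites) == []


class TestContext:
    def test_intra_subunit(self, planted_k_site):
        model, _ = planted_k_site
        (site,) = detect_sites(model, ["K"])
        assert classify_context(site) == "INTRA_SUBUNIT"

    def test_inter_subunit(self, helix10):
        model, _ = syn.plant_site(helix10, "K_carbonyl_cluster", cn=7, seed=9)
        # move two of the four carbonyl fragments to a second chain of the
        # same assembly
        moved, count = [], 0
        frag_seqs = sorted(
            {a.residue_seq for a in model.atoms if a.chain_id == "A" and a.residue_seq > 10}
        )[:2]
        for a in model.atoms:
            if a.chain_id == "A" and a.residue_seq in frag_seqs:
                moved.append(replace(a, chain_id="B"))
            else:
                moved.append(a)
        model2 = model.with_atoms(moved)
        (site,) = detect_sites(model2, ["K"])
        ctx = classify_context(site, assembly_map={"A": "1", "B": "1", "W": "1", "I": "1"})
        assert ctx == "INTER_SUBUNIT"

    def test_crystal_contact_via_symmetry_copy(self, helix10):
        model, truth = syn.plant_crystal_contact_site(helix10, seed=2)
        sites = detect_sites(model, ["K"], include_symmetry=True)
        from halosite.xtal import expand_symmetry

        copies = expand_symmetry(model, radius=7.5)
        for s in sites:
            classify_context(s, placed_copies=copies)
        assert [s.context for s in sites] == ["CRYSTAL_CONTACT"]

    def test_context_invariant_under_translation(self, helix10):
        """P1 lattice context is unchanged by a joint rigid translation."""
        model, _ = syn.plant_crystal_contact_site(helix10, seed=2)

        def context_of(m):
            from halosite.xtal import expand_symmetry

            copies = expand_symmetry(m, radius=7.5)
            (site,) = detect_sites(m, ["K"], include_symmetry=True, placed_copies=copies)
            return classify_context(site, placed_copies=copies)

        shift = np.array([3.1, -2.2, 5.7])
        shifted = model.with_atoms(
            [replace(a, position=tuple(a.xyz + shift)) for a in model.atoms]
        )
        assert context_of(model) == context_of(shifted) == "CRYSTAL_CONTACT"


class TestClustering:
    @staticmethod
    def _ncs_copies(n=4):
        host = syn.gen_helix(8, "A" * 8)
        base, _ = syn.plant_site(host, "K_carbonyl_cluster", cn=7, seed=11)
        atoms, serial = [], 0
        for i in range(n):
            R = rotation_matrix([0, 0, 1], 90.0 * i)
            off = np.array([60.0 * (i % 2), 60.0 * (i // 2), 0.0])
            ch = "ABCD"[i]
            for a in base.atoms:
                serial += 1
                cid = ch if a.chain_id == "A" else a.chain_id + str(i)
                atoms.append(replace(a, serial=serial, chain_id=cid, position=tuple(R @ a.xyz + off)))
        return StructureModel(atoms=atoms)

    def test_four_ncs_copies_one_class(self):
        model = self._ncs_copies()
        sites = detect_sites(model, ["K"])
        assert len(sites) == 4
        assignment = cluster_equivalent_sites(sites, model, reference_chain="A")
        assert set(assignment.values()) == {1}
        assert all(s.site_class_id == 1 for s in sites)

    def test_separated_sites_distinct_classes(self, composite_crystal):
        model, _ = composite_crystal
        sites = detect_sites(model, ["K"])
        assignment = cluster_equivalent_sites(sites, model)
        assert len(set(assignment.values())) == len(sites)


class TestMatchSites:
    def test_identical_structures_perfect_matching(self, composite_crystal):
        model, _ = composite_crystal
        sites = detect_sites(model, ["K"])
        res = match_sites(sites, sites)
        assert len(res["pairs"]) == len(sites)
        assert res["unmatched_a"] == [] and res["unmatched_b"] == []
        assert all(p["distance"] == 0.0 for p in res["pairs"])

    def test_disjoint_sites_no_matches(self, helix10):
        m1, _ = syn.plant_site(helix10, "K_carbonyl_cluster", seed=1)
        m2, _ = syn.plant_site(helix10, "K_carbonyl_cluster", seed=2,
                               position=np.array([200.0, 200.0, 200.0]))
        s1 = detect_sites(m1, ["K"])
        s2 = detect_sites(m2, ["K"])
        res = match_sites(s1, s2)
        assert res["pairs"] == []


class TestAnalyzeMg:
    def test_ideal_hexaaqua_octahedron(self, helix10):
        model, _ = syn.plant_site(helix10, "Mg_hexaaqua", seed=4)
        (report,) = analyze_mg(model, include_symmetry=False)
        assert report["cn"] == 6
        assert report["octahedral_score_deg"] == pytest.approx(0.0, abs=1.0)
        assert not report["direct_carboxyl"]
        assert not report["water_mediated_carboxyl"]

    def test_direct_carboxyl_flag(self):
        atoms = [
            make_atom(1, "OD1", "O", residue_name="ASP", residue_seq=1,
                      position=(2.1, 0, 0)),
            make_atom(2, "O", "O", residue_name="HOH", residue_seq=2, chain_id="W",
                      position=(-2.1, 0, 0)),
            make_atom(3, "MG", "MG", residue_name="MG", residue_seq=3, chain_id="I",
                      position=(0, 0, 0), is_hetero=True),
        ]
        model = StructureModel(atoms=atoms)
        (report,) = analyze_mg(model, include_symmetry=False)
        assert report["direct_carboxyl"]

    def test_water_mediated_carboxyl_flag(self):
        atoms = [
            make_atom(1, "O", "O", residue_name="HOH", residue_seq=1, chain_id="W",
                      position=(2.1, 0, 0)),
            # carboxylate O one hydrogen bond beyond the first-shell water
            make_atom(2, "OD1", "O", residue_name="ASP", residue_seq=2,
                      position=(4.9, 0, 0)),
            make_atom(3, "MG", "MG", residue_name="MG", residue_seq=3, chain_id="I",
                      position=(0, 0, 0), is_hetero=True),
        ]
        model = StructureModel(atoms=atoms)
        (report,) = analyze_mg(model, include_symmetry=False)
        assert not report["direct_carboxyl"]
        assert report["water_mediated_carboxyl"]
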