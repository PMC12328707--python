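import numpy as np
import pytest
from dataclasses import replace

from conftest import make_atom
from halosite.structio import StructureModel
from halosite.surface import (
    VDW_RADII,
    classify_miller,
    compare_profiles,
    miller_composition,
    sasa,
)


def grid_quadrature_sasa(coords, radii, probe, n_theta=120, n_phi=240):
    """Independent dense lat-long quadrature oracle for SASA."""
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack(
        [np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH), np.cos(TH)], axis=-1
    ).reshape(-1, 3)
    weights = (np.sin(TH) * (np.pi / n_theta) * (2 * np.pi / n_phi)).reshape(-1)
    R = np.asarray(radii) + probe
    out = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + R[i] * dirs
        free = np.ones(len(pts), dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= ((pts - coords[j]) ** 2).sum(axis=1) > R[j] ** 2
        out[i] = (R[i] ** 2) * weights[free].sum()
    return out


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        model = StructureModel(atoms=[make_atom(1, "C", "C")])
        area = sasa(model)[0]
        analytic = 4 * np.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert area == pytest.approx(analytic, rel=0.01)

    def test_two_distant_atoms_full_spheres(self):
        atoms = [
            make_atom(1, "C", "C", position=(0, 0, 0)),
            make_atom(2, "C", "C", position=(20, 0, 0), residue_seq=2),
        ]
        areas = sasa(StructureModel(atoms=atoms))
        analytic = 4 * np.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert np.allclose(areas, analytic, rtol=0.01)

    def test_two_sphere_closed_form(self):
        """Two equal intersecting spheres lose a cap of area 2*pi*R*(R-d/2) each."""
        d = 3.0
        atoms = [
            make_atom(1, "C", "C", position=(0, 0, 0)),
            make_atom(2, "C", "C", position=(d, 0, 0), residue_seq=2),
        ]
        areas = sasa(StructureModel(atoms=atoms), n_points=5000)
        R = VDW_RADII["C"] + 1.4
        expected = 4 * np.pi * R**2 - 2 * np.pi * R * (R - d / 2)
        assert np.allclose(areas, expected, rtol=0.01)

    def test_caged_atom_zero(self):
        # central atom fully enclosed by a tight icosahedral-ish cage
        from halosite.surface import sphere_points

        cage = sphere_points(40) * 2.2
        atoms = [make_atom(1, "C", "C", position=(0, 0, 0))]
        atoms += [
            make_atom(i + 2, "C", "C", position=tuple(p), residue_seq=i + 2)
            for i, p in enumerate(cage)
        ]
        areas = sasa(StructureModel(atoms=atoms))
        assert areas[0] == 0.0

    def test_random_cluster_matches_grid_oracle(self, rng):
        n = 40
        coords = rng.uniform(0, 12, size=(n, 3))
        atoms = [
            make_atom(i + 1, "C", "C", position=tuple(p), residue_seq=i + 1)
            for i, p in enumerate(coords)
        ]
        model = StructureModel(atoms=atoms)
        got = sasa(model, n_points=2000)
        oracle = grid_quadrature_sasa(coords, [VDW_RADII["C"]] * n, 1.4)
        assert got.sum() == pytest.approx(oracle.sum(), rel=0.02)

    def test_translation_invariance_exact_lattice(self, mixed_helix):
        t = np.array([11.0, -7.0, 3.0])
        moved = mixed_helix.with_atoms(
            [replace(a, position=tuple(a.xyz + t)) for a in mixed_helix.atoms]
        )
        assert sasa(moved).sum() == pytest.approx(sasa(mixed_helix).sum(), rel=1e-9)

    def test_rotation_invariance_dense_lattice(self, mixed_helix):
        # quadrature orientation error shrinks with lattice density; at 4000
        # points a rigid rotation moves the total by well under 0.1%
        from halosite.conformation import rotation_matrix

        base = sasa(mixed_helix, n_points=4000).sum()
        R = rotation_matrix([1, 2, 3], 61.0)
        moved = mixed_helix.with_atoms(
            [replace(a, position=tuple(R @ a.xyz)) for a in mixed_helix.atoms]
        )
        assert sasa(moved, n_points=4000).sum() == pytest.approx(base, rel=0.001)

    def test_adding_atom_never_increases_sasa(self, rng):
        coords = rng.uniform(0, 8, size=(15, 3))
        atoms = [
            make_atom(i + 1, "C", "C", position=tuple(p), residue_seq=i + 1)
            for i, p in enumerate(coords)
        ]
        before = sasa(StructureModel(atoms=atoms))
        extra = atoms + [make_atom(99, "C", "C", position=(4, 4, 4), residue_seq=99)]
        after = sasa(StructureModel(atoms=extra))[:-1]
        assert np.all(after <= before + 1e-9)

    def test_unknown_element_raises(self):
        model = StructureModel(atoms=[make_atom(1, "XX", "XX")])
        with pytest.raises(ValueError, match="XX"):
            sasa(model)


class TestMillerComposition:
    def test_poly_ala_has_zero_charged(self, helix10):
        prof = miller_composition(helix10)
        assert prof.fraction_charged == 0.0
        assert prof.fraction_nonpolar + prof.fraction_polar == pytest.approx(1.0, abs=1e-6)

    def test_fractions_sum_to_one(self, mixed_helix):
        prof = miller_composition(mixed_helix)
        total = prof.fraction_nonpolar + prof.fraction_polar + prof.fraction_charged
        assert total == pytest.approx(1.0, abs=1e-6)
        assert prof.fraction_charged > 0  # contains Asp/Glu/Lys

    def test_asp_charged_share_is_carboxylate_sasa(self):
        from halosite.synthetic import gen_helix

        model = gen_helix(4, "GDGG")
        areas = sasa(model)
        prof = miller_composition(model, areas)
        carbox = sum(
            float(ar)
            for a, ar in zip(model.atoms, areas)
            if a.name in ("OD1", "OD2")
        )
        assert prof.fraction_charged == pytest.approx(carbox / areas.sum(), abs=1e-9)

    def test_residue_composition_metrics(self, mixed_helix):
        prof = miller_composition(mixed_helix)
        # sequence ADSEKGTMAF: 1 Asp + 1 Glu, 1 Lys, 1 Thr, 1 Phe of 10
        assert prof.frac_asp_glu == pytest.approx(0.2)
        assert prof.frac_lys == pytest.approx(0.1)
        assert prof.frac_thr == pytest.approx(0.1)
        assert prof.frac_phe == pytest.approx(0.1)

    def test_hetero_atoms_rejected(self, planted_k_site):
        model, _ = planted_k_site
        with pytest.raises(ValueError, match="strip"):
            miller_composition(model)

    def test_his_sidechain_n_is_polar(self):
        atom = make_atom(1, "ND1", "N", residue_name="HIS")
        assert classify_miller(atom) == "polar"

    @pytest.mark.parametrize(
        "res,name,expected",
        [
            ("ASP", "OD1", "charged"),
            ("LYS", "NZ", "charged"),
            ("ARG", "NH1", "charged"),
            ("ALA", "OXT", "charged"),
            ("SER", "OG", "polar"),
            ("ALA", "CB", "nonpolar"),
            ("MET", "SD", "nonpolar"),
        ],
    )
    def test_miller_table(self, res, name, expected):
        elem = "S" if name == "SD" else name[0]
        assert classify_miller(make_atom(1, name, elem, residue_name=res)) == expected


class TestCompareProfiles:
    def _profile(self, val):
        import copy

        from halosite.surface import SurfaceProfile

        return SurfaceProfile(
            total_sasa=1000.0,
            per_atom=np.zeros(1),
            fraction_nonpolar=0.5,
            fraction_polar=0.5 - val,
            fraction_charged=val,
            n_residues=100,
            frac_asp_glu=val,
            frac_lys=0.05,
            frac_thr=0.05,
            frac_phe=0.04,
        )

    def test_query_at_mean_is_z_zero(self):
        refs = [self._profile(v) for v in (0.1, 0.2, 0.3)]
        res = compare_profiles(self._profile(0.2), refs)
        assert res["fraction_charged"]["z_score"] == pytest.approx(0.0)

    def test_max_query_ranks_first(self):
        refs = [self._profile(v) for v in (0.1, 0.2, 0.3)]
        res = compare_profiles(self._profile(0.35), refs)
        assert res["frac_asp_glu"]["rank"] == 1

    def test_reference_order_irrelevant(self):
        refs = [self._profile(v) for v in (0.1, 0.2, 0.3, 0.15)]
        a = compare_profiles(self._profile(0.25), refs)
        b = compare_profiles(self._profile(0.25), refs[::-1])
        assert a == b

    def test_too_few_references(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_profiles(self._profile(0.2), [self._profile(0.1)])
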