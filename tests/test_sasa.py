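"""Shrake–Rupley surface areas against closed-form sphere oracles."""

import math

import numpy as np
import pytest

from siakit import (
    AtomSphere,
    PolarClass,
    PolarityRule,
    SasaConfig,
    classify_polarity,
    isolated_sphere_area,
    pair_sphere_areas,
    read_structure,
    sasa_report,
    shrake_rupley,
)
from siakit.sasa import UnknownElementError, assign_polarity, sphere_points


def carbon(x, y, z, r=1.6):
    return AtomSphere(element="C", center=(x, y, z), vdw_radius=r)


class TestSpherePoints:
    def test_unit_vectors_on_sphere(self):
        pts = sphere_points(960)
        assert pts.shape == (960, 3)
        assert np.linalg.norm(pts, axis=1) == pytest.approx(1.0, abs=1e-12)

    def test_lattice_is_deterministic(self):
        assert np.array_equal(sphere_points(960), sphere_points(960))

    def test_near_uniform_coverage(self):
        # centroid of a uniform point set is near the origin
        assert np.linalg.norm(sphere_points(960).mean(axis=0)) < 1e-3


class TestIsolatedSpheres:
    def test_single_sphere_area(self):
        result = shrake_rupley([carbon(0, 0, 0, r=1.6)])
        expected = 4 * math.pi * 3.0**2  # 113.10 A^2
        assert result.total == pytest.approx(expected, rel=0.005)
        assert result.total == pytest.approx(113.10, rel=0.005)

    def test_distant_pair_adds_up(self):
        result = shrake_rupley([carbon(0, 0, 0), carbon(100, 0, 0)])
        assert result.total == pytest.approx(2 * isolated_sphere_area(1.6), rel=0.005)

    def test_per_atom_bounded_by_isolated_sphere(self):
        atoms = [carbon(1.5 * i, 0, 0) for i in range(5)]
        result = shrake_rupley(atoms)
        bound = isolated_sphere_area(1.6)
        assert all(a <= bound + 1e-9 for a in result.per_atom)

    def test_quadrature_error_decreases_with_points(self):
        exact = isolated_sphere_area(1.6)
        errors = [
            abs(shrake_rupley([carbon(0, 0, 0)], SasaConfig(n_quadrature_points=n)).total - exact)
            for n in (60, 240, 960, 3840)
        ]
        assert errors == sorted(errors, reverse=True) or errors[-1] < 1e-9


class TestTwoSphereOracle:
    @pytest.mark.parametrize("distance", [1.0, 2.0, 3.0, 4.5, 5.9])
    def test_matches_spherical_cap_formula(self, distance):
        atoms = [carbon(0, 0, 0), carbon(distance, 0, 0)]
        result = shrake_rupley(atoms, SasaConfig(n_quadrature_points=960))
        expected = sum(pair_sphere_areas(1.6, 1.6, distance))
        assert result.total == pytest.approx(expected, rel=0.005)

    def test_unequal_radii(self):
        atoms = [
            AtomSphere(element="O", center=(0, 0, 0), vdw_radius=1.52),
            AtomSphere(element="C", center=(2.2, 0, 0), vdw_radius=1.70),
        ]
        result = shrake_rupley(atoms, SasaConfig(n_quadrature_points=3840))
        expected = sum(pair_sphere_areas(1.52, 1.70, 2.2))
        assert result.total == pytest.approx(expected, rel=0.005)

    def test_occlusion_monotone_in_distance(self):
        totals = [
            shrake_rupley([carbon(0, 0, 0), carbon(d, 0, 0)]).total
            for d in (1.0, 2.0, 3.0, 4.0, 5.0)
        ]
        assert totals == sorted(totals)


class TestRigidMotionInvariance:
    def test_translation_and_rotation(self):
        atoms = [carbon(0, 0, 0), carbon(1.8, 0.4, -0.3), carbon(3.1, -1.0, 0.8)]
        base = shrake_rupley(atoms)
        # rotate 30 deg about z then translate
        c, s = math.cos(math.pi / 6), math.sin(math.pi / 6)
        moved = [
            AtomSphere(
                element=a.element,
                center=(
                    c * a.center[0] - s * a.center[1] + 10.0,
                    s * a.center[0] + c * a.center[1] - 4.0,
                    a.center[2] + 2.5,
                ),
                vdw_radius=a.vdw_radius,
            )
            for a in atoms
        ]
        assert shrake_rupley(moved).total == pytest.approx(base.total, rel=0.001)


class TestPolarity:
    def test_backbone_oxygen_polar_and_cb_apolar(self):
        o = AtomSphere(element="O", center=(0, 0, 0), vdw_radius=1.52, atom_name="O")
        cb = AtomSphere(element="C", center=(0, 0, 0), vdw_radius=1.70, atom_name="CB")
        assert classify_polarity(o) is PolarClass.POLAR
        assert classify_polarity(cb) is PolarClass.APOLAR

    def test_sulfur_class_follows_rule(self):
        sd = AtomSphere(element="S", center=(0, 0, 0), vdw_radius=1.80, atom_name="SD")
        assert classify_polarity(sd) is PolarClass.POLAR
        assert classify_polarity(sd, PolarityRule(sulfur_polar=False)) is PolarClass.APOLAR

    def test_hydrogen_inherits_from_bonded_heavy_atom(self):
        n = AtomSphere(element="N", center=(0, 0, 0), vdw_radius=1.55)
        h = AtomSphere(element="H", center=(1.0, 0, 0), vdw_radius=1.20)
        assert classify_polarity(h, bonded_heavy=n) is PolarClass.POLAR
        assigned = assign_polarity([n, h])
        assert assigned[1].polar_class is PolarClass.POLAR

    def test_unbonded_hydrogen_rejected(self):
        n = AtomSphere(element="N", center=(0, 0, 0), vdw_radius=1.55)
        h = AtomSphere(element="H", center=(9.0, 0, 0), vdw_radius=1.20)
        with pytest.raises(ValueError, match="inherit"):
            assign_polarity([n, h])

    def test_polar_plus_apolar_equals_total_exactly(self):
        atoms = [
            AtomSphere(element="N", center=(0, 0, 0), vdw_radius=1.55),
            carbon(1.5, 0, 0),
            AtomSphere(element="O", center=(3.0, 0, 0), vdw_radius=1.52),
        ]
        result = shrake_rupley(atoms)
        assert result.total == result.polar + result.apolar
        assert result.total == pytest.approx(sum(result.per_atom), rel=1e-12)


class TestReadStructure:
    def test_single_oxygen(self, single_oxygen_pdb):
        atoms = read_structure(single_oxygen_pdb)
        assert len(atoms) == 1
        assert atoms[0].element == "O"
        assert atoms[0].vdw_radius == 1.52
        assert atoms[0].polar_class is PolarClass.POLAR

    def test_model_selection(self, two_model_pdb):
        first = read_structure(two_model_pdb, model_index=1)
        second = read_structure(two_model_pdb, model_index=2)
        assert first[0].center[0] == pytest.approx(0.0)
        assert second[0].center[0] == pytest.approx(5.0)
        with pytest.raises(ValueError, match="out of range"):
            read_structure(two_model_pdb, model_index=3)

    def test_atom_count_matches_atom_lines(self, tmp_path):
        from siakit import gen_toy_structure

        toy = gen_toy_structure("helix_like", {"n_atoms": 8})
        path = tmp_path / "helix.pdb"
        path.write_text(toy.pdb_text)
        n_lines = sum(1 for line in toy.pdb_text.splitlines() if line.startswith("ATOM"))
        assert len(read_structure(path)) == n_lines == 8

    def test_unknown_element_reported(self, tmp_path):
        path = tmp_path / "odd.pdb"
        path.write_text(
            "ATOM      1 XE1  TOY A   1       0.000   0.000   0.000  1.00  0.00"
            "          XE\nEND\n"
        )
        with pytest.raises(UnknownElementError, match="XE"):
            read_structure(path)


class TestSasaReport:
    def test_rows_match_structures_and_invariant(self, tmp_path):
        from siakit import gen_toy_structure

        paths = {}
        for kind in ("pair", "linear_chain"):
            toy = gen_toy_structure(kind)
            p = tmp_path / f"{kind}.pdb"
            p.write_text(toy.pdb_text)
            paths[kind] = p
        records = sasa_report(paths)
        assert [r.mutant_id for r in records] == ["pair", "linear_chain"]
        for r in records:
            assert r.total == pytest.approx(r.apolar + r.polar, abs=1e-9)

    def test_quadrature_convergence_within_one_percent(self, tmp_path):
        from siakit import gen_toy_structure

        toy = gen_toy_structure("linear_chain", {"n_atoms": 5, "spacing": 1.5})
        p = tmp_path / "chain.pdb"
        p.write_text(toy.pdb_text)
        coarse = sasa_report({"c": p}, SasaConfig(n_quadrature_points=960))[0]
        fine = sasa_report({"c": p}, SasaConfig(n_quadrature_points=3840))[0]
        assert coarse.total == pytest.approx(fine.total, rel=0.01)
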