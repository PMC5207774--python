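"""SASA, buried area, shape complementarity, H-bonds, solvation energy."""

import math

import numpy as np
import pytest

from crossbeta.geometry import ZipperAssembly
from crossbeta.interface import (DRY_THRESHOLD, RadiusTable, SolvationParams,
                                 atom_solvation_class, buried_area,
                                 classify_zipper, compute_interface_metrics,
                                 fibonacci_sphere, hydrogen_bonds, sasa,
                                 shape_complementarity, solvation_energy)
from crossbeta.model_io import AtomSite
from crossbeta.synthetic import (SheetSpec, ZipperSpec, build_sheet,
                                 build_zipper)

from conftest import SEQ_15_25_WT, SEQ_19_29_S20G, SYNTH_RADII, carbon


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        result = sasa([carbon(1, 0, 0, 0)], n_points=960)
        exact = 4 * math.pi * (1.70 + 1.40) ** 2
        assert result.total == pytest.approx(exact, rel=0.005)

    def test_distant_atoms_additive(self):
        atoms = [carbon(1, 0, 0, 0), carbon(2, 50, 0, 0)]
        iso = sasa([atoms[0]], n_points=480).total
        assert sasa(atoms, n_points=480).total == pytest.approx(2 * iso,
                                                                rel=1e-9)

    def test_density_doubling_converged(self, class1_zipper):
        """Doubling the default sampling density moves the total < 0.5%."""
        atoms = class1_zipper.sheet_a.strands[0]
        t1 = sasa(atoms, SYNTH_RADII, n_points=960).total
        t2 = sasa(atoms, SYNTH_RADII, n_points=1920).total
        assert abs(t2 - t1) / t1 < 0.005

    def test_total_equals_per_atom_sum(self, flat_parallel_sheet):
        res = sasa(flat_parallel_sheet.atoms, n_points=240)
        assert res.total == pytest.approx(res.per_atom.sum(), abs=1e-6)

    def test_waters_excluded_by_default(self):
        atoms = [carbon(1, 0, 0, 0),
                 AtomSite(2, "O", "O", "HOH", 101, "W",
                          np.array([2.0, 0, 0]), is_water=True)]
        excl = sasa(atoms, n_points=480)
        assert excl.per_atom[1] == 0.0
        incl = sasa(atoms, n_points=480, include_waters=True)
        assert incl.per_atom[1] > 0.0
        assert incl.per_atom[0] < excl.per_atom[0]  # water now occludes

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="64"):
            sasa([carbon(1, 0, 0, 0)], n_points=32)

    def test_unknown_element_named_in_error(self):
        bad = AtomSite(1, "XX", "ZZ", "UNK", 1, "A", np.zeros(3))
        bad.element = "ZZ"
        with pytest.raises(Exception, match="ZZ"):
            sasa([bad], n_points=128)


class TestBuriedArea:
    def test_symmetry_under_sheet_swap(self, class1_zipper):
        a, b = class1_zipper.sheet_a, class1_zipper.sheet_b
        ab = buried_area(a, b, SYNTH_RADII, n_points=240)
        ba = buried_area(b, a, SYNTH_RADII, n_points=240)
        assert ab == pytest.approx(ba, rel=1e-9)

    def test_per_residue_normalization(self, class1_zipper):
        per_strand, per_res = buried_area(class1_zipper.sheet_a,
                                          class1_zipper.sheet_b,
                                          SYNTH_RADII, n_points=240)
        assert per_res == pytest.approx(per_strand / 11, rel=1e-9)

    def test_clashing_sheets_rejected(self):
        sheet = build_sheet(SheetSpec(SEQ_19_29_S20G, n_strands=3))
        with pytest.raises(ValueError, match="clash"):
            buried_area(sheet, sheet)


class TestShapeComplementarity:
    @staticmethod
    def shell(radius, chain, spacing=0.7):
        n = max(12, int(4 * math.pi * radius ** 2 / spacing ** 2))
        return [AtomSite(k + 1, "C", "C", "ALA", 1, chain, radius * p)
                for k, p in enumerate(fibonacci_sphere(n))]

    def test_conforming_surfaces_score_high(self):
        """Closed complementary surfaces in exact van der Waals contact
        (concentric shells) approach the ideal score of 1."""
        inner = self.shell(4.0, "A")
        outer = self.shell(4.0 + 2 * 1.70, "B")
        assert shape_complementarity(inner, outer, n_points=240) > 0.95

    def test_rigid_motion_near_invariance(self, class1_zipper):
        base = shape_complementarity(class1_zipper.sheet_a,
                                     class1_zipper.sheet_b,
                                     radii=SYNTH_RADII, n_points=160)
        rng = np.random.default_rng(5)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = np.array([5.0, -3.0, 12.0])

        def move(sheet):
            from crossbeta.geometry import SheetAssembly
            return SheetAssembly(
                strands=[[AtomSite(a.serial, a.name, a.element, a.residue_name,
                                   a.residue_number, a.chain_id,
                                   q @ a.position + shift) for a in s]
                         for s in sheet.strands],
                fiber_axis=q @ sheet.fiber_axis)

        moved = shape_complementarity(move(class1_zipper.sheet_a),
                                      move(class1_zipper.sheet_b),
                                      radii=SYNTH_RADII, n_points=160)
        assert moved == pytest.approx(base, abs=0.05)

    def test_no_contact_rejected(self):
        a = [carbon(1, 0, 0, 0)]
        b = [carbon(2, 30, 0, 0, chain="B")]
        with pytest.raises(ValueError, match="no contact"):
            shape_complementarity(a, b)


def brute_force_hbonds(group_a, group_b, d_max=3.5, angle_min=90.0):
    """Plain O(n²) re-enumeration of the heavy-atom criterion."""
    from crossbeta.interface import HYDROXYL_O, _angle

    def cov_neighbors(atoms, i):
        out = []
        for j, other in enumerate(atoms):
            if j == i:
                continue
            d = np.linalg.norm(atoms[i].position - other.position)
            same_res = (other.chain_id == atoms[i].chain_id and
                        other.residue_number == atoms[i].residue_number)
            pept = (other.chain_id == atoms[i].chain_id and
                    {other.name, atoms[i].name} == {"C", "N"} and
                    abs(other.residue_number - atoms[i].residue_number) == 1)
            if d < 1.8 and (same_res or pept):
                out.append(j)
        return out

    found = set()
    for atoms_x, atoms_y in ((group_a, group_b), (group_b, group_a)):
        for i, don in enumerate(atoms_x):
            is_donor = don.element == "N" or (don.element == "O"
                                              and don.name in HYDROXYL_O)
            if not is_donor:
                continue
            for acc in atoms_y:
                if acc.element not in {"N", "O"}:
                    continue
                d = np.linalg.norm(acc.position - don.position)
                if d > d_max:
                    continue
                angles = [_angle(atoms_x[j].position, don.position,
                                 acc.position) for j in cov_neighbors(atoms_x, i)]
                if not angles or min(angles) >= angle_min:
                    found.add(frozenset((id(don), id(acc))))
    return found


class TestHydrogenBonds:
    @pytest.mark.parametrize("orientation,shift", [("parallel", 0),
                                                   ("antiparallel", 0),
                                                   ("antiparallel", 2)])
    def test_matches_brute_force_enumeration(self, orientation, shift):
        sheet = build_sheet(SheetSpec(SEQ_15_25_WT, n_strands=4,
                                      orientation=orientation,
                                      registry_shift=shift,
                                      pleat_out_of_plane=True))
        for i in range(3):
            got = hydrogen_bonds(sheet.strands[i], sheet.strands[i + 1])
            want = brute_force_hbonds(sheet.strands[i], sheet.strands[i + 1])
            assert len(got) == len(want)

    def test_ladder_is_backbone_only(self):
        sheet = build_sheet(SheetSpec(SEQ_19_29_S20G, n_strands=2,
                                      pleat_out_of_plane=True))
        bonds = hydrogen_bonds(sheet.strands[0], sheet.strands[1])
        assert len(bonds) > 0
        assert all(b.type == "backbone-backbone" for b in bonds)
        assert all(b.distance <= 3.5 for b in bonds)
        assert all(b.angle >= 90.0 for b in bonds)

    def test_distant_groups_have_none(self):
        a = build_sheet(SheetSpec("SGNN", n_strands=1)).strands[0]
        b = [AtomSite(x.serial, x.name, x.element, x.residue_name,
                      x.residue_number, "B", x.position + np.array([50.0, 0, 0]))
             for x in a]
        assert hydrogen_bonds(a, b) == []

    def test_overlapping_groups_rejected(self):
        strand = build_sheet(SheetSpec("SGNN", n_strands=1)).strands[0]
        with pytest.raises(ValueError, match="disjoint"):
            hydrogen_bonds(strand, strand)

    def test_each_bond_listed_once(self):
        sheet = build_sheet(SheetSpec(SEQ_19_29_S20G, n_strands=2,
                                      pleat_out_of_plane=True))
        bonds = hydrogen_bonds(sheet.strands[0], sheet.strands[1])
        keys = {(b.donor, b.acceptor) for b in bonds}
        assert len(keys) == len(bonds)


class TestSolvationEnergy:
    def test_single_strand_reference_is_zero(self):
        sheet = build_sheet(SheetSpec(SEQ_19_29_S20G, n_strands=1))
        assert solvation_energy(sheet, n_points=240) == pytest.approx(0.0,
                                                                      abs=1e-9)

    def test_carbon_burial_closed_form(self):
        """Two overlapping carbon spheres: the buried cap area is analytic,
        2πR(R − d/2) per sphere, so ΔG = σ_C · ΔASA exactly."""
        from crossbeta.geometry import SheetAssembly
        d = 2.0
        sheet = SheetAssembly(
            strands=[[carbon(1, 0, 0, 0)], [carbon(2, d, 0, 0, chain="B")]],
            fiber_axis=np.array([1.0, 0, 0]))
        got = solvation_energy(sheet, n_points=2000)
        r_acc = 1.70 + 1.40
        delta_asa = 2 * math.pi * r_acc * (r_acc - d / 2)
        assert got == pytest.approx(16.0 * delta_asa, rel=0.01)

    def test_atom_classes(self):
        mk = lambda name, el, res: AtomSite(1, name, el, res, 1, "A",
                                            np.zeros(3))
        assert atom_solvation_class(mk("CB", "C", "ALA")) == "C"
        assert atom_solvation_class(mk("OD1", "O", "ASP")) == "O-"
        assert atom_solvation_class(mk("OD1", "O", "ASN")) == "N/O"
        assert atom_solvation_class(mk("NZ", "N", "LYS")) == "N+"
        assert atom_solvation_class(mk("SG", "S", "CYS")) == "S"
        assert atom_solvation_class(mk("N", "N", "GLY")) == "N/O"

    def test_sign_convention(self):
        params = SolvationParams()
        assert params.sigma["C"] > 0  # burying apolar area is favorable


class TestClassificationGate:
    def test_loose_contact_is_not_a_zipper(self):
        zipper = build_zipper(ZipperSpec(
            sheet_a=SheetSpec(SEQ_19_29_S20G, n_strands=5),
            zipper_class=1, intersheet_distance=13.0))
        assert classify_zipper(zipper, SYNTH_RADII, n_points=240) is None

    def test_dry_flag_follows_threshold(self, class1_zipper):
        metrics = compute_interface_metrics(class1_zipper, SYNTH_RADII,
                                            n_points=240)
        assert metrics.dry == (metrics.buried_per_residue >= DRY_THRESHOLD)
        assert metrics.zipper_class == 1
        assert -1.0 <= metrics.sc <= 1.0
        assert metrics.buried_per_residue == pytest.approx(
            metrics.buried_per_strand / 11, rel=1e-6)
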