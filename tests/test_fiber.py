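"""Structure factors, fiber-pattern synthesis, and radial-profile analysis."""

import cmath
import math

import gemmi
import numpy as np
import pytest

from crossbeta.fiber import (DetectorGeometry, FiberPattern2D, Profile1D,
                             d_spacing_from_radius, extract_profile,
                             find_peaks, radial_profile,
                             simulate_fiber_pattern, structure_factors)
from crossbeta.model_io import AtomSite, CrystalModel, UnitCell
from crossbeta.synthetic import RingImageSpec, SheetSpec, build_sheet, \
    render_ring_image

from conftest import SEQ_19_29_S20G, carbon


def direct_sum_intensity(cell, atoms, hkl, b_default=15.0):
    """Scalar brute-force structure-factor oracle."""
    rec = np.linalg.inv(cell.orthogonalization_matrix)
    s = np.array(hkl) @ rec
    stol2 = (np.linalg.norm(s) / 2.0) ** 2
    F = 0j
    for a in atoms:
        f = gemmi.Element(a.element.capitalize()).it92.calculate_sf(stol2)
        B = a.b_factor if a.b_factor > 0 else b_default
        xf = cell.to_fractional(a.position)
        F += (f * a.occupancy * math.exp(-B * stol2)
              * cmath.exp(2j * math.pi * float(np.dot(hkl, xf))))
    return abs(F) ** 2


class TestStructureFactors:
    CELL = UnitCell(8.0, 9.5, 11.0, 75.0, 95.0, 102.0)

    def _toy_model(self):
        atoms = [AtomSite(1, "CA", "C", "ALA", 1, "A",
                          np.array([1.0, 2.0, 3.0]), 1.0, 12.0),
                 AtomSite(2, "N", "N", "ALA", 1, "A",
                          np.array([2.5, 0.5, 4.0]), 0.8, 20.0),
                 AtomSite(3, "O", "O", "ALA", 1, "A",
                          np.array([0.3, 4.2, 1.1]), 1.0, 0.0)]
        return CrystalModel(atoms=atoms, cell=self.CELL)

    def test_direct_summation_oracle(self):
        model = self._toy_model()
        peaks = structure_factors(model, d_min=2.5)
        imax = max(p.intensity for p in peaks)
        for p in peaks:
            want = direct_sum_intensity(self.CELL, model.atoms, p.hkl)
            assert abs(p.intensity - want) <= 1e-6 * want + 1e-9 * imax

    def test_single_atom_no_interference(self):
        model = CrystalModel(atoms=[carbon(1, 0, 0, 0)],
                             cell=UnitCell(10, 10, 10))
        by_d = {}
        for p in structure_factors(model, d_min=3.0):
            by_d.setdefault(round(p.d, 9), set()).add(round(p.intensity, 9))
        assert all(len(v) == 1 for v in by_d.values())

    def test_half_cell_translation_extinction(self):
        atoms = [carbon(1, 0, 0, 0), carbon(2, 0, 0, 5.0, resnum=2)]
        model = CrystalModel(atoms=atoms, cell=UnitCell(10, 10, 10))
        inten = {p.hkl: p.intensity for p in structure_factors(model, d_min=3.0)}
        assert inten[(0, 0, 1)] < 1e-12 * inten[(0, 0, 2)]

    def test_symmetry_expansion_included(self):
        """A symmetric two-op model equals the explicit two-atom cell."""
        from crossbeta.model_io import SymmetryOp
        op2 = SymmetryOp(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.5))
        model = CrystalModel(atoms=[carbon(1, 0, 0, 0)],
                             cell=UnitCell(10, 10, 10),
                             ops=[SymmetryOp.identity(), op2])
        explicit = CrystalModel(
            atoms=[carbon(1, 0, 0, 0), carbon(2, 0, 0, 5.0, resnum=2)],
            cell=UnitCell(10, 10, 10))
        got = {p.hkl: p.intensity for p in structure_factors(model, d_min=4.0)}
        want = {p.hkl: p.intensity for p in structure_factors(explicit,
                                                              d_min=4.0)}
        for hkl in want:
            assert got[hkl] == pytest.approx(want[hkl], abs=1e-8)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            structure_factors(CrystalModel(atoms=[], cell=self.CELL), 2.0)

    def test_too_small_d_min_rejected(self):
        with pytest.raises(ValueError, match="0.8"):
            structure_factors(self._toy_model(), d_min=0.5)


@pytest.fixture(scope="module")
def rise47_pattern():
    sheet = build_sheet(SheetSpec(SEQ_19_29_S20G, n_strands=21,
                                  orientation="parallel", rise=4.7))
    return simulate_fiber_pattern(sheet, d_min=2.0)


class TestFiberPattern:
    def test_meridional_orders_at_rise(self, rise47_pattern):
        peaks = find_peaks(extract_profile(rise47_pattern, "meridional"),
                           prominence=1e-3)
        ds = [d for d, _ in peaks]
        assert any(abs(d - 4.7) / 4.7 < 0.01 for d in ds)
        assert any(abs(d - 2.35) / 2.35 < 0.01 for d in ds)

    def test_strongest_meridional_is_first_order(self, rise47_pattern):
        peaks = find_peaks(extract_profile(rise47_pattern, "meridional"),
                           prominence=1e-3)
        assert peaks[0][0] == pytest.approx(4.7, abs=0.05)

    def test_mirror_symmetry_in_z(self, rise47_pattern):
        img = rise47_pattern.intensity
        assert np.allclose(img, img[::-1, :], atol=1e-12)

    def test_nonnegative_normalized(self, rise47_pattern):
        assert rise47_pattern.intensity.min() >= 0.0
        assert rise47_pattern.intensity.max() == pytest.approx(1.0)

    def test_peak_positions_stable_under_smearing(self):
        sheet = build_sheet(SheetSpec("SGNNFG", n_strands=9,
                                      orientation="parallel", rise=4.7))
        tops = []
        for smear in (0.004, 0.005, 0.006):
            pattern = simulate_fiber_pattern(sheet, d_min=2.0, smearing=smear)
            peaks = find_peaks(extract_profile(pattern, "meridional"),
                               prominence=1e-3)
            tops.append(peaks[0][0])
        assert max(tops) - min(tops) < 0.05


class TestProfiles:
    def _single_peak_pattern(self):
        r = np.linspace(0, 0.5, 101)
        z = np.linspace(-0.5, 0.5, 201)
        img = np.zeros((201, 101))
        zz = z[:, None]
        rr = r[None, :]
        for zsign in (1, -1):
            img += np.exp(-((rr - 0.0) ** 2 + (zz - zsign / 4.7) ** 2)
                          / (2 * 0.004 ** 2))
        return FiberPattern2D(r, z, img / img.max(), 0.004)

    def test_meridional_peak_leaves_equator_flat(self):
        pattern = self._single_peak_pattern()
        eq = extract_profile(pattern, "equatorial", band_width=0.02)
        sel = eq.d < 20.0  # away from the low-angle tail of the peak
        assert eq.intensity[sel].max() < 0.01

    def test_radial_profile_of_two_rings(self):
        r = np.linspace(0, 0.5, 201)
        z = np.linspace(-0.5, 0.5, 401)
        rr, zz = np.meshgrid(r, z)
        smag = np.hypot(rr, zz)
        img = (np.exp(-(smag - 1 / 4.6) ** 2 / (2 * 0.004 ** 2))
               + 0.5 * np.exp(-(smag - 1 / 9.0) ** 2 / (2 * 0.004 ** 2)))
        pattern = FiberPattern2D(r, z, img / img.max(), 0.004)
        peaks = find_peaks(extract_profile(pattern, "radial"), prominence=0.05)
        assert len(peaks) == 2
        assert peaks[0][0] == pytest.approx(4.6, abs=0.1)
        assert peaks[1][0] == pytest.approx(9.0, abs=0.3)

    def test_band_outside_grid_rejected(self):
        pattern = self._single_peak_pattern()
        with pytest.raises(ValueError):
            extract_profile(pattern, "meridional", band_width=-1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            extract_profile(self._single_peak_pattern(), "diagonal")


class TestFindPeaks:
    def test_single_gaussian(self):
        s = np.linspace(0.05, 0.5, 400)
        prof = Profile1D(1 / s, np.exp(-(s - 1 / 4.6) ** 2 / (2 * 0.005 ** 2)))
        peaks = find_peaks(prof, prominence=0.1)
        assert len(peaks) == 1
        assert peaks[0][0] == pytest.approx(4.6, abs=0.05)

    def test_monotone_profile_has_no_peaks(self):
        s = np.linspace(0.05, 0.5, 200)
        assert find_peaks(Profile1D(1 / s, np.exp(-5 * s))) == []

    def test_overlapping_gaussians_both_reported(self):
        s = np.linspace(0.08, 0.2, 800)
        prof = (np.exp(-(s - 1 / 8.4) ** 2 / (2 * 0.003 ** 2))
                + np.exp(-(s - 1 / 9.0) ** 2 / (2 * 0.003 ** 2)))
        peaks = find_peaks(Profile1D(1 / s, prof), prominence=0.05)
        ds = sorted(d for d, _ in peaks)
        assert len(ds) == 2
        assert ds[0] == pytest.approx(8.4, abs=0.1)
        assert ds[1] == pytest.approx(9.0, abs=0.1)

    def test_empty_profile(self):
        assert find_peaks(Profile1D(np.array([]), np.array([]))) == []

    def test_d_range_filter(self):
        s = np.linspace(0.05, 0.5, 400)
        prof = Profile1D(1 / s, np.exp(-(s - 1 / 4.6) ** 2 / (2 * 0.005 ** 2)))
        assert find_peaks(prof, prominence=0.1, d_range=(8.0, 12.0)) == []


class TestRadialProfile:
    GEO = DetectorGeometry(distance=50.0, pixel_size=0.2,
                           beam_center=(127.5, 127.5))

    def test_uniform_image_flat(self):
        img = np.full((64, 64), 3.25)
        geo = DetectorGeometry(beam_center=(31.5, 31.5))
        prof = radial_profile(img, geo)
        ok = np.isfinite(prof.mean_intensity)
        assert np.allclose(prof.mean_intensity[ok], 3.25)

    def test_ring_recovered_at_rendered_d(self):
        spec = RingImageSpec((4.6,), (1.0,), 256, self.GEO, ring_width=2.0,
                             noise_sd=0.02, seed=9)
        prof = radial_profile(render_ring_image(spec), self.GEO)
        peaks = find_peaks(prof.profile(), prominence=0.2)
        assert peaks[0][0] == pytest.approx(4.6, abs=0.05)

    def test_off_center_beam_consistent(self):
        geo2 = DetectorGeometry(distance=50.0, pixel_size=0.2,
                                beam_center=(100.0, 140.0))
        spec = RingImageSpec((4.6,), (1.0,), 256, geo2, ring_width=2.0,
                             noise_sd=0.0, seed=0)
        prof = radial_profile(render_ring_image(spec), geo2)
        peaks = find_peaks(prof.profile(), prominence=0.2)
        assert peaks[0][0] == pytest.approx(4.6, abs=0.05)

    def test_intensity_conserved(self):
        rng = np.random.default_rng(2)
        img = rng.random((64, 64))
        geo = DetectorGeometry(beam_center=(31.5, 31.5))
        prof = radial_profile(img, geo)
        ok = prof.n_pixels > 0
        total = float((prof.mean_intensity[ok] * prof.n_pixels[ok]).sum())
        assert total == pytest.approx(float(img.sum()), rel=1e-9)

    def test_beam_center_outside_rejected(self):
        with pytest.raises(ValueError, match="beam_center"):
            radial_profile(np.zeros((8, 8)),
                           DetectorGeometry(beam_center=(100, 100)))

    def test_d_monotone_decreasing(self):
        img = np.ones((32, 32))
        prof = radial_profile(img, DetectorGeometry(beam_center=(15.5, 15.5)))
        finite = prof.d[np.isfinite(prof.d)]
        assert np.all(np.diff(finite) < 0)


class TestDSpacing:
    GEO = DetectorGeometry()

    def test_round_trip(self):
        d0 = 4.7
        r = (self.GEO.distance
             * math.tan(2 * math.asin(self.GEO.wavelength / (2 * d0)))
             / self.GEO.pixel_size)
        assert d_spacing_from_radius(r, self.GEO) == pytest.approx(d0,
                                                                   abs=1e-6)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            d_spacing_from_radius(0.0, self.GEO)

    def test_monotone_in_radius_and_distance(self):
        d1 = d_spacing_from_radius(50, self.GEO)
        d2 = d_spacing_from_radius(100, self.GEO)
        assert d2 < d1
        far = DetectorGeometry(distance=2 * self.GEO.distance)
        assert d_spacing_from_radius(50, far) > d1
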