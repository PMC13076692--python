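"""Segmentation, time-activity fitting, TIA, S-value convolution, comparison."""

import numpy as np
import pytest

from spectpvc.core import Image3D, Units, rasterize_sphere
from spectpvc.dosimetry import (
    FLAG_EXCLUDED,
    FLAG_FALLBACK_PHYSICAL,
    FLAG_OK,
    LU177_LAMBDA_PHYS,
    LU177_MEAN_BETA_MEV,
    DoseKernel,
    SegmentationError,
    compare_doses,
    convolve_dose,
    default_lu177_kernel,
    fit_tac,
    integrate_tia,
    load_kernel_csv,
    measure_tbr,
    save_kernel_csv,
    segment_lesion,
)
from spectpvc.recovery import RCCurve


def _sphere_image(radius=12.0, inside=180.0, outside=20.0, shape=(32, 32, 32)):
    grid = Image3D(np.zeros(shape), (4.8,) * 3, Units.KBQ_PER_ML)
    center = tuple(n * 4.8 / 2 for n in shape)
    voi = rasterize_sphere(center, radius, grid, supersampling=4)
    img = grid.with_values(
        np.where(voi.mask, inside, outside).astype(float)
    )
    return img, voi, center


class TestSegmentLesion:
    def test_recovers_sphere_volume_on_sharp_image(self):
        img, voi, center = _sphere_image()
        seg = segment_lesion(img, center, threshold=0.5)
        # within one voxel shell of the rasterized truth
        shell = 4.0 * np.pi * 12.0**2 * 4.8 / 1000.0
        assert abs(seg.volume_mL - voi.volume_mL(img)) <= shell

    def test_fraction_above_one_rejected(self):
        img, _, center = _sphere_image()
        with pytest.raises(SegmentationError):
            segment_lesion(img, center, threshold=1.01)

    def test_absolute_threshold_mode(self):
        img, voi, center = _sphere_image()
        seg = segment_lesion(img, center, method="absolute-threshold",
                             threshold=100.0)
        assert seg.n_voxels == voi.n_voxels

    def test_absolute_threshold_above_max_rejected(self):
        img, _, center = _sphere_image()
        with pytest.raises(SegmentationError):
            segment_lesion(img, center, method="absolute-threshold",
                           threshold=500.0)

    def test_mask_is_connected_component_containing_seed(self):
        img, voi, center = _sphere_image()
        # add a second bright blob away from the seed; it must not be included
        vals = img.values.copy()
        vals[2:5, 2:5, 2:5] = 200.0
        seg = segment_lesion(img.with_values(vals), center, threshold=0.5)
        assert not seg.mask[2:5, 2:5, 2:5].any()


class TestMeasureTBR:
    def test_unit_ratio_for_flat_image(self):
        img, voi, center = _sphere_image(inside=50.0, outside=50.0)
        from spectpvc.dosimetry import LesionSeg

        seg = LesionSeg(voi.mask, voi.volume_mL(img), "fixed", 0.0)
        assert measure_tbr(img, seg) == pytest.approx(1.0)

    def test_recovers_configured_tbr_on_sharp_image(self):
        img, voi, center = _sphere_image(radius=10.0, inside=9.2 * 25.0,
                                         outside=25.0, shape=(40, 40, 40))
        from spectpvc.dosimetry import LesionSeg

        seg = LesionSeg(voi.mask, voi.volume_mL(img), "fixed", 0.0)
        assert measure_tbr(img, seg) == pytest.approx(9.2, rel=1e-6)

    def test_scale_invariance(self):
        img, voi, center = _sphere_image(radius=10.0, shape=(40, 40, 40))
        from spectpvc.dosimetry import LesionSeg

        seg = LesionSeg(voi.mask, voi.volume_mL(img), "fixed", 0.0)
        t1 = measure_tbr(img, seg)
        t2 = measure_tbr(img.with_values(img.values * 3.7), seg)
        assert t2 == pytest.approx(t1, rel=1e-12)

    def test_placement_failure_near_boundary(self):
        # lesion so large that four adjacent equal-volume VOIs cannot fit
        img, voi, center = _sphere_image(radius=30.0, shape=(16, 16, 16))
        from spectpvc.dosimetry import LesionSeg

        seg = LesionSeg(voi.mask, voi.volume_mL(img), "fixed", 0.0)
        with pytest.raises(SegmentationError):
            measure_tbr(img, seg)


class TestFitTAC:
    def test_exact_halving_series(self):
        series = np.array([100.0, 50.0, 25.0]).reshape(3, 1, 1, 1)
        fit = fit_tac(series, (24.0, 48.0, 72.0))
        assert fit.lam[0, 0, 0] == pytest.approx(np.log(2) / 24.0, rel=1e-12)
        assert fit.A0[0, 0, 0] == pytest.approx(200.0, rel=1e-12)
        assert fit.flags[0, 0, 0] == FLAG_OK

    def test_constant_series_floored_to_physical_decay(self):
        series = np.full((3, 1, 1, 1), 80.0)
        fit = fit_tac(series, (24.0, 48.0, 72.0))
        assert fit.lam[0, 0, 0] == LU177_LAMBDA_PHYS
        assert fit.flags[0, 0, 0] == FLAG_FALLBACK_PHYSICAL
        # floor-constrained refit: log A0 = mean(log a + lambda t)
        expected = np.exp(
            np.mean(np.log(80.0) + LU177_LAMBDA_PHYS * np.array([24.0, 48.0, 72.0]))
        )
        assert fit.A0[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_voxel_with_single_positive_sample_excluded(self):
        series = np.array([5.0, 0.0, 0.0]).reshape(3, 1, 1, 1)
        fit = fit_tac(series, (24.0, 48.0, 72.0))
        assert fit.flags[0, 0, 0] == FLAG_EXCLUDED
        tia = integrate_tia(fit, (4.8, 4.8, 4.8))
        assert tia.values[0, 0, 0] == 0.0

    def test_partial_samples_use_floored_decay(self):
        series = np.array([100.0, 50.0, 0.0]).reshape(3, 1, 1, 1)
        fit = fit_tac(series, (24.0, 48.0, 72.0))
        assert fit.flags[0, 0, 0] == FLAG_FALLBACK_PHYSICAL
        assert fit.lam[0, 0, 0] == LU177_LAMBDA_PHYS

    def test_noisy_decay_recovered_within_five_percent(self, rng):
        # simulation oracle: 5 % multiplicative noise, 100 voxels
        times = np.array([24.0, 48.0, 72.0])
        lam_true = np.log(2) / 40.0
        clean = 150.0 * np.exp(-lam_true * times)
        series = (
            clean[:, None] * rng.lognormal(0.0, 0.05, size=(3, 100))
        ).reshape(3, 100, 1, 1)
        fit = fit_tac(series, times)
        median_lam = np.median(fit.lam[fit.flags == FLAG_OK])
        assert median_lam == pytest.approx(lam_true, rel=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_tac(np.ones((3, 2, 2, 2)), (24.0, 24.0, 72.0))
        with pytest.raises(ValueError):
            fit_tac(np.ones((2, 2, 2)), (24.0, 48.0))


class TestIntegrateTIA:
    def test_closed_form_integral(self):
        # A0 / lambda: 200 kBq/mL over a 1 mL voxel at lambda = ln2/24
        lam = np.log(2) / 24.0
        fit = fit_tac(
            (200.0 * np.exp(-lam * np.array([24.0, 48, 72.0]))).reshape(3, 1, 1, 1),
            (24.0, 48.0, 72.0),
        )
        tia = integrate_tia(fit, (10.0, 10.0, 10.0))  # 1 mL voxel
        assert tia.values[0, 0, 0] == pytest.approx(200.0e3 / lam, rel=1e-9)
        assert tia.units == Units.BQ_H_PER_VOXEL

    def test_linearity_in_amplitude_and_decay(self):
        times = (24.0, 48.0, 72.0)
        lam = np.log(2) / 30.0

        def tia_of(a0, l):
            series = (a0 * np.exp(-l * np.asarray(times))).reshape(3, 1, 1, 1)
            return integrate_tia(fit_tac(series, times), (4.8,) * 3).values[0, 0, 0]

        base = tia_of(100.0, lam)
        assert tia_of(200.0, lam) == pytest.approx(2.0 * base, rel=1e-9)
        assert tia_of(100.0, 2 * lam) == pytest.approx(base / 2.0, rel=1e-9)


class TestDoseKernel:
    def test_local_deposition_scales_with_voxel_mass(self):
        k1 = default_lu177_kernel((4.8, 4.8, 4.8))
        k2 = default_lu177_kernel((4.8, 4.8, 2.4))  # half the volume
        assert k2.central == pytest.approx(2.0 * k1.central, rel=1e-12)

    def test_central_element_dimensional_analysis(self):
        # hand unit chain: E[J/decay] * 3600[decay/(Bq h)] / m_voxel[kg]
        spacing = (4.8, 4.8, 4.8)
        kernel = default_lu177_kernel(spacing)
        e_joule = LU177_MEAN_BETA_MEV * 1.602176634e-13
        mass_kg = (4.8**3 / 1000.0) * 1e-3
        assert kernel.central == pytest.approx(e_joule * 3600.0 / mass_kg, rel=1e-12)

    def test_csv_roundtrip_bit_exact(self, tmp_path, rng):
        values = rng.random((3, 3, 3))
        values = (values + values[::-1, ::-1, ::-1]) / 2  # symmetrize
        kernel = DoseKernel(values, (4.8, 4.8, 4.8), provenance="test")
        path = tmp_path / "kernel.csv"
        save_kernel_csv(kernel, path)
        back = load_kernel_csv(path)
        assert np.array_equal(back.values, kernel.values)
        assert back.spacing_mm == kernel.spacing_mm

    def test_invalid_kernels_rejected(self):
        with pytest.raises(ValueError):
            DoseKernel(np.ones((2, 2, 2)), (4.8,) * 3)  # even support
        asym = np.zeros((3, 3, 3))
        asym[1, 1, 1] = 1.0
        asym[0, 1, 1] = 0.5
        with pytest.raises(ValueError):
            DoseKernel(asym, (4.8,) * 3)


class TestConvolveDose:
    def _tia(self, values, spacing=(4.8, 4.8, 4.8)):
        return Image3D(values, spacing, Units.BQ_H_PER_VOXEL)

    def test_matches_direct_sum_oracle(self, rng):
        tia = self._tia(rng.random((16, 16, 16)))
        values = rng.random((3, 3, 3))
        values = (values + values[::-1, ::-1, ::-1]) / 2
        kernel = DoseKernel(values, tia.spacing_mm)
        dose = convolve_dose(tia, kernel)

        expected = np.zeros(tia.shape)
        n = 16
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    acc = 0.0
                    for a in range(3):
                        for b in range(3):
                            for c in range(3):
                                ii, jj, kk = i + a - 1, j + b - 1, k + c - 1
                                if 0 <= ii < n and 0 <= jj < n and 0 <= kk < n:
                                    acc += tia.values[ii, jj, kk] * values[
                                        2 - a, 2 - b, 2 - c
                                    ]
                    expected[i, j, k] = acc
        assert np.allclose(dose.values, expected, atol=1e-10 * expected.max())

    def test_single_voxel_source_and_kernel(self):
        tia_vals = np.zeros((8, 8, 8))
        tia_vals[4, 4, 4] = 123.0
        kernel = DoseKernel(np.full((1, 1, 1), 2.5e-7), (4.8,) * 3)
        dose = convolve_dose(self._tia(tia_vals), kernel)
        assert dose.values[4, 4, 4] == pytest.approx(123.0 * 2.5e-7, rel=1e-12)
        assert np.count_nonzero(dose.values) == 1

    def test_uniform_tia_gives_uniform_interior_dose(self):
        tia = self._tia(np.full((12, 12, 12), 5.0))
        values = np.zeros((3, 3, 3))
        values[1, 1, 1] = 0.6
        values[0, 1, 1] = values[2, 1, 1] = 0.2
        kernel = DoseKernel(values, tia.spacing_mm)
        dose = convolve_dose(tia, kernel)
        assert np.allclose(dose.values[1:-1, 1:-1, 1:-1], 5.0, rtol=1e-9)

    def test_linearity(self, rng):
        t1 = self._tia(rng.random((10, 10, 10)))
        t2 = self._tia(rng.random((10, 10, 10)))
        kernel = default_lu177_kernel(t1.spacing_mm)
        combo = self._tia(2.0 * t1.values + 3.0 * t2.values)
        lhs = convolve_dose(combo, kernel).values
        rhs = 2.0 * convolve_dose(t1, kernel).values + 3.0 * convolve_dose(
            t2, kernel
        ).values
        assert np.allclose(lhs, rhs, rtol=1e-9)

    def test_spacing_mismatch_rejected(self):
        tia = self._tia(np.ones((8, 8, 8)))
        kernel = default_lu177_kernel((2.4, 2.4, 2.4))
        from spectpvc.core import GeometryError

        with pytest.raises(GeometryError):
            convolve_dose(tia, kernel)


class TestCompareDoses:
    def _dose(self, values):
        return Image3D(values, (4.8,) * 3, Units.GY)

    def _lesion(self, volume_mL=7.0):
        from spectpvc.dosimetry import LesionSeg

        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[3:5, 3:5, 3:5] = True
        return {"seg": LesionSeg(mask, volume_mL, "fixed", 0.0), "tbr": 5.0}

    def test_percent_difference_arithmetic(self):
        or_dose = self._dose(np.full((8, 8, 8), 100.0))
        lrd_dose = self._dose(np.full((8, 8, 8), 122.0))
        rep = compare_doses(or_dose, lrd_dose, RCCurve(b=7.0, y=1.0),
                            [self._lesion()], injected_GBq=1.0)
        assert rep.loc[0, "pct_lrd"] == pytest.approx(22.0)

    def test_identical_maps_give_zero_difference(self):
        dose = self._dose(np.full((8, 8, 8), 50.0))
        rep = compare_doses(dose, dose, RCCurve(b=7.0, y=1.0),
                            [self._lesion()], injected_GBq=7.3)
        assert rep.loc[0, "pct_lrd"] == 0.0

    def test_half_recovery_volume_doubles_rc_dose(self):
        dose = self._dose(np.full((8, 8, 8), 40.0))
        rep = compare_doses(dose, dose, RCCurve(b=7.0, y=1.3),
                            [self._lesion(volume_mL=7.0)], injected_GBq=1.0)
        assert rep.loc[0, "ad_rc"] == pytest.approx(2.0 * rep.loc[0, "ad_or"])

    def test_dose_normalized_by_injected_activity(self):
        dose = self._dose(np.full((8, 8, 8), 90.0))
        rep = compare_doses(dose, dose, RCCurve(b=7.0, y=1.0),
                            [self._lesion()], injected_GBq=7.5)
        assert rep.loc[0, "ad_or"] == pytest.approx(90.0 / 7.5)

    def test_empty_lesion_list_gives_empty_report(self):
        dose = self._dose(np.ones((8, 8, 8)))
        rep = compare_doses(dose, dose, RCCurve(b=7.0, y=1.0), [], 1.0)
        assert len(rep) == 0
        assert "ad_rc" in rep.columns
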