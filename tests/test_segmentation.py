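"""Interface detection, quadratic fitting, motion alignment."""

import numpy as np
import pytest

from lenszones.errors import SegmentationError, ValidationError
from lenszones.phantom import SURFACE_NAMES
from lenszones.render import OctVolume, ScanGeometry, render_volume, trace_rays
from lenszones.segmentation import align_bscans, detect_interfaces, fit_surface_poly2


def _detection_errors(volume, phantom, scan, row_y, ctx):
    xs = scan.x_positions()
    pitch = scan.axial_pitch_mm
    cc = int(np.argmin(np.abs(xs)))
    half = int(np.ceil(1.45 * 1.75 / scan.lateral_pitch_mm))
    pupil = slice(max(cc - half, 0), min(cc + half + 1, xs.size))
    det = detect_interfaces(volume, pupil_columns=pupil, seed_context=ctx)
    tr = trace_rays(phantom, xs, np.full_like(xs, row_y), z0=-scan.standoff_mm)
    cols = np.arange(*pupil.indices(xs.size))
    keep = np.abs(xs[cols]) <= 1.75
    errs = det["positions"][:, cols][:, keep] - (tr.opl[:, cols][:, keep] / pitch)
    return errs, det


def test_noiseless_interfaces_found_within_one_sample(rendered_native, mean_phantom,
                                                      native_scan, native_rows):
    ic = len(native_rows) // 2
    row_y = (ic - (len(native_rows) - 1) / 2) * native_scan.extent_mm / native_scan.n_ascans_y
    ctx = np.delete(rendered_native.data, ic, axis=0)[:4]
    errs, _ = _detection_errors(rendered_native.bscan(ic), mean_phantom,
                                native_scan, row_y, ctx)
    for k, name in enumerate(SURFACE_NAMES):
        assert np.abs(errs[k]).max() < 1.0, name


def test_speckled_interfaces_median_error_within_two_samples(speckled_native,
                                                             mean_phantom,
                                                             native_scan,
                                                             native_rows):
    ic = len(native_rows) // 2
    row_y = (ic - (len(native_rows) - 1) / 2) * native_scan.extent_mm / native_scan.n_ascans_y
    ctx = np.delete(speckled_native.data, ic, axis=0)[:6]
    errs, _ = _detection_errors(speckled_native.bscan(ic), mean_phantom,
                                native_scan, row_y, ctx)
    for k, name in enumerate(SURFACE_NAMES):
        assert np.median(np.abs(errs[k])) <= 2.0, name


def test_single_interface_toy_bscan_is_located_exactly():
    nz, nx = 200, 30
    z = np.arange(nz, dtype=float)
    img = np.tile(1000.0 * np.exp(-0.5 * (z - 80.0) ** 2)[:, None], (1, nx))
    det = detect_interfaces(img, labels=("surface",), seed_context=None)
    assert np.allclose(det["positions"][0], 80.0, atol=0.05)


def test_constant_bscan_raises_segmentation_error():
    with pytest.raises(SegmentationError, match="constant"):
        detect_interfaces(np.ones((100, 20)))


def test_fitted_apex_depths_increase_front_to_back(measured_native):
    fits = measured_native["fits_raw"]
    depths = [fits[n].apex_z for n in SURFACE_NAMES]
    assert all(b > a for a, b in zip(depths, depths[1:]))


class TestFitSurfacePoly2:
    def test_exact_parabola_is_interpolated(self):
        x = np.linspace(-2, 2, 50)
        z = 0.05 * x**2 + 1.0
        fit = fit_surface_poly2(x, z, support_diameter=4.0)
        assert fit.a == pytest.approx(0.05, abs=1e-10)
        assert fit.b == pytest.approx(0.0, abs=1e-10)
        assert fit.c == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("radius,max_bias", [
        # quadratic truncation bias of a *circle* over the 3.5 mm chord is
        # approximately (3/14)(h/R)^2 toward smaller radii
        (5.91, 0.025),
        (3.67, 0.06),
    ])
    def test_circle_chord_truncation_bias_is_bounded(self, radius, max_bias):
        x = np.linspace(-1.75, 1.75, 131)
        z = radius - np.sqrt(radius**2 - x**2)
        fit = fit_surface_poly2(x, z)
        r_est = 1.0 / (2.0 * abs(fit.a))
        rel = abs(r_est - radius) / radius
        analytic = (3.0 / 14.0) * (1.75 / radius) ** 2
        assert rel < max_bias
        assert rel == pytest.approx(analytic, rel=0.25)

    def test_gross_outlier_is_rejected(self):
        x = np.linspace(-2, 2, 60)
        z = 0.08 * x**2 - 0.01 * x + 2.0
        z[17] += 5.0
        fit = fit_surface_poly2(x, z, support_diameter=4.0)
        assert fit.a == pytest.approx(0.08, abs=1e-6)
        assert fit.b == pytest.approx(-0.01, abs=1e-6)
        assert fit.c == pytest.approx(2.0, abs=1e-6)

    def test_too_few_points_and_degenerate_spread_raise(self):
        with pytest.raises(ValidationError, match=">= 10"):
            fit_surface_poly2([0, 1, 2], [0, 1, 2])
        x = np.full(20, 1.0) + np.linspace(0, 1e-4, 20)
        with pytest.raises(ValidationError, match="degenerate"):
            fit_surface_poly2(x, np.ones(20))

    def test_lateral_translation_equivariance(self):
        x = np.linspace(-1.7, 1.7, 40)
        z = 0.07 * x**2 + 0.02 * x + 3.0
        f0 = fit_surface_poly2(x, z)
        f1 = fit_surface_poly2(x + 0.8, z, center=0.8)
        assert f1.a == pytest.approx(f0.a, abs=1e-9)  # apex curvature invariant
        assert f1.apex_z == pytest.approx(f0.apex_z, abs=1e-9)


class TestAlignBscans:
    def test_jitter_free_volume_gets_zero_shifts(self, rendered_reduced):
        _, info = align_bscans(rendered_reduced)
        assert (info["shifts"] == 0).all()

    def test_injected_jitter_is_recovered_to_one_sample(self, rendered_reduced):
        rng = np.random.default_rng(3)
        jitter = rng.integers(-5, 6, rendered_reduced.data.shape[0])
        data = rendered_reduced.data.copy()
        for i, j in enumerate(jitter):
            data[i] = np.roll(data[i], j, axis=0)
        vol = OctVolume(data=data, scan=rendered_reduced.scan)
        _, info = align_bscans(vol)
        resid = jitter - info["shifts"]
        resid = resid - int(round(np.median(resid)))  # global offset is unobservable
        assert np.abs(resid).max() <= 1

    def test_constant_volume_is_flagged_and_unshifted(self):
        scan = ScanGeometry(n_ascans_x=30, n_ascans_y=6, n_axial=100)
        vol = OctVolume(data=np.ones((6, 100, 30), dtype=np.float32), scan=scan)
        out, info = align_bscans(vol)
        assert (info["shifts"] == 0).all()
        assert info["flagged"][1:].all()
        assert np.array_equal(out.data, vol.data)
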