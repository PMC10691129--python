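"""Snell's law, OPL-to-geometric conversion, correction round trips."""

import math

import numpy as np
import pytest

from lenszones.errors import CorrectionError, TotalInternalReflection
from lenszones.phantom import CohortSpec, MediaChain, make_eye_for_age
from lenszones.pipeline import measure_volume
from lenszones.refraction import correct_bscan, opl_to_geometric, snell_refract
from lenszones.render import render_volume
from lenszones.segmentation import SurfaceFit


def _planar_fit(label, depth, support=(-2.0, 2.0)):
    return SurfaceFit(label=label, a=0.0, b=0.0, c=depth, rms_residual=0.0,
                      support=support, n_points=40)


class TestSnell:
    def test_normal_incidence_is_unchanged(self):
        d = np.array([0.0, 0.0, 1.0])
        out = snell_refract(d, np.array([0.0, 0.0, -1.0]), 1.0, 1.7)
        assert np.allclose(out, d, atol=1e-12)

    def test_identity_medium_is_unchanged(self):
        d = np.array([0.3, 0.0, math.sqrt(1 - 0.09)])
        n = np.array([0.1, 0.0, -math.sqrt(1 - 0.01)])
        out = snell_refract(d, n, 1.336, 1.336)
        assert np.allclose(out, d, atol=1e-12)

    def test_45_degree_refraction_angle(self):
        s = math.sqrt(0.5)
        d = np.array([s, 0.0, s])
        out = snell_refract(d, np.array([0.0, 0.0, -1.0]), 1.0, 1.5)
        angle = math.degrees(math.asin(abs(out[0])))
        assert angle == pytest.approx(28.1255, abs=1e-3)

    def test_total_internal_reflection_is_signalled(self):
        s = math.sqrt(0.5)
        d = np.array([s, 0.0, s])
        with pytest.raises(TotalInternalReflection):
            snell_refract(d, np.array([0.0, 0.0, -1.0]), 1.5, 1.0)

    def test_direction_stays_unit_length(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = rng.normal(size=3)
            d[2] = abs(d[2]) + 1.0
            d /= np.linalg.norm(d)
            out = snell_refract(d, np.array([0.0, 0.0, -1.0]), 1.0, 1.4)
            assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)


class TestOplToGeometric:
    def test_nucleus_index_conversion(self):
        assert opl_to_geometric(1.3947, 1.3947) == pytest.approx(1.0, abs=1e-12)

    def test_unit_index_is_identity(self):
        assert opl_to_geometric(2.34, 1.0) == 2.34

    def test_additivity(self):
        a, b, n = 0.7, 1.9, 1.376
        assert opl_to_geometric(a + b, n) == pytest.approx(
            opl_to_geometric(a, n) + opl_to_geometric(b, n), abs=1e-12
        )

    def test_index_below_one_rejected(self):
        with pytest.raises(ValueError):
            opl_to_geometric(1.0, 0.9)


class TestCorrectBscan:
    def _toy(self, indices, depths=(0.5, 1.0, 1.5, 2.0, 2.5, 3.0)):
        nz, nx = 400, 24
        rng = np.random.default_rng(1)
        img = rng.uniform(100, 1000, size=(nz, nx))
        labels = ("cornea_ant", "cornea_post", "lens_ant", "nucleus_ant",
                  "nucleus_post", "lens_post")
        fits = {lb: _planar_fit(lb, z) for lb, z in zip(labels, depths)}
        x = np.linspace(-1.15, 1.15, nx)
        return img, fits, x, indices

    def test_unit_indices_are_the_identity(self):
        img, fits, x, _ = self._toy([1.0] * 7)
        for mode in ("bilinear", "nearest"):
            res = correct_bscan(img, fits, [1.0] * 7, axial_pitch_mm=0.01,
                                x_positions=x, mode=mode, support_diameter=2.0)
            inside = res.bscan[5:-5]
            assert np.max(np.abs(inside - img[5:-5])) < 1e-6

    def test_layer_extent_shrinks_by_the_medium_index(self):
        n = 1.3947
        img, fits, x, _ = self._toy([1.0, n, 1.0, 1.0, 1.0, 1.0, 1.0])
        res = correct_bscan(img, fits, [1.0, n, 1.0, 1.0, 1.0, 1.0, 1.0],
                            axial_pitch_mm=0.01, x_positions=x, mode="nearest",
                            support_diameter=2.0)
        cfits = res.corrected_fits
        raw_extent = fits["cornea_post"].c - fits["cornea_ant"].c
        corr_extent = cfits["cornea_post"].apex_z - cfits["cornea_ant"].apex_z
        assert corr_extent == pytest.approx(raw_extent / n, abs=1e-9)

    def test_unknown_mode_and_bad_chain_are_rejected(self):
        img, fits, x, _ = self._toy([1.0] * 7)
        with pytest.raises(CorrectionError):
            correct_bscan(img, fits, [1.0] * 3, axial_pitch_mm=0.01, x_positions=x)
        with pytest.raises(CorrectionError):
            correct_bscan(img, fits, [1.0] * 7, axial_pitch_mm=0.01,
                          x_positions=x, mode="cubic")


@pytest.mark.parametrize("age", [15.0, 39.24, 70.0])
def test_render_correct_round_trip_recovers_geometry(age, native_scan, native_rows):
    """Full forward + inverse chain across the age range: radii within 2%,
    central thicknesses within 2 axial samples, surface order preserved."""
    spec = CohortSpec()
    ph = make_eye_for_age(age, spec)
    vol = render_volume(ph, native_scan, y_rows=native_rows)
    m = measure_volume(vol, media=ph.media)
    b = m["biometry"]
    for key in ("lens_ant", "nucleus_ant", "nucleus_post", "lens_post"):
        measured = getattr(b, f"radius_{key}")
        assert measured == pytest.approx(ph.surfaces[key].radius, rel=0.02), key
    tol = 2 * native_scan.axial_pitch_mm
    assert b.thickness_lens == pytest.approx(ph.lens_thickness, abs=tol)
    assert b.thickness_nucleus == pytest.approx(ph.nucleus_thickness, abs=tol)
    fits = m["correction"].corrected_fits
    depths = [fits[n].apex_z for n in ("cornea_ant", "cornea_post", "lens_ant",
                                       "nucleus_ant", "nucleus_post", "lens_post")]
    assert all(bb > aa for aa, bb in zip(depths, depths[1:]))
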