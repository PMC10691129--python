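"""Densitogram extraction, smoothing, OSD-zone segmentation, zone metrics."""

import numpy as np
import pytest

from lenszones.densitometry import (
    Densitogram,
    ZONE_SEQUENCE,
    extract_densitogram,
    find_zone_boundaries,
    roi_column_offsets,
    smooth_densitogram,
    zone_metrics,
)
from lenszones.errors import ValidationError
from lenszones.render import OctVolume, ScanGeometry


def _uniform_volume(value=500.0, n=9, pitch_um=26.7, nz=64):
    extent = n * pitch_um * 1e-3
    scan = ScanGeometry(n_ascans_x=n, n_ascans_y=n, n_axial=nz, extent_mm=extent)
    data = np.full((n, nz, n), value, dtype=np.float32)
    return OctVolume(data=data, scan=scan)


class TestExtract:
    def test_uniform_volume_gives_a_constant_profile(self):
        d = extract_densitogram(_uniform_volume(500.0))
        assert np.allclose(d.intensity, 500.0)

    def test_roi_at_reference_pitch_contains_21_columns(self):
        # lattice enumeration: offsets with sqrt(i^2+j^2)*26.7 <= 66.5
        assert roi_column_offsets(26.7, 66.5).shape[0] == 21
        d = extract_densitogram(_uniform_volume())
        assert d.n_columns == 21

    def test_roi_clipped_by_the_field_edge_raises(self):
        vol = _uniform_volume()
        with pytest.raises(ValidationError, match="clipped|field"):
            extract_densitogram(vol, axis_xy_mm=(0.11, 0.0))

    def test_lens_span_crop_rebases_depth(self):
        vol = _uniform_volume(nz=128)
        pitch = vol.axial_pitch_mm
        d = extract_densitogram(vol, lens_span_mm=(10 * pitch, 50 * pitch))
        assert d.z_mm[0] == pytest.approx(0.0, abs=1e-12)
        assert d.z_mm[-1] == pytest.approx(40 * pitch, abs=1e-9)


class TestSmoothing:
    def test_unit_impulse_becomes_five_fifths(self):
        y = np.zeros(41)
        y[20] = 1.0
        d = Densitogram(z_mm=np.arange(41.0) * 0.01, intensity=y)
        s = smooth_densitogram(d, 5)
        assert np.allclose(s.intensity[18:23], 0.2)
        assert s.intensity.sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_profile_is_unchanged_including_edges(self):
        d = Densitogram(z_mm=np.arange(30.0) * 0.01, intensity=np.full(30, 7.0))
        s = smooth_densitogram(d, 5)
        assert np.allclose(s.intensity, 7.0)

    def test_linear_ramp_interior_is_preserved(self):
        y = np.linspace(10, 50, 60)
        d = Densitogram(z_mm=np.arange(60.0) * 0.01, intensity=y)
        s = smooth_densitogram(d, 5)
        assert np.allclose(s.intensity[2:-2], y[2:-2], atol=1e-9)

    def test_even_or_oversized_window_rejected(self):
        d = Densitogram(z_mm=np.arange(10.0), intensity=np.ones(10))
        with pytest.raises(ValidationError):
            smooth_densitogram(d, 4)
        with pytest.raises(ValidationError):
            smooth_densitogram(d, 11)


def _synthetic_lens_profile(pitch=0.0089):
    """Pure logistic-step profile with the full bright/dark zone sequence;
    returns (densitogram, true boundary depths at the logistic midpoints)."""
    levels = [33.6, 39.8, 33.1, 43.0, 25.5, 14.8, 25.5, 43.0, 33.1, 39.8, 33.6]
    # full zone widths keep adjacent smoothed steps well separated
    widths_mm = [0.16, 0.20, 0.27, 1.07, 0.30, 2.39, 0.30, 1.07, 0.27, 0.20, 0.16]
    edges = np.concatenate([[0.0], np.cumsum(widths_mm)])
    z = np.arange(0.0, edges[-1], pitch)
    y = np.zeros_like(z)
    k = 1.5 * pitch  # logistic steepness
    y += levels[0]
    for i in range(1, 11):
        y += (levels[i] - levels[i - 1]) / (1.0 + np.exp(-(z - edges[i]) / k))
    y *= 1e3
    return Densitogram(z_mm=z, intensity=y), edges


class TestZoneBoundaries:
    def test_logistic_steps_are_located_within_one_sample(self):
        d, edges = _synthetic_lens_profile()
        s = smooth_densitogram(d, 5)
        zones = find_zone_boundaries(s)
        assert zones.labels == ZONE_SEQUENCE
        assert zones.missing == ()
        for found, true in zip(zones.boundaries[1:-1], edges[1:-1]):
            assert abs(found - true) <= 1.5 * d.pitch_mm

    def test_monotone_profile_yields_an_explicit_empty_result(self):
        z = np.arange(0.0, 2.0, 0.01)
        d = Densitogram(z_mm=z, intensity=np.linspace(100, 5000, z.size))
        zones = find_zone_boundaries(smooth_densitogram(d, 5))
        assert zones.labels == ("unsegmented",)
        assert len(zones.missing) == 11

    def test_unsmoothed_input_is_rejected(self):
        d, _ = _synthetic_lens_profile()
        with pytest.raises(ValidationError, match="smoothed"):
            find_zone_boundaries(d)

    def test_override_replaces_a_boundary(self):
        d, edges = _synthetic_lens_profile()
        s = smooth_densitogram(d, 5)
        zones = find_zone_boundaries(s, override={"C4_ant": edges[5] - 0.01})
        assert zones.overridden == ("C4_ant",)
        i = zones.labels.index("C4_ant")
        assert zones.boundaries[i + 1] == pytest.approx(edges[5] - 0.01)

    def test_non_monotone_override_is_rejected(self):
        d, _ = _synthetic_lens_profile()
        s = smooth_densitogram(d, 5)
        with pytest.raises(ValidationError, match="monotone"):
            find_zone_boundaries(s, override={"C2_ant": 4.0})

    def test_external_anchors_pin_the_nucleus(self):
        d, edges = _synthetic_lens_profile()
        s = smooth_densitogram(d, 5)
        zones = find_zone_boundaries(s, anchors=(edges[5], edges[6]))
        i = zones.labels.index("C4_ant")
        assert zones.boundaries[i + 1] == pytest.approx(edges[5], abs=1e-9)


class TestZoneMetrics:
    def test_uniform_zone_density_in_table_units(self):
        from lenszones.densitometry import ZoneSet
        z = np.arange(0.0, 1.0, 0.01)
        d = Densitogram(z_mm=z, intensity=np.full(z.size, 14800.0))
        zones = ZoneSet(boundaries=np.array([0.0, 0.5, 0.99]),
                        labels=("nucleus", "C4_post"))
        table = zone_metrics(d, zones)
        row = table[table.label == "region_nucleus"].iloc[0]
        assert row["density_e3au"] == pytest.approx(14.8, abs=1e-9)

    def test_thickness_additivity_and_union_density(self):
        d, edges = _synthetic_lens_profile()
        s = smooth_densitogram(d, 5)
        zones = find_zone_boundaries(s)
        table = zone_metrics(d, zones)
        segs = table[table.kind == "segment"]
        lens_row = table[table.label == "region_lens"].iloc[0]
        assert segs["thickness_mm"].sum() == pytest.approx(
            lens_row["thickness_mm"], abs=1e-9
        )
        # density of a union equals the thickness-weighted mean of its parts
        cortex = table[table.label == "region_cortex"].iloc[0]
        parts = segs[segs.label != "nucleus"]
        weighted = (parts["thickness_mm"] * parts["density_e3au"]).sum() / parts["thickness_mm"].sum()
        assert cortex["density_e3au"] == pytest.approx(weighted, rel=1e-6)

    def test_density_is_computed_on_the_unsmoothed_profile(self):
        d, _ = _synthetic_lens_profile()
        s = smooth_densitogram(d, 5)
        with pytest.raises(ValidationError, match="unsmoothed"):
            zone_metrics(s, find_zone_boundaries(s))

    def test_empty_zone_is_an_error(self):
        from lenszones.densitometry import ZoneSet
        z = np.arange(0.0, 1.0, 0.01)
        d = Densitogram(z_mm=z, intensity=np.ones(z.size))
        zones = ZoneSet(boundaries=np.array([0.0, 0.5005, 0.5008, 0.99]),
                        labels=("a", "b", "c"))
        with pytest.raises(ValidationError, match="empty"):
            zone_metrics(d, zones)


def test_end_to_end_zone_recovery(measured_native, mean_phantom, native_scan):
    """Noiseless imaging chain: every zone thickness within 2 axial samples
    of the phantom truth."""
    truth = mean_phantom.zone_thicknesses()
    pitch = native_scan.axial_pitch_mm
    table = measured_native["zone_metrics"]
    for _, row in table[table.kind == "zone"].iterrows():
        err = abs(row["thickness_mm"] - truth[row["label"].lower()])
        assert err <= 2 * pitch, row["label"]
    assert measured_native["zones"].missing == ()


def test_end_to_end_zone_boundaries_under_speckle(speckled_native, mean_phantom,
                                                  native_scan):
    """With default speckle each zone boundary stays within 4 axial samples
    of truth (the C4/nucleus region is the least reproducible)."""
    from lenszones.pipeline import measure_volume
    m = measure_volume(speckled_native, media=mean_phantom.media)
    zones = m["zones"]
    tz = mean_phantom.zone_thicknesses()
    ant = [tz[k] / 2 for k in ("c1a", "c1b", "c2", "c3", "c4")]
    cum = np.cumsum(ant)
    truth = np.concatenate([[0], cum, [cum[-1] + tz["nucleus"]],
                            cum[-1] + tz["nucleus"] + np.cumsum(ant[::-1])])
    pitch = native_scan.axial_pitch_mm
    assert zones.labels == ZONE_SEQUENCE
    errs = np.abs(zones.boundaries - truth) / pitch
    assert errs.max() <= 4.0
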