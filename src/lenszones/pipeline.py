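"""End-to-end orchestration: simulate -> render -> align -> segment ->
correct -> biometry -> densitometry -> statistics.

Each stage writes plain-text intermediates (CSV/JSON/TIFF bundles) into the
output directory so any stage can be re-run from the previous one's files.
All randomness flows from explicit integer seeds recorded in the run log.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biometry as bm
from . import densitometry as dens
from . import refraction, segmentation, stats
from .errors import LensZonesError, ValidationError
from .phantom import CohortSpec, EyePhantom, phantom_from_params, sample_cohort
from .render import OctVolume, ScanGeometry, render_volume
from .volume_io import read_volume, write_volume


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; defaults are the study constants
    (66.5 um ROI radius, 5-sample smoothing, 3.5 mm analysis diameter,
    the double-shell index chain, 300 x 300 x 1500 scan)."""

    seed: int = 0
    n_eyes: int = 49
    n_imaging_eyes: int = 0  # eyes run through the full imaging chain
    scan: ScanGeometry = field(default_factory=ScanGeometry)
    speckle: bool = True
    roi_radius_um: float = 66.5
    smooth_window: int = 5
    fit_diameter_mm: float = 3.5
    prominence_frac: float = 0.05
    bh_family: tuple[str, ...] = stats.DEFAULT_FAMILY
    align: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scan = ScanGeometry(**raw.pop("scan", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "bh_family" in raw:
            raw["bh_family"] = tuple(raw["bh_family"])
        return cls(scan=scan, **raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["scan"] = self.scan.to_dict()
        d["bh_family"] = list(self.bh_family)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def measure_volume(volume: OctVolume, *, config: PipelineConfig | None = None,
                   media=None) -> dict:
    """Measure one eye from its raw volume: segmentation of the central
    B-scan, refraction correction, biometry, and ROI densitometry with
    OSD-zone metrics.

    Returns a dict with the BiometryResult, the ZoneSet, the zone-metrics
    table and the corrected central B-scan result.
    """
    from .phantom import MediaChain

    config = config or PipelineConfig()
    media = media or MediaChain()
    scan = volume.scan
    xs = scan.x_positions()

    if config.align and volume.data.shape[0] > 1:
        volume, _ = segmentation.align_bscans(volume)

    ic = volume.central_bscan_index()
    pitch = volume.axial_pitch_mm
    # analysis restricted to the central pupil region; detection extends 25%
    # beyond it because refraction pulls deep-surface points toward the
    # axis, and the corrected fit must still cover the full analysis zone
    half_cols = int(np.ceil(1.45 * config.fit_diameter_mm / 2 / scan.lateral_pitch_mm))
    centre_col = np.argmin(np.abs(xs))
    pupil = slice(max(centre_col - half_cols, 0), min(centre_col + half_cols + 1, xs.size))

    # adjacent B-scans (independent speckle) stabilise the seed profile
    ctx_rows = [iy for iy in range(max(ic - 3, 0), min(ic + 4, volume.data.shape[0])) if iy != ic]
    detection = segmentation.detect_interfaces(
        volume.bscan(ic), pupil_columns=pupil,
        seed_context=volume.data[ctx_rows] if ctx_rows else None,
    )
    fits = segmentation.fit_interfaces(detection, xs, pitch,
                                       support_diameter=config.fit_diameter_mm)
    # per-column measured OPLs drive the correction; columns that are
    # invalid or stray from the robust quadratic fall back to the fit
    raw_opl = {}
    measured_mask = {}
    for k, label in enumerate(detection["labels"]):
        meas = detection["positions"][k] * pitch
        fit_z = fits[label](xs)
        resid = meas - fit_z
        tol = max(3 * 1.4826 * np.nanmedian(np.abs(resid - np.nanmedian(resid))),
                  2 * pitch)
        ok = (detection["valid"][k] & np.isfinite(meas)
              & (np.abs(resid - np.nanmedian(resid)) <= tol))
        raw_opl[label] = np.where(ok, meas, fit_z)
        measured_mask[label] = ok
    corr = refraction.correct_bscan(
        volume.bscan(ic), fits, media, axial_pitch_mm=pitch, x_positions=xs,
        mode="nearest", support_diameter=config.fit_diameter_mm, raw_opl=raw_opl,
        measured_mask=measured_mask,
    )
    biometry_result = bm.measure_biometry(corr.corrected_fits,
                                          corrected_points=corr.corrected_points,
                                          zone_diameter=config.fit_diameter_mm)

    # densitometry: nearest-neighbour-corrected mini-volume around the axis
    n_pages = volume.data.shape[0]
    if n_pages == scan.n_ascans_y:
        ys = scan.y_positions()
    else:
        ys = (np.arange(n_pages) - (n_pages - 1) / 2) * (scan.extent_mm / scan.n_ascans_y)
    rows = np.nonzero(np.abs(ys) <= config.roi_radius_um * 1e-3 + 1e-12)[0]
    if rows.size == 0:
        rows = np.array([ic])
    mini = np.empty((rows.size, volume.data.shape[1], xs.size), dtype=np.float32)
    for k, iy in enumerate(rows):
        res = refraction.correct_bscan(
            volume.bscan(iy), fits, media, axial_pitch_mm=pitch, x_positions=xs,
            mode="nearest", support_diameter=config.fit_diameter_mm,
        )
        mini[k] = res.bscan
    mini_vol = OctVolume(data=mini, scan=scan, coordinate_state=refraction.CORRECTED_STATE,
                         axial_pitch_mm=pitch, provenance=volume.provenance + ["measure_volume"])
    ax = biometry_result.axis
    z_ant = min(ax.z_ant, ax.z_post)
    z_post = max(ax.z_ant, ax.z_post)
    densito = dens.extract_densitogram(
        mini_vol, axis_xy_mm=(ax.x_at(0.5 * (z_ant + z_post)), 0.0),
        roi_radius_um=config.roi_radius_um, lens_span_mm=(z_ant, z_post),
    )
    smoothed = dens.smooth_densitogram(densito, config.smooth_window)
    # nucleus-interface anchors from the B-scan segmentation (more robust
    # than re-detecting them on the narrow-ROI densitogram)
    ant_cortex = bm.central_thickness(corr.corrected_fits["lens_ant"],
                                      corr.corrected_fits["nucleus_ant"], ax)
    zones = dens.find_zone_boundaries(
        smoothed, prominence_frac=config.prominence_frac,
        anchors=(ant_cortex, ant_cortex + biometry_result.thickness_nucleus),
    )
    metrics = dens.zone_metrics(densito, zones) if "unsegmented" not in zones.labels else None
    return {
        "biometry": biometry_result,
        "zones": zones,
        "zone_metrics": metrics,
        "correction": corr,
        "densitogram": densito,
        "fits_raw": fits,
    }


def image_and_measure(phantom: EyePhantom, scan: ScanGeometry, *,
                      speckle: bool = True, seed=None,
                      config: PipelineConfig | None = None) -> dict:
    """Render a phantom and measure it (the full imaging chain)."""
    volume = render_volume(phantom, scan, speckle=speckle, seed=seed)
    out = measure_volume(volume, config=config, media=phantom.media)
    out["volume"] = volume
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write the cohort and report files.

    Outputs: ``cohort.csv`` (generated per-eye parameters),
    ``measured.csv`` (imaging-chain measurements when n_imaging_eyes > 0),
    ``age_correlations.csv``, ``group_comparisons.csv``, ``mvlr.json`` and
    ``run_log.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(n_eyes=config.n_eyes)
    cohort = sample_cohort(spec, seed=config.seed)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    log = {"seed": config.seed, "n_eyes": config.n_eyes, "stages": ["simulate"]}

    if config.n_imaging_eyes > 0:
        rows = []
        for i in range(min(config.n_imaging_eyes, len(cohort))):
            row = cohort.iloc[i]
            eye_seed = int(np.random.SeedSequence([config.seed, 1000 + i]).generate_state(1)[0] % (2**31))
            ph = phantom_from_params(row.drop(labels=["eye_id"]).to_dict(), spec, age=row["age"])
            try:
                vol = render_volume(ph, config.scan, speckle=config.speckle,
                                    seed=eye_seed if config.speckle else None)
                bundle = write_volume(vol, outdir / f"{row['eye_id']}_raw.tiff")
                m = measure_volume(read_volume(bundle.tiff_path), config=config, media=ph.media)
            except LensZonesError as e:
                raise type(e)(f"stage imaging failed for {row['eye_id']}: {e}") from e
            rec = {"eye_id": row["eye_id"], "age": row["age"], "render_seed": eye_seed,
                   **{f"measured_{k}": v for k, v in m["biometry"].as_dict().items()}}
            if m["zone_metrics"] is not None:
                for _, zrow in m["zone_metrics"].iterrows():
                    rec[f"thick_{zrow['label']}"] = zrow["thickness_mm"]
                    rec[f"dens_{zrow['label']}"] = zrow["density_e3au"]
            rows.append(rec)
        pd.DataFrame(rows).to_csv(outdir / "measured.csv", index=False)
        log["stages"].append("imaging")

    report = stats.spearman_with_bh(cohort, config.bh_family)
    report.table.to_csv(outdir / "age_correlations.csv", index=False)
    stats.group_comparisons(cohort).to_csv(outdir / "group_comparisons.csv", index=False)
    zone_cols = [f"thickness_{z}" for z in ("c1a", "c1b", "c2", "c3", "c4")]
    predictors = ["thickness_nucleus"] + zone_cols
    if len(cohort) > len(predictors) + 2:
        mv = stats.mvlr(cohort, "thickness_lens", predictors)
        (outdir / "mvlr.json").write_text(json.dumps(mv.to_dict(), indent=1))
    else:
        (outdir / "mvlr.json").write_text(json.dumps(
            {"skipped": f"n={len(cohort)} too small for {len(predictors)} predictors"}))
    log["stages"] += ["stats"]
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    return {"cohort": cohort, "correlations": report, "outdir": outdir}
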