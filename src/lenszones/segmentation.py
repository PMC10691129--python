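"""Interface detection and quadratic surface fitting in B-scans.

The renderer produces clean specular peaks at the six optical interfaces
(cornea anterior/posterior, lens anterior/posterior, nucleus
anterior/posterior), so detection is peak-based: a laterally averaged seed
profile at the scan centre locates all interfaces, which are then tracked
column by column outward with a local windowed search (robust to speckle),
refined to sub-sample precision by parabolic interpolation, and summarised
per interface by a 2nd-order polynomial fit with one-pass outlier rejection.
A simple axial cross-correlation step aligns B-scans against motion jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .errors import SegmentationError, ValidationError
from .phantom import SURFACE_NAMES
from .render import OctVolume

INTERFACE_LABELS = SURFACE_NAMES


@dataclass(frozen=True)
class SurfaceFit:
    """Quadratic interface model z = a x^2 + b x + c in a B-scan plane.

    z is in the coordinate units of the fitted points (mm of OPL for raw
    scans, geometric mm after correction); x is lateral position (mm).
    """

    label: str
    a: float
    b: float
    c: float
    rms_residual: float
    support: tuple[float, float]
    n_points: int = 0

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.a * x**2 + self.b * x + self.c

    def slope(self, x):
        return 2.0 * self.a * np.asarray(x, dtype=float) + self.b

    @property
    def apex_x(self) -> float:
        if abs(self.a) < 1e-9:
            return 0.5 * (self.support[0] + self.support[1])
        return -self.b / (2.0 * self.a)

    @property
    def apex_z(self) -> float:
        return float(self(self.apex_x))

    @property
    def support_width(self) -> float:
        return self.support[1] - self.support[0]


def fit_surface_poly2(x, z, *, support_diameter: float = 3.5, center: float | None = None,
                      label: str = "", min_points: int = 10,
                      reject_scale: float = 3.0) -> SurfaceFit:
    """Least-squares quadratic through interface points.

    Points outside the ``support_diameter`` window around ``center`` (default:
    the median x) are ignored; points further than ``reject_scale`` robust
    scale units (1.4826 MAD) from an initial fit are excluded once and the
    fit repeated.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    good = np.isfinite(x) & np.isfinite(z)
    x, z = x[good], z[good]
    if center is None:
        center = float(np.median(x)) if x.size else 0.0
    keep = np.abs(x - center) <= support_diameter / 2
    x, z = x[keep], z[keep]
    if x.size < min_points:
        raise ValidationError(f"need >= {min_points} points to fit {label or 'surface'}, got {x.size}")
    if np.ptp(x) < 0.05 * support_diameter:
        raise ValidationError(f"degenerate lateral spread {np.ptp(x):.4f} mm for {label or 'surface'}")

    coeffs = np.polyfit(x, z, 2)
    resid = z - np.polyval(coeffs, x)
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad
    if scale > 0:
        inlier = np.abs(resid - np.median(resid)) <= reject_scale * scale
        if inlier.sum() >= min_points and not inlier.all():
            x, z = x[inlier], z[inlier]
            coeffs = np.polyfit(x, z, 2)
            resid = z - np.polyval(coeffs, x)
    rms = float(np.sqrt(np.mean(resid**2)))
    return SurfaceFit(label=label, a=float(coeffs[0]), b=float(coeffs[1]), c=float(coeffs[2]),
                      rms_residual=rms, support=(float(x.min()), float(x.max())),
                      n_points=int(x.size))


def _parabolic_refine(profile: np.ndarray, idx: int) -> float:
    """Sub-sample peak position from the 3 samples around a maximum."""
    if idx <= 0 or idx >= profile.size - 1:
        return float(idx)
    y0, y1, y2 = profile[idx - 1], profile[idx], profile[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0 or abs(denom) < 1e-12:
        return float(idx)
    return float(idx + 0.5 * (y0 - y2) / denom)


def _refine_peak(profile: np.ndarray, idx: int, *, baseline_offset: int = 5,
                 ramp_width: int = 5, iters: int = 3) -> float:
    """Sub-sample peak position with model-consistent baseline removal.

    A specular peak sits on the reflectivity step between the two media it
    separates; after axial moving-average smoothing the step becomes a ramp
    of the smoothing width, and its residual slope under the (flattened)
    peak pulls a naive parabolic vertex toward the brighter side by up to
    ~1 sample.  The baseline is therefore modelled as that ramp, centred on
    the current position estimate, and the parabolic refinement is iterated.
    """
    lo, hi = idx - baseline_offset, idx + baseline_offset
    if lo - 1 < 0 or hi + 1 >= profile.size:
        return _parabolic_refine(profile, idx)
    x = np.arange(lo, hi + 1, dtype=float)
    level_lo = 0.5 * (profile[lo - 1] + profile[lo])
    level_hi = 0.5 * (profile[hi] + profile[hi + 1])
    pos = float(idx)
    for _ in range(iters):
        ramp = np.clip((x - (pos - 0.5)) / ramp_width + 0.5, 0.0, 1.0)
        window = profile[lo:hi + 1] - (level_lo + (level_hi - level_lo) * ramp)
        j = int(np.argmax(window))
        pos = lo + _parabolic_refine(window, j) if 0 < j < window.size - 1 else float(lo + j)
    return pos


def _best_candidate(prof: np.ndarray, lo: int, hi: int, w_bg: int,
                    prefer_deep: bool | None = None) -> int:
    """Candidate index in [lo, hi) for a specular interface peak.

    Candidates are scored by local contrast (height above the darkest
    sample within +-w_bg): interfaces abut a dark medium, so true peaks
    outscore bright-zone speckle bumps of similar raw intensity.  Spurious
    bumps only exist on the *bright* side of an interface, which makes
    plain maximisation drift one-sidedly; among candidates within half the
    best contrast the one furthest toward the dark side is therefore
    taken (``prefer_deep`` True = dark side below, False = above, None =
    plain contrast maximum).
    """
    idx = np.arange(lo, hi)
    vals = prof[lo:hi]
    bg = np.array([prof[max(i - w_bg, 0):min(i + w_bg + 1, prof.size)].min() for i in idx])
    contrast = vals - bg
    if prefer_deep is None:
        return int(idx[np.argmax(contrast)])
    # restrict to distinct local maxima so a peak's own flank samples
    # cannot qualify as "strong" candidates
    interior = (vals[1:-1] >= vals[:-2]) & (vals[1:-1] >= vals[2:])
    is_max = np.zeros_like(vals, dtype=bool)
    is_max[1:-1] = interior
    if not is_max.any():
        return int(idx[np.argmax(contrast)])
    strong = is_max & (contrast >= 0.5 * contrast[is_max].max())
    cand = idx[strong]
    return int(cand[-1] if prefer_deep else cand[0])


def detect_interfaces(bscan: np.ndarray, labels=INTERFACE_LABELS, *,
                      axial_smooth: int = 5, lateral_avg: int = 7,
                      seed_halfwidth: int = 5, search_halfwidth: int = 6,
                      prominence_frac: float = 0.10,
                      pupil_columns: slice | None = None,
                      seed_context: np.ndarray | None = None) -> dict:
    """Locate the labelled interfaces in every A-scan of a B-scan.

    A laterally averaged seed profile at the scan centre identifies the
    interfaces as the most prominent specular peaks; each interface is then
    tracked column by column outward.  At every column the ``lateral_avg``
    neighbouring A-scans are shear-aligned along the locally estimated
    surface slope and averaged (suppressing speckle without smearing sloped
    interfaces), the maximum is searched within ``search_halfwidth`` of the
    linear prediction, and the position is refined to sub-sample precision
    by parabolic interpolation after baseline-ramp removal.

    Returns ``{"positions": (n_labels, nx) float samples, "valid": bool
    mask, "labels": labels}``.  Raises SegmentationError when an interface
    is missing from the seed profile or lost on more than half of the
    analysed A-scans.
    """
    bscan = np.asarray(bscan, dtype=float)
    if np.ptp(bscan) == 0:
        raise SegmentationError("constant B-scan: no interfaces to detect")
    nz, nx = bscan.shape
    n_ifc = len(labels)
    ax_img = uniform_filter1d(bscan, size=axial_smooth, axis=0, mode="nearest")
    cols = range(nx) if pupil_columns is None else range(*pupil_columns.indices(nx))
    cols = np.asarray(list(cols))
    centre = cols[len(cols) // 2]

    c0, c1 = max(centre - seed_halfwidth, 0), min(centre + seed_halfwidth + 1, nx)
    # seed block kept narrow (surface sag < ~2 samples at the apex) and,
    # when adjacent B-scans are supplied, averaged across them too: their
    # speckle is independent, so the seed peaks stand far above the noise
    block = bscan[:, c0:c1]
    if seed_context is not None:
        ctx = np.asarray(seed_context, dtype=float)
        if ctx.ndim == 2:
            ctx = ctx[None]
        block = np.concatenate([block] + [c[:, c0:c1] for c in ctx], axis=1)
    seed_profile = uniform_filter1d(block.mean(axis=1), size=axial_smooth, mode="nearest")
    prom = prominence_frac * np.ptp(seed_profile)
    peaks, _ = find_peaks(seed_profile, prominence=prom)
    if peaks.size < n_ifc:
        missing = list(labels[peaks.size:])
        raise SegmentationError(
            f"only {peaks.size}/{n_ifc} interfaces in seed profile; "
            f"missing (by depth order): {missing}"
        )
    # rank candidate peaks by local contrast (height above the darkest
    # sample within the peak footprint): true interfaces abut a dark
    # medium (aqueous, vitreous, nucleus), whereas speckle bumps and
    # bright zones ride on bright plateaus and score low; greedy
    # min-separation selection avoids double-counting one interface
    w_bg = 2 * axial_smooth + 2
    contrast = np.array([
        seed_profile[p] - seed_profile[max(p - w_bg, 0):p + w_bg + 1].min()
        for p in peaks
    ])
    chosen: list[int] = []
    for idx in np.argsort(contrast)[::-1]:
        p = peaks[idx]
        if all(abs(p - q) > 15 for q in chosen):
            chosen.append(int(p))
        if len(chosen) == n_ifc:
            break
    if len(chosen) < n_ifc:
        raise SegmentationError(
            f"only {len(chosen)}/{n_ifc} separable interfaces in seed profile"
        )
    seed_peaks = np.sort(np.asarray(chosen)).astype(float)
    amp_ref = seed_profile[seed_peaks.astype(int)]
    # which side of each interface is the dark medium (spurious bumps can
    # only live on the bright side)
    prefer_deep = []
    for pk in seed_peaks.astype(int):
        above = seed_profile[max(pk - 15, 0):max(pk - 4, 1)].mean()
        below = seed_profile[pk + 5:pk + 16].mean() if pk + 16 <= nz else above
        prefer_deep.append(bool(above > below))

    positions = np.full((n_ifc, nx), np.nan)
    valid = np.zeros((n_ifc, nx), dtype=bool)
    half_avg = max(lateral_avg // 2, 0)
    win = search_halfwidth + axial_smooth + 4
    zrel = np.arange(-win, win + 1, dtype=float)
    z_idx = np.arange(nz, dtype=float)

    def sheared_profile(ic: int, pred: float, slope: float) -> np.ndarray:
        js = np.arange(max(ic - half_avg, 0), min(ic + half_avg + 1, nx))
        acc = np.zeros(zrel.size)
        for j in js:
            acc += np.interp(np.clip(zrel + pred + slope * (j - ic), 0, nz - 1),
                             z_idx, ax_img[:, j])
        return acc / js.size

    # Interfaces are processed strong-first: the cornea and lens capsule
    # abut optically empty media and track robustly; the weaker
    # nucleo-cortical interfaces are then tracked relative to their capsule
    # reference (a smooth offset polynomial), which carries the steep
    # lateral geometry and prevents capture by bright zone structure.
    ref_of = {"nucleus_ant": "lens_ant", "nucleus_post": "lens_post"}
    label_idx = {lab: i for i, lab in enumerate(labels)}
    proc_order = [i for i, lab in enumerate(labels) if lab not in ref_of] + \
        [i for i, lab in enumerate(labels) if lab in ref_of]
    order_out = cols[np.argsort(np.abs(cols - centre), kind="stable")]
    ref_track: dict[int, np.ndarray] = {}   # robust quadratic per interface

    def robust_quad(t, p):
        co = np.polyfit(t, p, 2 if t.size >= 8 else 1)
        for _ in range(3):
            resid = p - np.polyval(co, t)
            med = np.median(resid)
            mad = np.median(np.abs(resid - med))
            keep = np.abs(resid - med) <= max(3 * 1.4826 * mad, 1.0)
            if keep.sum() < 5 or keep.all():
                break
            co = np.polyfit(t[keep], p[keep], 2 if keep.sum() >= 8 else 1)
            t, p = t[keep], p[keep]
        return np.concatenate([np.zeros(3 - co.size), co])

    for k in proc_order:
        ref_idx = None
        ref_lab = ref_of.get(labels[k]) if isinstance(labels[k], str) else None
        if ref_lab in label_idx and label_idx[ref_lab] in ref_track:
            ref_idx = label_idx[ref_lab]

        def model_pred(ic, co):
            if ref_idx is None:
                return (float(np.polyval(co, ic)),
                        float(2 * co[0] * ic + co[1]))
            rc = ref_track[ref_idx]
            return (float(np.polyval(rc, ic) + np.polyval(co, ic)),
                    float(2 * (rc[0] + co[0]) * ic + rc[1] + co[1]))

        # pass 1: grow outward from the centre with a model refit to the
        # accepted columns so far (offset from the reference where one
        # exists, absolute track otherwise)
        acc_ic: list[int] = []
        acc_val: list[float] = []
        if ref_idx is None:
            co = np.array([0.0, 0.0, seed_peaks[k]])
        else:
            co = np.array([0.0, 0.0, seed_peaks[k] - float(np.polyval(ref_track[ref_idx], centre))])
        for ic in order_out:
            pred, vel = model_pred(ic, co)
            p = float(np.clip(pred, win, nz - win - 1))
            prof = sheared_profile(ic, p, vel)
            lo = win - search_halfwidth
            hi = win + search_halfwidth + 1
            j = _best_candidate(prof, lo, hi, 2 * axial_smooth + 2,
                                prefer_deep=prefer_deep[k])
            refined = _refine_peak(prof, j, ramp_width=axial_smooth)
            positions[k, ic] = p + (refined - win)
            valid[k, ic] = prof[j] >= 0.25 * amp_ref[k]
            if valid[k, ic]:
                acc_ic.append(ic)
                base = 0.0 if ref_idx is None else float(np.polyval(ref_track[ref_idx], ic))
                acc_val.append(positions[k, ic] - base)
                t = np.asarray(acc_ic, dtype=float)
                pv = np.asarray(acc_val)
                # polynomial degree gated on the *lateral span* covered
                # (fractions of the analysed width): a quadratic fitted
                # across a few columns has an unbounded curvature
                # coefficient and the extrapolated track runs away
                span = np.ptp(t)
                deg = 2 if span >= max(0.16 * cols.size, 8) else \
                    (1 if span >= max(0.05 * cols.size, 3) and t.size >= 4 else 0)
                deg = int(min(deg, max(t.size - 2, 0)))
                co_new = np.polyfit(t, pv, deg)
                resid = pv - np.polyval(co_new, t)
                mad = np.median(np.abs(resid - np.median(resid)))
                keep = np.abs(resid - np.median(resid)) <= max(3 * 1.4826 * mad, 1.0)
                if keep.sum() > deg + 2 and not keep.all():
                    co_new = np.polyfit(t[keep], pv[keep], deg)
                co = np.concatenate([np.zeros(3 - co_new.size), co_new])

        # pass 2: re-search every column around a robust global model of the
        # pass-1 positions (iterated MAD rejection), which repairs any
        # capture by bright neighbouring structure
        ok = valid[k, cols] & np.isfinite(positions[k, cols])
        if ok.sum() >= 5:
            t = cols[ok].astype(float)
            base = np.zeros(t.size) if ref_idx is None else np.polyval(ref_track[ref_idx], t)
            co2 = robust_quad(t, positions[k, cols][ok] - base)
            for ic in cols:
                pred, vel = model_pred(ic, co2)
                pc = float(np.clip(pred, win, nz - win - 1))
                prof = sheared_profile(ic, pc, vel)
                half2 = 4
                lo = win - half2
                hi = win + half2 + 1
                j = _best_candidate(prof, lo, hi, 2 * axial_smooth + 2,
                                    prefer_deep=prefer_deep[k])
                refined = _refine_peak(prof, j, ramp_width=axial_smooth)
                positions[k, ic] = pc + (refined - win)
                valid[k, ic] = bool(
                    prof[j] >= 0.25 * amp_ref[k]
                    and abs(positions[k, ic] - pred) <= 3.0
                )
        # store this interface's robust absolute quadratic as a possible
        # reference for later interfaces
        okf = valid[k, cols] & np.isfinite(positions[k, cols])
        if okf.sum() >= 5:
            ref_track[k] = robust_quad(cols[okf].astype(float), positions[k, cols][okf])

    frac_ok = valid[:, cols].mean(axis=1)
    lost = [labels[k] for k in range(n_ifc) if frac_ok[k] < 0.5]
    if lost:
        raise SegmentationError(f"interfaces lost on > 50% of pupil A-scans: {lost}")
    return {"positions": positions, "valid": valid, "labels": tuple(labels)}


def fit_interfaces(detection: dict, x_positions: np.ndarray, axial_pitch_mm: float, *,
                   support_diameter: float = 3.5, center: float = 0.0) -> dict[str, SurfaceFit]:
    """Quadratic fit (in mm) for each detected interface."""
    fits = {}
    for k, label in enumerate(detection["labels"]):
        mask = detection["valid"][k]
        fits[label] = fit_surface_poly2(
            x_positions[mask], detection["positions"][k, mask] * axial_pitch_mm,
            support_diameter=support_diameter, center=center, label=label,
        )
    return fits


def align_bscans(volume: OctVolume, *, max_shift: int = 30,
                 min_correlation: float = 0.3) -> tuple[OctVolume, dict]:
    """Remove axial motion jitter between B-scans.

    Neighbouring B-scans are cross-correlated (2-D, on the central columns,
    lightly smoothed) to estimate the axial lag between them.  The lag
    sequence mixes true motion with the smooth anatomical curvature of the
    surfaces across the slow scan axis, so the cumulative lag curve is
    detrended with a quadratic (the shape of a conicoid sag) and only the
    high-frequency residual is applied as an integer shift per B-scan.
    B-scans whose best correlation is below ``min_correlation`` are flagged
    and left unshifted.
    """
    data = volume.data.copy()
    n, nz, nx = data.shape
    shifts = np.zeros(n, dtype=int)
    flagged = np.zeros(n, dtype=bool)
    if n < 3:
        out = OctVolume(
            data=data, scan=volume.scan, coordinate_state=volume.coordinate_state,
            axial_pitch_mm=volume.axial_pitch_mm,
            provenance=volume.provenance + ["align_bscans(identity)"],
            flagged=volume.flagged,
        )
        return out, {"shifts": shifts, "flagged": flagged}

    c_lo = max(nx // 2 - 12, 0)
    c_hi = min(nx // 2 + 13, nx)
    # corneal-peak profile per B-scan: deeper surfaces sag at different,
    # even opposite, rates across the slow axis, so only the first surface
    # gives a unimodal lag estimate
    profiles = uniform_filter1d(data[:, :, c_lo:c_hi].astype(float).mean(axis=2), 3, axis=1)

    def corneal_peak(p):
        pk, _ = find_peaks(p, prominence=0.2 * np.ptp(p))
        return int(pk[0]) if pk.size else None

    def pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        den = np.sqrt((a * a).sum() * (b * b).sum())
        return float((a * b).sum() / den) if den > 0 else -np.inf

    lags = np.arange(-max_shift, max_shift + 1)
    deltas = np.zeros(n)
    ok_pair = np.ones(n, dtype=bool)
    half_win = 20
    for i in range(1, n):
        cur, ref = profiles[i], profiles[i - 1]
        if cur.std() == 0 or ref.std() == 0:
            ok_pair[i] = False
            continue
        apex = corneal_peak(ref)
        if apex is None or apex - half_win - max_shift < 0 or apex + half_win + max_shift >= nz:
            ok_pair[i] = False
            continue
        ref_win = ref[apex - half_win:apex + half_win + 1]
        scores = np.array([
            pearson(cur[apex - half_win + l:apex + half_win + 1 + l], ref_win)
            for l in lags
        ])
        best = int(np.argmax(scores))
        if scores[best] < min_correlation:
            ok_pair[i] = False
            continue
        # sub-sample lag from the score parabola: integer-rounded deltas
        # would random-walk when accumulated
        deltas[i] = lags[best] + (_parabolic_refine(scores, best) - best)

    cumulative = np.cumsum(deltas)
    rows = np.arange(n, dtype=float)
    good = ok_pair.copy()
    trend = np.polyval(np.polyfit(rows[good], cumulative[good], 2), rows) if good.sum() > 3 \
        else cumulative
    residual = np.round(cumulative - trend).astype(int)
    residual = np.clip(residual, -max_shift, max_shift)

    for i in range(n):
        if not ok_pair[i] and i > 0:
            flagged[i] = True
            continue
        shift = int(residual[i])
        shifts[i] = shift
        if shift:
            rolled = np.roll(data[i], -shift, axis=0)
            if shift > 0:
                rolled[-shift:] = 0
            else:
                rolled[:-shift] = 0
            data[i] = rolled
    out = OctVolume(
        data=data, scan=volume.scan, coordinate_state=volume.coordinate_state,
        axial_pitch_mm=volume.axial_pitch_mm,
        provenance=volume.provenance + [f"align_bscans(nonzero={int((shifts != 0).sum())})"],
        flagged=volume.flagged,
    )
    return out, {"shifts": shifts, "flagged": flagged}
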