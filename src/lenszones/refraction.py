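"""Ray-tracing refraction correction of raw (optical-path) B-scans.

The raw B-scan records, in each A-scan column, optical path length (OPL)
along the refracted ray launched at that column.  Correction proceeds layer
by layer: the entry surface in air is geometric already; each deeper
interface is mapped to geometric coordinates by propagating every column's
ray through the previous medium over a geometric distance OPL-increment / n,
the mapped interface points are refitted with a 2nd-order polynomial in
corrected coordinates, the rays are Snell-refracted at that corrected
surface, and so on through the equivalent-index double-shell lens chain
(1, 1.3665, 1.3266, 1.3749, 1.3947, 1.3749, 1.3270).  The corrected image is
resampled onto a regular geometric grid (bilinear by default;
nearest-neighbour per-column for densitometry, which must not smooth
intensities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator

from .errors import CorrectionError, TotalInternalReflection
from .phantom import SURFACE_NAMES, MediaChain
from .render import CORRECTED_STATE, snell_3d
from .segmentation import SurfaceFit, fit_surface_poly2


@dataclass
class Ray:
    """A 2-D ray in the B-scan plane: origin (x, z) in mm, unit direction."""

    origin: tuple[float, float]
    direction: tuple[float, float]
    medium_index: float = 1.0

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-12:
            self.direction = tuple(d / n)


def snell_refract(direction, normal, n1: float, n2: float):
    """Vectorial Snell's law for unit vectors (2-D or 3-D).

    Raises TotalInternalReflection when the refraction discriminant is
    negative for any input ray.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    single = d.ndim == 1
    d2, n2v = np.atleast_2d(d), np.atleast_2d(np.broadcast_to(n, d.shape))
    refracted, tir = snell_3d(d2, n2v, n1, n2)
    if tir.any():
        raise TotalInternalReflection(f"TIR on {int(tir.sum())} ray(s) at n1={n1}, n2={n2}")
    return refracted[0] if single else refracted.reshape(d.shape)


def opl_to_geometric(opl_increment, n: float):
    """Geometric path length for an OPL increment in a medium of index n."""
    if n < 1:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    return np.asarray(opl_increment, dtype=float) / n


@dataclass
class CorrectionResult:
    """Corrected B-scan and the geometry that produced it."""

    bscan: np.ndarray
    corrected_fits: dict[str, SurfaceFit]
    corrected_points: dict[str, np.ndarray]  # (nx, 2) arrays of (x, z) mm
    axial_pitch_mm: float
    x_positions: np.ndarray
    flagged_columns: np.ndarray
    coordinate_state: str = CORRECTED_STATE
    log: list[str] = field(default_factory=list)


def _propagate_surfaces(fits: dict[str, SurfaceFit], media: MediaChain,
                        x: np.ndarray, *, support_diameter: float = 3.5,
                        raw_opl: dict[str, np.ndarray] | None = None,
                        measured_mask: dict[str, np.ndarray] | None = None):
    """Layer-by-layer mapping of all interfaces to geometric coordinates.

    Returns per-surface corrected point arrays, refits, per-column entry
    points/directions/OPL of every medium, and a flag mask for columns that
    failed (TIR)."""
    labels = [lb for lb in SURFACE_NAMES if lb in fits] or list(fits)
    indices = (
        list(media.indices) if isinstance(media, MediaChain) else [float(v) for v in media]
    )
    if len(indices) != len(labels) + 1:
        raise CorrectionError(
            f"media chain length {len(indices)} must be one more than the "
            f"{len(labels)} supplied surfaces"
        )
    nx = x.size
    flagged = np.zeros(nx, dtype=bool)

    # per-medium ray state: medium k is entered at surface k
    entry_pts = np.zeros((len(labels), nx, 2))
    entry_dirs = np.zeros((len(labels) + 1, nx, 2))
    entry_dirs[0, :, 1] = 1.0  # air: straight down
    entry_opl = np.zeros((len(labels), nx))

    corrected_points: dict[str, np.ndarray] = {}
    corrected_fits: dict[str, SurfaceFit] = {}

    prev_pts = np.stack([x, np.zeros(nx)], axis=1)
    prev_opl = np.zeros(nx)
    for k, label in enumerate(labels):
        n_before = indices[k]
        # per-column OPL depth of this interface: measured positions when
        # available (keeps the true surface shape), quadratic fit otherwise
        if raw_opl is not None and label in raw_opl:
            opl_here = np.asarray(raw_opl[label], dtype=float)
        else:
            opl_here = fits[label](x)
        d = entry_dirs[k]
        geom = (opl_here - prev_opl) / n_before
        neg = geom < 0
        if neg.any():
            flagged |= neg
            geom = np.clip(geom, 0.0, None)
        pts = prev_pts + d * geom[:, None]
        corrected_points[label] = pts
        # columns without a measured position carry extrapolated depths:
        # they may refract into the fit support but must not shape the fit
        if measured_mask is not None and label in measured_mask:
            fit_pts = pts[measured_mask[label]]
            in_zone = fit_pts[np.abs(fit_pts[:, 0]) <= support_diameter / 2]
            if in_zone.shape[0] < 10 or np.ptp(in_zone[:, 0]) < 0.9 * support_diameter:
                fit_pts = pts  # not enough measured span: accept all columns
        else:
            fit_pts = pts
        fit = fit_surface_poly2(fit_pts[:, 0], fit_pts[:, 1],
                                support_diameter=support_diameter, center=0.0,
                                label=label)
        corrected_fits[label] = fit
        # refract at the corrected surface
        slope = fit.slope(pts[:, 0])
        normal = np.stack([-slope, np.ones(nx)], axis=1)
        normal /= np.linalg.norm(normal, axis=1, keepdims=True)
        refracted, tir = snell_3d(d, normal, indices[k], indices[k + 1])
        flagged |= tir
        entry_pts[k] = pts
        entry_opl[k] = opl_here
        entry_dirs[k + 1] = np.where(tir[:, None], d, refracted)
        prev_pts, prev_opl = pts, opl_here
    return labels, corrected_points, corrected_fits, entry_pts, entry_dirs, entry_opl, flagged


def correct_bscan(bscan: np.ndarray, fits: dict[str, SurfaceFit], media: MediaChain,
                  *, axial_pitch_mm: float, x_positions: np.ndarray,
                  mode: str = "bilinear", support_diameter: float = 3.5,
                  raw_opl: dict[str, np.ndarray] | None = None,
                  measured_mask: dict[str, np.ndarray] | None = None) -> CorrectionResult:
    """Convert a raw (OPL) B-scan to geometric coordinates.

    ``fits`` maps surface labels (a front-to-back subset of the six standard
    interfaces) to their raw-coordinate quadratic fits; the media chain must
    have one more medium than there are absent-surface gaps.  ``mode``
    selects the output resampling: "bilinear" (scattered linear
    interpolation, for imaging/biometry) or "nearest" (per-column
    nearest-neighbour along the ray, intensity-preserving, for
    densitometry).
    """
    bscan = np.asarray(bscan, dtype=float)
    nz, nx = bscan.shape
    x = np.asarray(x_positions, dtype=float)
    if x.size != nx:
        raise CorrectionError(f"x grid size {x.size} != B-scan width {nx}")
    labels, cpoints, cfits, entry_pts, entry_dirs, entry_opl, flagged = _propagate_surfaces(
        fits, media, x, support_diameter=support_diameter, raw_opl=raw_opl,
        measured_mask=measured_mask,
    )
    indices = (
        list(media.indices) if isinstance(media, MediaChain) else [float(v) for v in media]
    )
    z_opl = np.arange(nz) * axial_pitch_mm
    n_surf = len(labels)

    # medium occupancy of every sample: number of interfaces already passed
    seg = (z_opl[None, :, None] >= entry_opl[:, None, :]).sum(axis=0)  # (nz, nx)

    gx = np.empty((nz, nx))
    gz = np.empty((nz, nx))
    air = seg == 0
    gx[air] = np.broadcast_to(x, (nz, nx))[air]
    gz[air] = np.broadcast_to(z_opl[:, None], (nz, nx))[air]
    for m in range(1, n_surf + 1):
        mask = seg == m
        if not mask.any():
            continue
        iz, ix = np.nonzero(mask)
        geom = (z_opl[iz] - entry_opl[m - 1, ix]) / indices[m]
        p = entry_pts[m - 1, ix] + entry_dirs[m][ix] * geom[:, None]
        gx[mask], gz[mask] = p[:, 0], p[:, 1]

    out = np.zeros_like(bscan)
    if mode == "nearest":
        # per-column inverse mapping along the column's own ray path;
        # valid near the axis where lateral ray walk is negligible
        z_out = z_opl
        for j in range(nx):
            zj = gz[:, j]
            order = np.argsort(zj)
            src = np.interp(z_out, zj[order], np.arange(nz)[order].astype(float),
                            left=np.nan, right=np.nan)
            ok = np.isfinite(src)
            out[ok, j] = bscan[np.round(src[ok]).astype(int), j]
    elif mode == "bilinear":
        pts = np.stack([gx.ravel(), gz.ravel()], axis=1)
        interp = LinearNDInterpolator(pts, bscan.ravel(), fill_value=0.0)
        gridx, gridz = np.meshgrid(x, z_opl)
        out = interp(np.stack([gridx.ravel(), gridz.ravel()], axis=1)).reshape(nz, nx)
    else:
        raise CorrectionError(f"unknown resampling mode {mode!r}")

    return CorrectionResult(
        bscan=out, corrected_fits=cfits, corrected_points=cpoints,
        axial_pitch_mm=axial_pitch_mm, x_positions=x, flagged_columns=flagged,
        log=[f"correct_bscan(mode={mode}, surfaces={labels})"],
    )
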