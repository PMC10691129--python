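"""Forward model: raster-scan OCT rendering of an EyePhantom.

A telecentric beam is assumed: every A-scan is a ray launched parallel to the
z axis.  The ray is refracted at each conicoid interface by vectorial Snell's
law and sample depth is *optical* path length (sum of n_k * geometric path),
so the raw volume shows the familiar refraction-distorted anterior segment.
Interfaces deposit narrow specular peaks; media deposit their mean
backscatter level, with the cortical level further subdivided into the OSD
zone layers.  Speckle is modelled as i.i.d. unit-mean exponential
multiplicative noise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .phantom import SURFACE_NAMES, EyePhantom

RAW_STATE = "raw-OPL"
CORRECTED_STATE = "corrected-geometric"

#: axial extent (samples) and width (samples) of a specular interface peak
PEAK_SIGMA = 1.0
PEAK_HALFWIDTH = 4


@dataclass(frozen=True)
class ScanGeometry:
    """Raster-scan geometry; defaults are the reference protocol
    (300 x 300 A-scans over 8 x 8 mm^2, 1500 axial samples of 8.9 um in air,
    i.e. 26.7 x 26.7 x 8.9 um^3 voxels)."""

    n_ascans_x: int = 300
    n_ascans_y: int = 300
    n_axial: int = 1500
    extent_mm: float = 8.0
    axial_pitch_um: float = 8.9
    #: air gap between the zero-delay reference plane and the corneal apex
    standoff_mm: float = 0.5

    def __post_init__(self):
        if min(self.n_ascans_x, self.n_ascans_y, self.n_axial) < 1:
            raise ValidationError("scan dimensions must be positive")
        if self.extent_mm <= 0 or self.axial_pitch_um <= 0:
            raise ValidationError("scan extent and axial pitch must be positive")

    @property
    def lateral_pitch_mm(self) -> float:
        return self.extent_mm / self.n_ascans_x

    @property
    def lateral_pitch_um(self) -> float:
        return 1e3 * self.lateral_pitch_mm

    @property
    def axial_pitch_mm(self) -> float:
        return self.axial_pitch_um * 1e-3

    def x_positions(self) -> np.ndarray:
        """Lateral A-scan centres (mm), centred on the scan axis."""
        return (np.arange(self.n_ascans_x) - (self.n_ascans_x - 1) / 2) * self.lateral_pitch_mm

    def y_positions(self) -> np.ndarray:
        return (np.arange(self.n_ascans_y) - (self.n_ascans_y - 1) / 2) * (
            self.extent_mm / self.n_ascans_y
        )

    def z_opl_mm(self) -> np.ndarray:
        return np.arange(self.n_axial) * self.axial_pitch_mm

    def to_dict(self) -> dict:
        return {
            "n_ascans_x": self.n_ascans_x,
            "n_ascans_y": self.n_ascans_y,
            "n_axial": self.n_axial,
            "extent_mm": self.extent_mm,
            "axial_pitch_um": self.axial_pitch_um,
            "standoff_mm": self.standoff_mm,
        }


@dataclass
class OctVolume:
    """3-D OCT intensity volume with scan metadata.

    ``data`` has shape (n_bscans_y, n_axial, n_ascans_x), float32 on a linear
    16-bit a.u. scale.  ``coordinate_state`` is raw-OPL after rendering and
    may only become corrected-geometric through the refraction module.
    """

    data: np.ndarray
    scan: ScanGeometry
    coordinate_state: str = RAW_STATE
    axial_pitch_mm: float | None = None
    provenance: list[str] = field(default_factory=list)
    flagged: np.ndarray | None = None

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3-D, got shape {self.data.shape}")
        if self.axial_pitch_mm is None:
            self.axial_pitch_mm = self.scan.axial_pitch_mm
        if np.any(self.data < 0):
            raise ValidationError("volume intensities must be >= 0")

    @property
    def n_bscans(self) -> int:
        return self.data.shape[0]

    def bscan(self, iy: int) -> np.ndarray:
        return self.data[iy]

    def central_bscan_index(self) -> int:
        return self.data.shape[0] // 2

    def sha256(self) -> str:
        return hashlib.sha256(np.ascontiguousarray(self.data).tobytes()).hexdigest()


@dataclass
class RayTrace:
    """Per-ray path through the six surfaces (arrays over n rays).

    ``opl`` (6, n): cumulative optical path length at each surface hit.
    ``points`` (6, n, 3): geometric hit coordinates.  ``dirs`` (7, n, 3):
    unit propagation direction in each medium (index 0 = air).
    ``flags`` (n,): True where the trace failed (TIR / no intersection).
    """

    opl: np.ndarray
    points: np.ndarray
    dirs: np.ndarray
    flags: np.ndarray


def snell_3d(d: np.ndarray, normal: np.ndarray, n1: float, n2: float):
    """Vectorial Snell refraction of unit direction(s) ``d`` at unit
    ``normal`` (oriented either way); returns (refracted, tir_mask)."""
    d = np.asarray(d, dtype=float)
    n = np.asarray(normal, dtype=float)
    cos_i = -np.sum(d * n, axis=-1, keepdims=True)
    n = np.where(cos_i < 0, -n, n)  # orient normal against the ray
    cos_i = np.abs(cos_i)
    eta = n1 / n2
    disc = 1.0 - eta**2 * (1.0 - cos_i**2)
    tir = disc[..., 0] < 0
    disc = np.clip(disc, 0.0, None)
    t = eta * d + (eta * cos_i - np.sqrt(disc)) * n
    norm = np.linalg.norm(t, axis=-1, keepdims=True)
    t = np.where(norm > 0, t / np.where(norm == 0, 1.0, norm), d)
    return t, tir


def _intersect(surface, origins, dirs, t_min):
    """Newton solve for ray/conicoid intersection distance t >= t_min."""
    ox, oy, oz = origins[:, 0], origins[:, 1], origins[:, 2]
    dx, dy, dz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    x0, y0 = surface.lateral_offset
    t = np.where(np.abs(dz) > 1e-9, (surface.apex_z - oz) / np.where(dz == 0, 1.0, dz), t_min)
    t = np.maximum(t, t_min)
    for _ in range(40):
        px, py, pz = ox + t * dx, oy + t * dy, oz + t * dz
        rho = np.hypot(px - x0, py - y0)
        f = pz - surface.apex_z - surface.sag(rho)
        slope = surface.sag_slope(rho)
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(rho > 0, (px - x0) / np.where(rho == 0, 1.0, rho), 0.0)
            uy = np.where(rho > 0, (py - y0) / np.where(rho == 0, 1.0, rho), 0.0)
        df = dz - slope * (ux * dx + uy * dy)
        df = np.where(np.abs(df) < 1e-9, 1e-9, df)
        step = f / df
        t = t - step
        if np.all(np.abs(step) < 1e-12):
            break
    converged = np.abs(step) < 1e-6
    t = np.maximum(t, t_min)
    return t, ~converged


def trace_rays(phantom: EyePhantom, x: np.ndarray, y: np.ndarray,
               z0: float = 0.0) -> RayTrace:
    """Trace telecentric rays entering at lateral positions (x, y), z = z0
    (the zero-delay reference plane; OPL is accumulated from there)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.broadcast_to(np.atleast_1d(np.asarray(y, dtype=float)), x.shape).copy()
    n = x.size
    origins = np.stack([x, y, np.full(n, float(z0))], axis=1)
    d = np.zeros((n, 3))
    d[:, 2] = 1.0
    indices = phantom.media.indices

    opl = np.zeros((6, n))
    points = np.zeros((6, n, 3))
    dirs = np.zeros((7, n, 3))
    dirs[0] = d
    flags = np.zeros(n, dtype=bool)
    t_prev = np.zeros(n)
    opl_prev = np.zeros(n)
    p_prev = origins
    for i, name in enumerate(SURFACE_NAMES):
        surf = phantom.surfaces[name]
        t, bad = _intersect(surf, p_prev, dirs[i], t_min=0.0)
        flags |= bad
        # clamp: never step backwards (zero-thickness media near the equator)
        t = np.maximum(t, 0.0)
        p = p_prev + t[:, None] * dirs[i]
        opl_here = opl_prev + indices[i] * t
        points[i] = p
        opl[i] = opl_here

        x0, y0 = surf.lateral_offset
        rho = np.hypot(p[:, 0] - x0, p[:, 1] - y0)
        slope = surf.sag_slope(rho)
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(rho > 0, (p[:, 0] - x0) / np.where(rho == 0, 1.0, rho), 0.0)
            uy = np.where(rho > 0, (p[:, 1] - y0) / np.where(rho == 0, 1.0, rho), 0.0)
        normal = np.stack([-slope * ux, -slope * uy, np.ones(n)], axis=1)
        normal /= np.linalg.norm(normal, axis=1, keepdims=True)
        refracted, tir = snell_3d(dirs[i], normal, indices[i], indices[i + 1])
        flags |= tir
        dirs[i + 1] = refracted
        t_prev, opl_prev, p_prev = t, opl_here, p
    # enforce monotone OPL ordering (zero-thickness clamp)
    opl = np.maximum.accumulate(opl, axis=0)
    return RayTrace(opl=opl, points=points, dirs=dirs, flags=flags)


def _zone_levels(phantom: EyePhantom):
    z = phantom.reflectivity.zones
    ant = np.array([z["c1a"], z["c1b"], z["c2"], z["c3"], z["c4"]])
    post = ant[::-1]
    return ant, post


def _render_bscan(phantom: EyePhantom, scan: ScanGeometry, y: float) -> tuple[np.ndarray, np.ndarray]:
    """Render one B-scan (n_axial, n_ascans_x) at scan row position y (mm)."""
    xs = scan.x_positions()
    nx, nz = xs.size, scan.n_axial
    trace = trace_rays(phantom, xs, np.full(nx, y), z0=-scan.standoff_mm)
    z_opl = scan.z_opl_mm()
    pitch = scan.axial_pitch_mm
    refl = phantom.reflectivity
    indices = phantom.media.indices

    # media occupancy per sample: number of surfaces already passed
    seg = (z_opl[None, :, None] >= trace.opl[:, None, :]).sum(axis=0)  # (nz, nx)
    base_levels = np.array([
        refl.media_background["air"],
        refl.media_background["cornea"],
        refl.media_background["aqueous"],
        0.0,  # anterior cortex: zone-resolved below
        refl.zones["nucleus"],
        0.0,  # posterior cortex
        refl.media_background["vitreous"],
    ])
    img = base_levels[seg]

    ant_levels, post_levels = _zone_levels(phantom)
    cum_ant = np.cumsum(phantom.zone_fractions_ant)
    cum_post = np.cumsum(phantom.zone_fractions_post)
    surf = [phantom.surfaces[nm] for nm in SURFACE_NAMES]
    for s_idx, (top_i, bot_i, cum, levels) in (
        (3, (2, 3, cum_ant, ant_levels)),
        (5, (4, 5, cum_post, post_levels)),
    ):
        top_i, bot_i, cum, levels = top_i, bot_i, cum, levels
        mask = seg == s_idx
        if not mask.any():
            continue
        iz, ix = np.nonzero(mask)
        opl_entry = trace.opl[s_idx - 1, ix]
        geom = (z_opl[iz] - opl_entry) / indices[s_idx]
        p = trace.points[s_idx - 1, ix] + trace.dirs[s_idx][ix] * geom[:, None]
        z_top = surf[top_i].height(p[:, 0], p[:, 1])
        z_bot = surf[bot_i].height(p[:, 0], p[:, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (p[:, 2] - z_top) / np.where(z_bot - z_top <= 0, 1.0, z_bot - z_top)
        f = np.clip(f, 0.0, 1.0 - 1e-12)
        zone_idx = np.minimum(np.searchsorted(cum, f, side="right"), 4)
        img[iz, ix] = levels[zone_idx]

    # specular interface peaks (Gaussian, sigma 1 sample)
    peak_amp = refl.interface_peaks
    for i, name in enumerate(SURFACE_NAMES):
        centre = trace.opl[i] / pitch  # (nx,) fractional sample index
        lo = np.floor(centre).astype(int) - PEAK_HALFWIDTH
        offs = np.arange(2 * PEAK_HALFWIDTH + 2)
        idx = lo[None, :] + offs[:, None]  # (w, nx)
        valid = (idx >= 0) & (idx < nz)
        gauss = peak_amp[name] * np.exp(-0.5 * ((idx - centre[None, :]) / PEAK_SIGMA) ** 2)
        np.add.at(img, (np.clip(idx, 0, nz - 1), np.broadcast_to(np.arange(nx), idx.shape)),
                  np.where(valid, gauss, 0.0))

    # failed rays carry no signal beyond the cornea
    if trace.flags.any():
        bad = np.nonzero(trace.flags)[0]
        img[:, bad] = 0.0
    return img.astype(np.float32), trace.flags


def render_volume(phantom: EyePhantom, scan: ScanGeometry | None = None, *,
                  speckle: bool = False, seed=None,
                  y_rows: np.ndarray | None = None) -> OctVolume:
    """Render a raw (optical-path coordinate) OCT volume of the phantom.

    ``y_rows`` optionally restricts rendering to a subset of B-scan row
    indices (e.g. only the central B-scan); the output volume then has that
    many pages.  Speckle requires a seed.
    """
    scan = scan or ScanGeometry()
    ys = scan.y_positions()
    if y_rows is None:
        y_rows = np.arange(ys.size)
    y_rows = np.asarray(y_rows, dtype=int)
    data = np.empty((y_rows.size, scan.n_axial, scan.n_ascans_x), dtype=np.float32)
    flags = np.zeros((y_rows.size, scan.n_ascans_x), dtype=bool)
    for k, iy in enumerate(y_rows):
        data[k], flags[k] = _render_bscan(phantom, scan, ys[iy])
    vol = OctVolume(
        data=data, scan=scan, coordinate_state=RAW_STATE,
        provenance=[f"render_volume(rows={y_rows.size}, speckle={speckle}, seed={seed})"],
        flagged=flags,
    )
    if speckle:
        if seed is None:
            raise ValidationError("speckle rendering requires an explicit seed")
        vol = add_speckle(vol, seed)
    return vol


def add_speckle(volume: OctVolume, seed) -> OctVolume:
    """Multiply intensities by i.i.d. unit-mean exponential variates.

    The expected value of every voxel is preserved; a zero voxel stays zero.
    """
    if seed is None:
        raise ValidationError("add_speckle requires an explicit seed")
    rng = np.random.default_rng(seed)
    out = np.empty_like(volume.data)
    for iy in range(volume.data.shape[0]):  # chunked to bound memory
        out[iy] = volume.data[iy] * rng.exponential(1.0, size=volume.data.shape[1:]).astype(np.float32)
    return OctVolume(
        data=out, scan=volume.scan, coordinate_state=volume.coordinate_state,
        axial_pitch_mm=volume.axial_pitch_mm,
        provenance=volume.provenance + [f"add_speckle(seed={seed})"],
        flagged=volume.flagged,
    )
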