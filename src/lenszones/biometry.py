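"""Lens biometry from refraction-corrected surfaces.

Radii of curvature follow the study convention: the apical radius is
1/(2|a|) of the 2nd-order polynomial restricted to the central 3.5 mm
region, reported as a magnitude with an orientation flag.  Central
thicknesses are measured along the apex axis, the line connecting the
anterior and posterior lens apices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import ValidationError
from .segmentation import SurfaceFit, fit_surface_poly2

PLANAR_CURVATURE = 1e-6  # mm^-1; below this the surface is reported planar


@dataclass(frozen=True)
class ApexAxis:
    """Line through the anterior and posterior lens apices: x(z) = x0 + s*(z - z0)."""

    x_ant: float
    z_ant: float
    x_post: float
    z_post: float

    @property
    def slope(self) -> float:
        dz = self.z_post - self.z_ant
        return (self.x_post - self.x_ant) / dz if dz != 0 else 0.0

    def x_at(self, z: float) -> float:
        return self.x_ant + self.slope * (z - self.z_ant)


@dataclass(frozen=True)
class BiometryResult:
    """Radii (mm, magnitudes) and central thicknesses (mm) of one eye."""

    radius_lens_ant: float
    radius_nucleus_ant: float
    radius_nucleus_post: float
    radius_lens_post: float
    thickness_lens: float
    thickness_cortex: float
    thickness_nucleus: float
    axis: ApexAxis

    def as_dict(self) -> dict:
        return {
            "radius_lens_ant": self.radius_lens_ant,
            "radius_nucleus_ant": self.radius_nucleus_ant,
            "radius_nucleus_post": self.radius_nucleus_post,
            "radius_lens_post": self.radius_lens_post,
            "thickness_lens": self.thickness_lens,
            "thickness_cortex": self.thickness_cortex,
            "thickness_nucleus": self.thickness_nucleus,
        }


def apex_axis(fit_ant: SurfaceFit, fit_post: SurfaceFit, *,
              decentration_warn_mm: float = 1.0) -> ApexAxis:
    """Axis through the two lens apex points of the quadratic fits."""
    ax = ApexAxis(
        x_ant=fit_ant.apex_x, z_ant=fit_ant.apex_z,
        x_post=fit_post.apex_x, z_post=fit_post.apex_z,
    )
    if abs(ax.x_post - ax.x_ant) > decentration_warn_mm:
        warnings.warn(
            f"lens apices laterally separated by {abs(ax.x_post - ax.x_ant):.2f} mm "
            "(decentration)", stacklevel=2,
        )
    return ax


def radius_of_curvature(fit: SurfaceFit, *, zone_diameter: float = 3.5,
                        points=None) -> float:
    """Apical radius magnitude 1/(2|a|) within the central zone.

    When the raw ``points`` (x, z arrays) are supplied and the fit support
    exceeds the zone, the quadratic is refitted restricted to
    ``zone_diameter`` around the apex first.  Planar surfaces
    (|a| < 1e-6 mm^-1) are reported as ``math.inf``.
    """
    # slack: refraction contracts the lateral span of deep surfaces ~6%,
    # plus one grid pitch
    if fit.support_width < 0.9 * zone_diameter:
        raise ValidationError(
            f"fit support {fit.support_width:.2f} mm smaller than the "
            f"{zone_diameter} mm measurement zone for {fit.label or 'surface'}"
        )
    a = fit.a
    if points is not None and fit.support_width > zone_diameter + 1e-9:
        x, z = points
        refit = fit_surface_poly2(x, z, support_diameter=zone_diameter,
                                  center=fit.apex_x, label=fit.label)
        a = refit.a
    if abs(a) < 0.5 * PLANAR_CURVATURE:
        return math.inf
    return 1.0 / (2.0 * abs(a))


def _axis_intersection(fit: SurfaceFit, axis: ApexAxis) -> tuple[float, float]:
    """Intersection (x, z) of the near-vertical apex axis with a quadratic."""
    z = fit.apex_z
    for _ in range(20):
        x = axis.x_at(z)
        z_new = float(fit(x))
        if abs(z_new - z) < 1e-12:
            z = z_new
            break
        z = z_new
    return axis.x_at(z), z


def central_thickness(fit_front: SurfaceFit, fit_back: SurfaceFit, axis: ApexAxis) -> float:
    """Axial distance between two surfaces along the apex axis (mm)."""
    xf, zf = _axis_intersection(fit_front, axis)
    xb, zb = _axis_intersection(fit_back, axis)
    if zb < zf - 1e-9:
        raise ValidationError(
            f"surfaces cross along the axis: {fit_front.label}@{zf:.3f} mm "
            f"behind {fit_back.label}@{zb:.3f} mm"
        )
    return math.hypot(xb - xf, zb - zf)


def measure_biometry(corrected_fits: dict[str, SurfaceFit], *,
                     corrected_points: dict | None = None,
                     zone_diameter: float = 3.5) -> BiometryResult:
    """Full biometry from the four corrected lens-surface fits.

    Thicknesses are measured along the apex axis from the same intersection
    points, so lens = cortex + nucleus holds exactly.
    """
    needed = ("lens_ant", "nucleus_ant", "nucleus_post", "lens_post")
    missing = [s for s in needed if s not in corrected_fits]
    if missing:
        raise ValidationError(f"biometry needs corrected fits for {missing}")
    ax = apex_axis(corrected_fits["lens_ant"], corrected_fits["lens_post"])

    def rad(label):
        pts = None
        if corrected_points is not None and label in corrected_points:
            arr = corrected_points[label]
            pts = (arr[:, 0], arr[:, 1])
        return radius_of_curvature(corrected_fits[label], zone_diameter=zone_diameter,
                                   points=pts)

    t_lens = central_thickness(corrected_fits["lens_ant"], corrected_fits["lens_post"], ax)
    t_nuc = central_thickness(corrected_fits["nucleus_ant"], corrected_fits["nucleus_post"], ax)
    return BiometryResult(
        radius_lens_ant=rad("lens_ant"),
        radius_nucleus_ant=rad("nucleus_ant"),
        radius_nucleus_post=rad("nucleus_post"),
        radius_lens_post=rad("lens_post"),
        thickness_lens=t_lens,
        thickness_cortex=t_lens - t_nuc,
        thickness_nucleus=t_nuc,
        axis=ax,
    )
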