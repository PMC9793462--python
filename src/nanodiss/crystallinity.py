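"""Solid-state estimators for nanocrystal amorphicity and crystallite size.

A crystal's outermost unit-cell layers cannot carry the full lattice
order of the bulk; for nanoparticles this surface layer is a significant
volume fraction. A core-shell model of concentric spheres — amorphous
shell of thickness Z unit-cell diameters around a crystalline core —
gives the intrinsic surface amorphicity of a particle of diameter x:

    AM(x) = 100 (1 - ((x - 2 Z D_cell) / x)^3)   [%],

capped at 100% once the shell consumes the whole particle. Weighted over
a volume-based PSD, this yields the minimum amorphous content expected
purely from particle size. The module also provides the Scherrer
crystallite size from XRPD peak broadening, an ordinary-least-squares
XRPD calibration line (baseline intensity vs crystalline mass fraction)
with prediction intervals, and the semilog detection-limit extrapolation
of peak height vs particle size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, GeometryError, RegressionError, ValidationError
from .psd import DiscretePSD

__all__ = [
    "UnitCell",
    "unit_cell_volume",
    "effective_cell_diameter",
    "solve_cell_diameter",
    "core_shell_amorphicity",
    "psd_amorphicity",
    "scherrer_size",
    "XRPDCalibration",
    "fit_xrpd_calibration",
    "predict_crystallinity",
    "amorphous_content",
    "detection_limit_size",
]

#: Effective unit-cell diameter of the reference compound, m. The cell
#: parameters themselves are proprietary; this value is solved in closed
#: form from the core-shell model at the (x = 20 nm, Z = 1, AM = 28.5%)
#: reference point (see :func:`solve_cell_diameter`) and is consistent
#: with the reported "three unit cells span about 3.3 nm".
DEFAULT_CELL_DIAMETER = 1.058e-9

#: Cu K-alpha wavelength, m.
CU_KALPHA = 1.5406e-10

#: Dimensionless Scherrer shape factor for near-spherical crystallites.
DEFAULT_SHAPE_FACTOR = 0.9


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: axes in m, angles in radians."""

    a: float
    b: float
    c: float
    alpha: float = math.pi / 2
    beta: float = math.pi / 2
    gamma: float = math.pi / 2

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValidationError("unit cell axes must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < math.pi:
                raise GeometryError("unit cell angles must lie in (0, pi)")

    @property
    def volume(self) -> float:
        """Cell volume, m^3."""
        return unit_cell_volume(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def effective_diameter(self) -> float:
        """Diameter of the sphere with the cell's volume, m."""
        return effective_cell_diameter(self.volume)


def unit_cell_volume(a, b, c, alpha, beta, gamma) -> float:
    """General triclinic cell volume V = abc sqrt(1 - cos^2 a - cos^2 b
    - cos^2 g + 2 cos a cos b cos g); angles in radians."""
    if not (a > 0 and b > 0 and c > 0):
        raise GeometryError("cell axes must be positive")
    ca, cb, cg = math.cos(alpha), math.cos(beta), math.cos(gamma)
    disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if disc <= 0:
        raise GeometryError(f"degenerate cell geometry (discriminant {disc:.3g} <= 0)")
    return a * b * c * math.sqrt(disc)


def effective_cell_diameter(v_cell: float) -> float:
    """Diameter of a sphere of volume ``v_cell``, m."""
    if not v_cell > 0:
        raise GeometryError("cell volume must be positive")
    return (6.0 * v_cell / math.pi) ** (1.0 / 3.0)


def solve_cell_diameter(x: float, z: int, amorphicity_percent: float) -> float:
    """Invert the core-shell model for D_cell given one (x, Z, AM) point.

    D_cell = x (1 - (1 - AM/100)^(1/3)) / (2 Z); used to calibrate the
    effective cell diameter when the true unit cell is unavailable.
    """
    if not (x > 0 and z >= 1 and 0 < amorphicity_percent < 100):
        raise DomainError("need x > 0, Z >= 1 and amorphicity strictly inside (0, 100)%")
    core = (1.0 - amorphicity_percent / 100.0) ** (1.0 / 3.0)
    return x * (1.0 - core) / (2.0 * z)


def core_shell_amorphicity(x, z: int, d_cell: float = DEFAULT_CELL_DIAMETER):
    """Intrinsic surface amorphicity of spherical particles, percent.

    ``x`` is the particle diameter (scalar or array, m), ``z`` the shell
    depth in unit-cell layers, ``d_cell`` the effective unit-cell
    diameter (m). Particles smaller than the shell (x <= 2 Z D_cell) are
    fully amorphous (100%). Z = 0 means no shell, hence 0%.
    """
    if z < 0 or int(z) != z:
        raise ValidationError(f"layer count Z must be a nonnegative integer, got {z!r}")
    if not d_cell > 0:
        raise ValidationError(f"cell diameter must be positive, got {d_cell!r}")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("particle size must be strictly positive")
    core = np.clip((x - 2.0 * z * d_cell) / x, 0.0, None)
    am = 100.0 * (1.0 - core**3)
    if am.ndim == 0:
        return float(am)
    return am


def psd_amorphicity(
    dpsd: DiscretePSD, z: int, d_cell: float = DEFAULT_CELL_DIAMETER
) -> float:
    """Volume-fraction-weighted mean surface amorphicity of a PSD, percent."""
    per_class = core_shell_amorphicity(dpsd.class_sizes, z, d_cell)
    return float(np.dot(dpsd.volume_fractions, per_class))


def scherrer_size(
    fwhm_rad: float,
    two_theta_deg: float,
    wavelength: float = CU_KALPHA,
    shape_factor: float = DEFAULT_SHAPE_FACTOR,
) -> float:
    """Scherrer crystallite size tau = K lambda / (beta cos theta), m.

    ``fwhm_rad`` is the peak full width at half maximum in radians,
    ``two_theta_deg`` the peak position in degrees 2-theta.
    """
    if not fwhm_rad > 0:
        raise DomainError("peak width must be strictly positive (zero width means infinite size)")
    if not 0 < two_theta_deg < 180:
        raise DomainError("2-theta must lie in (0, 180) degrees")
    theta = math.radians(two_theta_deg / 2.0)
    return shape_factor * wavelength / (fwhm_rad * math.cos(theta))


@dataclass(frozen=True)
class XRPDCalibration:
    """OLS calibration line: baseline intensity = slope * w_cryst + intercept.

    ``w_cryst`` is the crystalline mass fraction in percent (0-100);
    intensities in whatever unit the diffractometer reports (cps).
    ``residual_sd`` is the regression standard error; prediction
    intervals use the t-distribution with ``dof`` degrees of freedom.
    """

    slope: float
    intercept: float
    residual_sd: float
    dof: int
    w_mean: float
    s_ww: float  # sum of squared centered fractions
    n_points: int

    def intensity(self, w_cryst: float) -> float:
        return self.slope * w_cryst + self.intercept


def fit_xrpd_calibration(points) -> XRPDCalibration:
    """Fit the intensity-vs-crystallinity calibration line by OLS.

    ``points`` is an iterable of (crystalline mass fraction %, intensity)
    pairs; at least 2 points (3+ for meaningful confidence intervals),
    fractions in [0, 100].
    """
    pts = [(float(w), float(i)) for w, i in points]
    if len(pts) < 2:
        raise RegressionError("at least two calibration points are required")
    w = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.any((w < 0) | (w > 100)):
        raise ValidationError("crystalline fractions must lie in [0, 100] percent")
    if np.unique(w).size < 2:
        raise RegressionError("calibration points are vertical (all at one fraction)")
    slope, intercept = np.polyfit(w, y, 1)
    resid = y - (slope * w + intercept)
    dof = len(pts) - 2
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return XRPDCalibration(
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=residual_sd,
        dof=dof,
        w_mean=float(w.mean()),
        s_ww=float(((w - w.mean()) ** 2).sum()),
        n_points=len(pts),
    )


def predict_crystallinity(
    cal: XRPDCalibration, intensity: float, confidence: float = 0.95
) -> tuple[float, float]:
    """Invert the calibration line: crystalline mass fraction % +/- CI.

    Returns (w_cryst, half-width of the ``confidence`` prediction
    interval, both in percent). The interval is the standard OLS
    prediction interval for a new observation, propagated through the
    line inversion via the slope.
    """
    if cal.slope == 0:
        raise RegressionError("calibration line has zero slope; cannot invert")
    w = (intensity - cal.intercept) / cal.slope
    if cal.dof > 0 and cal.residual_sd > 0:
        t = stats.t.ppf(0.5 + confidence / 2.0, cal.dof)
        se = cal.residual_sd * math.sqrt(
            1.0 + 1.0 / cal.n_points + (w - cal.w_mean) ** 2 / cal.s_ww
        )
        half = t * se / abs(cal.slope)
    else:
        half = 0.0
    return float(w), float(half)


def amorphous_content(w_cryst_percent: float) -> float:
    """Amorphous mass fraction, percent: w_amorph = 100 - w_cryst."""
    return 100.0 - w_cryst_percent


def detection_limit_size(points) -> float:
    """Extrapolate the particle size at which a diffraction peak vanishes.

    ``points`` are (particle size m, peak height) pairs. A least-squares
    line of peak height against log10(size) is fitted; its root
    10^(-intercept/slope) estimates the size below which the peak merges
    into the amorphous background. The slope must be positive (peaks
    grow with size).
    """
    pts = [(float(s), float(h)) for s, h in points]
    if len(pts) < 2:
        raise RegressionError("at least two (size, height) points are required")
    sizes = np.array([p[0] for p in pts])
    heights = np.array([p[1] for p in pts])
    if np.any(sizes <= 0):
        raise ValidationError("particle sizes must be strictly positive")
    if np.unique(sizes).size < 2:
        raise RegressionError("all points share one size; line is vertical")
    slope, intercept = np.polyfit(np.log10(sizes), heights, 1)
    if slope <= 0:
        raise RegressionError(
            "fitted peak height decreases with size; no physical detection limit"
        )
    return float(10.0 ** (-intercept / slope))
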