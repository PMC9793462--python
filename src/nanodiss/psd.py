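"""Log-normal volume-based particle size distributions and their discretization.

Photon-correlation sizing of nanosuspensions is reported as volume-based
(Q3) percentiles. A log-normal distribution is fitted through the
percentiles in probit space, and the continuous distribution is then
discretized into n equal-volume classes (999 by default, i.e. classes
placed at the 0.1%, 0.2%, ..., 99.9% volume quantiles) for the
population-balance dissolution engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError, DomainError

__all__ = [
    "LogNormalPSD",
    "DiscretePSD",
    "fit_lognormal",
    "discretize",
    "attach_mass",
    "read_percentiles_csv",
    "write_classes_csv",
]

DEFAULT_CLASSES = 999


@dataclass(frozen=True)
class LogNormalPSD:
    """Volume-based log-normal particle size distribution.

    Parameters
    ----------
    median : float
        Volume median diameter x50 (the x_50,3 percentile), m.
    sigma : float
        Standard deviation of ln(x), dimensionless.
    """

    median: float
    sigma: float

    def __post_init__(self):
        if not (np.isfinite(self.median) and self.median > 0):
            raise ValidationError(f"median must be positive, got {self.median!r}")
        if not (np.isfinite(self.sigma) and self.sigma >= 0):
            raise ValidationError(f"sigma must be nonnegative, got {self.sigma!r}")

    def quantile(self, q):
        """Size at cumulative volume fraction ``q``: x = x50 exp(sigma probit(q))."""
        q = np.asarray(q, dtype=float)
        if np.any((q <= 0) | (q >= 1)):
            raise DomainError("quantile must lie strictly inside (0, 1)")
        x = self.median * np.exp(self.sigma * norm.ppf(q))
        if x.ndim == 0:
            return float(x)
        return x

    def mean_inverse_size(self) -> float:
        """Analytic volume-weighted mean of 1/x: exp(-ln x50 + sigma^2/2)."""
        return math.exp(-math.log(self.median) + self.sigma**2 / 2.0)


@dataclass(frozen=True)
class DiscretePSD:
    """Equal-volume-fraction discretization of a PSD into n size classes.

    ``class_sizes`` are strictly increasing diameters (m), each carrying
    volume fraction 1/n. ``particle_counts`` is populated once a total
    solid mass is attached (see :func:`attach_mass`) and is held constant
    during dissolution: particles shrink but never leave their class.
    """

    class_sizes: np.ndarray
    volume_fractions: np.ndarray
    particle_counts: np.ndarray | None = field(default=None)

    def __post_init__(self):
        sizes = np.asarray(self.class_sizes, dtype=float)
        fractions = np.asarray(self.volume_fractions, dtype=float)
        object.__setattr__(self, "class_sizes", sizes)
        object.__setattr__(self, "volume_fractions", fractions)
        if sizes.ndim != 1 or sizes.size < 1:
            raise ValidationError("class_sizes must be a nonempty 1-D array")
        if np.any(sizes <= 0):
            raise ValidationError("class sizes must be strictly positive")
        if np.any(np.diff(sizes) < 0):
            raise ValidationError("class sizes must be nondecreasing")
        if fractions.shape != sizes.shape:
            raise ValidationError("volume_fractions must match class_sizes in shape")
        if abs(fractions.sum() - 1.0) > 1e-12:
            raise ValidationError("volume fractions must sum to 1")
        if self.particle_counts is not None:
            counts = np.asarray(self.particle_counts, dtype=float)
            object.__setattr__(self, "particle_counts", counts)
            if counts.shape != sizes.shape or np.any(counts < 0):
                raise ValidationError("particle_counts must be nonnegative and match shape")

    @property
    def n_classes(self) -> int:
        return int(self.class_sizes.size)

    def to_frame(self) -> pd.DataFrame:
        """Class table with sizes in nm, one row per class."""
        return pd.DataFrame(
            {
                "class": np.arange(1, self.n_classes + 1),
                "size_nm": self.class_sizes * 1e9,
                "volume_fraction": self.volume_fractions,
            }
        )


def fit_lognormal(percentiles) -> LogNormalPSD:
    """Fit a log-normal PSD through volume-based percentile points.

    Parameters
    ----------
    percentiles : iterable of (quantile, size)
        At least two distinct points, quantiles in (0, 1), sizes in m
        (any consistent length unit works; the median is returned in the
        same unit).

    The fit is an unweighted least-squares line in (probit(q), ln x)
    space; it is exact when the points lie on a log-normal. The slope is
    sigma and the intercept at q = 0.5 the log of the median.
    """
    pts = [(float(q), float(x)) for q, x in percentiles]
    if len(pts) < 2:
        raise ValidationError("at least two percentile points are required")
    qs = np.array([p[0] for p in pts])
    xs = np.array([p[1] for p in pts])
    if np.any((qs <= 0) | (qs >= 1)):
        raise ValidationError("quantiles must lie strictly inside (0, 1)")
    if np.any(xs <= 0):
        raise ValidationError("sizes must be strictly positive")
    if np.unique(qs).size < 2:
        raise ValidationError("at least two distinct quantiles are required")
    probits = norm.ppf(qs)
    slope, intercept = np.polyfit(probits, np.log(xs), 1)
    if slope < 0:
        raise ValidationError(
            "sizes decrease with quantile; not a valid cumulative distribution"
        )
    return LogNormalPSD(median=float(np.exp(intercept)), sigma=float(slope))


def discretize(psd: LogNormalPSD, n: int = DEFAULT_CLASSES) -> DiscretePSD:
    """Discretize a log-normal PSD into ``n`` equal-volume classes.

    Class k (k = 1..n) sits at the volume quantile k/(n+1), so the
    default n = 999 places classes at the 0.1%, 0.2%, ..., 99.9%
    percentiles. Every class carries volume fraction 1/n.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValidationError(f"number of classes must be a positive integer, got {n!r}")
    ks = np.arange(1, n + 1, dtype=float)
    sizes = psd.median * np.exp(psd.sigma * norm.ppf(ks / (n + 1)))
    fractions = np.full(n, 1.0 / n)
    return DiscretePSD(class_sizes=sizes, volume_fractions=fractions)


def attach_mass(dpsd: DiscretePSD, m_total: float, rho: float) -> DiscretePSD:
    """Attach a total solid mass and derive per-class particle counts.

    Each class receives mass m_i = w_i m_total; with spherical particles
    the (generally fractional) particle count is
    N_i = m_i / (rho pi/6 x_i^3). Counts stay fixed during dissolution.
    """
    if not m_total > 0:
        raise ValidationError(f"total mass must be positive, got {m_total!r}")
    if not rho > 0:
        raise ValidationError(f"density must be positive, got {rho!r}")
    class_masses = dpsd.volume_fractions * m_total
    particle_mass = rho * (math.pi / 6.0) * dpsd.class_sizes**3
    counts = class_masses / particle_mass
    return DiscretePSD(
        class_sizes=dpsd.class_sizes.copy(),
        volume_fractions=dpsd.volume_fractions.copy(),
        particle_counts=counts,
    )


def read_percentiles_csv(path) -> list[tuple[float, float]]:
    """Read a percentile table with columns ``quantile`` and ``size_nm``.

    Returns (quantile, size in m) pairs ready for :func:`fit_lognormal`.
    """
    df = pd.read_csv(path)
    missing = {"quantile", "size_nm"} - set(df.columns)
    if missing:
        raise ValidationError(f"percentile CSV is missing columns: {sorted(missing)}")
    return [(float(q), float(s) * 1e-9) for q, s in zip(df["quantile"], df["size_nm"])]


def write_classes_csv(dpsd: DiscretePSD, path) -> None:
    """Write the class table (class, size_nm, volume_fraction) to CSV."""
    dpsd.to_frame().to_csv(path, index=False)
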