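"""Synthetic fixtures with known ground truth.

Everything the package consumes can be generated here without any
external data: exact log-normal percentile tables (for PSD fitting
round-trips) and pseudo-experimental apparent-solubility datasets
produced by running the dissolution engine at a known interfacial energy
and perturbing the equilibrium concentrations with seeded multiplicative
Gaussian noise. The noise model mirrors the few-percent duplicate-assay
spread typical of HPLC solubility determinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import SimulationCache, SolubilityMeasurement
from .errors import ValidationError
from .physchem import CompoundMedium
from .psd import LogNormalPSD

__all__ = ["SyntheticSpec", "make_psd_percentiles", "make_solubility_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a pseudo-experimental solubility dataset.

    ``psds`` are the (median m, sigma) pairs to simulate; each is paired
    elementwise with a (mass kg, volume m^3) scenario from
    ``scenarios`` (a single scenario is broadcast to all PSDs).
    ``true_sigma_sl`` (J/m^2) is the ground-truth interfacial energy and
    ``noise_sd`` the relative SD of the multiplicative Gaussian noise
    applied to each simulated equilibrium concentration.
    """

    seed: int
    psds: tuple[tuple[float, float], ...]
    true_sigma_sl: float
    noise_sd: float = 0.03
    scenarios: tuple[tuple[float, float], ...] = ((0.25e-3, 1e-3),)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError(f"noise SD must be nonnegative, got {self.noise_sd!r}")
        if not self.true_sigma_sl > 0:
            raise ValidationError("true interfacial energy must be positive")
        if not self.psds:
            raise ValidationError("at least one PSD is required")


def make_psd_percentiles(median: float, sigma: float, quantiles) -> list[tuple[float, float]]:
    """Exact log-normal percentile table (quantile, size) in the median's unit.

    Round-trips through the percentile fit to machine precision, making
    it the canonical fixture for fit validation.
    """
    psd = LogNormalPSD(median=median, sigma=sigma)
    return [(float(q), psd.quantile(q)) for q in quantiles]


def make_solubility_dataset(
    spec: SyntheticSpec,
    cm: CompoundMedium,
    *,
    cache: SimulationCache | None = None,
) -> tuple[list[SolubilityMeasurement], dict]:
    """Model-generated apparent-solubility measurements with recorded truth.

    Runs the dissolution engine at ``spec.true_sigma_sl`` for every
    (PSD, scenario) pair, applies seeded multiplicative Gaussian noise to
    the equilibrium concentrations, and returns the measurement list
    together with a manifest holding the seed, the ground truth and the
    noiseless values. Identical spec (including seed) yields an
    identical dataset.
    """
    cache = cache or SimulationCache()
    cm = replace(cm, interfacial_energy=spec.true_sigma_sl)
    scenarios = spec.scenarios
    if len(scenarios) == 1:
        scenarios = scenarios * len(spec.psds)
    if len(scenarios) != len(spec.psds):
        raise ValidationError("scenarios must match psds in length (or be a single entry)")

    rng = np.random.default_rng(spec.seed)
    measurements: list[SolubilityMeasurement] = []
    clean: list[float] = []
    for i, ((median, sig), (mass, volume)) in enumerate(zip(spec.psds, scenarios)):
        probe = SolubilityMeasurement(
            label=f"synth-{i + 1}",
            psd=LogNormalPSD(median=median, sigma=sig),
            solids_mass=mass,
            volume=volume,
            s0=cm.s0,
            measured_s_app=cm.s0,  # placeholder until simulated
        )
        c_eq = cache.equilibrium_concentration(probe, cm)
        clean.append(c_eq)
        noisy = c_eq * (1.0 + spec.noise_sd * rng.standard_normal())
        measurements.append(replace(probe, measured_s_app=max(noisy, 1e-12)))

    manifest = {
        "seed": spec.seed,
        "true_sigma_sl_J_per_m2": spec.true_sigma_sl,
        "noise_sd": spec.noise_sd,
        "noiseless_c_eq_kg_per_m3": clean,
    }
    return measurements, manifest
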