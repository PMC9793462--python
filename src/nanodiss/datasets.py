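"""Bundled reference dataset: a wet-media-milled nanosuspension study.

A published characterization study of a proprietary poorly-soluble weak
base (molecular weight > 500 g/mol) milled to eight particle size
distributions, from coarse 2.4 um crystals down to a sub-100 nm
nanosuspension, provides the canonical worked example for this package:

* the compound/medium constants (pH 3 citrate buffer at 22 degC),
* the fitted log-normal PSDs of the eight batches,
* measured apparent solubilities at constant dose number Do = 8.9 for
  all eight batches, plus a Do sweep (2.7 to 179) for the 111 nm batch,
* XRPD peak heights at 13.7 deg 2-theta used for crystallite size and
  detection-limit analysis, and reflection-XRPD crystallinity results.

All tables are small printed values, shipped as plain Python data. They
are inputs for examples, tests and the reproduction script, not outputs
of this package.
"""

from __future__ import annotations

from .calibration import SolubilityMeasurement
from .physchem import CompoundMedium, DEFAULT_TEMPERATURE_K
from .psd import LogNormalPSD

__all__ = [
    "reference_compound",
    "reference_psds",
    "reference_percentiles",
    "reference_solubility_measurements",
    "REFERENCE_XRPD_PEAKS",
    "REFERENCE_CRYSTALLINITY",
    "REFERENCE_AMORPHICITY_TABLE",
]

#: Compound/medium constants (pH 3 medium). sigma_sl = 30 mJ/m^2 is the
#: interfacial energy selected by calibration against the measured
#: apparent solubilities; see :mod:`nanodiss.calibration`.
_COMPOUND = dict(
    molar_volume=3.72e-4,  # m^3/mol
    density=1364.0,  # kg/m^3
    viscosity=1e-3,  # Pa s
    temperature=DEFAULT_TEMPERATURE_K,  # 295.15 K (22 degC)
    thermodynamic_solubility=0.028,  # kg/m^3 (28 mg/L at pH 3)
    interfacial_energy=0.030,  # J/m^2
)

#: Fitted log-normal PSDs per experiment: (x10 nm, x50 nm, x90 nm, sigma).
#: Experiment 1 is the coarse starting material (laser diffraction); 2-8
#: are wet-media-milled nanosuspensions (photon correlation spectroscopy).
_PSD_TABLE = {
    1: (1116.0, 2443.0, 5344.0, 0.611),
    2: (152.0, 261.0, 449.0, 0.422),
    3: (116.0, 201.0, 348.0, 0.427),
    4: (78.0, 140.0, 252.0, 0.456),
    5: (57.0, 111.0, 213.0, 0.513),
    6: (53.0, 93.0, 162.0, 0.432),
    7: (53.0, 90.0, 150.0, 0.404),
    8: (47.0, 79.0, 133.0, 0.402),
}

#: Apparent solubility measurements in pH 3 medium at 22 degC:
#: experiment -> (PSD experiment no., solids mass g, dose number,
#: measured apparent solubility mg/L). Volume is 1 L throughout.
#: Experiments 9-15 reuse the 111 nm PSD (no. 5) at varied dose numbers.
_SOLUBILITY_TABLE = {
    1: (1, 0.25, 8.9, 30.3),
    2: (2, 0.25, 8.9, 34.9),
    3: (3, 0.25, 8.9, 39.8),
    4: (4, 0.25, 8.9, 48.1),
    5: (5, 0.25, 8.9, 49.9),
    6: (6, 0.25, 8.9, 53.9),
    7: (7, 0.25, 8.9, 52.6),
    8: (8, 0.25, 8.9, 55.7),
    9: (5, 0.075, 2.7, 41.6),
    10: (5, 0.125, 4.5, 47.2),
    11: (5, 0.25, 8.9, 49.9),
    12: (5, 0.5, 18.0, 51.3),
    13: (5, 1.25, 45.0, 51.9),
    14: (5, 2.5, 89.0, 52.1),
    15: (5, 5.0, 179.0, 52.5),
}

#: Transmission-XRPD peak data at 13.7 deg 2-theta:
#: experiment -> (median size x50 nm, peak intensity cps).
REFERENCE_XRPD_PEAKS = {
    1: (2443.0, 2114.0),
    6: (93.0, 618.0),
    7: (90.0, 563.0),
    8: (79.0, 516.0),
}

#: Reflection-XRPD crystallinity results:
#: experiment -> (x50 nm, crystalline content %, amorphous content %).
REFERENCE_CRYSTALLINITY = {
    1: (2443.0, 92.0, 8.0),
    5: (111.0, 77.0, 23.0),
    8: (79.0, 80.0, 20.0),
}

#: Core-shell intrinsic surface amorphicity (%) for single sizes:
#: size nm -> {Z layers: amorphous %}. Used to calibrate the effective
#: unit-cell diameter (the compound's unit cell is unpublished).
REFERENCE_AMORPHICITY_TABLE = {
    20.0: {1: 28.5, 2: 51.0, 3: 68.1},
    50.0: {1: 12.2, 2: 23.3, 3: 33.4},
    100.0: {1: 6.2, 2: 12.2, 3: 17.8},
    200.0: {1: 3.1, 2: 6.2, 3: 9.2},
    1000.0: {1: 0.6, 2: 1.3, 3: 1.9},
}


def reference_compound(sigma_sl: float | None = None) -> CompoundMedium:
    """The reference compound in pH 3 medium; optionally override sigma_sl (J/m^2)."""
    kwargs = dict(_COMPOUND)
    if sigma_sl is not None:
        kwargs["interfacial_energy"] = sigma_sl
    return CompoundMedium(**kwargs)


def reference_psds() -> dict[int, LogNormalPSD]:
    """Fitted log-normal PSDs of the eight reference batches (SI units)."""
    return {
        no: LogNormalPSD(median=x50 * 1e-9, sigma=sigma)
        for no, (_, x50, _, sigma) in _PSD_TABLE.items()
    }


def reference_percentiles(no: int) -> list[tuple[float, float]]:
    """(quantile, size m) triplet x10/x50/x90 for one reference batch."""
    x10, x50, x90, _ = _PSD_TABLE[no]
    return [(0.1, x10 * 1e-9), (0.5, x50 * 1e-9), (0.9, x90 * 1e-9)]


def reference_solubility_measurements(
    experiments=None,
) -> list[SolubilityMeasurement]:
    """Apparent solubility measurements as calibration-ready objects.

    Parameters
    ----------
    experiments : iterable of int, optional
        Experiment numbers to include (default: all 15).
    """
    psds = reference_psds()
    if experiments is None:
        experiments = sorted(_SOLUBILITY_TABLE)
    out = []
    for no in experiments:
        psd_no, mass_g, _do, s_app_mg_L = _SOLUBILITY_TABLE[no]
        out.append(
            SolubilityMeasurement(
                label=f"exp-{no}",
                psd=psds[psd_no],
                solids_mass=mass_g * 1e-3,
                volume=1e-3,
                s0=0.028,
                measured_s_app=s_app_mg_L * 1e-3,
            )
        )
    return out
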