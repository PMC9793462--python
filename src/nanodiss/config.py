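"""Configuration and CSV dialects used at the tool boundary.

Internally everything is SI; these helpers convert the customary bench
units (nm, mg/L, mJ/m^2, g, mL, um) exactly once, on the way in or out.

Config file (YAML key-value) for the compound/medium block::

    molar_volume_m3_per_mol: 3.72e-4
    density_kg_per_m3: 1364
    viscosity_Pa_s: 1.0e-3
    temperature_K: 295.15
    s0_mg_per_L: 28
    sigma_sl_mJ_per_m2: 30
    delta_max_um: 0.5        # optional, default uncapped
"""

from __future__ import annotations

import yaml
import pandas as pd

from .calibration import SolubilityMeasurement
from .errors import ValidationError
from .physchem import CompoundMedium, DEFAULT_TEMPERATURE_K
from .psd import LogNormalPSD

__all__ = [
    "load_compound_medium",
    "compound_medium_from_mapping",
    "read_measurements_csv",
    "write_measurements_csv",
]

_REQUIRED_KEYS = {
    "molar_volume_m3_per_mol",
    "density_kg_per_m3",
    "viscosity_Pa_s",
    "s0_mg_per_L",
    "sigma_sl_mJ_per_m2",
}
_OPTIONAL_KEYS = {"temperature_K", "delta_max_um"}


def compound_medium_from_mapping(cfg: dict) -> CompoundMedium:
    """Build a :class:`CompoundMedium` from a config mapping (bench units)."""
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a key-value mapping")
    missing = _REQUIRED_KEYS - cfg.keys()
    if missing:
        raise ValidationError(f"config is missing required keys: {sorted(missing)}")
    unknown = cfg.keys() - _REQUIRED_KEYS - _OPTIONAL_KEYS
    if unknown:
        raise ValidationError(f"config has unknown keys: {sorted(unknown)}")

    def num(key, default=None):
        value = cfg.get(key, default)
        try:
            return float(value)
        except (TypeError, ValueError):
            raise ValidationError(f"config key {key!r} must be a number, got {value!r}")

    delta_max = None
    if cfg.get("delta_max_um") is not None:
        delta_max = num("delta_max_um") * 1e-6
    return CompoundMedium(
        molar_volume=num("molar_volume_m3_per_mol"),
        density=num("density_kg_per_m3"),
        viscosity=num("viscosity_Pa_s"),
        temperature=num("temperature_K", DEFAULT_TEMPERATURE_K),
        thermodynamic_solubility=num("s0_mg_per_L") * 1e-3,
        interfacial_energy=num("sigma_sl_mJ_per_m2") * 1e-3,
        delta_max=delta_max,
    )


def load_compound_medium(path) -> CompoundMedium:
    """Load the compound/medium block from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return compound_medium_from_mapping(cfg)


_MEAS_COLUMNS = ["label", "x50_nm", "sigma", "mass_g", "volume_L", "s0_mg_per_L", "s_app_mg_per_L"]


def read_measurements_csv(path) -> list[SolubilityMeasurement]:
    """Read an apparent-solubility measurement table (bench units)."""
    df = pd.read_csv(path)
    missing = set(_MEAS_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"measurements CSV is missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SolubilityMeasurement(
                label=str(row["label"]),
                psd=LogNormalPSD(median=float(row["x50_nm"]) * 1e-9, sigma=float(row["sigma"])),
                solids_mass=float(row["mass_g"]) * 1e-3,
                volume=float(row["volume_L"]) * 1e-3,
                s0=float(row["s0_mg_per_L"]) * 1e-3,
                measured_s_app=float(row["s_app_mg_per_L"]) * 1e-3,
            )
        )
    return out


def write_measurements_csv(measurements, path) -> None:
    """Write measurements back to the CSV dialect above."""
    rows = [
        {
            "label": m.label,
            "x50_nm": m.psd.median * 1e9,
            "sigma": m.psd.sigma,
            "mass_g": m.solids_mass * 1e3,
            "volume_L": m.volume * 1e3,
            "s0_mg_per_L": m.s0 * 1e3,
            "s_app_mg_per_L": m.measured_s_app * 1e3,
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=_MEAS_COLUMNS).to_csv(path, index=False)
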