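"""Scenario-grid orchestration: batch equilibrium runs over formulation/medium grids.

Typical use is an in-vivo or in-vitro study grid: dose strengths x fluid
volumes x media (each medium represented solely by its thermodynamic
solubility s0) x candidate PSDs. Cells are independent; a failing cell is
reported in the results table without aborting the remaining cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .dissolution import Scenario, simulate
from .errors import ValidationError
from .physchem import CompoundMedium, dose_number
from .psd import LogNormalPSD, attach_mass, discretize

__all__ = ["GridCell", "ScenarioGrid", "run_grid"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridCell:
    """One grid entry: label, solid mass (kg), volume (m^3), s0 (kg/m^3), PSD."""

    label: str
    mass: float
    volume: float
    s0: float
    psd: LogNormalPSD

    def __post_init__(self):
        if not (self.mass > 0 and self.volume > 0 and self.s0 > 0):
            raise ValidationError(f"grid cell {self.label!r}: mass, volume and s0 must be positive")


@dataclass(frozen=True)
class ScenarioGrid:
    cells: tuple[GridCell, ...]
    n_classes: int = 999

    def __post_init__(self):
        labels = [c.label for c in self.cells]
        if len(set(labels)) != len(labels):
            raise ValidationError("grid cell labels must be unique")


def run_grid(grid: ScenarioGrid, cm: CompoundMedium) -> pd.DataFrame:
    """Run every grid cell to equilibrium and tabulate the results.

    Returns a DataFrame with one row per cell: dose number, equilibrium
    concentration (mg/L), dissolved fraction, smallest surviving size
    (nm; NaN if fully dissolved) and a status column ('ok' or the error
    message for cells that failed). Rows are in input order; cells are
    independent, so the table is invariant to reordering.
    """
    rows = []
    for cell in grid.cells:
        record = {
            "label": cell.label,
            "mass_g": cell.mass * 1e3,
            "volume_mL": cell.volume * 1e6,
            "s0_mg_per_L": cell.s0 * 1e3,
            "x50_nm": cell.psd.median * 1e9,
            "do": dose_number(cell.mass, cell.s0, cell.volume),
        }
        try:
            cm_cell = replace(cm, thermodynamic_solubility=cell.s0)
            dpsd = attach_mass(discretize(cell.psd, grid.n_classes), cell.mass, cm_cell.density)
            result = simulate(
                Scenario(dpsd=dpsd, m_total=cell.mass, V_l=cell.volume, cm=cm_cell)
            )
            s = result.summary
            record.update(
                c_eq_mg_per_L=s.c_eq * 1e3,
                dissolved_fraction=s.dissolved_fraction,
                smallest_surviving_nm=(
                    s.smallest_surviving_size * 1e9
                    if s.smallest_surviving_size is not None
                    else float("nan")
                ),
                status="ok",
            )
        except Exception as exc:  # keep the remaining cells running
            log.error("grid cell %s failed: %s", cell.label, exc)
            record.update(
                c_eq_mg_per_L=float("nan"),
                dissolved_fraction=float("nan"),
                smallest_surviving_nm=float("nan"),
                status=f"error: {exc}",
            )
        rows.append(record)
    return pd.DataFrame(rows)
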