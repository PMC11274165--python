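"""Apparent intestinal permeability from Ussing-chamber FD4 flux.

A mucosal biopsy mounted in an Ussing chamber separates a donor
compartment, loaded with the 4 kDa paracellular probe FITC-dextran
(FD4), from a receiver compartment.  The apparent permeability is

    Pm = Qt * delta_m / (S * t * C0)          [cm^2/s]

where Qt is the amount of probe transported by elapsed time t, S the
exposed tissue area, C0 the initial donor concentration and delta_m the
membrane thickness.  Transepithelial electrical resistance (TEER,
ohm*cm^2) is measured in the same chamber but enters the pipeline as
raw data only — no equation couples it to the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "UssingMeasurement",
    "TEERObservation",
    "compute_pm",
    "pm_to_table_units",
    "read_ussing_table",
]

#: Default chamber geometry: exposed area (cm^2), initial donor FD4
#: concentration (pmol/cm^3) and membrane thickness (cm).
DEFAULT_AREA_CM2 = 0.017
DEFAULT_C0_PMOL_PER_CM3 = 1.0e4
DEFAULT_THICKNESS_CM = 2.175e-3

VALID_PHASES = ("t0", "t1", "t2", "control")


@dataclass(frozen=True)
class UssingMeasurement:
    """Raw inputs of one flux measurement.

    ``qt``: FD4 amount transported at elapsed time ``t`` (pmol);
    ``t``: elapsed time (s); ``s``: exchange area (cm^2);
    ``c0``: initial donor concentration (pmol/cm^3);
    ``delta_m``: membrane thickness (cm).
    """

    qt: float
    t: float
    s: float = DEFAULT_AREA_CM2
    c0: float = DEFAULT_C0_PMOL_PER_CM3
    delta_m: float = DEFAULT_THICKNESS_CM

    def __post_init__(self) -> None:
        if self.qt < 0:
            raise ValueError(f"transported amount qt must be >= 0, got {self.qt!r}")
        for name in ("t", "s", "c0", "delta_m"):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class TEERObservation:
    """One transepithelial electrical resistance reading (ohm*cm^2)."""

    value: float
    phase: str

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"TEER must be strictly positive, got {self.value!r}")
        if self.phase not in VALID_PHASES:
            raise ValueError(f"phase must be one of {VALID_PHASES}, got {self.phase!r}")


def compute_pm(m: UssingMeasurement) -> float:
    """Apparent permeability in cm^2/s: Qt*delta_m / (S*t*C0)."""
    return m.qt * m.delta_m / (m.s * m.t * m.c0)


def pm_to_table_units(pm: float) -> float:
    """Scale a permeability (cm^2/s) to the conventional 1e-6 cm^2/s units."""
    return pm * 1.0e6


def read_ussing_table(
    path: str | Path,
    s: float = DEFAULT_AREA_CM2,
    c0: float = DEFAULT_C0_PMOL_PER_CM3,
    delta_m: float = DEFAULT_THICKNESS_CM,
) -> pd.DataFrame:
    """Read raw flux measurements and append the computed permeability.

    Expects delimited text with columns ``patient_id``, ``phase``,
    ``Qt_pmol``, ``t_s``; geometry constants come from configuration.
    Returns the table with an added ``Pm_cm2_per_s`` column.
    """
    df = pd.read_csv(path)
    required = {"patient_id", "phase", "Qt_pmol", "t_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ussing table missing columns: {sorted(missing)}")
    df = df.copy()
    df["Pm_cm2_per_s"] = [
        compute_pm(UssingMeasurement(qt=row.Qt_pmol, t=row.t_s, s=s, c0=c0, delta_m=delta_m))
        for row in df.itertuples()
    ]
    return df
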