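"""Method-comparison reports: experimental vs analytic model vs ML model.

Each estimation route produces a :class:`RunReport` (its recommended
printing parameters, resulting strand diameter and similarity, and its
agreement statistics); :func:`compare_methods` assembles them into one
table and flags the method with the lowest mean absolute error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["RunReport", "compare_methods", "PRINTER_LIMITS"]

#: Hard printer envelope used to validate reported parameters.
PRINTER_LIMITS = {"pressure_kPa": 200.0, "velocity_mm_s": 45.0}

_METHODS = ("experimental", "analytic_model", "ml_model")


@dataclass(frozen=True)
class RunReport:
    """One estimation method's outcome.

    ``parameters`` holds nozzle_G, pressure_kPa, velocity_mm_s,
    temperature_C; missing metrics stay ``None`` and are serialized as
    explicit nulls, never dropped.
    """

    method: str
    parameters: dict = field(default_factory=dict)
    filament_diameter_mm: float | None = None
    similarity_pct: float | None = None
    mae: float | None = None
    mse: float | None = None
    pearson_r: float | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        p = self.parameters.get("pressure_kPa")
        if p is not None and p > PRINTER_LIMITS["pressure_kPa"]:
            raise ValueError(f"pressure {p} kPa exceeds printer limit")
        v = self.parameters.get("velocity_mm_s")
        if v is not None and v > PRINTER_LIMITS["velocity_mm_s"]:
            raise ValueError(f"velocity {v} mm/s exceeds printer limit")

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "nozzle_G": self.parameters.get("nozzle_G"),
            "pressure_kPa": self.parameters.get("pressure_kPa"),
            "velocity_mm_s": self.parameters.get("velocity_mm_s"),
            "temperature_C": self.parameters.get("temperature_C"),
            "filament_diameter_mm": self.filament_diameter_mm,
            "similarity_pct": self.similarity_pct,
            "mae": self.mae,
            "mse": self.mse,
            "pearson_r": self.pearson_r,
        }


def compare_methods(reports: list[RunReport]) -> pd.DataFrame:
    """Assemble the per-method comparison table.

    Requires at least two reports with distinct method names. The method
    with the lowest MAE (among those reporting one) gets ``best = True``.
    """
    if len(reports) < 2:
        raise ValueError("need at least two method reports to compare")
    names = [r.method for r in reports]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate method names in reports: {names}")
    table = pd.DataFrame([r.as_row() for r in reports])
    table["best"] = False
    with_mae = table["mae"].notna()
    if with_mae.any():
        table.loc[table.loc[with_mae, "mae"].idxmin(), "best"] = True
    return table
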