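"""Analytic power-law extrusion model for a cylindrical bioprinter nozzle.

The deposited strand of a shear-thinning ink is predicted from its
Ostwald-de Waele (power-law) rheology, eta(gamma_dot) = K * gamma_dot**(n-1),
and the nozzle geometry, using a one-dimensional generalization of
Hagen-Poiseuille pipe flow:

* volumetric flow rate        Q     = V_ext * pi * R**2
* centreline (max) velocity   V_max = V_ext * (3n + 1) / n
* pressure-driven velocity    V_ext = n/(3n+1) * R**2/K * dP/L
* consistency index           K     = n/(3n+1) * R**2/V_ext * dP/L
* Newtonian pressure drop     dP    = 8 * eta * V_ext * L / R**2
* strand (filament) diameter  D_f   = 4 * W_n * V_ext / (n * V_max)

where W_n is the nozzle inner diameter, R = W_n/2, L the channel length,
and n, K the flow-behavior and consistency indices.  With V_max taken from
the velocity-ratio relation the strand diameter collapses to
D_f = 4 * W_n / (3n + 1): a Newtonian ink (n = 1) yields exactly the bore
diameter, and shear-thinning inks (n < 1) swell beyond it.

The velocity-ratio form (3n+1)/n is used as the model default; the textbook
power-law profile ratio (3n+1)/(n+1) is available via ``profile="textbook"``
for comparison.

Public functions accept printer-native units (mm, mm/s, kPa); conversions to
SI happen internally (see :mod:`printfid._units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _units

__all__ = [
    "RheologyCurve",
    "PowerLawFit",
    "NozzleGeometry",
    "ExtrusionConditions",
    "FilamentPrediction",
    "GAUGE_INNER_DIAMETER_MM",
    "DEFAULT_CHANNEL_LENGTH_MM",
    "fit_power_law",
    "flow_rate",
    "max_velocity",
    "pressure_drop",
    "extrusion_velocity_from_pressure",
    "consistency_index",
    "filament_diameter",
    "predict_filament",
    "read_rheology_csv",
]

#: Needle gauge -> inner diameter in mm. 25G is the 0.250 mm bore of the
#: printer's standard tip; 27G is 0.210 mm. User-overridable per call.
GAUGE_INNER_DIAMETER_MM: dict[int, float] = {25: 0.250, 27: 0.210}

#: Standard half-inch dispensing tip channel length (mm). The true channel
#: length of a given tip is rarely published; every report that uses the
#: default flags it.
DEFAULT_CHANNEL_LENGTH_MM = 12.7


@dataclass(frozen=True)
class RheologyCurve:
    """A measured flow curve: apparent viscosity versus shear rate.

    Parameters
    ----------
    shear_rate : array-like
        Shear rates in 1/s, strictly positive and strictly increasing.
    viscosity : array-like
        Apparent viscosities in Pa*s, strictly positive, same length.
    shear_stress : array-like, optional
        Shear stresses in Pa.
    temperature : float, optional
        Measurement temperature in deg C (metadata only).
    """

    shear_rate: np.ndarray
    viscosity: np.ndarray
    shear_stress: np.ndarray | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        sr = np.asarray(self.shear_rate, dtype=float)
        visc = np.asarray(self.viscosity, dtype=float)
        if sr.ndim != 1 or sr.size < 3:
            raise ValueError("shear_rate must be a 1-D array with >= 3 points")
        if visc.shape != sr.shape:
            raise ValueError("viscosity must have the same length as shear_rate")
        if not np.all(sr > 0):
            raise ValueError("shear rates must be strictly positive")
        if not np.all(np.diff(sr) > 0):
            raise ValueError("shear rates must be strictly increasing")
        if not np.all(visc > 0):
            raise ValueError("viscosities must be strictly positive")
        object.__setattr__(self, "shear_rate", sr)
        object.__setattr__(self, "viscosity", visc)
        if self.shear_stress is not None:
            ss = np.asarray(self.shear_stress, dtype=float)
            if ss.shape != sr.shape:
                raise ValueError("shear_stress must match shear_rate in length")
            object.__setattr__(self, "shear_stress", ss)

    def __len__(self) -> int:
        return self.shear_rate.size


@dataclass(frozen=True)
class PowerLawFit:
    """Results of an Ostwald-de Waele fit eta = K * gamma_dot**(n-1).

    ``n`` is the dimensionless flow-behavior index (n < 1: shear thinning),
    ``K`` the consistency index in Pa*s**n, ``r_squared`` the coefficient of
    determination of the log-log regression, and ``shear_rate_window`` the
    (low, high) range of shear rates used.
    """

    n: float
    K: float
    r_squared: float
    shear_rate_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("consistency index K must be positive")
        if self.n <= 0:
            raise ValueError("flow-behavior index n must be positive")

    def viscosity(self, shear_rate):
        """Model viscosity (Pa*s) at the given shear rate(s) in 1/s."""
        return self.K * np.asarray(shear_rate, dtype=float) ** (self.n - 1.0)

    def summary(self) -> str:
        lo, hi = self.shear_rate_window
        return (
            "Power-law (Ostwald-de Waele) fit\n"
            f"  n  (flow-behavior index) : {self.n:.6g}\n"
            f"  K  (consistency, Pa*s^n) : {self.K:.6g}\n"
            f"  R^2 (log-log OLS)        : {self.r_squared:.4f}\n"
            f"  shear-rate window (1/s)  : [{lo:g}, {hi:g}]"
        )


@dataclass(frozen=True)
class NozzleGeometry:
    """Cylindrical nozzle described by bore diameter and channel length (mm)."""

    inner_diameter: float
    channel_length: float = DEFAULT_CHANNEL_LENGTH_MM
    gauge: int | None = None
    channel_length_is_default: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0:
            raise ValueError("inner_diameter must be positive")
        if self.channel_length <= 0:
            raise ValueError("channel_length must be positive")

    @property
    def radius(self) -> float:
        """Inner radius in mm (always exactly inner_diameter / 2)."""
        return self.inner_diameter / 2.0

    @classmethod
    def from_gauge(
        cls,
        gauge: int,
        channel_length: float | None = None,
        gauge_table: dict[int, float] | None = None,
    ) -> "NozzleGeometry":
        """Build a nozzle from its needle gauge.

        ``gauge_table`` overrides the shipped gauge -> bore mapping.
        """
        table = GAUGE_INNER_DIAMETER_MM if gauge_table is None else gauge_table
        try:
            bore = table[int(gauge)]
        except KeyError:
            known = ", ".join(f"{g}G" for g in sorted(table))
            raise KeyError(
                f"unknown nozzle gauge {gauge}G (known: {known}); "
                "pass inner_diameter directly or supply gauge_table"
            ) from None
        return cls(
            inner_diameter=bore,
            channel_length=DEFAULT_CHANNEL_LENGTH_MM if channel_length is None else channel_length,
            gauge=int(gauge),
            channel_length_is_default=channel_length is None,
        )


@dataclass(frozen=True)
class ExtrusionConditions:
    """Process conditions at the nozzle inlet.

    extrusion_velocity in mm/s, applied_pressure in kPa, temperature in
    deg C, dynamic_viscosity (effective) in Pa*s. Any field left ``None``
    is simply not used by the computation that would need it.
    """

    extrusion_velocity: float | None = None
    applied_pressure: float | None = None
    temperature: float | None = None
    dynamic_viscosity: float | None = None

    def __post_init__(self) -> None:
        for name in ("extrusion_velocity", "applied_pressure", "dynamic_viscosity"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive when set")


@dataclass(frozen=True)
class FilamentPrediction:
    """Predicted nozzle flow and strand size: Q (mm^3/s), V_max (mm/s), D_f (mm)."""

    flow_rate: float
    max_velocity: float
    filament_diameter: float

    def __post_init__(self) -> None:
        for name in ("flow_rate", "max_velocity", "filament_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def fit_power_law(
    curve: RheologyCurve,
    window: tuple[float, float] | None = None,
) -> PowerLawFit:
    """Fit the power-law viscosity model to a flow curve.

    Ordinary least squares on log(viscosity) = log K + (n - 1) log(shear_rate),
    restricted to shear rates inside ``window`` (inclusive). The window
    defaults to the full curve.

    Raises
    ------
    ValueError
        If fewer than 3 points fall inside the window.
    """
    sr, visc = curve.shear_rate, curve.viscosity
    if window is None:
        window = (float(sr[0]), float(sr[-1]))
    lo, hi = window
    mask = (sr >= lo) & (sr <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"power-law fit needs >= 3 points in window [{lo:g}, {hi:g}] 1/s; "
            f"found {int(mask.sum())}"
        )
    x = np.log(sr[mask])
    y = np.log(visc[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return PowerLawFit(
        n=float(slope + 1.0),
        K=float(np.exp(intercept)),
        r_squared=min(1.0, r2),
        shear_rate_window=(float(lo), float(hi)),
    )


def flow_rate(v_ext: float, nozzle: NozzleGeometry) -> float:
    """Volumetric flow rate Q = V_ext * pi * R^2, in mm^3/s.

    The multiplier is the nozzle cross-sectional area; ``v_ext`` in mm/s.
    """
    if v_ext < 0:
        raise ValueError("extrusion velocity must be non-negative")
    return v_ext * np.pi * nozzle.radius**2


def max_velocity(v_ext: float, n: float, profile: str = "ratio") -> float:
    """Maximum (centreline) velocity from the extrusion velocity.

    ``profile="ratio"`` (default) uses V_max = V_ext * (3n + 1)/n.
    ``profile="textbook"`` uses the power-law pipe-profile ratio
    V_max = V_ext * (3n + 1)/(n + 1) for comparison.
    """
    if n <= 0:
        raise ValueError("flow-behavior index n must be positive")
    if v_ext < 0:
        raise ValueError("extrusion velocity must be non-negative")
    if profile == "ratio":
        return v_ext * (3.0 * n + 1.0) / n
    if profile == "textbook":
        return v_ext * (3.0 * n + 1.0) / (n + 1.0)
    raise ValueError(f"unknown profile {profile!r}; use 'ratio' or 'textbook'")


def pressure_drop(eta: float, v_ext: float, length: float, radius: float) -> float:
    """Hagen-Poiseuille pressure drop dP = 8 * eta * V_ext * L / R^2, in Pa.

    All inputs SI and strictly positive: eta in Pa*s, v_ext in m/s,
    length and radius in m.
    """
    for name, v in (("eta", eta), ("v_ext", v_ext), ("length", length), ("radius", radius)):
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive")
    return 8.0 * eta * v_ext * length / radius**2


def extrusion_velocity_from_pressure(
    n: float, K: float, radius: float, dP: float, length: float
) -> float:
    """Mean extrusion velocity of a power-law fluid driven by dP.

    V_ext = n/(3n+1) * R^2/K * dP/L. Consistent units (SI recommended);
    exact algebraic inverse of :func:`consistency_index`.
    """
    for name, v in (("n", n), ("K", K), ("radius", radius), ("dP", dP), ("length", length)):
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive")
    return n / (3.0 * n + 1.0) * radius**2 / K * dP / length


def consistency_index(n: float, radius: float, v_ext: float, dP: float, length: float) -> float:
    """Consistency index implied by an observed velocity under pressure dP.

    K = n/(3n+1) * R^2/V_ext * dP/L; exact algebraic inverse of
    :func:`extrusion_velocity_from_pressure`.
    """
    for name, v in (("n", n), ("radius", radius), ("v_ext", v_ext), ("dP", dP), ("length", length)):
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive")
    return n / (3.0 * n + 1.0) * radius**2 / v_ext * dP / length


def filament_diameter(
    nozzle: NozzleGeometry, v_ext: float, n: float, v_max: float | None = None
) -> float:
    """Predicted strand diameter D_f = 4 * W_n * V_ext / (n * V_max), in mm.

    ``W_n`` is the nozzle inner diameter (a length; the relation is only
    dimensionally consistent with that reading). When ``v_max`` is omitted
    it is taken from :func:`max_velocity`, and the expression reduces to
    D_f = 4 * W_n / (3n + 1): exactly the bore for a Newtonian ink, larger
    (die swell) for shear-thinning inks.
    """
    if v_ext <= 0:
        raise ValueError("extrusion velocity must be strictly positive")
    if n <= 0:
        raise ValueError("flow-behavior index n must be positive")
    if v_max is None:
        v_max = max_velocity(v_ext, n)
    if v_max <= 0 or n * v_max == 0:
        raise ValueError("maximum velocity must be strictly positive")
    return 4.0 * nozzle.inner_diameter * v_ext / (n * v_max)


def predict_filament(
    fit: PowerLawFit,
    nozzle: NozzleGeometry,
    conditions: ExtrusionConditions,
) -> FilamentPrediction:
    """Full per-condition prediction: flow rate, max velocity, strand diameter."""
    v = conditions.extrusion_velocity
    if v is None or v <= 0:
        raise ValueError("conditions must include a positive extrusion_velocity")
    q = flow_rate(v, nozzle)
    vmax = max_velocity(v, fit.n)
    d_f = filament_diameter(nozzle, v, fit.n, vmax)
    return FilamentPrediction(flow_rate=q, max_velocity=vmax, filament_diameter=d_f)


def pressure_drop_kpa(eta: float, v_ext_mm_s: float, nozzle: NozzleGeometry) -> float:
    """Newtonian pressure drop for printer-native inputs, returned in kPa.

    eta in Pa*s, v_ext in mm/s, nozzle dimensions in mm; computed in SI.
    """
    dp_pa = pressure_drop(
        eta,
        _units.mm_s_to_m_s(v_ext_mm_s),
        _units.mm_to_m(nozzle.channel_length),
        _units.mm_to_m(nozzle.radius),
    )
    return _units.pa_to_kpa(dp_pa)


def read_rheology_csv(path) -> RheologyCurve:
    """Read a flow curve from CSV.

    Expected columns: ``shear_rate_1_per_s``, ``viscosity_Pa_s``; optional
    ``shear_stress_Pa`` and ``temperature_C`` (first value used).
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"shear_rate_1_per_s", "viscosity_Pa_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rheology CSV missing columns: {sorted(missing)}")
    stress = df["shear_stress_Pa"].to_numpy() if "shear_stress_Pa" in df else None
    temp = float(df["temperature_C"].iloc[0]) if "temperature_C" in df else None
    return RheologyCurve(
        shear_rate=df["shear_rate_1_per_s"].to_numpy(),
        viscosity=df["viscosity_Pa_s"].to_numpy(),
        shear_stress=stress,
        temperature=temp,
    )
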