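"""Bioprocess unit conversions and harvest analytics.

Small, exactly-testable arithmetic used around the cultivation pipeline:
the OD730 <-> dry-cell-weight calibration (1.0 OD730 ~ 0.39 g DCW/L for the
fast-growing cyanobacterium modelled here), slurry solids content,
volumetric <-> areal productivity bridging photobioreactor (g/L/day) and
pond (g/m^2/day) reporting, cumulative yields, Stokes settling velocity,
sedimentation time courses, aggregation and hydrocarbon-adherence (BATH)
fractions, and per-OD normalized product productivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

#: standard gravity, m s^-2
G_STANDARD = 9.81


@dataclass(frozen=True)
class BiomassCalibration:
    """Linear OD730 -> dry cell weight calibration (g/L per OD unit)."""

    dcw_per_od: float = 0.39

    def __post_init__(self) -> None:
        if self.dcw_per_od <= 0:
            raise ValueError("dcw_per_od must be positive")


@dataclass(frozen=True)
class PondGeometry:
    """Open-pond culture geometry: 20 cm standard depth."""

    depth_m: float = 0.20
    area_m2: float = 0.15

    def __post_init__(self) -> None:
        if self.depth_m <= 0 or self.area_m2 <= 0:
            raise ValueError("pond dimensions must be positive")


@dataclass(frozen=True)
class TurbidityCalibration:
    """Pluggable linear turbidity (AU) -> OD730 map; constants are
    instrument-specific and must be supplied by the user."""

    slope: float
    intercept: float = 0.0

    def to_od(self, turbidity_au: float) -> float:
        return self.slope * turbidity_au + self.intercept


@dataclass(frozen=True)
class CellComposition:
    """Dry-mass composition with component densities (kg m^-3).

    The residual fraction (whatever protein, carbohydrate and lipid do not
    account for) is treated as water-density material.
    """

    protein_frac: float = 0.428
    carb_frac: float = 0.365
    lipid_frac: float = 0.112
    protein_density: float = 1300.0
    carb_density: float = 1500.0
    lipid_density: float = 860.0
    water_density: float = 1000.0

    def __post_init__(self) -> None:
        fracs = (self.protein_frac, self.carb_frac, self.lipid_frac)
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
            raise ValueError("mass fractions must be >= 0 and sum to <= 1")

    @property
    def residual_frac(self) -> float:
        return max(0.0, 1.0 - (self.protein_frac + self.carb_frac
                               + self.lipid_frac))


@dataclass
class SedimentationSeries:
    """Surface-layer concentration (OD or g/L) during settling."""

    times: np.ndarray
    surface: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.surface = np.asarray(self.surface, dtype=float)
        if self.times.shape != self.surface.shape or self.times.ndim != 1:
            raise ValueError("times and surface must be equal-length 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


# ---------------------------------------------------------------------------
# biomass conversions
# ---------------------------------------------------------------------------

def od_to_dcw(od: float, calibration: BiomassCalibration | None = None) -> float:
    """Dry cell weight (g/L) from an OD730 reading."""
    if od < 0:
        raise ValueError("od must be non-negative")
    calibration = calibration or BiomassCalibration()
    return od * calibration.dcw_per_od


def dcw_to_od(dcw_g_per_l: float,
              calibration: BiomassCalibration | None = None) -> float:
    """Inverse of :func:`od_to_dcw`."""
    if dcw_g_per_l < 0:
        raise ValueError("dcw must be non-negative")
    calibration = calibration or BiomassCalibration()
    return dcw_g_per_l / calibration.dcw_per_od


def solids_content(dcw_g_per_l: float,
                   slurry_density_g_per_l: float = 1000.0) -> float:
    """Solids content (percent) of a slurry: 100 * dcw / slurry density.

    Reported values are conventionally rounded to the nearest integer
    percent; this function returns the unrounded value.
    """
    if dcw_g_per_l < 0:
        raise ValueError("dcw must be non-negative")
    if slurry_density_g_per_l <= 0:
        raise ValueError("slurry density must be positive")
    return 100.0 * dcw_g_per_l / slurry_density_g_per_l


def volumetric_to_areal(rate_g_per_l_per_day: float,
                        geometry: PondGeometry | None = None) -> float:
    """g L^-1 day^-1 -> g m^-2 day^-1 for a culture of given depth
    (1 m^3 = 1000 L, so areal = volumetric * depth_m * 1000)."""
    geometry = geometry or PondGeometry()
    return rate_g_per_l_per_day * geometry.depth_m * 1000.0


def areal_to_volumetric(rate_g_per_m2_per_day: float,
                        geometry: PondGeometry | None = None) -> float:
    """Inverse of :func:`volumetric_to_areal`."""
    geometry = geometry or PondGeometry()
    return rate_g_per_m2_per_day / (geometry.depth_m * 1000.0)


def cumulative_yield(daily_values: Iterable[float]) -> float:
    """Total yield: the sum of per-day productivities (empty -> 0)."""
    return float(np.sum(np.fromiter(daily_values, dtype=float)))


# ---------------------------------------------------------------------------
# sedimentation physics and harvest analytics
# ---------------------------------------------------------------------------

def composite_density(composition: CellComposition | None = None) -> float:
    """Mass-fraction-weighted mean cell density (kg m^-3); the residual
    fraction is counted at water density."""
    c = composition or CellComposition()
    return (c.protein_frac * c.protein_density
            + c.carb_frac * c.carb_density
            + c.lipid_frac * c.lipid_density
            + c.residual_frac * c.water_density)


def stokes_velocity(radius_m: float, particle_density: float,
                    fluid_density: float = 1000.0,
                    viscosity_pa_s: float = 1.0e-3,
                    g: float = G_STANDARD) -> float:
    """Stokes settling velocity v = 2 (rho_p - rho_f) g r^2 / (9 mu), m/s.

    Positive for settling particles, negative for floating ones.  Larger or
    denser particles settle faster — the rationale for aggregation-based
    sedimentation, where cell clumping inflates the effective radius.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    if viscosity_pa_s <= 0:
        raise ValueError("viscosity must be positive")
    return (2.0 * (particle_density - fluid_density) * g * radius_m ** 2
            / (9.0 * viscosity_pa_s))


def settled_fraction(series: SedimentationSeries) -> list[tuple[float, float]]:
    """Fraction of cells settled out of the surface layer over time.

    ``fraction(t) = 1 - surface(t) / surface(0)``, clipped to [0, 1].
    """
    if series.surface[0] <= 0:
        raise ValueError("initial surface concentration must be positive")
    frac = np.clip(1.0 - series.surface / series.surface[0], 0.0, 1.0)
    return list(zip(series.times.tolist(), frac.tolist()))


def aggregation_fraction(free_count_engineered: float,
                         free_count_reference: float) -> float:
    """Fraction of engineered cells found in aggregates, estimated from the
    deficit of free (unaggregated) cells against a non-aggregating
    reference count: (reference - engineered) / reference, clipped."""
    if free_count_reference <= 0:
        raise ValueError("reference count must be positive")
    return float(np.clip(
        (free_count_reference - free_count_engineered) / free_count_reference,
        0.0, 1.0))


def bath_adherence(fluorescence_sample: float,
                   fluorescence_control: float) -> float:
    """Hydrocarbon-adherent cell fraction from a BATH assay: residual
    chlorophyll fluorescence in the aqueous phase counts the cells that did
    not adhere, so adherence = 1 - sample/control, clipped to [0, 1]."""
    if fluorescence_control <= 0:
        raise ValueError("control fluorescence must be positive")
    return float(np.clip(1.0 - fluorescence_sample / fluorescence_control,
                         0.0, 1.0))


def normalized_productivity(total_mg_per_l: float, days: float,
                            mean_od: float) -> float:
    """Product productivity normalized per day and per OD unit
    (mg L^-1 day^-1 OD^-1); ``mean_od`` is conventionally the time-averaged
    culture OD over the production window."""
    if days <= 0 or mean_od <= 0:
        raise ValueError("days and mean_od must be positive")
    return total_mg_per_l / (days * mean_od)
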