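"""Physics-based synthetic LDP and growth-curve generator.

Real training corpora for the light-distribution surrogate come from camera
photographs of illuminated cultures.  This module replaces the camera with a
forward optical model whose ground truth is known exactly, so every later
stage (calibration, surrogate training, coupled simulation, schedule
optimization) can be tested against an oracle:

* depth attenuation follows Beer--Lambert, ``I(z) = I0 exp(-k C z)``, with
  the extinction coefficient ``k`` in (g/L)^-1 m^-1;
* lateral scattering is proxied by a Gaussian blur across columns;
* the camera response is linear in irradiance with additive Gaussian noise,
  clipped to the 8-bit range — reproducing the documented near-linear
  GSV/irradiance relation with saturation;
* a reference growth law turns light fields into growth curves: the rate is
  ``mu_max * OD * f(mean irradiance) * g(dark fraction)`` with a saturating
  light response ``f`` and a shading penalty ``g`` that is 1 below a
  dark-area onset of 43.1 % and falls to 0 at a 65 % plateau, matching the
  empirically observed peak-then-decline of growth against dark area.

Two presets bundle the study conditions: a flat-panel photobioreactor (5 cm
light path, two opposed light sources) and an open pond (20 cm deep, top
illumination).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import csv

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import imaging
from .grm import GrowthCurve
from .imaging import GSV_MAX, LDP_COLS, LDP_ROWS

#: OD730 -> g DCW / L linear calibration used when converting culture OD to
#: the concentration that sets optical attenuation.
DCW_PER_OD = 0.39

#: packaged preset: the 23-point reference concentration grid (g/L) spanning
#: 0.120--3.678 g/L used for calibration-style datasets.
REFERENCE_CONCENTRATIONS_G_L = (
    0.11973, 0.21294, 0.40872, 0.45162, 0.54405, 0.62712, 0.74256, 0.82056,
    0.90948, 0.96915, 1.10604, 1.2246, 1.3026, 1.3923, 1.443, 1.5444,
    1.7901, 1.9188, 2.0241, 2.3556, 2.535, 2.9601, 3.6777,
)


@dataclass(frozen=True)
class OpticalParams:
    """Forward optics of the virtual culture/camera system.

    extinction_coeff : per-(g/L)-per-meter Beer--Lambert attenuation rate
    lateral_blur_sigma : Gaussian blur across columns, pixels (scattering proxy)
    noise_sd : additive camera noise, gray-value units
    gsv_slope / gsv_intercept : linear camera response, gray per µmol m^-2 s^-1
    gsv_max : clipping ceiling (8-bit: 255)
    """

    extinction_coeff: float = 155.0
    lateral_blur_sigma: float = 1.5
    noise_sd: float = 3.0
    gsv_slope: float = 0.3
    gsv_intercept: float = 2.0
    gsv_max: int = GSV_MAX

    def __post_init__(self) -> None:
        if self.extinction_coeff <= 0:
            raise ValueError("extinction_coeff must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.gsv_max <= GSV_MAX:
            raise ValueError("gsv_max must lie in (0, 255]")


@dataclass(frozen=True)
class Geometry:
    """Vessel geometry mapped onto the 18x40 LDP grid.

    Rows run along the light path (row 0 nearest the source); columns run
    parallel to the light panel.  ``depth_m`` is the full light-path length.
    """

    depth_m: float = 0.05
    width_m: float = 0.10
    rows: int = LDP_ROWS
    cols: int = LDP_COLS
    n_sources: int = 1

    def __post_init__(self) -> None:
        if self.depth_m <= 0 or self.width_m <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.n_sources not in (1, 2):
            raise ValueError("n_sources must be 1 or 2")

    def row_depths(self) -> np.ndarray:
        """Depth (m) at each row centre, increasing with row index."""
        return (np.arange(self.rows) + 0.5) / self.rows * self.depth_m


@dataclass(frozen=True)
class TrueGrowthModel:
    """Reference growth law used as the simulation oracle.

    mu_max : maximal specific growth rate, h^-1
    light_half_sat : half-saturation irradiance of the light response, µmol
        m^-2 s^-1 (0 disables light limitation)
    dark_penalty_onset / dark_penalty_full : dark-area fractions at which the
        shading penalty starts (growth peak, 0.431) and completes (~0.65)
    penalty_strength : exponent shaping the penalty ramp
    """

    mu_max: float = 0.10
    light_half_sat: float = 120.0
    dark_penalty_onset: float = 0.431
    dark_penalty_full: float = 0.65
    penalty_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_max < 0:
            raise ValueError("mu_max must be non-negative")
        if not 0 <= self.dark_penalty_onset < self.dark_penalty_full <= 1:
            raise ValueError("require 0 <= onset < full <= 1")


@dataclass(frozen=True)
class LdpRecord:
    intensity: float
    concentration: float
    ldp: np.ndarray


@dataclass
class SyntheticDataset:
    records: list[LdpRecord]
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    def as_tuples(self) -> list[tuple[float, float, np.ndarray]]:
        return [(r.intensity, r.concentration, r.ldp) for r in self.records]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def pbr_preset() -> tuple[Geometry, OpticalParams, TrueGrowthModel]:
    """Flat-panel photobioreactor: 5 cm path, two opposed light sources."""
    return (
        Geometry(depth_m=0.05, width_m=0.10, n_sources=2),
        OpticalParams(extinction_coeff=155.0, gsv_slope=0.3),
        TrueGrowthModel(),
    )


def pond_preset() -> tuple[Geometry, OpticalParams, TrueGrowthModel]:
    """Open pond: 20 cm deep, top illumination, gentler camera slope so the
    high outdoor intensities (up to ~1500 µmol m^-2 s^-1) stay on scale, and
    a lower effective extinction reflecting raceway mixing."""
    return (
        Geometry(depth_m=0.20, width_m=0.15, n_sources=1),
        OpticalParams(extinction_coeff=50.0, gsv_slope=0.15),
        TrueGrowthModel(),
    )


PRESETS = {"pbr": pbr_preset, "pond": pond_preset}


# ---------------------------------------------------------------------------
# forward optics
# ---------------------------------------------------------------------------

def generate_irradiance_field(
    intensity: float,
    concentration: float,
    geometry: Geometry | None = None,
    optics: OpticalParams | None = None,
) -> np.ndarray:
    """Real-valued irradiance field (µmol m^-2 s^-1) on the LDP grid.

    Single source: ``I(row) = intensity * exp(-k C depth(row))`` with depth
    increasing along rows.  Two sources superpose the front field and its
    row-reversed mirror; any camera-side saturation is applied later at the
    grayscale conversion.  The Gaussian scattering blur acts across columns.
    """
    if intensity < 0 or concentration < 0:
        raise ValueError("intensity and concentration must be non-negative")
    geometry = geometry or Geometry()
    optics = optics or OpticalParams()

    depths = geometry.row_depths()
    front = intensity * np.exp(
        -optics.extinction_coeff * concentration * depths
    )
    field_1d = front if geometry.n_sources == 1 else front + front[::-1]
    grid = np.tile(field_1d[:, None], (1, geometry.cols))
    if optics.lateral_blur_sigma > 0:
        grid = gaussian_filter1d(grid, optics.lateral_blur_sigma, axis=1,
                                 mode="nearest")
    return grid


def irradiance_to_gsv(
    field: np.ndarray,
    optics: OpticalParams | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Map an irradiance field to an 8-bit LDP via the linear camera response.

    ``gsv = clip(slope * I + intercept + noise, 0, gsv_max)`` rounded to
    integers; noise is added only when an ``rng`` is supplied and
    ``noise_sd > 0``.
    """
    optics = optics or OpticalParams()
    arr = np.asarray(field, dtype=float)
    if arr.min() < 0:
        raise ValueError("irradiance field must be non-negative")
    gsv = optics.gsv_slope * arr + optics.gsv_intercept
    if rng is not None and optics.noise_sd > 0:
        gsv = gsv + rng.normal(0.0, optics.noise_sd, size=arr.shape)
    return np.clip(np.rint(gsv), 0, optics.gsv_max).astype(np.int64)


def generate_ldp(
    intensity: float,
    concentration: float,
    geometry: Geometry | None = None,
    optics: OpticalParams | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Convenience: irradiance field followed by grayscale conversion."""
    field = generate_irradiance_field(intensity, concentration, geometry, optics)
    return irradiance_to_gsv(field, optics, rng)


def generate_ldp_dataset(
    intensities: Sequence[float],
    concentrations: Sequence[float],
    geometry: Geometry | None = None,
    optics: OpticalParams | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """One LDP record per (intensity, concentration) pair, reproducible from
    ``seed`` (byte-identical on regeneration)."""
    if len(intensities) == 0 or len(concentrations) == 0:
        raise ValueError("intensity and concentration grids must be non-empty")
    geometry = geometry or Geometry()
    optics = optics or OpticalParams()
    rng = np.random.default_rng(seed)
    records = [
        LdpRecord(float(i), float(c),
                  generate_ldp(i, c, geometry, optics, rng))
        for i in intensities
        for c in concentrations
    ]
    return SyntheticDataset(records=records, seed=seed)


def mean_irradiance(
    intensity: float,
    concentration: float,
    geometry: Geometry | None = None,
    optics: OpticalParams | None = None,
) -> float:
    """Grid-mean irradiance of the noise-free field."""
    return float(
        generate_irradiance_field(intensity, concentration, geometry, optics)
        .mean()
    )


def gsv_irradiance_samples(
    dataset: SyntheticDataset,
    geometry: Geometry | None = None,
    optics: OpticalParams | None = None,
    pixels_per_record: int | None = 40,
    seed: int = 0,
):
    """Matched (gsv, true irradiance, concentration) calibration samples.

    Pairs each dataset LDP with its regenerated noise-free irradiance field
    pixel-by-pixel; ``pixels_per_record`` subsamples pixels to keep the
    calibration table small (None keeps all 720).
    """
    import pandas as pd

    geometry = geometry or Geometry()
    optics = optics or OpticalParams()
    rng = np.random.default_rng(seed)
    rows = []
    for rec in dataset.records:
        field = generate_irradiance_field(rec.intensity, rec.concentration,
                                          geometry, optics).ravel()
        gsv = rec.ldp.ravel()
        idx = np.arange(field.size)
        if pixels_per_record is not None and pixels_per_record < field.size:
            idx = rng.choice(field.size, size=pixels_per_record, replace=False)
        for j in idx:
            rows.append((int(gsv[j]), float(field[j]), rec.concentration))
    return pd.DataFrame(rows, columns=["gsv", "irradiance", "concentration"])


# ---------------------------------------------------------------------------
# reference growth law
# ---------------------------------------------------------------------------

def shading_penalty(dark_fraction: float, model: TrueGrowthModel) -> float:
    """Penalty factor g in [0, 1]: 1 below the dark-area onset, ramping to 0
    at the full-penalty plateau."""
    if dark_fraction <= model.dark_penalty_onset:
        return 1.0
    if dark_fraction >= model.dark_penalty_full:
        return 0.0
    ramp = (model.dark_penalty_full - dark_fraction) / (
        model.dark_penalty_full - model.dark_penalty_onset
    )
    return float(ramp ** model.penalty_strength)


#: depth resolution of the continuous optical profile used by the
#: reference growth law (the 18-row LDP is its coarse discretization)
_TRUE_DEPTH_SAMPLES = 2048


def continuous_depth_profile(
    intensity: float,
    concentration: float,
    geometry: Geometry,
    optics: OpticalParams,
    n_samples: int = _TRUE_DEPTH_SAMPLES,
) -> np.ndarray:
    """Finely sampled irradiance along the continuous light path."""
    z = (np.arange(n_samples) + 0.5) / n_samples * geometry.depth_m
    front = intensity * np.exp(-optics.extinction_coeff * concentration * z)
    return front if geometry.n_sources == 1 else front + front[::-1]


def continuous_dark_fraction(
    intensity: float,
    concentration: float,
    geometry: Geometry,
    optics: OpticalParams,
) -> float:
    """Dark fraction of the continuous depth profile.

    The fraction of the light path whose grayscale rendering would fall
    below the dark threshold.  This is the physical quantity that the
    pixel-count statistic on an 18-row LDP discretizes; using it keeps the
    reference growth law smooth in cell concentration instead of jumping
    whenever a whole pixel row crosses the threshold.
    """
    profile = continuous_depth_profile(intensity, concentration, geometry,
                                       optics)
    gsv = optics.gsv_slope * profile + optics.gsv_intercept
    return float(np.mean(gsv < imaging.DARK_THRESHOLD_GSV))


def true_instantaneous_rate(
    od: float,
    intensity: float,
    model: TrueGrowthModel,
    geometry: Geometry,
    optics: OpticalParams,
    dcw_per_od: float = DCW_PER_OD,
) -> tuple[float, float]:
    """(rate OD730 h^-1, dark fraction) of the reference growth law.

    Light limitation and shading are evaluated on the continuous depth
    profile of the current culture state: ``rate = mu_max * OD * f(mean
    irradiance) * g(dark fraction)`` with ``f`` a Monod-type saturation and
    ``g`` the shading penalty.
    """
    conc = od * dcw_per_od
    profile = continuous_depth_profile(intensity, conc, geometry, optics)
    dark = continuous_dark_fraction(intensity, conc, geometry, optics)
    mean_i = float(profile.mean())
    if model.light_half_sat > 0:
        f = mean_i / (mean_i + model.light_half_sat)
    else:
        f = 1.0
    rate = model.mu_max * od * f * shading_penalty(dark, model)
    return max(rate, 0.0), dark


def simulate_true_growth(
    initial_od: float,
    light_schedule,
    true_model: TrueGrowthModel | None = None,
    geometry: Geometry | None = None,
    optics: OpticalParams | None = None,
    dt: float = 0.5,
    hours: float | None = None,
    dcw_per_od: float = DCW_PER_OD,
    substeps: int = 4,
) -> GrowthCurve:
    """Forward-Euler integration of the reference growth law.

    ``light_schedule`` is either a constant intensity (then ``hours`` is
    required) or an object exposing ``intensity_at(t)`` and ``horizon_h``.
    Returns the OD730 trajectory sampled every ``dt`` hours; the true rate
    and dark-fraction series ride along in ``metadata``.  The integrator
    advances on ``dt / substeps`` internally so the reported samples carry
    negligible integration error and finite differences of the curve
    recover the instantaneous rate law accurately.
    """
    if initial_od <= 0:
        raise ValueError("initial_od must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    true_model = true_model or TrueGrowthModel()
    geometry = geometry or Geometry()
    optics = optics or OpticalParams()

    if hasattr(light_schedule, "intensity_at"):
        horizon = float(light_schedule.horizon_h)
        intensity_at = light_schedule.intensity_at
    else:
        if hours is None:
            raise ValueError("constant-intensity runs need `hours`")
        horizon = float(hours)
        const = float(light_schedule)
        intensity_at = lambda t: const  # noqa: E731

    n_steps = int(round(horizon / dt))
    times = np.arange(n_steps + 1) * dt
    od = np.empty(n_steps + 1)
    rates = np.empty(n_steps + 1)
    darks = np.empty(n_steps + 1)
    od[0] = initial_od
    h = dt / substeps
    for i in range(n_steps):
        rates[i], darks[i] = true_instantaneous_rate(
            od[i], intensity_at(times[i]), true_model, geometry, optics,
            dcw_per_od,
        )
        od_sub = od[i]
        for s in range(substeps):
            rate, _ = true_instantaneous_rate(
                od_sub, intensity_at(times[i] + s * h), true_model, geometry,
                optics, dcw_per_od,
            )
            od_sub += rate * h
        od[i + 1] = od_sub
    rates[-1], darks[-1] = true_instantaneous_rate(
        od[-1], intensity_at(times[-1]), true_model, geometry, optics,
        dcw_per_od,
    )
    return GrowthCurve(times, od, metadata={
        "true_rates": rates, "dark_fraction": darks,
    })


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def write_dataset_csv(dataset: SyntheticDataset, path: str | Path) -> None:
    """Write the dataset in the flat CSV dialect (px_000..px_719 row-major)."""
    imaging.write_ldp_csv(dataset.as_tuples(), path)


def read_dataset_csv(path: str | Path, seed: int = -1) -> SyntheticDataset:
    """Read a flat CSV back into a dataset (seed unknown -> -1)."""
    records = [LdpRecord(i, c, g) for i, c, g in imaging.read_ldp_csv(path)]
    return SyntheticDataset(records=records, seed=seed)


def write_dataset_pngs(dataset: SyntheticDataset, directory: str | Path) -> Path:
    """Write one grayscale PNG per record plus a manifest CSV.

    Manifest columns: intensity_umol_m2_s, concentration_g_L, png_path.
    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["intensity_umol_m2_s", "concentration_g_L", "png_path"])
        for k, rec in enumerate(dataset.records):
            name = f"ldp_{k:04d}_i{rec.intensity:g}_c{rec.concentration:g}.png"
            imaging.write_ldp_png(rec.ldp, directory / name)
            writer.writerow([repr(rec.intensity), repr(rec.concentration), name])
    return manifest


def with_noise(optics: OpticalParams, noise_sd: float) -> OpticalParams:
    """Copy of ``optics`` with a different camera noise level."""
    return replace(optics, noise_sd=noise_sd)
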