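"""Coupled surrogate growth simulation and cultivation optimization.

The simulator iterates the two surrogates in a forward-Euler loop: at each
step the culture OD730 fixes the cell concentration (via the biomass
calibration), the LDP model predicts the current light field, the growth
model turns the field's features into an instantaneous rate, and the OD is
advanced one step.  On top of the loop sit the cultivation experiments:

* fed-batch runs (no biomass removal, daily productivity series),
* semi-continuous cultivation (SAC) — harvest every ``harvest_interval``
  hours and reset to a fixed inoculum OD, reporting per-cycle volumetric
  (and, for ponds, areal) productivity,
* inoculum optimization — scan candidate starting ODs for the most
  productive single cycle (ties break toward the lower OD, since a leaner
  inoculum costs less biomass to maintain).

``build_default_models`` runs the whole training pipeline for a preset
(generate synthetic LDP corpus, fit the LDP model, simulate reference
growth curves, fit the growth model on LDP-model-predicted features) and is
the canonical entry point for benchmarks, tests and the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import synthgen
from .bioprocess import BiomassCalibration, PondGeometry, volumetric_to_areal
from .grm import (
    FeatureConfig,
    GrmModel,
    GrmTrainingConfig,
    build_training_pairs,
    evaluate_grm,
    train_grm,
)
from .imaging import dark_area_fraction
from .ldpm import (
    LdpmEvaluation,
    LdpmModel,
    LdpmTrainingConfig,
    evaluate_ldpm,
    split_records,
    train_ldpm,
)

_BOUNDARY_TOL = 1e-9


# ---------------------------------------------------------------------------
# light schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    start_h: float
    end_h: float
    intensity: float  # µmol m^-2 s^-1 per source
    n_sources: int = 1

    def __post_init__(self) -> None:
        if self.end_h <= self.start_h:
            raise ValueError("segment must have positive duration")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class LightSchedule:
    """Piecewise-constant incident-light program covering [start, horizon]."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        for prev, nxt in zip(self.segments, self.segments[1:]):
            if abs(prev.end_h - nxt.start_h) > _BOUNDARY_TOL:
                raise ValueError(
                    f"schedule gap/overlap between t={prev.end_h} and "
                    f"t={nxt.start_h}"
                )

    @property
    def start_h(self) -> float:
        return self.segments[0].start_h

    @property
    def horizon_h(self) -> float:
        return self.segments[-1].end_h

    def _segment_at(self, t: float) -> Segment:
        if t < self.start_h - _BOUNDARY_TOL or t > self.horizon_h + _BOUNDARY_TOL:
            raise ValueError(f"t={t} outside schedule horizon")
        for seg in self.segments:
            if t < seg.end_h - _BOUNDARY_TOL:
                return seg
        return self.segments[-1]

    def intensity_at(self, t: float) -> float:
        return self._segment_at(t).intensity

    def n_sources_at(self, t: float) -> int:
        return self._segment_at(t).n_sources

    # -- constructors -------------------------------------------------------

    @classmethod
    def constant(cls, intensity: float, hours: float,
                 n_sources: int = 1) -> "LightSchedule":
        return cls((Segment(0.0, hours, intensity, n_sources),))

    @classmethod
    def from_steps(cls, steps: Sequence[tuple[float, float]],
                   n_sources: int = 1) -> "LightSchedule":
        """Build from (duration_h, intensity) steps starting at t=0."""
        t, segs = 0.0, []
        for dur, inten in steps:
            segs.append(Segment(t, t + dur, inten, n_sources))
            t += dur
        return cls(tuple(segs))

    @classmethod
    def changing_light(cls, n_sources: int = 1) -> "LightSchedule":
        """Low-high-low program (178 / 714 / 178 µmol m^-2 s^-1, 8 h each)."""
        return cls.from_steps([(8, 178.0), (8, 714.0), (8, 178.0)], n_sources)

    @classmethod
    def texas_summer(cls) -> "LightSchedule":
        """Surface-light program emulating a Texas summer day on a pond:
        400/800/1300 for 1 h each, 1500 for 10 h, back down, then night."""
        return cls.from_steps(
            [(1, 400.0), (1, 800.0), (1, 1300.0), (10, 1500.0),
             (1, 1300.0), (1, 800.0), (1, 400.0), (8, 0.0)]
        )

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(s.start_h, s.end_h, s.intensity, s.n_sources)
             for s in self.segments],
            columns=["start_h", "end_h", "intensity", "n_sources"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LightSchedule":
        df = pd.read_csv(path)
        return cls(tuple(
            Segment(float(r.start_h), float(r.end_h), float(r.intensity),
                    int(r.n_sources))
            for r in df.itertuples()
        ))


# ---------------------------------------------------------------------------
# simulation core
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    times: np.ndarray
    od730: np.ndarray
    rates: np.ndarray
    dark_fraction: np.ndarray
    extrapolated: np.ndarray  # bool per step

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times,
            "od730": self.od730,
            "rate_od_per_h": self.rates,
            "dark_fraction": self.dark_fraction,
            "extrapolated": self.extrapolated.astype(int),
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @property
    def any_extrapolation(self) -> bool:
        return bool(self.extrapolated.any())


def _check_dt(schedule: LightSchedule, dt: float) -> None:
    if dt <= 0:
        raise ValueError("dt must be positive")
    for seg in schedule.segments:
        for edge in (seg.start_h - schedule.start_h,
                     seg.end_h - schedule.start_h):
            steps = edge / dt
            if abs(steps - round(steps)) > 1e-6:
                raise ValueError(
                    f"dt={dt} does not divide segment boundary at {edge} h"
                )


def simulate_growth(
    ldpm_model,
    grm_model,
    initial_od: float,
    schedule: LightSchedule,
    dt: float = 1.0,
    calibration: BiomassCalibration | None = None,
) -> SimulationResult:
    """Iterate the coupled LDP -> growth-rate surrogates with forward Euler.

    Each step: concentration = OD * calibration -> predict LDP at (current
    intensity, concentration) -> predict rate from the LDP -> advance OD.
    The models are duck-typed: anything exposing ``predict(intensity,
    concentration) -> LdpPrediction`` and ``predict_rate(ldp) -> float``
    works, so test stubs can replace either surrogate.
    """
    if initial_od <= 0:
        raise ValueError("initial_od must be positive")
    calibration = calibration or BiomassCalibration()
    _check_dt(schedule, dt)

    n_steps = int(round((schedule.horizon_h - schedule.start_h) / dt))
    times = schedule.start_h + np.arange(n_steps + 1) * dt
    od = np.empty(n_steps + 1)
    rates = np.empty(n_steps + 1)
    dark = np.empty(n_steps + 1)
    extrap = np.zeros(n_steps + 1, dtype=bool)

    od[0] = initial_od
    for i in range(n_steps + 1):
        intensity = schedule.intensity_at(min(times[i],
                                              schedule.horizon_h))
        pred = ldpm_model.predict(float(intensity),
                                  float(od[i] * calibration.dcw_per_od))
        rates[i] = grm_model.predict_rate(pred.grid)
        dark[i] = dark_area_fraction(pred.grid)
        extrap[i] = pred.extrapolated
        if i < n_steps:
            od[i + 1] = od[i] + rates[i] * dt
    return SimulationResult(times, od, rates, dark, extrap)


def _tile_schedule(schedule: LightSchedule, horizon_h: float) -> LightSchedule:
    """Repeat a schedule end-to-end until it covers ``horizon_h``."""
    period = schedule.horizon_h - schedule.start_h
    if period <= 0:
        raise ValueError("schedule has zero duration")
    reps = int(np.ceil((horizon_h - _BOUNDARY_TOL) / period))
    segs = []
    for k in range(max(reps, 1)):
        for s in schedule.segments:
            start = (s.start_h - schedule.start_h) + k * period
            end = min((s.end_h - schedule.start_h) + k * period, horizon_h)
            if end <= start + _BOUNDARY_TOL:
                continue
            segs.append(Segment(start, end, s.intensity, s.n_sources))
    return LightSchedule(tuple(segs))


def simulate_fed_batch(
    ldpm_model,
    grm_model,
    initial_od: float,
    schedule: LightSchedule,
    horizon_h: float | None = None,
    dt: float = 1.0,
    calibration: BiomassCalibration | None = None,
) -> tuple[SimulationResult, np.ndarray]:
    """Run the coupled loop without harvest resets, cycling the daily light
    schedule over ``horizon_h`` (default: one schedule period).

    Returns the trajectory and the daily volumetric productivity series
    (g L^-1 day^-1 from the OD gained each 24 h window).
    """
    calibration = calibration or BiomassCalibration()
    if horizon_h is None:
        horizon_h = schedule.horizon_h - schedule.start_h
    tiled = _tile_schedule(schedule, horizon_h)
    result = simulate_growth(ldpm_model, grm_model, initial_od, tiled, dt,
                             calibration)
    daily = []
    t0 = result.times[0]
    day_edges = np.arange(t0, result.times[-1] + _BOUNDARY_TOL, 24.0)
    for a, b in zip(day_edges, day_edges[1:]):
        oa = np.interp(a, result.times, result.od730)
        ob = np.interp(b, result.times, result.od730)
        daily.append((ob - oa) * calibration.dcw_per_od)
    return result, np.asarray(daily)


# ---------------------------------------------------------------------------
# semi-continuous cultivation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SacPlan:
    """Harvest-and-reset plan: every ``harvest_interval_h`` the culture is
    drawn down to ``reset_od`` (the machine-chosen inoculum)."""

    harvest_interval_h: float = 24.0
    reset_od: float = 2.3
    n_cycles: int = 7

    def __post_init__(self) -> None:
        if self.harvest_interval_h <= 0 or self.reset_od <= 0:
            raise ValueError("harvest interval and reset OD must be positive")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")


@dataclass
class ProductivityReport:
    per_cycle_g_per_l_day: np.ndarray
    per_cycle_g_per_m2_day: np.ndarray | None
    cumulative_yield_g_per_l: float
    end_ods: np.ndarray
    cycle_results: list[SimulationResult]
    warnings: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "cycle": np.arange(1, len(self.per_cycle_g_per_l_day) + 1),
            "productivity_g_per_l_day": self.per_cycle_g_per_l_day,
            "end_od730": self.end_ods,
        }
        if self.per_cycle_g_per_m2_day is not None:
            data["productivity_g_per_m2_day"] = self.per_cycle_g_per_m2_day
        return pd.DataFrame(data)


def simulate_sac(
    ldpm_model,
    grm_model,
    plan: SacPlan,
    schedule: LightSchedule,
    dt: float = 1.0,
    calibration: BiomassCalibration | None = None,
    pond: PondGeometry | None = None,
) -> ProductivityReport:
    """Semi-continuous cultivation: ``n_cycles`` independent harvest cycles.

    Each cycle starts at ``reset_od`` and runs one schedule period (which
    must equal the harvest interval); cycle productivity is the harvested
    biomass scaled to a daily rate, and the cumulative yield adds up the
    per-cycle productivities over their cycle lengths.  Pond mode also
    reports areal productivity.
    """
    calibration = calibration or BiomassCalibration()
    period = schedule.horizon_h - schedule.start_h
    if abs(period - plan.harvest_interval_h) > _BOUNDARY_TOL:
        raise ValueError(
            "schedule period must equal the harvest interval "
            f"({period} h vs {plan.harvest_interval_h} h)"
        )

    prods, end_ods, results, warns = [], [], [], []
    for cycle in range(plan.n_cycles):
        res = simulate_growth(ldpm_model, grm_model, plan.reset_od, schedule,
                              dt, calibration)
        od_end = float(res.od730[-1])
        prod = ((od_end - plan.reset_od) * calibration.dcw_per_od
                * 24.0 / plan.harvest_interval_h)
        if od_end < plan.reset_od:
            warns.append(
                f"cycle {cycle + 1}: end OD {od_end:.3f} below reset OD; "
                "negative productivity reported"
            )
        prods.append(prod)
        end_ods.append(od_end)
        results.append(res)

    prods = np.asarray(prods)
    areal = None
    if pond is not None:
        areal = np.asarray([volumetric_to_areal(p, pond) for p in prods])
    cumulative = float(np.sum(prods * plan.harvest_interval_h / 24.0))
    return ProductivityReport(
        per_cycle_g_per_l_day=prods,
        per_cycle_g_per_m2_day=areal,
        cumulative_yield_g_per_l=cumulative,
        end_ods=np.asarray(end_ods),
        cycle_results=results,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# inoculum optimization
# ---------------------------------------------------------------------------

@dataclass
class OptimizationResult:
    best_od: float
    candidate_ods: np.ndarray
    productivities: np.ndarray  # g L^-1 day^-1, aligned with candidate_ods

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "initial_od730": self.candidate_ods,
            "productivity_g_per_l_day": self.productivities,
        })


def optimize_initial_od(
    ldpm_model,
    grm_model,
    candidate_ods: Sequence[float],
    plan: SacPlan,
    schedule: LightSchedule,
    dt: float = 1.0,
    calibration: BiomassCalibration | None = None,
) -> OptimizationResult:
    """Pick the inoculum OD that maximizes single-cycle productivity.

    Candidates are sorted ascending before evaluation, so the result is
    invariant to input ordering and exact ties resolve to the lower OD.
    """
    if len(candidate_ods) < 3:
        raise ValueError("need at least 3 candidate ODs")
    calibration = calibration or BiomassCalibration()
    cands = np.sort(np.asarray(candidate_ods, dtype=float))
    prods = np.empty_like(cands)
    one_cycle = SacPlan(plan.harvest_interval_h, plan.reset_od, 1)
    for j, od0 in enumerate(cands):
        cycle_plan = SacPlan(one_cycle.harvest_interval_h, float(od0), 1)
        report = simulate_sac(ldpm_model, grm_model, cycle_plan, schedule, dt,
                              calibration)
        prods[j] = report.per_cycle_g_per_l_day[0]
    best = int(np.argmax(prods))  # first (= lowest-OD) maximum wins ties
    return OptimizationResult(float(cands[best]), cands, prods)


def brute_force_true_optimum(
    candidate_ods: Sequence[float],
    schedule: LightSchedule,
    true_model: synthgen.TrueGrowthModel,
    geometry: synthgen.Geometry,
    optics: synthgen.OpticalParams,
    interval_h: float = 24.0,
    dt: float = 0.5,
    calibration: BiomassCalibration | None = None,
) -> tuple[float, np.ndarray]:
    """Exhaustive single-cycle optimum of the reference growth law.

    Independent oracle for the surrogate optimizer: integrates the true
    model itself on a fine OD grid and returns (best OD, productivities).
    """
    calibration = calibration or BiomassCalibration()
    cands = np.sort(np.asarray(candidate_ods, dtype=float))
    prods = np.empty_like(cands)
    for j, od0 in enumerate(cands):
        curve = synthgen.simulate_true_growth(
            float(od0), schedule, true_model, geometry, optics, dt=dt,
            dcw_per_od=calibration.dcw_per_od,
        )
        prods[j] = ((curve.od730[-1] - od0) * calibration.dcw_per_od
                    * 24.0 / interval_h)
    return float(cands[int(np.argmax(prods))]), prods


# ---------------------------------------------------------------------------
# end-to-end training pipeline
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """Everything the simulator needs for one preset, plus training metrics."""

    preset: str
    ldpm: LdpmModel
    grm: GrmModel
    geometry: synthgen.Geometry
    optics: synthgen.OpticalParams
    truth: synthgen.TrueGrowthModel
    ldpm_eval: LdpmEvaluation
    grm_r2: float
    n_ldp_records: int
    n_grm_pairs: int


_PBR_GRM_INITIAL_ODS = (0.3, 0.8, 1.5, 2.3, 3.2, 4.5)
_PBR_GRM_INTENSITIES = (107.0, 300.0, 574.0, 714.0)
_POND_GRM_INITIAL_ODS = (0.15, 0.4, 1.0, 1.55, 2.1, 3.0)
_POND_GRM_INTENSITIES = (400.0, 1000.0, 1500.0)


def _training_grids(preset: str, n_intensities: int,
                    n_concentrations: int) -> tuple[np.ndarray, np.ndarray]:
    if preset == "pbr":
        return (np.linspace(0.0, 800.0, n_intensities),
                np.linspace(0.05, 3.9, n_concentrations))
    return (np.linspace(0.0, 1600.0, n_intensities),
            np.linspace(0.05, 2.5, n_concentrations))


def _grm_schedules(preset: str, geometry: synthgen.Geometry):
    if preset == "pbr":
        return [LightSchedule.constant(i, 24.0, geometry.n_sources)
                for i in _PBR_GRM_INTENSITIES]
    scheds = [LightSchedule.texas_summer()]
    scheds += [LightSchedule.constant(i, 24.0) for i in _POND_GRM_INTENSITIES]
    return scheds


def build_default_models(
    preset: str = "pbr",
    seed: int = 0,
    noise_sd: float | None = None,
    n_intensities: int = 20,
    n_concentrations: int = 20,
    use_predicted_ldps: bool = True,
    ldpm_config: LdpmTrainingConfig | None = None,
    grm_config: GrmTrainingConfig | None = None,
    grm_initial_ods: Sequence[float] | None = None,
) -> ModelBundle:
    """Train the full surrogate stack for a preset from synthetic data.

    Pipeline: generate the LDP corpus on an (intensity x concentration)
    grid, fit and evaluate the LDP model on a seeded 80/20 record split,
    integrate reference growth curves across inoculum ODs and light
    programs, assemble feature/rate pairs (features from LDP-model
    predictions unless ``use_predicted_ldps=False`` for ablation), and fit
    and evaluate the growth model.
    """
    if preset not in synthgen.PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    geometry, optics, truth = synthgen.PRESETS[preset]()
    if noise_sd is not None:
        optics = synthgen.with_noise(optics, noise_sd)

    intensities, concentrations = _training_grids(
        preset, n_intensities, n_concentrations
    )
    dataset = synthgen.generate_ldp_dataset(
        intensities, concentrations, geometry, optics, seed=seed
    )
    ldpm_config = ldpm_config or LdpmTrainingConfig(seed=seed)
    train_recs, test_recs = split_records(
        dataset, ldpm_config.test_fraction, seed=ldpm_config.seed
    )
    ldpm_model = train_ldpm(train_recs, ldpm_config)
    ldpm_eval = evaluate_ldpm(ldpm_model, test_recs)

    initials = tuple(grm_initial_ods) if grm_initial_ods is not None else (
        _PBR_GRM_INITIAL_ODS if preset == "pbr" else _POND_GRM_INITIAL_ODS
    )
    schedules = _grm_schedules(preset, geometry)
    curves, scheds = [], []
    for od0 in initials:
        for sched in schedules:
            curve = synthgen.simulate_true_growth(
                od0, sched, truth, geometry, optics, dt=0.5
            )
            # sample hourly, as a plate-reader growth curve would be
            curves.append(type(curve)(curve.times[::2], curve.od730[::2]))
            scheds.append(sched)

    if use_predicted_ldps:
        predictor = lambda i, c: ldpm_model.predict(i, c).grid  # noqa: E731
    else:
        predictor = lambda i, c: synthgen.generate_ldp(  # noqa: E731
            i, c, geometry, optics, rng=None
        )
    feature_config = FeatureConfig()
    x, y = build_training_pairs(curves, scheds, predictor, feature_config)

    grm_config = grm_config or GrmTrainingConfig(seed=seed)
    rng = np.random.default_rng(grm_config.seed + 1)
    idx = rng.permutation(len(x))
    n_test = max(1, int(round(grm_config.test_fraction * len(x))))
    te, tr = idx[:n_test], idx[n_test:]
    grm_model = train_grm((x[tr], y[tr]), grm_config)
    grm_r2 = evaluate_grm(grm_model, (x[te], y[te]))

    return ModelBundle(
        preset=preset,
        ldpm=ldpm_model,
        grm=grm_model,
        geometry=geometry,
        optics=optics,
        truth=truth,
        ldpm_eval=ldpm_eval,
        grm_r2=grm_r2,
        n_ldp_records=len(dataset),
        n_grm_pairs=len(x),
    )


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_growth(result: SimulationResult, path: str | Path,
                title: str = "Simulated growth") -> None:
    """Write a PNG growth-curve figure (OD and dark fraction vs time)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.times, result.od730, lw=2, label="OD730")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("OD730")
    ax2 = ax.twinx()
    ax2.plot(result.times, result.dark_fraction, lw=1, ls="--", color="gray",
             label="dark fraction")
    ax2.set_ylabel("dark-area fraction")
    ax2.set_ylim(0, 1)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
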