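"""Growth-rate prediction model (GRM).

The GRM closes the loop between light availability and biology: it maps an
LDP-derived feature vector to the instantaneous culture growth rate (OD730
per hour).  Features are the 720 gray values scaled to [0, 1] (row-major),
optionally with two appended summaries (mean GSV and dark-area fraction);
labels are finite-difference growth rates computed from measured or
simulated growth curves at the same time points.

The regressor is an RBF support-vector machine with a small cross-validated
grid over regularization and tube width; labels are z-scored internally so
the epsilon grid is scale-free.  Predicted rates are floored at zero
(cultures do not shrink under the modelled conditions) and flooring events
are counted on the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import json
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .imaging import (
    GSV_MAX,
    dark_area_fraction,
    validate_ldp,
)

#: OD730 -> g DCW / L, duplicated here only as a keyword default; the
#: authoritative constant lives in :mod:`phycolight.bioprocess`.
_DEFAULT_DCW_PER_OD = 0.39


# ---------------------------------------------------------------------------
# growth curves and finite-difference rates
# ---------------------------------------------------------------------------

@dataclass
class GrowthCurve:
    """A time series of optical density readings.

    Attributes
    ----------
    times : array, hours, strictly increasing
    od730 : array, dimensionless optical density, strictly positive
    metadata : free-form dict (e.g. light-schedule id)
    """

    times: np.ndarray
    od730: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od730 = np.asarray(self.od730, dtype=float)
        if self.times.shape != self.od730.shape or self.times.ndim != 1:
            raise ValueError("times and od730 must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od730 <= 0):
            raise ValueError("od730 readings must be positive")


def compute_growth_rates(curve: GrowthCurve) -> np.ndarray:
    """Growth rates (OD730 h^-1) at each time point of ``curve``.

    Central finite differences at interior points, second-order one-sided
    differences at the two ends; handles non-uniform sampling.
    """
    if curve.times.size < 3:
        raise ValueError("need at least 3 time points to differentiate")
    return np.gradient(curve.od730, curve.times, edge_order=2)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureConfig:
    """Layout of the LDP feature vector.

    include_summaries appends mean GSV (scaled to [0,1]) and the dark-area
    fraction after the 720 per-pixel values.
    """

    include_summaries: bool = True

    @property
    def n_features(self) -> int:
        return 720 + (2 if self.include_summaries else 0)


def extract_features(ldp: np.ndarray,
                     config: FeatureConfig | None = None) -> np.ndarray:
    """Row-major [0, 1]-scaled feature vector of an LDP."""
    config = config or FeatureConfig()
    grid = validate_ldp(ldp)
    vec = grid.ravel().astype(float) / GSV_MAX
    if config.include_summaries:
        vec = np.concatenate([vec, [float(vec.mean()),
                                    dark_area_fraction(grid)]])
    return vec


def build_training_pairs(
    curves: Sequence[GrowthCurve],
    schedules: Sequence,
    ldp_predictor: Callable[[float, float], np.ndarray],
    config: FeatureConfig | None = None,
    dcw_per_od: float = _DEFAULT_DCW_PER_OD,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble aligned (features, rate) training pairs from growth curves.

    For every time point of every curve the cell concentration is derived
    from the OD reading, the LDP at (current intensity, concentration) is
    obtained from ``ldp_predictor`` — normally the trained LDP model, so the
    GRM learns from the same surrogate patterns it will see in simulation —
    and the rate label is the finite-difference derivative of the curve.

    ``schedules`` is aligned with ``curves``; each entry is either an object
    with an ``intensity_at(t)`` method or a plain constant intensity.
    """
    if len(curves) != len(schedules):
        raise ValueError("curves and schedules must be aligned")
    config = config or FeatureConfig()
    feats, rates = [], []
    for curve, sched in zip(curves, schedules):
        rate = compute_growth_rates(curve)
        for t, od, r in zip(curve.times, curve.od730, rate):
            intensity = (
                sched.intensity_at(t) if hasattr(sched, "intensity_at")
                else float(sched)
            )
            grid = ldp_predictor(float(intensity), float(od * dcw_per_od))
            feats.append(extract_features(grid, config))
            rates.append(r)
    return np.asarray(feats), np.asarray(rates)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class GrmTrainingConfig:
    """Training settings; C/epsilon are in z-scored label units.

    ``gamma_multiplier`` sharpens the RBF kernel against the usual
    1/(d * var) heuristic: the 722-dimensional feature vectors live on an
    intrinsically low-dimensional manifold (they are driven by two physical
    variables), so pairwise distances are compressed and a tighter kernel
    resolves the rate surface much better.
    """

    kernel: str = "rbf"
    regularization: float = 100.0
    epsilon_tube: float = 0.01  # in z-scored label units
    gamma_multiplier: float = 16.0
    cv_folds: int = 3
    hyperparameter_grid: dict | None = None  # None -> default 3x3 grid
    seed: int = 0
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")

    def grid(self) -> dict:
        if self.hyperparameter_grid is not None:
            return self.hyperparameter_grid
        return {"regularization": [100.0, 1000.0],
                "epsilon_tube": [0.003, 0.01],
                "gamma_multiplier": [1.0, 4.0, 16.0, 64.0]}


@dataclass
class GrmModel:
    """Fitted RBF-SVR mapping LDP features to growth rate (OD730 h^-1).

    Prediction is evaluated from the stored support-vector arrays so that a
    saved and reloaded model reproduces outputs bit-for-bit.
    """

    sv: np.ndarray            # (n_sv, d) standardized support vectors
    dual: np.ndarray          # (n_sv,)
    intercept: float
    gamma: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    feature_config: FeatureConfig
    config: GrmTrainingConfig
    rate_domain: tuple[float, float]  # label range seen in training
    floor_count: int = 0

    def _predict_raw(self, features: np.ndarray) -> np.ndarray:
        x = (np.atleast_2d(features) - self.x_mean) / self.x_scale
        d2 = cdist(x, self.sv, "sqeuclidean")
        z = np.exp(-self.gamma * d2) @ self.dual + self.intercept
        return z * self.y_scale + self.y_mean

    def predict_rate(self, ldp: np.ndarray) -> float:
        """Predicted growth rate for an LDP, floored at zero."""
        raw = float(self._predict_raw(extract_features(ldp,
                                                       self.feature_config))[0])
        if raw < 0.0:
            self.floor_count += 1
            return 0.0
        return raw


def _as_xy(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, tuple) and len(pairs) == 2:
        x, y = np.asarray(pairs[0], float), np.asarray(pairs[1], float)
    else:
        x = np.asarray([p[0] for p in pairs], float)
        y = np.asarray([p[1] for p in pairs], float)
    if len(x) != len(y):
        raise ValueError("feature/label length mismatch")
    return x, y


def train_grm(feature_rate_pairs,
              config: GrmTrainingConfig | None = None) -> GrmModel:
    """Fit the GRM on aligned (feature vector, rate) pairs.

    Accepts either an ``(X, y)`` tuple or a sequence of ``(features, rate)``
    pairs.  Features are standardized (constant features get unit scale),
    labels z-scored; the hyperparameter grid is selected by seeded K-fold
    cross-validated MSE, then the winner is refit on all pairs.
    """
    config = config or GrmTrainingConfig()
    x, y = _as_xy(feature_rate_pairs)
    if len(x) < 10:
        raise ValueError("need at least 10 training pairs")

    x_mean = x.mean(axis=0)
    x_scale = x.std(axis=0)
    x_scale[x_scale == 0.0] = 1.0
    xs = (x - x_mean) / x_scale
    y_mean = float(y.mean())
    y_scale = float(y.std()) or 1.0
    ys = (y - y_mean) / y_scale
    gamma_base = 1.0 / (xs.shape[1] * xs.var()) if xs.var() > 0 else 1.0

    grid = config.grid()
    combos = [
        (c, e, g)
        for c in grid.get("regularization", [config.regularization])
        for e in grid.get("epsilon_tube", [config.epsilon_tube])
        for g in grid.get("gamma_multiplier", [config.gamma_multiplier])
    ]
    if len(combos) > 1:
        kf = KFold(n_splits=config.cv_folds, shuffle=True,
                   random_state=config.seed)
        folds = list(kf.split(xs))
        best, best_mse = combos[0], np.inf
        for c, e, g in combos:
            mse = 0.0
            for tr, te in folds:
                m = SVR(kernel=config.kernel, C=c, epsilon=e,
                        gamma=g * gamma_base)
                m.fit(xs[tr], ys[tr])
                mse += float(np.mean((m.predict(xs[te]) - ys[te]) ** 2))
            mse /= len(folds)
            if mse < best_mse - 1e-15:
                best, best_mse = (c, e, g), mse
        c_best, e_best, g_best = best
    else:
        c_best, e_best, g_best = combos[0]

    gamma = g_best * gamma_base
    svr = SVR(kernel=config.kernel, C=c_best, epsilon=e_best, gamma=gamma)
    svr.fit(xs, ys)
    return GrmModel(
        sv=xs[svr.support_].copy(),
        dual=svr.dual_coef_[0].copy(),
        intercept=float(svr.intercept_[0]),
        gamma=float(gamma),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        feature_config=FeatureConfig(
            include_summaries=x.shape[1] > 720
        ),
        config=config,
        rate_domain=(float(y.min()), float(y.max())),
    )


def predict_growth_rate(model: GrmModel, ldp: np.ndarray) -> float:
    """Module-level convenience wrapper around :meth:`GrmModel.predict_rate`."""
    return model.predict_rate(ldp)


def evaluate_grm(model: GrmModel, test_pairs) -> float:
    """Pooled R^2 (1 - SSE/SST about the test-label mean) on held-out pairs."""
    x, y = _as_xy(test_pairs)
    pred = model._predict_raw(x)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise ValueError("test labels have zero variance; R^2 undefined")
    sse = float(((y - pred) ** 2).sum())
    return 1.0 - sse / sst


# ---------------------------------------------------------------------------
# persistence: JSON metadata header + npz array store
# ---------------------------------------------------------------------------

def save_grm(model: GrmModel, path: str | Path) -> None:
    """Persist a GRM to directory ``path`` (meta.json + arrays.npz)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "phycolight-grm-1",
        "intercept": model.intercept,
        "gamma": model.gamma,
        "y_mean": model.y_mean,
        "y_scale": model.y_scale,
        "rate_domain": list(model.rate_domain),
        "include_summaries": model.feature_config.include_summaries,
        "config": {
            "kernel": model.config.kernel,
            "regularization": model.config.regularization,
            "epsilon_tube": model.config.epsilon_tube,
            "gamma_multiplier": model.config.gamma_multiplier,
            "cv_folds": model.config.cv_folds,
            "seed": model.config.seed,
            "test_fraction": model.config.test_fraction,
        },
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    np.savez(path / "arrays.npz", sv=model.sv, dual=model.dual,
             x_mean=model.x_mean, x_scale=model.x_scale)


def load_grm(path: str | Path) -> GrmModel:
    """Load a GRM saved by :func:`save_grm`; predictions match bit-for-bit."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("format") != "phycolight-grm-1":
        raise ValueError(f"unrecognized GRM archive at {path}")
    arrays = np.load(path / "arrays.npz")
    cfg = GrmTrainingConfig(**meta["config"])
    return GrmModel(
        sv=arrays["sv"],
        dual=arrays["dual"],
        intercept=float(meta["intercept"]),
        gamma=float(meta["gamma"]),
        x_mean=arrays["x_mean"],
        x_scale=arrays["x_scale"],
        y_mean=float(meta["y_mean"]),
        y_scale=float(meta["y_scale"]),
        feature_config=FeatureConfig(bool(meta["include_summaries"])),
        config=cfg,
        rate_domain=tuple(meta["rate_domain"]),
    )
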