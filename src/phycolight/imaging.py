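"""Light-distribution-pattern (LDP) image handling.

An LDP is a 2-D map of light availability inside an algal culture, stored as
an 18-row x 40-column grid of 8-bit grayscale values (GSV, 0--255).  Rows run
along the light path: row 0 is nearest the light source, row 17 deepest into
the culture.  Because the GSV responds near-linearly to local irradiance, a
per-concentration linear calibration links the two scales, and the fraction
of pixels darker than 25.5 gray (10 % of the 8-bit maximum) — the *dark-area
fraction* — quantifies mutual shading.

This module owns LDP validation, block-mean compression of raw camera frames
onto the 18x40 grid, the GSV <-> irradiance calibration, the dark-area
statistic, and plain-text / PNG serialization of LDPs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats

#: canonical LDP grid shape (rows along the light path, row 0 nearest source)
LDP_ROWS = 18
LDP_COLS = 40
LDP_PIXELS = LDP_ROWS * LDP_COLS

#: 8-bit grayscale ceiling
GSV_MAX = 255

#: dark-area threshold: pixels with GSV strictly below 10 % of the maximum
DARK_THRESHOLD_GSV = 25.5


def validate_ldp(grid: np.ndarray) -> np.ndarray:
    """Return ``grid`` as an integer array, checking LDP invariants.

    Raises ``ValueError`` if the shape is not 18x40 or any value falls
    outside [0, 255].
    """
    arr = np.asarray(grid)
    if arr.shape != (LDP_ROWS, LDP_COLS):
        raise ValueError(
            f"LDP grid must be {LDP_ROWS}x{LDP_COLS}, got {arr.shape}"
        )
    if arr.min() < 0 or arr.max() > GSV_MAX:
        raise ValueError("LDP gray values must lie in [0, 255]")
    return arr.astype(np.int64)


# ---------------------------------------------------------------------------
# compression of raw frames onto the 18x40 grid
# ---------------------------------------------------------------------------

def _overlap_weights(n_out: int, n_in: int) -> np.ndarray:
    """Exact area-overlap weights mapping ``n_in`` cells onto ``n_out`` cells.

    Row *i* of the returned (n_out, n_in) matrix holds the fractional overlap
    of each input cell with output cell *i*; rows sum to 1, so applying the
    matrix computes the exact area-weighted mean.  For divisible sizes this
    reduces to plain block averaging.
    """
    edges_out = np.linspace(0.0, 1.0, n_out + 1)
    edges_in = np.linspace(0.0, 1.0, n_in + 1)
    lo = np.maximum(edges_out[:-1, None], edges_in[None, :-1])
    hi = np.minimum(edges_out[1:, None], edges_in[None, 1:])
    return np.clip(hi - lo, 0.0, None) * n_out


def compress_to_ldp(raw_image: np.ndarray) -> np.ndarray:
    """Compress a raw grayscale frame to the canonical 18x40 LDP.

    Pooling is the arithmetic block mean (exact area-weighted mean for sizes
    that do not divide evenly), which preserves the brightness of uniform
    regions and hence the GSV-as-irradiance semantics.  An 18x40 input is
    returned unchanged apart from validation.
    """
    arr = np.asarray(raw_image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("raw image must be a 2-D grayscale array")
    h, w = arr.shape
    if h < LDP_ROWS or w < LDP_COLS:
        raise ValueError(
            f"image ({h}x{w}) smaller than the {LDP_ROWS}x{LDP_COLS} target grid"
        )
    if h % LDP_ROWS == 0 and w % LDP_COLS == 0:
        pooled = arr.reshape(LDP_ROWS, h // LDP_ROWS,
                             LDP_COLS, w // LDP_COLS).mean(axis=(1, 3))
    else:
        pooled = _overlap_weights(LDP_ROWS, h) @ arr \
            @ _overlap_weights(LDP_COLS, w).T
    return validate_ldp(np.clip(np.rint(pooled), 0, GSV_MAX))


# ---------------------------------------------------------------------------
# dark-area statistic
# ---------------------------------------------------------------------------

def dark_area_fraction(ldp: np.ndarray, threshold: float = DARK_THRESHOLD_GSV) -> float:
    """Fraction of LDP pixels strictly darker than ``threshold`` gray.

    The comparison is strict (<), so integer grids with values equal to the
    threshold do not count as dark.
    """
    if not 0 < threshold < GSV_MAX:
        raise ValueError("threshold must lie strictly inside (0, 255)")
    arr = np.asarray(ldp)
    return float(np.mean(arr < threshold))


# ---------------------------------------------------------------------------
# GSV <-> irradiance calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GsvFit:
    """Per-concentration linear fit GSV = slope * irradiance + intercept."""

    concentration: float
    slope: float
    intercept: float
    r2: float
    n_samples: int
    flagged: bool = False  # too few unsaturated samples to fit


@dataclass
class GsvCalibration:
    """Collection of per-concentration GSV/irradiance fits."""

    fits: list[GsvFit] = field(default_factory=list)

    @property
    def mean_r2(self) -> float:
        """Arithmetic mean R^2 over un-flagged concentrations."""
        vals = [f.r2 for f in self.fits if not f.flagged]
        return float(np.mean(vals)) if vals else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "concentration_g_L": f.concentration,
                    "slope_gray_per_umol": f.slope,
                    "intercept_gray": f.intercept,
                    "r2": f.r2,
                    "n_samples": f.n_samples,
                    "flagged": f.flagged,
                }
                for f in self.fits
            ]
        )


def fit_gsv_calibration(
    samples: pd.DataFrame | Iterable[tuple[float, float, float]],
    gsv_max: int = GSV_MAX,
    min_samples: int = 3,
) -> GsvCalibration:
    """Fit per-concentration linear GSV ~ irradiance calibrations by OLS.

    Parameters
    ----------
    samples
        A DataFrame with columns ``gsv``, ``irradiance``, ``concentration``,
        or an iterable of ``(gsv, irradiance, concentration)`` tuples.
    gsv_max
        Saturated readings (``gsv >= gsv_max``) are excluded before fitting,
        since clipping at the camera ceiling breaks linearity.
    min_samples
        Concentrations with fewer unsaturated samples are flagged and
        excluded from ``mean_r2``.
    """
    if not isinstance(samples, pd.DataFrame):
        samples = pd.DataFrame(
            list(samples), columns=["gsv", "irradiance", "concentration"]
        )
    if samples.empty:
        raise ValueError("no calibration samples provided")

    cal = GsvCalibration()
    for conc, grp in samples.groupby("concentration", sort=True):
        ok = grp[grp["gsv"] < gsv_max]
        if len(ok) < min_samples:
            cal.fits.append(
                GsvFit(float(conc), float("nan"), float("nan"), float("nan"),
                       len(ok), flagged=True)
            )
            continue
        res = stats.linregress(ok["irradiance"].to_numpy(float),
                               ok["gsv"].to_numpy(float))
        cal.fits.append(
            GsvFit(float(conc), float(res.slope), float(res.intercept),
                   float(res.rvalue ** 2), len(ok))
        )
    return cal


# ---------------------------------------------------------------------------
# serialization: 8-bit PNG and the flat CSV dialect
# ---------------------------------------------------------------------------

def write_ldp_png(ldp: np.ndarray, path: str | Path) -> None:
    """Write an LDP as an 8-bit grayscale PNG."""
    arr = validate_ldp(ldp).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def read_ldp_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back into an LDP grid."""
    with Image.open(Path(path)) as img:
        arr = np.asarray(img.convert("L"))
    return validate_ldp(arr)


def _px_columns() -> list[str]:
    return [f"px_{i:03d}" for i in range(LDP_PIXELS)]


def write_ldp_csv(
    records: Sequence[tuple[float, float, np.ndarray]], path: str | Path
) -> None:
    """Write (intensity, concentration, LDP) records as one flat CSV.

    Columns: ``intensity``, ``concentration``, ``px_000`` ... ``px_719`` in
    row-major order with row 0 nearest the light source.  This is also the
    reader dialect for externally deposited LDP training tables.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["intensity", "concentration", *_px_columns()])
        for intensity, concentration, grid in records:
            flat = validate_ldp(grid).ravel()
            writer.writerow(
                [repr(float(intensity)), repr(float(concentration)),
                 *flat.tolist()]
            )


def read_ldp_csv(path: str | Path) -> list[tuple[float, float, np.ndarray]]:
    """Read the flat CSV dialect back into (intensity, concentration, LDP)."""
    df = pd.read_csv(path)
    cols = _px_columns()
    missing = [c for c in ("intensity", "concentration", *cols) if c not in df]
    if missing:
        raise ValueError(f"flat LDP CSV missing columns: {missing[:5]} ...")
    out = []
    for _, row in df.iterrows():
        grid = row[cols].to_numpy(dtype=np.int64).reshape(LDP_ROWS, LDP_COLS)
        out.append((float(row["intensity"]), float(row["concentration"]),
                    validate_ldp(grid)))
    return out
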