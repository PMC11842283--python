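"""Green-Value growth-curve analysis.

The raw observable is the Green Value (GV): an image-derived pixel
statistic that correlates linearly with culture OD600.  A linear
calibration GV -> OD can be fitted from sacrificial-sampling pairs, but
headline metrics are deliberately computed on raw GV — the GV/OD relation
depends on cell morphology and breaks down under solvent stress, so raw
GV is the less biased readout and conversion is opt-in.

Metrics extracted per curve
---------------------------
delta_green_value
    GV(t2) - GV(t1) between two stated times (default 0 h and 10 h),
    linearly interpolated: the dynamic-range readout used to compare fill
    volumes.
lag_time
    With a sterile-blank GV available, the classic tangent construction:
    the maximum-slope window of ln(GV - blank) is extrapolated back to the
    inoculum level, which recovers the true lag exactly for exponential
    growth.  Without a blank, the first time GV exceeds the baseline by a
    configurable fraction (5%) of the dynamic range — a robust but
    rate-biased surrogate (it includes part of the rise time).
max_rate
    Maximum sliding-window slope (ordinary least squares over
    ``rate_window`` points) of ln(background-subtracted GV), restricted to
    windows whose signal exceeds ``rate_min_fraction`` of the dynamic
    range so the log transform is not evaluated in the noise floor.  With
    a blank the background is the blank; otherwise the pre-growth baseline
    (which removes the inoculum signal too, biasing early-window slopes
    upward — documented, and the reason the blank path exists).
t_stationary
    First time the curve reaches ``stationary_fraction`` (default 0.95) of
    its background-subtracted maximum.  Defined on the
    baseline-subtracted range so it is invariant under affine rescaling
    of GV.

Stationary-phase GV data in solvent cultures is unreliable (aggregate
formation inflates the signal), so curves are flagged rather than
trusted: ``reliable`` is False when the dynamic range does not clear the
baseline noise floor.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, DomainError, RangeError

__all__ = [
    "GrowthCurve",
    "Calibration",
    "GrowthMetrics",
    "ODEstimate",
    "fit_calibration",
    "gv_to_od",
    "growth_metrics",
    "glucose_from_coelution",
    "read_timeseries",
    "write_timeseries",
    "read_layout",
    "write_layout",
    "read_calibration_pairs",
    "analyze_plate",
    "BLANK_CONDITION",
]

#: Layout condition string identifying sterile-medium blank wells.
BLANK_CONDITION = "blank"


@dataclass(frozen=True)
class GrowthCurve:
    """One well's Green-Value time series.

    ``times`` are hours, strictly increasing; ``green_values`` has the
    same length (at least 3 points).  ``condition`` is free-text metadata
    (strain, solvent dose, ...).
    """

    well: str
    times: np.ndarray
    green_values: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        gv = np.asarray(self.green_values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "green_values", gv)
        if times.ndim != 1 or gv.ndim != 1 or len(times) != len(gv):
            raise DomainError("times and green_values must be 1-D, equal length")
        if len(times) < 3:
            raise DomainError("a growth curve needs at least 3 points")
        if not np.all(np.diff(times) > 0):
            raise DomainError("times must be strictly increasing")


@dataclass(frozen=True)
class Calibration:
    """Linear GV -> OD600 calibration: od = slope * gv + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def valid_gv_min(self) -> float | None:
        """GV at which the predicted OD crosses zero (None if slope <= 0)."""
        if self.slope > 0:
            return -self.intercept / self.slope
        return None


@dataclass(frozen=True)
class GrowthMetrics:
    """Derived features of one curve; fields are None when not computable."""

    delta_green_value: float
    lag_time: float | None
    max_rate: float | None
    t_stationary: float | None
    reliable: bool


class ODEstimate(NamedTuple):
    od: float | np.ndarray
    below_calibration: bool | np.ndarray


def fit_calibration(pairs: Sequence[tuple[float, float]]) -> Calibration:
    """Ordinary least squares on (green_value, od600) pairs.

    Requires at least 3 pairs with non-degenerate GV spread.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DomainError("need at least 3 (green_value, od600) pairs")
    gv, od = arr[:, 0], arr[:, 1]
    if np.ptp(gv) == 0:
        raise DegenerateFitError("all Green Values identical; cannot fit a line")
    fit = stats.linregress(gv, od)
    return Calibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def gv_to_od(gv, cal: Calibration) -> ODEstimate:
    """Convert Green Values to OD600 equivalents.

    Values whose prediction would be negative (GV below ``valid_gv_min``)
    are clamped to 0 and flagged.
    """
    gv = np.asarray(gv, dtype=float)
    od = cal.slope * gv + cal.intercept
    below = od < 0
    od = np.where(below, 0.0, od)
    if od.ndim == 0:
        return ODEstimate(float(od), bool(below))
    return ODEstimate(od, below)


def _interp_crossing(times: np.ndarray, values: np.ndarray, level: float) -> float | None:
    """First time ``values`` reaches ``level``, linearly interpolated."""
    above = values >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def growth_metrics(
    curve: GrowthCurve,
    baseline_points: int = 3,
    rate_window: int = 5,
    delta_times: tuple[float, float] = (0.0, 10.0),
    stationary_fraction: float = 0.95,
    lag_fraction: float = 0.05,
    rate_min_fraction: float = 0.2,
    blank_gv: float | None = None,
    epsilon: float = 1e-6,
) -> GrowthMetrics:
    """Extract :class:`GrowthMetrics` from one curve.

    ``blank_gv`` is the mean GV of sterile-medium wells; when provided,
    the background-subtracted signal is proportional to biomass including
    the inoculum, which makes the lag and rate estimators unbiased for
    exponential growth (see module docstring).  ``epsilon`` stabilises the
    log transform near the background.
    """
    t = curve.times
    gv = curve.green_values

    t1, t2 = delta_times
    if t1 < t[0] - 1e-12 or t2 > t[-1] + 1e-12:
        raise RangeError(
            f"delta_times {delta_times} outside the curve span "
            f"[{t[0]}, {t[-1]}] for well {curve.well!r}"
        )
    delta = float(np.interp(t2, t, gv) - np.interp(t1, t, gv))

    nb = min(baseline_points, len(t))
    baseline = float(np.mean(gv[:nb]))
    baseline_sd = float(np.std(gv[:nb]))
    amplitude = float(gv.max() - baseline)

    reliable = amplitude > 3.0 * baseline_sd and amplitude > 0
    if not reliable:
        return GrowthMetrics(delta, None, None, None, False)

    # Threshold-crossing lag (always computable; used directly when no blank)
    lag_threshold = baseline + lag_fraction * amplitude
    lag_crossing = _interp_crossing(t, gv, lag_threshold)

    t_stat = _interp_crossing(t, gv, baseline + stationary_fraction * amplitude)

    background = blank_gv if blank_gv is not None else baseline
    y = gv - background
    growth_signal = gv - baseline
    rate_threshold = rate_min_fraction * amplitude

    best_slope = None
    best_fit = None
    w = rate_window
    if w >= 2 and len(t) >= w:
        for i in range(len(t) - w + 1):
            seg_y = y[i : i + w]
            seg_g = growth_signal[i : i + w]
            if seg_g.min() < rate_threshold or seg_y.min() <= 0:
                continue
            slope, intercept = np.polyfit(t[i : i + w], np.log(seg_y + epsilon), 1)
            if best_slope is None or slope > best_slope:
                best_slope = float(slope)
                best_fit = (float(slope), float(intercept))

    lag = lag_crossing
    if blank_gv is not None and best_fit is not None:
        y0 = baseline - blank_gv
        slope, intercept = best_fit
        if y0 > 0 and slope > 0:
            # tangent construction: where the max-slope line meets the
            # inoculum level
            lag = (np.log(y0) - intercept) / slope
            lag = float(max(lag, 0.0))

    return GrowthMetrics(delta, lag, best_slope, t_stat, True)


def glucose_from_coelution(mixed_rid_mM_equiv: float, gluconate_dad: float) -> float:
    """Glucose (mM) from a mixed glucose+gluconate RID signal.

    Glucose and gluconate co-elute on the HPLC column used here, but only
    gluconate absorbs at 210 nm, so its DAD quantification is subtracted
    from the mixed refractive-index signal.  Negative differences are
    clamped to 0 with a warning.
    """
    if mixed_rid_mM_equiv < 0 or gluconate_dad < 0:
        raise DomainError("concentrations must be >= 0")
    diff = mixed_rid_mM_equiv - gluconate_dad
    if diff < 0:
        warnings.warn(
            f"gluconate ({gluconate_dad} mM) exceeds the mixed signal "
            f"({mixed_rid_mM_equiv} mM); glucose clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return diff


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a Green-Value time-series CSV: column ``time_h`` + one per well."""
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise DomainError(f"{path}: first column must be 'time_h'")
    return df.set_index("time_h")


def write_timeseries(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "time_h"
    out.to_csv(path)


def read_layout(path: str | Path) -> pd.DataFrame:
    """Read a plate-layout CSV mapping well -> condition metadata."""
    df = pd.read_csv(path)
    if "well" not in df.columns:
        raise DomainError(f"{path}: layout must have a 'well' column")
    return df.set_index("well")


def write_layout(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "well"
    out.to_csv(path)


def read_calibration_pairs(path: str | Path) -> list[tuple[float, float]]:
    """Read a calibration CSV with columns ``green_value,od600``."""
    df = pd.read_csv(path)
    for col in ("green_value", "od600"):
        if col not in df.columns:
            raise DomainError(f"{path}: calibration needs a {col!r} column")
    return list(zip(df["green_value"].astype(float), df["od600"].astype(float)))


def analyze_plate(
    timeseries: pd.DataFrame,
    layout: pd.DataFrame | None = None,
    **metric_kwargs,
) -> pd.DataFrame:
    """Compute growth metrics for every well of a plate.

    Wells whose layout condition equals :data:`BLANK_CONDITION` are pooled
    into the sterile background estimate (their mean GV is passed to the
    metric extractor as ``blank_gv``) and excluded from the output.
    """
    t = timeseries.index.to_numpy(dtype=float)
    blank_wells: list[str] = []
    if layout is not None and "condition" in layout.columns:
        blank_wells = [
            w
            for w in layout.index
            if str(layout.loc[w, "condition"]) == BLANK_CONDITION
            and w in timeseries.columns
        ]
    blank_gv = metric_kwargs.pop("blank_gv", None)
    if blank_gv is None and blank_wells:
        blank_gv = float(timeseries[blank_wells].to_numpy().mean())

    rows = []
    for well in timeseries.columns:
        if well in blank_wells:
            continue
        condition = ""
        if layout is not None and well in layout.index and "condition" in layout.columns:
            condition = str(layout.loc[well, "condition"])
        curve = GrowthCurve(well, t, timeseries[well].to_numpy(dtype=float), condition)
        m = growth_metrics(curve, blank_gv=blank_gv, **metric_kwargs)
        rows.append(
            {
                "well": well,
                "condition": condition,
                "delta_green_value": m.delta_green_value,
                "lag_time_h": m.lag_time,
                "max_rate_per_h": m.max_rate,
                "t_stationary_h": m.t_stationary,
                "reliable": m.reliable,
            }
        )
    return pd.DataFrame(rows).set_index("well")
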