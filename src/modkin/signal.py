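"""Raw assay signal to product concentration and initial velocities.

Chromogenic plate assays report absorbance (e.g. p-nitroaniline at
405 nm) that is linear in product concentration; fluorogenic endpoint
assays report derivatized product at discrete stop times.  This module
fits the standard curve, converts signal to product, and extracts
initial velocities by restricting the regression window to the early,
low-consumption part of each progress curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .units import canonical_unit

__all__ = [
    "StandardCurve", "ProgressCurve", "VelocityPoint",
    "fit_standard_curve", "signal_to_product",
    "initial_velocity", "endpoint_velocity",
    "VelocityExtractionError",
    "read_plate_csv", "velocities_to_frame",
]


class VelocityExtractionError(ValueError):
    """Progress curve unusable for an initial-velocity estimate."""


@dataclass(frozen=True)
class StandardCurve:
    """Linear signal-vs-concentration calibration.

    ``slope`` is signal per concentration unit, ``intercept`` the blank
    signal, ``sigma`` the residual standard deviation of the calibration
    fit (used to tolerate slightly negative back-converted blanks).
    """

    slope: float
    intercept: float
    concentration_unit: str = "uM"
    r_squared: float = 1.0
    sigma: float = 0.0

    def __post_init__(self):
        if not self.slope > 0:
            raise ValueError(f"standard-curve slope must be positive, got {self.slope!r}")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared!r}")
        object.__setattr__(self, "concentration_unit", canonical_unit(self.concentration_unit))


@dataclass(frozen=True)
class ProgressCurve:
    """One well's time series of raw signal.

    ``s0`` and ``x`` are the nominal initial substrate and modifier
    concentrations for the well; ``s0`` shares the standard curve's
    concentration unit when velocities are to be consumption-checked.
    """

    well_id: str
    times: np.ndarray
    signal: np.ndarray
    s0: float
    x: float
    replicate_index: int = 0
    s_unit: str = "uM"
    x_unit: str = "uM"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        if times.shape != signal.shape or times.ndim != 1:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if times.size and (np.any(np.diff(times) <= 0) or times[0] < 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "s_unit", canonical_unit(self.s_unit))
        object.__setattr__(self, "x_unit", canonical_unit(self.x_unit))


@dataclass(frozen=True)
class VelocityPoint:
    """Initial velocity extracted from one well."""

    s0: float
    x: float
    v: float  # concentration/time in the curve's unit per s
    n_points_used: int
    window_end_fraction: float
    replicate_index: int = 0
    s_unit: str = "uM"
    x_unit: str = "uM"
    flags: tuple = ()


def fit_standard_curve(concentrations, signals, concentration_unit: str = "uM") -> StandardCurve:
    """Ordinary least-squares line through (concentration, signal) pairs.

    Needs at least three points with nonzero concentration spread.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(signals, dtype=float)
    if c.size < 3:
        raise ValueError(f"standard curve needs >= 3 points, got {c.size}")
    if np.unique(c).size < 3 or np.ptp(c) == 0:
        raise ValueError("standard curve needs >= 3 distinct concentrations")
    res = stats.linregress(c, y)
    resid = y - (res.intercept + res.slope * c)
    dof = max(c.size - 2, 1)
    return StandardCurve(
        slope=float(res.slope), intercept=float(res.intercept),
        concentration_unit=concentration_unit,
        r_squared=float(res.rvalue**2),
        sigma=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def signal_to_product(curve: StandardCurve, signal):
    """Invert the standard curve: product = (signal - intercept)/slope.

    Small negative products (within 3 sigma of the blank, in
    concentration units) are clipped to zero; larger negatives raise,
    because they indicate a wrong blank or curve.
    """
    p = (np.asarray(signal, dtype=float) - curve.intercept) / curve.slope
    floor = -3.0 * curve.sigma / curve.slope if curve.sigma > 0 else 0.0
    if np.any(p < floor - 1e-12):
        worst = float(np.min(p))
        raise ValueError(
            f"signal below blank by more than 3 sigma "
            f"(product {worst:.4g} {curve.concentration_unit} < floor {floor:.4g})")
    out = np.clip(p, 0.0, None)
    return out if out.ndim else float(out)


def _windowed_slope(times, product, s0, max_consumption, min_points, what):
    consumed = product / s0
    ok = consumed <= max_consumption
    # truncate at the LAST index still within the consumption cap
    n_keep = int(np.max(np.nonzero(ok)[0])) + 1 if np.any(ok) else 0
    if n_keep < min_points:
        raise VelocityExtractionError(
            f"{what}: only {n_keep} points with consumption <= "
            f"{max_consumption:.0%}; need at least {min_points}")
    t, pdt = times[:n_keep], product[:n_keep]
    res = stats.linregress(t, pdt)
    if res.slope <= 0:
        raise VelocityExtractionError(
            f"{what}: non-increasing product trend (slope {res.slope:.3g}); "
            "refusing to report an initial velocity")
    slope = float(res.slope)
    # substrate depletion bends the window downward, so the straight OLS
    # chord underestimates the t=0 rate; with enough points a quadratic
    # least-squares fit absorbs the curvature and its derivative at the
    # window start is the initial rate
    if n_keep >= 6:
        c2, c1, _ = np.polyfit(t - t[0], pdt, 2)
        if c1 > 0:
            slope = float(c1)
    return slope, n_keep, float(consumed[n_keep - 1])


def initial_velocity(pc: ProgressCurve, curve: StandardCurve,
                     max_consumption: float = 0.10, min_points: int = 5) -> VelocityPoint:
    """Initial velocity from a continuous progress curve.

    Converts signal to product with the standard curve, truncates the
    series at the last read where product/S0 <= ``max_consumption``
    (default 10%, the conventional initial-rate criterion), and returns
    the least-squares slope of product versus time over that window.
    """
    if not 0 < max_consumption <= 0.2:
        raise ValueError(f"max_consumption must lie in (0, 0.2], got {max_consumption!r}")
    if pc.times.size < 5:
        raise VelocityExtractionError(
            f"well {pc.well_id}: need >= 5 time points, got {pc.times.size}")
    if canonical_unit(pc.s_unit) != curve.concentration_unit:
        raise ValueError(
            f"well {pc.well_id}: substrate unit {pc.s_unit} does not match "
            f"standard-curve unit {curve.concentration_unit}")
    product = np.asarray(signal_to_product(curve, pc.signal))
    slope, n_used, frac = _windowed_slope(
        pc.times, product, pc.s0, max_consumption, min_points, f"well {pc.well_id}")
    flags = ("short_window",) if n_used < pc.times.size // 4 else ()
    return VelocityPoint(s0=pc.s0, x=pc.x, v=slope, n_points_used=n_used,
                         window_end_fraction=frac, replicate_index=pc.replicate_index,
                         s_unit=pc.s_unit, x_unit=pc.x_unit, flags=flags)


def endpoint_velocity(product_concs, times, s0: float | None = None,
                      max_consumption: float = 0.10, min_points: int = 3) -> float:
    """Velocity from endpoint (stopped-reaction) product measurements.

    Least-squares slope of product versus stop time; when ``s0`` is
    given, stop points beyond the consumption cap are excluded first.
    """
    p = np.asarray(product_concs, dtype=float)
    t = np.asarray(times, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("product_concs and times must be 1-D arrays of equal length")
    if t.size < 3:
        raise VelocityExtractionError(f"need >= 3 stop points, got {t.size}")
    if s0 is not None:
        slope, _, _ = _windowed_slope(t, p, s0, max_consumption, min_points, "endpoint series")
        return slope
    res = stats.linregress(t, p)
    if res.slope <= 0:
        raise VelocityExtractionError("non-increasing endpoint product trend")
    return float(res.slope)


# ---------------------------------------------------------------------------
# plate-format IO

def read_plate_csv(data_path, layout_path) -> list[ProgressCurve]:
    """Read long-format kinetic data plus a plate layout into progress curves.

    ``data_path``: CSV with columns well, time_s, signal.
    ``layout_path``: CSV mapping well -> substrate, S0, s_unit, X, x_unit,
    replicate.
    """
    data = pd.read_csv(data_path)
    layout = pd.read_csv(layout_path)
    for col in ("well", "time_s", "signal"):
        if col not in data.columns:
            raise ValueError(f"kinetic data file lacks required column {col!r}")
    for col in ("well", "S0", "s_unit", "X", "x_unit", "replicate"):
        if col not in layout.columns:
            raise ValueError(f"layout file lacks required column {col!r}")
    lay = layout.set_index("well")
    curves = []
    for well, grp in data.groupby("well", sort=True):
        if well not in lay.index:
            raise ValueError(f"well {well!r} present in data but absent from layout")
        row = lay.loc[well]
        grp = grp.sort_values("time_s")
        curves.append(ProgressCurve(
            well_id=str(well),
            times=grp["time_s"].to_numpy(float),
            signal=grp["signal"].to_numpy(float),
            s0=float(row["S0"]), x=float(row["X"]),
            replicate_index=int(row["replicate"]),
            s_unit=str(row["s_unit"]), x_unit=str(row["x_unit"]),
        ))
    return curves


def velocities_to_frame(points: list[VelocityPoint], substrate: str = "") -> pd.DataFrame:
    """Tabulate velocity points as the CSV layout downstream fits read."""
    return pd.DataFrame({
        "substrate": substrate,
        "S0": [p.s0 for p in points],
        "X": [p.x for p in points],
        "replicate": [p.replicate_index for p in points],
        "v": [p.v for p in points],
        "s_unit": [p.s_unit for p in points],
        "x_unit": [p.x_unit for p in points],
        "flags": [";".join(p.flags) for p in points],
    })
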