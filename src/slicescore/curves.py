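"""Interpolation-based metrics on normalized dose-response curves.

All quantities are read off the measured piecewise-linear curve — never a
fitted Hill/4PL equation.  Concentration curves (µM) interpolate on a
log10-dose axis (screens use log-spaced doses); radiation curves (Gy)
interpolate on linear dose.  The axis is configurable per call.

ECx semantics: the dose of the first upward crossing of the kill fraction
through x/100, scanning low to high.  A curve whose maximal kill never
reaches x/100 is "not reached" (NR).  A curve already at or above x/100 at
the lowest tested dose is flagged ``below_range`` and reported at that
dose; no extrapolation is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .assay import AssayError, DoseResponseCurve, kill_fraction

__all__ = [
    "EcxResult",
    "CurveShape",
    "BiphasicRule",
    "dose_axis",
    "interpolate_response",
    "compute_ecx",
    "compute_icx",
    "compute_normalized_auc",
    "compute_slope_at_ec50",
    "detect_shape",
]

Axis = Literal["log", "linear", "auto"]

ECX_LEVELS = (10, 25, 50, 75, 90)


@dataclass(frozen=True)
class EcxResult:
    """Dose at which kill reaches x%, or NR if the curve never gets there."""

    x: float
    dose_at_x: float | None
    reached: bool
    below_range: bool = False

    def __post_init__(self) -> None:
        if not self.reached and self.dose_at_x is not None:
            raise AssayError("NR result must not carry a dose")


@dataclass(frozen=True)
class BiphasicRule:
    """Operational definition of a biphasic (plateauing) kill curve.

    The curve is biphasic when substantial killing occurs over the lower
    half of the dose grid (>= ``low_half_kill``), the upper half adds
    little (``tail_gain`` or less), and meaningful tumor remains at the top
    dose (> ``min_remaining_percent``).  A flat zero-kill curve is not
    biphasic (no rapid killing at low doses), nor is a curve that kills
    essentially everything.
    """

    low_half_kill: float = 0.25
    tail_gain: float = 0.10
    min_remaining_percent: float = 10.0


@dataclass(frozen=True)
class CurveShape:
    """Shape diagnostics of a tumor survival curve."""

    max_kill: float
    max_growth_percent: float
    remaining_at_max: float
    biphasic: bool
    slope_at_ec50: float


def _resolve_axis(curve: DoseResponseCurve, axis: Axis) -> str:
    if axis == "auto":
        return "log" if curve.log_axis() else "linear"
    return axis


def dose_axis(doses: np.ndarray, axis: str) -> np.ndarray:
    """Map doses onto the interpolation axis (log10 or identity)."""
    doses = np.asarray(doses, dtype=float)
    if axis == "log":
        if np.any(doses <= 0):
            raise AssayError("log axis requires strictly positive doses")
        return np.log10(doses)
    if axis == "linear":
        return doses
    raise AssayError(f"unknown axis {axis!r}")


def _axis_inverse(x: float, axis: str) -> float:
    return float(10.0 ** x) if axis == "log" else float(x)


def interpolate_response(
    curve: DoseResponseCurve, dose: float, axis: Axis = "auto"
) -> float:
    """Piecewise-linear response at an in-range dose; no extrapolation."""
    ax = _resolve_axis(curve, axis)
    d = curve.dose_array
    if not (d[0] <= dose <= d[-1]):
        raise AssayError(
            f"dose {dose:g} outside tested range [{d[0]:g}, {d[-1]:g}]"
        )
    x = dose_axis(d, ax)
    return float(np.interp(dose_axis(np.array([dose]), ax)[0], x, curve.value_array))


def _first_crossing(
    x: np.ndarray, k: np.ndarray, threshold: float, axis: str
) -> EcxResult:
    """First upward crossing of k through threshold, ties toward lower dose."""
    at_or_above = np.nonzero(k >= threshold)[0]
    if at_or_above.size == 0:
        return EcxResult(x=threshold * 100, dose_at_x=None, reached=False)
    i = int(at_or_above[0])
    if i == 0:
        return EcxResult(
            x=threshold * 100,
            dose_at_x=_axis_inverse(x[0], axis),
            reached=True,
            below_range=True,
        )
    # k[i-1] < threshold <= k[i]: interpolate within the bracketing segment
    frac = (threshold - k[i - 1]) / (k[i] - k[i - 1])
    xc = x[i - 1] + frac * (x[i] - x[i - 1])
    return EcxResult(x=threshold * 100, dose_at_x=_axis_inverse(xc, axis), reached=True)


def compute_ecx(
    kill: Sequence[float] | np.ndarray,
    doses: Sequence[float] | np.ndarray,
    x: float,
    axis: str = "log",
) -> EcxResult:
    """ECx of a kill series: dose of the first crossing of kill = x/100.

    Parameters
    ----------
    kill : kill fractions (1 − survival) per dose; may be negative (growth)
        or non-monotone.
    doses : strictly increasing positive doses matching ``kill``.
    x : target kill percent, one of 10, 25, 50, 75, 90.
    axis : interpolation axis, ``"log"`` or ``"linear"``.
    """
    if x not in ECX_LEVELS:
        raise AssayError(f"x must be one of {ECX_LEVELS}, got {x}")
    doses = np.asarray(doses, dtype=float)
    kill = np.asarray(kill, dtype=float)
    if doses.size < 2:
        raise AssayError("ECx requires at least 2 doses")
    if doses.size != kill.size:
        raise AssayError("kill and doses must have equal length")
    if np.any(np.diff(doses) <= 0):
        raise AssayError("doses must be strictly increasing")
    return _first_crossing(dose_axis(doses, axis), kill, x / 100.0, axis)


def compute_icx(curve: DoseResponseCurve, x: float, axis: Axis = "auto") -> EcxResult:
    """ICx of a survival curve: dose at which viability falls to (100−x)%.

    Identical machinery to :func:`compute_ecx` applied to kill = 1 − s(d);
    exists as the named quantity reported in ICx tables (NR when maximal
    kill stays below x%).
    """
    if curve.kind != "tumor_survival":
        raise AssayError("ICx requires a tumor_survival curve")
    return compute_ecx(
        kill_fraction(curve), curve.dose_array, x, _resolve_axis(curve, axis)
    )


def compute_normalized_auc(
    values: Sequence[float] | np.ndarray,
    doses: Sequence[float] | np.ndarray,
    axis: str = "log",
) -> float:
    """Trapezoidal area over the interpolation axis divided by axis length.

    Equivalently the mean response across the tested range; a uniformly
    growing kill series (negative values) yields a negative area.
    """
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    if doses.size < 2:
        raise AssayError("normalized AUC requires at least 2 doses")
    if doses.size != values.size:
        raise AssayError("values and doses must have equal length")
    x = dose_axis(doses, axis)
    span = x[-1] - x[0]
    if span <= 0:
        raise AssayError("degenerate dose axis (d_min = d_max)")
    return float(np.trapezoid(values, x) / span)


def compute_slope_at_ec50(
    values: Sequence[float] | np.ndarray,
    doses: Sequence[float] | np.ndarray,
    axis: str = "log",
) -> float:
    """Slope of the segment containing the series' own 50% crossing.

    In response units per interpolation-axis unit (per log10 decade on the
    log axis, per dose unit on the linear axis).  If the series never
    reaches 0.5 the steepest (maximum) segment slope is used; a flat curve
    has slope 0.
    """
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    if doses.size < 2:
        raise AssayError("slope requires at least 2 doses")
    x = dose_axis(doses, axis)
    slopes = np.diff(values) / np.diff(x)
    res = _first_crossing(x, values, 0.5, axis)
    if not res.reached:
        return float(np.max(slopes))
    if res.below_range:
        return float(slopes[0])
    xc = dose_axis(np.array([res.dose_at_x]), axis)[0]
    # segment index containing the crossing (crossing at a node belongs to
    # the segment whose upper end first attains the threshold)
    i = int(np.searchsorted(x, xc, side="left"))
    i = max(1, min(i, len(x) - 1))
    return float(slopes[i - 1])


def detect_shape(
    curve: DoseResponseCurve,
    axis: Axis = "auto",
    rule: BiphasicRule = BiphasicRule(),
) -> CurveShape:
    """Shape diagnostics: growth, residual tumor, biphasic plateau, slope."""
    if curve.kind != "tumor_survival":
        raise AssayError("detect_shape requires a tumor_survival curve")
    s = curve.value_array
    k = kill_fraction(curve)
    n = s.size
    max_kill = float(np.max(k))
    max_growth_percent = float(100.0 * np.max(s))
    remaining_at_max = float(100.0 * s[-1])

    low_half = k[: (n + 1) // 2]
    low_kill = float(np.max(low_half))
    biphasic = (
        low_kill >= rule.low_half_kill
        and (max_kill - low_kill) <= rule.tail_gain
        and remaining_at_max > rule.min_remaining_percent
    )

    if n >= 2:
        slope = compute_slope_at_ec50(k, curve.dose_array, _resolve_axis(curve, axis))
    else:
        slope = 0.0
    return CurveShape(
        max_kill=max_kill,
        max_growth_percent=max_growth_percent,
        remaining_at_max=remaining_at_max,
        biphasic=biphasic,
        slope_at_ec50=slope,
    )
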