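"""The eleven therapeutic-window parameters, each bounded in [−1, +1].

Parameters 1–8 compare tumor kill against normal-tissue (slice) toxicity:
+1 means tumor is killed with no collateral damage, −1 means the tissue
dies while the tumor thrives.  Parameters 9–11 judge the tumor curve's own
behavior (growth acceleration, biphasic plateau, incomplete kill) on a
ternary {−1, 0, +1} scale.

For the ECx windows (parameters 2–6) toxicity is read at the dose where
tumor kill passes through x%.  When that dose is never reached (NR) the
window is penalized by the kill shortfall and charged the toxicity at the
top tested dose, so an agent that never attains ECx cannot outscore one
that does at equal toxicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assay import AssayError, DoseResponseCurve, kill_fraction
from .curves import (
    Axis,
    BiphasicRule,
    CurveShape,
    ECX_LEVELS,
    _resolve_axis,
    compute_ecx,
    compute_normalized_auc,
    compute_slope_at_ec50,
    detect_shape,
    dose_axis,
    interpolate_response,
)

__all__ = [
    "TherapeuticWindows",
    "WINDOW_NAMES",
    "ecx_window",
    "max_kill_window",
    "slope_window",
    "auc_window",
    "growth_window",
    "biphasic_window",
    "incomplete_kill_window",
    "compute_all_windows",
]

#: Canonical window order; matches the weight-vector order.
WINDOW_NAMES = (
    "max_kill", "ec10", "ec25", "ec50", "ec75", "ec90",
    "slope", "auc", "growth", "biphasic", "incomplete",
)


def _clamp(w: float) -> float:
    return float(np.clip(w, -1.0, 1.0))


@dataclass(frozen=True)
class TherapeuticWindows:
    """The eleven window values plus per-ECx NR flags."""

    w_max_kill: float
    w_ec10: float
    w_ec25: float
    w_ec50: float
    w_ec75: float
    w_ec90: float
    w_slope: float
    w_auc: float
    w_growth: float
    w_biphasic: float
    w_incomplete: float
    nr_flags: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in zip(WINDOW_NAMES, self.as_tuple()):
            if not -1.0 <= v <= 1.0:
                raise AssayError(f"window {name} = {v} outside [-1, 1]")
        for name in ("w_growth", "w_biphasic", "w_incomplete"):
            if getattr(self, name) not in (-1.0, 0.0, 1.0):
                raise AssayError(f"{name} must be ternary (-1, 0, +1)")

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.w_max_kill, self.w_ec10, self.w_ec25, self.w_ec50,
            self.w_ec75, self.w_ec90, self.w_slope, self.w_auc,
            self.w_growth, self.w_biphasic, self.w_incomplete,
        )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(WINDOW_NAMES, self.as_tuple()))


def _check_pair(tumor: DoseResponseCurve, tox: DoseResponseCurve) -> None:
    if tumor.kind != "tumor_survival":
        raise AssayError("first curve must be tumor_survival")
    if tox.kind != "slice_toxicity":
        raise AssayError("second curve must be slice_toxicity")
    if tumor.dose_unit != tox.dose_unit:
        raise AssayError(
            f"dose-unit mismatch: tumor {tumor.dose_unit}, tox {tox.dose_unit}"
        )
    if tumor.doses[0] < tox.doses[0] or tumor.doses[-1] > tox.doses[-1]:
        raise AssayError(
            "tumor dose grid extends beyond the toxicity grid; toxicity can "
            "only be interpolated in-range"
        )


def ecx_window(
    tumor: DoseResponseCurve,
    tox: DoseResponseCurve,
    x: float,
    axis: Axis = "auto",
    nr_mode: str = "shortfall",
) -> tuple[float, bool]:
    """ECx window (parameters 2–6): kill level minus toxicity at the
    tumor's x% crossing dose.

    Returns ``(window, reached)``.  If ECx is reached at dose d*,
    w = clamp(x/100 − tox(d*)) — tumor kill at the crossing is x/100 by
    construction.  If the crossing precedes the dose grid (kill already at
    or above x% at the lowest dose) both responses are read at the lowest
    dose: w = clamp(k(d_min) − tox(d_min)), so a maximally potent,
    non-toxic agent scores +1 rather than x/100.  If NR, the default
    ``shortfall`` fallback gives w = clamp(k_max − x/100 − tox(d_max)):
    the shortfall from the target plus top-dose toxicity is the penalty;
    ``worst`` assigns −1.
    """
    _check_pair(tumor, tox)
    ax = _resolve_axis(tumor, axis)
    kill = kill_fraction(tumor)
    doses = tumor.dose_array
    res = compute_ecx(kill, doses, x, ax)
    if res.below_range:
        w = _clamp(float(kill[0]) - interpolate_response(tox, doses[0], ax))
    elif res.reached:
        w = _clamp(x / 100.0 - interpolate_response(tox, res.dose_at_x, ax))
    elif nr_mode == "shortfall":
        k_max = float(np.max(kill))
        tox_top = interpolate_response(tox, doses[-1], ax)
        w = _clamp(k_max - x / 100.0 - tox_top)
    elif nr_mode == "worst":
        w = -1.0
    else:
        raise AssayError(f"unknown nr_mode {nr_mode!r}")
    return w, res.reached


def max_kill_window(
    tumor: DoseResponseCurve, tox: DoseResponseCurve, axis: Axis = "auto"
) -> float:
    """Parameter 1: kill minus toxicity, both at the maximum tested dose."""
    _check_pair(tumor, tox)
    ax = _resolve_axis(tumor, axis)
    k_top = float(kill_fraction(tumor)[-1])
    return _clamp(k_top - interpolate_response(tox, tumor.doses[-1], ax))


def slope_window(
    tumor: DoseResponseCurve, tox: DoseResponseCurve, axis: Axis = "auto"
) -> float:
    """Parameter 7: bounded contrast of the slopes through the tumor EC50
    and the toxicity EC50, (m_T − m_O) / (|m_T| + |m_O|).

    When both measured slopes are zero the ratio is degenerate and the
    comparison falls back to 50%-crossing status: a tumor curve that sits
    at or above 50% kill while toxicity never crosses is maximally
    favorable (+1), the reverse maximally unfavorable (−1), and two flat
    curves on the same side of 50% score 0.
    """
    _check_pair(tumor, tox)
    ax = _resolve_axis(tumor, axis)
    kill = kill_fraction(tumor)
    m_t = compute_slope_at_ec50(kill, tumor.dose_array, ax)
    m_o = compute_slope_at_ec50(tox.value_array, tox.dose_array, ax)
    denom = abs(m_t) + abs(m_o)
    if denom == 0.0:
        t_crossed = compute_ecx(kill, tumor.dose_array, 50, ax).reached
        o_crossed = compute_ecx(tox.value_array, tox.dose_array, 50, ax).reached
        if t_crossed and not o_crossed:
            return 1.0
        if o_crossed and not t_crossed:
            return -1.0
        return 0.0
    return _clamp((m_t - m_o) / denom)


def auc_window(
    tumor: DoseResponseCurve, tox: DoseResponseCurve, axis: Axis = "auto"
) -> float:
    """Parameter 8: normalized kill AUC minus normalized toxicity AUC.

    Both areas are evaluated on the tumor's dose span (toxicity interpolated
    onto the tumor grid when the grids differ).
    """
    _check_pair(tumor, tox)
    ax = _resolve_axis(tumor, axis)
    doses = tumor.dose_array
    nauc_kill = compute_normalized_auc(kill_fraction(tumor), doses, ax)
    tox_on_grid = np.interp(
        dose_axis(doses, ax), dose_axis(tox.dose_array, ax), tox.value_array
    )
    nauc_tox = compute_normalized_auc(tox_on_grid, doses, ax)
    return _clamp(nauc_kill - nauc_tox)


def growth_window(shape: CurveShape) -> float:
    """Parameter 9: treatment-accelerated growth.

    Max survival <= 125% of untreated → +1; (125%, 150%] → 0; > 150% → −1.
    """
    g = shape.max_growth_percent
    if g <= 125.0:
        return 1.0
    if g <= 150.0:
        return 0.0
    return -1.0


def biphasic_window(shape: CurveShape) -> float:
    """Parameter 10: −1 for a biphasic (plateauing) curve, +1 otherwise."""
    return -1.0 if shape.biphasic else 1.0


def incomplete_kill_window(shape: CurveShape) -> float:
    """Parameter 11: residual tumor at the top dose.

    < 10% remaining → +1; 10%–25% → 0; > 25% → −1.
    """
    r = shape.remaining_at_max
    if r < 10.0:
        return 1.0
    if r <= 25.0:
        return 0.0
    return -1.0


def compute_all_windows(
    tumor: DoseResponseCurve,
    tox: DoseResponseCurve,
    axis: Axis = "auto",
    biphasic_rule: BiphasicRule = BiphasicRule(),
    nr_mode: str = "shortfall",
) -> TherapeuticWindows:
    """All eleven windows for one drug-tumor-slice interaction."""
    _check_pair(tumor, tox)
    shape = detect_shape(tumor, axis=axis, rule=biphasic_rule)
    ecx_vals: dict[int, float] = {}
    nr_flags: dict[int, bool] = {}
    for x in ECX_LEVELS:
        w, reached = ecx_window(tumor, tox, x, axis, nr_mode=nr_mode)
        ecx_vals[x] = w
        nr_flags[x] = not reached
    return TherapeuticWindows(
        w_max_kill=max_kill_window(tumor, tox, axis),
        w_ec10=ecx_vals[10],
        w_ec25=ecx_vals[25],
        w_ec50=ecx_vals[50],
        w_ec75=ecx_vals[75],
        w_ec90=ecx_vals[90],
        w_slope=slope_window(tumor, tox, axis),
        w_auc=auc_window(tumor, tox, axis),
        w_growth=growth_window(shape),
        w_biphasic=biphasic_window(shape),
        w_incomplete=incomplete_kill_window(shape),
        nr_flags=nr_flags,
    )
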