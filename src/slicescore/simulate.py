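"""Synthetic assay generator with analytic ground truth.

Simulated screens stand in for raw screening data: tumor survival follows
a Hill form s(d) = g·[f + (1−f)/(1+(d/EC50)^h)] with optional growth
acceleration (g > 1) and an optional plateau cap producing biphasic
shapes; slice toxicity follows a monotone Hill death curve.  Raw
measurements are back-constructed so that the normalization pipeline
recovers the closed-form curves — exactly when noise is zero, in
expectation under multiplicative log-normal replicate noise.

The module also provides a dense-grid analytic oracle: the same window and
score definitions evaluated on a 10⁴-point sampling of the closed-form
curves, used as ground truth in recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .assay import (
    AssayDesign,
    AssayError,
    DoseResponseCurve,
    RawSliceMeasurement,
    RawTumorMeasurement,
)
from .curves import BiphasicRule
from .score import DssResult, WeightVector, DEFAULT_WEIGHTS, aggregate_dss
from .windows import TherapeuticWindows, compute_all_windows

__all__ = [
    "HillParams",
    "SyntheticAssay",
    "hill_survival",
    "hill_toxicity",
    "default_doses",
    "simulate_assay",
    "oracle_windows",
    "SCENARIOS",
]

ORACLE_GRID_POINTS = 10_000

#: Healthy-baseline and dead-control PI anchor levels (arbitrary units).
PI_HEALTHY = 100.0
PI_DEAD = 1000.0
FLUOR_DAY1 = 1000.0


@dataclass(frozen=True)
class HillParams:
    """Generative Hill parameters for one arm of a synthetic assay.

    floor — residual survival fraction at infinite dose (0 = complete
    kill); ec50 — dose of half-maximal effect; hill — slope coefficient;
    growth_factor — ≥ 1 multiplier emulating treatment-accelerated growth;
    plateau_kill — optional cap on kill fraction producing biphasic shapes.
    """

    floor: float = 0.0
    ec50: float = 1.0
    hill: float = 1.0
    growth_factor: float = 1.0
    plateau_kill: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.floor <= 1.0:
            raise AssayError("floor must be in [0, 1]")
        if self.ec50 <= 0:
            raise AssayError("ec50 must be > 0")
        if self.hill <= 0:
            raise AssayError("hill must be > 0")
        if self.growth_factor < 1.0:
            raise AssayError("growth_factor must be >= 1")
        if self.plateau_kill is not None and not 0.0 < self.plateau_kill <= 1.0:
            raise AssayError("plateau_kill must be in (0, 1]")


def hill_survival(params: HillParams, doses: np.ndarray) -> np.ndarray:
    """Closed-form tumor survival fraction at each dose."""
    d = np.asarray(doses, dtype=float)
    u = (d / params.ec50) ** params.hill
    s = params.growth_factor * (params.floor + (1.0 - params.floor) / (1.0 + u))
    if params.plateau_kill is not None:
        s = np.maximum(s, 1.0 - params.plateau_kill)
    return s


def hill_toxicity(params: HillParams, doses: np.ndarray) -> np.ndarray:
    """Closed-form slice toxicity: the Hill death fraction, clipped to [0, 1]."""
    return np.clip(1.0 - hill_survival(params, doses), 0.0, 1.0)


def default_doses(design: AssayDesign, center: float) -> np.ndarray:
    """Default dose grid: log-spaced over 3 decades centered on ``center``
    for concentration screens, linear up to 3x ``center`` for radiation.
    """
    if design.dose_spacing == "log":
        return np.logspace(
            np.log10(center) - 1.5, np.log10(center) + 1.5, design.n_doses
        )
    return np.linspace(3.0 * center / design.n_doses, 3.0 * center, design.n_doses)


@dataclass(frozen=True)
class SyntheticAssay:
    """One simulated drug-tumor screen plus its analytic ground truth."""

    design: AssayDesign
    tumor_params: HillParams
    tox_params: HillParams
    doses: tuple[float, ...]
    tumor_raw: list[RawTumorMeasurement]
    slice_raw: list[RawSliceMeasurement]
    truth_survival: tuple[float, ...]
    truth_toxicity: tuple[float, ...]
    oracle: DssResult
    noise_cv: float
    seed: int
    tumor_id: str = "sim_tumor"
    drug_id: str = "sim_drug"

    def truth_curves(self) -> tuple[DoseResponseCurve, DoseResponseCurve]:
        """Noiseless design-grid curves (not the dense oracle grid)."""
        tumor = DoseResponseCurve(
            doses=self.doses, values=self.truth_survival, kind="tumor_survival",
            dose_unit=self.design.dose_unit, tumor_id=self.tumor_id,
            drug_id=self.drug_id,
        )
        tox = DoseResponseCurve(
            doses=self.doses, values=self.truth_toxicity, kind="slice_toxicity",
            dose_unit=self.design.dose_unit, drug_id=self.drug_id,
        )
        return tumor, tox

    def truth_dict(self) -> dict:
        """JSON-serializable ground truth (curves, windows, DSS, seed)."""
        return {
            "tumor_id": self.tumor_id,
            "drug_id": self.drug_id,
            "seed": self.seed,
            "noise_cv": self.noise_cv,
            "doses": list(self.doses),
            "dose_unit": self.design.dose_unit,
            "truth_survival": list(self.truth_survival),
            "truth_toxicity": list(self.truth_toxicity),
            "oracle_windows": self.oracle.windows.as_dict(),
            "oracle_dss": self.oracle.dss,
        }


def _noise_multipliers(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Mean-one log-normal multipliers with coefficient of variation ``cv``."""
    if cv == 0.0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=n)


def simulate_assay(
    tumor: HillParams,
    tox: HillParams,
    design: AssayDesign = AssayDesign(),
    noise_cv: float = 0.10,
    seed: int = 0,
    doses: np.ndarray | None = None,
    tumor_id: str = "sim_tumor",
    drug_id: str = "sim_drug",
    weights: WeightVector = DEFAULT_WEIGHTS,
) -> SyntheticAssay:
    """Generate one synthetic screen with known ground truth.

    Raw tumor foci carry a constant day-1 fluorescence and an end-point
    BLI of ``fluor · s(d) · noise``; untreated controls use s = 1, so the
    normalization ratio recovers s(d).  Raw slices carry PI signals scaled
    between the healthy and dead anchors by tox(d), with the same
    multiplicative noise model.  Identical seeds reproduce identical data.
    """
    if noise_cv < 0:
        raise AssayError("noise_cv must be >= 0")
    if doses is None:
        doses = default_doses(design, tumor.ec50)
    doses = np.asarray(doses, dtype=float)
    if doses.size != design.n_doses:
        raise AssayError("dose grid length must match design.n_doses")

    rng = np.random.default_rng(seed)
    s_true = hill_survival(tumor, doses)
    tox_true = hill_toxicity(tox, doses)

    tumor_raw: list[RawTumorMeasurement] = []
    n = design.n_foci_per_dose
    for i in range(n):  # untreated controls
        mult = _noise_multipliers(rng, 1, noise_cv)[0]
        tumor_raw.append(
            RawTumorMeasurement(
                focus_id=f"ctrl_{i}", tumor_id=tumor_id, drug_id=drug_id,
                dose=0.0, dose_unit=design.dose_unit,
                bli_end=FLUOR_DAY1 * mult, fluor_day1=FLUOR_DAY1,
                is_untreated_control=True,
            )
        )
    for j, d in enumerate(doses):
        mults = _noise_multipliers(rng, n, noise_cv)
        for i in range(n):
            tumor_raw.append(
                RawTumorMeasurement(
                    focus_id=f"d{j}_f{i}", tumor_id=tumor_id, drug_id=drug_id,
                    dose=float(d), dose_unit=design.dose_unit,
                    bli_end=FLUOR_DAY1 * s_true[j] * mults[i],
                    fluor_day1=FLUOR_DAY1,
                )
            )

    slice_raw: list[RawSliceMeasurement] = []
    for i in range(n):
        slice_raw.append(
            RawSliceMeasurement(
                slice_id=f"healthy_{i}", drug_id=drug_id, dose=0.0,
                dose_unit=design.dose_unit,
                pi_signal=PI_HEALTHY * _noise_multipliers(rng, 1, noise_cv)[0],
                role="healthy_baseline",
            )
        )
        slice_raw.append(
            RawSliceMeasurement(
                slice_id=f"dead_{i}", drug_id=drug_id, dose=0.0,
                dose_unit=design.dose_unit,
                pi_signal=PI_DEAD * _noise_multipliers(rng, 1, noise_cv)[0],
                role="dead_control",
            )
        )
    for j, d in enumerate(doses):
        mults = _noise_multipliers(rng, n, noise_cv)
        for i in range(n):
            pi = PI_HEALTHY + (PI_DEAD - PI_HEALTHY) * tox_true[j]
            slice_raw.append(
                RawSliceMeasurement(
                    slice_id=f"d{j}_s{i}", drug_id=drug_id, dose=float(d),
                    dose_unit=design.dose_unit, pi_signal=pi * mults[i],
                )
            )

    oracle = oracle_windows(
        tumor, tox, design, doses=doses, weights=weights,
        tumor_id=tumor_id, drug_id=drug_id,
    )
    return SyntheticAssay(
        design=design, tumor_params=tumor, tox_params=tox,
        doses=tuple(float(d) for d in doses),
        tumor_raw=tumor_raw, slice_raw=slice_raw,
        truth_survival=tuple(float(v) for v in s_true),
        truth_toxicity=tuple(float(v) for v in tox_true),
        oracle=oracle, noise_cv=noise_cv, seed=seed,
        tumor_id=tumor_id, drug_id=drug_id,
    )


def oracle_windows(
    tumor: HillParams,
    tox: HillParams,
    design: AssayDesign = AssayDesign(),
    doses: np.ndarray | None = None,
    n_grid: int = ORACLE_GRID_POINTS,
    weights: WeightVector = DEFAULT_WEIGHTS,
    biphasic_rule: BiphasicRule = BiphasicRule(),
    tumor_id: str = "sim_tumor",
    drug_id: str = "sim_drug",
) -> DssResult:
    """Analytic oracle: windows and DSS from the closed-form curves.

    ECx, AUC, max-kill and shape windows are evaluated on a 10⁴-point
    dense grid over the design's dose span, where the piecewise-linear
    metrics are indistinguishable from the continuous curve.  The slope
    window is the one quantity defined relative to a measurement grid —
    a segment slope tends to the local derivative under refinement — so
    its ground truth is evaluated at the design's own dose grid.  Serves
    as ground truth for recovery tests.
    """
    if doses is None:
        doses = default_doses(design, tumor.ec50)
    doses = np.asarray(doses, dtype=float)
    if design.dose_spacing == "log":
        grid = np.logspace(np.log10(doses[0]), np.log10(doses[-1]), n_grid)
    else:
        grid = np.linspace(doses[0], doses[-1], n_grid)
    # guard against round-off at the endpoints
    grid[0], grid[-1] = doses[0], doses[-1]

    tumor_curve = DoseResponseCurve(
        doses=tuple(grid), values=tuple(hill_survival(tumor, grid)),
        kind="tumor_survival", dose_unit=design.dose_unit,
        tumor_id=tumor_id, drug_id=drug_id,
    )
    tox_curve = DoseResponseCurve(
        doses=tuple(grid), values=tuple(hill_toxicity(tox, grid)),
        kind="slice_toxicity", dose_unit=design.dose_unit, drug_id=drug_id,
    )
    axis = "log" if design.dose_spacing == "log" else "linear"
    win = compute_all_windows(tumor_curve, tox_curve, axis=axis,
                              biphasic_rule=biphasic_rule)

    design_tumor = DoseResponseCurve(
        doses=tuple(doses), values=tuple(hill_survival(tumor, doses)),
        kind="tumor_survival", dose_unit=design.dose_unit,
        tumor_id=tumor_id, drug_id=drug_id,
    )
    design_tox = DoseResponseCurve(
        doses=tuple(doses), values=tuple(hill_toxicity(tox, doses)),
        kind="slice_toxicity", dose_unit=design.dose_unit, drug_id=drug_id,
    )
    from .windows import slope_window
    win = dataclasses.replace(
        win, w_slope=slope_window(design_tumor, design_tox, axis)
    )
    return aggregate_dss(win, weights, tumor_id=tumor_id, drug_id=drug_id)


#: Named scenario pack spanning the qualitative behaviors screens produce.
SCENARIOS: dict[str, tuple[HillParams, HillParams]] = {
    # potent, selective agent: complete kill well before tissue toxicity
    "sensitive": (
        HillParams(floor=0.0, ec50=0.3, hill=2.0),
        HillParams(floor=0.1, ec50=30.0, hill=2.0),
    ),
    # tumor barely responds; tissue also mostly spared
    "resistant": (
        HillParams(floor=0.9, ec50=10.0, hill=1.0),
        HillParams(floor=0.8, ec50=50.0, hill=1.0),
    ),
    # treatment accelerates tumor growth at sub-lethal doses
    "growth_promoted": (
        HillParams(floor=0.2, ec50=20.0, hill=1.5, growth_factor=1.6),
        HillParams(floor=0.7, ec50=40.0, hill=1.0),
    ),
    # rapid low-dose killing that plateaus with residual tumor
    "biphasic": (
        HillParams(floor=0.0, ec50=0.2, hill=2.0, plateau_kill=0.6),
        HillParams(floor=0.5, ec50=20.0, hill=1.0),
    ),
    # tissue dies faster than tumor: negative therapeutic window
    "toxic_only": (
        HillParams(floor=0.85, ec50=5.0, hill=1.0),
        HillParams(floor=0.0, ec50=0.5, hill=2.0),
    ),
    # tumor and tissue respond identically: all comparative windows zero
    "matched": (
        HillParams(floor=0.0, ec50=1.0, hill=1.5),
        HillParams(floor=0.0, ec50=1.0, hill=1.5),
    ),
}
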