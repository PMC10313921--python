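"""Raw assay measurements and normalization to dose-response fractions.

Two readouts feed the scoring pipeline:

* Tumor kill — per-focus bioluminescence (BLI, photons/s) at assay end,
  normalized to each focus's day-1 fluorescence (engrafted tumor size) and
  then to the mean of untreated control foci.  The resulting *survival*
  fraction s(d) is 1 for an untreated-like tumor, 0 for complete kill, and
  may exceed 1 when treatment accelerates growth.
* Normal-tissue toxicity — per-slice propidium-iodide (PI) signal, rescaled
  between a healthy-baseline slice population (tox = 0) and a dead positive
  control (tox = 1).

Both are collapsed to a :class:`DoseResponseCurve`, the container every
downstream metric operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawTumorMeasurement",
    "RawSliceMeasurement",
    "DoseResponseCurve",
    "AssayDesign",
    "AssayError",
    "normalize_tumor_survival",
    "normalize_toxicity",
    "kill_fraction",
    "read_tumor_csv",
    "read_slice_csv",
]

DoseUnit = Literal["uM", "Gy"]
SliceRole = Literal["treated", "healthy_baseline", "dead_control"]

#: Units interpolated on a log10-dose axis by default (concentrations);
#: radiation doses (Gy) default to a linear axis.
LOG_AXIS_UNITS = frozenset({"uM"})


class AssayError(ValueError):
    """Raised when raw measurements violate assay preconditions."""


@dataclass(frozen=True)
class RawTumorMeasurement:
    """One tumor focus: end-point BLI plus day-1 size reference.

    ``dose`` is 0 for untreated controls; controls enter normalization only
    as the denominator and never appear on the dose grid.
    """

    focus_id: str
    tumor_id: str
    drug_id: str
    dose: float
    dose_unit: DoseUnit
    bli_end: float
    fluor_day1: float
    is_untreated_control: bool = False

    def __post_init__(self) -> None:
        if self.bli_end < 0:
            raise AssayError(f"focus {self.focus_id}: bli_end must be >= 0")
        if self.fluor_day1 <= 0:
            raise AssayError(f"focus {self.focus_id}: fluor_day1 must be > 0")
        if self.dose < 0:
            raise AssayError(f"focus {self.focus_id}: dose must be >= 0")
        if self.is_untreated_control and self.dose != 0:
            raise AssayError(
                f"focus {self.focus_id}: untreated controls must have dose 0"
            )


@dataclass(frozen=True)
class RawSliceMeasurement:
    """One slice-level PI readout; role anchors the toxicity rescale."""

    slice_id: str
    drug_id: str
    dose: float
    dose_unit: DoseUnit
    pi_signal: float
    role: SliceRole = "treated"

    def __post_init__(self) -> None:
        if self.pi_signal < 0:
            raise AssayError(f"slice {self.slice_id}: pi_signal must be >= 0")
        if self.dose < 0:
            raise AssayError(f"slice {self.slice_id}: dose must be >= 0")
        if self.role not in ("treated", "healthy_baseline", "dead_control"):
            raise AssayError(f"slice {self.slice_id}: unknown role {self.role!r}")


@dataclass(frozen=True)
class AssayDesign:
    """Screen layout: dose count, replication, unit, dose spacing."""

    n_doses: int = 6
    n_foci_per_dose: int = 4
    dose_unit: DoseUnit = "uM"
    dose_spacing: Literal["log", "linear"] = "log"

    def __post_init__(self) -> None:
        if self.n_doses < 2:
            raise AssayError("n_doses must be >= 2")
        if self.n_foci_per_dose < 1:
            raise AssayError("n_foci_per_dose must be >= 1")


@dataclass(frozen=True)
class DoseResponseCurve:
    """Normalized response indexed by a strictly increasing dose grid.

    ``kind`` distinguishes tumor survival (>= 0, uncapped above 1 so that
    treatment-accelerated growth survives normalization) from slice
    toxicity (clamped to [0, 1]).
    """

    doses: tuple[float, ...]
    values: tuple[float, ...]
    kind: Literal["tumor_survival", "slice_toxicity"]
    dose_unit: DoseUnit = "uM"
    replicate_n: tuple[int, ...] = ()
    replicate_sem: tuple[float, ...] = ()
    tumor_id: str = ""
    drug_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if d.size != v.size:
            raise AssayError("doses and values must have equal length")
        if d.size == 0:
            raise AssayError("curve must contain at least one dose")
        if not np.all(np.isfinite(d)) or not np.all(np.isfinite(v)):
            raise AssayError("doses and values must be finite")
        if np.any(np.diff(d) <= 0):
            raise AssayError("doses must be strictly increasing")
        if np.any(d <= 0):
            raise AssayError("doses must be positive (controls are excluded)")
        if self.kind == "slice_toxicity":
            if np.any((v < 0) | (v > 1)):
                raise AssayError("slice_toxicity values must lie in [0, 1]")
        elif self.kind == "tumor_survival":
            if np.any(v < 0):
                raise AssayError("tumor_survival values must be >= 0")
        else:
            raise AssayError(f"unknown curve kind {self.kind!r}")

    @property
    def dose_array(self) -> np.ndarray:
        return np.asarray(self.doses, dtype=float)

    @property
    def value_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    def log_axis(self) -> bool:
        """Whether this curve's unit interpolates on log10 dose by default."""
        return self.dose_unit in LOG_AXIS_UNITS


def _mean(values: np.ndarray, aggregate: str) -> float:
    if aggregate == "mean":
        return float(np.mean(values))
    if aggregate == "median":
        return float(np.median(values))
    raise AssayError(f"unknown aggregate {aggregate!r}")


def normalize_tumor_survival(
    raw: Iterable[RawTumorMeasurement],
    aggregate: str = "mean",
) -> DoseResponseCurve:
    """Collapse per-focus BLI to a tumor-survival curve.

    Each focus contributes the ratio ``bli_end / fluor_day1`` (end-point
    signal per unit of day-1 tumor).  Per dose, the aggregated treated
    ratio is divided by the aggregated untreated-control ratio, so s(d) = 1
    means treated tumors fared exactly like untreated ones.  The result is
    scale-invariant in the BLI units.

    Raises
    ------
    AssayError
        If there is no untreated control, no treated measurement, or a dose
        level with zero foci cannot arise (empty groups are impossible with
        groupby, but an all-control input is rejected).
    """
    raw = list(raw)
    if not raw:
        raise AssayError("no measurements")
    units = {m.dose_unit for m in raw}
    if len(units) > 1:
        raise AssayError(f"mixed dose units in tumor input: {sorted(units)}")
    controls = [m for m in raw if m.is_untreated_control]
    treated = [m for m in raw if not m.is_untreated_control]
    if not controls:
        raise AssayError("no untreated controls: cannot normalize survival")
    if not treated:
        raise AssayError("no treated measurements")
    if any(m.dose <= 0 for m in treated):
        raise AssayError("treated foci must have dose > 0")

    control_ratio = _mean(
        np.array([m.bli_end / m.fluor_day1 for m in controls]), aggregate
    )
    if control_ratio <= 0:
        raise AssayError("untreated control ratio is zero: cannot normalize")

    by_dose: dict[float, list[float]] = {}
    for m in treated:
        by_dose.setdefault(m.dose, []).append(m.bli_end / m.fluor_day1)

    doses = sorted(by_dose)
    survivals, ns, sems = [], [], []
    for d in doses:
        ratios = np.array(by_dose[d])
        survivals.append(_mean(ratios, aggregate) / control_ratio)
        ns.append(ratios.size)
        sems.append(
            float(np.std(ratios, ddof=1) / np.sqrt(ratios.size) / control_ratio)
            if ratios.size > 1
            else 0.0
        )
    return DoseResponseCurve(
        doses=tuple(doses),
        values=tuple(survivals),
        kind="tumor_survival",
        dose_unit=raw[0].dose_unit,
        replicate_n=tuple(ns),
        replicate_sem=tuple(sems),
        tumor_id=treated[0].tumor_id,
        drug_id=treated[0].drug_id,
    )


def normalize_toxicity(
    raw: Iterable[RawSliceMeasurement],
    aggregate: str = "mean",
) -> DoseResponseCurve:
    """Rescale PI signals between healthy-baseline and dead-control anchors.

    tox(d) = clamp((PI(d) − PI_healthy) / (PI_dead − PI_healthy), 0, 1).
    PI below the healthy baseline is treated as measurement noise, not
    negative death, hence the lower clamp.
    """
    raw = list(raw)
    if not raw:
        raise AssayError("no measurements")
    units = {m.dose_unit for m in raw}
    if len(units) > 1:
        raise AssayError(f"mixed dose units in slice input: {sorted(units)}")
    healthy = [m.pi_signal for m in raw if m.role == "healthy_baseline"]
    dead = [m.pi_signal for m in raw if m.role == "dead_control"]
    treated = [m for m in raw if m.role == "treated"]
    if not healthy or not dead:
        raise AssayError("toxicity requires >=1 healthy_baseline and >=1 dead_control")
    if not treated:
        raise AssayError("no treated slices")
    if any(m.dose <= 0 for m in treated):
        raise AssayError("treated slices must have dose > 0")

    lo = _mean(np.array(healthy), aggregate)
    hi = _mean(np.array(dead), aggregate)
    if hi <= lo:
        raise AssayError(
            f"dead-control PI ({hi:g}) must exceed healthy baseline ({lo:g})"
        )

    by_dose: dict[float, list[float]] = {}
    for m in treated:
        by_dose.setdefault(m.dose, []).append(m.pi_signal)

    doses = sorted(by_dose)
    tox, ns, sems = [], [], []
    span = hi - lo
    for d in doses:
        signals = np.array(by_dose[d])
        tox.append(float(np.clip((_mean(signals, aggregate) - lo) / span, 0.0, 1.0)))
        ns.append(signals.size)
        sems.append(
            float(np.std(signals, ddof=1) / np.sqrt(signals.size) / span)
            if signals.size > 1
            else 0.0
        )
    return DoseResponseCurve(
        doses=tuple(doses),
        values=tuple(tox),
        kind="slice_toxicity",
        dose_unit=raw[0].dose_unit,
        replicate_n=tuple(ns),
        replicate_sem=tuple(sems),
        drug_id=treated[0].drug_id,
    )


def kill_fraction(curve: DoseResponseCurve) -> np.ndarray:
    """Kill series k(d) = 1 − s(d); negative values encode net growth."""
    if curve.kind != "tumor_survival":
        raise AssayError("kill_fraction requires a tumor_survival curve")
    return 1.0 - curve.value_array


# ---------------------------------------------------------------------------
# CSV input dialects


_TUMOR_COLUMNS = [
    "focus_id", "tumor_id", "drug_id", "dose", "dose_unit",
    "bli_end", "fluor_day1", "is_untreated_control",
]
_SLICE_COLUMNS = ["slice_id", "drug_id", "dose", "dose_unit", "pi_signal", "role"]


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise AssayError(f"cannot parse boolean value {x!r}")


def read_tumor_csv(path) -> list[RawTumorMeasurement]:
    """Read the tumor_raw.csv dialect (header required, '.' decimal)."""
    df = pd.read_csv(path)
    missing = [c for c in _TUMOR_COLUMNS if c not in df.columns]
    if missing:
        raise AssayError(f"{path}: missing columns {missing}")
    if df.empty:
        raise AssayError(f"{path}: no measurements")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                RawTumorMeasurement(
                    focus_id=str(row.focus_id),
                    tumor_id=str(row.tumor_id),
                    drug_id=str(row.drug_id),
                    dose=float(row.dose),
                    dose_unit=str(row.dose_unit),
                    bli_end=float(row.bli_end),
                    fluor_day1=float(row.fluor_day1),
                    is_untreated_control=_parse_bool(row.is_untreated_control),
                )
            )
        except (AssayError, ValueError) as exc:
            raise AssayError(f"{path}: line {i}: {exc}") from exc
    return out


def read_slice_csv(path) -> list[RawSliceMeasurement]:
    """Read the slice_raw.csv dialect (header required, '.' decimal)."""
    df = pd.read_csv(path)
    missing = [c for c in _SLICE_COLUMNS if c not in df.columns]
    if missing:
        raise AssayError(f"{path}: missing columns {missing}")
    if df.empty:
        raise AssayError(f"{path}: no measurements")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                RawSliceMeasurement(
                    slice_id=str(row.slice_id),
                    drug_id=str(row.drug_id),
                    dose=float(row.dose),
                    dose_unit=str(row.dose_unit),
                    pi_signal=float(row.pi_signal),
                    role=str(row.role),
                )
            )
        except (AssayError, ValueError) as exc:
            raise AssayError(f"{path}: line {i}: {exc}") from exc
    return out
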