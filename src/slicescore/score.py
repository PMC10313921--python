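"""Drug sensitivity score (DSS): weighted aggregation of the eleven
therapeutic windows onto a ±100 scale, and multi-drug, multi-tumor arrays.

DSS = 100 × Σ wᵢ · windowᵢ with the default weights (fractions of DSS):
max kill 10%, EC10 5%, EC25 5%, EC50 10%, EC75 5%, EC90 5%, slope 10%,
AUC 35%, growth 5%, biphasic 5%, incomplete kill 5%.  +100 is the best
case (complete kill, zero toxicity, clean monotone curve); −100 the worst
(tumor thrives while the tissue dies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import AssayError
from .windows import WINDOW_NAMES, TherapeuticWindows

__all__ = [
    "WeightVector",
    "DEFAULT_WEIGHTS",
    "DssResult",
    "DssMatrix",
    "aggregate_dss",
    "build_dss_matrix",
    "waterfall_order",
    "dss_delta",
]

_WEIGHT_SUM_TOL = 1e-12


@dataclass(frozen=True)
class WeightVector:
    """Eleven window weights, each a fraction of the DSS; must sum to 1."""

    max_kill: float = 0.10
    ec10: float = 0.05
    ec25: float = 0.05
    ec50: float = 0.10
    ec75: float = 0.05
    ec90: float = 0.05
    slope: float = 0.10
    auc: float = 0.35
    growth: float = 0.05
    biphasic: float = 0.05
    incomplete: float = 0.05

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.as_tuple()):
            raise AssayError("weights must be non-negative")
        total = float(np.sum(np.asarray(self.as_tuple(), dtype=float)))
        if abs(total - 1.0) > _WEIGHT_SUM_TOL:
            raise AssayError(f"weights must sum to 1, got {total!r}")

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in WINDOW_NAMES)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(WINDOW_NAMES, self.as_tuple()))


DEFAULT_WEIGHTS = WeightVector()


@dataclass(frozen=True)
class DssResult:
    """Per drug-tumor score with the windows and weights that produced it."""

    tumor_id: str
    drug_id: str
    dss: float
    windows: TherapeuticWindows
    weights: WeightVector = DEFAULT_WEIGHTS
    cohort: str = ""


@dataclass(frozen=True)
class DssMatrix:
    """Drugs × tumors grid of scores; untested pairs stay missing (NaN)."""

    table: pd.DataFrame  # index = drug_id, columns = tumor_id, values = DSS
    results: dict[tuple[str, str], DssResult] = field(default_factory=dict)

    @property
    def drugs(self) -> list[str]:
        return list(self.table.index)

    @property
    def tumors(self) -> list[str]:
        return list(self.table.columns)


def aggregate_dss(
    windows: TherapeuticWindows,
    weights: WeightVector = DEFAULT_WEIGHTS,
    tumor_id: str = "",
    drug_id: str = "",
    cohort: str = "",
) -> DssResult:
    """Collapse the eleven windows into one DSS = 100 × Σ wᵢ·windowᵢ."""
    w = np.asarray(weights.as_tuple(), dtype=float)
    v = np.asarray(windows.as_tuple(), dtype=float)
    dss = float(100.0 * np.dot(w, v))
    return DssResult(
        tumor_id=tumor_id, drug_id=drug_id, dss=dss,
        windows=windows, weights=weights, cohort=cohort,
    )


def build_dss_matrix(results: list[DssResult]) -> DssMatrix:
    """Assemble per-pair results into a drugs × tumors grid.

    Ordering is stable (first appearance); untested pairs are left missing,
    mirroring screens where not every drug meets every tumor.
    """
    keyed: dict[tuple[str, str], DssResult] = {}
    drugs: list[str] = []
    tumors: list[str] = []
    for r in results:
        key = (r.drug_id, r.tumor_id)
        if key in keyed:
            raise AssayError(f"duplicate (drug, tumor) pair {key}")
        keyed[key] = r
        if r.drug_id not in drugs:
            drugs.append(r.drug_id)
        if r.tumor_id not in tumors:
            tumors.append(r.tumor_id)
    table = pd.DataFrame(np.nan, index=drugs, columns=tumors, dtype=float)
    for (drug, tumor), r in keyed.items():
        table.loc[drug, tumor] = r.dss
    table.index.name = "drug_id"
    table.columns.name = "tumor_id"
    return DssMatrix(table=table, results=keyed)


def waterfall_order(matrix: DssMatrix) -> list[tuple[str, str, float, str]]:
    """Present entries sorted descending by DSS for a waterfall plot.

    Ties break lexicographically by (drug, tumor); each entry carries its
    cohort tag (e.g., cell line vs patient tissue).
    """
    entries = [
        (drug, tumor, r.dss, r.cohort)
        for (drug, tumor), r in matrix.results.items()
    ]
    if not entries:
        raise AssayError("waterfall requires at least one scored pair")
    return sorted(entries, key=lambda e: (-e[2], e[0], e[1]))


def dss_delta(a: DssResult, b: DssResult) -> float:
    """Score change b − a for the same drug (e.g., primary vs recurrence)."""
    if a.drug_id != b.drug_id:
        raise AssayError(
            f"dss_delta compares the same drug, got {a.drug_id!r} vs {b.drug_id!r}"
        )
    return b.dss - a.dss
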