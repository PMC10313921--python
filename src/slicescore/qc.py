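"""Batch-level slice viability quality control.

Every slice batch contributes a small random QC sample (six slices in the
original screening practice) that runs the PI death assay untreated.  Each
sampled slice gets a normalized death index in [0, 1] — the same
healthy/dead rescale used for toxicity curves — and the batch passes when
the mean index is low in absolute terms and consistent with the history of
previous batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assay import AssayError, RawSliceMeasurement

__all__ = ["QcThresholds", "QcReport", "qc_batch"]


@dataclass(frozen=True)
class QcThresholds:
    """Pass/fail conventions; the comparison to history is the procedure,
    the numeric cutoffs are this tool's declared defaults.

    ``tau_abs`` — maximum acceptable batch-mean death index (absolute rule).
    ``kappa`` — allowed deviation from the historical mean, in historical
    standard deviations (applied only when >= 2 prior batches exist).
    """

    tau_abs: float = 0.25
    kappa: float = 3.0


@dataclass(frozen=True)
class QcReport:
    batch_id: str
    n_sampled: int
    mean_index: float
    historical_mean: float | None
    historical_sd: float | None
    passed: bool
    reasons: tuple[str, ...] = ()
    thresholds: QcThresholds = QcThresholds()


def _death_index(pi: float, healthy: float, dead: float) -> float:
    return float(np.clip((pi - healthy) / (dead - healthy), 0.0, 1.0))


def qc_batch(
    sampled: Iterable[RawSliceMeasurement],
    history: Sequence[float] | pd.Series | None = None,
    thresholds: QcThresholds = QcThresholds(),
    batch_id: str = "",
) -> QcReport:
    """Grade one batch's QC sample against absolute and historical rules.

    Parameters
    ----------
    sampled : the QC sample — treated-role entries are the sampled slices
        (dose 0, no drug), plus healthy_baseline and dead_control anchors.
    history : mean death indices of previous batches, one per batch.
    thresholds : absolute and historical cutoffs.

    The batch passes iff mean index <= ``tau_abs`` AND, when at least two
    historical batches exist, |mean − hist_mean| <= kappa · hist_sd.
    """
    sampled = list(sampled)
    healthy = [m.pi_signal for m in sampled if m.role == "healthy_baseline"]
    dead = [m.pi_signal for m in sampled if m.role == "dead_control"]
    slices = [m for m in sampled if m.role == "treated"]
    if not slices:
        raise AssayError("QC requires at least one sampled slice")
    if not healthy or not dead:
        raise AssayError("QC requires healthy_baseline and dead_control anchors")
    lo = float(np.mean(healthy))
    hi = float(np.mean(dead))
    if hi <= lo:
        raise AssayError("dead-control PI must exceed healthy baseline")

    indices = np.array([_death_index(m.pi_signal, lo, hi) for m in slices])
    mean_index = float(np.mean(indices))

    reasons: list[str] = []
    if mean_index > thresholds.tau_abs:
        reasons.append(
            f"mean death index {mean_index:.3f} exceeds tau_abs={thresholds.tau_abs}"
        )

    hist_mean = hist_sd = None
    if history is not None:
        hist = np.asarray(history, dtype=float)
        if hist.size >= 2:
            hist_mean = float(np.mean(hist))
            hist_sd = float(np.std(hist, ddof=1))
            if abs(mean_index - hist_mean) > thresholds.kappa * hist_sd:
                reasons.append(
                    f"mean death index {mean_index:.3f} deviates from historical "
                    f"mean {hist_mean:.3f} by more than "
                    f"{thresholds.kappa}*sd ({hist_sd:.3f})"
                )
        elif hist.size == 1:
            hist_mean = float(hist[0])

    return QcReport(
        batch_id=batch_id,
        n_sampled=len(slices),
        mean_index=mean_index,
        historical_mean=hist_mean,
        historical_sd=hist_sd,
        passed=not reasons,
        reasons=tuple(reasons),
        thresholds=thresholds,
    )
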