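"""Event-level quality control and normalization for mass-cytometry data.

The QC stage implements the fixed, cohort-wide gating used throughout:
events whose nuclear (death) marker falls below a raw-intensity threshold
are treated as dead and removed, and only events whose acquisition length
lies inside a closed interval are kept as singlets. Both thresholds are
applied on the raw ion-count scale, before the variance-stabilizing
arcsinh transform.

Boundary convention: the death rule removes events strictly below the
threshold (an event exactly at the threshold survives) and the length gate
is a closed interval (both bounds inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ARCSINH, RAW, ExpressionMatrix
from .panel import DEATH_MARKER

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Gating thresholds for dead-cell removal and singlet selection."""

    death_marker: str = DEATH_MARKER
    death_threshold: float = 10.0     # raw intensity; "< threshold" = dead
    length_min: float = 10.0          # closed interval, instrument units
    length_max: float = 70.0
    cofactor: float = 5.0             # arcsinh divisor

    def __post_init__(self) -> None:
        if self.length_min >= self.length_max:
            raise ValueError("length_min must be < length_max")
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")


@dataclass
class QCReport:
    """Per-sample accounting of the QC stage."""

    n_input: dict = field(default_factory=dict)
    n_removed_dead: dict = field(default_factory=dict)
    n_removed_nonsinglet: dict = field(default_factory=dict)
    n_retained: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_input": self.n_input,
                "n_removed_dead": self.n_removed_dead,
                "n_removed_nonsinglet": self.n_removed_nonsinglet,
                "n_retained": self.n_retained,
            }
        ).rename_axis("sample_id")

    def totals(self) -> dict:
        return {
            "n_input": int(sum(self.n_input.values())),
            "n_removed_dead": int(sum(self.n_removed_dead.values())),
            "n_removed_nonsinglet": int(sum(self.n_removed_nonsinglet.values())),
            "n_retained": int(sum(self.n_retained.values())),
        }


def filter_events(
    data: ExpressionMatrix, qc: QCConfig | None = None
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove dead events and non-singlets.

    An event is retained iff ``death_marker >= death_threshold`` and
    ``length_min <= event_length <= length_max``. Events failing the death
    gate are counted as dead; events passing it but failing the length gate
    are counted as non-singlets.
    """
    qc = qc or QCConfig()
    if data.scale_state != RAW:
        raise ValueError("QC thresholds are defined on the raw scale")
    if qc.death_marker not in data.values.columns:
        raise KeyError(
            f"death marker {qc.death_marker!r} not present in the expression table"
        )
    marker = data.values[qc.death_marker].to_numpy(dtype=float)
    length = data.event_length.to_numpy(dtype=float)

    alive = marker >= qc.death_threshold
    singlet = (length >= qc.length_min) & (length <= qc.length_max)
    keep = alive & singlet

    report = QCReport()
    sid = data.sample_id.to_numpy()
    for s in pd.unique(sid):
        in_s = sid == s
        report.n_input[s] = int(in_s.sum())
        report.n_removed_dead[s] = int((in_s & ~alive).sum())
        report.n_removed_nonsinglet[s] = int((in_s & alive & ~singlet).sum())
        report.n_retained[s] = int((in_s & keep).sum())
    return data.subset(keep), report


def arcsinh_transform(data: ExpressionMatrix, cofactor: float = 5.0) -> ExpressionMatrix:
    """Apply ``asinh(x / cofactor)`` to every marker value.

    The transform is variance-stabilizing for ion counts and is applied
    exactly once per cohort; attempting to re-apply it raises.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if data.scale_state == ARCSINH:
        raise ValueError("data already arcsinh-transformed")
    values = pd.DataFrame(
        np.arcsinh(data.values.to_numpy(dtype=float) / cofactor),
        columns=data.values.columns,
    )
    return ExpressionMatrix(
        values=values,
        sample_id=data.sample_id,
        event_length=data.event_length,
        scale_state=ARCSINH,
    )


def subsample_events(
    data: ExpressionMatrix, n_per_sample: int, seed: int
) -> ExpressionMatrix:
    """Random equal subsampling without replacement, per sample.

    Samples with fewer than ``n_per_sample`` events are retained in full
    (logged). Event order within the output follows the original order.
    """
    if n_per_sample < 1:
        raise ValueError("n_per_sample must be >= 1")
    rng = np.random.default_rng(seed)
    sid = data.sample_id.to_numpy()
    keep = np.zeros(data.n_events, dtype=bool)
    for s in pd.unique(sid):
        idx = np.flatnonzero(sid == s)
        if len(idx) <= n_per_sample:
            if len(idx) < n_per_sample:
                logger.info(
                    "sample %s has %d events (< %d); retained in full",
                    s, len(idx), n_per_sample,
                )
            keep[idx] = True
        else:
            keep[rng.choice(idx, size=n_per_sample, replace=False)] = True
    return data.subset(keep)
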