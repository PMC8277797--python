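"""In-memory containers shared across the pipeline.

All containers are thin, validated wrappers around pandas objects so that
every stage can be inspected, serialized to CSV, and round-tripped exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RAW = "raw"
ARCSINH = "arcsinh"


@dataclass
class ExpressionMatrix:
    """Events × markers expression table for a (multi-sample) cohort.

    Parameters
    ----------
    values
        One row per event, one column per marker. Raw ion counts are
        non-negative; after the arcsinh transform values may be any real.
    sample_id
        Sample of origin per event, aligned with ``values``.
    event_length
        Per-event acquisition length (instrument units), used for singlet
        gating.
    scale_state
        ``"raw"`` or ``"arcsinh"``. The transform may be applied once.
    """

    values: pd.DataFrame
    sample_id: pd.Series
    event_length: pd.Series
    scale_state: str = RAW

    def __post_init__(self) -> None:
        if self.scale_state not in (RAW, ARCSINH):
            raise ValueError(f"invalid scale_state {self.scale_state!r}")
        n = len(self.values)
        if len(self.sample_id) != n or len(self.event_length) != n:
            raise ValueError("sample_id / event_length length mismatch")
        # keep everything on one positional index so boolean masks align
        self.values = self.values.reset_index(drop=True)
        self.sample_id = pd.Series(
            np.asarray(self.sample_id), name="sample_id"
        )
        self.event_length = pd.Series(
            np.asarray(self.event_length, dtype=float), name="event_length"
        )

    @property
    def markers(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_events(self) -> int:
        return len(self.values)

    @property
    def samples(self) -> list:
        return list(pd.unique(self.sample_id))

    def subset(self, mask: np.ndarray) -> "ExpressionMatrix":
        """Row subset by boolean mask or integer positions."""
        mask = np.asarray(mask)
        return ExpressionMatrix(
            values=self.values.iloc[mask].reset_index(drop=True)
            if mask.dtype.kind in "iu"
            else self.values.loc[mask].reset_index(drop=True),
            sample_id=self.sample_id[mask].reset_index(drop=True),
            event_length=self.event_length[mask].reset_index(drop=True),
            scale_state=self.scale_state,
        )

    def to_frame(self) -> pd.DataFrame:
        """Single flat table: markers + sample_id + event_length."""
        out = self.values.copy()
        out["sample_id"] = self.sample_id.values
        out["event_length"] = self.event_length.values
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, markers: list[str] | None = None,
        scale_state: str = RAW,
    ) -> "ExpressionMatrix":
        meta = {"sample_id", "event_length"}
        if markers is None:
            markers = [c for c in frame.columns if c not in meta]
        missing = meta - set(frame.columns)
        if missing:
            raise ValueError(f"expression frame missing columns: {sorted(missing)}")
        return cls(
            values=frame[markers].copy(),
            sample_id=frame["sample_id"],
            event_length=frame["event_length"],
            scale_state=scale_state,
        )


@dataclass
class AnnotationResult:
    """Cluster assignment and cell-type labels for a set of events.

    ``cluster_id`` and ``cell_type`` are aligned with the events of the
    ExpressionMatrix the clustering ran on. ``cluster_profiles`` holds the
    per-cluster median arcsinh expression (clusters × markers) and
    ``cluster_labels`` the rule-based label per cluster.
    """

    cluster_id: pd.Series
    cell_type: pd.Series
    cluster_profiles: pd.DataFrame
    cluster_labels: dict = field(default_factory=dict)
    sample_id: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.cluster_id) != len(self.cell_type):
            raise ValueError("cluster_id / cell_type length mismatch")

    @property
    def n_events(self) -> int:
        return len(self.cluster_id)

    def cluster_sizes(self) -> pd.Series:
        return self.cluster_id.value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"cluster_id": self.cluster_id.values, "cell_type": self.cell_type.values}
        )
        if self.sample_id is not None:
            out.insert(0, "sample_id", self.sample_id.values)
        return out


@dataclass
class AbundanceTable:
    """Samples × categories relative abundances, in percent of each row."""

    percentages: pd.DataFrame          # rows: samples, cols: categories
    groups: pd.Series | None = None    # sample -> group label

    def __post_init__(self) -> None:
        vals = self.percentages.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 100 + 1e-9):
            raise ValueError("abundances must lie in [0, 100]")
        row_sums = vals.sum(axis=1)
        if vals.size and not np.allclose(row_sums, 100.0, atol=1e-6):
            raise ValueError("abundance rows must each sum to 100%")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.percentages.index)

    @property
    def samples(self) -> list:
        return list(self.percentages.index)

    def to_csv(self, path: str | Path) -> None:
        out = self.percentages.copy()
        if self.groups is not None:
            out.insert(0, "group", self.groups.values)
        out.to_csv(path, index_label="sample_id")
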