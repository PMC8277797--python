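"""Reading and writing cohort tables, panels, and configuration.

Expression cohorts are exchanged as flat CSV (UTF-8, comma-separated,
header row, '.' decimal): one row per event, one column per marker, plus
``sample_id`` and ``event_length``. Columns may be named by instrument
channel instead of marker, in which case the panel's channel → marker map
is applied. FCS containers are not read directly; export the events to CSV
upstream (the column contract above is the interface).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .containers import ExpressionMatrix
from .panel import PanelDefinition

logger = logging.getLogger(__name__)

META_COLUMNS = ("sample_id", "event_length")


def read_expression(
    path: str | Path, panel: PanelDefinition, sample_id: str | None = None
) -> ExpressionMatrix:
    """Read a raw-scale expression CSV and map channels to markers.

    Columns matching panel channel names are renamed to markers; columns
    already named by marker are kept. Extra columns are ignored (logged).
    A missing ``sample_id`` column may be filled from the argument; a
    missing required marker is an error listing the gaps.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - reraise with file context
        raise ValueError(f"cannot parse expression file {path}: {exc}") from exc
    frame = frame.rename(columns=panel.channel_map)
    if "sample_id" not in frame.columns:
        if sample_id is None:
            raise ValueError(f"{path}: no sample_id column and none supplied")
        frame["sample_id"] = sample_id
    if "event_length" not in frame.columns:
        raise ValueError(f"{path}: no event_length column")
    missing = [m for m in panel.markers if m not in frame.columns]
    if missing:
        raise ValueError(f"{path}: unmapped required markers: {missing}")
    extra = [c for c in frame.columns
             if c not in panel.markers and c not in META_COLUMNS]
    if extra:
        logger.info("%s: ignoring extra columns %s", path, extra)
    return ExpressionMatrix.from_frame(frame, markers=panel.markers)


def read_spatial(path: str | Path) -> pd.DataFrame:
    """Read a spatial cell table CSV (x_um, y_um plus marker columns)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse spatial file {path}: {exc}") from exc
    for col in ("x_um", "y_um"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing coordinate column {col!r}")
    return frame


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    try:
        return obj.item()          # numpy scalars
    except AttributeError:
        return str(obj)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
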