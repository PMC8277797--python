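"""Antibody panel definition: marker names, roles, and per-stage feature sets.

A panel maps instrument channels to marker names and assigns each marker a
role that determines where it is used downstream:

* ``lineage``    — round-1 clustering features separating the major
  compartments (tumor epithelium, endothelium, mesenchyme, immune).
* ``immune``     — round-2 clustering features resolving immune subsets.
* ``functional`` — markers carried along for profiling (signalling states,
  antigen presentation, proliferation); the epithelial-cancer-cell
  subclustering runs on a 28-marker functional set.
* ``qc``         — event-quality markers (nuclear stain used to flag dead
  events) that never enter clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

#: Round-1 features: the six markers separating major cell compartments.
ROUND1_MARKERS = ["EpCAM", "CD31", "CD45", "vimentin", "cytokeratin", "CK7"]

#: Round-2 features for immune subsets. CD4 is deliberately absent: it is
#: used for labeling helper T cells but not as a clustering feature.
IMMUNE_MARKERS = ["CD8", "CD24", "CD3", "CD11b", "CD56", "HLA-DR"]

#: Feature set for subclustering epithelial cancer cells (28 markers).
ECC_FUNCTIONAL_MARKERS = [
    "EpCAM", "c-casp3", "TP53", "HLA-DR", "HLA-ABC", "CD31", "thioredoxin",
    "beta-catenin", "HER2", "p-STAT3", "p-STAT5", "p-STAT6", "TTF1", "p-AKT",
    "Ki67", "CD56", "vimentin", "MDM2", "cytokeratin", "MET", "TP63", "CK7",
    "EGFR", "CD44", "p-ERK", "CD24", "p-S6", "PDL1",
]

#: Default QC / death marker (nuclear histone stain).
DEATH_MARKER = "HistoneH3"

_DEFAULT_PANEL_ROWS = [
    # (channel, marker, role)
    ("141Pr", "EpCAM", "lineage"),
    ("142Nd", "c-casp3", "functional"),
    ("143Nd", "TP53", "functional"),
    ("144Nd", "HLA-ABC", "functional"),
    ("145Nd", "CD31", "lineage"),
    ("146Nd", "thioredoxin", "functional"),
    ("147Sm", "beta-catenin", "functional"),
    ("148Nd", "HER2", "functional"),
    ("149Sm", "p-STAT6", "functional"),
    ("150Nd", "p-STAT5", "functional"),
    ("151Eu", "TTF1", "functional"),
    ("152Sm", "p-AKT", "functional"),
    ("153Eu", "Ki67", "functional"),
    ("154Sm", "CD45", "lineage"),
    ("155Gd", "CD56", "immune"),
    ("156Gd", "vimentin", "lineage"),
    ("158Gd", "p-STAT3", "functional"),
    ("159Tb", "CD4", "immune"),
    ("160Gd", "MDM2", "functional"),
    ("161Dy", "cytokeratin", "lineage"),
    ("162Dy", "MET", "functional"),
    ("163Dy", "TP63", "functional"),
    ("164Dy", "CK7", "lineage"),
    ("165Ho", "EGFR", "functional"),
    ("166Er", "CD44", "functional"),
    ("167Er", "p-ERK", "functional"),
    ("168Er", "CD8", "immune"),
    ("169Tm", "CD24", "immune"),
    ("170Yb", "CD3", "immune"),
    ("171Yb", "CD11b", "immune"),
    ("172Yb", "p-S6", "functional"),
    ("174Yb", "HLA-DR", "immune"),
    ("175Lu", "PDL1", "functional"),
    ("176Yb", "HistoneH3", "qc"),
]

VALID_ROLES = frozenset({"lineage", "immune", "functional", "qc"})


@dataclass
class PanelDefinition:
    """Channel → marker mapping with a role per marker."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"channel", "marker", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        bad = set(self.table["role"]) - VALID_ROLES
        if bad:
            raise ValueError(f"unknown panel roles: {sorted(bad)}")
        if self.table["marker"].duplicated().any():
            dups = self.table.loc[self.table["marker"].duplicated(), "marker"]
            raise ValueError(f"duplicate markers in panel: {sorted(set(dups))}")

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])

    def markers_with_role(self, role: str) -> list[str]:
        if role not in VALID_ROLES:
            raise ValueError(f"unknown role {role!r}")
        return list(self.table.loc[self.table["role"] == role, "marker"])

    @property
    def channel_map(self) -> dict[str, str]:
        return dict(zip(self.table["channel"], self.table["marker"]))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PanelDefinition":
        return cls(pd.read_csv(path))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelDefinition":
        with open(path) as fh:
            rows = yaml.safe_load(fh)
        return cls(pd.DataFrame(rows))


def default_panel() -> PanelDefinition:
    """The 34-antibody lung-adenocarcinoma panel used throughout."""
    return PanelDefinition(
        pd.DataFrame(_DEFAULT_PANEL_ROWS, columns=["channel", "marker", "role"])
    )
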