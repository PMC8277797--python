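"""Spatial single-cell statistics for multiplex-immunofluorescence data.

Cells carry µm coordinates plus per-marker classifier probabilities (or
intensities with thresholds). Binary marker calls at a probability cutoff
(default 0.9) combine into four classes:

* Tumor         — PanCK+ CD45− CD3−
* T cell        — CD3+ CD45+ PanCK−
* Immune non-T  — CD45+ CD3− PanCK−
* Other         — CD45− CD3− PanCK−

Marker combinations outside this table (e.g. PanCK+CD45+) are Unassigned.

Two spatial statistics follow: (a) for every tumor cell, the number of
T cells and the median HLA-DR of *other* tumor cells within a 50 µm radius
(a 100 µm-diameter neighborhood), correlated per sample or per
neighborhood; (b) for every T cell, the exact Euclidean distance to its
1st- and 2nd-nearest tumor cell, compared between groups with the sample
as the unit of analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu

from .abundance import spearman_rho_p

logger = logging.getLogger(__name__)

TUMOR = "Tumor"
T_CELL = "T cell"
IMMUNE_NON_T = "Immune non-T"
OTHER = "Other"
UNASSIGNED = "Unassigned"

# (PanCK, CD45, CD3) call → class
_CLASS_TABLE = {
    (True, False, False): TUMOR,
    (False, True, True): T_CELL,
    (False, True, False): IMMUNE_NON_T,
    (False, False, False): OTHER,
}

_MARKERS = ("PanCK", "CD45", "CD3")


def classify_cells(
    table: pd.DataFrame,
    prob_cutoff: float = 0.9,
    intensity_thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Assign each cell a class from binary PanCK/CD45/CD3 calls.

    A marker is called positive when ``prob_<marker> >= prob_cutoff``; for
    markers without a probability column an intensity column plus a
    threshold in ``intensity_thresholds`` may be supplied instead
    (``<marker> >= threshold``). Classification is per-row and
    order-independent. Returns a copy with a ``cell_class`` column.
    """
    calls = {}
    for m in _MARKERS:
        prob_col = f"prob_{m}"
        if prob_col in table.columns:
            calls[m] = table[prob_col].to_numpy(dtype=float) >= prob_cutoff
        elif intensity_thresholds and m in intensity_thresholds and m in table.columns:
            calls[m] = table[m].to_numpy(dtype=float) >= intensity_thresholds[m]
        else:
            raise KeyError(
                f"no classification input for marker {m!r}: provide "
                f"{prob_col!r} or an intensity column with a threshold"
            )
    keys = list(zip(calls["PanCK"], calls["CD45"], calls["CD3"]))
    out = table.copy()
    out["cell_class"] = [_CLASS_TABLE.get(k, UNASSIGNED) for k in keys]
    return out


def neighborhood_stats(
    table: pd.DataFrame,
    radius_um: float = 50.0,
    hladr_column: str = "HLA-DR",
    include_focal: bool = False,
    class_column: str = "cell_class",
) -> pd.DataFrame:
    """Disc-neighborhood statistics around every tumor cell.

    For each tumor cell, counts T cells within ``radius_um`` (boundary
    inclusive) and takes the median HLA-DR over the *other* tumor cells in
    the same disc (the focal cell itself is excluded unless
    ``include_focal``). Tumor cells with no tumor neighbor get a missing
    median. One row per tumor cell.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    if class_column not in table.columns:
        raise KeyError(f"table has no {class_column!r} column; classify first")
    is_tumor = (table[class_column] == TUMOR).to_numpy()
    if not is_tumor.any():
        raise ValueError("no tumor cells in the table")
    xy = table[["x_um", "y_um"]].to_numpy(dtype=float)
    tumor_xy = xy[is_tumor]
    tumor_idx = np.flatnonzero(is_tumor)
    hladr = table[hladr_column].to_numpy(dtype=float)[is_tumor]

    t_xy = xy[(table[class_column] == T_CELL).to_numpy()]
    tumor_tree = cKDTree(tumor_xy)
    t_tree = cKDTree(t_xy) if len(t_xy) else None

    t_counts = (
        tumor_tree.query_ball_tree(t_tree, r=radius_um) if t_tree is not None
        else [[] for _ in range(len(tumor_xy))]
    )
    tumor_neighbors = tumor_tree.query_ball_tree(tumor_tree, r=radius_um)

    rows = []
    for i in range(len(tumor_xy)):
        neigh = tumor_neighbors[i] if include_focal else [
            j for j in tumor_neighbors[i] if j != i
        ]
        rows.append({
            "tumor_cell": int(tumor_idx[i]),
            "t_cell_count": len(t_counts[i]),
            "hladr_median_neighbors": float(np.median(hladr[neigh])) if neigh else np.nan,
            "radius_um": radius_um,
        })
    return pd.DataFrame(rows)


def correlate_hladr_tcells(
    records: pd.DataFrame,
    aggregation: str = "per_sample",
    sample_id: pd.Series | np.ndarray | None = None,
    min_units: int = 4,
) -> dict:
    """Spearman correlation of neighborhood HLA-DR vs T-cell counts.

    ``aggregation="per_sample"`` (default) averages both quantities over
    each sample's neighborhoods first; ``"per_neighborhood"`` correlates
    the raw records pooled together. Records with a missing HLA-DR median
    are excluded. Returns a dict with rho, p, n and the aggregation mode;
    rho is missing when either input is constant.
    """
    if aggregation not in ("per_sample", "per_neighborhood"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    rec = records.dropna(subset=["hladr_median_neighbors"])
    if aggregation == "per_sample":
        if sample_id is not None:
            sid = np.asarray(sample_id)[rec.index]
        elif "sample_id" in rec.columns:
            sid = rec["sample_id"].to_numpy()
        else:
            raise ValueError("per-sample aggregation requires sample_id")
        agg = rec.groupby(sid)[["hladr_median_neighbors", "t_cell_count"]].mean()
        x, y = agg["hladr_median_neighbors"], agg["t_cell_count"]
    else:
        x, y = rec["hladr_median_neighbors"], rec["t_cell_count"]
    n = len(x)
    if n < min_units:
        raise ValueError(f"only {n} usable units after aggregation (< {min_units})")
    rho, p = spearman_rho_p(x, y)
    if np.isnan(rho):
        logger.warning("constant input: correlation undefined")
    return {"rho": rho, "p": p, "n": n, "aggregation": aggregation}


def t_to_tumor_distances(
    table: pd.DataFrame, class_column: str = "cell_class"
) -> pd.DataFrame:
    """Exact 1st- and 2nd-nearest tumor-cell distance for every T cell.

    With a single tumor cell only ``d1`` is emitted (``d2`` missing, with a
    warning); with no T cells the result is empty. Distances are Euclidean
    in µm and equal the O(n²) brute-force answer.
    """
    is_tumor = (table[class_column] == TUMOR).to_numpy()
    is_t = (table[class_column] == T_CELL).to_numpy()
    n_tumor = int(is_tumor.sum())
    if n_tumor == 0:
        raise ValueError("no tumor cells: nearest-tumor distances undefined")
    xy = table[["x_um", "y_um"]].to_numpy(dtype=float)
    t_idx = np.flatnonzero(is_t)
    if len(t_idx) == 0:
        return pd.DataFrame(columns=["t_cell", "d1_um", "d2_um"])
    tree = cKDTree(xy[is_tumor])
    k = min(2, n_tumor)
    if n_tumor < 2:
        logger.warning("single tumor cell: 2nd-nearest distance undefined")
    dist, _ = tree.query(xy[t_idx], k=k)
    dist = np.atleast_2d(dist.reshape(len(t_idx), k))
    return pd.DataFrame({
        "t_cell": t_idx,
        "d1_um": dist[:, 0],
        "d2_um": dist[:, 1] if k == 2 else np.nan,
    })


@dataclass
class DistanceGroupComparison:
    per_sample: pd.DataFrame     # sample_id, group, median_d1, median_d2, n_t
    p_d1: float
    p_d2: float
    direction: str               # which group has the shorter median d1
    low_power: bool


def compare_distance_groups(
    distances_by_sample: dict,
    groups: pd.Series,
) -> DistanceGroupComparison:
    """Compare per-sample median T→tumor distances between two groups.

    ``distances_by_sample`` maps sample_id → the distance table from
    :func:`t_to_tumor_distances`. The sample is the unit of analysis;
    samples with zero T cells are excluded with a warning.
    """
    rows = []
    for sid, rec in distances_by_sample.items():
        if len(rec) == 0:
            logger.warning("sample %s has no T cells; excluded", sid)
            continue
        rows.append({
            "sample_id": sid,
            "group": groups.get(sid),
            "median_d1": float(rec["d1_um"].median()),
            "median_d2": float(rec["d2_um"].median()),
            "n_t": int(len(rec)),
        })
    per_sample = pd.DataFrame(rows)
    levels = list(pd.unique(per_sample["group"].dropna()))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, found {levels}")
    g1, g2 = levels
    a = per_sample[per_sample["group"] == g1]
    b = per_sample[per_sample["group"] == g2]
    _, p1 = mannwhitneyu(a["median_d1"], b["median_d1"], alternative="two-sided")
    _, p2 = mannwhitneyu(a["median_d2"].dropna(), b["median_d2"].dropna(),
                         alternative="two-sided")
    direction = g1 if a["median_d1"].median() <= b["median_d1"].median() else g2
    low_power = len(a) < 3 or len(b) < 3
    if low_power:
        logger.warning("fewer than 3 samples in a group: low-power comparison")
    return DistanceGroupComparison(
        per_sample=per_sample, p_d1=float(p1), p_d2=float(p2),
        direction=direction, low_power=low_power,
    )
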