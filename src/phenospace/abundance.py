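"""Relative-abundance profiling and cohort-level statistics.

Cell-type composition is expressed in percent per sample and compared
across samples with rank-based statistics throughout: Spearman correlation
(with Benjamini–Hochberg adjustment across each declared family of tests),
sample–sample Spearman dendrograms on distance ``1 − ρ`` (average linkage),
and two-sided Mann–Whitney U tests for group contrasts.

Spearman p-values are exact (full enumeration of pairings) for small
tie-free vectors (n ≤ 8) and use the standard large-sample approximation
otherwise.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceTable, AnnotationResult, ExpressionMatrix

logger = logging.getLogger(__name__)

_EXACT_SPEARMAN_MAX_N = 8


def compute_abundance(
    annotation: AnnotationResult,
    groups: pd.Series | None = None,
    categories: list[str] | None = None,
) -> AbundanceTable:
    """Per-sample relative abundances (percent) over the annotation's labels.

    The denominator for each sample is the number of its events present in
    ``annotation`` — pass a cohort-level annotation for cell-type
    abundances, or a cancer-cell subcluster annotation for subcluster
    abundances (where the denominator is that sample's cancer cells).
    """
    if annotation.sample_id is None:
        raise ValueError("annotation carries no sample_id")
    if annotation.n_events == 0:
        raise ValueError("annotation covers no events")
    counts = (
        pd.crosstab(
            np.asarray(annotation.sample_id), np.asarray(annotation.cell_type)
        )
        .rename_axis(index="sample_id", columns=None)
    )
    if categories is not None:
        counts = counts.reindex(columns=categories, fill_value=0)
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("samples with zero events excluded: %s",
                       list(counts.index[empty]))
        counts, totals = counts.loc[~empty], totals[~empty]
    pct = counts.div(totals, axis=0) * 100.0
    return AbundanceTable(percentages=pct, groups=groups)


def spearman_rho_p(x, y) -> tuple[float, float]:
    """Spearman rank correlation with an exact small-sample p-value.

    For n ≤ 8 without ties the p-value is computed by full enumeration of
    all pairings (two-sided on \\|ρ\\|); otherwise the usual asymptotic
    approximation is used. Returns ``(nan, nan)`` when either vector is
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    n = len(x)
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = spearmanr(x, y)
    if n <= _EXACT_SPEARMAN_MAX_N and not ties:
        rx = rankdata(x) - (n + 1) / 2
        ry = rankdata(y) - (n + 1) / 2
        denom = float(rx @ rx)
        perms = np.array(list(itertools.permutations(range(n))))
        rho_perm = (ry[perms] @ rx) / denom
        rho_obs = float(ry @ rx) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))
        return rho_obs, p
    return float(rho), float(p)


@dataclass
class DendrogramResult:
    """Sample–sample correlation dendrogram."""

    rho: pd.DataFrame          # samples × samples Spearman matrix
    linkage: np.ndarray        # scipy linkage (average, distance 1 − ρ)
    samples: list
    newick: str

    def cut(self, n_groups: int) -> pd.Series:
        """Flat cluster labels (1-based) at the cut giving n_groups."""
        labels = fcluster(self.linkage, t=n_groups, criterion="maxclust")
        return pd.Series(labels, index=self.samples, name="dendrogram_group")

    @property
    def leaf_order(self) -> list:
        return [self.samples[i] for i in to_tree(self.linkage).pre_order()]


def correlation_dendrogram(table: AbundanceTable) -> DendrogramResult:
    """Hierarchical clustering of samples on Spearman correlation distance.

    Pairs involving a constant abundance profile have undefined ρ; these are
    recorded as missing in the ρ matrix and imputed as distance 1 for the
    linkage (with a warning).
    """
    samples = table.samples
    if len(samples) < 3:
        raise ValueError("dendrogram requires at least 3 samples")
    profiles = table.percentages.to_numpy(dtype=float)
    n = len(samples)
    rho = np.full((n, n), np.nan)
    np.fill_diagonal(rho, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            if np.ptp(profiles[i]) == 0 or np.ptp(profiles[j]) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = spearmanr(profiles[i], profiles[j]).statistic
            rho[i, j] = rho[j, i] = r
    if np.isnan(rho).any():
        logger.warning("constant abundance profiles: undefined correlations "
                       "imputed as distance 1")
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.where(np.isnan(dist), 1.0, dist)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = average(squareform(dist, checks=False))
    rho_df = pd.DataFrame(rho, index=samples, columns=samples)
    return DendrogramResult(
        rho=rho_df, linkage=linkage, samples=list(samples),
        newick=_linkage_to_newick(linkage, [str(s) for s in samples]),
    )


def _linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage tree to a Newick string with branch lengths."""
    tree = to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    body = render(tree, tree.dist)
    # strip the root's zero-length branch
    return body.rsplit(":", 1)[0] + ";"


def correlate_features(
    table_a: AbundanceTable,
    table_b: AbundanceTable,
    min_samples: int = 4,
) -> pd.DataFrame:
    """Spearman correlation of every column of ``table_a`` against every
    column of ``table_b``, BH-adjusted across the whole family.

    Both tables must cover the same samples. With fewer than
    ``min_samples`` samples the results are flagged low-power and p-values
    are reported missing.
    """
    a, b = table_a.percentages, table_b.percentages
    common = a.index.intersection(b.index)
    if not a.index.equals(b.index):
        if len(common) == 0:
            raise ValueError("tables share no samples")
        logger.warning("tables restricted to %d shared samples", len(common))
    a, b = a.loc[common], b.loc[common]
    low_power = len(common) < min_samples

    rows = []
    for ca in a.columns:
        for cb in b.columns:
            rho, p = spearman_rho_p(a[ca], b[cb])
            rows.append({
                "feature_a": ca, "feature_b": cb, "rho": rho,
                "p": np.nan if low_power else p,
                "n": len(common), "low_power": low_power,
            })
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs are passed through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def compare_groups(
    table: AbundanceTable | pd.DataFrame,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-sided Mann–Whitney U per feature between two sample groups.

    Accepts an :class:`AbundanceTable` carrying group labels or any
    samples × features frame plus a group series. Reports per-group medians,
    the U statistic of the first group, and the two-sided p (exact where
    scipy's method selection allows, tie-corrected normal approximation
    otherwise).
    """
    if isinstance(table, AbundanceTable):
        frame, groups = table.percentages, table.groups if groups is None else groups
    else:
        frame = table
    if groups is None:
        raise ValueError("group labels required")
    groups = groups.reindex(frame.index)
    levels = [g for g in pd.unique(groups.dropna())]
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, found {levels}")
    g1, g2 = levels
    m1, m2 = groups == g1, groups == g2
    if m1.sum() == 0 or m2.sum() == 0:
        empty = g1 if m1.sum() == 0 else g2
        raise ValueError(f"group {empty!r} has no samples")

    rows = []
    for col in frame.columns:
        x, y = frame.loc[m1, col].dropna(), frame.loc[m2, col].dropna()
        u, p = mannwhitneyu(x, y, alternative="two-sided")
        rows.append({
            "feature": col,
            f"median_{g1}": float(np.median(x)),
            f"median_{g2}": float(np.median(y)),
            "U": float(u), "p": float(p),
            "n_low_power": len(x) < 3 or len(y) < 3,
        })
    return pd.DataFrame(rows)


def median_marker_by_group(
    data: ExpressionMatrix,
    cell_type: pd.Series,
    marker: str,
    target_type: str,
    groups: pd.Series,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample median marker expression within one cell type + group test.

    Returns the per-sample medians (arcsinh scale) and the Mann–Whitney
    comparison between the two groups. Samples lacking the cell type are
    missing from the medians (logged).
    """
    if marker not in data.markers:
        raise KeyError(f"marker {marker!r} not in the panel")
    present = set(np.asarray(cell_type))
    if target_type not in present:
        raise ValueError(f"cell type {target_type!r} absent from the annotation")
    mask = (np.asarray(cell_type) == target_type)
    values = data.values.loc[mask, marker]
    sids = data.sample_id[mask]
    medians = values.groupby(np.asarray(sids)).median().rename(marker)
    missing = set(data.samples) - set(medians.index)
    if missing:
        logger.info("samples without %r events: %s", target_type, sorted(missing))
    frame = medians.to_frame()
    test = compare_groups(frame, groups.reindex(frame.index))
    return medians, test
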