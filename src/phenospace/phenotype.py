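"""Elbow-guided k-means phenotyping with rule-based cluster annotation.

The phenotyping strategy is a two-round gating-by-clustering scheme common
in mass-cytometry studies:

1. k-means (k = 10 by default) on six lineage markers (EpCAM, CD31, CD45,
   vimentin, cytokeratin, CK7) over the pooled cohort, followed by
   rule-based annotation of the cluster median profiles into major
   compartments: epithelial cancer cells (EpCAM+/cytokeratin+/CK7+),
   endothelial (CD45−/CD31+), mesenchymal (vimentin+/CD45−/CD31−/epithelial
   markers−) and immune (CD45+). Clusters hitting the same rule are merged.
2. A second k-means round (k = 10) on the immune subset only, using six
   immune markers (CD8, CD24, CD3, CD11b, CD56, HLA-DR), annotated into
   cytotoxic T (CD3+/CD8+), helper T (CD3+/CD4+; CD4 is used for labeling
   but is not a clustering feature), myeloid (CD3−/CD11b+) and "Other
   immune".

Epithelial cancer cells can additionally be subclustered (k = 10) on a
28-marker functional panel to expose intra-tumor heterogeneity ("ECCc"
clusters).

Positivity policy: a marker counts as "high" in a cluster when the cluster
median (arcsinh scale) exceeds the midpoint between the cohort's 10th and
90th percentile for that marker. The policy is deterministic and
scale-aware; no per-marker manual gates are required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import ARCSINH, AnnotationResult, ExpressionMatrix
from .panel import ECC_FUNCTIONAL_MARKERS, IMMUNE_MARKERS, ROUND1_MARKERS

logger = logging.getLogger(__name__)

OTHER = "Other"
OTHER_IMMUNE = "Other immune"
IMMUNE = "Immune"


@dataclass
class ClusteringConfig:
    """Settings for one k-means round."""

    k: int | str = "auto"
    k_range: tuple[int, ...] = tuple(range(1, 13))
    marker_subset: list[str] | None = None
    n_init: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k != "auto":
            if int(self.k) < 1:
                raise ValueError("k must be >= 1")
        elif not self.k_range:
            raise ValueError("k_range required when k='auto'")


@dataclass
class AnnotationRule:
    """One labeling rule: all required_high markers high, required_low low."""

    cell_type: str
    required_high: list[str] = field(default_factory=list)
    required_low: list[str] = field(default_factory=list)
    priority: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.required_high) & set(self.required_low)
        if overlap:
            raise ValueError(f"rule {self.cell_type!r}: markers in both "
                             f"required_high and required_low: {sorted(overlap)}")


def default_round1_rules() -> list[AnnotationRule]:
    """Major-compartment rules, checked in priority order."""
    return [
        AnnotationRule("Epithelial cancer cells",
                       required_high=["EpCAM", "cytokeratin", "CK7"], priority=0),
        AnnotationRule("Endothelial",
                       required_high=["CD31"], required_low=["CD45"], priority=1),
        AnnotationRule("Mesenchymal",
                       required_high=["vimentin"],
                       required_low=["CD45", "CD31", "EpCAM", "cytokeratin", "CK7"],
                       priority=2),
        AnnotationRule(IMMUNE, required_high=["CD45"], priority=3),
    ]


def default_immune_rules() -> list[AnnotationRule]:
    """Immune-subset rules for the second clustering round."""
    return [
        AnnotationRule("Cytotoxic T cells",
                       required_high=["CD3", "CD8"], required_low=["CD4"], priority=0),
        AnnotationRule("Helper T cells",
                       required_high=["CD3", "CD4"], required_low=["CD8"], priority=1),
        AnnotationRule("Myeloid",
                       required_high=["CD11b"], required_low=["CD3"], priority=2),
    ]


def positivity_thresholds(
    data: ExpressionMatrix, q_low: float = 0.10, q_high: float = 0.90
) -> pd.Series:
    """Per-marker positivity cutoffs: midpoint of the 10th/90th percentile.

    Computed over the whole (arcsinh-transformed) cohort so both clustering
    rounds share one scale-aware gate per marker.
    """
    q = data.values.quantile([q_low, q_high])
    return (q.iloc[0] + q.iloc[1]) / 2.0


@dataclass
class ElbowResult:
    k: int
    wcss: pd.Series            # indexed by candidate k
    elbow_found: bool


def elbow_select_k(
    data: ExpressionMatrix, config: ClusteringConfig, tail_ratio_min: float = 3.0
) -> ElbowResult:
    """Choose k by the elbow criterion on the within-cluster sum of squares.

    The WCSS is computed for every candidate in ``k_range``; the elbow is
    the interior candidate maximizing the second difference of the
    range-normalized curve. A genuine elbow requires the drop into the
    candidate to dominate the entire residual tail
    (``drop / tail >= tail_ratio_min``); otherwise the curve is declared
    elbow-free and the smallest candidate is returned (logged).
    """
    ks = sorted(int(k) for k in set(config.k_range))
    if len(ks) < 3:
        raise ValueError("k_range needs at least 3 candidates for an elbow")
    features = _feature_matrix(data, config.marker_subset)
    if max(ks) > len(features):
        raise ValueError("largest k exceeds the number of events")

    wcss = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=config.n_init, random_state=config.seed)
        km.fit(features)
        wcss[k] = float(km.inertia_)
    curve = pd.Series(wcss).sort_index()

    span = curve.max() - curve.min()
    if span <= 0:
        logger.info("flat WCSS curve: no elbow; returning k=%d", ks[0])
        return ElbowResult(ks[0], curve, False)
    norm = (curve - curve.min()) / span

    best_k, best_d2 = None, -np.inf
    for j in range(1, len(ks) - 1):
        d2 = norm.iloc[j - 1] - 2 * norm.iloc[j] + norm.iloc[j + 1]
        if d2 > best_d2:
            best_d2, best_k = d2, ks[j]
    j = ks.index(best_k)
    drop = norm.iloc[j - 1] - norm.iloc[j]
    tail = norm.iloc[j] - norm.iloc[-1]
    if tail <= 0 or drop / tail >= tail_ratio_min:
        return ElbowResult(best_k, curve, True)
    logger.info("no clear elbow (drop/tail = %.2f < %.2f); returning k=%d",
                drop / max(tail, 1e-300), tail_ratio_min, ks[0])
    return ElbowResult(ks[0], curve, False)


def _feature_matrix(
    data: ExpressionMatrix, marker_subset: list[str] | None
) -> np.ndarray:
    markers = marker_subset or data.markers
    missing = set(markers) - set(data.markers)
    if missing:
        raise KeyError(f"markers not in the expression table: {sorted(missing)}")
    return data.values[markers].to_numpy(dtype=float)


def cluster_events(
    data: ExpressionMatrix, config: ClusteringConfig
) -> AnnotationResult:
    """Pooled k-means over the cohort; returns cluster ids and median profiles.

    Cluster ids are 1-based. Median profiles are computed over *all* panel
    markers (not only the clustering features) so annotation rules may use
    markers outside the feature set.
    """
    if data.scale_state != ARCSINH:
        raise ValueError("clustering expects arcsinh-transformed data")
    k = config.k if config.k != "auto" else elbow_select_k(data, config).k
    k = int(k)
    if k > data.n_events:
        raise ValueError(f"k={k} exceeds the number of events ({data.n_events})")
    features = _feature_matrix(data, config.marker_subset)
    km = KMeans(n_clusters=k, n_init=config.n_init, random_state=config.seed)
    labels = km.fit_predict(features) + 1

    cluster_id = pd.Series(labels, name="cluster_id")
    profiles = data.values.groupby(cluster_id).median()
    profiles.index.name = "cluster_id"
    return AnnotationResult(
        cluster_id=cluster_id,
        cell_type=pd.Series([OTHER] * len(labels), name="cell_type"),
        cluster_profiles=profiles,
        cluster_labels={},
        sample_id=data.sample_id,
    )


def annotate_clusters(
    result: AnnotationResult,
    rules: list[AnnotationRule],
    thresholds: pd.Series,
    default_label: str = OTHER,
) -> AnnotationResult:
    """Label each cluster by the highest-priority matching rule.

    A rule matches when every ``required_high`` marker's cluster median
    exceeds its positivity threshold and every ``required_low`` median does
    not. Clusters matching no rule receive ``default_label``. Clusters that
    share a label are thereby merged.
    """
    profiles = result.cluster_profiles
    for rule in rules:
        unknown = (set(rule.required_high) | set(rule.required_low)) - set(profiles.columns)
        if unknown:
            raise KeyError(f"rule {rule.cell_type!r} references unknown markers: "
                           f"{sorted(unknown)}")
    labels = {}
    for cid, profile in profiles.iterrows():
        label = default_label
        for rule in sorted(rules, key=lambda r: r.priority):
            high_ok = all(profile[m] > thresholds[m] for m in rule.required_high)
            low_ok = all(profile[m] <= thresholds[m] for m in rule.required_low)
            if high_ok and low_ok:
                label = rule.cell_type
                break
        labels[cid] = label
    cell_type = result.cluster_id.map(labels).rename("cell_type")
    return AnnotationResult(
        cluster_id=result.cluster_id,
        cell_type=cell_type,
        cluster_profiles=profiles,
        cluster_labels=labels,
        sample_id=result.sample_id,
    )


def annotate_immune(
    immune_data: ExpressionMatrix,
    config: ClusteringConfig | None = None,
    rules: list[AnnotationRule] | None = None,
    thresholds: pd.Series | None = None,
) -> AnnotationResult:
    """Second clustering round on the CD45+ subset.

    Features are the six immune markers; unmatched clusters are labeled
    "Other immune". Returns an empty result (with a warning) if the immune
    subset is empty.
    """
    if immune_data.n_events == 0:
        logger.warning("empty immune subset: skipping round-2 clustering")
        return AnnotationResult(
            cluster_id=pd.Series([], dtype=int, name="cluster_id"),
            cell_type=pd.Series([], dtype=object, name="cell_type"),
            cluster_profiles=pd.DataFrame(columns=immune_data.markers),
            cluster_labels={},
            sample_id=immune_data.sample_id,
        )
    config = config or ClusteringConfig(k=10, marker_subset=list(IMMUNE_MARKERS))
    if config.marker_subset is None:
        config.marker_subset = list(IMMUNE_MARKERS)
    k = int(config.k) if config.k != "auto" else None
    if k is not None and k > immune_data.n_events:
        logger.warning("immune subset smaller than k=%d; reducing", k)
        config = ClusteringConfig(
            k=immune_data.n_events, marker_subset=config.marker_subset,
            n_init=config.n_init, seed=config.seed,
        )
    result = cluster_events(immune_data, config)
    if thresholds is None:
        thresholds = positivity_thresholds(immune_data)
    return annotate_clusters(
        result, rules or default_immune_rules(), thresholds,
        default_label=OTHER_IMMUNE,
    )


def subcluster_ecc(
    ecc_data: ExpressionMatrix,
    k: int = 10,
    markers: list[str] | None = None,
    n_init: int = 10,
    seed: int = 0,
) -> AnnotationResult:
    """Subcluster epithelial cancer cells on the functional marker panel.

    Clusters are labeled "ECCc 1" … "ECCc k". If fewer distinct events than
    ``k`` are available, k is reduced with a warning.
    """
    if ecc_data.n_events == 0:
        raise ValueError("empty cancer-cell subset")
    markers = markers or [m for m in ECC_FUNCTIONAL_MARKERS if m in ecc_data.markers]
    if ecc_data.n_events < k:
        logger.warning("only %d cancer-cell events; reducing k from %d",
                       ecc_data.n_events, k)
        k = ecc_data.n_events
    result = cluster_events(
        ecc_data, ClusteringConfig(k=k, marker_subset=markers, n_init=n_init, seed=seed)
    )
    labels = {cid: f"ECCc {cid}" for cid in result.cluster_profiles.index}
    return AnnotationResult(
        cluster_id=result.cluster_id,
        cell_type=result.cluster_id.map(labels).rename("cell_type"),
        cluster_profiles=result.cluster_profiles,
        cluster_labels=labels,
        sample_id=result.sample_id,
    )


@dataclass
class PhenotypeResult:
    """Output of the full two-round phenotyping of a cohort."""

    cell_type: pd.Series            # final per-event label
    sample_id: pd.Series
    round1: AnnotationResult
    round2: AnnotationResult        # immune subset (aligned to immune events)
    immune_mask: np.ndarray
    thresholds: pd.Series


def two_round_phenotype(
    data: ExpressionMatrix,
    k_round1: int = 10,
    k_round2: int = 10,
    n_init: int = 10,
    seed: int = 0,
    round1_rules: list[AnnotationRule] | None = None,
    immune_rules: list[AnnotationRule] | None = None,
) -> PhenotypeResult:
    """Run both clustering rounds and propagate immune labels to the cohort."""
    thresholds = positivity_thresholds(data)
    r1 = cluster_events(
        data, ClusteringConfig(k=k_round1, marker_subset=list(ROUND1_MARKERS),
                               n_init=n_init, seed=seed)
    )
    r1 = annotate_clusters(r1, round1_rules or default_round1_rules(), thresholds)

    immune_mask = (r1.cell_type == IMMUNE).to_numpy()
    r2 = annotate_immune(
        data.subset(immune_mask),
        ClusteringConfig(k=k_round2, marker_subset=list(IMMUNE_MARKERS),
                         n_init=n_init, seed=seed),
        rules=immune_rules,
        thresholds=thresholds,
    )
    cell_type = r1.cell_type.copy()
    if immune_mask.any():
        cell_type.iloc[np.flatnonzero(immune_mask)] = r2.cell_type.to_numpy()
    return PhenotypeResult(
        cell_type=cell_type.rename("cell_type"),
        sample_id=data.sample_id,
        round1=r1,
        round2=r2,
        immune_mask=immune_mask,
        thresholds=thresholds,
    )
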