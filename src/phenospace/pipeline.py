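"""End-to-end orchestration: simulate/ingest → QC → transform → phenotype →
abundance statistics → (optional) spatial analysis.

Every stage writes its artifact into the output directory as plain text
(CSV / JSON / Newick), every stochastic stage derives its stream from the
single configured seed, and the run report reconciles event counts across
stages and carries a hash of the configuration so outputs are attributable
and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import (
    compare_groups,
    compute_abundance,
    correlate_features,
    correlation_dendrogram,
)
from .containers import ExpressionMatrix
from .io import write_json
from .panel import PanelDefinition, default_panel
from .phenotype import subcluster_ecc, two_round_phenotype
from .preprocess import QCConfig, arcsinh_transform, filter_events, subsample_events
from .simulate import (
    CohortConfig,
    SpatialConfig,
    generate_cytof_cohort,
    generate_spatial_cohort,
)
from .spatial import (
    classify_cells,
    compare_distance_groups,
    correlate_hladr_tcells,
    neighborhood_stats,
    t_to_tumor_distances,
)

logger = logging.getLogger(__name__)

T_LABELS = ("Helper T cells", "Cytotoxic T cells")


@dataclass
class PipelineConfig:
    """Configuration of one full run on a synthetic cohort."""

    out_dir: str = "phenospace_run"
    seed: int = 0
    n_events_per_sample: int = 5000
    subsample_to: int | None = None       # optional equal subsampling post-QC
    k_round1: int = 10
    k_round2: int = 10
    k_ecc: int = 10
    qc: QCConfig = field(default_factory=QCConfig)
    include_spatial: bool = True
    spatial_radius_um: float = 50.0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    version: str
    seed: int
    stage_counts: dict = field(default_factory=dict)
    chosen_k: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        write_json(asdict(self), path)


def hladr_positive_ecc_abundance(
    ecc_annotation, thresholds, ecc_label_prefix: str = "ECCc",
    hladr_marker: str = "HLA-DR",
) -> pd.Series:
    """Percent of each sample's cancer cells in HLA-DR-high subclusters.

    A subcluster counts as HLA-DR+ when its median HLA-DR exceeds the
    cohort positivity threshold for that marker.
    """
    profiles = ecc_annotation.cluster_profiles
    hladr_high = profiles.index[profiles[hladr_marker] > thresholds[hladr_marker]]
    sid = np.asarray(ecc_annotation.sample_id)
    is_high = ecc_annotation.cluster_id.isin(hladr_high).to_numpy()
    totals = pd.Series(sid).value_counts()
    highs = pd.Series(sid[is_high]).value_counts().reindex(totals.index, fill_value=0)
    return (highs / totals * 100.0).rename("hladr_pos_ecc_pct")


def run_pipeline(config: PipelineConfig | None = None) -> RunReport:
    """Run the full synthetic-cohort analysis and write all artifacts."""
    cfg = config or PipelineConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=cfg.hash(), version=__version__, seed=cfg.seed)

    # --- simulate ---------------------------------------------------------
    cohort_cfg = CohortConfig(
        n_events_per_sample=cfg.n_events_per_sample, seed=cfg.seed
    )
    data, truth = generate_cytof_cohort(cohort_cfg)
    groups = truth.groups
    report.stage_counts["simulated"] = data.n_events
    truth.composition.to_csv(out / "truth_composition.csv", index_label="sample_id")
    truth.sample_table.to_csv(out / "truth_samples.csv")

    # --- QC + transform ---------------------------------------------------
    filtered, qc_report = filter_events(data, cfg.qc)
    report.stage_counts["qc_retained"] = filtered.n_events
    report.stage_counts["qc_removed_dead"] = qc_report.totals()["n_removed_dead"]
    report.stage_counts["qc_removed_nonsinglet"] = (
        qc_report.totals()["n_removed_nonsinglet"]
    )
    qc_report.to_frame().to_csv(out / "qc_report.csv")
    transformed = arcsinh_transform(filtered, cfg.qc.cofactor)
    if cfg.subsample_to:
        transformed = subsample_events(transformed, cfg.subsample_to, seed=cfg.seed)
        report.stage_counts["subsampled"] = transformed.n_events

    # --- phenotyping ------------------------------------------------------
    pheno = two_round_phenotype(
        transformed, k_round1=cfg.k_round1, k_round2=cfg.k_round2, seed=cfg.seed
    )
    report.chosen_k = {"round1": cfg.k_round1, "round2": cfg.k_round2,
                       "ecc": cfg.k_ecc}
    assignments = pd.DataFrame({
        "sample_id": pheno.sample_id.values,
        "cell_type": pheno.cell_type.values,
        "round1_cluster": pheno.round1.cluster_id.values,
    })
    assignments.to_csv(out / "cell_assignments.csv", index=False)
    pheno.round1.cluster_profiles.to_csv(out / "round1_cluster_profiles.csv")
    if pheno.round2.n_events:
        pheno.round2.cluster_profiles.to_csv(out / "round2_cluster_profiles.csv")

    # --- abundances and statistics ---------------------------------------
    from .containers import AnnotationResult  # local to avoid cycle at import

    cohort_annotation = AnnotationResult(
        cluster_id=pheno.round1.cluster_id,
        cell_type=pheno.cell_type,
        cluster_profiles=pheno.round1.cluster_profiles,
        sample_id=pheno.sample_id,
    )
    abundance = compute_abundance(cohort_annotation, groups=groups)
    abundance.to_csv(out / "cell_type_abundance.csv")

    dendro = correlation_dendrogram(abundance)
    (out / "patient_dendrogram.nwk").write_text(dendro.newick + "\n")
    dendro.cut(2).to_csv(out / "dendrogram_groups.csv")

    group_tests = compare_groups(abundance)
    group_tests.to_csv(out / "group_comparisons.csv", index=False)

    # ECC subclustering + cross-compartment correlation
    ecc_mask = (pheno.cell_type == "Epithelial cancer cells").to_numpy()
    ecc_result = None
    if ecc_mask.sum() >= 2:
        ecc_result = subcluster_ecc(
            transformed.subset(ecc_mask), k=cfg.k_ecc, seed=cfg.seed
        )
        ecc_result.cluster_profiles.to_csv(out / "ecc_cluster_profiles.csv")
        ecc_abundance = compute_abundance(ecc_result, groups=groups)
        ecc_abundance.to_csv(out / "ecc_cluster_abundance.csv")
        immune_cols = [c for c in abundance.percentages.columns
                       if c in T_LABELS + ("Myeloid", "Other immune")]
        imm_pct = abundance.percentages[immune_cols]
        common = ecc_abundance.percentages.index.intersection(imm_pct.index)
        from .containers import AbundanceTable
        renorm = lambda f: f.div(f.sum(axis=1), axis=0) * 100.0  # noqa: E731
        corr = correlate_features(
            AbundanceTable(renorm(ecc_abundance.percentages.loc[common])),
            AbundanceTable(renorm(imm_pct.loc[common])),
        )
        corr.to_csv(out / "ecc_immune_correlations.csv", index=False)
        hladr_pct = hladr_positive_ecc_abundance(ecc_result, pheno.thresholds)
        hladr_pct.to_csv(out / "hladr_pos_ecc_abundance.csv")
    else:
        report.warnings.append("too few cancer cells for subclustering")

    # --- spatial ----------------------------------------------------------
    if cfg.include_spatial:
        sp_cfg = SpatialConfig(seed=cfg.seed)
        cells, sp_truth = generate_spatial_cohort(sp_cfg)
        cells = classify_cells(cells)
        cells.to_csv(out / "spatial_cells.csv", index=False)
        sp_groups = sp_truth.sample_table["group"]

        nb_frames, dist_by_sample = [], {}
        for sid, sub in cells.groupby("sample_id"):
            sub = sub.reset_index(drop=True)
            nb = neighborhood_stats(sub, radius_um=cfg.spatial_radius_um)
            nb.insert(0, "sample_id", sid)
            nb_frames.append(nb)
            dist_by_sample[sid] = t_to_tumor_distances(sub)
        neighborhoods = pd.concat(nb_frames, ignore_index=True)
        neighborhoods.to_csv(out / "neighborhoods.csv", index=False)
        pd.concat(
            [d.assign(sample_id=s) for s, d in dist_by_sample.items()],
            ignore_index=True,
        ).to_csv(out / "t_tumor_distances.csv", index=False)

        corr = correlate_hladr_tcells(neighborhoods, aggregation="per_sample")
        dist_cmp = compare_distance_groups(dist_by_sample, sp_groups)
        dist_cmp.per_sample.to_csv(out / "distance_per_sample.csv", index=False)
        write_json(
            {
                "hladr_tcell_correlation": corr,
                "distance_comparison": {
                    "p_d1": dist_cmp.p_d1, "p_d2": dist_cmp.p_d2,
                    "shorter_d1_group": dist_cmp.direction,
                },
            },
            out / "spatial_stats.json",
        )
        report.stage_counts["spatial_cells"] = len(cells)

    report.to_json(out / "run_report.json")
    return report
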