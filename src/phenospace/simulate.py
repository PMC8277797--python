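"""Synthetic cohort generators with planted, recoverable ground truth.

Two generators are provided:

``generate_cytof_cohort``
    A mass-cytometry-like cohort: each sample is a mixture of seven cell
    archetypes (epithelial cancer cells, endothelial, mesenchymal, helper T,
    cytotoxic T, myeloid, other immune) drawn on the arcsinh scale and
    mapped back to raw ion counts through ``5 * sinh(v)``, so the standard
    ``asinh(x / 5)`` transform inverts the generator in expectation.
    Dead events carry a low nuclear (histone) signal; doublets are sums of
    two live events with an out-of-range event length, so the stated QC
    gates separate them cleanly.

    Sample composition is Dirichlet-distributed per group. A single latent
    Gaussian factor per sample loads on both (a) the HLA-DR-positive share
    of that sample's cancer cells and (b) a multiplicative tilt on the
    T-cell abundance, which plants a tunable positive correlation
    (``hladr_tcell_rho``) between the HLA-DR+ cancer-cell fraction and the
    T-cell fraction across samples.

``generate_spatial_cohort``
    A multiplex-immunofluorescence-like point pattern per sample: tumor
    cells placed uniformly in the field, T cells placed as displaced
    offspring of randomly chosen tumor cells (Thomas-process style) with a
    per-group displacement scale, so a smaller scale yields stochastically
    shorter T-cell-to-tumor distances. Tumor-cell HLA-DR intensity rises
    with the number of T cells within 50 µm when ``hladr_gradient > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import ExpressionMatrix
from .panel import default_panel

# canonical archetype names; these match the final annotation labels so
# that recovery can be scored by direct string comparison
ECC = "Epithelial cancer cells"
ENDOTHELIAL = "Endothelial"
MESENCHYMAL = "Mesenchymal"
HELPER_T = "Helper T cells"
CYTOTOXIC_T = "Cytotoxic T cells"
MYELOID = "Myeloid"
OTHER_IMMUNE = "Other immune"

CELL_TYPES = [ECC, ENDOTHELIAL, MESENCHYMAL, HELPER_T, CYTOTOXIC_T, MYELOID, OTHER_IMMUNE]
T_CELL_TYPES = (HELPER_T, CYTOTOXIC_T)

_BASELINE_MEAN = 0.45
_BASELINE_SD = 0.12
_HIGH_SD = 0.3

# per-archetype positive markers on the arcsinh scale (everything else sits
# at the negative baseline); HLA-DR on cancer cells is set per event from
# the planted HLA-DR-positive flag
_ARCHETYPE_HIGHS: dict[str, dict[str, float]] = {
    ECC: {
        "EpCAM": 3.5, "cytokeratin": 3.5, "CK7": 3.3, "TTF1": 2.5,
        "beta-catenin": 2.5, "EGFR": 2.8, "MET": 2.6, "HER2": 2.0,
        "p-ERK": 2.2, "p-S6": 2.2, "p-STAT3": 1.8, "Ki67": 2.0,
        "CD24": 2.2, "CD44": 2.2, "TP53": 1.8, "HLA-ABC": 2.5,
    },
    ENDOTHELIAL: {"CD31": 3.4, "vimentin": 2.6, "CD44": 1.8, "HLA-ABC": 2.0},
    MESENCHYMAL: {"vimentin": 3.5, "CD44": 2.0, "HLA-ABC": 1.8},
    HELPER_T: {"CD45": 3.6, "CD3": 3.4, "CD4": 3.2, "HLA-ABC": 2.2},
    CYTOTOXIC_T: {"CD45": 3.6, "CD3": 3.4, "CD8": 3.3, "HLA-ABC": 2.2},
    MYELOID: {"CD45": 3.4, "CD11b": 3.3, "HLA-DR": 2.8, "HLA-ABC": 2.2},
    OTHER_IMMUNE: {"CD45": 3.4, "CD56": 3.0, "HLA-ABC": 2.2},
}

HLADR_POS_MEAN = 3.2     # arcsinh HLA-DR on HLA-DR+ cancer cells
LIVE_H3_MEAN = 4.0       # arcsinh nuclear signal on live events
DEAD_H3_MEAN = 0.5       # below the raw death threshold of 10 (= asinh 1.44)


def default_archetype_means(markers: list[str] | None = None) -> pd.DataFrame:
    """Archetype × marker mean table on the arcsinh scale."""
    markers = markers or default_panel().markers
    means = pd.DataFrame(_BASELINE_MEAN, index=CELL_TYPES, columns=markers)
    for ctype, highs in _ARCHETYPE_HIGHS.items():
        for m, v in highs.items():
            if m in means.columns:
                means.loc[ctype, m] = v
    means["HistoneH3"] = LIVE_H3_MEAN
    return means


def default_archetype_sds(markers: list[str] | None = None) -> pd.DataFrame:
    """Archetype × marker spread table; wider on positive markers."""
    means = default_archetype_means(markers)
    sds = pd.DataFrame(_BASELINE_SD, index=means.index, columns=means.columns)
    sds[means > 1.0] = _HIGH_SD
    return sds


# default per-group Dirichlet concentrations: the first group is
# immune-rich (higher T-cell mass, less mesenchyme), the second
# immune-poor, matching a long- vs short-predicted-survival contrast
DEFAULT_COMPOSITION_ALPHA: dict[str, dict[str, float]] = {
    "LPS": {
        ECC: 90.0, ENDOTHELIAL: 14.0, MESENCHYMAL: 16.0,
        HELPER_T: 64.0, CYTOTOXIC_T: 52.0, MYELOID: 40.0, OTHER_IMMUNE: 24.0,
    },
    "SPS": {
        ECC: 156.0, ENDOTHELIAL: 18.0, MESENCHYMAL: 66.0,
        HELPER_T: 12.0, CYTOTOXIC_T: 9.0, MYELOID: 21.0, OTHER_IMMUNE: 18.0,
    },
}

# group-level mean of the shared latent factor: the immune-rich group sits
# higher on both the HLA-DR+ cancer-cell share and the T-cell tilt, so the
# two-group composition contrast is identifiable while the within-group
# correlation stays at the planted rho
DEFAULT_GROUP_LATENT_OFFSET: dict[str, float] = {"LPS": 1.0, "SPS": -1.0}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic mass-cytometry cohort.

    Defaults mirror a two-group lung-tumor cohort: 4 long-predicted-survival
    and 6 short-predicted-survival samples, an immune-rich vs immune-poor
    composition contrast, and a strongly planted correlation (rho = 0.9)
    between the HLA-DR+ cancer-cell fraction and the T-cell fraction.
    """

    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"LPS": 4, "SPS": 6}
    )
    cell_types: list[str] = field(default_factory=lambda: list(CELL_TYPES))
    archetype_means: pd.DataFrame | None = None
    archetype_sds: pd.DataFrame | None = None
    composition_alpha: Mapping[str, Mapping[str, float]] | None = None
    hladr_tcell_rho: float = 0.9
    tcell_tilt_sd: float = 0.5           # latent loading on log T abundance
    group_latent_offset: Mapping[str, float] | None = None
    hladr_share_range: tuple[float, float] = (0.1, 0.9)
    n_events_per_sample: int = 5000
    dead_fraction: float = 0.05
    doublet_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype_means is None:
            self.archetype_means = default_archetype_means()
        if self.archetype_sds is None:
            self.archetype_sds = default_archetype_sds()
        if self.composition_alpha is None:
            self.composition_alpha = {
                g: dict(DEFAULT_COMPOSITION_ALPHA.get(g)
                        or DEFAULT_COMPOSITION_ALPHA["LPS"])
                for g in self.n_samples_per_group
            }
        if self.group_latent_offset is None:
            self.group_latent_offset = {
                g: DEFAULT_GROUP_LATENT_OFFSET.get(g, 0.0)
                for g in self.n_samples_per_group
            }
        if not -1.0 < self.hladr_tcell_rho < 1.0:
            raise ValueError("hladr_tcell_rho must lie in (-1, 1)")
        if self.dead_fraction + self.doublet_fraction >= 1.0:
            raise ValueError("dead_fraction + doublet_fraction must be < 1")
        if min(self.dead_fraction, self.doublet_fraction) < 0:
            raise ValueError("fractions must be non-negative")
        for g, alphas in self.composition_alpha.items():
            if set(alphas) != set(self.cell_types):
                raise ValueError(f"composition_alpha for group {g!r} must "
                                 "cover exactly the configured cell types")
            if any(a <= 0 for a in alphas.values()):
                raise ValueError(f"composition_alpha for group {g!r} has "
                                 "non-positive entries")
        missing = set(self.cell_types) - set(self.archetype_means.index)
        if missing:
            raise ValueError(f"archetype_means missing rows: {sorted(missing)}")


@dataclass
class CytofGroundTruth:
    """Per-event and per-sample truth for a synthetic cohort."""

    events: pd.DataFrame       # sample_id, cell_type, is_dead, is_doublet, hladr_positive
    composition: pd.DataFrame  # samples × cell types, fractions of live singlets
    sample_table: pd.DataFrame # group, hladr_pos_ecc_fraction, t_cell_fraction

    @property
    def groups(self) -> pd.Series:
        return self.sample_table["group"]


def _sample_composition(
    rng: np.random.Generator, cfg: CohortConfig, group: str
) -> tuple[np.ndarray, float]:
    """Draw one sample's type fractions and HLA-DR+ share of cancer cells.

    A latent factor drives the HLA-DR share directly and, through a
    correlated factor (within-group correlation = ``hladr_tcell_rho``), a
    log-normal tilt on the combined T-cell Dirichlet mass. Both factors are
    shifted by the group's latent offset so that group contrasts act on the
    HLA-DR share and T-cell abundance jointly.
    """
    rho = cfg.hladr_tcell_rho
    delta = float(cfg.group_latent_offset.get(group, 0.0))
    u = rng.standard_normal()
    z = u + delta
    y = rho * u + np.sqrt(1.0 - rho * rho) * rng.standard_normal() + delta

    alphas = cfg.composition_alpha[group]
    gammas = {t: rng.gamma(alphas[t]) for t in cfg.cell_types}
    tilt = float(np.exp(cfg.tcell_tilt_sd * y))
    for t in cfg.cell_types:
        if t in T_CELL_TYPES:
            gammas[t] *= tilt
    total = sum(gammas.values())
    fractions = np.array([gammas[t] / total for t in cfg.cell_types])

    lo, hi = cfg.hladr_share_range
    share = lo + (hi - lo) * float(norm.cdf(z))
    return fractions, share


def generate_cytof_cohort(
    config: CohortConfig | None = None,
) -> tuple[ExpressionMatrix, CytofGroundTruth]:
    """Generate a raw-scale expression cohort with event-level truth.

    Returns the raw (untransformed) expression matrix including planted dead
    events and doublets, plus a :class:`CytofGroundTruth` whose composition
    table is computed over live singlet events only.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    markers = list(cfg.archetype_means.columns)
    means = cfg.archetype_means.loc[cfg.cell_types, markers].to_numpy()
    sds = cfg.archetype_sds.loc[cfg.cell_types, markers].to_numpy()
    hladr_col = markers.index("HLA-DR") if "HLA-DR" in markers else None
    ecc_idx = cfg.cell_types.index(ECC) if ECC in cfg.cell_types else None

    frames, truth_rows, comp_rows, sample_rows = [], [], [], []
    for group, n_samples in cfg.n_samples_per_group.items():
        for i in range(n_samples):
            sid = f"{group}-{i + 1:02d}"
            fractions, share = _sample_composition(rng, cfg, group)
            n = cfg.n_events_per_sample

            u = rng.random(n)
            is_dead = u < cfg.dead_fraction
            is_doublet = (~is_dead) & (u < cfg.dead_fraction + cfg.doublet_fraction)
            is_live = ~(is_dead | is_doublet)

            type_idx = rng.choice(len(cfg.cell_types), size=n, p=fractions)
            v = rng.normal(means[type_idx], sds[type_idx])   # arcsinh scale

            hladr_pos = np.zeros(n, dtype=bool)
            if hladr_col is not None and ecc_idx is not None:
                is_ecc = type_idx == ecc_idx
                hladr_pos[is_ecc] = rng.random(is_ecc.sum()) < share
                v[is_ecc, hladr_col] = rng.normal(
                    np.where(hladr_pos[is_ecc], HLADR_POS_MEAN, _BASELINE_MEAN),
                    np.where(hladr_pos[is_ecc], _HIGH_SD, _BASELINE_SD),
                )
            if "HistoneH3" in markers:
                h3 = markers.index("HistoneH3")
                v[is_dead, h3] = rng.normal(DEAD_H3_MEAN, 0.2, is_dead.sum())

            raw = np.clip(5.0 * np.sinh(v), 0.0, None)
            length = rng.uniform(20.0, 60.0, size=n)

            # doublets: sum of the event's own ion counts and a random
            # live event's, with an over-long acquisition
            n_dbl = int(is_doublet.sum())
            if n_dbl:
                live_pool = np.flatnonzero(is_live)
                if len(live_pool) == 0:
                    raise ValueError("cannot form doublets without live events")
                partners = rng.choice(live_pool, size=n_dbl)
                raw[is_doublet] = raw[is_doublet] + raw[partners]
                length[is_doublet] = rng.uniform(75.0, 120.0, size=n_dbl)

            frame = pd.DataFrame(raw, columns=markers)
            frame["sample_id"] = sid
            frame["event_length"] = length
            frames.append(frame)

            truth_rows.append(pd.DataFrame({
                "sample_id": sid,
                "cell_type": np.asarray(cfg.cell_types, dtype=object)[type_idx],
                "is_dead": is_dead,
                "is_doublet": is_doublet,
                "hladr_positive": hladr_pos,
            }))

            live_types = type_idx[is_live]
            counts = np.bincount(live_types, minlength=len(cfg.cell_types))
            live_total = max(int(counts.sum()), 1)
            comp = counts / live_total
            comp_rows.append(pd.Series(comp, index=cfg.cell_types, name=sid))
            n_ecc_live = counts[ecc_idx] if ecc_idx is not None else 0
            n_hladr_ecc_live = int((hladr_pos & is_live).sum())
            t_frac = float(sum(
                comp[cfg.cell_types.index(t)]
                for t in T_CELL_TYPES if t in cfg.cell_types
            ))
            sample_rows.append({
                "sample_id": sid,
                "group": group,
                "hladr_share": share,
                "hladr_pos_ecc_fraction": n_hladr_ecc_live / live_total,
                "hladr_pos_share_of_ecc": (
                    n_hladr_ecc_live / n_ecc_live if n_ecc_live else np.nan
                ),
                "t_cell_fraction": t_frac,
            })

    cohort = pd.concat(frames, ignore_index=True)
    truth_events = pd.concat(truth_rows, ignore_index=True)
    data = ExpressionMatrix.from_frame(cohort, markers=markers, scale_state="raw")
    truth = CytofGroundTruth(
        events=truth_events,
        composition=pd.DataFrame(comp_rows),
        sample_table=pd.DataFrame(sample_rows).set_index("sample_id"),
    )
    return data, truth


# ---------------------------------------------------------------------------
# spatial (multiplex-immunofluorescence-like) generator
# ---------------------------------------------------------------------------

TUMOR = "Tumor"
T_CELL = "T cell"
IMMUNE_NON_T = "Immune non-T"
OTHER = "Other"

SPATIAL_CLASSES = [TUMOR, T_CELL, IMMUNE_NON_T, OTHER]

# binary marker template per class: (PanCK, CD45, CD3)
_CLASS_MARKERS = {
    TUMOR: (True, False, False),
    T_CELL: (False, True, True),
    IMMUNE_NON_T: (False, True, False),
    OTHER: (False, False, False),
}


@dataclass
class SpatialConfig:
    """Study conditions for a synthetic multiplex-IF spatial cohort.

    The per-group ``attraction_scale_by_group`` (µm) is the displacement
    scale of T cells around their tumor-cell parents: 15 µm for the
    immune-infiltrated group vs 60 µm for the excluded group by default.
    ``np.inf`` places T cells uniformly (no attraction).
    """

    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"LPS": 10, "SPS": 10}
    )
    field_size: tuple[float, float] = (1000.0, 1000.0)   # µm
    n_tumor_cells: int = 400
    n_t_cells: int = 150
    n_other_cells: int = 250   # split evenly: immune non-T / other
    attraction_scale_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"LPS": 15.0, "SPS": 60.0}
    )
    hladr_gradient: float = 0.15     # intensity per T cell within the radius
    hladr_baseline: float = 1.0
    hladr_noise_sd: float = 0.3
    coupling_radius_um: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor_cells == 0 and self.n_t_cells > 0:
            raise ValueError(
                "T cells without tumor cells: nearest-tumor distance analysis undefined"
            )
        if min(self.field_size) <= 0:
            raise ValueError("field_size must be positive")
        for g in self.n_samples_per_group:
            if g not in self.attraction_scale_by_group:
                raise ValueError(f"no attraction scale for group {g!r}")


@dataclass
class SpatialGroundTruth:
    sample_table: pd.DataFrame   # sample_id → group, attraction_scale, counts


def _marker_probs(rng: np.random.Generator, positive: np.ndarray) -> np.ndarray:
    """Classifier-like probabilities: high for positive calls, low otherwise."""
    p = rng.uniform(0.001, 0.08, size=positive.shape)
    p[positive] = rng.uniform(0.92, 0.999, size=int(positive.sum()))
    return p


def generate_spatial_cohort(
    config: SpatialConfig | None = None,
) -> tuple[pd.DataFrame, SpatialGroundTruth]:
    """Generate per-cell spatial tables for every sample in the cohort.

    Returns one concatenated cell table (columns: sample_id, group, x_um,
    y_um, true_class, prob_PanCK, prob_CD45, prob_CD3, HLA-DR) and the
    per-sample ground truth.
    """
    cfg = config or SpatialConfig()
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.field_size
    frames, rows = [], []
    for group, n_samples in cfg.n_samples_per_group.items():
        scale = float(cfg.attraction_scale_by_group[group])
        for i in range(n_samples):
            sid = f"{group}-F{i + 1:02d}"
            tumor_xy = rng.uniform([0, 0], [w, h], size=(cfg.n_tumor_cells, 2))

            if cfg.n_t_cells and cfg.n_tumor_cells and np.isfinite(scale):
                parents = rng.choice(cfg.n_tumor_cells, size=cfg.n_t_cells)
                t_xy = tumor_xy[parents] + rng.normal(
                    0.0, scale, size=(cfg.n_t_cells, 2)
                )
                t_xy = np.clip(t_xy, [0, 0], [w, h])
            else:
                t_xy = rng.uniform([0, 0], [w, h], size=(cfg.n_t_cells, 2))

            n_imm = cfg.n_other_cells // 2
            n_oth = cfg.n_other_cells - n_imm
            imm_xy = rng.uniform([0, 0], [w, h], size=(n_imm, 2))
            oth_xy = rng.uniform([0, 0], [w, h], size=(n_oth, 2))

            xy = np.vstack([tumor_xy, t_xy, imm_xy, oth_xy])
            classes = np.repeat(
                np.array(SPATIAL_CLASSES, dtype=object),
                [cfg.n_tumor_cells, cfg.n_t_cells, n_imm, n_oth],
            )

            # tumor HLA-DR increases with local T-cell density
            hladr = np.abs(rng.normal(0.0, 0.1, size=len(xy)))
            if cfg.n_tumor_cells:
                if cfg.n_t_cells:
                    d2 = (
                        (tumor_xy[:, None, :] - t_xy[None, :, :]) ** 2
                    ).sum(axis=2)
                    n_t_near = (d2 <= cfg.coupling_radius_um ** 2).sum(axis=1)
                else:
                    n_t_near = np.zeros(cfg.n_tumor_cells)
                hladr[: cfg.n_tumor_cells] = np.clip(
                    cfg.hladr_baseline
                    + cfg.hladr_gradient * n_t_near
                    + rng.normal(0.0, cfg.hladr_noise_sd, size=cfg.n_tumor_cells),
                    0.0, None,
                )

            pos = np.array([_CLASS_MARKERS[c] for c in classes], dtype=bool)
            frame = pd.DataFrame({
                "sample_id": sid,
                "group": group,
                "x_um": xy[:, 0],
                "y_um": xy[:, 1],
                "true_class": classes,
                "prob_PanCK": _marker_probs(rng, pos[:, 0]),
                "prob_CD45": _marker_probs(rng, pos[:, 1]),
                "prob_CD3": _marker_probs(rng, pos[:, 2]),
                "HLA-DR": hladr,
            })
            frames.append(frame)
            rows.append({
                "sample_id": sid, "group": group, "attraction_scale": scale,
                "n_tumor": cfg.n_tumor_cells, "n_t": cfg.n_t_cells,
            })

    table = pd.concat(frames, ignore_index=True)
    truth = SpatialGroundTruth(pd.DataFrame(rows).set_index("sample_id"))
    return table, truth
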