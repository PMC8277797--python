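"""Spatial classification, neighborhood statistics, and distance analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from phenospace import (
    SpatialConfig,
    classify_cells,
    compare_distance_groups,
    correlate_hladr_tcells,
    generate_spatial_cohort,
    neighborhood_stats,
    t_to_tumor_distances,
)


def _table(rows):
    """rows: (x, y, class) or (x, y, class, hladr)"""
    recs = []
    for r in rows:
        x, y, cls = r[:3]
        recs.append({"x_um": x, "y_um": y, "cell_class": cls,
                     "HLA-DR": r[3] if len(r) > 3 else 1.0})
    return pd.DataFrame(recs)


def brute_force_neighborhood(table, radius):
    xy = table[["x_um", "y_um"]].to_numpy(float)
    cls = table["cell_class"].to_numpy()
    hladr = table["HLA-DR"].to_numpy(float)
    out = []
    for i in np.flatnonzero(cls == "Tumor"):
        d = np.sqrt(((xy - xy[i]) ** 2).sum(1))
        t_count = int(((d <= radius) & (cls == "T cell")).sum())
        neigh = (d <= radius) & (cls == "Tumor")
        neigh[i] = False
        med = float(np.median(hladr[neigh])) if neigh.any() else np.nan
        out.append((i, t_count, med))
    return out


def brute_force_distances(table):
    xy = table[["x_um", "y_um"]].to_numpy(float)
    cls = table["cell_class"].to_numpy()
    tumor = xy[cls == "Tumor"]
    out = []
    for i in np.flatnonzero(cls == "T cell"):
        d = np.sort(np.sqrt(((tumor - xy[i]) ** 2).sum(1)))
        out.append((i, d[0], d[1] if len(d) > 1 else np.nan))
    return out


class TestClassify:
    @pytest.mark.parametrize("panck,cd45,cd3,expected", [
        (0.95, 0.01, 0.02, "Tumor"),
        (0.10, 0.95, 0.97, "T cell"),
        (0.05, 0.95, 0.10, "Immune non-T"),
        (0.50, 0.50, 0.50, "Other"),
        (0.95, 0.95, 0.10, "Unassigned"),
    ])
    def test_probability_combinations(self, panck, cd45, cd3, expected):
        cells = pd.DataFrame({"prob_PanCK": [panck], "prob_CD45": [cd45],
                              "prob_CD3": [cd3]})
        assert classify_cells(cells)["cell_class"].iloc[0] == expected

    def test_cutoff_boundary_inclusive(self):
        cells = pd.DataFrame({"prob_PanCK": [0.9], "prob_CD45": [0.0],
                              "prob_CD3": [0.0]})
        assert classify_cells(cells)["cell_class"].iloc[0] == "Tumor"

    def test_order_independent(self):
        rng = np.random.default_rng(0)
        cells = pd.DataFrame({f"prob_{m}": rng.uniform(size=50)
                              for m in ("PanCK", "CD45", "CD3")})
        a = classify_cells(cells)["cell_class"]
        perm = rng.permutation(50)
        b = classify_cells(cells.iloc[perm])["cell_class"]
        assert (a.to_numpy()[perm] == b.to_numpy()).all()

    def test_intensity_thresholds(self):
        cells = pd.DataFrame({"PanCK": [10.0, 1.0], "prob_CD45": [0.0, 0.0],
                              "prob_CD3": [0.0, 0.0]})
        out = classify_cells(cells, intensity_thresholds={"PanCK": 5.0})
        assert list(out["cell_class"]) == ["Tumor", "Other"]

    def test_missing_marker_input_rejected(self):
        with pytest.raises(KeyError, match="CD3"):
            classify_cells(pd.DataFrame({"prob_PanCK": [0.1], "prob_CD45": [0.1]}))


class TestNeighborhoods:
    def test_counts_at_radius_boundary(self):
        """T cells at 30, 49, 51 from the focal tumor: two inside 50 µm."""
        t = _table([
            (0, 0, "Tumor"),
            (30, 0, "T cell"), (0, 49, "T cell"), (51, 0, "T cell"),
        ])
        rec = neighborhood_stats(t, radius_um=50)
        assert rec.loc[0, "t_cell_count"] == 2
        assert np.isnan(rec.loc[0, "hladr_median_neighbors"])

    def test_exact_radius_included(self):
        t = _table([(0, 0, "Tumor"), (50, 0, "T cell"), (0, 50, "Tumor", 7.0)])
        rec = neighborhood_stats(t, radius_um=50)
        assert rec.loc[0, "t_cell_count"] == 1
        assert rec.loc[0, "hladr_median_neighbors"] == 7.0

    def test_focal_excluded_from_median(self):
        t = _table([(0, 0, "Tumor", 100.0), (10, 0, "Tumor", 2.0)])
        rec = neighborhood_stats(t, radius_um=50)
        assert rec.loc[0, "hladr_median_neighbors"] == 2.0
        inc = neighborhood_stats(t, radius_um=50, include_focal=True)
        assert inc.loc[0, "hladr_median_neighbors"] == pytest.approx(51.0)

    def test_matches_brute_force_on_random_fields(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(20, 300))
            t = pd.DataFrame({
                "x_um": rng.uniform(0, 300, n),
                "y_um": rng.uniform(0, 300, n),
                "cell_class": rng.choice(["Tumor", "T cell", "Other"], n),
                "HLA-DR": rng.uniform(0, 5, n),
            })
            if not (t["cell_class"] == "Tumor").any():
                continue
            rec = neighborhood_stats(t, radius_um=40)
            ref = brute_force_neighborhood(t, 40)
            assert len(rec) == len(ref)
            for (i, cnt, med), (_, row) in zip(ref, rec.iterrows()):
                assert row["tumor_cell"] == i
                assert row["t_cell_count"] == cnt
                if np.isnan(med):
                    assert np.isnan(row["hladr_median_neighbors"])
                else:
                    assert row["hladr_median_neighbors"] == pytest.approx(med)

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_stats(_table([(0, 0, "Tumor")]), radius_um=0)


class TestDistances:
    def test_pythagorean_example(self):
        t = _table([(0, 0, "T cell"), (3, 4, "Tumor"), (6, 8, "Tumor")])
        rec = t_to_tumor_distances(t)
        assert rec.loc[0, "d1_um"] == pytest.approx(5.0)
        assert rec.loc[0, "d2_um"] == pytest.approx(10.0)

    def test_coincident_cells(self):
        t = _table([(5, 5, "T cell"), (5, 5, "Tumor"), (9, 5, "Tumor")])
        rec = t_to_tumor_distances(t)
        assert rec.loc[0, "d1_um"] == 0.0

    def test_single_tumor_cell(self):
        t = _table([(0, 0, "T cell"), (1, 0, "Tumor")])
        rec = t_to_tumor_distances(t)
        assert rec.loc[0, "d1_um"] == pytest.approx(1.0)
        assert np.isnan(rec.loc[0, "d2_um"])

    def test_no_t_cells_empty(self):
        t = _table([(0, 0, "Tumor"), (1, 1, "Tumor")])
        assert len(t_to_tumor_distances(t)) == 0

    def test_no_tumor_rejected(self):
        with pytest.raises(ValueError):
            t_to_tumor_distances(_table([(0, 0, "T cell")]))

    def test_matches_brute_force_and_d1_le_d2(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(10, 400))
            t = pd.DataFrame({
                "x_um": rng.uniform(0, 500, n),
                "y_um": rng.uniform(0, 500, n),
                "cell_class": rng.choice(["Tumor", "T cell"], n, p=[0.6, 0.4]),
                "HLA-DR": 1.0,
            })
            if (t["cell_class"] == "Tumor").sum() < 2:
                continue
            rec = t_to_tumor_distances(t)
            assert (rec["d1_um"] <= rec["d2_um"] + 1e-12).all()
            for (i, d1, d2), (_, row) in zip(brute_force_distances(t), rec.iterrows()):
                assert row["t_cell"] == i
                assert row["d1_um"] == pytest.approx(d1, abs=1e-9)
                assert row["d2_um"] == pytest.approx(d2, abs=1e-9)


class TestHladrTcellCorrelation:
    def test_perfectly_ordered_records(self):
        rec = pd.DataFrame({
            "hladr_median_neighbors": [1.0, 2.0, 3.0, 4.0, 5.0],
            "t_cell_count": [0, 1, 2, 3, 4],
        })
        out = correlate_hladr_tcells(rec, aggregation="per_neighborhood")
        assert out["rho"] == pytest.approx(1.0)

    def test_null_gradient_centered_at_zero(self):
        """Without a planted HLA-DR/T coupling, per-sample rho is near zero."""
        rhos = []
        for seed in range(8):
            cfg = SpatialConfig(seed=seed, hladr_gradient=0.0,
                                n_samples_per_group={"A": 10, "B": 10},
                                attraction_scale_by_group={"A": 30.0, "B": 30.0})
            cells, _ = generate_spatial_cohort(cfg)
            cells = classify_cells(cells)
            nbs = []
            for sid, sub in cells.groupby("sample_id"):
                nb = neighborhood_stats(sub.reset_index(drop=True))
                nb.insert(0, "sample_id", sid)
                nbs.append(nb)
            out = correlate_hladr_tcells(pd.concat(nbs, ignore_index=True))
            rhos.append(out["rho"])
        assert abs(np.mean(rhos)) < 0.25

    def test_too_few_units_rejected(self):
        rec = pd.DataFrame({"hladr_median_neighbors": [1.0, 2.0],
                            "t_cell_count": [0, 1]})
        with pytest.raises(ValueError):
            correlate_hladr_tcells(rec, aggregation="per_neighborhood")


class TestDistanceGroups:
    def test_identical_groups_p_one(self):
        rec = pd.DataFrame({"t_cell": [0], "d1_um": [5.0], "d2_um": [7.0]})
        by_sample = {f"A{i}": rec for i in range(3)} | {f"B{i}": rec for i in range(3)}
        groups = pd.Series({s: s[0] for s in by_sample})
        res = compare_distance_groups(by_sample, groups)
        assert res.p_d1 == pytest.approx(1.0)

    def test_generator_contrast_detected(self, spatial_cohort):
        """15 µm vs 60 µm attraction: the tight group has shorter d1."""
        cells, truth = spatial_cohort
        cells = classify_cells(cells)
        by_sample = {
            sid: t_to_tumor_distances(sub.reset_index(drop=True))
            for sid, sub in cells.groupby("sample_id")
        }
        res = compare_distance_groups(by_sample, truth.sample_table["group"])
        assert res.direction == "LPS"
        assert res.p_d1 < 0.05

    def test_empty_sample_excluded(self):
        rec = pd.DataFrame({"t_cell": [0], "d1_um": [5.0], "d2_um": [7.0]})
        empty = pd.DataFrame(columns=["t_cell", "d1_um", "d2_um"])
        by_sample = {"A1": rec, "A2": rec, "A3": empty,
                     "B1": rec, "B2": rec}
        groups = pd.Series({s: s[0] for s in by_sample})
        res = compare_distance_groups(by_sample, groups)
        assert "A3" not in set(res.per_sample["sample_id"])
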