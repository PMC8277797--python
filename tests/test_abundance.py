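"""Abundance tables, Spearman/BH/Mann-Whitney statistics, dendrograms."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from phenospace import (
    benjamini_hochberg,
    compare_groups,
    compute_abundance,
    correlate_features,
    correlation_dendrogram,
    median_marker_by_group,
    spearman_rho_p,
)
from phenospace.containers import AbundanceTable, AnnotationResult

from conftest import make_expression


def _annotation(sample_id, cell_type):
    n = len(sample_id)
    return AnnotationResult(
        cluster_id=pd.Series(np.zeros(n, dtype=int)),
        cell_type=pd.Series(cell_type),
        cluster_profiles=pd.DataFrame(),
        sample_id=pd.Series(sample_id),
    )


class TestAbundance:
    def test_simple_percentage(self):
        ann = _annotation(["s1"] * 100, ["ECC"] * 50 + ["Other"] * 50)
        table = compute_abundance(ann)
        assert table.percentages.loc["s1", "ECC"] == 50.0

    def test_rows_sum_to_100(self, phenotyped_cohort):
        data, result, _, _ = phenotyped_cohort
        ann = _annotation(result.sample_id, result.cell_type)
        table = compute_abundance(ann)
        np.testing.assert_allclose(table.percentages.sum(axis=1), 100.0, atol=1e-9)

    def test_matches_generator_truth(self, phenotyped_cohort):
        """Estimated composition within 3 percentage points (MAE) of truth."""
        data, result, _, truth = phenotyped_cohort
        ann = _annotation(result.sample_id, result.cell_type)
        est = compute_abundance(ann).percentages
        ref = (truth.composition * 100.0).reindex(index=est.index,
                                                  columns=est.columns).fillna(0.0)
        mae = (est - ref).abs().to_numpy().mean()
        assert mae <= 3.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            AbundanceTable(pd.DataFrame({"a": [120.0], "b": [-20.0]}, index=["s"]))


class TestSpearman:
    def test_rank_identical_vectors(self):
        rho, p = spearman_rho_p([1, 5, 9, 12], [2, 40, 41, 100])
        assert rho == pytest.approx(1.0)

    def test_equals_rank_then_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(5, 30)
            x, y = rng.normal(size=n), rng.normal(size=n)
            rho, _ = spearman_rho_p(x, y)
            rx, ry = rankdata(x), rankdata(y)
            ref = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(ref, abs=1e-12)

    def test_exact_small_sample_p(self):
        # n=3, perfect correlation: 2 of 3! = 6 pairings reach |rho| = 1
        rho, p = spearman_rho_p([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert rho == 1.0
        assert p == pytest.approx(2 / 6)

    def test_constant_vector_undefined(self):
        rho, p = spearman_rho_p([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)


class TestBenjaminiHochberg:
    def test_textbook_family(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_step_up_definition(self):
        """BH equals the step-up formula min_{j>=i} p(j)·m/j on random families."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = int(rng.integers(1, 11))
            p = rng.uniform(size=m)
            adj = benjamini_hochberg(p)
            order = np.argsort(p)
            ref = np.empty(m)
            running = 1.0
            for rank in range(m - 1, -1, -1):
                i = order[rank]
                running = min(running, p[i] * m / (rank + 1))
                ref[i] = running
            np.testing.assert_allclose(adj, ref, atol=1e-12)

    def test_nan_passthrough(self):
        adj = benjamini_hochberg(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(adj[1]) and not np.isnan(adj[0])


class TestMannWhitney:
    def test_identical_groups(self):
        frame = pd.DataFrame({"f": [1.0, 2, 3, 1, 2, 3]},
                             index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=frame.index)
        res = compare_groups(frame, groups)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_exact_disjoint_groups(self):
        """{1,2,3} vs {10,11,12}: U = 0, exact two-sided p = 2/20."""
        frame = pd.DataFrame({"f": [1.0, 2, 3, 10, 11, 12]},
                             index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=frame.index)
        res = compare_groups(frame, groups)
        assert res.loc[0, "U"] == 0.0
        assert res.loc[0, "p"] == pytest.approx(0.1)

    def test_power_under_location_shift(self):
        """2-pooled-SD shift, n = 20 vs 20 → significant in >= 90% of reps."""
        rng = np.random.default_rng(2)
        hits = 0
        reps = 40
        for _ in range(reps):
            frame = pd.DataFrame({
                "f": np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)])
            }, index=[f"s{i}" for i in range(40)])
            groups = pd.Series(["A"] * 20 + ["B"] * 20, index=frame.index)
            hits += compare_groups(frame, groups).loc[0, "p"] < 0.05
        assert hits >= 0.9 * reps

    def test_empty_group_is_named(self):
        frame = pd.DataFrame({"f": [1.0, 2.0]}, index=["s0", "s1"])
        groups = pd.Series(["A", "B"], index=frame.index)
        with pytest.raises(ValueError):
            compare_groups(frame, groups.map({"A": "A"}))  # B becomes NaN


class TestDendrogram:
    def _table(self, profiles, samples):
        frame = pd.DataFrame(profiles, index=samples)
        frame = frame.div(frame.sum(axis=1), axis=0) * 100
        return AbundanceTable(frame)

    def test_identical_profiles_merge_at_zero(self):
        table = self._table([[10, 20, 70], [10, 20, 70], [60, 30, 10]],
                            ["a", "b", "c"])
        res = correlation_dendrogram(table)
        assert res.rho.loc["a", "b"] == pytest.approx(1.0)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_zero_diagonal(self, phenotyped_cohort):
        _, result, _, truth = phenotyped_cohort
        ann = _annotation(result.sample_id, result.cell_type)
        res = correlation_dendrogram(compute_abundance(ann))
        rho = res.rho.to_numpy()
        np.testing.assert_allclose(rho, rho.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_permutation_invariant_partition(self):
        rng = np.random.default_rng(3)
        profiles = rng.uniform(1, 10, size=(6, 4))
        samples = [f"s{i}" for i in range(6)]
        t1 = self._table(profiles, samples)
        perm = rng.permutation(6)
        t2 = AbundanceTable(t1.percentages.iloc[perm])
        cut1 = correlation_dendrogram(t1).cut(2)
        cut2 = correlation_dendrogram(t2).cut(2).reindex(cut1.index)
        # same bipartition regardless of label numbering
        grp1 = {frozenset(cut1.index[cut1 == g]) for g in (1, 2)}
        grp2 = {frozenset(cut2.index[cut2 == g]) for g in (1, 2)}
        assert grp1 == grp2

    def test_constant_profile_imputed(self):
        table = self._table([[25, 25, 25, 25], [10, 20, 30, 40], [40, 30, 20, 10]],
                            ["flat", "up", "down"])
        res = correlation_dendrogram(table)
        assert np.isnan(res.rho.loc["flat", "up"])

    def test_newick_contains_all_leaves(self):
        table = self._table(np.random.default_rng(4).uniform(1, 5, (5, 3)),
                            [f"p{i}" for i in range(5)])
        res = correlation_dendrogram(table)
        assert res.newick.endswith(";")
        for s in table.samples:
            assert s in res.newick

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            correlation_dendrogram(self._table([[1, 2], [3, 4]], ["a", "b"]))


class TestCorrelateFeatures:
    def _tables(self, x, y, samples):
        a = pd.DataFrame({"x": x, "rest": 100 - np.asarray(x)}, index=samples)
        b = pd.DataFrame({"y": y, "rest": 100 - np.asarray(y)}, index=samples)
        return AbundanceTable(a), AbundanceTable(b)

    def test_bh_applied_across_family(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(12)]
        a, b = self._tables(rng.uniform(10, 90, 12), rng.uniform(10, 90, 12), samples)
        res = correlate_features(a, b)
        assert len(res) == 4  # 2 x 2 columns
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
        assert (res["p_adj"] <= 1.0 + 1e-12).all()

    def test_low_power_flagged(self):
        a, b = self._tables([10, 20, 30], [30, 20, 10], ["s1", "s2", "s3"])
        res = correlate_features(a, b)
        assert res["low_power"].all()
        assert res["p"].isna().all()

    def test_planted_correlation_estimated(self):
        """A strongly coupled pair of abundance columns is recovered."""
        rng = np.random.default_rng(6)
        z = rng.normal(size=40)
        x = 50 + 10 * z + rng.normal(0, 2, 40)
        y = 30 + 8 * z + rng.normal(0, 2, 40)
        samples = [f"s{i}" for i in range(40)]
        a, b = self._tables(x, y, samples)
        res = correlate_features(a, b)
        rho = res.set_index(["feature_a", "feature_b"]).loc[("x", "y"), "rho"]
        assert rho >= 0.7


class TestMedianMarkerByGroup:
    def test_planted_offset_detected(self):
        rng = np.random.default_rng(7)
        frames, sids, types = [], [], []
        groups = {}
        for g, offset in (("A", 2.0), ("B", 0.0)):
            for i in range(5):
                sid = f"{g}{i}"
                groups[sid] = g
                vals = rng.normal(offset, 0.3, size=(50, 1))
                frames.append(vals)
                sids += [sid] * 50
                types += ["Mesenchymal"] * 50
        data = make_expression(np.vstack(frames), ["HLA-DR"], sample_id=sids)
        medians, test = median_marker_by_group(
            data, pd.Series(types), "HLA-DR", "Mesenchymal",
            pd.Series(groups),
        )
        assert len(medians) == 10
        assert test.loc[0, "median_A"] > test.loc[0, "median_B"]
        assert test.loc[0, "p"] < 0.05

    def test_all_equal_gives_p_one(self):
        data = make_expression(np.ones((20, 1)), ["m"],
                               sample_id=[f"s{i % 4}" for i in range(20)])
        groups = pd.Series({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        medians, test = median_marker_by_group(
            data, pd.Series(["T"] * 20), "m", "T", groups)
        assert test.loc[0, "p"] == pytest.approx(1.0)

    def test_unknown_marker_rejected(self):
        data = make_expression(np.ones((4, 1)), ["m"])
        with pytest.raises(KeyError):
            median_marker_by_group(data, pd.Series(["T"] * 4), "nope", "T",
                                   pd.Series({"s1": "A"}))
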