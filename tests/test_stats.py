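"""Profiles, overrepresentation testing, detection sets, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from bloodsrna import SimConfig, preprocess, simulate, stats
from bloodsrna.errors import StatisticsError, VocabularyError


class TestComponentProfile:
    def test_single_feature_is_whole_profile(self, build_count_matrix):
        m = build_count_matrix([[1e6]], ["plasma"], units="RPM")
        out = stats.component_profile(m)
        assert out["feature"].tolist() == ["f0"]
        assert out["proportion"].tolist() == [1.0]

    def test_minor_features_pool_into_others(self, build_count_matrix):
        props = [0.5, 0.4, 0.06, 0.03, 0.01]
        m = build_count_matrix(np.array(props)[:, None] * 1e6, ["plasma"], units="RPM")
        out = stats.component_profile(m)
        named = out[out["feature"] != "others"]
        assert named["proportion"].tolist() == pytest.approx([0.5, 0.4, 0.06, 0.03])
        assert out[out["feature"] == "others"]["proportion"].iloc[0] == pytest.approx(0.01)

    def test_rows_sum_to_one_per_component(self, small_counts):
        rpm = preprocess.rpm_normalize(small_counts)
        out = stats.component_profile(rpm)
        sums = out.groupby("component")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestClassProfile:
    def test_single_class_gets_everything(self, build_count_matrix):
        m = build_count_matrix(
            [[4e5], [6e5]], ["plasma"], units="RPM", classes=["miRNA", "miRNA"]
        )
        out = stats.class_profile(m)
        assert out.loc["plasma", "miRNA"] == pytest.approx(1.0)

    def test_constant_composition(self, build_count_matrix):
        m = build_count_matrix(
            [[8e5, 8e5], [2e5, 2e5]],
            ["plasma", "plasma"],
            units="RPM",
            classes=["miRNA", "tRNA"],
        )
        out = stats.class_profile(m)
        assert out.loc["plasma", "miRNA"] == pytest.approx(0.8)
        assert out.loc["plasma", "tRNA"] == pytest.approx(0.2)

    def test_sums_within_sample_before_averaging(self, build_count_matrix):
        """With unequal per-sample totals (as after feature filtering), the
        stated order (sum per sample, then mean) differs from averaging
        per-sample class fractions; the implementation must follow the
        former."""
        m = build_count_matrix(
            [[800000.0, 100000.0], [100000.0, 100000.0]],
            ["plasma", "plasma"],
            units="RPM",
            classes=["miRNA", "tRNA"],
        )
        out = stats.class_profile(m)
        sum_then_mean = np.array([450000.0, 100000.0]) / 550000.0
        mean_of_fractions = np.mean([[8 / 9, 1 / 9], [0.5, 0.5]], axis=0)
        np.testing.assert_allclose(out.loc["plasma"], sum_then_mean)
        assert not np.allclose(out.loc["plasma"], mean_of_fractions)

    def test_unmapped_feature_is_vocabulary_error(self, build_count_matrix):
        m = build_count_matrix([[1e6]], ["plasma"], units="RPM")
        with pytest.raises(VocabularyError):
            stats.class_profile(m)


def exact_rank_sum_p(group: np.ndarray, rest: np.ndarray) -> float:
    """Exact two-sided permutation p-value of the rank-sum statistic."""
    pooled = np.concatenate([group, rest])
    ranks = rankdata(pooled)
    n1 = len(group)
    w_obs = ranks[:n1].sum()
    ws = np.array(
        [ranks[list(idx)].sum() for idx in itertools.combinations(range(len(pooled)), n1)]
    )
    mu = ws.mean()
    return float(np.mean(np.abs(ws - mu) >= np.abs(w_obs - mu) - 1e-9))


class TestWilcoxon:
    def test_matches_exact_permutation_oracle_small_n(self):
        rng = np.random.default_rng(2)
        worst = 0.0
        for n1, n2 in [(4, 4), (5, 7), (8, 8), (3, 8)]:
            for _ in range(5):
                g = rng.normal(0.0, 1.0, n1)
                r = rng.normal(0.5, 1.0, n2)
                p_asym = stats.wilcoxon_rank_sum(g, r)
                p_exact = exact_rank_sum_p(g, r)
                worst = max(worst, abs(p_asym - p_exact))
        assert worst < 0.05

    def test_identical_distributions_give_p_near_one(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        assert stats.wilcoxon_rank_sum(vals, vals) == pytest.approx(1.0)
        assert exact_rank_sum_p(vals, vals) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def marker_cohort():
    cfg = SimConfig(
        n_donors=10,
        components=("monocytes", "neutrophils", "B cells", "NK cells"),
        library_size=100_000,
        purity_fail_rate=0.0,
        outlier_rate=0.0,
        missing_content_rate=0.0,
        dropout=0,
        seed=31,
    )
    donors, samples, truth = simulate.simulate_cohort(cfg)
    records = simulate.simulate_counts(donors, samples, truth, cfg)
    cm = simulate.cohort_count_matrix(samples, records)
    rpm = preprocess.rpm_normalize(cm)
    return rpm, truth


class TestOverrepresented:
    def test_constant_feature_never_passes(self, build_count_matrix):
        m = build_count_matrix(
            np.full((2, 8), 5e5), ["A"] * 4 + ["B"] * 4, units="RPM"
        )
        out = stats.overrepresented_srnas(preprocess.log_transform(m), rpm_matrix=m)
        assert not out["passes"].any()
        assert (out["log2_fold_change"] == 0).all()

    def test_exclusive_markers_pass_only_their_component(self, marker_cohort):
        rpm, truth = marker_cohort
        log = preprocess.log_transform(rpm)
        out = stats.overrepresented_srnas(log, rpm_matrix=rpm)
        passing = out[out["passes"]]
        markers = truth.marker_map.dropna()
        for feature, comp in markers.items():
            hits = set(passing.loc[passing["feature"] == feature, "component"])
            assert comp in hits, f"marker {feature} missed in {comp}"
            assert hits == {comp}, f"marker {feature} also called in {hits - {comp}}"

    def test_bh_adjustment_monotone_in_raw_p(self, marker_cohort):
        rpm, _ = marker_cohort
        out = stats.overrepresented_srnas(preprocess.log_transform(rpm), rpm_matrix=rpm)
        for _, grp in out.groupby("component"):
            ordered = grp.sort_values("p_value")["adj_p_value"].to_numpy()
            assert (np.diff(ordered) >= -1e-12).all()

    def test_agrees_with_scanpy_rank_genes_groups(self, marker_cohort):
        """Independent route: the same one-vs-rest Wilcoxon scan via scanpy
        yields matching p-values (both use the tie-corrected normal
        approximation; small differences come from the continuity
        correction)."""
        anndata = pytest.importorskip("anndata")
        sc = pytest.importorskip("scanpy")
        rpm, _ = marker_cohort
        log = preprocess.log_transform(rpm)
        adata = anndata.AnnData(
            X=log.values.to_numpy().T,
            obs=pd.DataFrame({"component": log.components.to_numpy()}, index=list(log.samples)),
            var=pd.DataFrame(index=list(log.features)),
        )
        sc.tl.rank_genes_groups(
            adata, "component", method="wilcoxon", tie_correct=True, corr_method="benjamini-hochberg"
        )
        mine = stats.overrepresented_srnas(log, rpm_matrix=rpm)
        comp = "monocytes"
        names = adata.uns["rank_genes_groups"]["names"][comp]
        pvals = adata.uns["rank_genes_groups"]["pvals"][comp]
        theirs = pd.Series(pvals, index=names)
        ours = mine[mine["component"] == comp].set_index("feature")["p_value"]
        diff = (ours - theirs.reindex(ours.index)).abs()
        assert diff.max() < 0.05
        # concordant significance calls (ranking among near-zero ties is arbitrary)
        assert set(ours.index[ours < 1e-6]) <= set(theirs.index[theirs < 1e-3])
        assert set(theirs.index[theirs < 1e-6]) <= set(ours.index[ours < 1e-3])

    def test_too_small_group_is_statistics_error(self, build_count_matrix):
        m = build_count_matrix([[1e6] * 3], ["A", "B", "B"], units="log2RPM")
        with pytest.raises(StatisticsError):
            stats.overrepresented_srnas(m)


class TestDetectionSet:
    def test_matches_brute_force(self, build_count_matrix):
        rng = np.random.default_rng(9)
        values = rng.integers(0, 3, size=(12, 9)).astype(float)
        comps = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        m = build_count_matrix(values, comps)
        sets = stats.detection_set(m)
        for comp in "ABC":
            ids = [s for s, c in zip(m.samples, comps) if c == comp]
            expected = {
                f for f in m.features if (m.values.loc[f, ids] > 0).all()
            }
            assert sets[comp] == expected

    def test_zero_in_one_sample_excludes(self, build_count_matrix):
        m = build_count_matrix([[5, 0, 2]], ["A", "A", "A"])
        assert stats.detection_set(m)["A"] == set()


class TestWholeBloodCorrelation:
    def wb_matrix(self, build, values, donors):
        return build(
            values,
            ["whole_blood"] * len(donors),
            units="RPM",
            donors=donors,
        )

    def test_proportional_expression_gives_r_one(self, build_count_matrix):
        donors = [f"d{i}" for i in range(5)]
        counts = pd.DataFrame({"neutrophils": [1.0, 2, 3, 4, 5]}, index=donors)
        m = self.wb_matrix(build_count_matrix, [[10.0, 20, 30, 40, 50]], donors)
        m.sample_meta["is_whole_blood"] = True
        r = stats.whole_blood_correlation(m, counts)
        assert r.loc["f0", "neutrophils"] == pytest.approx(1.0)

    def test_constant_expression_is_undefined(self, build_count_matrix):
        donors = [f"d{i}" for i in range(4)]
        counts = pd.DataFrame({"neutrophils": [1.0, 2, 3, 4]}, index=donors)
        m = self.wb_matrix(build_count_matrix, [[7.0, 7, 7, 7]], donors)
        m.sample_meta["is_whole_blood"] = True
        r = stats.whole_blood_correlation(m, counts)
        assert np.isnan(r.loc["f0", "neutrophils"])

    def test_independent_counts_give_near_zero_mean_abs_r(self, build_count_matrix):
        """Permutation simulation: with shuffled counts, |r| concentrates
        near its null expectation sqrt(2/(pi*n))."""
        rng = np.random.default_rng(12)
        n = 50
        donors = [f"d{i}" for i in range(n)]
        expr = rng.uniform(10, 100, size=(1, n))
        m = self.wb_matrix(build_count_matrix, expr, donors)
        m.sample_meta["is_whole_blood"] = True
        base = rng.uniform(100, 1000, n)
        rs = []
        for _ in range(100):
            counts = pd.DataFrame({"x": rng.permutation(base)}, index=donors)
            rs.append(abs(stats.whole_blood_correlation(m, counts).iloc[0, 0]))
        assert np.mean(rs) < 0.2

    def test_fewer_than_three_donors_is_error(self, build_count_matrix):
        donors = ["d0", "d1"]
        counts = pd.DataFrame({"x": [1.0, 2.0]}, index=donors)
        m = self.wb_matrix(build_count_matrix, [[1.0, 2.0]], donors)
        with pytest.raises(StatisticsError):
            stats.whole_blood_correlation(m, counts)


class TestMeanExpressionCorrelation:
    def test_identical_and_affine_matrices_give_r_one(self, build_count_matrix):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 1000, size=(6, 4))
        a = build_count_matrix(vals, ["A", "A", "B", "B"], units="RPM")
        b = build_count_matrix(vals, ["A", "A", "B", "B"], units="RPM")
        r = stats.mean_expression_correlation(a, b)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)
        # positive affine transform on the log-mean scale preserves r
        c = build_count_matrix(vals**1.5, ["A", "A", "B", "B"], units="RPM")
        r2 = stats.mean_expression_correlation(a, c)
        assert (r2 > 0.99).all()

    def test_anti_ordered_means_give_minus_one(self, build_count_matrix):
        # log2(RPM+1) means are (1, 2, 3) vs (3, 2, 1): exactly anti-linear
        a = build_count_matrix([[1.0], [3.0], [7.0]], ["A"], units="RPM")
        b = build_count_matrix([[7.0], [3.0], [1.0]], ["A"], units="RPM")
        r = stats.mean_expression_correlation(a, b)
        assert r["A"] == pytest.approx(-1.0, abs=1e-12)

    def test_too_few_shared_features_is_error(self, build_count_matrix):
        a = build_count_matrix([[1.0], [2.0]], ["A"], units="RPM")
        b = build_count_matrix([[1.0], [2.0]], ["A"], units="RPM")
        with pytest.raises(StatisticsError):
            stats.mean_expression_correlation(a, b)
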