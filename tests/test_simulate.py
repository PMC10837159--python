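"""Synthetic-cohort generator: determinism, planted defects, ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bloodsrna import SimConfig, simulate
from bloodsrna.errors import ConfigurationError, DataConsistencyError
from bloodsrna.simulate import SyntheticTruth
from bloodsrna.types import DonorRecord


def tiny_config(**kw):
    defaults = dict(n_donors=3, library_size=20_000, seed=5)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_donors", 1),
            ("library_size", 0),
            ("marker_fraction", 1.5),
            ("purity_fail_rate", -0.1),
            ("outlier_rate", 2.0),
            ("noise_dispersion", -1.0),
            ("dropout", -3),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            tiny_config(**{field: value})

    def test_duplicate_components_rejected(self):
        with pytest.raises(ConfigurationError, match="components"):
            tiny_config(components=("plasma", "plasma"))


class TestCohort:
    def test_seeded_determinism_end_to_end(self):
        cfg = tiny_config()
        runs = []
        for _ in range(2):
            donors, samples, truth = simulate.simulate_cohort(cfg)
            records = simulate.simulate_counts(donors, samples, truth, cfg)
            wb = simulate.simulate_whole_blood(donors, truth, cfg)
            runs.append((donors, samples, truth, records, wb))
        d1, s1, t1, r1, w1 = runs[0]
        d2, s2, t2, r2, w2 = runs[1]
        assert [dataclasses.asdict(x) for x in d1] == [dataclasses.asdict(x) for x in d2]
        assert [dataclasses.asdict(x) for x in s1] == [dataclasses.asdict(x) for x in s2]
        pd.testing.assert_frame_equal(t1.component_profiles, t2.component_profiles)
        pd.testing.assert_frame_equal(t1.true_contributions, t2.true_contributions)
        assert [(x.seq_id, x.counts) for x in r1] == [(x.seq_id, x.counts) for x in r2]
        pd.testing.assert_frame_equal(w1.values, w2.values)

    def test_zero_purity_fail_rate_means_all_pure(self):
        _, samples, _ = simulate.simulate_cohort(tiny_config(purity_fail_rate=0.0))
        assert all(s.is_plasma or s.purity_pct > 70 for s in samples)

    def test_full_scale_cohort_has_539_fractions(self):
        cfg = SimConfig(n_donors=52, dropout=33, seed=1)
        _, samples, _ = simulate.simulate_cohort(cfg)
        assert len(samples) == 539
        assert len({s.sample_id for s in samples}) == 539

    def test_zero_outlier_rate_means_no_outliers(self):
        _, _, truth = simulate.simulate_cohort(tiny_config(outlier_rate=0.0))
        assert truth.outlier_samples == set()

    def test_dropout_hits_only_deprioritized_components(self):
        cfg = tiny_config(n_donors=10, dropout=8)
        _, samples, _ = simulate.simulate_cohort(cfg)
        per_comp = pd.Series([s.component for s in samples]).value_counts()
        for comp in set(cfg.components) - set(simulate.DEPRIORITIZED_COMPONENTS):
            assert per_comp[comp] == 10

    def test_missing_content_rate_rounds_to_sample_count(self):
        cfg = tiny_config(missing_content_rate=0.1)
        _, samples, _ = simulate.simulate_cohort(cfg)
        n_missing = sum(s.srna_conc is None for s in samples)
        assert n_missing == round(0.1 * len(samples))

    def test_truth_invariants(self, small_cohort):
        _, _, truth, _ = small_cohort
        np.testing.assert_allclose(truth.component_profiles.sum(axis=1), 1.0, atol=1e-9)
        sums = truth.true_contributions.sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums[sums > 0], 1.0, atol=1e-9)


class TestCounts:
    def test_counts_sum_to_library_size(self, small_cohort, small_counts, small_config):
        totals = small_counts.values.sum(axis=0)
        assert (totals == small_config.library_size).all()

    def test_noise_free_limit_matches_profile(self):
        cfg = tiny_config(exact_counts=True, split_fraction=0.0)
        donors, samples, truth = simulate.simulate_cohort(cfg)
        records = simulate.simulate_counts(donors, samples, truth, cfg)
        cm = simulate.cohort_count_matrix(samples, records)
        s = samples[0]
        profile = truth.component_profiles.loc[s.component]
        observed = cm.values[s.sample_id].reindex(profile.index) / cfg.library_size
        np.testing.assert_allclose(observed, profile, atol=1e-12)

    def test_marker_features_absent_from_other_components(self, small_cohort, small_counts):
        _, samples, truth, _ = small_cohort
        markers = truth.marker_map.dropna()
        comp_of = {s.sample_id: s.component for s in samples}
        for feature, comp in markers.items():
            other = [s for s in small_counts.samples if comp_of[s] != comp]
            assert small_counts.values.loc[feature, other].sum() == 0

    def test_unknown_component_is_consistency_error(self, small_cohort, small_config):
        donors, samples, truth, _ = small_cohort
        bad = dataclasses.replace(samples[1], component="spleen")
        with pytest.raises(DataConsistencyError, match="spleen"):
            simulate.simulate_counts(donors, [bad], truth, small_config)


def _manual_truth(profiles: pd.DataFrame) -> SyntheticTruth:
    features = profiles.columns
    contrib = pd.DataFrame(
        np.full((len(features), len(profiles)), 1.0 / len(profiles)),
        index=features,
        columns=profiles.index,
    )
    return SyntheticTruth(
        component_profiles=profiles,
        content_per_cell={c: 0.05 for c in profiles.index},
        true_contributions=contrib,
        outlier_samples=set(),
        marker_map=pd.Series([None] * len(features), index=features, dtype=object),
        feature_catalog=pd.DataFrame(
            {"rna_class": "miRNA", "parent_gene": list(features), "start_pos": None},
            index=features,
        ),
    )


class TestWholeBlood:
    def donor(self, counts):
        return DonorRecord("D1", "healthy", 60.0, "female", counts)

    def test_single_component_reproduces_its_profile(self):
        profiles = pd.DataFrame([[0.7, 0.3]], index=["A"], columns=["f1", "f2"])
        cfg = SimConfig(n_donors=2, components=("A",), exact_counts=True, seed=1)
        wb = simulate.simulate_whole_blood(
            [self.donor({"A": 100.0})], _manual_truth(profiles), cfg
        )
        np.testing.assert_allclose(wb.values.iloc[:, 0] / cfg.library_size, [0.7, 0.3])

    def test_equal_weights_average_disjoint_profiles(self):
        profiles = pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0]], index=["A", "B"], columns=["f1", "f2"]
        )
        cfg = SimConfig(n_donors=2, components=("A", "B"), exact_counts=True, seed=1)
        wb = simulate.simulate_whole_blood(
            [self.donor({"A": 100.0, "B": 100.0})], _manual_truth(profiles), cfg
        )
        np.testing.assert_allclose(wb.values.iloc[:, 0] / cfg.library_size, [0.5, 0.5])

    def test_alpha_ratios_1_2_3_give_sixths(self):
        """Three components on disjoint single markers with content weights
        1:2:3 must mix to proportions 1/6, 2/6, 3/6."""
        profiles = pd.DataFrame(
            np.eye(3), index=["A", "B", "C"], columns=["f1", "f2", "f3"]
        )
        cfg = SimConfig(n_donors=2, components=("A", "B", "C"), exact_counts=True, seed=1)
        # expected_alpha = 0.05 * blood_count, so counts 20:40:60 give alpha 1:2:3
        wb = simulate.simulate_whole_blood(
            [self.donor({"A": 20.0, "B": 40.0, "C": 60.0})], _manual_truth(profiles), cfg
        )
        np.testing.assert_allclose(
            wb.values.iloc[:, 0] / cfg.library_size, [1 / 6, 2 / 6, 3 / 6]
        )

    def test_missing_blood_count_is_error(self):
        profiles = pd.DataFrame([[1.0]], index=["A"], columns=["f1"])
        cfg = SimConfig(n_donors=2, components=("A",), seed=1)
        with pytest.raises(DataConsistencyError):
            simulate.simulate_whole_blood([self.donor({})], _manual_truth(profiles), cfg)


class TestSubpopulationCounts:
    @pytest.mark.parametrize(
        "rel, parent, expected",
        [(0.2, 1000.0, 200.0), (1.0, 860.0, 860.0), (0.35, 860.0, 301.0)],
    )
    def test_product(self, rel, parent, expected):
        assert simulate.absolute_subpopulation_counts(rel, parent) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ConfigurationError):
            simulate.absolute_subpopulation_counts(1.2, 100.0)
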