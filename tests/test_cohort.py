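"""Cohort validation, cluster-level group statistics, and performer
stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ran_mvpa import (
    READING_TESTS,
    StratificationConfig,
    cluster_mean_by_group,
    group_difference_test,
    performer_classification,
    stratify_performers,
    validate_cohort,
    voxel_features,
)
from ran_mvpa.cohort import compare_groups_by_visit


def simple_cohort():
    rows = []
    for s, g in [("p1", "survivor"), ("p2", "survivor"),
                 ("c1", "control"), ("c2", "control")]:
        for v in ("TP1", "TP2"):
            rows.append({"subject": s, "group": g, "visit": v})
    return pd.DataFrame(rows)


class TestValidation:
    def test_nested_participation_accepted(self):
        df = simple_cohort()
        assert validate_cohort(df) is df

    def test_gap_in_visits_rejected(self):
        df = simple_cohort()
        df.loc[len(df)] = {"subject": "p9", "group": "survivor", "visit": "TP3"}
        with pytest.raises(ValueError, match="nested"):
            validate_cohort(df)

    def test_duplicate_subject_visit_rejected(self):
        df = pd.concat([simple_cohort()] * 2, ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            validate_cohort(df)

    def test_unknown_group_rejected(self):
        df = simple_cohort()
        df.loc[0, "group"] = "patient"
        with pytest.raises(ValueError, match="group"):
            validate_cohort(df)


class TestClusterMeans:
    def test_constant_maps_recovered(self):
        cohort = simple_cohort()
        maps = {}
        consts = {}
        for i, r in enumerate(cohort.itertuples(index=False)):
            consts[(r.subject, r.visit)] = float(i)
            maps[(r.subject, r.visit)] = np.full((4, 4, 4), float(i))
        vox = np.array([[0, 0, 0], [1, 2, 3], [3, 3, 3]])
        by_group = cluster_mean_by_group(maps, vox, cohort, "TP1")
        assert sorted(by_group["survivor"].tolist()) == sorted(
            consts[(s, "TP1")] for s in ("p1", "p2"))

    def test_single_voxel_cluster(self, rng):
        cohort = simple_cohort()
        maps = {(r.subject, r.visit): rng.normal(size=(4, 4, 4))
                for r in cohort.itertuples(index=False)}
        vox = np.array([[2, 1, 3]])
        by_group = cluster_mean_by_group(maps, vox, cohort, "TP2")
        got = np.sort(np.concatenate([by_group["survivor"], by_group["control"]]))
        want = np.sort([maps[(r.subject, "TP2")][2, 1, 3]
                        for r in cohort.itertuples(index=False) if r.visit == "TP2"])
        np.testing.assert_allclose(got, want)

    def test_matches_loop_oracle(self, rng):
        cohort = simple_cohort()
        maps = {(r.subject, r.visit): rng.normal(size=(5, 5, 5))
                for r in cohort.itertuples(index=False)}
        vox = np.argwhere(rng.random((5, 5, 5)) < 0.25)
        by_group = cluster_mean_by_group(maps, vox, cohort, "TP1")
        for subject, group in [("p1", "survivor"), ("c1", "control")]:
            m = maps[(subject, "TP1")]
            total = 0.0
            for i, j, k in vox:
                total += m[i, j, k]
            assert np.isclose(total / len(vox), by_group[group]).any()

    def test_missing_map_rejected(self):
        cohort = simple_cohort()
        with pytest.raises(KeyError, match="p1"):
            cluster_mean_by_group({}, np.array([[0, 0, 0]]), cohort, "TP1")


class TestGroupDifference:
    def test_identical_samples_give_p_one(self):
        assert group_difference_test([1.0, 1.0, 2.0], [1.0, 1.0, 2.0]) == \
            pytest.approx(1.0)

    def test_constant_equal_groups_give_p_one(self):
        assert group_difference_test([3.0, 3.0], [3.0, 3.0]) == 1.0

    def test_matches_welch_from_scipy(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(loc=0.5, size=12)
        assert group_difference_test(a, b) == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue)

    def test_group_order_invariance(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=14)
        assert group_difference_test(a, b) == group_difference_test(b, a)

    def test_separated_groups_detected(self, rng):
        ps = []
        for _ in range(200):
            a = rng.normal(loc=2.0, size=21)  # 2-SD mean separation
            b = rng.normal(loc=0.0, size=21)
            ps.append(group_difference_test(a, b))
        assert np.median(ps) < 0.01

    def test_pooled_variance_option(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=9)
        assert group_difference_test(a, b, equal_var=True) == pytest.approx(
            stats.ttest_ind(a, b, equal_var=True).pvalue)


class TestStratification:
    def make_scored_cohort(self):
        df = simple_cohort()
        scores = {
            ("p1", "TP1"): 100.0,  # boundary: exactly 100 is high
            ("p1", "TP2"): 85.0,
            ("p2", "TP1"): 120.0,
            ("p2", "TP2"): np.nan,
        }
        df["word_attack"] = [
            scores.get((r.subject, r.visit), 90.0)
            for r in df.itertuples(index=False)
        ]
        return df

    def test_cutoff_is_inclusive_for_high(self):
        strat = stratify_performers(self.make_scored_cohort(), "word_attack")
        lut = strat.set_index(["subject", "visit"])["performer"]
        assert lut[("p1", "TP1")] == "high"
        assert lut[("p1", "TP2")] == "low"

    def test_missing_scores_dropped(self):
        strat = stratify_performers(self.make_scored_cohort(), "word_attack")
        assert ("p2", "TP2") not in strat.set_index(["subject", "visit"]).index
        assert len(strat) == 3  # survivor visits only, one missing

    def test_controls_never_included(self):
        strat = stratify_performers(self.make_scored_cohort(), "word_attack")
        assert set(strat["subject"]) <= {"p1", "p2"}

    def test_unknown_test_rejected(self):
        with pytest.raises(KeyError, match="unknown reading test"):
            stratify_performers(self.make_scored_cohort(), "arithmetic")

    def test_all_missing_warns_and_returns_empty(self):
        df = self.make_scored_cohort()
        df["word_attack"] = np.nan
        with pytest.warns(UserWarning, match="non-missing"):
            strat = stratify_performers(df, "word_attack")
        assert strat.empty

    def test_standard_scores_split_near_even(self, rng):
        fracs = []
        for _ in range(200):
            df = simple_cohort()
            df["sound_awareness"] = rng.normal(100, 15, size=len(df))
            strat = stratify_performers(df, "sound_awareness")
            fracs.append((strat["performer"] == "high").mean())
        assert abs(np.mean(fracs) - 0.5) < 0.05

    def test_custom_cutoff(self):
        strat = stratify_performers(self.make_scored_cohort(), "word_attack",
                                    StratificationConfig(cutoff=90.0))
        assert (strat["performer"] == "high").sum() == 2


class TestPerformerClassification:
    def test_linked_scores_are_decodable(self, small_dataset):
        parc, cohort, maps = small_dataset
        planted = [16, 17, 18, 19]
        vf = voxel_features(maps, parc, planted, cohort)
        res = performer_classification(vf, cohort, "sound_awareness")
        assert res.positive_class == "high"
        assert res.n_pos + res.n_neg <= (cohort["group"] == "survivor").sum()
        assert 0.0 <= res.accuracy <= 1.0

    def test_sample_count_bounded_by_survivor_visits(self, small_dataset):
        parc, cohort, maps = small_dataset
        vf = voxel_features(maps, parc, [16], cohort)
        n_surv_visits = int((cohort["group"] == "survivor").sum())
        for test in READING_TESTS:
            res = performer_classification(vf, cohort, test)
            assert res.n_pos + res.n_neg <= n_surv_visits


class TestCompareGroupsByVisit:
    def test_one_result_per_visit_with_sizes(self, small_dataset):
        parc, cohort, maps = small_dataset
        vox = parc.voxels_of([16, 17, 18, 19])
        results = compare_groups_by_visit(maps, vox, cohort,
                                          ("TP1", "TP2", "TP3"))
        assert [r.visit for r in results] == ["TP1", "TP2", "TP3"]
        assert results[0].n_survivor == 12 and results[2].n_survivor == 6
        for r in results:
            assert 0.0 <= r.p_value <= 1.0
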