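"""Parcellation handling, region averaging, and voxel feature extraction."""

import numpy as np
import pandas as pd
import pytest

from ran_mvpa import (
    Parcellation,
    contralateral_homolog,
    region_means,
    stack_region_features,
    voxel_features,
)


def loop_region_means(data, parcellation):
    """Brute-force oracle: explicit sum/count loop over every voxel."""
    sums = {lab: 0.0 for lab in parcellation.region_labels}
    counts = {lab: 0 for lab in parcellation.region_labels}
    ni, nj, nk = parcellation.grid_shape
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                lab = int(parcellation.labels[i, j, k])
                if lab != 0:
                    sums[lab] += data[i, j, k]
                    counts[lab] += 1
    return {
        lab: (sums[lab] / counts[lab] if counts[lab] else np.nan)
        for lab in parcellation.region_labels
    }


def two_subject_cohort(visit="TP1"):
    return pd.DataFrame(
        {
            "subject": ["s1", "s2", "s3"],
            "group": ["survivor", "control", "survivor"],
            "visit": [visit] * 3,
        }
    )


class TestParcellationValidation:
    def test_tiny_fixture_is_valid(self, tiny_parcellation):
        assert tiny_parcellation.region_labels == [1, 2, 3, 4, 5]

    def test_orphan_volume_label_rejected(self, tiny_parcellation):
        labels = tiny_parcellation.labels.copy()
        labels[0, 0, 2] = 99
        with pytest.raises(ValueError, match="absent from the table"):
            Parcellation(labels=labels, table=tiny_parcellation.table)

    def test_asymmetric_homolog_rejected(self, tiny_parcellation):
        table = tiny_parcellation.table.copy()
        table.loc[table["label"] == 2, "homolog_label"] = 3
        with pytest.raises(ValueError, match="not symmetric"):
            Parcellation(labels=tiny_parcellation.labels, table=table)

    def test_same_hemisphere_homolog_rejected(self, tiny_parcellation):
        table = tiny_parcellation.table.copy()
        table.loc[table["label"] == 2, "hemisphere"] = "L"
        with pytest.raises(ValueError, match="same hemisphere"):
            Parcellation(labels=tiny_parcellation.labels, table=table)

    def test_voxels_of_is_lexicographic(self, tiny_parcellation):
        coords = tiny_parcellation.voxels_of([1, 2, 5])
        as_tuples = [tuple(c) for c in coords]
        assert as_tuples == sorted(as_tuples)


class TestRegionMeans:
    def test_constant_map(self, tiny_parcellation):
        means = region_means(np.full(tiny_parcellation.grid_shape, 2.5),
                             tiny_parcellation)
        assert np.allclose(means.to_numpy(), 2.5)

    def test_label_identity_map(self, tiny_parcellation):
        means = region_means(tiny_parcellation.labels.astype(float),
                             tiny_parcellation)
        assert np.allclose(means.to_numpy(), tiny_parcellation.region_labels)

    def test_matches_loop_oracle_on_random_map(self, tiny_parcellation, rng):
        data = rng.normal(size=tiny_parcellation.grid_shape)
        got = region_means(data, tiny_parcellation)
        expected = loop_region_means(data, tiny_parcellation)
        for lab in tiny_parcellation.region_labels:
            assert got[lab] == pytest.approx(expected[lab], abs=1e-12)

    def test_matches_loop_oracle_on_generated_parcellation(self, parcellation, rng):
        data = rng.normal(size=parcellation.grid_shape)
        got = region_means(data, parcellation)
        # vectorized check equivalent to the voxel loop
        for lab in parcellation.region_labels:
            mask = parcellation.labels == lab
            assert got[lab] == pytest.approx(data[mask].mean(), abs=1e-12)

    def test_traversal_order_invariance(self, tiny_parcellation, rng):
        data = rng.normal(size=tiny_parcellation.grid_shape)
        base = region_means(data, tiny_parcellation)
        flipped = Parcellation(
            labels=np.ascontiguousarray(tiny_parcellation.labels[::-1, :, :]),
            table=tiny_parcellation.table,
        )
        same = region_means(data[::-1, :, :], flipped)
        assert np.allclose(base.to_numpy(), same.to_numpy())

    def test_empty_region_is_missing_not_zero(self, tiny_parcellation):
        table = pd.concat(
            [tiny_parcellation.table,
             pd.DataFrame({"label": [9], "name": ["ghost"],
                           "hemisphere": ["midline"],
                           "homolog_label": pd.array([None], dtype="Int64")})],
            ignore_index=True,
        )
        parc = Parcellation(labels=tiny_parcellation.labels, table=table)
        with pytest.warns(UserWarning, match="zero voxels"):
            means = region_means(np.ones(parc.grid_shape), parc)
        assert np.isnan(means[9])
        assert means[1] == 1.0

    def test_grid_mismatch_rejected(self, tiny_parcellation):
        with pytest.raises(ValueError, match="grid"):
            region_means(np.zeros((2, 2, 2)), tiny_parcellation)


class TestFeatureMatrices:
    def make_maps(self, parc, rng, cohort):
        return {
            (r.subject, r.visit): rng.normal(size=parc.grid_shape)
            for r in cohort.itertuples(index=False)
        }

    def test_one_row_per_subject_visit(self, tiny_parcellation, rng):
        cohort = two_subject_cohort()
        maps = self.make_maps(tiny_parcellation, rng, cohort)
        rfm = stack_region_features(maps, tiny_parcellation, cohort)
        assert len(rfm.meta) == 3
        assert list(rfm.values.columns) == tiny_parcellation.region_labels

    def test_input_order_does_not_matter(self, tiny_parcellation, rng):
        cohort = two_subject_cohort()
        maps = self.make_maps(tiny_parcellation, rng, cohort)
        shuffled = dict(reversed(list(maps.items())))
        a = stack_region_features(maps, tiny_parcellation, cohort)
        b = stack_region_features(shuffled, tiny_parcellation, cohort)
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.meta, b.meta)

    def test_missing_map_names_the_subject_visit(self, tiny_parcellation, rng):
        cohort = two_subject_cohort()
        maps = self.make_maps(tiny_parcellation, rng, cohort)
        del maps[("s2", "TP1")]
        with pytest.raises(KeyError, match="s2"):
            stack_region_features(maps, tiny_parcellation, cohort)

    def test_voxel_feature_column_counts(self, tiny_parcellation, rng):
        cohort = two_subject_cohort()
        maps = self.make_maps(tiny_parcellation, rng, cohort)
        one = voxel_features(maps, tiny_parcellation, [1], cohort)
        assert one.values.shape == (3, 2)
        two = voxel_features(maps, tiny_parcellation, [1, 3], cohort)
        assert two.values.shape[1] == 4  # disjoint regions add up
        dup = voxel_features(maps, tiny_parcellation, [1, 1], cohort)
        assert dup.values.shape[1] == 2  # set semantics, no duplication

    def test_voxel_features_average_back_to_region_means(self, tiny_parcellation, rng):
        cohort = two_subject_cohort()
        maps = self.make_maps(tiny_parcellation, rng, cohort)
        rfm = stack_region_features(maps, tiny_parcellation, cohort)
        for lab in [1, 2, 3, 4, 5]:
            vf = voxel_features(maps, tiny_parcellation, [lab], cohort)
            np.testing.assert_allclose(
                vf.values.mean(axis=1),
                rfm.values[lab].to_numpy(),
                atol=1e-12,
            )

    def test_empty_region_set_rejected(self, tiny_parcellation, rng):
        cohort = two_subject_cohort()
        maps = self.make_maps(tiny_parcellation, rng, cohort)
        with pytest.raises(ValueError, match="nonempty"):
            voxel_features(maps, tiny_parcellation, [], cohort)


class TestContralateralHomolog:
    def test_mirrors_each_region(self, tiny_parcellation):
        assert contralateral_homolog({1}, tiny_parcellation) == {2}
        assert contralateral_homolog({2, 4}, tiny_parcellation) == {1, 3}

    def test_involution(self, tiny_parcellation):
        start = {1, 4}
        there = contralateral_homolog(start, tiny_parcellation)
        assert contralateral_homolog(there, tiny_parcellation) == start

    def test_midline_region_rejected(self, tiny_parcellation):
        with pytest.raises(ValueError, match="5"):
            contralateral_homolog({1, 5}, tiny_parcellation)

    def test_generated_right_set_maps_to_left_set(self, parcellation):
        right = set(
            int(x) for x in parcellation.table.loc[
                parcellation.table["hemisphere"] == "R", "label"
            ].iloc[:4]
        )
        left = contralateral_homolog(right, parcellation)
        hemis = parcellation.table.set_index("label").loc[sorted(left), "hemisphere"]
        assert len(left) == 4 and (hemis == "L").all()
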