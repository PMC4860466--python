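"""Analysis battery: profiles, Fisher z, geometry, stepwise DFA, outliers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bilexmap.dataset import NamingDataset
from bilexmap.stats import (
    CategoryGeometry,
    NameDistributionTable,
    _weighted_mean,
    _weighted_median,
    build_distribution_table,
    category_geometry,
    compare_group_correlations,
    fisher_z,
    fisher_z_inverse,
    indirect_direct_ratio,
    outlier_proportions,
    profile_correlation,
    similarity_profile,
    stepwise_dfa,
    typicality_activation,
    typicality_correlation,
)


def dataset_with_counts(n_names=42, counts=(11, 10, 4)):
    """One object, one group, a 42-name inventory, counts on the first names."""
    words = [f"w{i:02d}" for i in range(n_names)]
    lexicon = pd.DataFrame(dict(word=words, language="A",
                                ipa=["pa"] * n_names, spelling=["pa"] * n_names))
    stimuli = pd.DataFrame({"object_id": ["obj000", "obj001"],
                            "f0": [0.5, 0.2], "f1": [0.1, 0.9]})
    responses = pd.DataFrame([
        dict(object="obj000", group="mono_A", language="A", name=w, count=c)
        for w, c in zip(words, counts)
    ])
    return NamingDataset(stimuli=stimuli, lexicon=lexicon, responses=responses)


class TestDistributionTable:
    def test_counts_land_in_named_columns(self):
        """An 11/10/4 split fills three dimensions and leaves 39 zeros."""
        ds = dataset_with_counts()
        table = build_distribution_table(ds, "mono_A", "A")
        row = table.table.loc["obj000"]
        assert list(row[:3]) == [11.0, 10.0, 4.0]
        assert (row[3:] == 0).all()
        assert len(row) == 42

    def test_row_sum_equals_participant_count(self):
        ds = dataset_with_counts()
        assert build_distribution_table(ds, "mono_A", "A").table.loc["obj000"].sum() == 25

    def test_unresponded_object_is_flagged_empty(self):
        ds = dataset_with_counts()
        table = build_distribution_table(ds, "mono_A", "A")
        assert table.empty_objects == ["obj001"]

    def test_unknown_name_rejected(self):
        ds = dataset_with_counts()
        ds.responses.loc[0, "name"] = "ghost"
        with pytest.raises(ValueError):
            build_distribution_table(ds, "mono_A", "A")


class TestSimilarityProfile:
    def make_table(self, mat):
        df = pd.DataFrame(np.asarray(mat, dtype=float))
        return NameDistributionTable(group="g", table=df)

    def test_73_objects_give_2628_pairs(self, rng):
        profile = similarity_profile(self.make_table(rng.random((73, 10))))
        assert profile.values.size == 2628

    def test_identical_rows_correlate_perfectly(self):
        profile = similarity_profile(self.make_table(
            [[1, 2, 3], [2, 4, 6], [5, 1, 0]]))
        assert profile.values[0] == pytest.approx(1.0)

    def test_matches_pairwise_pearson_oracle(self, rng):
        mat = rng.random((4, 7))
        profile = similarity_profile(self.make_table(mat))
        expected = [
            sps.pearsonr(mat[i], mat[j]).statistic
            for i in range(4) for j in range(i + 1, 4)
        ]
        assert np.allclose(profile.values, expected)

    def test_constant_rows_are_excluded_and_counted(self, rng):
        mat = rng.random((4, 5))
        mat[1] = 0.3
        profile = similarity_profile(self.make_table(mat))
        assert profile.n_excluded == 3  # the 3 pairs involving the flat row
        assert np.isnan(profile.values[0])


class TestFisher:
    def test_anchor_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=5e-5)

    def test_odd_and_invertible(self, rng):
        r = rng.uniform(-0.99, 0.99, 50)
        assert np.allclose(fisher_z(-r), -np.asarray(fisher_z(r)))
        assert np.allclose(fisher_z_inverse(fisher_z(r)), r, atol=1e-12)

    def test_rejects_unit_correlation(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    def test_equal_correlations_give_zero_Z(self, rng):
        p1 = similarity_profile(NameDistributionTable(
            group="g1", table=pd.DataFrame(rng.random((10, 6)))))
        p2 = similarity_profile(NameDistributionTable(
            group="g2", table=pd.DataFrame(rng.random((10, 6)))))
        cmp_ = compare_group_correlations(p1, p2, p1, p2)
        assert cmp_.Z == 0.0
        assert cmp_.p_value == pytest.approx(1.0)

    def test_pairwise_exclusion_shrinks_n(self, rng):
        a = similarity_profile(NameDistributionTable(
            group="a", table=pd.DataFrame(rng.random((6, 5)))))
        b_mat = rng.random((6, 5))
        b_mat[0] = 0.7  # constant row -> 5 undefined pairs
        b = similarity_profile(NameDistributionTable(
            group="b", table=pd.DataFrame(b_mat)))
        corr = profile_correlation(a, b)
        assert corr.n == 15 - 5


class TestTypicality:
    @staticmethod
    def varying_word(model, language):
        """First word whose typicality vector has variance (needed for r)."""
        for w in model.words_of(language):
            if typicality_activation(model, w).std() > 0:
                return w
        pytest.fail(f"no varying typicality vector in language {language}")

    def test_same_name_correlates_perfectly(self, tiny_model):
        word = self.varying_word(tiny_model, "A")
        corr = typicality_correlation((tiny_model, tiny_model), (word, word))
        assert corr.r == pytest.approx(1.0)

    def test_matches_manual_pearson(self, tiny_model):
        wa = self.varying_word(tiny_model, "A")
        wb = self.varying_word(tiny_model, "B")
        ta = typicality_activation(tiny_model, wa)
        tb = typicality_activation(tiny_model, wb)
        expected = sps.pearsonr(ta, tb).statistic
        corr = typicality_correlation((tiny_model, tiny_model), (wa, wb))
        assert corr.r == pytest.approx(expected)
        assert corr.n == len(tiny_model.object_ids)


class TestGeometryPrimitives:
    def test_single_point_centers_on_itself(self):
        xy = np.array([[4.0, 7.0]])
        w = np.array([1.0])
        assert np.array_equal(_weighted_mean(xy, w), [4.0, 7.0])
        assert np.array_equal(_weighted_median(xy, w), [4.0, 7.0])

    def test_equal_weights_mean_is_midpoint(self):
        xy = np.array([[0.0, 0.0], [2.0, 4.0]])
        w = np.array([1.0, 1.0])
        assert np.array_equal(_weighted_mean(xy, w), [1.0, 2.0])

    def test_weighted_mean_tracks_heavy_point(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0]])
        w = np.array([3.0, 1.0])
        assert np.allclose(_weighted_mean(xy, w), [2.5, 0.0])


class TestCategoryGeometry:
    def test_centers_inside_grid_and_outliers_consistent(self, tiny_model):
        names = [tiny_model.words_of("A")[0], tiny_model.words_of("A")[1]]
        geo = category_geometry(tiny_model, names, "A")
        rows, cols = tiny_model.maps["S"].rows, tiny_model.maps["S"].cols
        coords = tiny_model.maps["S"].coordinates
        for nm in names:
            r, c = geo.center_mean[nm]
            assert 0 <= r <= rows - 1 and 0 <= c <= cols - 1
        # outlier flags equal a manual nearest-center comparison
        for nm in names:
            own = geo.center_mean[nm]
            for obj in geo.members[nm]:
                xy = coords[tiny_model.object_bmu[obj]]
                d_own = np.linalg.norm(xy - own)
                others = [np.linalg.norm(xy - geo.center_mean[o])
                          for o in names if o != nm]
                is_outlier = any(d < d_own for d in others)
                assert (obj in geo.outliers[nm]) == is_outlier


class TestDistanceRatio:
    def test_identical_prototypes_give_unit_ratio(self):
        mono_a, mono_b = np.array([0.0, 0.0]), np.array([3.0, 4.0])
        assert indirect_direct_ratio(mono_a, mono_b, mono_a, mono_b) == pytest.approx(1.0)

    def test_ratio_at_least_one_on_random_geometries(self, rng):
        for _ in range(100):
            pts = rng.uniform(0, 30, size=(4, 2))
            if np.linalg.norm(pts[0] - pts[1]) < 1e-9:
                continue
            assert indirect_direct_ratio(*pts) >= 1.0 - 1e-12

    def test_hand_placed_coordinates(self):
        # a = 10, b = 3, c = 4, d = 5 -> ratio 1.2
        ratio = indirect_direct_ratio(
            np.array([0.0, 0.0]), np.array([10.0, 0.0]),
            np.array([0.0, 3.0]), np.array([10.0, 4.0]))
        b, c = 3.0, 4.0
        d = np.hypot(10.0, 1.0)
        assert ratio == pytest.approx((b + c + d) / 10.0)

    def test_coincident_monolingual_centers_rejected(self):
        p = np.array([1.0, 1.0])
        with pytest.raises(ValueError):
            indirect_direct_ratio(p, p, p + 1, p + 2)


class TestStepwiseDFA:
    def test_single_informative_feature_selected(self, rng):
        """Two clusters split by one feature; the rest is pure noise."""
        n = 40
        labels = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, size=(n, 8))
        X[:, 3] = labels * 6 + rng.normal(0, 0.5, n)
        res = stepwise_dfa(X, labels)
        assert res.selected == [3]
        assert res.n_dims == 1
        assert res.p_value < 0.05
        assert res.separable

    def test_identical_distributions_select_nothing(self, rng):
        X = rng.normal(0, 1, size=(30, 5))
        labels = np.repeat([0, 1], 15)
        res = stepwise_dfa(X, labels)
        assert res.n_dims == 0
        assert not res.separable

    def test_separable_fixture_is_significant(self, rng):
        n = 30
        labels = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, size=(n, 4))
        X[:, 0] += labels * 8
        X[:, 1] -= labels * 8
        res = stepwise_dfa(X, labels)
        assert res.separable and res.p_value < 0.05
        assert 0 < res.canonical_correlation <= 1

    def test_wilks_lambda_matches_manova_oracle(self, rng):
        """The Wilks' lambda statistic agrees with statsmodels' MANOVA."""
        from statsmodels.multivariate.manova import MANOVA

        from bilexmap.stats import _wilks_lambda

        n = 30
        labels = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, size=(n, 3))
        X[:, 0] += labels * 3
        cols = [0, 1]
        lam = _wilks_lambda(X, labels, cols, ridge=0.0)
        mv = MANOVA(endog=X[:, cols],
                    exog=np.column_stack([np.ones(n), labels]))
        table = mv.mv_test().results["x1"]["stat"]
        expected = float(table.loc["Wilks' lambda", "Value"])
        assert lam == pytest.approx(expected, rel=1e-9)

    def test_small_category_rejected(self, rng):
        X = rng.normal(0, 1, size=(5, 3))
        with pytest.raises(ValueError):
            stepwise_dfa(X, np.array([0, 0, 0, 0, 1]))


class TestOutlierProportions:
    def make_geometry(self, members, outliers):
        names = list(members)
        return CategoryGeometry(
            language="A", names=names,
            center_mean={n: np.zeros(2) for n in names},
            center_median={n: np.zeros(2) for n in names},
            members=members, outliers=outliers,
        )

    def test_no_outliers_gives_zero(self):
        geo = self.make_geometry({"a": ["o1", "o2"]}, {"a": []})
        assert outlier_proportions(geo) == {"a": 0.0}

    def test_one_in_four(self):
        geo = self.make_geometry({"a": ["o1", "o2", "o3", "o4"]}, {"a": ["o3"]})
        assert outlier_proportions(geo) == {"a": 0.25}

    def test_empty_category_rejected(self):
        geo = self.make_geometry({"a": []}, {"a": []})
        with pytest.raises(ValueError):
            outlier_proportions(geo)
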