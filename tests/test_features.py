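import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from fcstage.connectivity import index_to_pair
from fcstage.features import (
    FeatureChain,
    choose_components,
    fit_pca,
    fit_standardizer,
    ks_normality_filter,
    ks_normality_pvalues,
    mad_outlier_flags,
    paired_t_select,
    screen_outlier_features,
    transform_scores,
)


class TestMadFlags:
    def test_hand_computed_rule(self):
        # med=3, MAD=1, threshold 3*1.4826 = 4.4478 -> only 100 flagged
        flags = mad_outlier_flags(np.array([1, 2, 3, 4, 100.0]))
        assert flags.tolist() == [False, False, False, False, True]

    def test_all_equal_values_unflagged(self):
        assert not mad_outlier_flags(np.full(6, 2.5)).any()

    def test_degenerate_mad_flags_any_off_median(self):
        flags = mad_outlier_flags(np.array([1, 1, 1, 1, 2.0]))
        assert flags.tolist() == [False, False, False, False, True]

    def test_requires_three_values(self):
        with pytest.raises(ValueError):
            mad_outlier_flags(np.array([1.0, 2.0]))

    @given(arrays(np.float64, st.integers(3, 40),
                  elements=st.floats(-100, 100, allow_nan=False)))
    def test_matches_definition(self, x):
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        expected = (x != med) if mad == 0 else np.abs(x - med) > 3 * 1.4826 * mad
        assert np.array_equal(mad_outlier_flags(x), expected)


class TestOutlierScreen:
    def test_matches_per_feature_oracle(self):
        rng = np.random.default_rng(0)
        xp = rng.standard_normal((20, 120))
        xq = rng.standard_normal((20, 120))
        res = screen_outlier_features(xp, xq)
        expected = [
            f for f in range(120)
            if not mad_outlier_flags(xp[:, f]).any() and not mad_outlier_flags(xq[:, f]).any()
        ]
        assert res.retained_indices.tolist() == expected

    def test_extreme_value_in_one_stage_removes_feature_everywhere(self):
        rng = np.random.default_rng(1)
        xp = rng.standard_normal((10, 5))
        xq = rng.standard_normal((10, 5))
        res0 = screen_outlier_features(xp, xq)
        target = int(res0.retained_indices[0])  # a feature clean in both stages
        xp[3, target] = 1e6
        res = screen_outlier_features(xp, xq)
        assert target not in res.retained_indices
        assert target in res.removed_pre

    def test_symmetric_in_stage_order(self):
        rng = np.random.default_rng(2)
        xp = rng.standard_normal((12, 40))
        xq = rng.standard_normal((12, 40))
        a = screen_outlier_features(xp, xq).retained_indices
        b = screen_outlier_features(xq, xp).retained_indices
        assert np.array_equal(a, b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            screen_outlier_features(np.zeros((5, 3)), np.zeros((5, 4)))


class TestKsFilter:
    def test_matches_scipy_kstest_per_feature(self):
        rng = np.random.default_rng(3)
        x = np.column_stack(
            [rng.standard_normal(25), rng.uniform(size=25), rng.exponential(size=25)]
        )
        got = ks_normality_pvalues(x)
        for f in range(3):
            z = (x[:, f] - x[:, f].mean()) / x[:, f].std(ddof=1)
            expected = stats.kstest(z, "norm").pvalue
            assert got[f] == pytest.approx(expected, rel=1e-9)

    def test_level_on_normal_data(self):
        # each of 50 seeded replicates is 1000 normal draws; near-all retained
        rng = np.random.default_rng(4)
        x = rng.standard_normal((1000, 50))
        kept = ks_normality_filter(x, alpha_ks=0.05)
        assert kept.size >= 45  # >= 90% of replicates retained

    def test_power_against_uniform(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=(1000, 100))
        kept = ks_normality_filter(x, alpha_ks=0.05)
        assert kept.size <= 1  # >= 99% rejected

    def test_constant_feature_excluded_with_warning(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((30, 3))
        x[:, 1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            kept = ks_normality_filter(x)
        assert 1 not in kept


class TestPairedTSelect:
    def test_closed_form_worked_example(self):
        # d = [1, 2, 3]: t = 2 / (1/sqrt(3)) = 3.4641, df = 2
        xp = np.zeros((3, 1))
        xq = np.array([[1.0], [2.0], [3.0]])
        p, sel = paired_t_select(xp, xq, alpha=0.05)
        t = 2.0 / (1.0 / np.sqrt(3))
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p[0] == pytest.approx(2 * stats.t.sf(t, df=2), rel=1e-9)
        assert p[0] == pytest.approx(0.0742, abs=1e-4)
        assert sel.size == 0

    def test_identical_stages_select_nothing(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((10, 20))
        with pytest.warns(UserWarning, match="zero-variance"):
            p, sel = paired_t_select(x, x.copy())
        assert sel.size == 0
        assert np.all(p == 1.0)

    def test_null_selection_rate_near_alpha(self):
        # calibration: fraction with p < alpha concentrates near alpha
        rng = np.random.default_rng(8)
        xp = rng.standard_normal((20, 4000))
        xq = rng.standard_normal((20, 4000))
        _, sel = paired_t_select(xp, xq, alpha=0.05)
        rate = sel.size / 4000
        # 99.9% binomial band around 0.05 for 4000 trials
        assert abs(rate - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / 4000)

    def test_recovers_planted_effects_reaching_selection(self, planted_cohort):
        xp, xq = planted_cohort["x_pre"], planted_cohort["x_post"]
        truth = planted_cohort["truth"]
        chain = FeatureChain().fit(xp, xq)
        planted = truth.planted_indices(30)
        reaching = [k for k in planted if k in set(chain.selection.normal_indices.tolist())]
        selected = set(chain.selection.selected_indices.tolist())
        assert len(reaching) > 0
        recovered = sum(1 for k in reaching if k in selected)
        assert recovered / len(reaching) >= 0.8


class TestPca:
    def test_sample_limited_rank(self):
        rng = np.random.default_rng(9)
        basis = fit_pca(rng.standard_normal((40, 679)))
        positive = np.sum(basis.variance_fractions > 1e-12)
        assert positive == 39
        assert basis.loadings.shape == (679, 39)

    def test_collinear_points_have_one_component(self):
        t = np.linspace(0, 1, 20)[:, None]
        x = t @ np.array([[1.0, -2.0, 0.5, 3.0, 1.5]])
        basis = fit_pca(x)
        assert np.sum(basis.variance_fractions > 1e-10) == 1

    def test_variance_conservation(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((30, 15)) * rng.uniform(0.5, 3, size=15)
        basis = fit_pca(x)
        centered = x - x.mean(axis=0)
        total = (centered**2).sum() / (30 - 1)
        scores = centered @ basis.loadings
        comp_var = (scores**2).sum(axis=0) / (30 - 1)
        assert comp_var.sum() == pytest.approx(total, rel=1e-9)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((12, 8))
        basis = fit_pca(x)
        centered = x - basis.mean_vector
        recon = (centered @ basis.loadings) @ basis.loadings.T
        assert np.allclose(recon, centered, atol=1e-8)

    def test_orthonormal_loadings(self):
        rng = np.random.default_rng(12)
        basis = fit_pca(rng.standard_normal((20, 10)))
        g = basis.loadings.T @ basis.loadings
        assert np.allclose(g, np.eye(g.shape[0]), atol=1e-10)


class TestChooseComponents:
    @pytest.mark.parametrize(
        "fractions, threshold, expected",
        [
            ([0.5, 0.3, 0.1, 0.1], 0.85, 3),
            (np.full(39, 1 / 39), 0.85, 34),  # 33/39 = 0.846 < 0.85 < 34/39
            ([1.0], 0.85, 1),
        ],
    )
    def test_cumulative_rule(self, fractions, threshold, expected):
        assert choose_components(np.asarray(fractions, float), threshold) == expected

    def test_default_threshold_is_085(self):
        import inspect

        sig = inspect.signature(choose_components)
        assert sig.parameters["threshold"].default == 0.85

    def test_total_below_threshold_keeps_all_with_warning(self):
        with pytest.warns(UserWarning, match="threshold"):
            assert choose_components(np.array([0.4, 0.2]), 0.85) == 2


class TestScoresAndStandardizer:
    def test_training_scores_reproduce_variance_fractions(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((25, 10)) * rng.uniform(0.5, 4, 10)
        basis = fit_pca(x, variance_threshold=0.99999)
        scores = transform_scores(x, basis)
        var = scores.var(axis=0, ddof=1)
        frac = var / (x - x.mean(axis=0)).var(axis=0, ddof=1).sum()
        assert np.allclose(frac, basis.variance_fractions[: basis.n_components_kept], atol=1e-9)

    def test_mean_input_maps_to_zero(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((10, 6))
        basis = fit_pca(x)
        scores = transform_scores(np.tile(basis.mean_vector, (3, 1)), basis)
        assert np.allclose(scores, 0.0, atol=1e-12)

    def test_kept_scores_uncorrelated(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal((30, 12))
        scores = transform_scores(x, fit_pca(x))
        c = np.cov(scores, rowvar=False)
        off = c - np.diag(np.diag(c))
        assert np.max(np.abs(off)) < 1e-9

    def test_standardizer_definition_and_round_trip(self):
        rng = np.random.default_rng(16)
        scores = rng.standard_normal((20, 5)) * 3 + 2
        std = fit_standardizer(scores)
        z = std.apply(scores)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1, atol=1e-12)
        assert np.allclose(std.invert(z), scores, atol=1e-10)

    def test_heldout_uses_training_statistics(self):
        rng = np.random.default_rng(17)
        train = rng.standard_normal((20, 3))
        held = rng.standard_normal((5, 3)) + 10
        std = fit_standardizer(train)
        z = std.apply(held)
        assert np.allclose(z, (held - train.mean(axis=0)) / train.std(axis=0), atol=1e-12)

    def test_zero_sd_component_rejected(self):
        with pytest.raises(ValueError):
            fit_standardizer(np.ones((5, 2)))


class TestFeatureChain:
    def test_selected_features_map_to_unique_seed_pairs(self, planted_cohort):
        chain = FeatureChain().fit(planted_cohort["x_pre"], planted_cohort["x_post"])
        sel = chain.selection.selected_indices
        pairs = set(zip(*index_to_pair(sel, 30)))
        assert len(pairs) == sel.size
        # masks nest: selected ⊆ normal ⊆ retained
        assert set(sel) <= set(chain.selection.normal_indices)
        assert set(chain.selection.normal_indices) <= set(chain.screen.retained_indices)

    def test_transform_is_deterministic_and_idempotent_artifacts(self, planted_cohort):
        xp, xq = planted_cohort["x_pre"], planted_cohort["x_post"]
        chain = FeatureChain().fit(xp, xq)
        a = chain.transform(xp)
        b = chain.transform(xp)
        assert np.array_equal(a, b)
        stacked = np.vstack([chain.transform(xp), chain.transform(xq)])
        assert np.allclose(stacked.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(stacked.std(axis=0), 1, atol=1e-10)

    def test_serialization_round_trip(self, tmp_path, planted_cohort):
        xp, xq = planted_cohort["x_pre"], planted_cohort["x_post"]
        chain = FeatureChain().fit(xp, xq)
        chain.to_json(tmp_path / "chain.json")
        back = FeatureChain.from_json(tmp_path / "chain.json")
        assert np.array_equal(
            back.selection.selected_indices, chain.selection.selected_indices
        )
        assert np.allclose(back.transform(xp), chain.transform(xp), atol=1e-12)

    def test_empty_selection_falls_back_to_best_feature(self):
        rng = np.random.default_rng(18)
        xp = rng.standard_normal((8, 10))
        xq = xp + rng.standard_normal((8, 10)) * 0.01
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chain = FeatureChain(alpha=1e-9).fit(xp, xq)
        assert chain.selection.selected_indices.size == 1
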