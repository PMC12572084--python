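import numpy as np
import pandas as pd
import pytest
from scipy import stats

import contrastkit as ck
from contrastkit.errors import AlignmentError, ZeroVarianceError


def _long(groups, rng=None, labels=None):
    """Build a long-format frame from a dict label -> values."""
    frames = [
        pd.DataFrame({"condition": lab, "dv": np.asarray(vals, float)})
        for lab, vals in groups.items()
    ]
    return pd.concat(frames, ignore_index=True)


class TestContrastEstimate:
    def test_worked_example_estimate(self, maraver, hyp1):
        L = ck.contrast_estimate(maraver.means, hyp1)
        assert round(L, 3) == 0.189

    def test_printed_difference_weights_estimate(self, maraver):
        printed = ck.validate_weights(maraver.labels, (0.19, -0.71, 0.52))
        # the hand-rounded difference vector applied to the observed means
        L = ck.contrast_estimate(maraver.means, printed)
        assert L == pytest.approx(0.0667, abs=5e-4)

    def test_equal_means_give_zero(self, hyp1):
        assert ck.contrast_estimate((3, 3, 3), hyp1) == pytest.approx(0)

    def test_length_mismatch(self, hyp1):
        with pytest.raises(AlignmentError):
            ck.contrast_estimate((1, 2), hyp1)


class TestPooledVariance:
    def test_balanced_methods_coincide(self, maraver):
        v1 = ck.pooled_within_variance(maraver, "unweighted")
        v2 = ck.pooled_within_variance(maraver, "df_weighted")
        assert v1 == pytest.approx(v2)
        assert v1 == pytest.approx(0.052 / 3, rel=1e-12)
        assert round(v1, 3) == 0.017

    def test_shared_variance_is_returned_unchanged(self):
        s = ck.GroupSummaries(("a", "b", "c"), (0, 1, 2), (2.5, 2.5, 2.5), (5, 9, 3))
        for method in ("unweighted", "df_weighted"):
            assert ck.pooled_within_variance(s, method) == pytest.approx(2.5)

    def test_unbalanced_hand_arithmetic(self):
        s = ck.GroupSummaries(("a", "b"), (0, 0), (1.0, 2.0), (2, 10))
        assert ck.pooled_within_variance(s, "unweighted") == pytest.approx(1.5)
        assert ck.pooled_within_variance(s, "df_weighted") == pytest.approx(1.9)

    def test_small_groups_rejected(self):
        with pytest.raises(ck.InsufficientDataError):
            ck.GroupSummaries(("a", "b"), (0, 0), (1, 1), (1, 10))


class TestBetweenTest:
    def test_worked_example_chain(self, maraver, hyp1):
        res = ck.between_contrast_test(maraver, hyp1, mse_method="unweighted")
        assert round(res.l_estimate, 3) == 0.189
        assert res.se == pytest.approx(0.0255, abs=5e-4)
        assert res.t == pytest.approx(7.41, abs=0.01)
        assert res.df == 117
        assert res.p_one_tailed < 0.05
        assert res.t > ck.critical_t(res.df, 0.05, "one")

    def test_f_is_t_squared_and_p_relations(self, maraver, hyp1):
        res = ck.between_contrast_test(maraver, hyp1)
        assert res.f == pytest.approx(res.t**2, rel=1e-9)
        assert res.ms_contrast == res.ss_contrast
        assert res.p_one_tailed == pytest.approx(res.p_two_tailed / 2)
        assert res.p_f == pytest.approx(res.p_two_tailed, rel=1e-9)

    def test_two_group_contrast_equals_pooled_t_test(self, rng):
        x = rng.normal(0.0, 1.0, 14)
        y = rng.normal(0.7, 1.0, 9)
        data = _long({"treat": x, "ctrl": y})
        w = ck.validate_weights(("treat", "ctrl"), (1, -1))
        res = ck.between_contrast_test(data, w)
        t_ref, p_ref = stats.ttest_ind(x, y)
        assert res.t == pytest.approx(t_ref, abs=1e-12)
        assert res.p_two_tailed == pytest.approx(p_ref, abs=1e-12)
        assert res.df == 21

    def test_zero_variance_guard(self):
        s = ck.GroupSummaries(("a", "b"), (0, 1), (0.0, 0.0), (5, 5))
        with pytest.raises(ZeroVarianceError):
            ck.between_contrast_test(s, ck.validate_weights(("a", "b"), (1, -1)))

    def test_weights_follow_labels_not_column_order(self, maraver, hyp1):
        shuffled = ck.ContrastWeights.from_mapping(
            {"pay attention": -0.5, "imagine": 1.0, "memorize": -0.5}
        )
        a = ck.between_contrast_test(maraver, hyp1)
        b = ck.between_contrast_test(maraver, shuffled)
        assert a.l_estimate == b.l_estimate
        assert a.t == b.t

    def test_label_mismatch_rejected(self, maraver):
        w = ck.validate_weights(("x", "y", "z"), (1, -0.5, -0.5))
        with pytest.raises(AlignmentError):
            ck.between_contrast_test(maraver, w)

    def test_scale_invariance_of_inference(self, rng, hyp1, maraver):
        a = ck.between_contrast_test(maraver, hyp1)
        b = ck.between_contrast_test(maraver, hyp1.scaled(7.3))
        assert b.t == pytest.approx(a.t, rel=1e-12)
        assert b.p_one_tailed == pytest.approx(a.p_one_tailed, rel=1e-12)
        assert b.f == pytest.approx(a.f, rel=1e-12)
        assert b.l_estimate == pytest.approx(7.3 * a.l_estimate, rel=1e-12)
        assert b.ss_contrast == pytest.approx(a.ss_contrast, rel=1e-12)
        assert b.r_alerting == pytest.approx(a.r_alerting, rel=1e-12)
        assert b.r_contrast == pytest.approx(a.r_contrast, rel=1e-12)


class TestEffectSizes:
    def test_alerting_is_one_for_proportional_means(self):
        lam = (1.0, -0.5, -0.5)
        s = ck.GroupSummaries(
            ("a", "b", "c"), tuple(2 * v + 5 for v in lam), (1, 1, 1), (10, 10, 10)
        )
        _, r_alert, _ = ck.between_effect_sizes(
            s, ck.validate_weights(("a", "b", "c"), lam)
        )
        assert r_alert == pytest.approx(1.0)

    def test_r_contrast_matches_point_biserial_identity(self):
        # six observations, two groups: r_contrast^2 == t^2/(t^2 + N - 2)
        data = _long({"a": [1.0, 2.0, 4.0], "b": [3.0, 5.0, 9.0]})
        w = ck.validate_weights(("a", "b"), (1, -1))
        res = ck.between_contrast_test(data, w)
        t_ref = stats.ttest_ind(
            data.loc[data.condition == "a", "dv"],
            data.loc[data.condition == "b", "dv"],
        ).statistic
        assert res.r_contrast**2 == pytest.approx(
            t_ref**2 / (t_ref**2 + 4), rel=1e-12
        )
        assert np.sign(res.r_contrast) == np.sign(res.t)

    def test_alerting_bounds_effectsize_on_random_data(self, rng):
        w = ck.validate_weights(("a", "b", "c", "d"), (3, -1, -1, -1))
        for _ in range(20):
            groups = {
                lab: rng.normal(rng.normal(0, 1), 1.0, 12) for lab in "abcd"
            }
            res = ck.between_contrast_test(_long(groups), w)
            assert abs(res.r_effectsize) <= abs(res.r_alerting) + 1e-12
            assert abs(res.r_alerting) <= 1 + 1e-12

    def test_near_zero_noise_drives_all_correlations_to_one(self, rng):
        lam = (1.0, -0.5, -0.5)
        groups = {
            lab: mu + 1e-7 * rng.standard_normal(20)
            for lab, mu in zip("abc", lam)
        }
        res = ck.between_contrast_test(
            _long(groups), ck.validate_weights(("a", "b", "c"), lam)
        )
        assert res.r_alerting == pytest.approx(1.0, abs=1e-6)
        assert res.r_effectsize == pytest.approx(1.0, abs=1e-6)

    def test_summaries_alone_leave_r_effectsize_unset(self, maraver, hyp1):
        r_eff, r_alert, r_con = ck.between_effect_sizes(maraver, hyp1)
        assert r_eff is None
        assert 0 < r_alert <= 1
        assert 0 < r_con < 1


class TestCompetingContrast:
    def test_worked_competing_example(self, maraver, hyp1, hyp2):
        res = ck.compare_hypotheses_between(
            maraver, hyp1, hyp2, mse_method="unweighted"
        )
        assert res.l_estimate == pytest.approx(0.0664, abs=5e-4)
        assert res.t > ck.critical_t(117, 0.05, "one")
        assert res.p_one_tailed < 0.05
        assert res.df == 117
        assert res.favored is hyp1 and res.rival is hyp2

    def test_swapping_hypotheses_negates_the_test(self, maraver, hyp1, hyp2):
        a = ck.compare_hypotheses_between(maraver, hyp1, hyp2)
        b = ck.compare_hypotheses_between(maraver, hyp2, hyp1)
        assert a.l_estimate == pytest.approx(-b.l_estimate, rel=1e-12)
        assert a.t == pytest.approx(-b.t, rel=1e-12)

    def test_identical_hypotheses_rejected(self, maraver, hyp1):
        with pytest.raises(ck.DegenerateContrastError):
            ck.compare_hypotheses_between(maraver, hyp1, hyp1)


class TestHelmertDecomposition:
    def test_ss_sums_to_between_group_ss_on_balanced_data(self, rng):
        labels = ("a", "b", "c", "d")
        groups = {lab: rng.normal(mu, 1.2, 15) for lab, mu in zip(labels, (0, 0.4, 0.9, 0.1))}
        data = _long(groups)
        ss_sum = sum(
            ck.between_contrast_test(data, w).ss_contrast
            for w in ck.helmert_set(labels)
        )
        grand = data["dv"].mean()
        ss_between = sum(
            len(v) * (np.mean(v) - grand) ** 2 for v in groups.values()
        )
        assert ss_sum == pytest.approx(ss_between, rel=1e-9)
        # cross-check the implied omnibus F against scipy's one-way ANOVA
        f_ref = stats.f_oneway(*groups.values()).statistic
        mse = ck.pooled_within_variance(
            ck.GroupSummaries.from_long(data), "df_weighted"
        )
        assert ss_sum / 3 / mse == pytest.approx(f_ref, rel=1e-9)
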