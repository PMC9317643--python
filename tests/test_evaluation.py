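import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from pairimpute import (
    GroupDesign,
    HIGH_CORRELATION,
    PairedStudy,
    between_specimen_correlations,
    bias_summary,
    correlation_records,
    generate_paired_study,
    log_transform,
    manova_calls,
    manova_two_group,
    validity_metrics,
)


def _study(a, b, groups):
    a = pd.DataFrame(np.asarray(a, float))
    b = pd.DataFrame(np.asarray(b, float))
    return PairedStudy(a, b, pd.Series(groups, index=a.columns), scale="log")


class TestCorrelations:
    def test_identical_matrices_give_r_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 10))
        s = _study(a, a.copy(), ["g1"] * 5 + ["g2"] * 5)
        assert np.allclose(between_specimen_correlations(s), 1.0)

    def test_negated_centered_row_gives_r_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(3, 8))
        b = -(a - a.mean(axis=1, keepdims=True))
        s = _study(a, b, ["g1"] * 4 + ["g2"] * 4)
        assert np.allclose(between_specimen_correlations(s), -1.0)

    def test_zero_variance_row_flagged_undefined(self):
        a = np.vstack([np.ones(6), np.arange(6.0)])
        b = np.vstack([np.arange(6.0), np.arange(6.0)])
        s = _study(a, b, ["g1"] * 3 + ["g2"] * 3)
        r = between_specimen_correlations(s)
        assert np.isnan(r.iloc[0]) and not np.isnan(r.iloc[1])

    def test_sample_r_unbiased_for_generating_r(self):
        # generator truth: sample correlations over many replicates center on
        # the drawn true_r (N = 79 per replicate)
        design = GroupDesign(48, 31)
        devs = []
        for seed in range(100):
            study = generate_paired_study(design, HIGH_CORRELATION, 20, seed=seed)
            r = between_specimen_correlations(log_transform(study))
            devs.extend(r.to_numpy() - study.true_r.to_numpy())
        assert abs(np.mean(devs)) < 0.02


class TestManova:
    def test_no_group_difference_gives_p_one(self):
        base = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 3.0], [4.0, 5.0]])
        y = np.vstack([base, base])  # identical data in both groups
        groups = np.array(["g1"] * 4 + ["g2"] * 4)
        t2, p = manova_two_group(y[:, 0], y[:, 1], groups)
        assert t2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_permutation_reference(self):
        # fixed 12-subject instance vs a 10,000-draw permutation null
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 12)
        b = 0.5 * a + rng.normal(0, 1, 12)
        a[:6] += 1.2
        groups = np.array(["g1"] * 6 + ["g2"] * 6)
        t2_obs, p_f = manova_two_group(a, b, groups)
        perm_rng = np.random.default_rng(7)
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = perm_rng.permutation(12)
            t2_perm, _ = manova_two_group(a[perm], b[perm], groups)
            if t2_perm >= t2_obs:
                count += 1
        p_perm = count / n_perm
        assert abs(p_f - p_perm) < 0.01

    def test_invariant_to_subject_reordering_and_coordinate_swap(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=12), rng.normal(size=12)
        groups = np.array(["g1"] * 6 + ["g2"] * 6)
        t2, p = manova_two_group(a, b, groups)
        perm = rng.permutation(12)
        t2_p, p_p = manova_two_group(a[perm], b[perm], groups[perm])
        t2_s, p_s = manova_two_group(b, a, groups)
        assert t2_p == pytest.approx(t2) and p_p == pytest.approx(p)
        assert t2_s == pytest.approx(t2) and p_s == pytest.approx(p)

    def test_vectorised_calls_match_scalar_test(self, small_masked_study):
        _, complete_log, _, _ = small_masked_study
        calls = manova_calls(complete_log)
        for met in complete_log.specimen_a.index[:5]:
            t2, p = manova_two_group(
                complete_log.specimen_a.loc[met],
                complete_log.specimen_b.loc[met],
                complete_log.groups.to_numpy(),
            )
            assert calls.loc[met, "p_value"] == pytest.approx(p)

    def test_singular_covariance_flagged_not_raised(self):
        a = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        groups = np.array(["g1"] * 3 + ["g2"] * 3)
        t2, p = manova_two_group(a, a, groups)
        assert np.isnan(p)


class TestValidityMetrics:
    def test_perfect_agreement(self):
        calls = np.array([True, False, True, False])
        vm = validity_metrics(calls, calls)
        assert (vm.sensitivity, vm.specificity, vm.accuracy) == (1.0, 1.0, 1.0)

    def test_hand_computed_rates(self):
        true = [True] * 4 + [False] * 6
        imputed = [True, True, True, False] + [False] * 5 + [True]
        vm = validity_metrics(true, imputed)
        assert (vm.tp, vm.fn, vm.tn, vm.fp) == (3, 1, 5, 1)
        assert vm.sensitivity == pytest.approx(0.75)
        assert vm.specificity == pytest.approx(5 / 6)
        assert vm.accuracy == pytest.approx(0.8)

    def test_all_negative_imputed_calls(self):
        vm = validity_metrics([True, False, False], [False, False, False])
        assert vm.sensitivity == 0.0 and vm.specificity == 1.0

    def test_undefined_rate_when_no_true_positives(self):
        vm = validity_metrics([False, False], [False, True])
        assert np.isnan(vm.sensitivity)

    @hsettings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
    def test_confusion_counts_partition_the_metabolites(self, pairs):
        true, imputed = zip(*pairs)
        vm = validity_metrics(list(true), list(imputed))
        assert vm.tp + vm.fp + vm.tn + vm.fn == len(pairs)


class TestBiasSummary:
    def test_zero_missing_records_have_zero_bias(self, small_masked_study):
        _, complete_log, _, _ = small_masked_study
        rec = correlation_records(complete_log, complete_log)
        summary = bias_summary(rec)
        assert summary.loc[0, "mean_bias"] == 0.0
        assert summary.loc[0, "mean_abs_bias"] == 0.0

    def test_symmetric_biases_average_to_zero(self):
        rec = pd.DataFrame({"bias": [-0.1, 0.1]})
        s = bias_summary(rec)
        assert s.loc[0, "mean_bias"] == pytest.approx(0.0)
        assert s.loc[0, "mean_abs_bias"] == pytest.approx(0.1)

    def test_undefined_records_excluded_and_counted(self):
        rec = pd.DataFrame({"bias": [0.2, np.nan, -0.2], "method": ["a", "a", "a"]})
        s = bias_summary(rec, by=["method"])
        assert s.loc[0, "n"] == 2 and s.loc[0, "n_undefined"] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bias_summary(pd.DataFrame({"bias": []}))
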