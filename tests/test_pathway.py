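"""Pathway activity scores, paired deltas, gated group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemoresist import (
    LOG2,
    AnalyteMatrix,
    InvariantError,
    RunConfig,
    SignedGeneSet,
    compare_groups,
    compute_pas,
    correlate_deltas,
    delta_pas,
    gen_paired,
)
from chemoresist.pathway import DOWN, MANN_WHITNEY, UP, WELCH_T, DeltaResult

from conftest import random_log2_matrix


class TestComputePAS:
    def test_worked_example(self, tiny_log2_matrix, sfk_set):
        res = compute_pas(tiny_log2_matrix, sfk_set)
        assert res.scores["s1"] == pytest.approx(2.5)  # (1.0 + 2.0) - 0.5
        assert res.members_used == {"positive": ["SRC", "FYN"], "negative": ["SRC_pY527"]}

    def test_empty_negative_set_is_plain_sum(self, tiny_log2_matrix):
        res = compute_pas(tiny_log2_matrix, SignedGeneSet("P", ["SRC", "FYN"], []))
        assert res.scores["s1"] == pytest.approx(3.0)

    def test_no_member_present_errors_instead_of_zero(self, tiny_log2_matrix):
        with pytest.raises(InvariantError, match="no member"):
            compute_pas(tiny_log2_matrix, SignedGeneSet("P", ["ABSENT"], []))

    def test_requires_log2_scale(self, sfk_set):
        m = AnalyteMatrix(pd.DataFrame({"s": [1.0]}, index=["SRC"]), scale="linear")
        with pytest.raises(InvariantError, match="log2"):
            compute_pas(m, sfk_set)

    def test_missing_policy_error_vs_skip(self, sfk_set):
        vals = pd.DataFrame({"s1": [1.0, np.nan, 0.5], "s2": [1.0, 2.0, 0.5]},
                            index=["SRC", "FYN", "SRC_pY527"])
        m = AnalyteMatrix(vals, scale=LOG2)
        with pytest.raises(InvariantError, match="FYN.*s1"):
            compute_pas(m, sfk_set)
        res = compute_pas(m, sfk_set, missing_policy="skip")
        assert res.scores["s1"] == pytest.approx(0.5)   # FYN omitted
        assert res.scores["s2"] == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_linearity_and_outside_set_invariance(self, seed, sfk_set):
        rng = np.random.default_rng(seed)
        m = random_log2_matrix(rng, 10, 6)
        m.values.index = ["SRC", "FYN", "SRC_pY527"] + list(m.values.index[3:])
        base = compute_pas(m, sfk_set).scores
        a = 2.7
        scaled = compute_pas(m.with_values(m.values * a), sfk_set).scores
        np.testing.assert_allclose(scaled.to_numpy(), a * base.to_numpy())
        # perturbing analytes outside the set leaves scores unchanged
        perturbed = m.values.copy()
        perturbed.iloc[3:] += rng.normal(size=perturbed.iloc[3:].shape)
        np.testing.assert_allclose(compute_pas(m.with_values(perturbed), sfk_set).scores,
                                   base)


class TestDeltaPAS:
    @staticmethod
    def _paired_matrices(sfk_set, n=4):
        rng = np.random.default_rng(0)
        analytes = sfk_set.members + ["OTHER"]
        pre_ids = [f"pre_{i}" for i in range(n)]
        post_ids = [f"post_{i}" for i in range(n)]
        vals = rng.normal(size=(len(analytes), n))
        pre = AnalyteMatrix(pd.DataFrame(vals, index=analytes, columns=pre_ids), scale=LOG2)
        post = AnalyteMatrix(pd.DataFrame(vals.copy(), index=analytes, columns=post_ids),
                             scale=LOG2)
        pairing = {f"p{i}": (pre_ids[i], post_ids[i]) for i in range(n)}
        return pre, post, pairing

    def test_identical_matrices_give_zero_deltas_called_down(self, sfk_set):
        pre, post, pairing = self._paired_matrices(sfk_set)
        res = delta_pas(pre, post, pairing, sfk_set)
        np.testing.assert_allclose(res.delta.to_numpy(), 0.0)
        assert (res.direction == DOWN).all()  # delta == 0 is Down: Up strictly means increase

    def test_unit_shift_on_one_positive_member(self, sfk_set):
        pre, post, pairing = self._paired_matrices(sfk_set)
        post.values.loc["SRC"] += 1.0
        res = delta_pas(pre, post, pairing, sfk_set)
        np.testing.assert_allclose(res.delta.to_numpy(), 1.0)
        assert (res.direction == UP).all()

    def test_pairing_to_missing_sample_lists_patient(self, sfk_set):
        pre, post, pairing = self._paired_matrices(sfk_set)
        pairing["ghost"] = ("nope", "post_0")
        with pytest.raises(InvariantError, match="ghost"):
            delta_pas(pre, post, pairing, sfk_set)

    def test_unpaired_samples_reported_excluded(self, sfk_set):
        pre, post, pairing = self._paired_matrices(sfk_set)
        del pairing["p0"]
        res = delta_pas(pre, post, pairing, sfk_set)
        assert res.excluded_pre == ["pre_0"]
        assert res.excluded_post == ["post_0"]

    def test_planted_responders_called_up_exactly(self, config):
        pre, post, truth = gen_paired(config, n_patients=10, n_responders=6, shift=2.0)
        res = delta_pas(pre, post, truth.pairing, truth.pathways[0])
        called_up = sorted(res.direction.index[res.direction == UP])
        assert called_up == sorted(truth.responder_ids)
        assert res.excluded_pre  # screening-only samples exist and are reported


class TestCorrelateDeltas:
    @staticmethod
    def _delta(values, patients=None):
        idx = patients or [f"p{i}" for i in range(len(values))]
        s = pd.Series(values, index=idx, dtype=float)
        return DeltaResult("x", s, pd.Series(np.where(s > 0, UP, DOWN), index=idx), [], [])

    def test_self_correlation_is_one(self):
        a = self._delta([1.0, 2.0, 3.0, 4.0])
        r, p, n = correlate_deltas(a, a)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_negated_correlation_is_minus_one(self):
        a = self._delta([1.0, 2.0, 3.0])
        b = self._delta([-1.0, -2.0, -3.0])
        assert correlate_deltas(a, b)[0] == pytest.approx(-1.0)

    def test_too_few_shared_patients(self):
        a = self._delta([1.0, 2.0], ["p0", "p1"])
        b = self._delta([1.0, 2.0], ["p1", "p2"])
        with pytest.raises(InvariantError, match=">= 3"):
            correlate_deltas(a, b)

    def test_zero_variance_undefined(self):
        a = self._delta([1.0, 1.0, 1.0])
        b = self._delta([1.0, 2.0, 3.0])
        with pytest.raises(InvariantError, match="zero variance"):
            correlate_deltas(a, b)

    def test_null_correlation_centered_and_p_uniform(self):
        rng = np.random.default_rng(42)
        rs, ps = [], []
        for _ in range(1000):
            a = self._delta(rng.normal(size=10))
            b = self._delta(rng.normal(size=10))
            r, p, _ = correlate_deltas(a, b)
            rs.append(r)
            ps.append(p)
        assert abs(np.mean(rs)) < 0.05
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCompareGroups:
    @staticmethod
    def _series(a, b):
        values = pd.Series(np.concatenate([a, b]),
                           index=[f"s{i}" for i in range(len(a) + len(b))])
        labels = pd.Series(["g1"] * len(a) + ["g2"] * len(b), index=values.index)
        return values, labels

    def test_normal_groups_use_welch(self):
        rng = np.random.default_rng(0)  # draw passing Shapiro in both groups
        values, labels = self._series(rng.normal(0, 1, 30), rng.normal(1, 2, 30))
        res = compare_groups(values, labels)
        assert min(res.normality_p.values()) >= 0.05
        assert res.test_used == WELCH_T

    def test_exponential_group_triggers_mann_whitney(self):
        rng = np.random.default_rng(0)
        values, labels = self._series(rng.normal(0, 1, 30), rng.exponential(1, 30))
        res = compare_groups(values, labels)
        assert min(res.normality_p.values()) < 0.05
        assert res.test_used == MANN_WHITNEY

    def test_gate_matches_independent_shapiro(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b = rng.normal(size=12), rng.standard_t(2, size=12)
            values, labels = self._series(a, b)
            res = compare_groups(values, labels)
            expect_mw = (stats.shapiro(a).pvalue < 0.05) or (stats.shapiro(b).pvalue < 0.05)
            assert res.test_used == (MANN_WHITNEY if expect_mw else WELCH_T)

    def test_small_group_rejected(self):
        values, labels = self._series([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(InvariantError, match="n=2"):
            compare_groups(values, labels)

    @pytest.mark.parametrize("sampler", ["normal", "lognormal"])
    def test_type_one_error_calibrated(self, sampler):
        """Rejection rate at alpha=0.05 stays in [0.035, 0.065] under the null."""
        rng = np.random.default_rng(11 if sampler == "normal" else 12)
        draw = rng.normal if sampler == "normal" else rng.lognormal
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            values, labels = self._series(draw(0, 1, 30), draw(0, 1, 30))
            if compare_groups(values, labels).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_rep <= 0.065
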