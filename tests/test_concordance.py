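"""Slope extraction, the pairwise concordance index, group averaging,
knowledge cosine similarity, and the surrogate-p identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from physiosync import (ConfigError, KnowledgeVector, PhysioRecording,
                        SlopeSeries, cosine_similarity, group_similarity,
                        knowledge_similarity, one_sample_test, pair_concordance,
                        rolling_slopes, surrogate_p)
from physiosync.concordance import DEFAULT_EPS, participant_means_from_pairs


def brute_force_index(a, b, w=15, eps=DEFAULT_EPS):
    """Window-enumeration oracle: Pearson r by definition per window."""
    pos = neg = 0.0
    for i in range(len(a) - w + 1):
        xa, xb = a[i:i + w], b[i:i + w]
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            continue
        r = stats.pearsonr(xa, xb)[0]
        if r > 0:
            pos += r
        elif r < 0:
            neg += -r
    return np.log((pos + eps) / (neg + eps))


def _slopes(values, pid="p"):
    return SlopeSeries(pid, "SC", np.asarray(values, float))


class TestRollingSlopes:
    def test_linear_signal_recovers_its_slope(self):
        rate = 250.0
        t = np.arange(0, 30, 1 / rate)
        rec = PhysioRecording("p", "SC", rate, 3.0 * t)
        s = rolling_slopes(rec)
        assert s.values.size == 26
        np.testing.assert_allclose(s.values, 3.0, atol=1e-9)

    def test_constant_signal_gives_zero_slopes(self):
        rec = PhysioRecording("p", "SC", 250.0, np.full(2500, 4.2))
        np.testing.assert_allclose(rolling_slopes(rec).values, 0.0, atol=1e-12)

    def test_five_point_toy_matches_normal_equations_oracle(self):
        y = np.array([2.0, 4.0, 3.0, 8.0, 6.0])
        rec = PhysioRecording("p", "SC", 1.0, y)
        got = rolling_slopes(rec, window_s=5, step_s=1).values
        expected = np.polyfit(np.arange(5.0), y, 1)[0]
        assert got.size == 1
        assert got[0] == pytest.approx(expected, abs=1e-12)

    def test_endpoint_method(self):
        y = np.array([0.0, 10.0, 0.0, 0.0, 20.0])
        rec = PhysioRecording("p", "SC", 1.0, y)
        got = rolling_slopes(rec, method="endpoint").values
        assert got[0] == pytest.approx(20.0 / 4.0)

    def test_short_recording_rejected(self):
        rec = PhysioRecording("p", "SC", 250.0, np.zeros(1000))
        with pytest.raises(ConfigError, match="shorter"):
            rolling_slopes(rec)


class TestPairConcordance:
    def test_identical_series_hit_the_upper_bound(self, rng):
        a = _slopes(np.cumsum(rng.normal(0, 1, 40)), "a")
        b = _slopes(a.values.copy(), "b")
        res = pair_concordance(a, b)
        n = 40 - 15 + 1
        assert res.n_windows == n and res.n_skipped == 0
        assert res.index == pytest.approx(np.log((n + DEFAULT_EPS) / DEFAULT_EPS))

    def test_half_positive_half_negative_cancels_to_zero(self):
        # with 2-slope windows every r is exactly +-1; b rises then falls
        a = _slopes([0.0, 1.0, 2.0, 3.0, 4.0], "a")
        b = _slopes([0.0, 1.0, 2.0, 1.0, 0.0], "b")
        res = pair_concordance(a, b, corr_window=2)
        assert res.index == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [20, 40, 60])
    def test_matches_brute_force_oracle(self, n, rng):
        a = _slopes(np.cumsum(rng.normal(0, 1, n)), "a")
        b = _slopes(0.3 * a.values + np.cumsum(rng.normal(0, 1, n)), "b")
        res = pair_concordance(a, b)
        assert res.index == pytest.approx(brute_force_index(a.values, b.values),
                                          abs=1e-10)

    def test_antisymmetry_under_negation_is_exact(self, rng):
        a = _slopes(rng.normal(0, 1, 50), "a")
        b = _slopes(rng.normal(0, 1, 50), "b")
        neg_b = _slopes(-b.values, "b")
        assert pair_concordance(a, neg_b).index == pytest.approx(
            -pair_concordance(a, b).index, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a = _slopes(rng.normal(0, 1, 30), "a")
        b = _slopes(rng.normal(0, 1, 30), "b")
        assert pair_concordance(a, b).index == pair_concordance(b, a).index

    def test_zero_variance_windows_are_skipped_and_counted(self):
        a = np.concatenate([np.zeros(20), np.cumsum(np.ones(20))])
        b = np.concatenate([np.zeros(20), np.cumsum(np.full(20, 2.0))])
        res = pair_concordance(_slopes(a, "a"), _slopes(b, "b"))
        assert res.n_skipped > 0
        assert res.n_windows + res.n_skipped == a.size - 15 + 1

    def test_overlap_shorter_than_window_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            pair_concordance(_slopes(np.arange(10.0)), _slopes(np.arange(10.0)))

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_property(self, seed):
        r = np.random.default_rng(seed)
        a = _slopes(r.normal(0, 1, 25), "a")
        b = _slopes(r.normal(0, 1, 25), "b")
        assert pair_concordance(a, b).index == pytest.approx(
            -pair_concordance(a, _slopes(-b.values, "b")).index, abs=1e-12)


class TestGroupSimilarity:
    def test_two_participants_share_the_single_pair_index(self, rng):
        a = _slopes(rng.normal(0, 1, 30), "a")
        b = _slopes(rng.normal(0, 1, 30), "b")
        table, parts = group_similarity([a, b])
        assert len(table) == 1
        assert parts[0].value == parts[1].value == pytest.approx(table["index"][0])

    def test_hand_set_pair_table_means(self):
        table = pd.DataFrame({
            "id_a": ["a", "a", "b"], "id_b": ["b", "c", "c"],
            "index": [0.2, 0.4, -0.1],
        })
        means = participant_means_from_pairs(table)
        assert means["a"] == pytest.approx(0.3)
        assert means["b"] == pytest.approx(0.05)
        assert means["c"] == pytest.approx(0.15)

    def test_group_of_24_yields_276_pairs(self, rng):
        slopes = [_slopes(rng.normal(0, 1, 20), f"p{i}") for i in range(24)]
        table, parts = group_similarity(slopes)
        assert len(table) == 276 and len(parts) == 24

    def test_group_of_one_rejected(self, rng):
        with pytest.raises(ConfigError):
            group_similarity([_slopes(rng.normal(0, 1, 20))])


class TestOneSampleTest:
    def test_matches_textbook_formula(self):
        vals = np.array([0.2, 0.5, 0.8, 0.5])
        t, p = one_sample_test(vals)
        se = vals.std(ddof=1) / 2.0
        assert t == pytest.approx(vals.mean() / se)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 3))

    def test_symmetric_values_give_zero_t(self):
        t, _ = one_sample_test(np.array([-0.4, -0.1, 0.1, 0.4]))
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_single_value_rejected(self):
        with pytest.raises(ConfigError):
            one_sample_test(np.array([0.5]))


class TestSurrogateP:
    def test_observed_equal_to_null_mean_gives_one(self):
        assert surrogate_p(5.0, 5.0, 2.0) == pytest.approx(1.0)

    def test_one_sigma_matches_two_sided_normal_tail(self):
        # |s - mu0| = sigma0 -> erfc(1/sqrt(2)) = 2*(1 - Phi(1)) ~ 0.3173
        assert surrogate_p(6.0, 5.0, 1.0) == pytest.approx(0.3173105079, abs=1e-9)
        assert surrogate_p(6.0, 5.0, 1.0) == pytest.approx(
            2 * stats.norm.sf(1.0), abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ConfigError):
            surrogate_p(1.0, 0.0, 0.0)


class TestKnowledgeSimilarity:
    def _vec(self, pid, answers, test="analytical", phase="pre"):
        return KnowledgeVector(pid, test, phase, np.array(answers))

    def test_identical_vectors_cosine_one(self):
        v = [1, 0, 1, 0, 1, 0, 1, 0, 1, 0]
        assert cosine_similarity(np.array(v), np.array(v)) == pytest.approx(1.0)

    def test_disjoint_support_cosine_zero(self):
        x = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        assert cosine_similarity(x, y) == pytest.approx(0.0)

    def test_partial_overlap_half(self):
        x = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        y = np.array([1, 0, 1, 0, 0, 0, 0, 0, 0, 0])
        assert cosine_similarity(x, y) == pytest.approx(0.5)

    def test_per_participant_means(self):
        vecs = [
            self._vec("a", [1] * 10),
            self._vec("b", [1] * 10),
            self._vec("c", [1] * 5 + [0] * 5),
        ]
        sim = knowledge_similarity(vecs)
        ac = np.sqrt(0.5)
        assert sim["a"] == pytest.approx((1.0 + ac) / 2)
        assert sim["c"] == pytest.approx(ac)

    def test_zero_norm_vector_excluded(self):
        vecs = [
            self._vec("a", [1] * 10),
            self._vec("b", [1] * 10),
            self._vec("z", [0] * 10),
        ]
        sim = knowledge_similarity(vecs)
        assert sim["a"] == pytest.approx(1.0)
        assert np.isnan(sim["z"])
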