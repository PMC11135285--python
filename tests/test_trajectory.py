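"""Relative change, group curves, attention flags and the amyloid cutoff."""

import numpy as np
import pytest

from trajgru.trajectory import (
    FLAG_NONE,
    FLAG_ORANGE,
    FLAG_RED,
    GroupError,
    attention_summary,
    derive_amyloid_cutoff,
    group_trajectories,
    normalize_signed,
    relative_change,
    threshold_map,
)


class TestRelativeChange:
    def test_constant_trajectory_is_zero(self):
        y = np.full((2, 3, 4), 5.0)
        rc = relative_change(y)
        assert np.all(rc.s_raw == 0) and np.all(rc.s_norm == 0)

    def test_quarter_decline(self):
        y = np.array([[[2.0, 1.5]]])
        rc = relative_change(y)
        assert np.isclose(rc.s_raw[0, 0, 1], -0.25)

    def test_zero_baseline_rejected(self):
        y = np.ones((1, 1, 2))
        y[0, 0, 0] = 0.0
        with pytest.raises(ZeroDivisionError):
            relative_change(y)

    def test_normalization_maps_extremes_to_unit(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(4, 5, 3))
        out = normalize_signed(s)
        assert np.isclose(out.min(), -1.0) and np.isclose(out.max(), 1.0)
        assert np.all(np.sign(out) == np.sign(s))

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(1, 3, size=(3, 4, 5))
        a = threshold_map(relative_change(y).s_norm)
        b = threshold_map(relative_change(y * 7.5).s_norm)
        assert np.array_equal(a, b)


class TestThresholdMap:
    def test_below_threshold_empty(self):
        assert threshold_map(np.full((2, 2), 0.2)).sum() == 0

    def test_boundary_value_flagged(self):
        assert threshold_map(np.array([[-0.25]]))[0, 0] == 1

    def test_counts_match_loop_oracle(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(-1, 1, size=(3, 4, 5))
        count = sum(
            1
            for i in range(3)
            for j in range(4)
            for k in range(5)
            if abs(s[i, j, k]) >= 0.25
        )
        assert threshold_map(s).sum() == count


class TestGroupTrajectories:
    def _data(self):
        rng = np.random.default_rng(3)
        truth = rng.normal(size=(6, 2, 4))
        mask = np.ones_like(truth)
        labels = np.array([0, 0, 0, 1, 1, 1])
        return truth, mask, labels

    def test_perfect_predictions_give_rho_one(self):
        truth, mask, labels = self._data()
        out = group_trajectories(truth, truth[:, :, 1:], mask, labels)
        assert np.isclose(out["abeta_neg"]["rho_mean"], 1.0)
        assert np.isclose(out["abeta_pos"]["rho_mean"], 1.0)

    def test_anticorrelated_predictions_give_rho_minus_one(self):
        truth, mask, labels = self._data()
        pred = -truth[:, :, 1:] + 3.0
        out = group_trajectories(truth, pred, mask, labels)
        assert np.isclose(out["abeta_neg"]["rho_mean"], -1.0)

    def test_missing_group_rejected(self):
        truth, mask, _ = self._data()
        with pytest.raises(GroupError):
            group_trajectories(truth, truth[:, :, 1:], mask, np.zeros(6, dtype=int))

    def test_subjects_without_enough_points_excluded(self):
        truth, mask, labels = self._data()
        mask[0, :, 1:] = 0  # no observed targets for subject 0
        out = group_trajectories(truth, truth[:, :, 1:], mask, labels)
        assert out["abeta_neg"]["n_excluded"] == 1


class TestAttentionSummary:
    def _attention(self, series):
        """One-cell-controlled attention stack: (N=2, T, B=2, B=2)."""
        t = len(series)
        att = np.zeros((2, t, 2, 2))
        rng = np.random.default_rng(0)
        base = rng.uniform(0.2, 0.8, size=(t, 2, 2))
        base[:, 0, 0] = series
        base[:, 1, 1] = 0.0  # pins per-slice min
        base[:, 0, 1] = 1.0  # pins per-slice max: normalization is identity
        att[0] = base
        att[1] = base
        return att

    def test_constant_series_unflagged(self):
        att = self._attention([0.4, 0.4, 0.4])
        labels = np.array([0, 1])
        summ = attention_summary(att, labels)
        assert (summ.flags["abeta_neg"][:, 0, 0] == FLAG_NONE).all()

    def test_rising_cell_gets_red_flag(self):
        summ = attention_summary(self._attention([0.10, 0.35]), np.array([0, 1]))
        assert summ.flags["abeta_pos"][1, 0, 0] == FLAG_RED

    def test_orange_boundary_cases(self):
        flags_hit = attention_summary(self._attention([0.30, 0.24]), np.array([0, 1]))
        assert flags_hit.flags["abeta_neg"][1, 0, 0] == FLAG_ORANGE
        flags_miss = attention_summary(self._attention([0.30, 0.27]), np.array([0, 1]))
        assert flags_miss.flags["abeta_neg"][1, 0, 0] == FLAG_NONE

    def test_maps_normalized_per_time_slice(self):
        summ = attention_summary(self._attention([0.3, 0.5, 0.2]), np.array([0, 1]))
        for m in summ.maps.values():
            for t in range(m.shape[0]):
                assert np.isclose(m[t].min(), 0.0) and np.isclose(m[t].max(), 1.0)

    def test_flags_stable_under_subject_relabeling(self):
        rng = np.random.default_rng(5)
        att = rng.uniform(size=(6, 3, 4, 4))
        labels = np.array([0, 0, 0, 1, 1, 1])
        a = attention_summary(att, labels)
        perm = np.array([2, 0, 1, 5, 3, 4])  # permutes within groups
        b = attention_summary(att[perm], labels[perm])
        assert np.array_equal(a.flags["abeta_neg"], b.flags["abeta_neg"])
        assert np.array_equal(a.flags["abeta_pos"], b.flags["abeta_pos"])

    def test_single_time_point_rejected(self):
        with pytest.raises(ValueError):
            attention_summary(np.ones((2, 1, 3, 3)), np.array([0, 1]))


class TestAmyloidCutoff:
    def test_obvious_partition_and_cutoff_formula(self):
        vals = [0.0, 1.0, 2.0, 100.0, 101.0, 102.0]
        out = derive_amyloid_cutoff(vals)
        assert list(out["lower"]) == [0.0, 1.0, 2.0]
        assert np.isclose(out["cutoff"], 1.0 + 2.0 * np.std([0, 1, 2], ddof=1))

    def test_matches_brute_force_sse_minimum(self):
        rng = np.random.default_rng(7)
        vals = np.sort(np.concatenate([rng.normal(5, 2, 40), rng.normal(60, 10, 30)]))
        out = derive_amyloid_cutoff(vals)
        best = min(
            (
                ((vals[:s] - vals[:s].mean()) ** 2).sum()
                + ((vals[s:] - vals[s:].mean()) ** 2).sum(),
                s,
            )
            for s in range(1, len(vals))
        )
        assert len(out["lower"]) == best[1]
        assert np.isclose(out["split_sse"], best[0])

    def test_degenerate_identical_values_warn(self):
        with pytest.warns(UserWarning):
            out = derive_amyloid_cutoff([5.0, 5.0, 5.0])
        assert out["cutoff"] == 5.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            derive_amyloid_cutoff([1.0])
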