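"""Cohort container, CSV round-trip, delta recurrence and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trajgru.cohort import (
    DegenerateFeatureError,
    IntegrityError,
    Normalizer,
    build_delta,
    load_cohort,
    write_cohort,
)
from trajgru.schema import SchemaError

from conftest import make_cohort_csv


def delta_oracle(mask, times):
    """Per-cell loop unrolling of the delay recurrence."""
    out = np.zeros_like(mask, dtype=float)
    for b in range(mask.shape[0]):
        for t in range(1, mask.shape[1]):
            gap = times[t] - times[t - 1]
            out[b, t] = gap + (0.0 if mask[b, t - 1] == 1 else out[b, t - 1])
    return out


class TestBuildDelta:
    def test_fully_observed_annual(self):
        delta = build_delta(np.array([[1, 1, 1]]), np.arange(3.0))
        assert np.array_equal(delta, [[0, 1, 1]])

    def test_gap_accumulates_across_missing_run(self):
        delta = build_delta(np.array([[1, 0, 0, 1]]), np.arange(4.0))
        assert np.array_equal(delta, [[0, 1, 2, 3]])

    def test_non_annual_gaps(self):
        delta = build_delta(np.array([[1, 0, 1]]), np.array([0.0, 1.5, 2.0]))
        assert np.allclose(delta, [[0, 1.5, 2.0]])

    def test_non_monotone_times_rejected(self):
        with pytest.raises(IntegrityError):
            build_delta(np.ones((1, 3)), np.array([0.0, 2.0, 1.0]))

    @settings(deadline=None, max_examples=40)
    @given(st.data())
    def test_matches_loop_oracle(self, data):
        b = data.draw(st.integers(1, 10))
        t = data.draw(st.integers(2, 6))
        mask = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(0, 1), min_size=t, max_size=t),
                    min_size=b,
                    max_size=b,
                )
            ),
            dtype=float,
        )
        gaps = np.array(data.draw(st.lists(st.floats(0.1, 3.0), min_size=t - 1, max_size=t - 1)))
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        assert np.allclose(build_delta(mask, times), delta_oracle(mask, times))


class TestLoadCohort:
    def test_complete_file_has_full_mask(self, tmp_path, schema):
        path = make_cohort_csv(tmp_path / "c.csv", schema)
        cohort = load_cohort(path, schema)
        assert cohort.mask.all()
        assert cohort.n_subjects == 2 and cohort.n_visits == 3

    def test_blank_cell_sets_mask_and_delta(self, tmp_path, schema):
        path = make_cohort_csv(tmp_path / "c.csv", schema, blank={(0, "kmmse", 1)})
        cohort = load_cohort(path, schema)
        fi = schema.index("kmmse")
        si = list(cohort.subject_ids).index("S0")
        assert cohort.mask[si, fi, 1] == 0
        # delay at visit 3 (1-based) spans the 2 years since visit 1
        assert cohort.delta[si, fi, 2] == 2.0

    def test_demographics_duplicated_and_age_incremented(self, tmp_path, schema):
        path = make_cohort_csv(
            tmp_path / "c.csv", schema, blank={(0, "education", 1), (0, "education", 2)}
        )
        cohort = load_cohort(path, schema)
        fi = schema.index("education")
        assert cohort.mask[:, fi, :].all()
        ai = schema.index("age")
        si = list(cohort.subject_ids).index("S0")
        assert np.allclose(np.diff(cohort.values[si, ai, :]), 1.0)

    def test_unknown_column_rejected(self, tmp_path, schema):
        path = make_cohort_csv(tmp_path / "c.csv", schema)
        df = pd.read_csv(path)
        df["mystery"] = 1.0
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError):
            load_cohort(path, schema)

    def test_duplicate_visit_rejected(self, tmp_path, schema):
        path = make_cohort_csv(tmp_path / "c.csv", schema)
        df = pd.read_csv(path)
        df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        df.to_csv(path, index=False)
        with pytest.raises(IntegrityError):
            load_cohort(path, schema)

    def test_missing_baseline_rejected(self, tmp_path, schema):
        path = make_cohort_csv(tmp_path / "c.csv", schema)
        df = pd.read_csv(path)
        df = df[~((df.subject_id == "S1") & (df.visit_year == 0))]
        df.to_csv(path, index=False)
        with pytest.raises(IntegrityError):
            load_cohort(path, schema)

    def test_round_trip(self, tmp_path, schema):
        path = make_cohort_csv(tmp_path / "c.csv", schema, blank={(1, "dsf", 2)})
        cohort = load_cohort(path, schema)
        out = tmp_path / "out.csv"
        write_cohort(cohort, out)
        back = load_cohort(out, schema)
        assert np.array_equal(back.mask, cohort.mask)
        obs = cohort.mask == 1
        assert np.allclose(back.values[obs], cohort.values[obs])


class TestNormalizer:
    def test_minmax_arithmetic(self, small_cohort):
        norm = Normalizer.fit(small_cohort, np.arange(small_cohort.n_subjects))
        normed = norm.apply(small_cohort)
        obs = small_cohort.mask == 1
        assert np.nanmin(normed.values[obs]) >= 0
        assert np.nanmax(normed.values[obs]) <= 1

    def test_round_trip_identity(self, small_cohort):
        norm = Normalizer.fit(small_cohort, np.arange(small_cohort.n_subjects))
        x = small_cohort.values
        back = norm.invert_values(norm.apply_values(x))
        obs = small_cohort.mask == 1
        assert np.allclose(back[obs], x[obs], atol=1e-10)

    def test_out_of_range_value_allowed(self):
        norm = Normalizer(np.array([2.0]), np.array([6.0]), ["f"])
        out = norm.apply_values(np.array([[[8.0]]]))
        assert np.isclose(out[0, 0, 0], 1.5)

    def test_constant_feature_named_in_error(self, small_cohort):
        cohort = small_cohort.subset(np.arange(small_cohort.n_subjects))
        fi = cohort.schema.index("kmmse")
        cohort.values[:, fi, :] = 5.0
        with pytest.raises(DegenerateFeatureError, match="kmmse"):
            Normalizer.fit(cohort, np.arange(cohort.n_subjects))

    def test_statistics_from_train_split_only(self, small_cohort):
        train = np.arange(10)
        norm_a = Normalizer.fit(small_cohort, train)
        mutated = small_cohort.subset(np.arange(small_cohort.n_subjects))
        mutated.values[20:] *= 3.0
        norm_b = Normalizer.fit(mutated, train)
        assert np.array_equal(norm_a.minimum, norm_b.minimum)
        assert np.array_equal(norm_a.maximum, norm_b.maximum)

    def test_json_round_trip(self, tmp_path, small_cohort):
        norm = Normalizer.fit(small_cohort, np.arange(5))
        norm.to_json(tmp_path / "n.json")
        back = Normalizer.from_json(tmp_path / "n.json")
        assert np.array_equal(back.minimum, norm.minimum)
        assert back.names == norm.names
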