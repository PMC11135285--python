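"""Longitudinal cohort container, CSV I/O, time-delay tensors and scaling.

Data layout follows the multivariate-panel convention: ``values`` is an
``N x B x T`` array (subjects x features x visits) with NaN marking
unobserved cells, ``mask`` the parallel 0/1 observation indicator and
``delta`` the elapsed years since each feature was last observed — the
time-delay matrix consumed by the decay-based imputation and by the
temporal decay factor of the recurrent module.

All code must consult ``mask``, never the NaN sentinel, to decide
observedness; NaN is purely a file-level convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .schema import DEMOGRAPHIC_ROLES, FeatureSchema, SchemaError, default_schema

logger = logging.getLogger(__name__)

LABELS = ("abeta_neg", "abeta_pos")


class IntegrityError(ValueError):
    """Raised when cohort data violates structural invariants."""


class DegenerateFeatureError(ValueError):
    """Raised when a feature has no usable variation in the training split."""


@dataclass
class LongitudinalCohort:
    """Aligned value/mask/delta tensors for N subjects x B features x T visits.

    ``labels`` holds the amyloid group per subject (0 = abeta_neg,
    1 = abeta_pos); ``visit_times`` the visit offsets in years from baseline
    (shared grid, shape ``(T,)``). Visits are indexed 1..T in interfaces and
    logs; arrays are 0-based internally.
    """

    values: np.ndarray  # (N, B, T), NaN where unobserved
    mask: np.ndarray  # (N, B, T), 1 = directly observed
    delta: np.ndarray  # (N, B, T), years since last observation
    labels: np.ndarray  # (N,), int 0/1
    schema: FeatureSchema
    visit_times: np.ndarray  # (T,), years from baseline
    subject_ids: np.ndarray  # (N,), str

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_visits(self) -> int:
        return self.values.shape[2]

    def validate(self) -> None:
        n, b, t = self.values.shape
        if self.mask.shape != (n, b, t) or self.delta.shape != (n, b, t):
            raise IntegrityError("values/mask/delta shapes disagree")
        if t < 2:
            raise IntegrityError("cohort must have at least 2 visits")
        if np.any(~np.isfinite(self.values[self.mask == 1])):
            raise IntegrityError("mask=1 cell holds a non-finite value")
        if np.any(self.delta[:, :, 0] != 0):
            raise IntegrityError("delta must be 0 at the baseline visit")
        demo = self.schema.demographic_indices
        if demo and np.any(self.mask[:, demo, 0] != 1):
            raise IntegrityError("baseline demographics must be observed")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise IntegrityError("labels must be 0 (abeta_neg) or 1 (abeta_pos)")

    def subset(self, subject_idx) -> "LongitudinalCohort":
        """Row-subset by positional subject indices (copying)."""
        idx = np.asarray(subject_idx)
        return replace(
            self,
            values=self.values[idx].copy(),
            mask=self.mask[idx].copy(),
            delta=self.delta[idx].copy(),
            labels=self.labels[idx].copy(),
            subject_ids=self.subject_ids[idx].copy(),
        )


def build_delta(mask: np.ndarray, visit_times: np.ndarray) -> np.ndarray:
    """Time-delay tensor: years since each feature was last observed.

    ``delta[..., 0] = 0``; for t > 1 the gap to the previous visit is added,
    plus the previous delay if the feature was unobserved there:

        delta[b, t] = gap(t-1, t) + (0 if mask[b, t-1] else delta[b, t-1])

    Accepts mask of shape (..., T) with a shared visit grid of shape (T,).
    """
    mask = np.asarray(mask, dtype=float)
    visit_times = np.asarray(visit_times, dtype=float)
    if mask.shape[-1] != visit_times.shape[-1]:
        raise IntegrityError("mask and visit_times disagree on T")
    gaps = np.diff(visit_times)
    if np.any(gaps <= 0):
        raise IntegrityError("visit times must be strictly increasing")
    delta = np.zeros_like(mask, dtype=float)
    for t in range(1, mask.shape[-1]):
        delta[..., t] = gaps[t - 1] + np.where(
            mask[..., t - 1] == 1, 0.0, delta[..., t - 1]
        )
    return delta


def load_cohort(path, schema: FeatureSchema | None = None) -> LongitudinalCohort:
    """Read a long-format cohort CSV (one row per subject-visit).

    Required columns: ``subject_id``, ``visit_year``, ``label`` and one
    column per schema feature. Subjects are sorted by id and visits aligned
    to the sorted union of visit years; a subject's absent rows become fully
    unobserved visits. Demographics other than age are duplicated forward
    from baseline; age is incremented by the visit offset.
    """
    schema = schema or default_schema()
    df = pd.read_csv(path)
    required = {"subject_id", "visit_year", "label"}
    missing_cols = (required | set(schema.names)) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"missing columns: {sorted(missing_cols)}")
    unknown = set(df.columns) - required - set(schema.names)
    if unknown:
        raise SchemaError(f"unknown columns: {sorted(unknown)}")
    if np.any(df["visit_year"].to_numpy() < 0):
        raise IntegrityError("visit_year values must be nonnegative")
    if df.duplicated(["subject_id", "visit_year"]).any():
        dup = df[df.duplicated(["subject_id", "visit_year"])].iloc[0]
        raise IntegrityError(
            f"duplicate (subject, visit): ({dup['subject_id']}, {dup['visit_year']})"
        )

    grid = np.sort(df["visit_year"].unique().astype(float))
    t_index = {v: i for i, v in enumerate(grid)}
    subjects = np.sort(df["subject_id"].astype(str).unique())
    n, b, t = len(subjects), schema.n_features, len(grid)
    if t < 2:
        raise IntegrityError("cohort must contain at least 2 visit times")

    values = np.full((n, b, t), np.nan)
    mask = np.zeros((n, b, t))
    labels = np.zeros(n, dtype=int)
    label_to_int = {name: i for i, name in enumerate(LABELS)}

    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    for si, sid in enumerate(subjects):
        rows = df[df["subject_id"] == sid]
        if float(rows["visit_year"].min()) != grid[0]:
            raise IntegrityError(f"subject {sid} has no baseline visit")
        lab = rows["label"].iloc[0]
        if lab not in label_to_int:
            raise IntegrityError(f"unknown label {lab!r} for subject {sid}")
        labels[si] = label_to_int[lab]
        for _, row in rows.iterrows():
            ti = t_index[float(row["visit_year"])]
            for fi, fname in enumerate(schema.names):
                v = row[fname]
                if pd.notna(v):
                    values[si, fi, ti] = float(v)
                    mask[si, fi, ti] = 1.0

    # demographics: duplicated across visits from baseline, age incremented
    for fi, role in zip(range(b), schema.roles):
        if role not in DEMOGRAPHIC_ROLES:
            continue
        base = values[:, fi, 0]
        if np.any(np.isnan(base)):
            bad = subjects[np.isnan(base)][0]
            raise IntegrityError(
                f"subject {bad} lacks baseline value for {schema.names[fi]}"
            )
        if role == "demographic_age":
            values[:, fi, :] = base[:, None] + (grid - grid[0])[None, :]
        else:
            values[:, fi, :] = base[:, None]
        mask[:, fi, :] = 1.0

    delta = build_delta(mask, grid)
    cohort = LongitudinalCohort(
        values=values,
        mask=mask,
        delta=delta,
        labels=labels,
        schema=schema,
        visit_times=grid,
        subject_ids=subjects,
    )
    cohort.validate()
    return cohort


def write_cohort(cohort: LongitudinalCohort, path) -> None:
    """Write the cohort back to the long-format CSV dialect of load_cohort."""
    rows = []
    for si in range(cohort.n_subjects):
        for ti in range(cohort.n_visits):
            row = {
                "subject_id": cohort.subject_ids[si],
                "visit_year": cohort.visit_times[ti],
                "label": LABELS[cohort.labels[si]],
            }
            for fi, name in enumerate(cohort.schema.names):
                row[name] = (
                    cohort.values[si, fi, ti]
                    if cohort.mask[si, fi, ti] == 1
                    else np.nan
                )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


class Normalizer:
    """Per-feature min-max scaling to [0, 1], fit on training subjects only.

    Statistics come exclusively from observed (mask=1) cells of the training
    subset, so no information leaks from validation or test splits.
    Out-of-range values on other splits are allowed (and counted in the log).
    """

    def __init__(self, minimum: np.ndarray, maximum: np.ndarray, names: list[str]):
        self.minimum = np.asarray(minimum, dtype=float)
        self.maximum = np.asarray(maximum, dtype=float)
        self.names = list(names)
        if np.any(self.maximum < self.minimum):
            raise ValueError("max < min in normalization state")

    @classmethod
    def fit(cls, cohort: LongitudinalCohort, train_idx) -> "Normalizer":
        train_idx = np.asarray(train_idx)
        if train_idx.size == 0:
            raise ValueError("training subset must be nonempty")
        vals = cohort.values[train_idx]
        msk = cohort.mask[train_idx]
        lo = np.empty(cohort.n_features)
        hi = np.empty(cohort.n_features)
        for fi, name in enumerate(cohort.schema.names):
            obs = vals[:, fi, :][msk[:, fi, :] == 1]
            if obs.size == 0 or np.nanmin(obs) == np.nanmax(obs):
                raise DegenerateFeatureError(
                    f"feature {name!r} constant or unobserved in training split"
                )
            lo[fi], hi[fi] = obs.min(), obs.max()
        return cls(lo, hi, list(cohort.schema.names))

    def apply_values(self, values: np.ndarray) -> np.ndarray:
        """Normalize an (N, B, T) value tensor (NaNs pass through)."""
        span = (self.maximum - self.minimum)[None, :, None]
        out = (values - self.minimum[None, :, None]) / span
        n_out = np.sum((out < 0) | (out > 1))
        if n_out:
            logger.info("normalization produced %d out-of-[0,1] cells", int(n_out))
        return out

    def invert_values(self, values: np.ndarray) -> np.ndarray:
        span = (self.maximum - self.minimum)[None, :, None]
        return values * span + self.minimum[None, :, None]

    def apply(self, cohort: LongitudinalCohort) -> LongitudinalCohort:
        return replace(cohort, values=self.apply_values(cohort.values))

    # -- serialization --------------------------------------------------------

    def to_json(self, path) -> None:
        state = {
            "method": "minmax",
            "features": self.names,
            "minimum": self.minimum.tolist(),
            "maximum": self.maximum.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(state, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Normalizer":
        with open(path) as fh:
            state = json.load(fh)
        return cls(state["minimum"], state["maximum"], state["features"])
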