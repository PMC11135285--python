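"""Decay-weighted imputation of missing observations.

A missing cell is filled with a convex combination of the subject's most
recent observation of that feature and the feature's training-split mean,

    x_hat = gamma * last_observed + (1 - gamma) * train_mean,
    gamma = exp(-max(0, w * delta + b)),

where ``delta`` is the time (years) since the feature was last observed.
Fresh gaps (small delta) trust the carried-forward observation; stale gaps
relax toward the population mean. The mask is left untouched: imputed cells
keep mask = 0 so the recurrent module knows which inputs were observed and
which were reconstructed. With no prior observation the cell falls back to
the training mean.

Decay parameters default to (w=1, b=0) per feature; they may also be
learned jointly with the network (see :mod:`trajgru.network`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import DegenerateFeatureError, LongitudinalCohort


@dataclass
class DecayParams:
    """Input-level (per-feature) decay weights; decay(delta=0) = 1 when b <= 0."""

    weight: np.ndarray  # (B,)
    bias: np.ndarray  # (B,)

    @classmethod
    def fixed(cls, n_features: int, weight: float = 1.0, bias: float = 0.0) -> "DecayParams":
        return cls(
            weight=np.full(n_features, float(weight)),
            bias=np.full(n_features, float(bias)),
        )


def compute_decay(delta: np.ndarray, weight, bias) -> np.ndarray:
    """Elementwise ``exp(-max(0, w*delta + b))`` — always in (0, 1]."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("delta must be nonnegative")
    return np.exp(-np.maximum(0.0, weight * delta + bias))


def train_feature_means(cohort: LongitudinalCohort, train_idx) -> np.ndarray:
    """Per-feature mean over observed cells of the training subjects only."""
    train_idx = np.asarray(train_idx)
    vals = cohort.values[train_idx]
    msk = cohort.mask[train_idx]
    means = np.empty(cohort.n_features)
    for fi, name in enumerate(cohort.schema.names):
        obs = vals[:, fi, :][msk[:, fi, :] == 1]
        if obs.size == 0:
            raise DegenerateFeatureError(
                f"feature {name!r} entirely missing in training split"
            )
        means[fi] = obs.mean()
    return means


def impute(
    cohort: LongitudinalCohort,
    params: DecayParams,
    train_means: np.ndarray,
) -> np.ndarray:
    """Completed (N, B, T) value tensor; observed cells pass through unchanged.

    Idempotent and convex: every imputed value lies between the subject's
    last observation of the feature and the training mean (inclusive).
    """
    n, b, t = cohort.values.shape
    out = np.where(cohort.mask == 1, cohort.values, 0.0)
    last = np.full((n, b), np.nan)  # most recent observed value per feature
    for ti in range(t):
        obs = cohort.mask[:, :, ti] == 1
        gamma = compute_decay(
            cohort.delta[:, :, ti], params.weight[None, :], params.bias[None, :]
        )
        carried = np.where(
            np.isnan(last),
            train_means[None, :],
            gamma * np.where(np.isnan(last), 0.0, last)
            + (1.0 - gamma) * train_means[None, :],
        )
        out[:, :, ti] = np.where(obs, out[:, :, ti], carried)
        last = np.where(obs, cohort.values[:, :, ti], last)
    return out


def mean_fill(cohort: LongitudinalCohort, train_means: np.ndarray) -> np.ndarray:
    """Training-mean imputation (the GRU-M baseline's filling rule)."""
    return np.where(
        cohort.mask == 1, cohort.values, train_means[None, :, None]
    )
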