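"""Trajectory and attention interpretation analyses.

* Relative change of MRI markers against baseline,
  ``s[i, t] = (y[i, t] - y[i, 0]) / y[i, 0]``, computed separately for
  observed and predicted trajectories, then min-max normalized to [-1, 1]
  (negative values scaled by |tensor min|, positive by tensor max, so both
  extremes map exactly to +/-1 and sign — atrophy vs growth — is preserved);
  a threshold (default 0.25) flags cells with substantial change.

* Group trajectory summaries: per-feature mean observed and predicted
  curves per amyloid group, and the mean per-subject Pearson correlation
  between observed and predicted series.

* Attention interpretation: group-averaged attention maps per time
  sequence, normalized to [0, 1] per time slice, with orange/red flags for
  cells whose weight drifts from the first observation (decrease > 0.05 /
  increase > 0.2 over time).

* The amyloid Centiloid cutoff: exact two-cluster 1-D K-means (sorted-sweep
  minimization of within-cluster SSE, deterministic) with the cutoff set to
  mean + 2 sd of the lower cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

FLAG_NONE, FLAG_ORANGE, FLAG_RED = 0, 1, 2


class GroupError(ValueError):
    pass


# -- relative change ----------------------------------------------------------


@dataclass
class RelativeChange:
    s_raw: np.ndarray  # (N, M, T) relative change vs baseline
    s_norm: np.ndarray  # same, normalized to [-1, 1]


def relative_change(y: np.ndarray, y0: np.ndarray | None = None) -> RelativeChange:
    """Relative change vs baseline for an (N, M, T) trajectory tensor.

    ``y0`` defaults to ``y[:, :, 0]``. Baselines must be nonzero.
    """
    y = np.asarray(y, dtype=float)
    y0 = y[:, :, 0] if y0 is None else np.asarray(y0, dtype=float)
    if np.any(y0 == 0):
        i, m = np.argwhere(y0 == 0)[0]
        raise ZeroDivisionError(f"zero baseline for subject {i}, marker {m}")
    s = (y - y0[:, :, None]) / y0[:, :, None]
    return RelativeChange(s_raw=s, s_norm=normalize_signed(s))


def normalize_signed(s: np.ndarray) -> np.ndarray:
    """Map a tensor into [-1, 1] preserving sign: negatives scaled by
    |min|, positives by max (extremes land exactly on -1 / +1)."""
    s = np.asarray(s, dtype=float)
    lo, hi = np.nanmin(s), np.nanmax(s)
    out = np.zeros_like(s)
    if lo < 0:
        out = np.where(s < 0, s / abs(lo), out)
    if hi > 0:
        out = np.where(s > 0, s / hi, out)
    return out


def threshold_map(s_norm: np.ndarray, tau: float = 0.25) -> np.ndarray:
    """Binary map of cells with |s| >= tau (boundary value is flagged)."""
    return (np.abs(np.asarray(s_norm)) >= tau).astype(int)


# -- group trajectories -------------------------------------------------------


def group_trajectories(
    truth: np.ndarray,
    pred: np.ndarray,
    mask: np.ndarray,
    labels: np.ndarray,
) -> dict:
    """Mean observed/predicted curves and mean per-subject Pearson rho per group.

    ``truth``/``mask`` are (N, F, T); ``pred`` is (N, F, T-1) (visits 2..T).
    The per-subject correlation uses visits 2..T where the truth is
    observed; subjects with < 2 such points are excluded (count reported).
    """
    labels = np.asarray(labels)
    out = {}
    for g, gname in enumerate(("abeta_neg", "abeta_pos")):
        rows = np.where(labels == g)[0]
        if rows.size == 0:
            raise GroupError(f"group {gname} absent")
        msk = mask[rows]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            obs_curve = np.nanmean(
                np.where(msk == 1, truth[rows], np.nan), axis=0
            )  # (F, T)
            pred_curve = np.nanmean(
                np.where(msk[:, :, 1:] == 1, pred[rows], np.nan), axis=0
            )  # (F, T-1)
        rhos, excluded = [], 0
        for i in rows:
            sel = mask[i, :, 1:] == 1
            t_obs = truth[i, :, 1:][sel]
            p_obs = pred[i][sel]
            if len(t_obs) < 2 or np.std(t_obs) == 0 or np.std(p_obs) == 0:
                excluded += 1
                continue
            rhos.append(sps.pearsonr(t_obs, p_obs).statistic)
        out[gname] = {
            "observed_curve": obs_curve,
            "predicted_curve": pred_curve,
            "rho_mean": float(np.mean(rhos)) if rhos else np.nan,
            "n_excluded": excluded,
        }
    return out


# -- attention interpretation -------------------------------------------------


@dataclass
class AttentionSummary:
    """Per-group time-normalized attention maps and drift flags."""

    maps: dict  # group -> (T', B', B') in [0, 1] per time slice
    flags: dict  # group -> (T', B', B') with FLAG_* codes


def attention_summary(
    attention: np.ndarray,
    labels: np.ndarray,
    thresholds: tuple[float, float] = (0.05, 0.2),
) -> AttentionSummary:
    """Group-average attention maps with drift flags.

    ``attention`` is (N, T', B', B') per-subject maps (one per consumed
    visit). Per group: average over subjects, min-max normalize each time
    slice to [0, 1], then flag each cell's time series against its first
    observation: orange when the value decreased by more than
    ``thresholds[0]`` and the series decreases over time (last <= first
    with at least one strict drop), red when it increased by more than
    ``thresholds[1]`` and the series increases over time.
    """
    attention = np.asarray(attention)
    if attention.shape[1] < 2:
        raise ValueError("need at least two time sequences to assess drift")
    orange_thr, red_thr = thresholds
    labels = np.asarray(labels)
    maps, flags = {}, {}
    for g, gname in enumerate(("abeta_neg", "abeta_pos")):
        rows = np.where(labels == g)[0]
        if rows.size == 0:
            raise GroupError(f"group {gname} absent")
        avg = attention[rows].mean(axis=0)  # (T', B', B')
        norm = np.empty_like(avg)
        for t in range(avg.shape[0]):
            lo, hi = avg[t].min(), avg[t].max()
            norm[t] = (avg[t] - lo) / (hi - lo) if hi > lo else 0.0
        fl = np.zeros_like(norm, dtype=int)
        first = norm[0]
        t_axis = norm.shape[0]
        decreasing = (norm[-1] <= first) & np.any(np.diff(norm, axis=0) < 0, axis=0)
        increasing = (norm[-1] >= first) & np.any(np.diff(norm, axis=0) > 0, axis=0)
        for t in range(1, t_axis):
            fl[t][(first - norm[t] > orange_thr) & decreasing] = FLAG_ORANGE
            fl[t][(norm[t] - first > red_thr) & increasing] = FLAG_RED
        maps[gname], flags[gname] = norm, fl
    return AttentionSummary(maps=maps, flags=flags)


# -- amyloid cutoff -----------------------------------------------------------


def derive_amyloid_cutoff(centiloid_values) -> dict:
    """Exact 1-D two-cluster K-means on Centiloid values plus the cutoff.

    The optimal 2-means partition of sorted 1-D data is a contiguous split;
    the sweep minimizes within-cluster SSE over all split points
    (deterministic, no Lloyd iteration). The cutoff is mean + 2 sd (sample
    sd) of the lower cluster. Degenerate data (all values equal) warns and
    returns the midpoint.
    """
    vals = np.sort(np.asarray(centiloid_values, dtype=float))
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 values")
    if vals[0] == vals[-1]:
        warnings.warn("all Centiloid values identical; cutoff set to midpoint")
        return {
            "cutoff": float(vals[0]),
            "lower": vals,
            "upper": np.array([]),
            "split_sse": 0.0,
        }
    csum = np.cumsum(vals)
    csq = np.cumsum(vals**2)

    def sse(lo, hi):  # [lo, hi) half-open on sorted values
        k = hi - lo
        s = csum[hi - 1] - (csum[lo - 1] if lo else 0.0)
        s2 = csq[hi - 1] - (csq[lo - 1] if lo else 0.0)
        return s2 - s * s / k

    best_split, best = None, np.inf
    for split in range(1, n):
        total = sse(0, split) + sse(split, n)
        if total < best - 1e-12:
            best, best_split = total, split
    lower, upper = vals[:best_split], vals[best_split:]
    sd = lower.std(ddof=1) if len(lower) > 1 else 0.0
    return {
        "cutoff": float(lower.mean() + 2.0 * sd),
        "lower": lower,
        "upper": upper,
        "split_sse": float(best),
    }
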