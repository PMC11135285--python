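"""Forecast-quality metrics, the paired Wilcoxon test, the GRU-M ablation
baseline and the downstream amyloid-positivity classification scenarios.

Prediction metrics (MAE, MAPE, R^2) are computed per feature over observed
target cells only, in normalized feature space. MAPE excludes cells whose
true value is below ``MAPE_EPS`` in magnitude (several cognitive scores
normalize near zero); the exclusion count is reported so feature-wise
comparability stays auditable.

The downstream task predicts amyloid-group membership with an RBF-kernel
SVM under three input scenarios: baseline visit only, longitudinal data
with missing cells mean-filled, and longitudinal data with decay-imputed
inputs plus the network's predicted next-visit features. The Centiloid
feature is withheld from all classifier inputs: the group label is derived
from Centiloid, so feeding it to the classifier is circular and saturates
every scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import LongitudinalCohort, Normalizer
from .imputation import mean_fill, train_feature_means
from .schema import FeatureSchema
from .training import FittedModel, TrainConfig, train

MAPE_EPS = 1e-8

SCENARIOS = ("baseline_only", "longitudinal_missing", "longitudinal_imputed")


class UndefinedMetricError(ValueError):
    pass


class DegenerateTestError(ValueError):
    pass


# -- regression metrics -------------------------------------------------------


def feature_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    """MAE, MAPE and R^2 for one feature's observed cells (1-D arrays)."""
    err = np.abs(pred - truth)
    mae = float(err.mean())
    usable = np.abs(truth) > MAPE_EPS
    mape = float((err[usable] / np.abs(truth[usable])).mean()) if usable.any() else np.nan
    sst = float(((truth - truth.mean()) ** 2).sum())
    if sst == 0:
        raise UndefinedMetricError("zero-variance truth: R^2 undefined")
    sse = float(((pred - truth) ** 2).sum())
    return {
        "mae": mae,
        "mape": mape,
        "r2": 1.0 - sse / sst,
        "mape_excluded": int((~usable).sum()),
    }


def regression_metrics(preds: dict, schema: FeatureSchema) -> pd.DataFrame:
    """Per-feature metric table from a :meth:`FittedModel.predict` result."""
    rows = []
    blocks = [
        ("mri", schema.mri_names, preds["pred_m"], preds["truth_m"], preds["mask_m"]),
        ("cognitive", schema.cognitive_names, preds["pred_c"], preds["truth_c"], preds["mask_c"]),
    ]
    for role, names, pred, truth, mask in blocks:
        for fi, name in enumerate(names):
            sel = mask[:, :, fi] == 1
            if sel.sum() < 2:
                raise UndefinedMetricError(f"fewer than 2 observed targets for {name}")
            m = feature_metrics(pred[:, :, fi][sel], truth[:, :, fi][sel])
            rows.append({"feature": name, "role": role, **m})
    return pd.DataFrame(rows)


# -- paired Wilcoxon signed-rank test -----------------------------------------


def paired_wilcoxon(a, b) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test; returns (W+, p).

    Zero differences are dropped (Wilcoxon convention), ties midranked.
    The null distribution is exact (sign-flip enumeration via dynamic
    programming) for n <= 25 usable pairs, and a normal approximation with
    continuity and tie corrections above.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 5:
        raise ValueError("need equal-length 1-D samples with n >= 5")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= 25:
        # doubled ranks are integers even with midranks
        r2 = np.rint(2 * ranks).astype(int)
        total = r2.sum()
        # DP over the distribution of doubled W+ under random signs
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: counts.size - r]
            counts = counts + shifted
        counts /= 2.0**n
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum()
        p_ge = counts[w2:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_plus, float(p)

    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    cc = 0.5 * np.sign(w_plus - mean)
    z = (w_plus - mean - cc) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return w_plus, float(min(1.0, p))


# -- GRU-M ablation baseline --------------------------------------------------


def gru_m_baseline(
    cohort: LongitudinalCohort,
    config: TrainConfig,
    train_idx,
    val_idx,
    **hyper,
) -> FittedModel:
    """Training-mean imputation + standard GRU (no attention, no decay).

    Identical protocol and input width (mask still appended) so any
    performance gap is attributable to attention/decay/imputation.
    """
    return train(cohort, config, train_idx, val_idx, model="gru_m", **hyper)


# -- downstream amyloid-positivity classification ------------------------------


@dataclass
class ClassificationReport:
    scenario: str
    accuracy: float
    sensitivity: float  # recall of abeta_pos
    specificity: float  # recall of abeta_neg
    auc: float
    chosen_c: float


def _scenario_features(
    cohort: LongitudinalCohort,
    scenario: str,
    train_idx: np.ndarray,
    fitted: FittedModel | None,
) -> np.ndarray:
    """Per-subject classifier inputs (Centiloid withheld, see module docs)."""
    sch = cohort.schema
    keep = [
        i
        for i in range(sch.n_features)
        if sch.roles[i] != "centiloid"
    ]
    if scenario == "baseline_only":
        normalizer = Normalizer.fit(cohort, train_idx)
        normed = normalizer.apply(cohort)
        base = np.where(normed.mask[:, :, 0] == 1, normed.values[:, :, 0], np.nan)
        means = train_feature_means(normed, train_idx)
        filled = np.where(np.isnan(base), means[None, :], base)
        return filled[:, keep]
    if scenario == "longitudinal_missing":
        normalizer = Normalizer.fit(cohort, train_idx)
        normed = normalizer.apply(cohort)
        means = train_feature_means(normed, train_idx)
        filled = mean_fill(normed, means)
        return filled[:, keep, :].reshape(cohort.n_subjects, -1)
    if scenario == "longitudinal_imputed":
        if fitted is None:
            raise ValueError("longitudinal_imputed needs a trained model")
        prep = fitted.prepare(cohort)
        inputs = np.concatenate(
            [prep.x_core, prep.demo], axis=-1
        ).reshape(cohort.n_subjects, -1)
        # drop the centiloid column from the core block at every visit
        core_names = sch.core_names
        demo_n = len(sch.demographic_indices)
        width = len(core_names) + demo_n
        cl_pos = core_names.index("centiloid")
        cols = [
            ti * width + j
            for ti in range(cohort.n_visits)
            for j in range(width)
            if j != cl_pos
        ]
        inputs = inputs[:, cols]
        preds = fitted.predict(cohort)
        pred_feats = np.concatenate(
            [
                preds["pred_m"].reshape(cohort.n_subjects, -1),
                preds["pred_c"].reshape(cohort.n_subjects, -1),
            ],
            axis=1,
        )
        return np.concatenate([inputs, pred_feats], axis=1)
    raise ValueError(f"unknown scenario {scenario!r}")


def downstream_classification(
    cohort: LongitudinalCohort,
    scenario: str,
    train_idx,
    test_idx,
    fitted: FittedModel | None = None,
    c_grid=(0.1, 1.0, 10.0),
    seed: int = 0,
) -> ClassificationReport:
    """Fit the scenario SVM on ``train_idx`` subjects, report on ``test_idx``.

    The RBF-kernel regularization constant is chosen by inner 3-fold
    stratified CV on the training subjects (AUC criterion); AUC is the rank
    statistic over decision scores.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    y = cohort.labels
    if len(np.unique(y[test_idx])) < 2:
        raise ValueError("test split contains a single class")
    X = _scenario_features(cohort, scenario, train_idx, fitted)
    scaler = StandardScaler().fit(X[train_idx])
    Xs = scaler.transform(X)

    best_c, best_score = None, -np.inf
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    for c in c_grid:
        scores = []
        for tr, va in inner.split(Xs[train_idx], y[train_idx]):
            clf = SVC(kernel="rbf", C=c)
            clf.fit(Xs[train_idx][tr], y[train_idx][tr])
            if len(np.unique(y[train_idx][va])) < 2:
                continue
            scores.append(
                roc_auc_score(y[train_idx][va], clf.decision_function(Xs[train_idx][va]))
            )
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score:
            best_score, best_c = score, c

    clf = SVC(kernel="rbf", C=best_c)
    clf.fit(Xs[train_idx], y[train_idx])
    pred = clf.predict(Xs[test_idx])
    scores = clf.decision_function(Xs[test_idx])
    yt = y[test_idx]
    return ClassificationReport(
        scenario=scenario,
        accuracy=float((pred == yt).mean()),
        sensitivity=float((pred[yt == 1] == 1).mean()),
        specificity=float((pred[yt == 0] == 0).mean()),
        auc=float(roc_auc_score(yt, scores)),
        chosen_c=float(best_c),
    )
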