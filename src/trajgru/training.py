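"""Composite-loss optimization, grid search and cross-validation.

The training objective is the weighted sum of two masked mean-squared
errors — MRI markers and cognitive scores —

    L_total = alpha * L_m + gamma * L_c,     alpha = 0.75, gamma = 1.0,

where each L is averaged over target cells that were *truly observed*
(mask = 1): predictions at imputed targets carry no loss, so the model
never chases its own imputations. The written losses are means rather than
raw sums so alpha/gamma keep their meaning across cohort sizes.

The evaluation protocol is five-fold cross-validation with five
repetitions: per repetition the subjects of each amyloid class are
partitioned into five folds; each fold serves once as the test set, a
validation split (10% per class) is drawn from the remaining folds, and the
rest trains the model. Early stopping returns the parameters of the epoch
with minimal validation loss.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .cohort import LongitudinalCohort, Normalizer
from .imputation import DecayParams, impute, mean_fill, train_feature_means
from .network import Dims, ModelParams, forward_sequence, init_params


class UndefinedLossError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


class SplitError(ValueError):
    pass


@dataclass
class TrainConfig:
    alpha: float = 0.75
    gamma: float = 1.0
    lr_grid: tuple = (5e-5, 1e-4, 1e-3, 1e-2)
    layer_grid: tuple = (1, 2, 3)
    hidden_grid: tuple = (16, 32, 48, 64, 80, 96)
    l2_grid: tuple = (1e-6, 1e-5, 1e-4, 1e-3)
    # fixed hyperparameters used when grid search is off
    lr: float = 1e-2
    ffn_layers: int = 1
    hidden: int = 48
    l2: float = 1e-5
    max_epochs: int = 300
    patience: int = 20
    batch_size: int | None = None  # None = full batch
    optimizer: str = "adam"  # "adam" (default, fast) or "sgd" (fidelity)
    loss: str = "mse"  # or "mae"
    seed: int = 0
    folds: int = 5
    repetitions: int = 5
    val_fraction: float = 0.10
    test_fraction: float = 0.10
    do_grid_search: bool = False

    def __post_init__(self):
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.val_fraction + self.test_fraction >= 1:
            raise ValueError("val + test fractions must sum below 1")
        if not (self.lr_grid and self.layer_grid and self.hidden_grid and self.l2_grid):
            raise ValueError("hyperparameter grids must be nonempty")


# -- losses -------------------------------------------------------------------


def masked_mse(pred, truth: np.ndarray, mask: np.ndarray):
    """Mean squared error over cells with mask = 1 (observed targets).

    ``pred`` may be a Tensor (differentiable path) or ndarray.
    """
    mask = np.asarray(mask, dtype=float)
    count = mask.sum()
    if count == 0:
        raise UndefinedLossError("no observed target cells")
    if isinstance(pred, Tensor):
        diff = pred - Tensor(truth)
        return (diff * diff * Tensor(mask)).sum() * (1.0 / count)
    return float((((pred - truth) ** 2) * mask).sum() / count)


def masked_mae(pred, truth: np.ndarray, mask: np.ndarray):
    """Mean absolute error over observed cells (alternative objective)."""
    from .autodiff import absolute

    mask = np.asarray(mask, dtype=float)
    count = mask.sum()
    if count == 0:
        raise UndefinedLossError("no observed target cells")
    if isinstance(pred, Tensor):
        return (absolute(pred - Tensor(truth)) * Tensor(mask)).sum() * (1.0 / count)
    return float(((np.abs(pred - truth)) * mask).sum() / count)


def total_loss(l_m, l_c, alpha: float, gamma: float):
    """L_total = alpha * L_m + gamma * L_c."""
    return l_m * alpha + l_c * gamma


# -- input preparation --------------------------------------------------------


@dataclass
class PreparedInputs:
    """Model-ready arrays: (N, T, B') inputs and (N, T-1, k) targets."""

    x_core: np.ndarray
    demo: np.ndarray
    mask_core: np.ndarray
    delta_core: np.ndarray
    truth_m: np.ndarray
    mask_m: np.ndarray
    truth_c: np.ndarray
    mask_c: np.ndarray


def prepare_inputs(
    cohort: LongitudinalCohort,
    normalizer: Normalizer,
    train_means_norm: np.ndarray,
    decay: DecayParams,
    imputation: str = "decay",
) -> PreparedInputs:
    """Normalize, impute and lay out tensors for the network.

    ``imputation`` is "decay" (the data-driven rule) or "mean" (GRU-M).
    Targets are the *observed* normalized values at visits 2..T; their masks
    restrict the loss and metrics to truly observed cells.
    """
    normed = normalizer.apply(cohort)
    if imputation == "decay":
        completed = impute(normed, decay, train_means_norm)
    elif imputation == "mean":
        completed = mean_fill(normed, train_means_norm)
    else:
        raise ValueError(f"unknown imputation mode {imputation!r}")

    sch = cohort.schema
    core, demo_i = sch.core_indices, sch.demographic_indices
    mri, cog = sch.indices_for("mri"), sch.indices_for("cognitive")

    def to_ntb(arr, idx):
        return np.transpose(arr[:, idx, :], (0, 2, 1))  # (N, B, T) -> (N, T, B)

    truth = np.where(normed.mask == 1, normed.values, 0.0)
    return PreparedInputs(
        x_core=to_ntb(completed, core),
        demo=to_ntb(completed, demo_i),
        mask_core=to_ntb(cohort.mask, core),
        delta_core=to_ntb(cohort.delta, core),
        truth_m=to_ntb(truth, mri)[:, 1:, :],
        mask_m=to_ntb(cohort.mask, mri)[:, 1:, :],
        truth_c=to_ntb(truth, cog)[:, 1:, :],
        mask_c=to_ntb(cohort.mask, cog)[:, 1:, :],
    )


@dataclass
class FittedModel:
    """Trained parameters together with the training-split preprocessing."""

    params: ModelParams
    normalizer: Normalizer
    train_means_norm: np.ndarray
    decay: DecayParams
    imputation: str
    config: TrainConfig
    history: dict = field(default_factory=dict)

    def prepare(self, cohort: LongitudinalCohort) -> PreparedInputs:
        return prepare_inputs(
            cohort, self.normalizer, self.train_means_norm, self.decay, self.imputation
        )

    def predict(self, cohort: LongitudinalCohort) -> dict:
        """Teacher-forced next-visit predictions for every subject."""
        prep = self.prepare(cohort)
        out = forward_sequence(
            prep.x_core, prep.demo, prep.mask_core, prep.delta_core, self.params
        )
        return {
            "pred_m": out["pred_m"].data,
            "pred_c": out["pred_c"].data,
            "truth_m": prep.truth_m,
            "mask_m": prep.mask_m,
            "truth_c": prep.truth_c,
            "mask_c": prep.mask_c,
            "attention": (
                np.stack([a.data for a in out["attention"]], axis=1)
                if out["attention"] is not None
                else None
            ),
        }


# -- optimizers ---------------------------------------------------------------


class _Adam:
    def __init__(self, tensors, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.tensors = tensors
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(t.data) for t in tensors]
        self.v = [np.zeros_like(t.data) for t in tensors]
        self.t = 0

    def step(self):
        self.t += 1
        for i, tensor in enumerate(self.tensors):
            g = tensor.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            tensor.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, tensors, lr):
        self.tensors = tensors
        self.lr = lr

    def step(self):
        for t in self.tensors:
            if t.grad is not None:
                t.data -= self.lr * t.grad


# -- training loop ------------------------------------------------------------


def _epoch_loss(prep: PreparedInputs, params: ModelParams, config: TrainConfig, l2: float):
    out = forward_sequence(prep.x_core, prep.demo, prep.mask_core, prep.delta_core, params)
    loss_fn = masked_mse if config.loss == "mse" else masked_mae
    l_m = loss_fn(out["pred_m"], prep.truth_m, prep.mask_m)
    l_c = loss_fn(out["pred_c"], prep.truth_c, prep.mask_c)
    loss = total_loss(l_m, l_c, config.alpha, config.gamma)
    if l2 > 0:
        reg = None
        for _, t in params.tensors():
            term = (t * t).sum()
            reg = term if reg is None else reg + term
        loss = loss + reg * l2
    return loss, float(l_m.data), float(l_c.data)


def _val_loss(prep: PreparedInputs, params: ModelParams, config: TrainConfig) -> float:
    out = forward_sequence(prep.x_core, prep.demo, prep.mask_core, prep.delta_core, params)
    loss_fn = masked_mse if config.loss == "mse" else masked_mae
    l_m = loss_fn(out["pred_m"].data, prep.truth_m, prep.mask_m)
    l_c = loss_fn(out["pred_c"].data, prep.truth_c, prep.mask_c)
    return float(total_loss(l_m, l_c, config.alpha, config.gamma))


def train(
    cohort: LongitudinalCohort,
    config: TrainConfig,
    train_idx,
    val_idx,
    lr: float | None = None,
    ffn_layers: int | None = None,
    hidden: int | None = None,
    l2: float | None = None,
    model: str = "full",
    use_attention: bool | None = None,
    use_decay: bool | None = None,
    imputation: str | None = None,
) -> FittedModel:
    """Fit the network (or the GRU-M baseline with ``model='gru_m'``).

    Deterministic under a fixed config seed and single-threaded execution.
    Returns the parameters of the epoch with minimal validation loss.
    """
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if np.intersect1d(train_idx, val_idx).size:
        raise SplitError("train and validation subjects overlap")
    lr = config.lr if lr is None else lr
    ffn_layers = config.ffn_layers if ffn_layers is None else ffn_layers
    hidden = config.hidden if hidden is None else hidden
    l2 = config.l2 if l2 is None else l2

    sch = cohort.schema
    normalizer = Normalizer.fit(cohort, train_idx)
    normed = normalizer.apply(cohort)
    means_norm = train_feature_means(normed, train_idx)
    decay = DecayParams.fixed(cohort.n_features)
    if imputation is None:
        imputation = "decay" if model == "full" else "mean"
    if use_attention is None:
        use_attention = model == "full"
    if use_decay is None:
        use_decay = model == "full"

    dims = Dims(
        b_core=sch.n_core,
        n_demo=len(sch.demographic_indices),
        hidden=hidden,
        n_mri=sch.role_count("mri"),
        n_cog=sch.role_count("cognitive"),
    )
    params = init_params(
        dims,
        ffn_layers=ffn_layers,
        seed=config.seed,
        use_attention=use_attention,
        use_decay=use_decay,
    )

    fitted = FittedModel(
        params=params,
        normalizer=normalizer,
        train_means_norm=means_norm,
        decay=decay,
        imputation=imputation,
        config=config,
    )
    prep_train = fitted.prepare(cohort.subset(train_idx))
    prep_val = fitted.prepare(cohort.subset(val_idx))

    tensors = [t for _, t in params.tensors()]
    opt = _Adam(tensors, lr) if config.optimizer == "adam" else _SGD(tensors, lr)
    rng = np.random.default_rng(config.seed + 1)

    best_val = np.inf
    best_state = [t.data.copy() for t in tensors]
    best_epoch = -1
    bad_epochs = 0
    history = {"train": [], "val": []}

    n_train = len(train_idx)
    for epoch in range(config.max_epochs):
        if config.batch_size is None or config.batch_size >= n_train:
            batches = [np.arange(n_train)]
        else:
            order = rng.permutation(n_train)
            batches = np.array_split(order, int(np.ceil(n_train / config.batch_size)))
        epoch_train = 0.0
        for batch in batches:
            sub = PreparedInputs(
                x_core=prep_train.x_core[batch],
                demo=prep_train.demo[batch],
                mask_core=prep_train.mask_core[batch],
                delta_core=prep_train.delta_core[batch],
                truth_m=prep_train.truth_m[batch],
                mask_m=prep_train.mask_m[batch],
                truth_c=prep_train.truth_c[batch],
                mask_c=prep_train.mask_c[batch],
            )
            params.zero_grad()
            loss, l_m, l_c = _epoch_loss(sub, params, config, l2)
            # invariant: the scalar stepped on decomposes as alpha*L_m + gamma*L_c (+ l2)
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"loss became non-finite at epoch {epoch} (lr={lr}, hidden={hidden})"
                )
            loss.backward()
            opt.step()
            epoch_train += float(loss.data) * len(batch)
        history["train"].append(epoch_train / n_train)

        vloss = _val_loss(prep_val, params, config)
        history["val"].append(vloss)
        if vloss < best_val - 1e-12:
            best_val = vloss
            best_state = [t.data.copy() for t in tensors]
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break

    for t, s in zip(tensors, best_state):
        t.data = s
    fitted.history = {**history, "best_epoch": best_epoch, "best_val": best_val}
    return fitted


# -- grid search --------------------------------------------------------------


def grid_search(
    cohort: LongitudinalCohort,
    config: TrainConfig,
    train_idx,
    val_idx,
    model: str = "full",
) -> tuple[dict, list[dict]]:
    """Exhaustive Cartesian search over the four hyperparameter grids.

    Selection key is validation loss; ties break toward the smaller model
    (fewer hidden units, then fewer layers, then larger l2). Diverged trials
    score infinity.
    """
    trials = []
    for lr, layers, hidden, l2 in itertools.product(
        config.lr_grid, config.layer_grid, config.hidden_grid, config.l2_grid
    ):
        try:
            fitted = train(
                cohort, config, train_idx, val_idx,
                lr=lr, ffn_layers=layers, hidden=hidden, l2=l2, model=model,
            )
            score = fitted.history["best_val"]
        except DivergenceError:
            score = np.inf
        trials.append(
            {"lr": lr, "layers": layers, "hidden": hidden, "l2": l2, "val_loss": score}
        )
    best = min(
        trials,
        key=lambda tr: (tr["val_loss"], tr["hidden"], tr["layers"], -tr["l2"]),
    )
    return best, trials


# -- cross-validation ---------------------------------------------------------


@dataclass
class FoldResult:
    fold: int
    repetition: int
    hyperparameters: dict
    metrics: "object"  # pandas DataFrame: one row per feature
    history: dict
    test_idx: np.ndarray


def stratified_splits(labels: np.ndarray, config: TrainConfig, seed: int):
    """Yield (train_idx, val_idx, test_idx) for folds x repetitions.

    Per repetition each class is shuffled and partitioned into ``folds``
    folds; fold k is the test set (so every subject tests exactly once per
    repetition), and a class-stratified ``val_fraction`` of the remainder
    forms the validation set.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    for c in classes:
        if (labels == c).sum() < config.folds:
            raise SplitError(f"class {c} has fewer subjects than folds")
    for rep in range(config.repetitions):
        rng = np.random.default_rng(seed + 1000 * rep)
        class_folds = {}
        for c in classes:
            idx = rng.permutation(np.where(labels == c)[0])
            class_folds[c] = np.array_split(idx, config.folds)
        for k in range(config.folds):
            test, val, trainset = [], [], []
            for c in classes:
                test.append(class_folds[c][k])
                rest = np.concatenate(
                    [class_folds[c][j] for j in range(config.folds) if j != k]
                )
                n_val = max(1, round(config.val_fraction * (labels == c).sum()))
                val.append(rest[:n_val])
                trainset.append(rest[n_val:])
            yield (
                rep,
                k,
                np.sort(np.concatenate(trainset)),
                np.sort(np.concatenate(val)),
                np.sort(np.concatenate(test)),
            )


def cross_validate(
    cohort: LongitudinalCohort,
    config: TrainConfig,
    model: str = "full",
) -> list[FoldResult]:
    """folds x repetitions results (25 for the default 5 x 5 protocol)."""
    from .evaluation import regression_metrics

    results = []
    for rep, k, tr, va, te in stratified_splits(cohort.labels, config, config.seed):
        if config.do_grid_search:
            best, _ = grid_search(cohort, config, tr, va, model=model)
            hyper = {kk: best[kk] for kk in ("lr", "layers", "hidden", "l2")}
            fitted = train(
                cohort, config, tr, va,
                lr=hyper["lr"], ffn_layers=hyper["layers"],
                hidden=hyper["hidden"], l2=hyper["l2"], model=model,
            )
        else:
            hyper = {
                "lr": config.lr, "layers": config.ffn_layers,
                "hidden": config.hidden, "l2": config.l2,
            }
            fitted = train(cohort, config, tr, va, model=model)
        preds = fitted.predict(cohort.subset(te))
        metrics = regression_metrics(preds, cohort.schema)
        results.append(
            FoldResult(
                fold=k, repetition=rep, hyperparameters=hyper,
                metrics=metrics, history=fitted.history, test_idx=te,
            )
        )
    return results


def aggregate_fold_metrics(results: list[FoldResult]):
    """Mean +/- sd of each metric per feature across folds (long DataFrame)."""
    import pandas as pd

    frames = []
    for r in results:
        df = r.metrics.copy()
        df["fold"] = r.fold
        df["repetition"] = r.repetition
        frames.append(df)
    allm = pd.concat(frames, ignore_index=True)
    agg = (
        allm.groupby("feature")[["mae", "mape", "r2"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    agg.columns = ["feature"] + [f"{m}_{s}" for m, s in agg.columns[1:]]
    return agg
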