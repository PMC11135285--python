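"""The forecasting network: attention fusion -> decay/mask GRU -> linear heads.

Three submodules process each visit of a subject:

* **Feature fusion (FRM)** — the B' core features (MRI markers, cognitive
  scores, APOE, Centiloid) of one visit are treated as B' scalar tokens.
  Query/key/value vectors ``q = x Wq``, ``k = x Wk``, ``v = x Wv`` are formed,
  the feature-by-feature attention matrix is ``A = softmax(q k^T / sqrt(B'))``
  (row-wise), and the attended vector ``A v`` is refined by a small
  feed-forward network and added back to ``x`` (residual). Demographics
  bypass the attention and are concatenated afterwards.

* **Temporal module (TRM)** — a GRU cell modified in two ways: the previous
  hidden state is attenuated elementwise by a temporal decay factor
  ``omega_t = exp(-max(0, W_d delta_t + b_d))`` driven by the per-feature
  time-delay vector, and the gate input is the fused feature vector
  concatenated with the observation mask ``n_t`` so the cell can discount
  imputed inputs:

      h~        = h_{t-1} * omega_t
      r_t       = sigmoid(W_r^i [x~_t, n_t] + b_r^i + W_r^h h~ + b_r^h)
      z_t       = sigmoid(W_z^i [x~_t, n_t] + b_z^i + W_z^h h~ + b_z^h)
      h'_t      = tanh(W_h^i [x~_t, n_t] + b_h^i + W_h^h (r_t * h~) + b_h^h)
      h_t       = (1 - z_t) * h~ + z_t * h'_t

* **Prediction heads (MPM)** — two affine maps from ``h_t`` to the next
  visit's 6 MRI markers and 9 cognitive scores (outputs live in normalized
  feature space; no activation).

Setting ``use_attention=False`` and ``use_decay=False`` yields the GRU-M
ablation baseline: raw (mean-filled) features plus demographics straight
into a standard GRU, mask still appended for input-width parity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class ShapeError(ValueError):
    pass


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


@dataclass
class FRMParams:
    """Square Q/K/V projections plus the post-attention FFN stack.

    The FFN has ``n_layers`` ReLU hidden layers followed by an affine
    output layer (all B' x B'), so its output is unconstrained in sign.
    """

    Wq: Tensor
    Wk: Tensor
    Wv: Tensor
    ffn: list  # (W, b) pairs; ReLU after all but the last

    @classmethod
    def init(cls, rng, b_core: int, n_layers: int = 1) -> "FRMParams":
        # the FFN output layer starts at zero so the residual fusion is the
        # identity at initialization; attention mixing is learned from there
        ffn = [(_glorot(rng, b_core, b_core), _zeros(b_core)) for _ in range(n_layers)]
        ffn.append((_zeros(b_core, b_core), _zeros(b_core)))
        return cls(
            Wq=_glorot(rng, b_core, b_core),
            Wk=_glorot(rng, b_core, b_core),
            Wv=_glorot(rng, b_core, b_core),
            ffn=ffn,
        )


@dataclass
class TRMParams:
    """Gate weights; each gate has an input-side and a hidden-side block."""

    Wri: Tensor
    Wrh: Tensor
    bri: Tensor
    brh: Tensor
    Wzi: Tensor
    Wzh: Tensor
    bzi: Tensor
    bzh: Tensor
    Whi: Tensor
    Whh: Tensor
    bhi: Tensor
    bhh: Tensor

    @classmethod
    def init(cls, rng, n_input: int, hidden: int) -> "TRMParams":
        def gate():
            return (
                _glorot(rng, n_input, hidden),
                _glorot(rng, hidden, hidden),
                _zeros(hidden),
                _zeros(hidden),
            )

        wri, wrh, bri, brh = gate()
        wzi, wzh, bzi, bzh = gate()
        whi, whh, bhi, bhh = gate()
        return cls(wri, wrh, bri, brh, wzi, wzh, bzi, bzh, whi, whh, bhi, bhh)


@dataclass
class MPMParams:
    """Affine heads for next-visit MRI markers (6) and cognitive scores (9)."""

    Wm: Tensor
    bm: Tensor
    Wc: Tensor
    bc: Tensor

    @classmethod
    def init(cls, rng, hidden: int, n_mri: int, n_cog: int) -> "MPMParams":
        return cls(
            Wm=_glorot(rng, hidden, n_mri),
            bm=_zeros(n_mri),
            Wc=_glorot(rng, hidden, n_cog),
            bc=_zeros(n_cog),
        )


@dataclass
class HiddenDecayParams:
    """Projection of the per-feature delay vector to the H-dim decay omega_t."""

    W: Tensor  # (B', H)
    b: Tensor  # (H,)

    @classmethod
    def init(cls, rng, b_core: int, hidden: int) -> "HiddenDecayParams":
        # near-neutral start: omega ~ 1 at init (plain-GRU regime) but the
        # pre-activation stays strictly positive so the decay is learnable
        return cls(
            W=Tensor(np.abs(rng.normal(0.0, 0.01, size=(b_core, hidden))), requires_grad=True),
            b=_zeros(hidden),
        )


@dataclass
class Dims:
    b_core: int
    n_demo: int
    hidden: int
    n_mri: int
    n_cog: int

    @property
    def gru_input(self) -> int:
        # fused features (B' + demographics) concatenated with the B' mask
        return self.b_core + self.n_demo + self.b_core


@dataclass
class ModelParams:
    """All learnable parameters plus the dimension record and ablation flags."""

    dims: Dims
    frm: FRMParams
    trm: TRMParams
    mpm: MPMParams
    hidden_decay: HiddenDecayParams
    use_attention: bool = True
    use_decay: bool = True
    extra: dict = field(default_factory=dict)

    def tensors(self) -> list[tuple[str, Tensor]]:
        out = []
        if self.use_attention:
            out += [("frm.Wq", self.frm.Wq), ("frm.Wk", self.frm.Wk), ("frm.Wv", self.frm.Wv)]
            for i, (w, b) in enumerate(self.frm.ffn):
                out += [(f"frm.ffn{i}.W", w), (f"frm.ffn{i}.b", b)]
        for name in (
            "Wri", "Wrh", "bri", "brh",
            "Wzi", "Wzh", "bzi", "bzh",
            "Whi", "Whh", "bhi", "bhh",
        ):
            out.append((f"trm.{name}", getattr(self.trm, name)))
        out += [
            ("mpm.Wm", self.mpm.Wm), ("mpm.bm", self.mpm.bm),
            ("mpm.Wc", self.mpm.Wc), ("mpm.bc", self.mpm.bc),
        ]
        if self.use_decay:
            out += [("decay.W", self.hidden_decay.W), ("decay.b", self.hidden_decay.b)]
        return out

    def zero_grad(self) -> None:
        for _, t in self.tensors():
            t.grad = None

    # -- serialization (JSON; text-only portable format) ----------------------

    def to_dict(self) -> dict:
        return {
            "dims": vars(self.dims),
            "use_attention": self.use_attention,
            "use_decay": self.use_decay,
            "params": {name: t.data.tolist() for name, t in self.tensors()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ModelParams":
        with open(path) as fh:
            d = json.load(fh)
        dims = Dims(**d["dims"])
        n_ffn = sum(1 for k in d["params"] if k.endswith(".W") and k.startswith("frm.ffn"))
        params = init_params(
            dims,
            ffn_layers=(n_ffn - 1) if n_ffn else 1,
            seed=0,
            use_attention=d["use_attention"],
            use_decay=d["use_decay"],
        )
        stored = d["params"]
        for name, t in params.tensors():
            arr = np.asarray(stored[name], dtype=float)
            if arr.shape != t.data.shape:
                raise ShapeError(f"stored {name} has shape {arr.shape}, expected {t.data.shape}")
            t.data = arr
        return params


def init_params(
    dims: Dims,
    ffn_layers: int = 1,
    seed: int = 0,
    use_attention: bool = True,
    use_decay: bool = True,
) -> ModelParams:
    rng = np.random.default_rng(seed)
    return ModelParams(
        dims=dims,
        frm=FRMParams.init(rng, dims.b_core, ffn_layers),
        trm=TRMParams.init(rng, dims.gru_input, dims.hidden),
        mpm=MPMParams.init(rng, dims.hidden, dims.n_mri, dims.n_cog),
        hidden_decay=HiddenDecayParams.init(rng, dims.b_core, dims.hidden),
        use_attention=use_attention,
        use_decay=use_decay,
    )


# -- forward operations -------------------------------------------------------


def fuse_features(x: Tensor, demo: Tensor, frm: FRMParams) -> tuple[Tensor, Tensor]:
    """Attention-fuse one visit's core features; returns (fused, A).

    ``x`` is (N, B'), ``demo`` (N, D); ``fused`` is (N, B'+D) and ``A`` the
    (N, B', B') row-stochastic feature-by-feature attention matrix.
    """
    n, b_core = x.shape
    if frm.Wq.shape != (b_core, b_core):
        raise ShapeError(f"Wq is {frm.Wq.shape}, expected {(b_core, b_core)}")
    q = x @ frm.Wq
    k = x @ frm.Wk
    v = x @ frm.Wv
    logits = q.reshape(n, b_core, 1) * k.reshape(n, 1, b_core) * (1.0 / np.sqrt(b_core))
    attn = ad.softmax(logits, axis=-1)
    av = (attn @ v.reshape(n, b_core, 1)).reshape(n, b_core)
    refined = av
    for li, (w, b) in enumerate(frm.ffn):
        refined = refined @ w + b
        if li < len(frm.ffn) - 1:
            refined = ad.relu(refined)
    fused = ad.concat([refined + x, demo], axis=-1)
    return fused, attn


def trm_step(
    h_prev: Tensor, omega: Tensor, x_fused: Tensor, n_t: Tensor, trm: TRMParams
) -> Tensor:
    """One decay/mask-modified GRU step (batched over subjects)."""
    if h_prev.shape[-1] != trm.Wrh.shape[0]:
        raise ShapeError("hidden size mismatch")
    g = ad.concat([x_fused, n_t], axis=-1)
    if g.shape[-1] != trm.Wri.shape[0]:
        raise ShapeError(
            f"gate input width {g.shape[-1]} != weight rows {trm.Wri.shape[0]}"
        )
    h_dec = h_prev * omega
    r = ad.sigmoid(g @ trm.Wri + trm.bri + h_dec @ trm.Wrh + trm.brh)
    z = ad.sigmoid(g @ trm.Wzi + trm.bzi + h_dec @ trm.Wzh + trm.bzh)
    h_cand = ad.tanh(g @ trm.Whi + trm.bhi + (r * h_dec) @ trm.Whh + trm.bhh)
    return (1.0 - z) * h_dec + z * h_cand


def predict_next(h: Tensor, mpm: MPMParams) -> tuple[Tensor, Tensor]:
    """Affine next-visit predictions (m_hat, c_hat) in normalized space."""
    return h @ mpm.Wm + mpm.bm, h @ mpm.Wc + mpm.bc


def hidden_decay_factor(delta_core: Tensor, params: ModelParams) -> Tensor:
    """omega_t = exp(-max(0, W_d delta_t + b_d)); ones when decay disabled."""
    if not params.use_decay:
        n = delta_core.shape[0]
        return Tensor(np.ones((n, params.dims.hidden)))
    pre = delta_core @ params.hidden_decay.W + params.hidden_decay.b
    return ad.exp(-ad.relu(pre))


class InsufficientHistoryError(ValueError):
    pass


def forward_sequence(
    x_core: np.ndarray,
    demo: np.ndarray,
    mask_core: np.ndarray,
    delta_core: np.ndarray,
    params: ModelParams,
) -> dict:
    """Teacher-forced pass over a batch of imputed visit sequences.

    Inputs are numpy arrays of shape (N, T, B') / (N, T, D); entry ``t``
    is consumed to emit the prediction for visit ``t+1`` (1-based visits
    2..T, i.e. T-1 prediction pairs). Returns Tensors: ``pred_m`` of shape
    (N, T-1, n_mri), ``pred_c`` (N, T-1, n_cog), plus per-step hidden states
    and attention maps (attention is None for the no-attention baseline).
    """
    n, t, _ = x_core.shape
    if t < 2:
        raise InsufficientHistoryError("need at least 2 visits to form a target")
    h = Tensor(np.zeros((n, params.dims.hidden)))
    preds_m, preds_c, hiddens, attns = [], [], [], []
    for ti in range(t - 1):
        h = _consume_visit(
            h,
            Tensor(x_core[:, ti]),
            Tensor(demo[:, ti]),
            Tensor(mask_core[:, ti]),
            Tensor(delta_core[:, ti]),
            params,
            attns,
        )
        m_hat, c_hat = predict_next(h, params.mpm)
        preds_m.append(m_hat.reshape(n, 1, params.dims.n_mri))
        preds_c.append(c_hat.reshape(n, 1, params.dims.n_cog))
        hiddens.append(h)
    return {
        "pred_m": ad.concat(preds_m, axis=1),
        "pred_c": ad.concat(preds_c, axis=1),
        "hidden": hiddens,
        "attention": attns if params.use_attention else None,
    }


def _consume_visit(h, x_t, demo_t, n_t, delta_t, params, attns: list) -> Tensor:
    if params.use_attention:
        fused, attn = fuse_features(x_t, demo_t, params.frm)
        attns.append(attn)
    else:
        fused = ad.concat([x_t, demo_t], axis=-1)
    omega = hidden_decay_factor(delta_t, params)
    return trm_step(h, omega, fused, n_t, params.trm)


def rollout(
    x_core: np.ndarray,
    demo: np.ndarray,
    mask_core: np.ndarray,
    delta_core: np.ndarray,
    params: ModelParams,
    horizon: int,
    schema_core_mri: list[int] | None = None,
    schema_core_cog: list[int] | None = None,
    age_index_in_demo: int = 0,
    age_step: float = 0.0,
    gap_years: float = 1.0,
) -> dict:
    """Autoregressive forecast beyond the observed history.

    The full history (all T visits) is consumed; each forecast step feeds
    the predicted MRI/cognitive values back as the next input with mask = 0
    (the cell treats them as imputed). Remaining core features (APOE,
    Centiloid) are carried forward, demographics are carried forward with
    age incremented by ``age_step`` per step (normalized units).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    n, t, b_core = x_core.shape
    mri_idx = schema_core_mri if schema_core_mri is not None else list(range(params.dims.n_mri))
    cog_idx = (
        schema_core_cog
        if schema_core_cog is not None
        else list(range(params.dims.n_mri, params.dims.n_mri + params.dims.n_cog))
    )

    h = Tensor(np.zeros((n, params.dims.hidden)))
    attns: list = []
    for ti in range(t):
        h = _consume_visit(
            h,
            Tensor(x_core[:, ti]),
            Tensor(demo[:, ti]),
            Tensor(mask_core[:, ti]),
            Tensor(delta_core[:, ti]),
            params,
            attns,
        )

    cur_x = x_core[:, -1].copy()
    cur_demo = demo[:, -1].copy()
    cur_mask = mask_core[:, -1].copy()
    cur_delta = delta_core[:, -1].copy()
    preds_m, preds_c = [], []
    for _step in range(horizon):
        m_hat, c_hat = predict_next(h, params.mpm)
        preds_m.append(m_hat.data.copy())
        preds_c.append(c_hat.data.copy())
        if _step == horizon - 1:
            break
        # feed predictions back as the next (model-generated) visit
        next_x = cur_x.copy()
        next_x[:, mri_idx] = m_hat.data
        next_x[:, cog_idx] = c_hat.data
        next_mask = cur_mask.copy()
        next_mask[:, mri_idx] = 0.0
        next_mask[:, cog_idx] = 0.0
        next_delta = gap_years + np.where(cur_mask == 1, 0.0, cur_delta)
        cur_demo = cur_demo.copy()
        cur_demo[:, age_index_in_demo] += age_step
        h = _consume_visit(
            h,
            Tensor(next_x),
            Tensor(cur_demo),
            Tensor(next_mask),
            Tensor(next_delta),
            params,
            attns,
        )
        cur_x, cur_mask, cur_delta = next_x, next_mask, next_delta
    return {
        "pred_m": np.stack(preds_m, axis=1),  # (N, horizon, n_mri)
        "pred_c": np.stack(preds_c, axis=1),
    }
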