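"""CNN-BiLSTM spirogram encoder with a COPD-probability head and
descending-limb saliency extraction.

A stack of 1-D convolution blocks (conv -> ReLU -> stride-2 average pool)
captures local flow-curve patterns and downsamples time by ``r`` = 2^blocks;
a bidirectional LSTM then models the temporal context, yielding per-curve
feature matrices of shape ceil(T_i / r) x D_feat with D_feat = 2 x
lstm_hidden.  A masked-mean pooling head with a logistic output provides the
COPD probability.  Curves are normalised per maneuver by their peak flow,
with a constant sampling-interval channel alongside.

Padding never leaks: activations beyond each curve's valid length are
zeroed after every convolution, pooling windows are anchored at the time
origin, and the reverse LSTM direction runs over each sequence's own valid
length.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .simulate import SpiroCurve

__all__ = [
    "EncoderConfig",
    "SpiroEncoder",
    "SaliencyMap",
    "encode",
    "classify",
    "train_encoder",
    "saliency",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class EncoderConfig:
    conv_channels: tuple = (32, 64, 64)
    kernel_sizes: tuple = (7, 5, 3)
    lstm_hidden: int = 64
    dropout: float = 0.0
    seed: int = 0
    # training
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 40
    patience: int = 5

    def __post_init__(self) -> None:
        if len(self.conv_channels) != len(self.kernel_sizes):
            raise ValueError("conv_channels and kernel_sizes must align")

    @property
    def downsample(self) -> int:
        """Total temporal downsampling ratio r (one stride-2 pool per block)."""
        return 2 ** len(self.conv_channels)

    @property
    def d_feat(self) -> int:
        return 2 * self.lstm_hidden


@dataclass
class SaliencyMap:
    """Per-input-timestep attention weight in [0, 1], max = 1."""

    weights: np.ndarray
    curve: SpiroCurve

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.curve.time,
                "flow_lps": self.curve.flow,
                "weight": self.weights,
            }
        )


class SpiroEncoder:
    """The CNN-BiLSTM network; holds all layers and parameters."""

    N_INPUT_CHANNELS = 2  # PEF-normalised flow + constant dt channel

    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.convs = []
        c_prev = self.N_INPUT_CHANNELS
        for c_out, k in zip(config.conv_channels, config.kernel_sizes):
            self.convs.append(nn.Conv1d(c_prev, c_out, k, rng))
            c_prev = c_out
        self.relus = [nn.ReLU() for _ in self.convs]
        self.pools = [nn.AvgPool2() for _ in self.convs]
        self.bilstm = nn.BiLSTM(c_prev, config.lstm_hidden, rng)
        self.head = nn.Linear(config.d_feat, 1, rng)
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self):
        tree = {"bilstm": self.bilstm.params, "head": self.head.params}
        for i, c in enumerate(self.convs):
            tree[f"conv{i}"] = c.params
        return tree

    @property
    def grads(self):
        tree = {"bilstm": self.bilstm.grads, "head": self.head.grads}
        for i, c in enumerate(self.convs):
            tree[f"conv{i}"] = c.grads
        return tree

    def zero_grads(self):
        nn.Adam.zero_grads(self.grads)

    # -- forward / backward -------------------------------------------------
    def features(self, x, lengths):
        """Conv stack + BiLSTM: (B, 2, T), lengths -> (B, L, D_feat), l_red."""
        lens = np.asarray(lengths, dtype=int).copy()
        h = x
        masks = []
        for conv, relu, pool in zip(self.convs, self.relus, self.pools):
            h = conv.forward(h)
            m = nn.mask_from_lengths(lens, h.shape[2])[:, None, :]
            h = h * m
            masks.append(m)
            h = relu.forward(h)
            h = pool.forward(h)
            lens = (lens + 1) // 2
        h = np.transpose(h, (0, 2, 1))  # (B, L, C)
        e = self.bilstm.forward(h, lens)
        m_seq = nn.mask_from_lengths(lens, e.shape[1])[:, :, None]
        e = e * m_seq
        self._cache = (masks, m_seq, lens)
        return e, lens

    def features_backward(self, de):
        masks, m_seq, _ = self._cache
        de = de * m_seq
        dh = self.bilstm.backward(de)
        dh = np.transpose(dh, (0, 2, 1))
        for conv, relu, pool, m in zip(
            reversed(self.convs), reversed(self.relus),
            reversed(self.pools), reversed(masks),
        ):
            dh = pool.backward(dh)
            dh = relu.backward(dh)
            dh = dh * m
            dh = conv.backward(dh)
        return dh

    def pool_and_logit(self, e, lens, dropout_rng=None):
        m = nn.mask_from_lengths(lens, e.shape[1])[:, :, None]
        denom = np.maximum(m.sum(axis=1), 1.0)
        pooled = (e * m).sum(axis=1) / denom
        drop = None
        if dropout_rng is not None and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            drop = (dropout_rng.random(pooled.shape) < keep) / keep
            pooled = pooled * drop
        logit = self.head.forward(pooled)[:, 0]
        self._pool_cache = (m, denom, e.shape, drop)
        return logit

    def pool_backward(self, dlogit):
        m, denom, e_shape, drop = self._pool_cache
        dpooled = self.head.backward(dlogit[:, None])
        if drop is not None:
            dpooled = dpooled * drop
        de = np.broadcast_to(dpooled[:, None, :], e_shape) * m / denom[:, None, :]
        return de

    def forward_logits(self, x, lengths, dropout_rng=None):
        e, lens = self.features(x, lengths)
        return self.pool_and_logit(e, lens, dropout_rng=dropout_rng)


# ---------------------------------------------------------------------------
# batching helpers
# ---------------------------------------------------------------------------


def _curve_input(curve: SpiroCurve) -> np.ndarray:
    pef = float(np.max(np.abs(curve.flow)))
    if pef <= 0:
        pef = 1.0
    return np.stack([curve.flow / pef, np.full(curve.flow.size, curve.dt)])


def _batch(curves: list) -> tuple:
    lengths = np.array([c.flow.size for c in curves], dtype=int)
    t_max = int(lengths.max())
    x = np.zeros((len(curves), SpiroEncoder.N_INPUT_CHANNELS, t_max))
    for i, c in enumerate(curves):
        x[i, :, : c.flow.size] = _curve_input(c)
    return x, lengths


def encode(curves: list, model: SpiroEncoder) -> list:
    """Per-curve feature embeddings, each of shape ceil(T_i/r) x D_feat."""
    r = model.config.downsample
    lengths = [c.flow.size for c in curves]
    if any(t < r for t in lengths):
        raise ValueError(
            f"curve shorter than the downsampling ratio r={r}"
        )
    x, lens = _batch(curves)
    e, l_red = model.features(x, lens)
    return [e[i, : l_red[i]].copy() for i in range(len(curves))]


def classify(curves_or_embeddings, model: SpiroEncoder) -> np.ndarray:
    """COPD probability in (0, 1) per curve (masked pooling + logistic head)."""
    items = curves_or_embeddings
    if isinstance(items, SpiroCurve) or (
        items and isinstance(items[0], SpiroCurve)
    ):
        single = isinstance(items, SpiroCurve)
        curves = [items] if single else list(items)
        x, lens = _batch(curves)
        logit = model.forward_logits(x, lens)
        prob = nn.sigmoid(logit)
        return float(prob[0]) if single else prob
    # embeddings path (list of L_i x D_feat)
    embs = items if isinstance(items, list) else [items]
    lens = np.array([e.shape[0] for e in embs])
    l_max = int(lens.max())
    e = np.zeros((len(embs), l_max, model.config.d_feat))
    for i, emb in enumerate(embs):
        e[i, : emb.shape[0]] = emb
    prob = nn.sigmoid(model.pool_and_logit(e, lens))
    return float(prob[0]) if not isinstance(items, list) else prob


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _records_to_xy(records: list) -> tuple:
    curves = [r.curves[0] for r in records]
    labels = np.array([r.label for r in records], dtype=float)
    return curves, labels


def train_encoder(
    train_records: list,
    val_records: list,
    config: EncoderConfig | None = None,
    model: SpiroEncoder | None = None,
) -> tuple:
    """Minimise binary cross-entropy with Adam and early stopping on the
    validation loss.  Returns (model, history)."""
    if not train_records:
        raise ValueError("empty training set")
    config = config or EncoderConfig()
    model = model or SpiroEncoder(config)
    curves, y = _records_to_xy(train_records)
    val_curves, val_y = _records_to_xy(val_records) if val_records else ([], None)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.params, lr=config.lr)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, wait = np.inf, None, 0

    # bucket curves by length to limit padding waste
    order0 = np.argsort([c.flow.size for c in curves], kind="stable")
    for epoch in range(config.max_epochs):
        n = len(curves)
        starts = np.arange(0, n, config.batch_size)
        rng.shuffle(starts)
        losses = []
        for s in starts:
            idx = order0[s : s + config.batch_size]
            batch = [curves[i] for i in idx]
            x, lens = _batch(batch)
            logit = model.forward_logits(
                x, lens, dropout_rng=rng if config.dropout > 0 else None
            )
            loss, dlogit = nn.bce_with_logits(logit, y[idx])
            model.zero_grads()
            de = model.pool_backward(dlogit)
            model.features_backward(de)
            opt.step(model.grads)
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))

        if val_curves:
            x, lens = _batch(val_curves)
            logit = model.forward_logits(x, lens)
            vloss, _ = nn.bce_with_logits(logit, val_y)
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-5:
                best_val, wait = vloss, 0
                best_state = {
                    k: v.copy() for k, v in nn.flatten_params(model.params).items()
                }
            else:
                wait += 1
                if wait >= config.patience:
                    break
    if best_state is not None:
        for k, v in nn.flatten_params(model.params).items():
            v[...] = best_state[k]
    return model, history


# ---------------------------------------------------------------------------
# saliency
# ---------------------------------------------------------------------------


def saliency(
    curve: SpiroCurve, model: SpiroEncoder, kind: str = "cam"
) -> SaliencyMap:
    """Final-layer activation map, upsampled to input length.

    ``kind="cam"`` (default) weights each final-layer feature row by its
    positive contribution to the disease logit through the pooling head — a
    class-activation map that localises where the network finds obstructive
    evidence.  ``kind="norm"`` uses the plain L2 norm of each row instead.
    Either map is linearly interpolated back to the input timesteps and
    min-max normalised to [0, 1]; a degenerate all-equal map falls back to
    uniform weights with a warning.
    """
    e = encode([curve], model)[0]
    if kind == "cam":
        w = model.head.params["W"][:, 0]
        norms = np.maximum(e @ w, 0.0)
    elif kind == "norm":
        norms = np.linalg.norm(e, axis=1)
    else:
        raise ValueError(f"unknown saliency kind {kind!r}")
    t_in = curve.flow.size
    # reduced step j covers input samples around j * r
    r = model.config.downsample
    centers = np.minimum(np.arange(norms.size) * r + (r - 1) / 2.0, t_in - 1)
    up = np.interp(np.arange(t_in), centers, norms)
    lo, hi = float(up.min()), float(up.max())
    if hi - lo < 1e-12:
        warnings.warn("degenerate activations; uniform saliency map")
        return SaliencyMap(np.ones(t_in), curve)
    return SaliencyMap((up - lo) / (hi - lo), curve)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: SpiroEncoder, path) -> None:
    """Single-file archive holding config and weights."""
    flat = nn.flatten_params(model.params)
    cfg = json.dumps(asdict(model.config))
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **flat)


def load_checkpoint(path) -> SpiroEncoder:
    data = np.load(path)
    cfg_raw = bytes(data["__config__"]).decode()
    cfg_dict = json.loads(cfg_raw)
    for key in ("conv_channels", "kernel_sizes"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = SpiroEncoder(EncoderConfig(**cfg_dict))
    flat = nn.flatten_params(model.params)
    for k, v in flat.items():
        v[...] = data[k]
    return model
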