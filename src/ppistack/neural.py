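"""The basic learner: convolution, multi-head attention with pooling, pair
merge, and a dense softmax classifier.

A protein pair (P1, P2) arrives as two fixed-length feature vectors, each
reshaped to a (positions x channels) 1-D sequence.  A shared (siamese)
convolution stack — n repetitions of Conv -> BatchNorm -> ReLU followed by a
final Conv — extracts per-position features S1, S2.  Cross-attention then
models the pair: S1' = pooledMultiHead(S1, S2, S1) attends protein 1's
positions over protein 2 (and symmetrically for S2'), where pooledMultiHead
reduces the attended output to a channel-interaction map pooled with both
average and max pooling into a fixed-length vector.  The merge layer concatenates a
cosine-similarity scalar, a learned bilinear interaction S1'^T A S2', and
both attended representations; dense ReLU layers and a 2-way softmax finish
the classifier.  Training minimizes cross-entropy with Adam and is
deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import (
    Adam,
    Parameter,
    Tensor,
    concat,
    conv1d_same,
    softmax_cross_entropy,
)

# additive guard in the cosine term: keeps zero-norm vectors at cosine 0 and
# stays representable in float32
_TINY = 1e-12


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ConvConfig:
    positions: int
    in_channels: int
    n_blocks: int = 1
    channels: int = 8
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.kernel % 2 == 0:
            raise ValueError("kernel width must be odd ('same' padding)")


@dataclass
class AttentionConfig:
    h: int = 2
    d_model: int = 8

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValueError("h must be >= 1")
        if self.d_model % self.h:
            raise ValueError(
                f"d_model={self.d_model} must be divisible by h={self.h}"
            )

    @property
    def d_k(self) -> int:
        return self.d_model // self.h


@dataclass
class LearnerConfig:
    technique: str
    conv: ConvConfig
    attn: AttentionConfig = field(default_factory=AttentionConfig)
    dense_layers: tuple[int, ...] = (128, 64)
    seed: int = 0
    epochs: int = 40
    batch_size: int = 64
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    patience: int = 6
    standardize: bool = True  # per-feature z-scoring fitted on the training set
    clip: float = 3.0         # winsorize standardized inputs at +-clip
    symmetrize: bool = True   # train on both pair orders, average both at predict
    merge_similarity: str = "cosine"  # scalar cosine; "elementwise" keeps per-coordinate products
    dtype: str = "float32"  # training precision; forward math is exact in both
    name: str = ""

    def __post_init__(self) -> None:
        if self.conv.channels != self.attn.d_model:
            raise ValueError(
                "conv output channels must equal attention d_model "
                f"({self.conv.channels} != {self.attn.d_model})"
            )


def technique_reshape(technique: str, length: int) -> tuple[int, int]:
    """(positions, channels) view of a flat feature vector.

    The 7-fold encodings keep their natural property/group axis as channels
    (AC: 30 lags x 7 properties; CT: 49 leading-digit pairs x 7; LD: 90
    region-statistics x 7); PseAAC is a 1-channel sequence of 20+lambda
    terms; concatenated vectors use 7 channels, zero-padded to a multiple of
    7 if needed.
    """
    technique = technique.lower()
    if technique in ("ac", "ct", "ld", "concat"):
        positions = -(-length // 7)
        return positions, 7
    if technique == "pseaac":
        return length, 1
    raise ValueError(f"unknown technique {technique!r}")


def reshape_features(X: np.ndarray, technique: str) -> np.ndarray:
    """(n, length) feature matrix -> (n, positions, channels) conv input."""
    n, length = X.shape
    positions, channels = technique_reshape(technique, length)
    padded = positions * channels
    if padded != length:
        X = np.pad(X, ((0, 0), (0, padded - length)))
    return X.reshape(n, positions, channels)


# ---------------------------------------------------------------------------
# functional building blocks (operate on Tensors; ndarrays are wrapped)


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def scaled_dot_attention(Q, K, V) -> tuple[Tensor, Tensor]:
    """softmax(Q K^T / sqrt(d_k)) V; returns (weights, output).

    Works on 2-D (positions x d) or batched (..., positions, d) operands.
    """
    Q, K, V = _t(Q), _t(K), _t(V)
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(
            f"query width {Q.shape[-1]} != key width {K.shape[-1]}"
        )
    if K.shape[-2] != V.shape[-2]:
        raise ValueError(
            f"key rows {K.shape[-2]} != value rows {V.shape[-2]}"
        )
    d_k = Q.shape[-1]
    # scaling the (smaller) query before the product is algebraically the
    # same as scaling the score matrix
    scores = (Q * float(1.0 / np.sqrt(d_k))) @ K.swapaxes(-1, -2)
    weights = scores.softmax(axis=-1)
    return weights, weights @ V


def multi_head(Q, K, V, Wq, Wk, Wv, Wmu, h: int) -> Tensor:
    """h parallel attentions on linear projections, concatenated and
    re-projected.

    Wq/Wk/Wv/Wmu are (d_model, d_model); the projected operands are split
    into h heads of width d_model // h.
    """
    Q, K, V = _t(Q), _t(K), _t(V)
    Wq, Wk, Wv, Wmu = _t(Wq), _t(Wk), _t(Wv), _t(Wmu)
    d_model = Wq.shape[1]
    if d_model % h:
        raise ValueError(f"d_model={d_model} not divisible by h={h}")
    d_k = d_model // h

    def split(x: Tensor) -> Tensor:
        # (..., P, d_model) -> (..., h, P, d_k)
        new = x.reshape(*x.shape[:-1], h, d_k)
        return new.swapaxes(-2, -3)

    Qh, Kh, Vh = split(Q @ Wq), split(K @ Wk), split(V @ Wv)
    _, heads = scaled_dot_attention(Qh, Kh, Vh)  # (..., h, P, d_k)
    merged = heads.swapaxes(-2, -3)
    merged = merged.reshape(*merged.shape[:-2], d_model)
    return merged @ Wmu


def pooled_multi_head(Q, K, V, Wq, Wk, Wv, Wmu, h: int) -> Tensor:
    """Fixed-length attention summary of a (variable-row) sequence.

    The bilinear interaction map G = M^T Q / P (M = MultiHead(Q, K, V), P
    the number of positions) averages position-wise products of attended and
    raw features into a (d_model x d_model) channel map; average and max
    pooling along its last axis are concatenated, giving a vector of length
    2 x d_model independent of the input row count.
    """
    Q = _t(Q)
    M = multi_head(Q, K, V, Wq, Wk, Wv, Wmu, h)
    G = (M.swapaxes(-1, -2) @ Q) * (1.0 / Q.shape[-2])  # (..., d, d)
    avg = G.mean(axis=-1)
    mx = G.max(axis=-1)
    return concat([avg, mx], axis=-1)


def merge_pair(S1p, S2p, A, similarity: str = "cosine") -> Tensor:
    """Pair fusion: [similarity(S1', S2'), S1'^T A S2', S1', S2'] concatenated.

    The normalized-product similarity term admits two readings:

    * "cosine" — the scalar S1'.S2' / (|S1'| |S2'|); output (..., 2d + 2).
    * "elementwise" — the vector S1' * S2' / (|S1'| |S2'|), the same
      normalized product kept per coordinate; output (..., 3d + 2).

    A zero-norm vector yields a zero similarity term under either reading.
    """
    S1p, S2p, A = _t(S1p), _t(S2p), _t(A)
    if S1p.shape != S2p.shape:
        raise ValueError(f"shape mismatch {S1p.shape} vs {S2p.shape}")
    prod = S1p * S2p
    n1 = ((S1p * S1p).sum(axis=-1, keepdims=True) + _TINY**2).sqrt()
    n2 = ((S2p * S2p).sum(axis=-1, keepdims=True) + _TINY**2).sqrt()
    if similarity == "cosine":
        sim = prod.sum(axis=-1, keepdims=True) / (n1 * n2 + _TINY)
    elif similarity == "elementwise":
        sim = prod * ((n1 * n2 + _TINY) ** -1.0)
    else:
        raise ValueError(f"unknown similarity reading {similarity!r}")
    bilinear = ((S1p @ A) * S2p).sum(axis=-1, keepdims=True)
    return concat([sim, bilinear, S1p, S2p], axis=-1)


# ---------------------------------------------------------------------------
# layers


class _Layers:
    """Parameter registry shared by the layer classes."""

    def __init__(self, dtype=np.float64) -> None:
        self.params: list[Parameter] = []
        self.dtype = np.dtype(dtype)

    def param(self, rng: np.random.Generator, shape, fan_in, fan_out) -> Parameter:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        p = Parameter(rng.uniform(-limit, limit, size=shape).astype(self.dtype))
        self.params.append(p)
        return p

    def zeros(self, shape) -> Parameter:
        p = Parameter(np.zeros(shape, dtype=self.dtype))
        self.params.append(p)
        return p

    def ones(self, shape) -> Parameter:
        p = Parameter(np.ones(shape, dtype=self.dtype))
        self.params.append(p)
        return p


class BatchNorm1d:
    """Per-channel batch normalization over (batch, positions)."""

    def __init__(self, reg: _Layers, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = reg.ones((channels,))
        self.beta = reg.zeros((channels,))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            m = x.mean(axis=(0, 1), keepdims=True)
            centered = x - m
            v = (centered * centered).mean(axis=(0, 1), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * m.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * v.data.ravel()
            )
            xhat = centered * ((v + self.eps) ** -0.5)
        else:
            dt = x.data.dtype
            xhat = (x - Tensor(self.running_mean.astype(dt))) * Tensor(
                (1.0 / np.sqrt(self.running_var + self.eps)).astype(dt)
            )
        return xhat * self.gamma + self.beta


class ConvStack:
    """n_blocks x (Conv -> BatchNorm -> ReLU), then a closing Conv."""

    def __init__(self, reg: _Layers, cfg: ConvConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.blocks = []
        c_in = cfg.in_channels
        for _ in range(cfg.n_blocks):
            w = reg.param(
                rng,
                (cfg.kernel, c_in, cfg.channels),
                cfg.kernel * c_in,
                cfg.channels,
            )
            b = reg.zeros((cfg.channels,))
            bn = BatchNorm1d(reg, cfg.channels)
            self.blocks.append((w, b, bn))
            c_in = cfg.channels
        self.w_out = reg.param(
            rng,
            (cfg.kernel, c_in, cfg.channels),
            cfg.kernel * c_in,
            cfg.channels,
        )
        self.b_out = reg.zeros((cfg.channels,))

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        expected = (self.cfg.positions, self.cfg.in_channels)
        if tuple(x.shape[-2:]) != expected:
            raise ValueError(
                f"conv stack expected input (*, {expected[0]}, {expected[1]}), "
                f"got {tuple(x.shape)}"
            )
        for w, b, bn in self.blocks:
            x = bn(conv1d_same(x, w, b), train).relu()
        return conv1d_same(x, self.w_out, self.b_out)


class AttentionBlock:
    """Multi-head attention with pooling, shared across the pair."""

    def __init__(self, reg: _Layers, cfg: AttentionConfig, rng: np.random.Generator):
        d = cfg.d_model
        self.cfg = cfg
        self.Wq = reg.param(rng, (d, d), d, d)
        self.Wk = reg.param(rng, (d, d), d, d)
        self.Wv = reg.param(rng, (d, d), d, d)
        self.Wmu = reg.param(rng, (d, d), d, d)

    def pooled(self, Q: Tensor, K: Tensor, V: Tensor) -> Tensor:
        return pooled_multi_head(
            Q, K, V, self.Wq, self.Wk, self.Wv, self.Wmu, self.cfg.h
        )


class Dense:
    def __init__(self, reg: _Layers, d_in: int, widths, d_out: int,
                 rng: np.random.Generator):
        self.layers = []
        for w_out in (*widths, d_out):
            W = reg.param(rng, (d_in, w_out), d_in, w_out)
            b = reg.zeros((w_out,))
            self.layers.append((W, b))
            d_in = w_out

    def __call__(self, x: Tensor) -> Tensor:
        for i, (W, b) in enumerate(self.layers):
            x = x @ W + b
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


# ---------------------------------------------------------------------------
# the basic learner


class BasicLearner:
    """Conv + attention + merge + dense pair classifier for one encoding."""

    def __init__(self, cfg: LearnerConfig):
        self.cfg = cfg
        self.reg = _Layers(dtype=cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        self.conv = ConvStack(self.reg, cfg.conv, rng)
        self.attn = AttentionBlock(self.reg, cfg.attn, rng)
        pooled_len = 2 * cfg.attn.d_model
        self.A = self.reg.param(rng, (pooled_len, pooled_len), pooled_len, pooled_len)
        sim_len = 1 if cfg.merge_similarity == "cosine" else pooled_len
        self.dense = Dense(
            self.reg, 2 * pooled_len + sim_len + 1, cfg.dense_layers, 2, rng
        )
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None
        self._fitted = False

    @property
    def params(self) -> list[Parameter]:
        return self.reg.params

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.reg.dtype)
        if self._mu is not None:
            X = (X - self._mu) / self._sd
            if self.cfg.clip:
                X = np.clip(X, -self.cfg.clip, self.cfg.clip)
        return X

    def forward(self, X1: np.ndarray, X2: np.ndarray, train: bool = False) -> Tensor:
        S1 = self.conv(Tensor(self._prepare(X1)), train)
        S2 = self.conv(Tensor(self._prepare(X2)), train)
        S1p = self.attn.pooled(S1, S2, S1)
        S2p = self.attn.pooled(S2, S1, S2)
        merged = merge_pair(S1p, S2p, self.A, self.cfg.merge_similarity)
        return self.dense(merged)

    def predict_proba(self, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
        """Class probabilities (n, 2); rows sum to 1.

        An interaction is a property of the unordered pair, so with
        cfg.symmetrize the two slot orders are scored and averaged.
        """
        proba = self.forward(X1, X2, train=False).softmax(axis=-1).data
        if self.cfg.symmetrize:
            swapped = self.forward(X2, X1, train=False).softmax(axis=-1).data
            proba = (proba + swapped) / 2
        return proba

    def predict_positive(self, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
        return self.predict_proba(X1, X2)[:, 1]

    def fit(self, X1: np.ndarray, X2: np.ndarray, y: np.ndarray) -> "BasicLearner":
        """Train by cross-entropy; deterministic given cfg.seed.

        A seeded fraction of the data is held out for early stopping on
        validation loss; the parameters of the best validation epoch are
        restored at the end.
        """
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        cfg = self.cfg
        if cfg.standardize:
            both = np.concatenate([X1, X2]).astype(self.reg.dtype)
            self._mu = both.mean(axis=0)
            self._sd = both.std(axis=0) + np.asarray(1e-8, dtype=self.reg.dtype)
        rng = np.random.default_rng([cfg.seed, 7])
        n = len(y)
        idx = rng.permutation(n)
        n_val = max(int(round(cfg.val_fraction * n)), 1) if cfg.val_fraction > 0 else 0
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        if n_val and (len(np.unique(y[tr_idx])) < 2 or n - n_val < 2):
            tr_idx = idx  # fall back to training on everything
            n_val = 0
        if cfg.symmetrize:
            # duplicate the training rows with slots swapped; an unordered
            # pair should be scored identically in either order
            n_tr = len(X1)
            X1 = np.concatenate([X1, X2])
            X2 = np.concatenate([X2, X1[:n_tr]])
            y = np.concatenate([y, y])
            tr_idx = np.concatenate([tr_idx, tr_idx + n_tr])
        opt = Adam(self.params, lr=cfg.learning_rate)
        best_val = np.inf
        best_state = None
        stale = 0
        self.history: list[dict[str, float]] = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(tr_idx)
            total = 0.0
            for lo in range(0, len(order), cfg.batch_size):
                batch = order[lo : lo + cfg.batch_size]
                if len(batch) < 2:
                    continue  # batchnorm needs >= 2 samples
                opt.zero_grad()
                logits = self.forward(X1[batch], X2[batch], train=True)
                loss = softmax_cross_entropy(logits, y[batch])
                loss.backward()
                opt.step()
                total += float(loss.data) * len(batch)
            entry = {"epoch": epoch, "train_loss": total / max(len(order), 1)}
            if n_val:
                logits = self.forward(X1[val_idx], X2[val_idx], train=False)
                val_loss = float(softmax_cross_entropy(logits, y[val_idx]).data)
                entry["val_loss"] = val_loss
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_state = [p.data.copy() for p in self.params]
                    stale = 0
                else:
                    stale += 1
                    if stale > cfg.patience:
                        self.history.append(entry)
                        break
            self.history.append(entry)
        if best_state is not None:
            for p, saved in zip(self.params, best_state):
                p.data = saved
        self._fitted = True
        return self

    # -- persistence --------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.data for i, p in enumerate(self.params)}
        bns = [bn for _, _, bn in self.conv.blocks]
        for i, bn in enumerate(bns):
            state[f"bn{i}_mean"] = bn.running_mean
            state[f"bn{i}_var"] = bn.running_var
        if self._mu is not None:
            state["scaler_mu"] = self._mu
            state["scaler_sd"] = self._sd
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            p.data = np.asarray(state[f"param_{i}"], dtype=self.reg.dtype)
        for i, (_, _, bn) in enumerate(self.conv.blocks):
            bn.running_mean = np.asarray(state[f"bn{i}_mean"], dtype=float)
            bn.running_var = np.asarray(state[f"bn{i}_var"], dtype=float)
        if "scaler_mu" in state:
            self._mu = np.asarray(state["scaler_mu"], dtype=self.reg.dtype)
            self._sd = np.asarray(state["scaler_sd"], dtype=self.reg.dtype)
        self._fitted = True


def conv_stack(x: np.ndarray, cfg: ConvConfig, seed: int = 0,
               train: bool = False) -> np.ndarray:
    """Standalone convolution stack on an (n, positions, channels) input."""
    reg = _Layers()
    stack = ConvStack(reg, cfg, np.random.default_rng(seed))
    return stack(Tensor(np.asarray(x, dtype=float)), train).data


def train_basic(X1: np.ndarray, X2: np.ndarray, y, cfg: LearnerConfig) -> BasicLearner:
    """Train a fresh basic learner on an encoded pair dataset."""
    if len(y) == 0:
        raise ValueError("empty training set")
    return BasicLearner(cfg).fit(X1, X2, np.asarray(y))


# ---------------------------------------------------------------------------
# the shipped configuration grid


# (dense widths, heads, model width): the four network settings assigned to
# every encoding; head count and width scale together so each head keeps a
# usable key dimension
DENSE_GRID: tuple[tuple[tuple[int, ...], int, int], ...] = (
    ((128, 64), 2, 32),
    ((256, 128), 2, 32),
    ((128, 64, 32), 4, 32),
    ((256, 128, 64), 4, 32),
)


def default_learner_grid(
    technique_lengths: dict[str, int],
    seed: int = 0,
    epochs: int = 40,
    channels: int | None = None,
    n_blocks: int = 1,
) -> list[LearnerConfig]:
    """The default first-layer ensemble: one config per (technique, dense
    stack) combination — 4 techniques x 4 dense/head settings = 16 learners.

    `channels` overrides the per-config model width when given.
    """
    grid = []
    for t_i, (technique, length) in enumerate(sorted(technique_lengths.items())):
        positions, in_ch = technique_reshape(technique, length)
        for c_i, (dense, h, d_model) in enumerate(DENSE_GRID):
            width = channels or d_model
            cfg_epochs = epochs
            if technique in ("ac", "pseaac"):
                # the low-order encodings carry less pair signal and plateau
                # early; a narrower, shorter-trained model suffices and keeps
                # the 16-learner stack fast
                width = min(width, 16)
                cfg_epochs = min(epochs, 20)
            grid.append(
                LearnerConfig(
                    technique=technique,
                    conv=ConvConfig(
                        positions=positions,
                        in_channels=in_ch,
                        n_blocks=n_blocks,
                        channels=width,
                    ),
                    attn=AttentionConfig(h=h, d_model=width),
                    dense_layers=dense,
                    seed=seed * 10007 + t_i * 101 + c_i,
                    epochs=cfg_epochs,
                    name=f"{technique}_cfg{c_i}",
                )
            )
    return grid
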