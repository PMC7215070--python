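"""Stacked generalization of the basic learners with a neural meta-learner.

First layer: M basic learners (default 16 = 4 encodings x 4 network
configurations), each trained K times under stratified K-fold cross
validation (default K = 5).  Each training sample's meta-feature for learner
m is the positive-class probability predicted by the one fold-model that did
NOT see that sample — the out-of-fold guarantee that keeps the second layer
leakage-free.  Test meta-features average the K fold-models of each learner.
Second layer: a small feed-forward network with ReLU hidden layers and a
2-way softmax, trained by full-batch gradient descent with rate eta until
the gradient max-norm falls below epsilon or max_iters is reached.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .autograd import Tensor, softmax_cross_entropy
from .neural import BasicLearner, Dense, LearnerConfig, _Layers, reshape_features


class PairLearner(Protocol):
    """What stacking needs from a first-layer learner."""

    cfg: LearnerConfig

    def fit(self, X1, X2, y) -> "PairLearner": ...

    def predict_positive(self, X1, X2) -> np.ndarray: ...


@dataclass
class EncodedPairs:
    """Per-technique conv-ready arrays for a list of labelled pairs.

    techniques maps technique name -> (X1, X2), each of shape
    (n, positions, channels); y holds the 0/1 labels.
    """

    techniques: dict[str, tuple[np.ndarray, np.ndarray]]
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.y)

    def arrays(self, technique: str) -> tuple[np.ndarray, np.ndarray]:
        return self.techniques[technique]

    def subset(self, idx) -> "EncodedPairs":
        idx = np.asarray(idx)
        return EncodedPairs(
            {t: (a[idx], b[idx]) for t, (a, b) in self.techniques.items()},
            self.y[idx],
        )


def encode_pairs(
    features: dict[str, dict[str, np.ndarray]],
    pairs,
) -> EncodedPairs:
    """Assemble conv-ready pair arrays from per-protein feature tables.

    features: technique -> {protein id -> flat feature vector}.
    """
    techniques = {}
    y = np.array([lab for _, _, lab in pairs], dtype=int)
    for tech, table in features.items():
        ids = list(table)
        length = len(table[ids[0]])
        X1 = np.empty((len(y), length))
        X2 = np.empty((len(y), length))
        for i, (a, b, _) in enumerate(pairs):
            X1[i] = table[a]
            X2[i] = table[b]
        techniques[tech] = (
            reshape_features(X1, tech),
            reshape_features(X2, tech),
        )
    return EncodedPairs(techniques, y)


@dataclass
class StackingConfig:
    K: int = 5
    meta_layers: tuple[int, ...] = (32, 16)
    eta: float = 0.05
    max_iters: int = 600
    epsilon: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")


# ---------------------------------------------------------------------------
# meta-feature construction


def build_meta_features(
    data: EncodedPairs,
    learner_factory: Callable[[int], PairLearner],
    n_learners: int,
    cfg: StackingConfig,
) -> tuple[np.ndarray, list[list[PairLearner]], np.ndarray]:
    """Out-of-fold meta features for the training set.

    learner_factory(m) must return a fresh untrained learner for slot m.
    Returns (meta matrix of shape (n, M), fold_models[m][k], fold_of_sample).
    Row i, column m holds the prediction for sample i made by the one
    fold-model of learner m whose held-out fold contains i.
    """
    n = len(data)
    y = data.y
    if n_learners < 1:
        raise ValueError("need at least one learner")
    skf = StratifiedKFold(n_splits=cfg.K, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(np.zeros(n), y))
    fold_of_sample = np.empty(n, dtype=int)
    for k, (_, test_idx) in enumerate(folds):
        fold_of_sample[test_idx] = k
    for k, (train_idx, _) in enumerate(folds):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                f"fold {k} has a single class; re-stratify or change the seed"
            )

    meta = np.empty((n, n_learners))
    fold_models: list[list[PairLearner]] = []
    for m in range(n_learners):
        models_m: list[PairLearner] = []
        for train_idx, test_idx in folds:
            learner = learner_factory(m)
            tech = learner.cfg.technique
            X1, X2 = data.arrays(tech)
            learner.fit(X1[train_idx], X2[train_idx], y[train_idx])
            meta[test_idx, m] = learner.predict_positive(
                X1[test_idx], X2[test_idx]
            )
            models_m.append(learner)
        fold_models.append(models_m)
    return meta, fold_models, fold_of_sample


def predict_meta_features(
    data: EncodedPairs, fold_models: Sequence[Sequence[PairLearner]]
) -> np.ndarray:
    """Test meta features: mean over the K fold-models of each learner."""
    n = len(data)
    meta = np.empty((n, len(fold_models)))
    for m, models_m in enumerate(fold_models):
        if not models_m:
            raise ValueError(f"learner {m} has no fold models")
        tech = models_m[0].cfg.technique
        X1, X2 = data.arrays(tech)
        preds = np.stack([mod.predict_positive(X1, X2) for mod in models_m])
        meta[:, m] = preds.mean(axis=0)
    return meta


def audit_out_of_fold(
    fold_of_sample: np.ndarray, trained_on: Sequence[Sequence[np.ndarray]]
) -> bool:
    """Check the leakage guarantee: the fold-model that produced sample i's
    meta feature was trained without sample i.

    trained_on[m][k] lists the training indices of learner m's fold-k model.
    """
    for models_m in trained_on:
        for k, train_idx in enumerate(models_m):
            own = np.flatnonzero(fold_of_sample == k)
            if np.intersect1d(own, train_idx).size:
                return False
    return True


# ---------------------------------------------------------------------------
# the meta-learner


class MetaNetwork:
    """Feed-forward second-level classifier trained by full-batch gradient
    descent (rate eta) until the gradient max-norm drops below epsilon."""

    def __init__(self, n_inputs: int, cfg: StackingConfig):
        self.cfg = cfg
        self.reg = _Layers()
        rng = np.random.default_rng([cfg.seed, 11])
        self.net = Dense(self.reg, n_inputs, cfg.meta_layers, 2, rng)
        self.n_inputs = n_inputs
        self.n_iters_run = 0

    def fit(self, meta: np.ndarray, y: np.ndarray) -> "MetaNetwork":
        meta = np.asarray(meta, dtype=float)
        y = np.asarray(y, dtype=int)
        if meta.size == 0:
            raise ValueError("empty meta-feature matrix")
        self.losses: list[float] = []
        for it in range(self.cfg.max_iters):
            for p in self.reg.params:
                p.grad = None
            logits = self.net(Tensor(meta))
            loss = softmax_cross_entropy(logits, y)
            loss.backward()
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at iteration {it}")
            self.losses.append(float(loss.data))
            gmax = max(
                np.abs(p.grad).max() for p in self.reg.params if p.grad is not None
            )
            if gmax < self.cfg.epsilon:
                break
            for p in self.reg.params:
                if p.grad is not None:
                    p.data -= self.cfg.eta * p.grad
            self.n_iters_run = it + 1
        return self

    def predict_proba(self, meta: np.ndarray) -> np.ndarray:
        logits = self.net(Tensor(np.asarray(meta, dtype=float)))
        return logits.softmax(axis=-1).data

    def predict_positive(self, meta: np.ndarray) -> np.ndarray:
        return self.predict_proba(meta)[:, 1]

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.data for i, p in enumerate(self.reg.params)}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.reg.params):
            p.data = np.asarray(state[f"param_{i}"], dtype=float)


def train_meta(meta: np.ndarray, y, cfg: StackingConfig) -> MetaNetwork:
    """Train the second-level network on an out-of-fold meta matrix."""
    meta = np.asarray(meta, dtype=float)
    return MetaNetwork(meta.shape[1], cfg).fit(meta, np.asarray(y))


# ---------------------------------------------------------------------------
# the stacked model


@dataclass
class StackedModel:
    fold_models: list[list[PairLearner]]
    meta: MetaNetwork
    meta_feature_names: list[str]
    stacking: StackingConfig
    train_meta_matrix: np.ndarray | None = None
    fold_of_sample: np.ndarray | None = None

    def predict_positive(self, data: EncodedPairs) -> np.ndarray:
        return self.meta.predict_positive(
            predict_meta_features(data, self.fold_models)
        )

    def predict_proba(self, data: EncodedPairs) -> np.ndarray:
        return self.meta.predict_proba(
            predict_meta_features(data, self.fold_models)
        )


def train_stacked(
    data: EncodedPairs,
    learner_configs: Sequence[LearnerConfig],
    cfg: StackingConfig | None = None,
    learner_class=BasicLearner,
) -> StackedModel:
    """Train the full two-layer stack on an encoded pair dataset."""
    cfg = cfg or StackingConfig()
    configs = list(learner_configs)

    def factory(m: int) -> PairLearner:
        return learner_class(configs[m])

    meta, fold_models, fold_of_sample = build_meta_features(
        data, factory, len(configs), cfg
    )
    meta_net = train_meta(meta, data.y, cfg)
    names = [c.name or f"learner_{m}" for m, c in enumerate(configs)]
    return StackedModel(
        fold_models=fold_models,
        meta=meta_net,
        meta_feature_names=names,
        stacking=cfg,
        train_meta_matrix=meta,
        fold_of_sample=fold_of_sample,
    )


def predict_ensemble(model: StackedModel, data: EncodedPairs) -> np.ndarray:
    """Positive-class probabilities of the stacked ensemble (threshold 0.5
    for hard labels)."""
    return model.predict_positive(data)


# ---------------------------------------------------------------------------
# architecture variants


def concat_features(
    features: dict[str, dict[str, np.ndarray]]
) -> dict[str, dict[str, np.ndarray]]:
    """Fuse per-technique feature tables into one 'concat' table."""
    techs = sorted(features)
    ids = list(features[techs[0]])
    return {
        "concat": {
            pid: np.concatenate([features[t][pid] for t in techs]) for pid in ids
        }
    }


def run_variant(
    features: dict[str, dict[str, np.ndarray]],
    pairs,
    variant: str = "full",
    cfg: StackingConfig | None = None,
    epochs: int = 40,
) -> StackedModel:
    """Train a stacked ensemble under one of the architecture variants."""
    from .neural import default_learner_grid

    cfg = cfg or StackingConfig()
    variant = variant.lower()
    if variant == "concat":
        features = concat_features(features)
    elif variant.startswith("single:"):
        tech = variant.split(":", 1)[1]
        if tech not in features:
            raise ValueError(
                f"unknown technique {tech!r}; have {sorted(features)}"
            )
        features = {tech: features[tech]}
    elif variant != "full":
        raise ValueError(
            f"unknown variant {variant!r}; expected 'full', 'concat' or "
            f"'single:<tech>'"
        )
    lengths = {t: len(next(iter(tab.values()))) for t, tab in features.items()}
    configs = default_learner_grid(lengths, seed=cfg.seed, epochs=epochs)
    data = encode_pairs(features, pairs)
    return train_stacked(data, configs, cfg)
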