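"""The desk-scale benchmark: the full method run end-to-end on the default
synthetic study conditions.

One call simulates the proteome and interaction network, samples negatives
by localization, encodes all four representations, trains the five-fold
stacked ensemble on a stratified 80% split and evaluates on the held-out
20%.  Used by the acceptance machinery and reproducible from the library or
CLI alike; everything is deterministic in `seed`.
"""

from __future__ import annotations

import numpy as np

from .encoders import encode_collection
from .ensemble import (
    StackingConfig,
    concat_features,
    encode_pairs,
    predict_meta_features,
    train_stacked,
)
from .io_filters import sample_negatives
from .metrics import auc, evaluate
from .neural import default_learner_grid
from .synthetic import SimConfig, simulate_dataset

TECHNIQUES = ("ac", "ct", "ld", "pseaac")


def stratified_split(y: np.ndarray, test_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    test_idx = []
    for label in (0, 1):
        cls = np.flatnonzero(y == label)
        take = rng.choice(cls, size=int(round(test_fraction * len(cls))),
                          replace=False)
        test_idx += take.tolist()
    mask = np.zeros(len(y), dtype=bool)
    mask[test_idx] = True
    return np.flatnonzero(~mask), np.flatnonzero(mask)


def run_default_benchmark(
    seed: int = 1,
    sim: SimConfig | None = None,
    variant: str = "full",
    epochs: int = 40,
    folds: int = 5,
    test_fraction: float = 0.2,
    permute_labels: bool = False,
) -> dict:
    """Run the complete pipeline on the synthetic study conditions.

    With `permute_labels` the pair labels are shuffled before the split — a
    negative control that destroys the sequence/label relation, so held-out
    AUC should sit near 0.5.

    Returns a dict with the held-out metrics, each single learner's AUC and
    bookkeeping sizes.
    """
    sim = sim or SimConfig(seed=seed)
    proteome, positives, _ = simulate_dataset(sim)
    negatives = sample_negatives(
        proteome, positives, ratio=1.0, rng_seed=2 * seed + 1
    )
    data = positives + negatives

    features = {t: encode_collection(proteome, t) for t in TECHNIQUES}
    if variant == "concat":
        features = concat_features(features)
    elif variant.startswith("single:"):
        tech = variant.split(":", 1)[1]
        features = {tech: features[tech]}
    encoded = encode_pairs(features, data)

    rng = np.random.default_rng([seed, 3])
    y = encoded.y
    if permute_labels:
        encoded.y = rng.permutation(y)
    train_idx, test_idx = stratified_split(encoded.y, test_fraction, rng)
    train, test = encoded.subset(train_idx), encoded.subset(test_idx)

    lengths = {t: tab[next(iter(tab))].shape[0] for t, tab in features.items()}
    grid = default_learner_grid(lengths, seed=seed, epochs=epochs)
    model = train_stacked(train, grid, StackingConfig(K=folds, seed=seed))

    test_meta = predict_meta_features(test, model.fold_models)
    singles = {
        name: float(auc(test.y, test_meta[:, m]))
        for m, name in enumerate(model.meta_feature_names)
    }
    scores = model.meta.predict_positive(test_meta)
    report = evaluate(test.y, scores)
    return {
        "metrics": {k: float(v) for k, v in report.items()},
        "single_learner_auc": singles,
        "best_single_auc": max(singles.values()),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "n_learners": len(grid),
        "variant": variant,
        "seed": seed,
    }
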