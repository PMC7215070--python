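"""End-to-end pipeline: simulate/ingest -> filter -> featurize -> stack-train
-> evaluate, with file-level caching and a run manifest.

The pipeline is driven by a single YAML config (see configs/default.yaml for
the documented schema and defaults).  Every stage writes its outputs under
the run directory and records a digest; on re-run, a stage whose outputs
exist and whose inputs/config section are unchanged is skipped, so deleting
one artifact (say the meta-learner weights) re-computes only that artifact.
The manifest records the config hash, seeds, input digests, per-stage
timings and cache status — enough to re-run identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .encoders import PseAACParams, encode_collection, feature_names
from .ensemble import (
    EncodedPairs,
    MetaNetwork,
    StackedModel,
    StackingConfig,
    build_meta_features,
    encode_pairs,
    concat_features,
    train_meta,
)
from .io_filters import (
    filter_positive_set,
    read_fasta,
    read_localization_tsv,
    read_pairs_tsv,
    sample_negatives,
    write_fasta,
    write_localization_tsv,
    write_pairs_tsv,
)
from .metrics import evaluate
from .neural import (
    AttentionConfig,
    BasicLearner,
    ConvConfig,
    LearnerConfig,
    default_learner_grid,
)
from .records import PairDataset
from .synthetic import SimConfig, simulate_dataset

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_proteins": 300,
        "length_range": [60, 400],
        "n_motif_families": 4,
        "motif_length": 30,
        "insertion_noise": 0.05,
        "motif_prob": 0.45,
        "max_families": 1,
        "n_positive_pairs": 500,
        "localization_count": 7,
    },
    "inputs": None,  # alternatively: {fasta, pairs, localization} paths
    "filter": {"min_len": 50, "max_identity": None, "neg_ratio": 1.0},
    "encoders": {"lag": 30, "lambda": 15, "ld_distribution": "paper",
                 "pseaac_correlation": "paper"},
    "split": {"test_fraction": 0.2},
    "ensemble": {
        "variant": "full",
        "folds": 5,
        "epochs": 40,
        "channels": None,
        "n_blocks": 1,
        "meta_layers": [32, 16],
        "eta": 0.05,
        "max_iters": 600,
        "epsilon": 1.0e-4,
    },
}

_SCHEMA_KEYS = set(DEFAULT_CONFIG)


def load_config(path=None) -> dict:
    """Load and validate a pipeline config, merging over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        bad = set(user) - _SCHEMA_KEYS
        if bad:
            raise ValueError(f"unknown config sections: {sorted(bad)}")
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                sub_bad = set(val) - set(cfg[key])
                if sub_bad:
                    raise ValueError(
                        f"unknown keys in config section {key!r}: {sorted(sub_bad)}"
                    )
                cfg[key].update(val)
            else:
                cfg[key] = val
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    if cfg["simulate"] is None and cfg["inputs"] is None:
        raise ValueError("config must provide either 'simulate' or 'inputs'")
    enc = cfg["encoders"]
    if enc["ld_distribution"] not in ("paper", "positional"):
        raise ValueError("encoders.ld_distribution must be 'paper' or 'positional'")
    if not 0 < cfg["split"]["test_fraction"] < 1:
        raise ValueError("split.test_fraction must be in (0, 1)")
    ens = cfg["ensemble"]
    if ens["folds"] < 2:
        raise ValueError("ensemble.folds must be >= 2")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# model persistence


def learner_config_to_dict(cfg: LearnerConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["dense_layers"] = list(cfg.dense_layers)
    return d


def learner_config_from_dict(d: dict) -> LearnerConfig:
    d = dict(d)
    d["conv"] = ConvConfig(**d["conv"])
    d["attn"] = AttentionConfig(**d["attn"])
    d["dense_layers"] = tuple(d["dense_layers"])
    return LearnerConfig(**d)


def save_stacked(model: StackedModel, configs: list[LearnerConfig], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_cfg = dataclasses.asdict(model.stacking)
    meta_cfg["meta_layers"] = list(model.stacking.meta_layers)
    (outdir / "model.json").write_text(
        json.dumps(
            {
                "version": __version__,
                "stacking": meta_cfg,
                "learners": [learner_config_to_dict(c) for c in configs],
                "meta_feature_names": model.meta_feature_names,
                "meta_inputs": model.meta.n_inputs,
            },
            indent=2,
        )
    )
    for m, models_m in enumerate(model.fold_models):
        for k, learner in enumerate(models_m):
            np.savez(outdir / f"learner_{m:02d}_{k}.npz", **learner.state_arrays())
    np.savez(outdir / "meta.npz", **model.meta.state_arrays())
    if model.train_meta_matrix is not None:
        np.savez(
            outdir / "meta_matrix.npz",
            meta=model.train_meta_matrix,
            fold_of_sample=model.fold_of_sample,
        )


def load_stacked(outdir) -> tuple[StackedModel, list[LearnerConfig]]:
    outdir = Path(outdir)
    spec = json.loads((outdir / "model.json").read_text())
    configs = [learner_config_from_dict(d) for d in spec["learners"]]
    stack_cfg = dict(spec["stacking"])
    stack_cfg["meta_layers"] = tuple(stack_cfg["meta_layers"])
    stacking = StackingConfig(**stack_cfg)
    fold_models = []
    for m, cfg in enumerate(configs):
        models_m = []
        for k in range(stacking.K):
            learner = BasicLearner(cfg)
            with np.load(outdir / f"learner_{m:02d}_{k}.npz") as z:
                learner.load_state_arrays(dict(z))
            models_m.append(learner)
        fold_models.append(models_m)
    meta = MetaNetwork(spec["meta_inputs"], stacking)
    with np.load(outdir / "meta.npz") as z:
        meta.load_state_arrays(dict(z))
    mm_path = outdir / "meta_matrix.npz"
    meta_matrix = fold_of_sample = None
    if mm_path.exists():
        with np.load(mm_path) as z:
            meta_matrix = z["meta"]
            fold_of_sample = z["fold_of_sample"]
    return (
        StackedModel(
            fold_models=fold_models,
            meta=meta,
            meta_feature_names=spec["meta_feature_names"],
            stacking=stacking,
            train_meta_matrix=meta_matrix,
            fold_of_sample=fold_of_sample,
        ),
        configs,
    )


# ---------------------------------------------------------------------------
# feature tables on disk


def write_feature_tsv(table: dict[str, np.ndarray], names: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(names) + "\n")
        for pid, vec in table.items():
            fh.write(pid + "\t" + "\t".join(f"{v:.10g}" for v in vec) + "\n")


def read_feature_tsv(path) -> dict[str, np.ndarray]:
    table = {}
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            table[fields[0]] = np.array([float(v) for v in fields[1:]])
    return table


# ---------------------------------------------------------------------------
# pipeline


class _Stage:
    """Timing + cache bookkeeping for one pipeline stage."""

    def __init__(self, manifest: dict, name: str):
        self.manifest = manifest
        self.name = name
        self.t0 = time.perf_counter()

    def done(self, cached: bool, outputs: list[Path]) -> None:
        self.manifest["stages"][self.name] = {
            "cached": cached,
            "seconds": round(time.perf_counter() - self.t0, 3),
            "outputs": [str(p) for p in outputs],
        }


def run_pipeline(config_path=None, outdir="run", seed: int | None = None) -> dict:
    """Execute the full pipeline; returns the run manifest (also written to
    <outdir>/manifest.json)."""
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "stages": {},
        "inputs": {},
        "outputs": {},
    }
    master = int(cfg["seed"])

    # -- stage: data (simulate or ingest) ----------------------------------
    st = _Stage(manifest, "data")
    fasta = out / "proteins.fasta"
    pos_tsv = out / "positive_pairs.tsv"
    loc_tsv = out / "localization.tsv"
    if cfg["inputs"]:
        fasta = Path(cfg["inputs"]["fasta"])
        pos_tsv = Path(cfg["inputs"]["pairs"])
        loc_tsv = Path(cfg["inputs"]["localization"])
        st.done(cached=True, outputs=[fasta, pos_tsv, loc_tsv])
    else:
        cached = fasta.exists() and pos_tsv.exists() and loc_tsv.exists()
        if not cached:
            sim = dict(cfg["simulate"])
            sim["length_range"] = tuple(sim["length_range"])
            proteome, positives, annotations = simulate_dataset(
                SimConfig(seed=master, **sim)
            )
            write_fasta(proteome, fasta)
            write_pairs_tsv(positives, pos_tsv)
            write_localization_tsv(annotations, loc_tsv)
        st.done(cached=cached, outputs=[fasta, pos_tsv, loc_tsv])
    manifest["inputs"] = {
        "fasta": _digest(fasta),
        "pairs": _digest(pos_tsv),
        "localization": _digest(loc_tsv),
    }

    records = read_fasta(fasta).with_localizations(read_localization_tsv(loc_tsv))
    positives = read_pairs_tsv(pos_tsv)

    # -- stage: filter + negative sampling ---------------------------------
    st = _Stage(manifest, "filter")
    pairs_tsv = out / "pairs.tsv"
    cached = pairs_tsv.exists()
    if not cached:
        flt = cfg["filter"]
        positives = filter_positive_set(
            records, positives, min_len=flt["min_len"],
            max_identity=flt["max_identity"],
        )
        negatives = sample_negatives(
            records, positives, ratio=flt["neg_ratio"],
            rng_seed=master * 2 + 1,
        )
        write_pairs_tsv(positives + negatives, pairs_tsv)
    st.done(cached=cached, outputs=[pairs_tsv])
    dataset = read_pairs_tsv(pairs_tsv)

    # -- stage: featurize ---------------------------------------------------
    st = _Stage(manifest, "featurize")
    enc = cfg["encoders"]
    lam = enc["lambda"]
    paths = {t: out / f"features_{t}.tsv" for t in ("ac", "ct", "ld", "pseaac")}
    cached = all(p.exists() for p in paths.values())
    if not cached:
        kwargs = {
            "ac": {"lg": enc["lag"]},
            "ct": {},
            "ld": {"distribution": enc["ld_distribution"]},
            "pseaac": {
                "params": PseAACParams(
                    lambda_=lam, correlation=enc["pseaac_correlation"]
                )
            },
        }
        for tech, p in paths.items():
            table = encode_collection(records, tech, **kwargs[tech])
            write_feature_tsv(
                table, feature_names(tech, lg=enc["lag"], lambda_=lam), p
            )
    st.done(cached=cached, outputs=list(paths.values()))
    features = {t: read_feature_tsv(p) for t, p in paths.items()}

    # -- stage: split -------------------------------------------------------
    rng = np.random.default_rng([master, 3])
    y = np.array(dataset.labels)
    n = len(dataset)
    test_frac = cfg["split"]["test_fraction"]
    test_idx: list[int] = []
    for label in (0, 1):
        cls = np.flatnonzero(y == label)
        take = rng.choice(cls, size=int(round(test_frac * len(cls))), replace=False)
        test_idx += take.tolist()
    test_mask = np.zeros(n, dtype=bool)
    test_mask[test_idx] = True
    train_set = dataset.subset(np.flatnonzero(~test_mask))
    test_set = dataset.subset(np.flatnonzero(test_mask))

    # -- stage: train (file-level caching per learner fold + meta) ----------
    st = _Stage(manifest, "train")
    ens = cfg["ensemble"]
    variant = ens["variant"]
    feats = features
    if variant == "concat":
        feats = concat_features(features)
    elif variant.startswith("single:"):
        tech = variant.split(":", 1)[1]
        feats = {tech: features[tech]}
    lengths = {t: len(next(iter(tab.values()))) for t, tab in feats.items()}
    configs = default_learner_grid(
        lengths, seed=master, epochs=ens["epochs"],
        channels=ens["channels"], n_blocks=ens["n_blocks"],
    )
    stacking = StackingConfig(
        K=ens["folds"],
        meta_layers=tuple(ens["meta_layers"]),
        eta=ens["eta"],
        max_iters=ens["max_iters"],
        epsilon=ens["epsilon"],
        seed=master,
    )
    model_dir = out / "model"
    model, cached_train = _train_with_cache(
        feats, train_set, configs, stacking, model_dir
    )
    st.done(cached=cached_train, outputs=[model_dir])

    # -- stage: evaluate ----------------------------------------------------
    st = _Stage(manifest, "evaluate")
    metrics_json = out / "metrics.json"
    test_data = encode_pairs(feats, test_set)
    scores = model.predict_positive(test_data)
    report = evaluate(test_data.y, scores)
    report["n_train"] = len(train_set)
    report["n_test"] = len(test_set)
    metrics_json.write_text(json.dumps(report, indent=2))
    st.done(cached=False, outputs=[metrics_json])

    manifest["outputs"] = {"metrics": report, "model_dir": str(model_dir)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _train_with_cache(
    feats: dict,
    train_set: PairDataset,
    configs: list[LearnerConfig],
    stacking: StackingConfig,
    model_dir: Path,
) -> tuple[StackedModel, bool]:
    """Train the stack, reusing any learner/meta weight files already in
    model_dir.  Returns (model, fully_cached)."""
    model_dir.mkdir(parents=True, exist_ok=True)
    learner_files = [
        model_dir / f"learner_{m:02d}_{k}.npz"
        for m in range(len(configs))
        for k in range(stacking.K)
    ]
    meta_file = model_dir / "meta.npz"
    mm_file = model_dir / "meta_matrix.npz"
    have_learners = all(p.exists() for p in learner_files) and mm_file.exists()
    have_meta = meta_file.exists()
    if have_learners and have_meta and (model_dir / "model.json").exists():
        model, _ = load_stacked(model_dir)
        return model, True

    data = encode_pairs(feats, train_set)
    if have_learners:
        # only the meta-learner is missing: reload the first layer and its
        # out-of-fold matrix, retrain the second layer alone
        model, _ = load_stacked_first_layer(model_dir, configs, stacking)
        with np.load(mm_file) as z:
            meta_matrix = z["meta"]
            fold_of_sample = z["fold_of_sample"]
        meta_net = train_meta(meta_matrix, data.y, stacking)
        model = StackedModel(
            fold_models=model,
            meta=meta_net,
            meta_feature_names=[c.name or f"learner_{m}" for m, c in enumerate(configs)],
            stacking=stacking,
            train_meta_matrix=meta_matrix,
            fold_of_sample=fold_of_sample,
        )
        save_stacked(model, configs, model_dir)
        return model, False

    def factory(m: int) -> BasicLearner:
        return BasicLearner(configs[m])

    meta_matrix, fold_models, fold_of_sample = build_meta_features(
        data, factory, len(configs), stacking
    )
    meta_net = train_meta(meta_matrix, data.y, stacking)
    model = StackedModel(
        fold_models=fold_models,
        meta=meta_net,
        meta_feature_names=[c.name or f"learner_{m}" for m, c in enumerate(configs)],
        stacking=stacking,
        train_meta_matrix=meta_matrix,
        fold_of_sample=fold_of_sample,
    )
    save_stacked(model, configs, model_dir)
    return model, False


def load_stacked_first_layer(
    model_dir: Path, configs: list[LearnerConfig], stacking: StackingConfig
) -> tuple[list[list[BasicLearner]], list[LearnerConfig]]:
    fold_models = []
    for m, cfg in enumerate(configs):
        models_m = []
        for k in range(stacking.K):
            learner = BasicLearner(cfg)
            with np.load(model_dir / f"learner_{m:02d}_{k}.npz") as z:
                learner.load_state_arrays(dict(z))
            models_m.append(learner)
        fold_models.append(models_m)
    return fold_models, configs
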