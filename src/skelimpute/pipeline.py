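"""High-level experiment pipeline: dataset assembly, desk-scale training
recipes, held-out gap evaluation and reproducible run manifests.

The desk presets are sized for a single CPU core: ~250 training samples of
60 frames with a 2-layer/dim-32 transformer or 2x48 bidirectional GRU,
trained for tens of epochs with 1-3 simultaneously masked keypoints per
sample.  These sizes are the package's supported configuration for the
bundled synthetic fixtures; the reference-scale hyperparameters remain the
defaults of ModelConfig/TrainConfig.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigError
from .gaps import GapSpec, GapStats, MaskedSample, apply_gaps, estimate_gap_stats
from .inference import linear_interpolate_array
from .io import Sample, build_dataset_split, load_recording, split_dataset
from .metrics import mpjpe, rmse
from .nn.models import (ModelConfig, build_model, desk_config, predict_batch,
                        save_checkpoint)
from .preprocess import HeadingRule, TransformMeta, inverse_transform, normalize_sample
from .synthetic import MotionSpec, mouse8_spec, simulate_recording
from .training import TrainConfig, TrainHistory, train

DESK_EPOCHS = {"transformer": 50, "gru": 40, "tcn": 40}
DESK_TRAIN = {
    "transformer": dict(lr=5e-3, batch_size=8, scheduler_gamma=0.7,
                        scheduler_step=8),
    "gru": dict(lr=1e-3, batch_size=32, scheduler_gamma=0.7, scheduler_step=10),
    "tcn": dict(lr=1e-3, batch_size=32, scheduler_gamma=0.7, scheduler_step=10),
}


@dataclass
class NormalizedSet:
    """Normalized samples with their transforms and originals, per split."""

    train: list[Sample]
    val: list[Sample]
    test: list[Sample]
    test_meta: list[TransformMeta]
    test_orig: list[Sample]


def desk_dataset(seed: int = 0, n_recordings: int = 12, frames: int = 1000,
                 spec: MotionSpec | None = None,
                 n_train: int = 256, n_val: int = 32,
                 heading_rule: HeadingRule | None = None) -> NormalizedSet:
    """Simulate recordings, split by recording, window and normalize."""
    spec = spec or mouse8_spec()
    recs = [simulate_recording(spec, T=frames, seed=seed * 1009 + i,
                               id=f"rec{i}") for i in range(n_recordings)]
    assign = split_dataset(recs, mode="by_recording", seed=seed)
    split = build_dataset_split(assign, length=60, stride=30,
                                complete_only=True)
    norm = {}
    metas = []
    for name in ("train", "val", "test"):
        out = []
        for s in getattr(split, name):
            ns, meta = normalize_sample(s, heading_rule)
            out.append(ns)
            if name == "test":
                metas.append(meta)
        norm[name] = out
    return NormalizedSet(norm["train"][:n_train], norm["val"][:n_val],
                         norm["test"], metas, split.test)


def desk_train(backbone: str, data: NormalizedSet, seed: int = 0,
               proba: bool = False, epochs: int | None = None,
               n_missing=(1, 3), switch_prob: float = 0.0,
               **model_overrides) -> tuple[object, TrainHistory]:
    """Train a desk-scale model with the recipe for its backbone."""
    K = data.train[0].coords.shape[1]
    D = data.train[0].coords.shape[2]
    cfgm = desk_config(backbone, K=K, D=D, proba=proba, **model_overrides)
    cfgm.n_missing_train = (n_missing[1] if isinstance(n_missing, tuple)
                            else int(n_missing))
    model = build_model(cfgm, seed=seed)
    cfg = TrainConfig(epochs=epochs or DESK_EPOCHS[backbone], seed=seed,
                      switch_prob=switch_prob, n_missing=n_missing,
                      **DESK_TRAIN[backbone])
    stats = GapStats.uniform(K, 58)
    return train(model, data.train, data.val, cfg, stats)


@dataclass
class EvalCase:
    """One held-out sample with a fixed artificial gap."""

    normalized: Sample
    masked: MaskedSample
    meta: TransformMeta
    original: Sample


def make_eval_cases(data: NormalizedSet, seed: int,
                    min_len: int = 30, max_len: int = 58,
                    n_cases: int | None = None) -> list[EvalCase]:
    """Fixed single-keypoint gaps of length [min_len, max_len] on test
    samples (first/last frame of the keypoint observed)."""
    rng = np.random.default_rng(seed)
    cases = []
    items = list(zip(data.test, data.test_meta, data.test_orig))
    if n_cases is not None:
        items = items[:n_cases]
    for ns, meta, orig in items:
        L, K, _ = ns.coords.shape
        k = int(rng.integers(0, K))
        ln = int(rng.integers(min_len, max_len + 1))
        st = int(rng.integers(1, L - ln))
        cases.append(EvalCase(ns, apply_gaps(ns, [GapSpec(k, st, ln)]),
                              meta, orig))
    return cases


def evaluate_model_on_cases(model, cases: list[EvalCase],
                            batch_size: int = 32) -> dict:
    """Original-units RMSE/MPJPE per case for a trained model."""
    per_rmse, per_mpjpe, est_err = [], [], []
    for i in range(0, len(cases), batch_size):
        chunk = cases[i:i + batch_size]
        inputs = np.stack([c.masked.input for c in chunk])
        masks = np.stack([c.masked.gap_mask for c in chunk])
        pred = predict_batch(model, inputs, masks)
        for j, c in enumerate(chunk):
            filled = c.normalized.copy()
            filled.coords = np.where(c.masked.gap_mask[..., None],
                                     pred.mean[j], c.normalized.coords)
            back = inverse_transform(filled, c.meta)
            per_rmse.append(rmse(back.coords, c.original.coords,
                                 c.masked.gap_mask))
            per_mpjpe.append(mpjpe(back.coords, c.original.coords,
                                   c.masked.gap_mask))
            if pred.std is not None:
                est_err.append(float(pred.std[j][c.masked.gap_mask].mean()))
    out = {"rmse": float(np.mean(per_rmse)),
           "mpjpe": float(np.mean(per_mpjpe)),
           "per_sample_rmse": per_rmse}
    if est_err:
        out["estimated_error"] = est_err
    return out


def evaluate_linear_on_cases(cases: list[EvalCase]) -> dict:
    """Linear-interpolation baseline on the same cases (original units)."""
    per_rmse = []
    for c in cases:
        coords = c.original.coords.copy()
        coords[c.masked.gap_mask] = np.nan
        filled, _ = linear_interpolate_array(coords, c.masked.gap_mask.copy())
        per_rmse.append(rmse(filled, c.original.coords, c.masked.gap_mask))
    return {"rmse": float(np.mean(per_rmse)), "per_sample_rmse": per_rmse}


# ---------------------------------------------------------------------------
# config-driven pipeline with manifest


_SCHEMA = {
    "io": {"inputs": list, "fps": (int, float)},
    "synth": {"preset": str, "n_recordings": int, "frames": int, "seed": int},
    "split": {"mode": str, "fractions": list, "seed": int,
              "length": int, "stride": int},
    "model": {"backbone": str, "proba": bool, "desk": bool},
    "train": {"epochs": int, "seed": int, "switch_prob": (int, float)},
    "impute": {"error_threshold": (int, float)},
}


def validate_config(cfg: dict) -> None:
    """Shallow schema check with field-path error messages."""
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    for section, val in cfg.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section '{section}'")
        if not isinstance(val, dict):
            raise ConfigError(f"'{section}' must be a mapping")
        for key, v in val.items():
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown field '{section}.{key}'")
            if not isinstance(v, _SCHEMA[section][key]):
                raise ConfigError(
                    f"field '{section}.{key}' has wrong type "
                    f"{type(v).__name__}")
    for required in ("split", "model"):
        if required not in cfg:
            raise ConfigError(f"missing required section '{required}'")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute split -> gap stats -> train -> eval -> (optional) impute and
    write a run manifest making the run reproducible."""
    import yaml

    if not isinstance(config, dict):
        cfg_path = Path(config)
        config = yaml.safe_load(cfg_path.read_text())
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"version": __version__, "config": config,
                      "inputs": {}, "outputs": {}}

    # -- data
    if "synth" in config:
        sy = config["synth"]
        seed = sy.get("seed", 0)
        spec = mouse8_spec() if sy.get("preset", "mouse8") == "mouse8" else None
        recs = [simulate_recording(spec or mouse8_spec(),
                                   T=sy.get("frames", 1000),
                                   seed=seed * 1009 + i, id=f"rec{i}")
                for i in range(sy.get("n_recordings", 12))]
    else:
        paths = [Path(p) for p in config.get("io", {}).get("inputs", [])]
        recs = [load_recording(p, fps=config.get("io", {}).get("fps"))
                for p in paths]
        manifest["inputs"] = {str(p): _digest(p) for p in paths}

    sp = config["split"]
    assign = split_dataset(recs, tuple(sp.get("fractions", (0.7, 0.15, 0.15))),
                           sp.get("mode", "by_recording"), sp.get("seed", 0))
    split = build_dataset_split(assign, sp.get("length", 60),
                                sp.get("stride", 30), complete_only=True)
    stats = estimate_gap_stats(recs)
    stats.to_json(out / "gap_stats.json")
    manifest["outputs"]["gap_stats"] = "gap_stats.json"

    # -- normalize
    data_norm, metas, origs = {}, [], []
    for name in ("train", "val", "test"):
        lst = []
        for s in getattr(split, name):
            ns, meta = normalize_sample(s)
            lst.append(ns)
            if name == "test":
                metas.append(meta)
                origs.append(s)
        data_norm[name] = lst
    data = NormalizedSet(data_norm["train"], data_norm["val"],
                         data_norm["test"], metas, origs)

    # -- train
    mc = config["model"]
    tr = config.get("train", {})
    model, history = desk_train(mc.get("backbone", "gru"), data,
                                seed=tr.get("seed", 0),
                                proba=mc.get("proba", False),
                                epochs=tr.get("epochs"),
                                switch_prob=tr.get("switch_prob", 0.0))
    save_checkpoint(model, out / "model.npz",
                    extra={"train_seed": tr.get("seed", 0)})
    hist_rows = ["epoch,loss,val_rmse,lr"]
    hist_rows += [f"{i},{l},{v},{r}" for i, (l, v, r) in
                  enumerate(zip(history.train_loss, history.val_rmse,
                                history.lr))]
    (out / "training_log.csv").write_text("\n".join(hist_rows) + "\n")
    manifest["outputs"]["checkpoint"] = "model.npz"
    manifest["outputs"]["training_log"] = "training_log.csv"

    # -- evaluate
    cases = make_eval_cases(data, seed=tr.get("seed", 0) + 17)
    res_model = evaluate_model_on_cases(model, cases)
    res_lin = evaluate_linear_on_cases(cases)
    metrics_out = {"model_rmse": res_model["rmse"],
                   "model_mpjpe": res_model["mpjpe"],
                   "linear_rmse": res_lin["rmse"],
                   "best_epoch": history.best_epoch,
                   "best_val_rmse": float(min(history.val_rmse))}
    (out / "metrics.json").write_text(json.dumps(metrics_out, indent=1))
    manifest["outputs"]["metrics"] = "metrics.json"
    manifest["seeds"] = {"split": sp.get("seed", 0), "train": tr.get("seed", 0)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return metrics_out
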