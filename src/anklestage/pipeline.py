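"""End-to-end orchestration: generate -> window -> balance -> tune ->
train -> evaluate -> emit scene control parameters.

The pipeline mirrors the online decision loop: cycle-level stage
predictions are smoothed over a five-cycle window centred on the
current cycle (two before, two after) by majority vote with ties broken
toward the centre prediction, and the decided stage selects the VR
scene control parameters.

Every random draw descends from the single config seed; a manifest
records each written artifact with its SHA-256 hash, so two runs with
the same config produce identical manifests.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import augmentation, decision_model, metrics, synthetic_data, vr_mapping
from .optimizers import WoaConfig
from .stages import STAGES, stage_index, stage_label

log = logging.getLogger("anklestage")


@dataclass
class RunConfig:
    seed: int = 7
    n_cycles_per_stage: dict[str, int] = field(
        default_factory=lambda: {"I": 24, "II": 8, "III": 8, "IV": 8, "V": 24})
    duration_s: float = 8.0
    window: int = 50
    stride: int = 25
    smote: augmentation.SmoteConfig = field(default_factory=augmentation.SmoteConfig)
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    tune: bool = True
    woa_agents: int = 8
    woa_iterations: int = 5
    epochs: int = 120
    batch_size: int = 16
    fitness_epochs: int = 30
    n_classes: int = 5

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def load_run_config(path=None) -> RunConfig:
    """Load a YAML run config; ``None`` loads the packaged default."""
    if path is None:
        text = (importlib.resources.files("anklestage") / "config" / "default_run.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    sm = raw.get("smote", {})
    return RunConfig(
        seed=int(raw.get("seed", 7)),
        n_cycles_per_stage={k: int(v) for k, v in raw["dataset"]["n_cycles_per_stage"].items()},
        duration_s=float(raw["dataset"]["duration_s"]),
        window=int(raw["window"]["length"]),
        stride=int(raw["window"]["stride"]),
        smote=augmentation.SmoteConfig(
            k_neighbors=int(sm.get("k_neighbors", 5)),
            sampling_ratio=float(sm.get("sampling_ratio", 1.0)),
            upsampling_rate=float(sm.get("upsampling_rate", 100.0)),
            seed=int(raw.get("seed", 7))),
        split_fractions=(float(raw["split"]["train"]), float(raw["split"]["valid"]),
                         float(raw["split"]["test"])),
        tune=bool(raw.get("tune", {}).get("enabled", True)),
        woa_agents=int(raw.get("tune", {}).get("n_agents", 8)),
        woa_iterations=int(raw.get("tune", {}).get("max_iteration", 5)),
        epochs=int(raw.get("train", {}).get("epochs", 120)),
        batch_size=int(raw.get("train", {}).get("batch_size", 16)),
        fitness_epochs=int(raw.get("train", {}).get("fitness_epochs", 30)),
        n_classes=int(raw.get("model", {}).get("n_classes", 5)),
    )


def smooth_decision(window: list[str]) -> str:
    """Majority vote over up to five cycle-level predictions.

    Ties are broken toward the centre prediction; if the centre's label
    is not among the tied leaders, the leader occurring closest to the
    centre index wins (earlier index on a further tie).
    """
    if not window:
        raise ValueError("decision window is empty")
    counts = Counter(window)
    top = max(counts.values())
    leaders = {lab for lab, c in counts.items() if c == top}
    centre = len(window) // 2
    if window[centre] in leaders:
        return window[centre]
    best = min((abs(i - centre), i) for i, lab in enumerate(window) if lab in leaders)
    return window[best[1]]


def smooth_stream(predictions: list[str], half_width: int = 2) -> list[str]:
    """Apply :func:`smooth_decision` across a stream of cycle predictions."""
    out = []
    for t in range(len(predictions)):
        lo = max(t - half_width, 0)
        hi = min(t + half_width + 1, len(predictions))
        out.append(smooth_decision(predictions[lo:hi]))
    return out


def split_cycles(cycles: list[synthetic_data.TrainingCycle],
                 fractions: tuple[float, float, float], seed: int):
    """Stratified-by-stage cycle-level split (before any augmentation)."""
    rng = np.random.default_rng(seed)
    train, valid, test = [], [], []
    for stage in STAGES:
        group = [c for c in cycles if c.stage_label == stage]
        if not group:
            continue
        order = rng.permutation(len(group))
        n = len(group)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        n_tr = min(n_tr, n - 2) if n >= 3 else max(n - 1, 1)
        n_va = max(min(n_va, n - n_tr - 1), 1 if n - n_tr >= 2 else 0)
        for j, k in enumerate(order):
            if j < n_tr:
                train.append(group[k])
            elif j < n_tr + n_va:
                valid.append(group[k])
            else:
                test.append(group[k])
    return train, valid, test


def make_splits(cycles, config: RunConfig,
                stride: int | None = None) -> decision_model.DataSplits:
    """Split cycles, segment each split, and SMOTE-balance the train split."""
    stride = stride if stride is not None else config.stride
    tr_c, va_c, te_c = split_cycles(cycles, config.split_fractions, config.seed)
    tr_w = augmentation.segment_dataset(tr_c, config.window, stride)
    tr_w = augmentation.smote_balance(tr_w, config.smote)
    va_w = augmentation.segment_dataset(va_c, config.window, stride)
    te_w = augmentation.segment_dataset(te_c, config.window, stride)
    Xtr, ytr = augmentation.windows_to_arrays(tr_w)
    Xva, yva = augmentation.windows_to_arrays(va_w)
    Xte, yte = augmentation.windows_to_arrays(te_w)
    return decision_model.DataSplits(Xtr, ytr, Xva, yva, Xte, yte), (tr_c, va_c, te_c)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def save_model(model: decision_model.CnnGruModel, path: Path) -> None:
    arrays = dict(model.params)
    if model.scaler is not None:
        arrays["scaler_mean"], arrays["scaler_std"] = model.scaler
    np.savez(path, **arrays)
    meta = {
        "spec": vars(model.spec) | {"conv_filters": list(model.spec.conv_filters)},
        "hyperparameters": vars(model.hp),
        "seed": model.seed,
        "n_parameters": model.n_parameters,
    }
    _write_json(path.with_suffix(".json"), meta)


def load_model(path: Path) -> decision_model.CnnGruModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_kw = dict(meta["spec"])
    spec_kw["conv_filters"] = tuple(spec_kw["conv_filters"])
    model = decision_model.build_model(
        decision_model.ModelSpec(**spec_kw),
        decision_model.Hyperparameters(**meta["hyperparameters"]),
        seed=meta["seed"])
    with np.load(path.with_suffix(".npz")) as npz:
        for k in model.params:
            model.params[k] = npz[k]
        if "scaler_mean" in npz:
            model.scaler = (npz["scaler_mean"], npz["scaler_std"])
    return model


def cycle_level_predictions(model, cycles, config: RunConfig) -> list[str]:
    """Predict a stage per cycle: argmax over its windows' summed scores."""
    preds = []
    for c in cycles:
        wins = augmentation.sliding_windows(c, config.window, config.stride)
        if not wins:
            continue
        X, _ = augmentation.windows_to_arrays(wins)
        _, probs = decision_model.predict(model, X)
        preds.append(stage_label(int(probs.sum(axis=0).argmax())))
    return preds


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full decision pipeline and write all artifacts.

    Returns a results dict; see the manifest for the artifact list.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: dict[str, str] = {}

    def record(path: Path) -> None:
        artifacts[path.name] = _sha256(path)

    log.info("stage 1/7: generate synthetic dataset")
    profiles = synthetic_data.default_profiles()
    cycles = synthetic_data.generate_dataset(
        profiles, config.n_cycles_per_stage, config.duration_s, config.seed)
    dataset_csv = out / "dataset.csv"
    synthetic_data.write_cycles_csv(cycles, dataset_csv)
    record(dataset_csv)

    log.info("stage 2/7: split, window (W=%d, stride=%d) and balance",
             config.window, config.stride)
    splits, (tr_c, va_c, te_c) = make_splits(cycles, config)
    windows_path = out / "train_windows"
    tr_w = augmentation.segment_dataset(tr_c, config.window, config.stride)
    tr_w = augmentation.smote_balance(tr_w, config.smote)
    augmentation.save_windows(tr_w, windows_path)
    record(out / "train_windows.npz")
    record(out / "train_windows.json")

    train_cfg = decision_model.TrainConfig(
        epochs=config.epochs, batch_size=config.batch_size,
        seed=config.seed, fitness_epochs=config.fitness_epochs)
    spec = decision_model.ModelSpec(window=config.window, n_classes=config.n_classes)

    if config.tune:
        log.info("stage 3/7: WOA hyperparameter search (%d agents, %d iterations)",
                 config.woa_agents, config.woa_iterations)
        woa_cfg = WoaConfig(n_agents=config.woa_agents,
                            max_iteration=config.woa_iterations, seed=config.seed)
        hp, run = decision_model.woa_tune(splits, woa_cfg, train_cfg, spec)
        trace_csv = out / "tuning_trace.csv"
        pd.DataFrame({"iteration": range(len(run.trace)),
                      "best_cost": run.trace}).to_csv(trace_csv, index=False)
        record(trace_csv)
    else:
        log.info("stage 3/7: tuning disabled; using control hyperparameters")
        hp = decision_model.CONTROL_HP

    log.info("stage 4/7: train final model (%d epochs, hp=%s)", config.epochs, hp)
    model = decision_model.build_model(spec, hp, seed=config.seed)
    result = train_history = decision_model.train(
        model, splits.X_train, splits.y_train, splits.X_valid, splits.y_valid,
        cfg=train_cfg)
    curves_csv = out / "training_curve.csv"
    pd.DataFrame({"epoch": range(1, len(result["loss"]) + 1),
                  "loss": result["loss"]}).to_csv(curves_csv, index=False)
    record(curves_csv)
    model_path = out / "model"
    save_model(model, model_path)
    record(out / "model.npz")
    record(out / "model.json")

    log.info("stage 5/7: evaluate on the held-out test split")
    y_pred, _ = decision_model.predict(model, splits.X_test)
    table = metrics.confusion_table(splits.y_test, y_pred, config.n_classes)
    report = metrics.metrics_report(table)
    metrics_json = out / "metrics.json"
    _write_json(metrics_json, report)
    record(metrics_json)
    confusion_csv = out / "confusion.csv"
    pd.DataFrame(table.counts,
                 index=[f"true_{s}" for s in STAGES[:config.n_classes]],
                 columns=[f"pred_{s}" for s in STAGES[:config.n_classes]]
                 ).to_csv(confusion_csv)
    record(confusion_csv)

    log.info("stage 6/7: cycle-level decision smoothing")
    cycle_preds = cycle_level_predictions(model, te_c, config)
    smoothed = smooth_stream(cycle_preds)
    decided = smooth_decision(smoothed[-min(5, len(smoothed)):]) if smoothed else None

    log.info("stage 7/7: emit scene control parameters")
    control = {}
    for s in STAGES[:min(config.n_classes, len(STAGES))]:
        p = vr_mapping.stage_to_control_params(s)
        control[s] = {"lambda_x": p.coefficients.lambda_x,
                      "lambda_y": p.coefficients.lambda_y,
                      "lambda_z": p.coefficients.lambda_z,
                      "max_contact_distance": p.max_contact_distance}
    control_json = out / "control_params.json"
    _write_json(control_json, {"table": control, "decided_stage": decided,
                               "decided_params": control.get(decided)})
    record(control_json)

    manifest = {
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items() if k != "smote"}
        | {"smote": vars(config.smote)},
        "artifacts": artifacts,
        "test_accuracy": report["accuracy"],
        "elapsed_s": round(time.time() - t0, 2),
    }
    # elapsed time is informational only; hashes exclude it
    _write_json(out / "manifest.json", manifest)

    return {"hyperparameters": hp, "metrics": report, "decided_stage": decided,
            "manifest": manifest, "history": train_history}
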