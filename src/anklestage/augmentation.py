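"""Data augmentation: sliding-window segmentation and SMOTE balancing.

Two augmentation steps compensate for the small number of recruited
subjects.  Sliding windows cut each training cycle into fixed-length
multichannel segments (the classifier's input unit; default length 50
timesteps, strides of 100/70/50/30% of the window).  SMOTE then
oversamples minority stages: a synthetic sample C = A + lambda * (B - A)
is placed on the segment between a minority original A and one of its k
nearest minority neighbors B (Euclidean distance on the flattened raw
window, no scaling), with lambda uniform on [0, 1], until class counts
reach the configured minority:majority ratio (1:1 by default).

Windowing is applied before balancing; callers should split train/test
before augmenting so synthetic points never leak into evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .stages import STAGES
from .synthetic_data import N_CHANNELS, TrainingCycle

DEFAULT_WINDOW = 50
DEFAULT_STRIDE = 25  # 50% of the window, the best-performing configuration


@dataclass(eq=False)
class FeatureWindow:
    """A fixed-length W x 6 segment inheriting its source cycle's label."""

    values: np.ndarray  # (W, 6)
    stage_label: str
    source_id: str
    start: int  # offset in timesteps within the source cycle; -1 for synthetic

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise ValueError(f"window values must be W x {N_CHANNELS}")

    def __eq__(self, other) -> bool:
        return (isinstance(other, FeatureWindow)
                and self.stage_label == other.stage_label
                and self.source_id == other.source_id
                and self.start == other.start
                and np.array_equal(self.values, other.values))

    @property
    def is_synthetic(self) -> bool:
        return self.start < 0


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    sampling_ratio: float = 1.0  # target minority:majority count ratio
    upsampling_rate: float = 100.0  # percent of the deficit to fill
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.sampling_ratio <= 1:
            raise ValueError("sampling_ratio must be in (0, 1]")
        if not 0 <= self.upsampling_rate <= 100:
            raise ValueError("upsampling_rate must be in [0, 100] percent")


def n_windows(T: int, window: int, stride: int) -> int:
    """Closed-form window count: floor((T - window)/stride) + 1, or 0 if window > T."""
    if stride <= 0:
        raise ValueError("stride must be >= 1")
    if window <= 0:
        raise ValueError("window must be >= 1")
    if window > T:
        return 0
    return (T - window) // stride + 1


def sliding_windows(cycle: TrainingCycle, window: int = DEFAULT_WINDOW,
                    stride: int = DEFAULT_STRIDE) -> list[FeatureWindow]:
    """Left-to-right fixed-stride segmentation of one cycle.

    A cycle shorter than the window yields an empty list (not an error).
    """
    count = n_windows(cycle.n_timesteps, window, stride)
    src = f"{cycle.subject_id}/{cycle.scene_id}/{cycle.cycle_index}"
    return [
        FeatureWindow(values=cycle.samples[i * stride: i * stride + window].copy(),
                      stage_label=cycle.stage_label, source_id=src, start=i * stride)
        for i in range(count)
    ]


def segment_dataset(cycles: list[TrainingCycle], window: int = DEFAULT_WINDOW,
                    stride: int = DEFAULT_STRIDE) -> list[FeatureWindow]:
    out: list[FeatureWindow] = []
    for c in cycles:
        out.extend(sliding_windows(c, window, stride))
    return out


def smote_sample(A: np.ndarray, B: np.ndarray, lam: float) -> np.ndarray:
    """Convex combination C = A + lam * (B - A), lam in [0, 1].

    Evaluated as (1 - lam) * A + lam * B so both endpoints are exact in
    floating point.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return (1.0 - lam) * A + lam * B


def _k_nearest(flat: np.ndarray, i: int, k: int) -> np.ndarray:
    """Indices of the k nearest rows to row i (excluding i), Euclidean,
    ties broken by lowest index (stable sort on distance)."""
    d = np.linalg.norm(flat - flat[i], axis=1)
    d[i] = np.inf
    order = np.argsort(d, kind="stable")
    return order[:k]


def smote_balance(windows: list[FeatureWindow],
                  config: SmoteConfig = SmoteConfig()) -> list[FeatureWindow]:
    """Oversample minority stages to the configured ratio with SMOTE.

    Original windows are returned unchanged (majority classes are never
    touched); synthetic windows carry the minority label, a
    ``smote:<stage>`` source id and start offset -1.  Reproducible via
    ``config.seed``.
    """
    if not windows:
        return []
    labels = np.array([w.stage_label for w in windows])
    counts = {s: int(np.sum(labels == s)) for s in STAGES if np.any(labels == s)}
    majority = max(counts.values())
    target = int(round(config.sampling_ratio * majority))

    rng = np.random.default_rng(config.seed)
    out = list(windows)
    shape = windows[0].values.shape
    for stage in STAGES:
        if stage not in counts:
            continue
        deficit = target - counts[stage]
        n_syn = int(round(deficit * config.upsampling_rate / 100.0))
        if n_syn <= 0:
            continue
        if counts[stage] < config.k_neighbors + 1:
            raise ValueError(
                f"stage {stage} has {counts[stage]} windows; SMOTE with "
                f"k_neighbors={config.k_neighbors} needs at least {config.k_neighbors + 1}")
        idx = np.flatnonzero(labels == stage)
        flat = np.stack([windows[j].values.ravel() for j in idx])
        neighbors = {i: _k_nearest(flat, i, config.k_neighbors) for i in range(len(idx))}
        for _ in range(n_syn):
            i = int(rng.integers(len(idx)))
            j = int(rng.choice(neighbors[i]))
            lam = float(rng.uniform())
            c = smote_sample(flat[i], flat[j], lam).reshape(shape)
            out.append(FeatureWindow(values=c, stage_label=stage,
                                     source_id=f"smote:{stage}", start=-1))
    return out


def windows_to_arrays(windows: list[FeatureWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into X (N, W, 6) and integer class labels y (N,)."""
    from .stages import stage_index
    X = np.stack([w.values for w in windows])
    y = np.array([stage_index(w.stage_label) for w in windows], dtype=np.int64)
    return X, y


def save_windows(windows: list[FeatureWindow], path) -> None:
    """Binary array container (.npz) plus a JSON sidecar with provenance."""
    path = Path(path)
    X, y = windows_to_arrays(windows)
    np.savez(path, values=X, labels=y)
    sidecar = {
        "shape": list(X.shape),
        "stage_labels": [w.stage_label for w in windows],
        "source_ids": [w.source_id for w in windows],
        "starts": [w.start for w in windows],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_windows(path) -> list[FeatureWindow]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as npz:
        X = npz["values"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return [FeatureWindow(values=X[i], stage_label=sidecar["stage_labels"][i],
                          source_id=sidecar["source_ids"][i], start=sidecar["starts"][i])
            for i in range(X.shape[0])]
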