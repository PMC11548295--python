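"""Synthetic stage-labelled ankle rehabilitation sessions.

The clinical dataset behind the decision model is confidential, so this
module generates sessions with the same statistical structure: per
training cycle a six-channel feature sequence sampled at 60 Hz —

    0. ankle joint angle trajectory (rad)
    1. angular velocity (rad/s, backward finite difference of channel 0)
    2. jerk (rad/s^3, third finite difference of channel 0)
    3. normalized rehabilitation assessment score in [0, 1] (constant
       within a cycle; the score is sampled, not computed)
    4. task completion count (constant non-negative integer)
    5. task completion degree in [0, 1] (constant)

— together with an expert Brunnstrom stage label I-V and a virtual scene
id in {s1, s2, s3}.

The angle trajectory follows the guidance protocol: a raised-cosine
flexion ramp at the stage's voluntary speed up to a peak drawn from the
stage's AROM distribution, a 2 s hold at maximum flexion, a raised-cosine
return, then rest.  A small 4 Hz tremor whose amplitude is set from the
stage's jerk level rides on the movement, so earlier (less recovered)
stages produce visibly rougher velocity and jerk channels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .stages import STAGES, stage_index

SAMPLE_RATE_HZ = 60.0
HOLD_SECONDS = 2.0
TREMOR_HZ = 4.0
N_CHANNELS = 6

CSV_COLUMNS = [
    "subject_id", "scene_id", "cycle_index", "time_s",
    "angle_rad", "ang_vel_rad_s", "jerk_rad_s3",
    "eval_score", "tc_count", "completion", "stage_label",
]

SCENES = ("s1", "s2", "s3")


@dataclass(frozen=True)
class StageProfile:
    """Feature distribution of one Brunnstrom stage.

    Angles in radians, velocities in rad/s, jerk in rad/s^3; the
    assessment score and completion degree are normalized to [0, 1];
    ``tc_rate`` is the expected completion count per session.
    """

    stage: str
    arom_mean: float
    arom_sd: float
    angvel_mean: float
    angvel_sd: float
    jerk_mean: float
    jerk_sd: float
    eval_score_mean: float
    eval_score_sd: float
    tc_rate: float
    completion_mean: float
    completion_sd: float

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        for name in ("arom_sd", "angvel_sd", "jerk_sd", "eval_score_sd", "completion_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.eval_score_mean <= 1.0:
            raise ValueError("eval_score_mean must lie in [0, 1]")
        if not 0.0 <= self.completion_mean <= 1.0:
            raise ValueError("completion_mean must lie in [0, 1]")
        if self.arom_mean <= 0 or self.angvel_mean <= 0 or self.tc_rate < 0:
            raise ValueError("arom_mean and angvel_mean must be > 0, tc_rate >= 0")


@dataclass
class TrainingCycle:
    """One rehabilitation training cycle: a T x 6 feature matrix plus labels."""

    subject_id: str
    scene_id: str
    cycle_index: int
    samples: np.ndarray  # (T, 6) float64
    stage_label: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(f"samples must be T x {N_CHANNELS}")
        if self.stage_label not in STAGES:
            raise ValueError(f"unknown stage label {self.stage_label!r}")

    @property
    def n_timesteps(self) -> int:
        return self.samples.shape[0]


def default_profiles() -> list[StageProfile]:
    """The five packaged stage profiles, ordered I..V.

    Deterministic: loaded from the packaged ``default_profiles.yaml``.
    """
    text = (importlib.resources.files("anklestage") / "config" / "default_profiles.yaml").read_text()
    return load_profiles_yaml(text)


def load_profiles_yaml(text: str) -> list[StageProfile]:
    raw = yaml.safe_load(text)
    profiles = [StageProfile(**entry) for entry in raw["profiles"]]
    _check_profile_ordering(profiles)
    return profiles


def dump_profiles_yaml(profiles: list[StageProfile]) -> str:
    return yaml.safe_dump({"profiles": [vars(p) for p in profiles]}, sort_keys=False)


def _check_profile_ordering(profiles: list[StageProfile]) -> None:
    if [p.stage for p in profiles] != list(STAGES)[: len(profiles)]:
        raise ValueError("profiles must be ordered I..V")
    aroms = [p.arom_mean for p in profiles]
    scores = [p.eval_score_mean for p in profiles]
    if not all(a < b for a, b in zip(aroms, aroms[1:])):
        raise ValueError("arom_mean must strictly increase with stage")
    if not all(a < b for a, b in zip(scores, scores[1:])):
        raise ValueError("eval_score_mean must strictly increase with stage")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -np.inf, hi: float = np.inf) -> float:
    # rejection sampling; the profile means sit far from the bounds so
    # this terminates almost immediately
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    return float(min(max(mean, lo + sd), hi - sd))


def generate_cycle(profile: StageProfile, scene_id: str, duration_s: float,
                   seed: int, subject_id: str = "sim", cycle_index: int = 0) -> TrainingCycle:
    """Synthesize one training cycle at 60 Hz.

    Identical ``(profile, seed)`` pairs give identical output; the angle
    channel is a smooth flex-hold-return trajectory, velocity and jerk
    are finite differences of it divided by the 1/60 s timestep.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if scene_id not in SCENES:
        raise ValueError(f"scene_id must be one of {SCENES}")
    rng = np.random.default_rng(seed)
    dt = 1.0 / SAMPLE_RATE_HZ
    n = int(round(duration_s * SAMPLE_RATE_HZ))
    t = np.arange(n) * dt

    peak = _truncated_normal(rng, profile.arom_mean, profile.arom_sd, lo=1e-3)
    speed = _truncated_normal(rng, profile.angvel_mean, profile.angvel_sd, lo=1e-2)
    jerk_level = _truncated_normal(rng, profile.jerk_mean, profile.jerk_sd, lo=0.0)

    hold = min(HOLD_SECONDS, 0.4 * duration_s)
    rise = peak / speed  # raised-cosine ramp whose mean speed is `speed`
    rise = float(np.clip(rise, 2 * dt, max((duration_s - hold) / 2.0, 2 * dt)))

    angle = np.zeros(n)
    up = t < rise
    angle[up] = 0.5 * peak * (1.0 - np.cos(np.pi * t[up] / rise))
    plateau = (t >= rise) & (t < rise + hold)
    angle[plateau] = peak
    down = (t >= rise + hold) & (t < 2 * rise + hold)
    angle[down] = 0.5 * peak * (1.0 + np.cos(np.pi * (t[down] - rise - hold) / rise))

    # tremor scaled so its third derivative magnitude matches the stage's
    # jerk level; multiplied by the movement envelope so rest stays quiet
    tremor_amp = jerk_level / (2.0 * np.pi * TREMOR_HZ) ** 3
    phase = rng.uniform(0.0, 2.0 * np.pi)
    envelope = angle / peak
    angle = angle + tremor_amp * np.sin(2.0 * np.pi * TREMOR_HZ * t + phase) * envelope

    vel = np.zeros(n)
    vel[1:] = np.diff(angle) / dt
    jerk = np.zeros(n)
    if n > 3:
        jerk[3:] = np.diff(angle, 3) / dt**3

    score = _truncated_normal(rng, profile.eval_score_mean, profile.eval_score_sd, 0.0, 1.0)
    tc = float(rng.poisson(profile.tc_rate))
    completion = _truncated_normal(rng, profile.completion_mean, profile.completion_sd, 0.0, 1.0)

    samples = np.column_stack([
        angle, vel, jerk,
        np.full(n, score), np.full(n, tc), np.full(n, completion),
    ])
    return TrainingCycle(subject_id=subject_id, scene_id=scene_id,
                         cycle_index=cycle_index, samples=samples,
                         stage_label=profile.stage)


def generate_dataset(profiles: list[StageProfile],
                     n_cycles_per_stage: dict[str, int],
                     duration_s: float, seed: int) -> list[TrainingCycle]:
    """Generate a labelled dataset with exactly the requested per-stage counts.

    Scene ids are assigned round-robin over {s1, s2, s3} in generation
    order; each cycle draws from an independent child seed of ``seed``,
    so the whole dataset is reproducible.
    """
    by_stage = {p.stage: p for p in profiles}
    unknown = set(n_cycles_per_stage) - set(by_stage)
    if unknown:
        raise ValueError(f"no profile for requested stage(s) {sorted(unknown)}")
    if any(c < 0 for c in n_cycles_per_stage.values()):
        raise ValueError("cycle counts must be >= 0")
    if sum(n_cycles_per_stage.values()) == 0:
        raise ValueError("at least one stage count must be positive")

    ss = np.random.SeedSequence(seed)
    cycles: list[TrainingCycle] = []
    k = 0
    for stage in STAGES:
        count = n_cycles_per_stage.get(stage, 0)
        for i in range(count):
            child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            cycles.append(generate_cycle(
                by_stage[stage], SCENES[k % len(SCENES)], duration_s,
                seed=child, subject_id=f"sim{stage}", cycle_index=i))
            k += 1
    return cycles


def cycles_to_frame(cycles: list[TrainingCycle]) -> pd.DataFrame:
    """Long-format table, one row per timestep, columns per CSV_COLUMNS."""
    frames = []
    dt = 1.0 / SAMPLE_RATE_HZ
    for c in cycles:
        n = c.n_timesteps
        frames.append(pd.DataFrame({
            "subject_id": c.subject_id,
            "scene_id": c.scene_id,
            "cycle_index": c.cycle_index,
            "time_s": np.arange(n) * dt,
            "angle_rad": c.samples[:, 0],
            "ang_vel_rad_s": c.samples[:, 1],
            "jerk_rad_s3": c.samples[:, 2],
            "eval_score": c.samples[:, 3],
            "tc_count": c.samples[:, 4],
            "completion": c.samples[:, 5],
            "stage_label": c.stage_label,
        }))
    return pd.concat(frames, ignore_index=True)[CSV_COLUMNS]


def write_cycles_csv(cycles: list[TrainingCycle], path) -> None:
    cycles_to_frame(cycles).to_csv(path, index=False, float_format="%.10g")


def read_cycles_csv(path) -> list[TrainingCycle]:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cycle CSV missing columns {sorted(missing)}")
    cycles = []
    for (subj, scene, idx), grp in df.groupby(
            ["subject_id", "scene_id", "cycle_index"], sort=False):
        grp = grp.sort_values("time_s")
        samples = grp[["angle_rad", "ang_vel_rad_s", "jerk_rad_s3",
                       "eval_score", "tc_count", "completion"]].to_numpy()
        labels = grp["stage_label"].unique()
        if len(labels) != 1:
            raise ValueError(f"cycle {(subj, scene, idx)} has mixed stage labels")
        cycles.append(TrainingCycle(subject_id=str(subj), scene_id=str(scene),
                                    cycle_index=int(idx), samples=samples,
                                    stage_label=str(labels[0])))
    return cycles
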