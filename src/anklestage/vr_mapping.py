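"""Ankle-pose transformation and stage-dependent scene control parameters.

The ankle-foot pose is decomposed as three consecutive rotations about
the x, y and z axes; each axis carries a patient-specific response
coefficient lambda (a dimensionless sensitivity gain) that scales the
whole axis-rotation matrix:

    A = (lx * Rx(phi)) @ (ly * Ry(theta)) @ (lz * Rz(psi))

With all gains equal to 1 the composed matrix is a proper rotation
(orthonormal, determinant 1); in general det(A) = (lx*ly*lz)^3.

Sign convention: right-handed axes, angles in radians, with sin above
-sin in each rotation matrix (the transpose of some textbook layouts).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

from .stages import STAGES


@dataclass(frozen=True)
class EulerAngles:
    phi: float    # about x
    theta: float  # about y
    psi: float    # about z

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.phi, self.theta, self.psi])):
            raise ValueError("Euler angles must be finite")


@dataclass(frozen=True)
class ResponseCoefficients:
    lambda_x: float = 1.0
    lambda_y: float = 1.0
    lambda_z: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lambda_x, self.lambda_y, self.lambda_z) <= 0:
            raise ValueError("response coefficients must be > 0")


@dataclass(frozen=True)
class SceneControlParams:
    stage: str
    coefficients: ResponseCoefficients
    max_contact_distance: float

    def __post_init__(self) -> None:
        if self.max_contact_distance <= 0:
            raise ValueError("max_contact_distance must be > 0")


def _check_lambda(lam: float) -> float:
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError(f"response coefficient must be finite and > 0, got {lam}")
    return float(lam)


def rotation_x(phi: float, lambda_x: float = 1.0) -> np.ndarray:
    lam = _check_lambda(lambda_x)
    c, s = np.cos(phi), np.sin(phi)
    return lam * np.array([[1.0, 0.0, 0.0],
                           [0.0, c, s],
                           [0.0, -s, c]])


def rotation_y(theta: float, lambda_y: float = 1.0) -> np.ndarray:
    lam = _check_lambda(lambda_y)
    c, s = np.cos(theta), np.sin(theta)
    return lam * np.array([[c, 0.0, -s],
                           [0.0, 1.0, 0.0],
                           [s, 0.0, c]])


def rotation_z(psi: float, lambda_z: float = 1.0) -> np.ndarray:
    lam = _check_lambda(lambda_z)
    c, s = np.cos(psi), np.sin(psi)
    return lam * np.array([[c, s, 0.0],
                           [-s, c, 0.0],
                           [0.0, 0.0, 1.0]])


def compose_transform(angles: EulerAngles,
                      coeffs: ResponseCoefficients = ResponseCoefficients()) -> np.ndarray:
    """Final pose transformation A = Rx @ Ry @ Rz (order fixed)."""
    return (rotation_x(angles.phi, coeffs.lambda_x)
            @ rotation_y(angles.theta, coeffs.lambda_y)
            @ rotation_z(angles.psi, coeffs.lambda_z))


def apply_transform(A: np.ndarray, v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,) or not np.all(np.isfinite(v)):
        raise ValueError("v must be a finite 3-vector")
    return A @ v


def load_control_table(text: str | None = None) -> dict[str, SceneControlParams]:
    """Stage -> control-parameter lookup, from YAML (packaged default table)."""
    if text is None:
        text = (importlib.resources.files("anklestage") / "config" / "control_params.yaml").read_text()
    raw = yaml.safe_load(text)["stages"]
    table: dict[str, SceneControlParams] = {}
    for stage in STAGES:
        if stage not in raw:
            raise ValueError(f"control table missing stage {stage}")
        row = raw[stage]
        table[stage] = SceneControlParams(
            stage=stage,
            coefficients=ResponseCoefficients(row["lambda_x"], row["lambda_y"], row["lambda_z"]),
            max_contact_distance=float(row["max_contact_distance"]),
        )
    dists = [table[s].max_contact_distance for s in STAGES]
    if not all(a > b for a, b in zip(dists, dists[1:])):
        raise ValueError("max_contact_distance must strictly decrease with stage")
    return table


_DEFAULT_TABLE: dict[str, SceneControlParams] | None = None


def stage_to_control_params(stage: str) -> SceneControlParams:
    """Deterministic lookup of scene control parameters for a stage."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_control_table()
    if stage not in _DEFAULT_TABLE:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return _DEFAULT_TABLE[stage]
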