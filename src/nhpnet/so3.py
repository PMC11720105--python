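"""Rotation mathematics for head-orientation estimation.

All head orientations are expressed either as proper rotation matrices
(orthonormal, det = +1) or as roll/pitch/yaw Euler angles in degrees under a
fixed anatomical convention:

* +x anterior, +y left, +z superior (right-handed, millimetres);
* roll is the rotation about +x, pitch about +y, yaw about +z;
* a triple (roll, pitch, yaw) composes as ``R = R_z(yaw) @ R_y(pitch) @ R_x(roll)``.

The convention is a package contract: the source data never states one, so
only internal consistency (exact round-trips) is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EulerAngles",
    "InvalidRotationError",
    "euler_to_matrix",
    "matrix_to_euler",
    "project_to_so3",
    "rotation_error",
    "angle_mae",
    "apply_rotation",
    "surface_distance",
    "is_rotation",
]

_ORTHO_TOL = 1e-9


class InvalidRotationError(ValueError):
    """Raised when a matrix claimed to be a rotation is not one."""


@dataclass(frozen=True)
class EulerAngles:
    """Roll/pitch/yaw in degrees; pitch in [-90, 90], roll/yaw in (-180, 180]."""

    roll: float
    pitch: float
    yaw: float

    def as_array(self) -> np.ndarray:
        return np.array([self.roll, self.pitch, self.yaw], dtype=float)


def is_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> bool:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.all(np.isfinite(R)):
        return False
    return (
        np.abs(R.T @ R - np.eye(3)).max() <= tol
        and abs(np.linalg.det(R) - 1.0) <= tol
    )


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if not is_rotation(R, tol=tol):
        raise InvalidRotationError(
            "matrix is not a proper rotation (orthonormal, det = +1)"
        )
    return R


def euler_to_matrix(angles: EulerAngles | tuple[float, float, float]) -> np.ndarray:
    """Rotation matrix for (roll, pitch, yaw) degrees, R = Rz @ Ry @ Rx."""
    if isinstance(angles, EulerAngles):
        roll, pitch, yaw = angles.roll, angles.pitch, angles.yaw
    else:
        roll, pitch, yaw = angles
    cr, sr = np.cos(np.radians(roll)), np.sin(np.radians(roll))
    cp, sp = np.cos(np.radians(pitch)), np.sin(np.radians(pitch))
    cy, sy = np.cos(np.radians(yaw)), np.sin(np.radians(yaw))
    Rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
    Ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
    Rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def matrix_to_euler(R: np.ndarray) -> EulerAngles:
    """Inverse of :func:`euler_to_matrix`.

    At gimbal lock (|pitch| = 90 deg within ~1e-7) the roll/yaw split is
    degenerate; by convention roll is set to 0 and yaw absorbs the remaining
    in-plane rotation.
    """
    R = _check_rotation(R)
    s = -R[2, 0]
    s = float(np.clip(s, -1.0, 1.0))
    pitch = np.degrees(np.arcsin(s))
    if 1.0 - abs(s) < 1e-7:
        # gimbal lock: only roll -/+ yaw is determined; put it all in yaw
        roll = 0.0
        if s > 0:  # pitch = +90
            yaw = np.degrees(np.arctan2(-R[0, 1], R[1, 1]))
        else:  # pitch = -90
            yaw = np.degrees(np.arctan2(R[0, 1], R[1, 1]))
    else:
        roll = np.degrees(np.arctan2(R[2, 1], R[2, 2]))
        yaw = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
    # map -180 to +180 so roll/yaw live in (-180, 180]
    if roll <= -180.0:
        roll += 360.0
    if yaw <= -180.0:
        yaw += 360.0
    return EulerAngles(float(roll), float(pitch), float(yaw))


def project_to_so3(A: np.ndarray) -> np.ndarray:
    """Frobenius-nearest proper rotation to an arbitrary 3x3 matrix.

    Computes the SVD ``A = U S V^T`` and returns ``U diag(1, 1, det(U V^T)) V^T``.
    The determinant correction keeps the output in SO(3) even when the plain
    ``U V^T`` product would be a reflection (det = -1).
    """
    A = np.asarray(A, dtype=float)
    if A.shape != (3, 3) or not np.all(np.isfinite(A)):
        raise ValueError("expected a finite 3x3 matrix")
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0:  # pathological; fall back to +1 deterministically
        d = 1.0
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def rotation_error(R_pred: np.ndarray, R_true: np.ndarray) -> float:
    """Geodesic angle between two rotations, degrees in [0, 180].

    RE = arccos((Tr(R_pred @ R_true^T) - 1) / 2), with the arccos argument
    clamped to [-1, 1] against floating-point drift.
    """
    R_pred = _check_rotation(R_pred)
    R_true = _check_rotation(R_true)
    c = (np.trace(R_pred @ R_true.T) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def angle_mae(
    predicted: list[EulerAngles], truth: list[EulerAngles]
) -> dict[str, dict[str, float | np.ndarray]]:
    """Per-angle mean absolute error between two equally long angle lists.

    Returns, for each of roll/pitch/yaw: the MAE, the standard deviation of the
    per-sample absolute errors (the "mean +/- SD" reporting style), and the raw
    per-sample absolute errors.
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth lists must have equal length")
    if len(predicted) == 0:
        raise ValueError("need at least one sample")
    p = np.array([e.as_array() for e in predicted])
    t = np.array([e.as_array() for e in truth])
    abs_err = np.abs(p - t)
    out: dict[str, dict[str, float | np.ndarray]] = {}
    for j, name in enumerate(("roll", "pitch", "yaw")):
        out[name] = {
            "mae": float(abs_err[:, j].mean()),
            "sd": float(abs_err[:, j].std(ddof=0)),
            "abs_errors": abs_err[:, j],
        }
    return out


def apply_rotation(
    vertices: np.ndarray, R: np.ndarray, center: np.ndarray | None = None
) -> np.ndarray:
    """Rotate an (n, 3) vertex array about ``center`` (default: its centroid)."""
    vertices = np.asarray(vertices, dtype=float)
    R = _check_rotation(R)
    if center is None:
        center = vertices.mean(axis=0)
    center = np.asarray(center, dtype=float)
    return (vertices - center) @ R.T + center


def surface_distance(
    vertices: np.ndarray,
    R_pred: np.ndarray,
    R_true: np.ndarray,
    center: np.ndarray | None = None,
) -> dict[str, float | np.ndarray]:
    """Per-vertex displacement between the two candidate alignments of a mesh.

    Both rotations act about the same shared center; the distances therefore
    grow linearly with each vertex's distance from that center (chord lengths
    of the relative rotation).
    """
    vertices = np.asarray(vertices, dtype=float)
    if center is None:
        center = vertices.mean(axis=0)
    a = apply_rotation(vertices, R_pred, center)
    b = apply_rotation(vertices, R_true, center)
    d = np.linalg.norm(a - b, axis=1)
    return {"distances": d, "mean": float(d.mean()), "max": float(d.max())}
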