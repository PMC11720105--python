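"""Synthetic skull-proxy cohorts with known canonical orientation.

Clinical CT data for head-orientation work is IRB-restricted, so every stage
of the pipeline is exercised on generated stand-ins. A proxy "skull" is a
star-shaped closed surface built on a subdivided icosphere: a superellipsoid
radial profile (the cranial vault), a smooth anterior-inferior bulge (the
jaw), and a single small lateral bump that breaks left-right symmetry. The
bump is essential: without it the surface can have rotational or mirror
self-symmetries and the ground-truth orientation would not be identifiable.

Each subject is generated in the canonical (natural head position) frame,
then rotated by a random acquisition misalignment — small roll/pitch/yaw
deviations drawn from truncated normals, emulating how a head sits in a CT
headrest. The stored ground truth is the rotation that maps the acquired
posture back to the canonical frame, i.e. exactly what an orientation
regressor must predict. Defaults: 5 degrees standard deviation per axis,
hard-truncated at 15 degrees, and a 10% relative spread on shape lengths —
plausible magnitudes for routine head CT, stated here as modelling choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.stats import truncnorm

from .geometry import TriangleMesh, write_stl
from .so3 import EulerAngles, euler_to_matrix, matrix_to_euler, apply_rotation

__all__ = [
    "ShapeParams",
    "MisalignmentModel",
    "CohortSpec",
    "LabeledSample",
    "Cohort",
    "make_skull_proxy",
    "sample_misalignment",
    "generate_cohort",
]

_ANTERIOR_INFERIOR = np.array([0.8, 0.0, -0.6])  # +x anterior, +z superior


@dataclass(frozen=True)
class ShapeParams:
    """Geometry of one skull proxy (millimetres, canonical frame)."""

    cranium_semiaxes: tuple[float, float, float] = (90.0, 70.0, 80.0)
    cranium_exponent: float = 1.25
    jaw_offset: tuple[float, float, float] = tuple(60.0 * _ANTERIOR_INFERIOR)
    jaw_scale: float = 0.35
    asymmetry_bump_position: tuple[float, float, float] = (0.25, 0.93, 0.27)
    asymmetry_bump_amplitude: float = 8.0
    mesh_resolution: int = 3  # icosphere subdivision level

    def __post_init__(self) -> None:
        if min(self.cranium_semiaxes) <= 0:
            raise ValueError("cranium semiaxes must be strictly positive")
        if self.cranium_exponent <= 0:
            raise ValueError("cranium exponent must be strictly positive")
        if self.mesh_resolution < 1:
            raise ValueError("mesh_resolution must be >= 1")
        if self.asymmetry_bump_amplitude < 0:
            raise ValueError("asymmetry bump amplitude must be non-negative")


@dataclass(frozen=True)
class MisalignmentModel:
    """Truncated-normal acquisition misalignment, degrees per axis."""

    sd_roll: float = 5.0
    sd_pitch: float = 5.0
    sd_yaw: float = 5.0
    truncation: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_roll, self.sd_pitch, self.sd_yaw) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.truncation <= 0:
            raise ValueError("truncation must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    n_train: int = 90
    n_val: int = 30
    n_test: int = 30
    shape_variability: float = 0.10  # relative spread on shape lengths
    misalignment: MisalignmentModel = field(default_factory=MisalignmentModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_val, self.n_test) < 0:
            raise ValueError("split counts must be >= 0")


@dataclass
class LabeledSample:
    """One subject: acquired mesh plus the orientation that restores NHP."""

    subject_id: str
    split: str
    mesh_canonical: TriangleMesh
    mesh_acquired: TriangleMesh
    rotation: np.ndarray  # acquired -> canonical (the regression target)
    angles: EulerAngles  # Euler decomposition of `rotation`

    def round_trip_residual(self) -> float:
        """Max vertex error after restoring the acquired mesh to canonical."""
        restored = apply_rotation(
            self.mesh_acquired.vertices,
            self.rotation,
            center=self.mesh_acquired.vertices.mean(axis=0),
        )
        return float(np.abs(restored - self.mesh_canonical.vertices).max())


@dataclass
class Cohort:
    samples: list[LabeledSample]
    spec: CohortSpec

    def split(self, name: str) -> list[LabeledSample]:
        return [s for s in self.samples if s.split == name]

    def table(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {
                "subject_id": s.subject_id,
                "split": s.split,
                "roll": s.angles.roll,
                "pitch": s.angles.pitch,
                "yaw": s.angles.yaw,
            }
            for i in range(3):
                for j in range(3):
                    row[f"r{i + 1}{j + 1}"] = s.rotation[i, j]
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in self.samples:
            write_stl(s.mesh_acquired, out_dir / f"{s.subject_id}.stl")
        self.table().to_csv(out_dir / "ground_truth.csv", index=False)


def _superellipsoid_radius(dirs: np.ndarray, semiaxes, exponent: float) -> np.ndarray:
    # radial distance of the superellipsoid |x/a|^m + |y/b|^m + |z/c|^m = 1
    m = 2.0 / exponent
    scaled = np.abs(dirs / np.asarray(semiaxes, float))
    return np.sum(scaled**m, axis=1) ** (-1.0 / m)


def _bump(dirs: np.ndarray, center: np.ndarray, width: float) -> np.ndarray:
    # smooth radial bump concentrated around the unit direction `center`
    t = dirs @ (center / np.linalg.norm(center))
    return np.exp((t - 1.0) / width)


def make_skull_proxy(params: ShapeParams) -> TriangleMesh:
    """Deterministically build the watertight proxy surface for ``params``."""
    base = trimesh.creation.icosphere(subdivisions=params.mesh_resolution, radius=1.0)
    dirs = np.asarray(base.vertices)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    r = _superellipsoid_radius(dirs, params.cranium_semiaxes, params.cranium_exponent)
    jaw_vec = np.asarray(params.jaw_offset, float)
    jaw_len = np.linalg.norm(jaw_vec)
    if params.jaw_scale != 0 and jaw_len > 0:
        r = r + params.jaw_scale * jaw_len * _bump(dirs, jaw_vec, width=0.18)
    if params.asymmetry_bump_amplitude > 0:
        bump_dir = np.asarray(params.asymmetry_bump_position, float)
        r = r + params.asymmetry_bump_amplitude * _bump(dirs, bump_dir, width=0.06)
    return TriangleMesh(dirs * r[:, None], np.asarray(base.faces))


def sample_misalignment(model: MisalignmentModel, k: int) -> list[EulerAngles]:
    """Draw ``k`` roll/pitch/yaw triples from per-axis truncated normals.

    Implemented as the truncated-normal quantile of seeded uniforms, so draws
    are deterministic and vectorized with no rejection loop.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(model.seed)
    u = rng.random((k, 3))
    sds = np.array([model.sd_roll, model.sd_pitch, model.sd_yaw])
    out = np.zeros((k, 3))
    for j, sd in enumerate(sds):
        if sd > 0:
            a = -model.truncation / sd
            out[:, j] = truncnorm.ppf(u[:, j], a, -a, loc=0.0, scale=sd)
    return [EulerAngles(*row) for row in out]


def _perturbed_shape(base: ShapeParams, spread: float, rng: np.random.Generator) -> ShapeParams:
    if spread == 0:
        return base
    f = lambda: 1.0 + spread * rng.uniform(-1.0, 1.0)  # noqa: E731
    semi = tuple(a * f() for a in base.cranium_semiaxes)
    jaw = tuple(np.asarray(base.jaw_offset) * f())
    bump_dir = np.asarray(base.asymmetry_bump_position) + 0.3 * spread * rng.standard_normal(3)
    bump_dir /= np.linalg.norm(bump_dir)
    return replace(
        base,
        cranium_semiaxes=semi,
        jaw_offset=jaw,
        jaw_scale=base.jaw_scale * f(),
        asymmetry_bump_position=tuple(bump_dir),
        asymmetry_bump_amplitude=base.asymmetry_bump_amplitude * f(),
    )


def generate_cohort(
    spec: CohortSpec, base_shape: ShapeParams = ShapeParams()
) -> Cohort:
    """Generate a train/val/test cohort of misaligned skull proxies.

    For each subject a canonical mesh is built from per-subject perturbed
    shape parameters, a misalignment Euler triple ``e`` is drawn, and the
    acquired mesh is the canonical mesh rotated by ``matrix(e)`` about its
    vertex centroid. The stored ground truth is ``matrix(e)^T`` — the
    rotation restoring the acquired posture to the canonical frame.
    Bit-reproducible for a fixed spec.
    """
    n_total = spec.n_train + spec.n_val + spec.n_test
    shape_rng = np.random.default_rng(spec.seed)
    model = replace(spec.misalignment, seed=spec.misalignment.seed)
    mis = sample_misalignment(model, n_total)
    splits = (
        ["train"] * spec.n_train + ["val"] * spec.n_val + ["test"] * spec.n_test
    )
    samples = []
    for i, (split, e) in enumerate(zip(splits, mis)):
        params = _perturbed_shape(base_shape, spec.shape_variability, shape_rng)
        canonical = make_skull_proxy(params)
        R_mis = euler_to_matrix(e)
        center = canonical.vertices.mean(axis=0)
        acquired = TriangleMesh(
            apply_rotation(canonical.vertices, R_mis, center=center),
            canonical.faces.copy(),
        )
        R_gt = R_mis.T
        samples.append(
            LabeledSample(
                subject_id=f"s{i:04d}",
                split=split,
                mesh_canonical=canonical,
                mesh_acquired=acquired,
                rotation=R_gt,
                angles=matrix_to_euler(R_gt),
            )
        )
    return Cohort(samples, spec)
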