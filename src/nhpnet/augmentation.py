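"""Training-set augmentation by perturbing ground-truth orientation angles.

Each training subject is expanded ``factor`` times (default 30) by rescaling
its ground-truth roll/pitch/yaw independently with per-axis factors drawn
from [1 - rel_range, 1 + rel_range] (default +/-50%). The factors are drawn
in antithetic pairs (s, 2 - s), so the mean of each augmented angle over a
subject's group equals the original angle *exactly*, not merely in
expectation — the augmented cohort keeps the per-subject mean orientation of
the original data. A subject with a zero angle on some axis keeps that axis
at zero (a relative perturbation of 0 is 0); this degeneracy is inherent to
relative scaling.

The acquired mesh of every augmented sample is re-derived by rotating the
subject's canonical mesh with the transpose of the new ground-truth rotation,
so the ground-truth round-trip invariant holds for augmented samples too. By
default the originals are replaced by their augmentations (90 subjects with
factor 30 yield exactly 2700 training samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import TriangleMesh
from .so3 import EulerAngles, euler_to_matrix, apply_rotation
from .synthetic import LabeledSample

__all__ = ["AugmentSpec", "augment_cohort"]


@dataclass(frozen=True)
class AugmentSpec:
    factor: int = 30
    rel_range: float = 0.5
    seed: int = 0
    keep_originals: bool = False
    preserve_mean: bool = True

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError("factor must be >= 1")
        if not 0 <= self.rel_range < 1:
            raise ValueError("rel_range must be in [0, 1)")
        if self.preserve_mean and self.factor % 2:
            raise ValueError("mean preservation needs an even factor (antithetic pairs)")


def _scale_factors(spec: AugmentSpec, rng: np.random.Generator) -> np.ndarray:
    """(factor, 3) per-axis scale factors, antithetically paired if requested."""
    if spec.preserve_mean:
        half = rng.uniform(1.0 - spec.rel_range, 1.0 + spec.rel_range, (spec.factor // 2, 3))
        return np.concatenate([half, 2.0 - half], axis=0)
    return rng.uniform(1.0 - spec.rel_range, 1.0 + spec.rel_range, (spec.factor, 3))


def augment_cohort(
    samples: list[LabeledSample], spec: AugmentSpec = AugmentSpec()
) -> list[LabeledSample]:
    """Expand training samples ``factor``-fold by rescaling their angles."""
    rng = np.random.default_rng(spec.seed)
    out: list[LabeledSample] = []
    for s in samples:
        if spec.keep_originals:
            out.append(s)
        base = s.angles.as_array()
        for j, scales in enumerate(_scale_factors(spec, rng)):
            angles = EulerAngles(*(scales * base))
            R_gt = euler_to_matrix(angles)
            center = s.mesh_canonical.vertices.mean(axis=0)
            acquired = TriangleMesh(
                apply_rotation(s.mesh_canonical.vertices, R_gt.T, center=center),
                s.mesh_canonical.faces,
            )
            out.append(
                LabeledSample(
                    subject_id=f"{s.subject_id}_a{j:02d}",
                    split=s.split,
                    mesh_canonical=s.mesh_canonical,
                    mesh_acquired=acquired,
                    rotation=R_gt,
                    angles=angles,
                )
            )
    return out
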