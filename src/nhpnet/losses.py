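"""Regression losses applied elementwise to predicted 3x3 rotation matrices.

The primary loss is the Wing loss: logarithmic near zero error (high gradient
sensitivity to small residuals) and linear beyond a width ``omega``, joined
continuously by the constant ``C = omega - omega * ln(1 + omega / epsilon)``:

    wing(d) = omega * ln(1 + d / epsilon)   if d < omega
              d - C                          otherwise,   d = |x - y|.

Defaults omega = 10, epsilon = 3. Since rotation-matrix entries differ by at
most 2, matrix regression always operates on the logarithmic branch with these
defaults; the linear branch exists for robustness and is exercised by tests.

All losses reduce by the mean over the 9 matrix elements, which keeps the
hyperparameters scale-free in the matrix size. Each loss also exposes its
gradient with respect to the prediction for the hand-written training loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WingParams", "wing_loss", "wing_loss_grad", "comparison_loss", "comparison_loss_grad", "make_loss"]


@dataclass(frozen=True)
class WingParams:
    omega: float = 10.0
    epsilon: float = 3.0
    C: float = field(init=False)

    def __post_init__(self) -> None:
        if self.omega <= 0 or self.epsilon <= 0:
            raise ValueError("omega and epsilon must be positive")
        object.__setattr__(
            self, "C", self.omega - self.omega * np.log1p(self.omega / self.epsilon)
        )


def wing_loss(x: np.ndarray, y: np.ndarray, params: WingParams = WingParams()) -> float:
    """Mean Wing loss between prediction ``x`` and target ``y`` (elementwise)."""
    d = np.abs(np.asarray(x, float) - np.asarray(y, float))
    inner = params.omega * np.log1p(d / params.epsilon)
    outer = d - params.C
    return float(np.where(d < params.omega, inner, outer).mean())


def wing_loss_grad(
    x: np.ndarray, y: np.ndarray, params: WingParams = WingParams()
) -> np.ndarray:
    """d(wing_loss)/dx. At d = 0 the subgradient 0 is returned."""
    x = np.asarray(x, float)
    diff = x - np.asarray(y, float)
    d = np.abs(diff)
    inner_slope = (params.omega / params.epsilon) / (1.0 + d / params.epsilon)
    slope = np.where(d < params.omega, inner_slope, 1.0)
    return np.sign(diff) * slope / x.size


def comparison_loss(x: np.ndarray, y: np.ndarray, kind: str, delta: float = 1.0) -> float:
    """Baseline losses: elementwise mean of |d| (mae), d^2 (mse), or Huber."""
    d = np.asarray(x, float) - np.asarray(y, float)
    if kind == "mae":
        return float(np.abs(d).mean())
    if kind == "mse":
        return float((d**2).mean())
    if kind == "huber":
        a = np.abs(d)
        quad = 0.5 * d**2
        lin = delta * (a - 0.5 * delta)
        return float(np.where(a <= delta, quad, lin).mean())
    raise ValueError(f"unknown loss kind: {kind!r}")


def comparison_loss_grad(
    x: np.ndarray, y: np.ndarray, kind: str, delta: float = 1.0
) -> np.ndarray:
    x = np.asarray(x, float)
    d = x - np.asarray(y, float)
    if kind == "mae":
        g = np.sign(d)
    elif kind == "mse":
        g = 2.0 * d
    elif kind == "huber":
        g = np.where(np.abs(d) <= delta, d, delta * np.sign(d))
    else:
        raise ValueError(f"unknown loss kind: {kind!r}")
    return g / x.size


def make_loss(kind: str, omega: float = 10.0, epsilon: float = 3.0, delta: float = 1.0):
    """Return (loss_fn, grad_fn) closures for the configured loss."""
    if kind == "wing":
        p = WingParams(omega=omega, epsilon=epsilon)
        return (lambda x, y: wing_loss(x, y, p)), (lambda x, y: wing_loss_grad(x, y, p))
    if kind in ("mae", "mse", "huber"):
        return (
            lambda x, y: comparison_loss(x, y, kind, delta),
            lambda x, y: comparison_loss_grad(x, y, kind, delta),
        )
    raise ValueError(f"unknown loss kind: {kind!r}")
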