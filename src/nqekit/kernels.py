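"""Matérn ν=5/2 kernel and the derivative blocks a force-field fit needs.

Gradient-domain regression observes forces, i.e. gradients of the latent
energy, so the Gram matrix is built from second derivatives of the kernel
with respect to both arguments. Matérn 5/2 is the least-smooth member of
the family that is still twice differentiable at the origin — exactly the
differentiability the force-force covariance requires.

For k(d) = (1 + a d + a² d²/3) exp(-a d), a = √5/σ, d = ||u - v||:

    ∂k/∂v               =  (a²/3)(1 + a d) e^{-a d} (u - v)
    ∂²k/∂u ∂vᵀ          =  (a²/3)(1 + a d) e^{-a d} I
                           - (a⁴/3) e^{-a d} (u - v)(u - v)ᵀ

Both are smooth through d = 0 (no 1/d factors survive).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["matern52", "matern52_grad_v", "matern52_hess_uv"]

_SQRT5 = math.sqrt(5.0)


def _check_sigma(sigma: float) -> float:
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError(f"kernel length-scale must be positive, got {sigma}")
    return sigma


def matern52(d, sigma: float):
    """Matérn ν=5/2 correlation, k(0)=1, for scalar or array distances d ≥ 0."""
    sigma = _check_sigma(sigma)
    d = np.asarray(d, dtype=float)
    x = _SQRT5 * d / sigma
    out = (1.0 + x + x * x / 3.0) * np.exp(-x)
    return out if out.ndim else float(out)

def matern52_grad_v(u: np.ndarray, v: np.ndarray, sigma: float) -> np.ndarray:
    """∂k(||u-v||)/∂v, shape like u."""
    sigma = _check_sigma(sigma)
    a = _SQRT5 / sigma
    delta = u - v
    d = np.linalg.norm(delta)
    return (a * a / 3.0) * (1.0 + a * d) * math.exp(-a * d) * delta


def matern52_hess_uv(u: np.ndarray, v: np.ndarray, sigma: float) -> np.ndarray:
    """∂²k(||u-v||)/∂u ∂vᵀ, shape (len(u), len(u)). Positive definite at d=0."""
    sigma = _check_sigma(sigma)
    a = _SQRT5 / sigma
    delta = u - v
    d = np.linalg.norm(delta)
    e = math.exp(-a * d)
    h = (a * a / 3.0) * (1.0 + a * d) * e * np.eye(len(u))
    h -= (a ** 4 / 3.0) * e * np.outer(delta, delta)
    return h
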