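"""Bernstein polynomial basis on a bounded support with a monotone parameterization.

The transformation h of a response is written as h(y) = sum_k theta_k B_{k,M}(z)
with z = (y - a)/(b - a) on the support (a, b) and B_{k,M} the Bernstein basis
C(M,k) z^k (1-z)^(M-k).  Non-decreasing coefficients theta give a monotone
non-decreasing h with h(a) = theta_0 and h(b) = theta_M.  For unconstrained
optimization theta is parameterized by log-increments:

    theta = (gamma_0, gamma_0 + e^{gamma_1}, gamma_0 + e^{gamma_1} + e^{gamma_2}, ...)
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.stats import binom

from .errors import SupportError

#: relative slack allowed when clamping evaluations to the support edges
_EDGE_SLACK = 1e-9


@dataclass(frozen=True)
class BernsteinBasis:
    """Basis of order M (dimension M + 1) on the bounded support (a, b)."""

    order: int
    support: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("Bernstein order must be >= 1")
        a, b = self.support
        if not (np.isfinite(a) and np.isfinite(b) and a < b):
            raise ValueError("support must satisfy a < b with both finite")

    @property
    def dim(self) -> int:
        return self.order + 1

    def _z(self, y) -> np.ndarray:
        a, b = self.support
        y = np.asarray(y, dtype=float)
        slack = _EDGE_SLACK * max(1.0, abs(a), abs(b))
        if np.any(y < a - slack) or np.any(y > b + slack):
            raise SupportError(f"evaluation outside support ({a}, {b})")
        z = np.clip((y - a) / (b - a), 0.0, 1.0)
        # snap to the exact boundary: subnormal z overflows the pmf backend
        z = np.where(z < 1e-14, 0.0, z)
        return np.where(z > 1.0 - 1e-14, 1.0, z)

    def design(self, y) -> np.ndarray:
        """Matrix of basis functions, shape ``(..., M + 1)``; rows sum to 1."""
        z = self._z(y)
        k = np.arange(self.order + 1)
        return binom.pmf(k, self.order, z[..., None])

    def design_deriv(self, y) -> np.ndarray:
        """d/dy of each basis function: M/(b-a) * (B_{k-1,M-1} - B_{k,M-1})."""
        z = self._z(y)
        a, b = self.support
        M = self.order
        k = np.arange(M)
        lower = binom.pmf(k, M - 1, z[..., None])  # B_{k, M-1}, k = 0..M-1
        out = np.zeros(z.shape + (M + 1,))
        out[..., 1:] += lower
        out[..., :-1] -= lower
        return out * (M / (b - a))


def basis_eval(basis: BernsteinBasis, y: float) -> np.ndarray:
    """Evaluate the basis at a single point; entries >= 0 and sum to 1."""
    return basis.design(np.asarray(float(y)))


def basis_deriv(basis: BernsteinBasis, y: float) -> np.ndarray:
    return basis.design_deriv(np.asarray(float(y)))


def theta_from_gamma(gamma: np.ndarray) -> np.ndarray:
    gamma = np.asarray(gamma, dtype=float)
    theta = np.empty_like(gamma)
    theta[0] = gamma[0]
    if gamma.size > 1:
        theta[1:] = gamma[0] + np.cumsum(np.exp(gamma[1:]))
    return theta


def gamma_from_theta(theta: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Inverse of :func:`theta_from_gamma`; increments are floored at ``floor``."""
    theta = np.asarray(theta, dtype=float)
    if np.any(np.diff(theta) < 0):
        raise ValueError("theta must be non-decreasing")
    gamma = np.empty_like(theta)
    gamma[0] = theta[0]
    if theta.size > 1:
        gamma[1:] = np.log(np.maximum(np.diff(theta), floor))
    return gamma


@dataclass(frozen=True)
class MonotoneCoefficients:
    """Non-decreasing Bernstein coefficients and their unconstrained image."""

    gamma: np.ndarray

    @property
    def theta(self) -> np.ndarray:
        return theta_from_gamma(self.gamma)

    @classmethod
    def from_theta(cls, theta: np.ndarray) -> "MonotoneCoefficients":
        return cls(gamma=gamma_from_theta(theta))


def transform(basis: BernsteinBasis, theta: np.ndarray, y) -> np.ndarray:
    """h(y) = basis(y) . theta; non-decreasing in y when theta is."""
    return basis.design(y) @ np.asarray(theta, dtype=float)


def transform_deriv(basis: BernsteinBasis, theta: np.ndarray, y) -> np.ndarray:
    """h'(y); non-negative whenever theta is non-decreasing."""
    return basis.design_deriv(y) @ np.asarray(theta, dtype=float)
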