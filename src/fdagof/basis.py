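"""Univariate clamped cubic B-spline bases with equally spaced interior knots.

A basis of dimension H and degree 3 uses H - 4 equally spaced interior knots
and endpoint knots of multiplicity 4, so the basis is a partition of unity on
[a, b] and the first/last basis functions attain 1 at the endpoints.  Exact
Gram matrices (integrals of products of basis functions or their derivatives)
are computed by per-interval Gauss-Legendre quadrature of sufficient order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .data_model import Domain

__all__ = ["SplineBasis", "build_basis"]


@dataclass(frozen=True)
class SplineBasis:
    """Clamped B-spline basis of dimension H on a domain."""

    domain: Domain
    H: int
    degree: int = 3
    knots: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.H < self.degree + 1:
            raise ValueError(f"need H >= degree+1 = {self.degree + 1} basis functions, got H={self.H}")
        if self.knots is None:
            k = self.degree
            interior = np.linspace(self.domain.a, self.domain.b, self.H - k + 1)[1:-1]
            knots = np.concatenate(
                [np.full(k + 1, self.domain.a), interior, np.full(k + 1, self.domain.b)]
            )
            object.__setattr__(self, "knots", knots)

    @property
    def n_interior_knots(self) -> int:
        return self.H - self.degree - 1

    def design(self, t: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions: returns an (len(t), H) matrix."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        # clip guards against round-off just outside the closed domain
        t = np.clip(t, self.domain.a, self.domain.b)
        return BSpline.design_matrix(t, self.knots, self.degree).toarray()

    def derivative_design(self, t: np.ndarray, nu: int) -> np.ndarray:
        t = np.clip(np.atleast_1d(np.asarray(t, dtype=float)), self.domain.a, self.domain.b)
        spl = BSpline(self.knots, np.eye(self.H), self.degree)
        return spl.derivative(nu)(t)

    def _gl_points(self, order: int) -> tuple[np.ndarray, np.ndarray]:
        """Gauss-Legendre nodes/weights tiled over the distinct knot spans."""
        x, w = np.polynomial.legendre.leggauss(order)
        breaks = np.unique(self.knots)
        lo, hi = breaks[:-1], breaks[1:]
        mid = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo)
        nodes = (mid[:, None] + half[:, None] * x[None, :]).ravel()
        weights = (half[:, None] * w[None, :]).ravel()
        return nodes, weights

    def gram(self, nu: int = 0) -> np.ndarray:
        """Exact H x H matrix of integrals of products of nu-th derivatives,
        M[h, l] = int_a^b Bh^(nu)(t) Bl^(nu)(t) dt."""
        deg = self.degree - nu
        if deg < 0:
            return np.zeros((self.H, self.H))
        order = deg + 1  # exact for polynomial products of degree 2*deg
        nodes, weights = self._gl_points(order)
        D = self.design(nodes) if nu == 0 else self.derivative_design(nodes, nu)
        return (D * weights[:, None]).T @ D


def build_basis(domain: Domain, H: int = 10, degree: int = 3) -> SplineBasis:
    """Clamped B-spline basis with `H` functions and equally spaced interior
    knots on `domain`; H must be at least degree+1 (4 for cubics)."""
    return SplineBasis(domain=domain, H=H, degree=degree)
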