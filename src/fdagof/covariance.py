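"""Nonparametric covariance estimation by tensor-product regression splines.

The covariance surface is modeled as G(t,t') = sum_{h,l} theta_hl Bh(t) Bl(t')
with cubic B-splines Bh and a symmetric coefficient matrix (theta_hl =
theta_lh imposed by reparameterization, not post-hoc averaging).  The
coefficients minimize the least-squares criterion over all ordered
off-diagonal pairs within subjects,

    sum_i sum_{j != j'} ( Ytilde_ij Ytilde_ij' - G(t_ij, t_ij') )^2,

using only j != j' pairs so the measurement-error variance on the diagonal
does not contaminate the surface.  The smoothed-null surface replaces the
cross-products by G0hat(t_ij, t_ij') with the identical pair set and design,
which removes the smoothing bias when the two surfaces are compared.

No penalty is applied; smoothness comes from the modest basis dimension
(default H = 10 per axis).  No positive-semidefiniteness correction is
applied either — the test statistic does not need one.

The solver never materializes the pair-level design matrix: per subject, the
Gram contribution of all ordered pairs is (B_i'B_i) (x) (B_i'B_i) minus the
j = j' terms, so building the normal equations costs O(N H^2) memory and
O(n H^4 + N H^2) time.  A `PairDesign` depends on the time points only and is
reused across bootstrap replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .basis import SplineBasis, build_basis
from .data_model import DemeanedSample, FunctionalSample

__all__ = [
    "SplineBasis",
    "build_basis",
    "SmoothedCovariance",
    "PairDesign",
    "smooth_cross_products",
    "smooth_null_surface",
    "estimate_noise_variance",
]


@dataclass
class SmoothedCovariance:
    """Bivariate covariance surface in a symmetric tensor-product spline span."""

    basis: SplineBasis
    theta: np.ndarray  # (H, H), symmetric

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        H = self.basis.H
        if self.theta.shape != (H, H):
            raise ValueError(f"theta must be {H}x{H}")
        if not np.allclose(self.theta, self.theta.T, atol=1e-8):
            raise ValueError("theta must be symmetric")
        self.theta = (self.theta + self.theta.T) / 2

    def evaluate(self, t: np.ndarray, t2: np.ndarray) -> np.ndarray:
        """Surface on the grid t x t2: returns (len(t), len(t2))."""
        B1 = self.basis.design(t)
        B2 = self.basis.design(t2)
        return B1 @ self.theta @ B2.T

    def diagonal(self, t: np.ndarray) -> np.ndarray:
        """G(t, t) evaluated pointwise."""
        B = self.basis.design(t)
        return np.einsum("nh,hl,nl->n", B, self.theta, B)

    def __call__(self, t, t2):
        B1 = self.basis.design(np.atleast_1d(t))
        B2 = self.basis.design(np.atleast_1d(t2))
        out = np.einsum("nh,hl,nl->n", B1, self.theta, B2)
        return float(out[0]) if np.isscalar(t) and np.isscalar(t2) else out

    def cov(self, t, t2) -> np.ndarray:
        """Broadcasting evaluation, signature-compatible with the parametric
        null's `cov` (so either surface can feed the pair regression)."""
        t, t2 = np.broadcast_arrays(np.asarray(t, float), np.asarray(t2, float))
        B1 = self.basis.design(t.ravel())
        B2 = self.basis.design(t2.ravel())
        return np.einsum("nh,hl,nl->n", B1, self.theta, B2).reshape(t.shape)


def _duplication(H: int) -> np.ndarray:
    """Maps the H(H+1)/2 free upper-triangle coefficients to vec(theta)."""
    p = H * (H + 1) // 2
    D = np.zeros((H * H, p))
    k = 0
    for h in range(H):
        for l in range(h, H):
            D[h * H + l, k] = 1.0
            if l != h:
                D[l * H + h, k] = 1.0
            k += 1
    return D


class PairDesign:
    """Normal equations of the symmetric pair regression for a fixed set of
    time points.  Reused across responses (data, null surface, bootstrap)."""

    def __init__(self, times_list: list[np.ndarray], basis: SplineBasis):
        self.basis = basis
        H = basis.H
        self.D = _duplication(H)
        n_pairs = sum(t.size * (t.size - 1) for t in times_list)
        p = H * (H + 1) // 2
        if n_pairs < p:
            raise ValueError(
                f"too few off-diagonal pairs ({n_pairs}) for {p} free coefficients; "
                "need subjects with more repeated observations"
            )
        self.times_list = times_list
        self.B_list = [basis.design(t) for t in times_list]
        # per-observation tensor rows kron(b_j, b_j) for the j = j' corrections
        Ball = np.vstack(self.B_list)
        self.C = (Ball[:, :, None] * Ball[:, None, :]).reshape(Ball.shape[0], H * H)
        A = np.zeros((H * H, H * H))
        for B in self.B_list:
            G = B.T @ B
            A += np.einsum("ab,cd->acbd", G, G).reshape(H * H, H * H)
        A -= self.C.T @ self.C
        self.A_free = self.D.T @ A @ self.D
        self._cho = None
        self._pinv = None
        try:
            self._cho = cho_factor(self.A_free)
        except np.linalg.LinAlgError:
            warnings.warn(
                "rank-deficient pair design; falling back to minimum-norm least squares"
            )
            self._pinv = np.linalg.pinv(self.A_free)

    def solve(self, rhs_full: np.ndarray) -> SmoothedCovariance:
        rhs = self.D.T @ rhs_full
        if self._cho is not None:
            coef = cho_solve(self._cho, rhs)
        else:
            coef = self._pinv @ rhs
        H = self.basis.H
        theta = np.zeros((H, H))
        iu = np.triu_indices(H)
        theta[iu] = coef
        theta = theta + theta.T - np.diag(np.diag(theta))
        return SmoothedCovariance(self.basis, theta)

    def rhs_from_values(self, values_list: list[np.ndarray]) -> np.ndarray:
        """Right-hand side for responses Ytilde_ij Ytilde_ij' over j != j'."""
        H = self.basis.H
        b = np.zeros((H, H))
        for B, y in zip(self.B_list, values_list):
            g = B.T @ y
            b += np.outer(g, g)
        yall2 = np.concatenate(values_list) ** 2
        return b.ravel() - self.C.T @ yall2

    def rhs_from_surface(self, cov_fn) -> np.ndarray:
        """Right-hand side for responses G0hat(t_ij, t_ij') over j != j'.

        `cov_fn(t, t2)` must evaluate the surface on broadcastable arrays.
        """
        H = self.basis.H
        b = np.zeros((H, H))
        diag_vals = []
        for B, t in zip(self.B_list, self.times_list):
            G0 = cov_fn(t[:, None], t[None, :])
            b += B.T @ G0 @ B
            diag_vals.append(np.diagonal(G0))
        return b.ravel() - self.C.T @ np.concatenate(diag_vals)


def smooth_cross_products(
    demeaned: DemeanedSample | FunctionalSample,
    basis: SplineBasis | None = None,
    design: PairDesign | None = None,
) -> SmoothedCovariance:
    """The nonparametric covariance estimate GAhat: least squares of the
    off-diagonal cross-products on the symmetric tensor-product basis."""
    if design is None:
        if basis is None:
            basis = build_basis(demeaned.domain)
        design = PairDesign(demeaned.times_list(), basis)
    return design.solve(design.rhs_from_values(demeaned.values_list()))


def smooth_null_surface(
    fit,
    demeaned: DemeanedSample | FunctionalSample,
    basis: SplineBasis | None = None,
    design: PairDesign | None = None,
) -> SmoothedCovariance:
    """The smoothed null surface K G0hat: same pair set and design as
    :func:`smooth_cross_products`, responses G0hat(t_ij, t_ij')."""
    if design is None:
        if basis is None:
            basis = build_basis(demeaned.domain)
        design = PairDesign(demeaned.times_list(), basis)
    return design.solve(design.rhs_from_surface(fit.cov))


def estimate_noise_variance(
    demeaned: DemeanedSample | FunctionalSample,
    ghat: SmoothedCovariance,
) -> float:
    """Measurement-error variance from the covariance diagonal:

        sigma2hat = mean over t_ij in the middle 50% of T of
                    ( Ytilde_ij^2 - GAhat(t_ij, t_ij) ),

    floored at zero.  Restricting to the central half of the domain avoids
    the smoother's boundary bias; the raw squared residuals estimate
    G(t,t) + sigma^2 while the fitted surface estimates G(t,t) alone.
    """
    t, y = demeaned.pooled()
    lo, hi = demeaned.domain.middle_half()
    mask = (t >= lo) & (t <= hi)
    if not np.any(mask):
        raise ValueError("no observations in the middle 50% of the domain")
    resid = y[mask] ** 2 - ghat.diagonal(t[mask])
    return max(float(resid.mean()), 0.0)
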