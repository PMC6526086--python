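"""Smooth mean estimation and de-meaning.

The mean mu(t) is estimated by penalized cubic regression splines on the
pooled observations: minimize ||y - B beta||^2 + lam * beta' P beta, where B
is a clamped cubic B-spline design and P penalizes the integrated squared
second derivative of the fitted curve.  The penalty null space is exactly the
linear functions of t, so lam -> infinity recovers the pooled OLS line and
constants/lines are reproduced without bias.  The smoothing parameter is
chosen by REML (default) or GCV; both criteria are evaluated in O(basis_dim)
per candidate lam via a Demmler-Reinsch decomposition, which also makes
repeated fits on bootstrap data (same time points, new responses) cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar

from .basis import SplineBasis, build_basis
from .data_model import DemeanedSample, FunctionalSample, SubjectRecord

__all__ = ["MeanFit", "MeanSmoother", "fit_mean", "demean"]

Selection = Literal["gcv", "reml", "fixed"]


@dataclass
class MeanFit:
    """Fitted smooth mean: basis + coefficients + chosen smoothing parameter."""

    basis: SplineBasis
    coef: np.ndarray
    lam: float
    selection: str
    edf: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.basis.design(t) @ self.coef

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self(t)


class MeanSmoother:
    """Reusable penalized-spline engine tied to a fixed set of time points.

    Precomputes the design and the Demmler-Reinsch rotation once, after which
    fitting any response vector on the same time points costs O(N * basis_dim)
    plus a 1-D smoothing-parameter search.
    """

    def __init__(self, times: np.ndarray, basis: SplineBasis):
        times = np.asarray(times, dtype=float)
        if times.size < basis.H:
            raise ValueError(
                f"insufficient data: {times.size} observations for {basis.H} basis functions"
            )
        if np.ptp(times) <= 0:
            raise ValueError("degenerate design: all observation times are equal")
        self.basis = basis
        self.B = basis.design(times)
        self.P = basis.gram(nu=2)  # integrated squared second derivative
        C = self.B.T @ self.B
        # tiny ridge keeps the Cholesky stable when some basis functions see few points
        eps = 1e-10 * np.trace(C) / basis.H
        self.R = np.linalg.cholesky(C + eps * np.eye(basis.H)).T  # C ~= R'R
        Rinv = np.linalg.inv(self.R)
        S = Rinv.T @ self.P @ Rinv
        s, U = np.linalg.eigh((S + S.T) / 2)
        s = np.clip(s, 0.0, None)
        # exact zeros for the penalty null space so lam -> inf keeps it unshrunk
        s[s < 1e-10 * max(s.max(), 1.0)] = 0.0
        self.s = s
        self.T = Rinv @ U  # beta = T a in rotated coordinates
        self.U = U
        self.RinvT_Bt = self.T.T  # maps B'y -> rotated w via w = T' B'y ... see fit()
        self._null_dim = int(np.sum(self.s < 1e-10 * max(self.s.max(), 1.0)))

    def fit(self, y: np.ndarray, selection: Selection = "reml", lam: float | None = None) -> MeanFit:
        y = np.asarray(y, dtype=float)
        By = self.B.T @ y
        w = self.T.T @ By  # rotated sufficient statistic
        yty = float(y @ y)
        N = y.size
        s = self.s
        d0 = self._null_dim

        def rss_pen(lam_: float) -> tuple[float, float]:
            shrink = 1.0 / (1.0 + lam_ * s)
            a2 = (w * shrink) ** 2
            rss = yty - 2 * float(w**2 @ shrink) + float(np.sum(a2))
            pen = float(np.sum(s * a2))
            return max(rss, 0.0), pen

        def gcv(loglam: float) -> float:
            lam_ = np.exp(loglam)
            rss, _ = rss_pen(lam_)
            edf = float(np.sum(1.0 / (1.0 + lam_ * s)))
            return N * rss / (N - edf) ** 2

        def reml(loglam: float) -> float:
            lam_ = np.exp(loglam)
            rss, pen = rss_pen(lam_)
            sig2 = (rss + lam_ * pen) / (N - d0)
            pos = s > 1e-10 * max(s.max(), 1.0)
            return (
                (N - d0) * np.log(max(sig2, 1e-300))
                + float(np.sum(np.log1p(lam_ * s[pos])))
                - pos.sum() * np.log(lam_)
            )

        if selection == "fixed":
            if lam is None:
                raise ValueError("selection='fixed' requires lam")
            lam_hat = float(lam)
        else:
            crit = gcv if selection == "gcv" else reml
            grid = np.linspace(-8.0, 14.0, 23)
            vals = [crit(g) for g in grid]
            j = int(np.argmin(vals))
            lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]
            res = minimize_scalar(crit, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-3})
            lam_hat = float(np.exp(res.x))

        shrink = 1.0 / (1.0 + lam_hat * s)
        coef = self.T @ (shrink * w)
        edf = float(np.sum(shrink))
        return MeanFit(self.basis, coef, lam_hat, selection, edf)


def fit_mean(
    sample: FunctionalSample,
    basis_dim: int = 10,
    selection: Selection = "reml",
    lam: float | None = None,
    smoother: MeanSmoother | None = None,
) -> MeanFit:
    """Penalized-spline fit of the pooled (t_ij, Y_ij) scatter.

    Pass a prebuilt `smoother` (from the same time points) to skip the design
    precomputation, e.g. inside a bootstrap loop.
    """
    t, y = sample.pooled()
    if smoother is None:
        smoother = MeanSmoother(t, build_basis(sample.domain, H=basis_dim))
    return smoother.fit(y, selection=selection, lam=lam)


def demean(sample: FunctionalSample, fit: MeanFit) -> DemeanedSample:
    """Subtract the fitted mean record-for-record: Ytilde_ij = Y_ij - muhat(t_ij)."""
    subs = [
        SubjectRecord(s.id, s.times.copy(), s.values - fit(s.times))
        for s in sample.subjects
    ]
    return DemeanedSample(subs, sample.domain, mean_fit=fit)
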