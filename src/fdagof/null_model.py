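"""Parametric null covariance models fitted by maximum likelihood.

The primary family is the quadratic polynomial covariance

    G0(t,t') = sigma0^2 + sigma01 (t + t') + sigma1^2 t t',

induced by the linear random-effects model X_i(t) = b0_i + b1_i t with
(b0_i, b1_i) ~ N(0, V0).  On de-meaned data Ytilde_i the subject marginal is
Ytilde_i ~ N(0, V_i) with V_i = Z_i V0 Z_i' + sigma^2 I and Z_i = [1, t_i],
and parameters maximize

    l(V0, sigma^2) = sum_i -1/2 ( log|V_i| + Ytilde_i' V_i^{-1} Ytilde_i ),

reported without the additive 2*pi constant.  Because the data are already
de-meaned there are no fixed effects, so this ML objective coincides with the
restricted likelihood.  V0 is parameterized by its log-Cholesky factor and
sigma^2 on the log scale, keeping the search unconstrained while V0 stays
positive semidefinite; optimization is quasi-Newton (L-BFGS-B) from a
method-of-moments start and an identity-scaled fallback start.

A stationary squared-exponential family G0(t,t') = theta * exp(-(t-t')^2 /
delta^2) is fitted by the same machinery over (log theta, log delta,
log sigma^2); any smooth parametric family could be added the same way.

The likelihood for the quadratic family is evaluated through the Woodbury
identity on per-subject 2x2 sufficient statistics, so one objective
evaluation is O(n) small dense operations regardless of m_i — this is what
makes the bootstrap loop affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize

from .data_model import DemeanedSample, FunctionalSample

__all__ = [
    "NullCovarianceFit",
    "fit_null",
    "fit_null_arrays",
    "eval_null_cov",
    "simulate_null_subject",
    "QuadraticLikelihood",
]

Family = Literal["quadratic_polynomial", "squared_exponential"]


@dataclass
class NullCovarianceFit:
    """Fitted parametric null covariance plus the ML noise variance."""

    family: Family
    V0: np.ndarray | None = None          # quadratic_polynomial: 2x2 [[s0^2, s01], [s01, s1^2]]
    theta: float | None = None            # squared_exponential scale
    delta: float | None = None            # squared_exponential range
    noise_var: float = 0.0
    loglik: float = np.nan
    converged: bool = False
    n_obs: int = 0
    message: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family == "quadratic_polynomial":
            if self.V0 is None:
                raise ValueError("quadratic_polynomial family requires V0")
            self.V0 = np.asarray(self.V0, dtype=float)
            if self.V0.shape != (2, 2) or not np.allclose(self.V0, self.V0.T, atol=1e-10):
                raise ValueError("V0 must be a symmetric 2x2 matrix")
            if np.linalg.eigvalsh(self.V0)[0] < -1e-8:
                raise ValueError("V0 must be positive semidefinite")
        elif self.family == "squared_exponential":
            if self.theta is None or self.delta is None:
                raise ValueError("squared_exponential family requires (theta, delta)")
            if self.theta < 0 or self.delta <= 0:
                raise ValueError("need theta >= 0 and delta > 0")
        else:
            raise ValueError(f"unknown family {self.family!r}")
        if self.noise_var < 0:
            raise ValueError("noise_var must be >= 0")

    def cov(self, t: np.ndarray, t2: np.ndarray) -> np.ndarray:
        """G0 evaluated elementwise at broadcastable arrays (t, t2)."""
        t = np.asarray(t, dtype=float)
        t2 = np.asarray(t2, dtype=float)
        if self.family == "quadratic_polynomial":
            s00, s01, s11 = self.V0[0, 0], self.V0[0, 1], self.V0[1, 1]
            return s00 + s01 * (t + t2) + s11 * t * t2
        return self.theta * np.exp(-((t - t2) ** 2) / self.delta**2)

    def cov_matrix(self, times: np.ndarray) -> np.ndarray:
        """G0 on the grid times x times (process covariance, no noise)."""
        times = np.asarray(times, dtype=float)
        return self.cov(times[:, None], times[None, :])

    def marginal_cov(self, times: np.ndarray) -> np.ndarray:
        """V_i = G0(times, times) + sigma^2 I for one subject."""
        return self.cov_matrix(times) + self.noise_var * np.eye(len(times))

    def to_dict(self) -> dict:
        out = {
            "family": self.family,
            "noise_var": self.noise_var,
            "loglik": self.loglik,
            "converged": self.converged,
        }
        if self.family == "quadratic_polynomial":
            out["V0"] = self.V0.tolist()
        else:
            out["theta"], out["delta"] = self.theta, self.delta
        return out


def eval_null_cov(fit: NullCovarianceFit, t, t2) -> np.ndarray | float:
    """G0(t, t') under the fitted (or user-supplied) parameters."""
    out = fit.cov(t, t2)
    return float(out) if np.isscalar(t) and np.isscalar(t2) else out


# ---------------------------------------------------------------------------
# quadratic polynomial family: Woodbury likelihood on sufficient statistics
# ---------------------------------------------------------------------------

class QuadraticLikelihood:
    """Marginal ML objective for the random intercept+slope model, built once
    per dataset from per-subject sufficient statistics (Z'Z, Z'y, y'y, m,
    plus the higher time/response moments the moment start needs)."""

    def __init__(self, times_list: list[np.ndarray], values_list: list[np.ndarray]):
        n = len(times_list)
        self.A = np.empty((n, 2, 2))
        self.c = np.empty((n, 2))
        self.q = np.empty(n)
        self.m = np.empty(n)
        self.S = np.empty((n, 5))   # S[k] = sum_j t_j^k, k = 0..4
        self.Qk = np.empty((n, 3))  # Qk[k] = sum_j t_j^k y_j^2, k = 0..2
        for i, (t, y) in enumerate(zip(times_list, values_list)):
            t2 = t * t
            st, stt = t.sum(), t2.sum()
            self.A[i] = [[t.size, st], [st, stt]]
            self.c[i] = [y.sum(), (t * y).sum()]
            y2 = y * y
            self.q[i] = y2.sum()
            self.m[i] = t.size
            self.S[i] = [t.size, st, stt, (t2 * t).sum(), (t2 * t2).sum()]
            self.Qk[i] = [self.q[i], (t * y2).sum(), (t2 * y2).sum()]
        self.N = int(self.m.sum())

    def negloglik(self, L: np.ndarray, sigma2: float) -> float:
        """-l(V0, sigma^2) with V0 = L L' (2*pi constant omitted)."""
        # W = I + L' Z'Z L / sigma^2, per subject (batched 2x2)
        LtAL = np.einsum("ab,nbc,cd->nad", L.T, self.A, L)
        W = np.eye(2)[None] + LtAL / sigma2
        detW = W[:, 0, 0] * W[:, 1, 1] - W[:, 0, 1] * W[:, 1, 0]
        if np.any(detW <= 0):
            return np.inf
        g = self.c @ L  # (n, 2) = L' Z'y
        # g' W^{-1} g via the 2x2 adjugate
        gWg = (
            g[:, 0] ** 2 * W[:, 1, 1]
            - 2 * g[:, 0] * g[:, 1] * W[:, 0, 1]
            + g[:, 1] ** 2 * W[:, 0, 0]
        ) / detW
        quad = (self.q - gWg / sigma2) / sigma2
        logdet = self.m * np.log(sigma2) + np.log(detW)
        return 0.5 * float(np.sum(logdet + quad))

    def negloglik_x(self, x: np.ndarray) -> float:
        L = np.array([[np.exp(x[0]), 0.0], [x[1], np.exp(x[2])]])
        return self.negloglik(L, np.exp(x[3]))

    def negloglik_grad_x(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Objective and its exact gradient in the log-Cholesky coordinates
        x = (log L11, L21, log L22, log sigma^2)."""
        L = np.array([[np.exp(x[0]), 0.0], [x[1], np.exp(x[2])]])
        s = np.exp(x[3])
        AL = self.A @ L                                  # (n, 2, 2)
        LtAL = np.einsum("ba,nbc->nac", L, AL)
        W = np.eye(2)[None] + LtAL / s
        detW = W[:, 0, 0] * W[:, 1, 1] - W[:, 0, 1] * W[:, 1, 0]
        if np.any(detW <= 0):
            return np.inf, np.zeros(4)
        Winv = np.empty_like(W)
        Winv[:, 0, 0] = W[:, 1, 1]
        Winv[:, 1, 1] = W[:, 0, 0]
        Winv[:, 0, 1] = -W[:, 0, 1]
        Winv[:, 1, 0] = -W[:, 1, 0]
        Winv /= detW[:, None, None]
        g = self.c @ L
        u = np.einsum("nab,nb->na", Winv, g)
        gWg = np.einsum("na,na->n", g, u)
        f = 0.5 * float(
            np.sum(self.m * np.log(s) + np.log(detW) + self.q / s - gWg / s**2)
        )
        ALW = np.einsum("nab,nbc->nac", AL, Winv)
        ALu = np.einsum("nab,nb->na", AL, u)
        # d/dL_ab of sum_i [log det W - g'W^{-1}g / s^2]:
        #   (2/s)(A L Winv)_ab - (2/s^2) c_a u_b + (2/s^3)(A L u)_a u_b
        dL = 0.5 * (
            (2.0 / s) * ALW.sum(axis=0)
            - (2.0 / s**2) * np.einsum("na,nb->ab", self.c, u)
            + (2.0 / s**3) * np.einsum("na,nb->ab", ALu, u)
        )
        trW = np.einsum("nab,nba->n", Winv, LtAL)      # tr(Winv L'AL)
        uLALu = np.einsum("na,nab,nb->n", u, LtAL, u)  # u'(L'AL)u
        ds = 0.5 * float(
            np.sum(
                self.m / s
                - trW / s**2
                - self.q / s**2
                + 2 * gWg / s**3
                - uLALu / s**4
            )
        )
        grad = np.array([dL[0, 0] * L[0, 0], dL[1, 0], dL[1, 1] * L[1, 1], ds * s])
        return f, grad


_KRON_POWERS = np.array([0, 1, 1, 2])  # t-powers of kron(z_j, z_j) for z = (1, t)
# map kron coordinates (1, t', t, t t') onto the pair design phi = (1, t+t', t t')
_MMAP = np.array([[1, 0, 0], [0, 1, 0], [0, 1, 0], [0, 0, 1.0]])


def _moment_start(ll: QuadraticLikelihood) -> tuple[np.ndarray, float]:
    """Method-of-moments start: regress off-diagonal cross-products
    Ytilde_ij Ytilde_ij' on (1, t+t', t t') and read off (s0^2, s01, s1^2);
    noise from the pooled second moment minus the fitted diagonal.  Fully
    vectorized over subjects via the stored moment statistics."""
    # ordered-pair sums = full kron sums minus the j = j' diagonal terms
    full = np.einsum("nab,ncd->nacbd", ll.A, ll.A).reshape(-1, 4, 4)
    diag = ll.S[:, _KRON_POWERS[:, None] + _KRON_POWERS[None, :]]
    A = _MMAP.T @ (full - diag).sum(axis=0) @ _MMAP
    ky = np.einsum("na,nb->nab", ll.c, ll.c).reshape(-1, 4) - ll.Qk[:, [0, 1, 1, 2]]
    b = _MMAP.T @ ky.sum(axis=0)
    sum_y2 = float(ll.q.sum())
    sum_diag = np.array([ll.S[:, 0].sum(), 2 * ll.S[:, 1].sum(), ll.S[:, 2].sum()])
    N = ll.N
    try:
        beta = np.linalg.lstsq(A, b, rcond=None)[0]
    except np.linalg.LinAlgError:
        beta = np.array([1.0, 0.0, 1.0])
    V0 = np.array([[beta[0], beta[1]], [beta[1], beta[2]]])
    # project onto the PSD cone
    w, Q = np.linalg.eigh(V0)
    V0 = Q @ np.diag(np.clip(w, 1e-6, None)) @ Q.T
    diag_fit = beta @ sum_diag / N  # average fitted G0(t, t)
    sigma2 = max(sum_y2 / N - diag_fit, 0.05 * sum_y2 / N, 1e-6)
    return V0, sigma2


def _fit_quadratic(times_list, values_list, tol: float, maxiter: int) -> NullCovarianceFit:
    ll = QuadraticLikelihood(times_list, values_list)
    if np.all(ll.m <= 1):
        raise ValueError(
            "all subjects have a single observation: sigma0^2 and sigma^2 are not identifiable"
        )

    starts = []
    V0_mom, s2_mom = _moment_start(ll)
    Lm = np.linalg.cholesky(V0_mom + 1e-8 * np.eye(2))
    starts.append(np.array([np.log(Lm[0, 0]), Lm[1, 0], np.log(Lm[1, 1]), np.log(s2_mom)]))
    v = max(float(np.var(np.concatenate(values_list))), 1e-4)
    starts.append(np.array([0.5 * np.log(v / 2), 0.0, 0.5 * np.log(v / 2), np.log(v / 2)]))

    best = None
    for x0 in starts:
        res = minimize(
            ll.negloglik_grad_x,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-10, 10), (-1e3, 1e3), (-10, 10), (-10, 10)],
            options={"ftol": tol, "maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    L = np.array([[np.exp(x[0]), 0.0], [x[1], np.exp(x[2])]])
    V0 = L @ L.T
    return NullCovarianceFit(
        family="quadratic_polynomial",
        V0=(V0 + V0.T) / 2,
        noise_var=float(np.exp(x[3])),
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_obs=ll.N,
        message=str(best.message),
    )


# ---------------------------------------------------------------------------
# squared-exponential family: generic dense-likelihood route
# ---------------------------------------------------------------------------

def _sqexp_negll(x: np.ndarray, blocks) -> float:
    theta, delta, sigma2 = np.exp(x)
    total = 0.0
    for times, values in blocks:  # (nb, mb) arrays grouped by m
        d2 = (times[:, :, None] - times[:, None, :]) ** 2
        V = theta * np.exp(-d2 / delta**2) + sigma2 * np.eye(times.shape[1])[None]
        sign, logdet = np.linalg.slogdet(V)
        if np.any(sign <= 0):
            return np.inf
        sol = np.linalg.solve(V, values[:, :, None])[:, :, 0]
        total += 0.5 * float(np.sum(logdet) + np.einsum("nm,nm->", values, sol))
    return total


def _group_by_m(times_list, values_list):
    groups: dict[int, list[int]] = {}
    for i, t in enumerate(times_list):
        groups.setdefault(t.size, []).append(i)
    out = []
    for m, idx in groups.items():
        times = np.stack([times_list[i] for i in idx])
        values = np.stack([values_list[i] for i in idx])
        out.append((times, values))
    return out


def _fit_sqexp(times_list, values_list, domain_width: float, tol: float, maxiter: int) -> NullCovarianceFit:
    blocks = _group_by_m(times_list, values_list)
    if all(t.shape[1] <= 1 for t, _ in blocks):
        raise ValueError("all subjects have a single observation: theta and sigma^2 confounded")
    v = max(float(np.var(np.concatenate(values_list))), 1e-4)
    width = domain_width
    starts = [
        np.log([v / 2, width / 4, v / 2]),
        np.log([v, width, v / 4]),
    ]
    best = None
    for x0 in starts:
        res = minimize(
            _sqexp_negll, x0, args=(blocks,), method="L-BFGS-B",
            bounds=[(-10, 10), (np.log(width) - 8, np.log(width) + 4), (-10, 10)],
            options={"ftol": tol, "maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta, delta, sigma2 = np.exp(best.x)
    return NullCovarianceFit(
        family="squared_exponential",
        theta=float(theta),
        delta=float(delta),
        noise_var=float(sigma2),
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_obs=sum(t.size for t, _ in blocks),
        message=str(best.message),
    )


def fit_null_arrays(
    times_list: list[np.ndarray],
    values_list: list[np.ndarray],
    domain,
    family: Family = "quadratic_polynomial",
    tol: float = 1e-8,
    maxiter: int = 500,
    warn: bool = False,
) -> NullCovarianceFit:
    """Array-level entry point used in hot loops (no sample construction)."""
    if not times_list:
        raise ValueError("empty sample")
    if family == "quadratic_polynomial":
        fit = _fit_quadratic(times_list, values_list, tol, maxiter)
    elif family == "squared_exponential":
        fit = _fit_sqexp(times_list, values_list, domain.width, tol, maxiter)
    else:
        raise ValueError(f"unknown family {family!r}")
    if warn and not fit.converged:
        warnings.warn(f"null model fit did not report convergence: {fit.message}")
    return fit


def fit_null(
    demeaned: DemeanedSample | FunctionalSample,
    family: Family = "quadratic_polynomial",
    tol: float = 1e-8,
    maxiter: int = 500,
) -> NullCovarianceFit:
    """Maximum-likelihood fit of the parametric null covariance to de-meaned
    data.  Non-convergence is flagged on the result, not raised."""
    return fit_null_arrays(
        demeaned.times_list(), demeaned.values_list(), demeaned.domain,
        family=family, tol=tol, maxiter=maxiter, warn=True,
    )


def simulate_null_subject(
    fit: NullCovarianceFit,
    times: np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """One mean-zero trajectory X_i at `times` from the fitted null process
    (no measurement noise — the caller adds it).

    Quadratic family: draw (b0, b1) ~ N(0, V0hat) and return b0 + b1 t, an
    exactly linear trajectory.  Other families: symmetric square root of the
    null covariance matrix applied to iid standard normals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    if fit.family == "quadratic_polynomial":
        w, Q = np.linalg.eigh(fit.V0)
        root = Q @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        b = root @ rng.standard_normal(2)
        return b[0] + b[1] * times
    G = fit.cov_matrix(times)
    w, Q = np.linalg.eigh((G + G.T) / 2)
    root = Q @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ Q.T
    return root @ rng.standard_normal(times.size)


def simulate_null_values(
    fit: NullCovarianceFit,
    times_list: list[np.ndarray],
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Mean-zero null trajectories for every subject (vectorized for the
    quadratic family); used by the bootstrap."""
    if fit.family == "quadratic_polynomial":
        n = len(times_list)
        w, Q = np.linalg.eigh(fit.V0)
        root = Q @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        b = rng.standard_normal((n, 2)) @ root.T
        return [b[i, 0] + b[i, 1] * t for i, t in enumerate(times_list)]
    return [simulate_null_subject(fit, t, rng) for t in times_list]
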