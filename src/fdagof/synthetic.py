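"""Synthetic data generator for the size/power study conditions.

Data follow

    Y_ij = mu(t_ij) + X_i(t_ij) + eps_ij,
    X_i(t) = b0_i + b1_i t + Delta * z_i(t),

with mu = 0, eps_ij ~ N(0, noise_sd^2) and (b0_i, b1_i) bivariate normal with
unit variances and covariance -0.5 by default, so that under Delta = 0 the
covariance of X is the quadratic polynomial G0(t,t') = 1 - 0.5(t+t') + t t'.
The deviation z_i is either quadratic (z_i(t) = b2_i t^2 with b2_i ~ N(0,1))
or trigonometric (z_i(t) = xi_1 sin(2 pi t) + xi_2 sin(4 pi t) with unit score
variances), and Delta >= 0 scales its size.

Time points sit on a grid of `grid_size` equally spaced points spanning the
domain (default 80 on [-1, 1]); each subject is observed at m points sampled
uniformly without replacement from the grid (all of them when m = grid_size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import simpson

from .data_model import Domain, FunctionalSample, SubjectRecord

__all__ = ["SimulationDesign", "simulate_dataset", "deviation_size", "deviation_variance"]

DeviationKind = Literal["none", "quadratic", "trigonometric"]

_DEFAULT_RE_COV = np.array([[1.0, -0.5], [-0.5, 1.0]])


@dataclass
class SimulationDesign:
    """One cell of the factorial simulation: who is observed, where, and how
    far the truth deviates from the quadratic-polynomial null."""

    n: int
    m: int
    delta: float = 0.0
    deviation: DeviationKind = "none"
    grid_size: int = 80
    domain: Domain = field(default_factory=lambda: Domain(-1.0, 1.0))
    noise_sd: float = 1.0
    re_cov: np.ndarray = field(default_factory=lambda: _DEFAULT_RE_COV.copy())
    # score variances for the trigonometric deviation / Var(b2) for quadratic
    quad_var: float = 1.0
    trig_lambdas: tuple[float, float] = (1.0, 1.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.re_cov = np.asarray(self.re_cov, dtype=float)
        if self.n < 1:
            raise ValueError("need n >= 1 subjects")
        if not 1 <= self.m <= self.grid_size:
            raise ValueError(f"need 1 <= m <= grid_size, got m={self.m}, grid_size={self.grid_size}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.re_cov.shape != (2, 2) or not np.allclose(self.re_cov, self.re_cov.T):
            raise ValueError("re_cov must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(self.re_cov)[0] < -1e-10:
            raise ValueError("re_cov must be positive semidefinite")
        if self.deviation not in ("none", "quadratic", "trigonometric"):
            raise ValueError(f"unknown deviation kind {self.deviation!r}")
        if min(self.trig_lambdas) < 0 or self.quad_var < 0:
            raise ValueError("score variances must be >= 0")

    def grid(self) -> np.ndarray:
        return np.linspace(self.domain.a, self.domain.b, self.grid_size)


def _deviation_draw(design: SimulationDesign, times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One subject's deviation trajectory Delta * z_i evaluated at `times`."""
    if design.deviation == "none" or design.delta == 0.0:
        return np.zeros_like(times)
    if design.deviation == "quadratic":
        b2 = rng.normal(0.0, np.sqrt(design.quad_var))
        return design.delta * b2 * times**2
    lam1, lam2 = design.trig_lambdas
    xi = rng.normal(0.0, [np.sqrt(lam1), np.sqrt(lam2)])
    return design.delta * (xi[0] * np.sin(2 * np.pi * times) + xi[1] * np.sin(4 * np.pi * times))


def simulate_dataset(design: SimulationDesign, seed: int | None = None) -> FunctionalSample:
    """Draw one dataset from the design.

    `seed` overrides `design.seed`; with a fixed seed the dataset is
    bit-reproducible.  Per-subject time points are sorted ascending.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    grid = design.grid()
    chol = np.linalg.cholesky(design.re_cov + 1e-12 * np.eye(2))
    subjects = []
    for i in range(design.n):
        if design.m == design.grid_size:
            t = grid.copy()
        else:
            idx = np.sort(rng.choice(design.grid_size, size=design.m, replace=False))
            t = grid[idx]
        b = chol @ rng.standard_normal(2)
        x = b[0] + b[1] * t + _deviation_draw(design, t, rng)
        y = x + rng.normal(0.0, design.noise_sd, size=t.size)
        subjects.append(SubjectRecord(i, t, y))
    return FunctionalSample(subjects, design.domain)


def deviation_variance(design: SimulationDesign, t: np.ndarray) -> np.ndarray:
    """Var{z_i(t)} (without the Delta^2 factor) at time points t."""
    t = np.asarray(t, dtype=float)
    if design.deviation == "none":
        return np.zeros_like(t)
    if design.deviation == "quadratic":
        return design.quad_var * t**4
    lam1, lam2 = design.trig_lambdas
    return lam1 * np.sin(2 * np.pi * t) ** 2 + lam2 * np.sin(4 * np.pi * t) ** 2


def deviation_size(design: SimulationDesign, n_points: int = 2001) -> float:
    """Scale-free size of the departure from the null covariance:

        Delta^2 * integral_T Var{z_i(t)} / Var{X_i(t)} dt,

    where Var{X_i(t)} = Var(b0 + b1 t) + Delta^2 Var{z_i(t)} includes the
    deviation.  Computed by composite Simpson quadrature (the integrand is
    smooth and bounded when the random-effects covariance is positive
    definite on the domain).  Zero when Delta = 0.
    """
    if design.delta == 0.0 or design.deviation == "none":
        return 0.0
    t = np.linspace(design.domain.a, design.domain.b, n_points)
    s00, s01, s11 = design.re_cov[0, 0], design.re_cov[0, 1], design.re_cov[1, 1]
    var_lin = s00 + 2 * s01 * t + s11 * t**2
    var_z = deviation_variance(design, t)
    var_x = var_lin + design.delta**2 * var_z
    integrand = np.where(var_x > 0, design.delta**2 * var_z / var_x, 0.0)
    return float(simpson(integrand, x=t))
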