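"""Factorial size/power simulation experiments for the covariance tests.

Each cell is a data-generating design (n subjects, m observations per
subject, deviation kind and size Delta).  A size study simulates null
datasets (Delta = 0) and records the rejection fraction of each configured
test at the nominal levels; a power study sweeps a Delta grid and reports
rejection rates against the scale-free deviation size.

Reproducibility contract: the seed of replicate r of cell c is derived from
(master_seed, c, r), so results are bit-identical for a fixed master seed
regardless of the worker count, and any single replicate can be re-run in
isolation.

For the direct test inside a study, the finite-sample RLRT reference
distribution is, by default, simulated once per cell (from the null model
fitted to the cell's first replicate) and shared across replicates: every
dataset in a cell comes from the same generating design, and the RLRT null
distribution depends on the design rather than on the particular replicate,
so sharing changes nothing but the cost.  Per-dataset simulation remains
available (`direct_shared_null=False`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .direct import run_direct_test, simulate_rlrt_null, _rlrt_stat
from .gof import GofEngine, run_gof_test
from .mean import MeanSmoother
from .basis import build_basis
from .synthetic import SimulationDesign, deviation_size, simulate_dataset

__all__ = ["StudyConfig", "StudyResult", "run_size_study", "run_power_study"]


@dataclass
class StudyConfig:
    """Specification of one batch of simulation cells."""

    designs: list[SimulationDesign]
    tests: tuple[str, ...] = ("bootstrap",)
    replications: int = 200
    L: int = 200                      # bootstrap samples per dataset
    alphas: tuple[float, ...] = (0.05, 0.10)
    null_sim_draws: int = 2000        # RLRT reference sample size
    direct_shared_null: bool = True
    master_seed: int = 0
    n_jobs: int = 1
    H: int = 10
    mean_basis_dim: int = 10
    mean_selection: str = "reml"

    def __post_init__(self) -> None:
        for t in self.tests:
            if t not in ("bootstrap", "direct"):
                raise ValueError(f"unknown test {t!r}; expected 'bootstrap' or 'direct'")
        if self.replications < 1 or self.L < 1:
            raise ValueError("replications and L must be >= 1")


@dataclass
class StudyResult:
    """Tidy per-cell rejection rates plus the raw p-value archive."""

    table: pd.DataFrame
    pvalues: dict = field(repr=False, default_factory=dict)

    def rate(self, test: str, n: int, m: int, alpha: float, delta: float = 0.0) -> float:
        tb = self.table
        row = tb[
            (tb.test == test) & (tb.n == n) & (tb.m == m)
            & np.isclose(tb.alpha, alpha) & np.isclose(tb.delta, delta)
        ]
        if row.empty:
            raise KeyError((test, n, m, alpha, delta))
        return float(row.rate.iloc[0])


def _replicate_seed(master: int, cell: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=(cell, rep))


def _run_one(design: SimulationDesign, cfg: StudyConfig, cell: int, rep: int,
             direct_reference: np.ndarray | None) -> dict:
    ss = _replicate_seed(cfg.master_seed, cell, rep)
    s_data, s_boot, s_direct = ss.spawn(3)
    sample = simulate_dataset(design, seed=np.random.default_rng(s_data))
    out: dict = {}
    if "bootstrap" in cfg.tests:
        try:
            res = run_gof_test(
                sample, L=cfg.L, seed=s_boot, H=cfg.H,
                mean_basis_dim=cfg.mean_basis_dim, mean_selection=cfg.mean_selection,
            )
            out["bootstrap"] = res.p_value
        except Exception:
            out["bootstrap"] = np.nan
    if "direct" in cfg.tests:
        try:
            res = run_direct_test(
                sample, null_sim_draws=cfg.null_sim_draws, seed=s_direct,
                mean_basis_dim=cfg.mean_basis_dim, mean_selection=cfg.mean_selection,
                null_reference=direct_reference,
            )
            out["direct"] = res.p_value
        except Exception:
            out["direct"] = np.nan
    return out


def _direct_reference_for_cell(design: SimulationDesign, cfg: StudyConfig, cell: int) -> np.ndarray:
    """Shared RLRT reference: fit the null to the cell's first replicate and
    simulate the reference distribution at that replicate's design points."""
    ss = _replicate_seed(cfg.master_seed, cell, 0)
    s_data, _, s_direct = ss.spawn(3)
    sample = simulate_dataset(design, seed=np.random.default_rng(s_data))
    pooled_t, pooled_y = sample.pooled()
    smoother = MeanSmoother(pooled_t, build_basis(sample.domain, H=cfg.mean_basis_dim))
    mean_fit = smoother.fit(pooled_y, selection=cfg.mean_selection)
    resid = pooled_y - smoother.B @ mean_fit.coef
    resid_list = np.split(resid, np.cumsum(sample.counts)[:-1])
    _, null_fit, _ = _rlrt_stat(sample.times_list(), resid_list, sample.domain)
    return simulate_rlrt_null(
        null_fit, sample.times_list(), draws=cfg.null_sim_draws,
        seed=np.random.default_rng(s_direct), domain=sample.domain,
    )


def _run_cells(designs: list[SimulationDesign], cfg: StudyConfig) -> StudyResult:
    rows = []
    pvalues: dict = {}
    for cell, design in enumerate(designs):
        reference = None
        if "direct" in cfg.tests and cfg.direct_shared_null:
            reference = _direct_reference_for_cell(design, cfg, cell)
        runner = Parallel(n_jobs=cfg.n_jobs) if cfg.n_jobs != 1 else None
        jobs = (
            delayed(_run_one)(design, cfg, cell, rep, reference)
            for rep in range(cfg.replications)
        )
        results = runner(jobs) if runner else [f[0](*f[1], **f[2]) for f in jobs]
        dsize = deviation_size(design)
        for test in cfg.tests:
            ps = np.array([r.get(test, np.nan) for r in results])
            pvalues[(cell, test)] = ps
            ok = ps[~np.isnan(ps)]
            n_ok = ok.size
            for alpha in cfg.alphas:
                rate = float(np.mean(ok < alpha)) if n_ok else np.nan
                se = float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else np.nan
                rows.append({
                    "test": test, "n": design.n, "m": design.m, "alpha": alpha,
                    "deviation": design.deviation, "delta": design.delta,
                    "deviation_size": dsize, "R": n_ok, "L": cfg.L,
                    "rate": rate, "se": se, "n_failed": int(ps.size - n_ok),
                })
    return StudyResult(table=pd.DataFrame(rows), pvalues=pvalues)


def run_size_study(config: StudyConfig) -> StudyResult:
    """Empirical type-I error rates: every design is run with Delta = 0."""
    null_designs = [
        dataclasses.replace(d, delta=0.0, deviation="none") for d in config.designs
    ]
    return _run_cells(null_designs, config)


def run_power_study(config: StudyConfig, deltas: list[float]) -> StudyResult:
    """Rejection rates across a Delta grid; the result table reports the
    computed deviation size alongside each Delta (the natural x-axis)."""
    if any(d <= 0 for d in deltas):
        raise ValueError("power deltas must be > 0 (Delta = 0 is the size study)")
    designs = []
    for base in config.designs:
        if base.deviation == "none":
            raise ValueError("power study designs need a deviation kind")
        designs.extend(dataclasses.replace(base, delta=float(dv)) for dv in deltas)
    return _run_cells(designs, config)
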