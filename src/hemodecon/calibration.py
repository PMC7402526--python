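"""Calibration of the 27 system parameters to drug-free kinetic data.

The fit adjusts 13 proliferation rates, 7 renewal fractions, 6 branching
fractions (renormalized so each branch point sums to one), the uniform death
rate, and 14 initial-condition multipliers (one per live readout plus the
dead pool, bounded to [0.1, 1] times the measured day-0 counts).  Only days
2-6 enter the objective: day-0 counts reflect post-thaw recovery and later
days follow a replating step, so neither is fit.

Identifiability is assessed by profile likelihood: one parameter is fixed
across a grid and all others re-optimized; a flat profile flags a
practically non-identifiable parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datasets import KineticDataset
from .fitting import FitResult, global_search, seeded_population
from .model import (
    BRANCH_EDGES,
    CELL_TYPES,
    KAPPA_MAX,
    READOUTS,
    RENEWING_TYPES,
    ModelState,
    SystemParameters,
)
from .simulate import simulate_control_kinetics

__all__ = [
    "FitSettings",
    "ProfileResult",
    "kinetic_objective",
    "fit_system",
    "profile_likelihood",
]

# canonical free-parameter ordering for the fit vector
RHO_ORDER: tuple[str, ...] = tuple(ct for ct in CELL_TYPES if ct in RENEWING_TYPES)
IC_ORDER: tuple[str, ...] = READOUTS  # 13 live + totalDeadCells


@dataclass
class FitSettings:
    """Hybrid-optimizer settings for the system calibration."""

    max_generations: int = 50
    population_size: int = 500
    seed: int = 0
    local_search: bool = True
    scaling: str = "mean"  # residual scaling: mean | raw | log
    ic_multiplier_bounds: tuple[float, float] = (0.1, 1.0)
    n_polish: int = 3
    polish_max_nfev: int = 500
    flatness_threshold: float = 1e-3

    def __post_init__(self) -> None:
        if self.max_generations <= 0 or self.population_size <= 0:
            raise ValueError("generations and population size must be > 0")
        if self.scaling not in ("mean", "raw", "log"):
            raise ValueError(f"unknown residual scaling {self.scaling!r}")


def kinetic_objective(
    sys: SystemParameters,
    initial: ModelState,
    data: KineticDataset,
    scaling: str = "mean",
) -> float:
    """Sum of squared scaled residuals over all 14 readouts, days 2-6.

    With ``scaling="mean"`` each residual is divided by that readout's mean
    observed level across the fitting days, so fast-expanding lineages do
    not dominate the loss; ``"raw"`` uses unscaled residuals and ``"log"``
    compares log1p counts.
    """
    r = _residual_vector(sys, initial, data, scaling)
    return float(r @ r)


def _observed_readouts(data: KineticDataset, days) -> list[str]:
    """Readouts with complete observations over the fitting days; a dataset
    may legitimately cover only part of the panel."""
    cols = []
    for r in READOUTS:
        if r in data.mean_table.columns and data.mean_table.loc[days, r].notna().all():
            cols.append(r)
    if not cols:
        raise ValueError("kinetic dataset has no fully observed readouts")
    return cols


def _residual_vector(sys, initial, data, scaling) -> np.ndarray:
    days = data.fitting_days()
    if not days:
        raise ValueError("kinetic dataset has no days in [2, 6]")
    cols = _observed_readouts(data, days)
    grid = sorted({0.0, *days})
    traj = simulate_control_kinetics(sys, initial, days=grid, validate=False)
    sim = traj.table.loc[days, cols]
    obs = data.mean_table.loc[days, cols]
    if scaling == "log":
        return (np.log1p(sim.values) - np.log1p(obs.values)).ravel()
    diff = sim.values - obs.values
    if scaling == "mean":
        scale = obs.values.mean(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        diff = diff / scale
    return diff.ravel()


class _SystemProblem:
    """Packs/unpacks the 41-dimensional fit vector (27 params + 14 initial
    multipliers) and evaluates the objective."""

    def __init__(self, data: KineticDataset, settings: FitSettings):
        self.data = data
        self.settings = settings
        # precompute observation matrices for the array-based residual path
        days = data.fitting_days()
        self._grid = np.array(sorted({0.0, *days}))
        self._rows = [i for i, t in enumerate(self._grid) if t in days]
        cols = _observed_readouts(data, days)
        self._cols = [READOUTS.index(r) for r in cols]
        obs = data.mean_table.loc[days, cols].values
        self._obs = obs
        scale = obs.mean(axis=0)
        self._scale = np.where(scale > 0, scale, 1.0)
        if data.day0_counts is None:
            raise ValueError("kinetic dataset lacks day-0 counts needed to "
                             "bound initial conditions")
        self.day0 = data.day0_counts.reindex(list(IC_ORDER)).fillna(0.0)
        lo_m, hi_m = settings.ic_multiplier_bounds
        b: list[tuple[float, float]] = []
        b += [(0.0, KAPPA_MAX)] * len(CELL_TYPES)
        b += [(0.5, 1.0) if ct == "HSC" else (0.0, 0.5) for ct in RHO_ORDER]
        b += [(0.001, 1.0)] * len(BRANCH_EDGES)
        b += [(0.0, 2.0)]
        b += [(lo_m, hi_m)] * len(IC_ORDER)
        self.bounds = np.array(b)
        self.names = (
            [f"kappa_{ct}" for ct in CELL_TYPES]
            + [f"rho_{ct}" for ct in RHO_ORDER]
            + [f"beta_{a}_{b_}" for a, b_ in BRANCH_EDGES]
            + ["delta"]
            + [f"ic_{r}" for r in IC_ORDER]
        )

    @property
    def n(self) -> int:
        return len(self.bounds)

    def unpack(self, x: np.ndarray) -> tuple[SystemParameters, ModelState]:
        i = 0
        kappa = {ct: float(x[i + j]) for j, ct in enumerate(CELL_TYPES)}
        i += 13
        rho = {ct: float(x[i + j]) for j, ct in enumerate(RHO_ORDER)}
        i += 7
        beta_raw = {e: float(x[i + j]) for j, e in enumerate(BRANCH_EDGES)}
        i += 6
        delta = float(x[i]); i += 1
        # project each branch point onto the unit simplex with the 0.001
        # floor: the floor is assigned first, the remainder is distributed
        # proportionally to the candidate's mass above the floor
        beta = dict(beta_raw)
        floor = 0.001
        for parent in ("MPP", "GMP"):
            edges = [e for e in BRANCH_EDGES if e[0] == parent]
            n = len(edges)
            vals = np.array([beta_raw[e] for e in edges])
            s = vals.sum()
            vals = vals / s if s > 0 else np.full(n, 1.0 / n)
            above = np.clip(vals - floor, 0.0, None)
            budget = 1.0 - floor * n
            if above.sum() > 0:
                vals = floor + above * (budget / above.sum())
            else:
                vals = np.full(n, 1.0 / n)
            for e, v in zip(edges, vals):
                beta[e] = float(v)
        sys = SystemParameters(kappa=kappa, rho=rho, beta=beta, delta=delta)
        mult = x[i:i + len(IC_ORDER)]
        counts = {ct: float(mult[j] * self.day0[ct])
                  for j, ct in enumerate(CELL_TYPES)}
        dead0 = float(mult[len(IC_ORDER) - 1] * self.day0["totalDeadCells"])
        initial = ModelState(counts=counts, quiescent_neutrophils=0.0,
                             total_dead=dead0)
        return sys, initial

    def residuals(self, x: np.ndarray) -> np.ndarray:
        sys, initial = self.unpack(x)
        traj = simulate_control_kinetics(sys, initial, days=self._grid,
                                         validate=False)
        S = traj.states[self._rows]
        sim = np.concatenate([S[:, :13], S[:, 14:15]], axis=1)
        sim[:, 7] += S[:, 13]  # reported Neut includes the quiescent pool
        sim = sim[:, self._cols]
        if self.settings.scaling == "log":
            return (np.log1p(sim) - np.log1p(self._obs)).ravel()
        diff = sim - self._obs
        if self.settings.scaling == "mean":
            diff = diff / self._scale
        return diff.ravel()

    def objective(self, x: np.ndarray) -> float:
        r = self.residuals(x)
        return float(r @ r)

    def heuristic_candidate(self) -> np.ndarray:
        """Crude data-driven start: per-readout exponential growth rates
        mapped onto (kappa, rho) with mid-range renewal, uniform branching."""
        x = self.bounds.mean(axis=1).copy()
        days = self.data.fitting_days()
        obs = self.data.mean_table.loc[days]
        for j, ct in enumerate(CELL_TYPES):
            if ct not in obs.columns or obs[ct].isna().any():
                continue
            y = obs[ct].values
            if (y > 0).all() and len(days) >= 2:
                rate = np.polyfit(days, np.log(y), 1)[0]
            else:
                rate = 0.0
            if ct in RENEWING_TYPES:
                r0 = 0.75 if ct == "HSC" else 0.25
                denom = 2.0 * r0 - 1.0
                k = rate / denom if denom != 0 else 1.0
            else:
                k = rate
            x[j] = np.clip(k, 0.0, KAPPA_MAX)
        x[-len(IC_ORDER):] = self.bounds[-len(IC_ORDER):, 1]  # start at day-0 counts
        return x


def fit_system(data: KineticDataset, settings: FitSettings) -> FitResult:
    """Hybrid global + local fit of system parameters and initial conditions.

    Deterministic for a fixed seed; the returned parameters satisfy all
    bounds, with branch fractions renormalized onto the simplex.
    """
    prob = _SystemProblem(data, settings)
    rng = np.random.default_rng(settings.seed)
    candidates = [prob.bounds.mean(axis=1), prob.heuristic_candidate()]
    pop = seeded_population(rng, prob.bounds, settings.population_size, candidates)
    best_cands, trace = global_search(
        prob.objective, prob.bounds, pop, settings.max_generations,
        settings.seed, n_best=settings.n_polish,
    )
    best_x, best_f = None, np.inf
    for c in best_cands:
        f = prob.objective(c)
        if settings.local_search:
            res = least_squares(
                prob.residuals, c,
                bounds=(prob.bounds[:, 0], prob.bounds[:, 1]),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-12,
                max_nfev=settings.polish_max_nfev,
            )
            if res.cost * 2.0 < f:
                c, f = res.x, res.cost * 2.0
        if f < best_f:
            best_x, best_f = c, f
    sys, initial = prob.unpack(best_x)
    return FitResult(
        parameters=sys, objective=best_f, x=np.asarray(best_x),
        seed=settings.seed, bounds=list(map(tuple, prob.bounds)), trace=trace,
        diagnostics={"names": prob.names, "scaling": settings.scaling},
        initial_state=initial,
    )


@dataclass
class ProfileResult:
    """Profile-likelihood curve for one parameter.

    ``flat`` flags practical non-identifiability when the profile varies by
    less than the configured threshold over the grid; the threshold is a
    stand-in for a formal confidence cutoff and reports must label it as
    such.
    """

    param: str
    curve: pd.DataFrame  # columns: value, objective
    flat: bool
    threshold: float


def profile_likelihood(
    param_id: str,
    grid,
    data: KineticDataset,
    settings: FitSettings,
    base: FitResult | None = None,
) -> ProfileResult:
    """Fix ``param_id`` at each grid value and re-optimize all other
    parameters (warm-started local refinement from the unconstrained
    optimum)."""
    prob = _SystemProblem(data, settings)
    if base is None:
        base = fit_system(data, settings)
    try:
        k = prob.names.index(param_id)
    except ValueError:
        raise ValueError(f"unknown parameter {param_id!r}") from None
    lo, hi = prob.bounds[k]
    grid = np.asarray(grid, float)
    if np.any(grid < lo) or np.any(grid > hi):
        raise ValueError(f"profile grid outside bounds [{lo}, {hi}] "
                         f"for {param_id}")
    free = [i for i in range(prob.n) if i != k]

    rows = []
    x_warm = np.asarray(base.x, float).copy()
    for v in grid:
        def residuals_fixed(xf, v=v):
            x = x_warm.copy()
            x[free] = xf
            x[k] = v
            return prob.residuals(x)

        res = least_squares(
            residuals_fixed, x_warm[free],
            bounds=(prob.bounds[free, 0], prob.bounds[free, 1]),
            method="trf", xtol=1e-12, ftol=1e-12,
            max_nfev=settings.polish_max_nfev,
        )
        rows.append({"value": float(v), "objective": float(res.cost * 2.0)})
        x_warm[free] = res.x  # walk the profile
        x_warm[k] = v
    curve = pd.DataFrame(rows)
    span = curve["objective"].max() - curve["objective"].min()
    flat = bool(span <= settings.flatness_threshold * (1.0 + curve["objective"].min()))
    return ProfileResult(param=param_id, curve=curve, flat=flat,
                         threshold=settings.flatness_threshold)
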