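"""Shared optimizer plumbing: hybrid global + local search and fit results.

The hybrid contract: a bounded population-based global search (differential
evolution with an explicitly seeded initial population, so candidate
solutions such as the all-zero drug mechanism can be injected) followed by
bounded local refinement from the best candidates.  Every fit records its
seed, bounds, and the best-objective trace per generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.optimize import differential_evolution

__all__ = ["FitResult", "global_search", "seeded_population"]


@dataclass
class FitResult:
    """Outcome of a calibration run."""

    parameters: Any
    objective: float
    x: np.ndarray
    seed: int
    bounds: list[tuple[float, float]]
    trace: list[float] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    initial_state: Any = None


def seeded_population(
    rng: np.random.Generator,
    bounds: np.ndarray,
    population_size: int,
    candidates: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Uniform-in-bounds population with specific candidates injected."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    n = len(lo)
    size = max(population_size, 5)  # differential evolution needs >= 5
    pop = rng.uniform(lo, hi, size=(size, n))
    for i, cand in enumerate(candidates or []):
        if i >= size:
            break
        pop[i] = np.clip(cand, lo, hi)
    return pop


def global_search(
    func: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    init_population: np.ndarray,
    max_generations: int,
    seed: int,
    n_best: int = 3,
) -> tuple[list[np.ndarray], list[float]]:
    """Run the global stage; return the ``n_best`` distinct candidates found
    and the per-generation best-objective trace."""
    trace: list[float] = []

    def cb(intermediate_result=None, convergence=None):
        if intermediate_result is not None and hasattr(intermediate_result, "fun"):
            trace.append(float(intermediate_result.fun))

    result = differential_evolution(
        func,
        bounds=list(map(tuple, bounds)),
        init=init_population,
        maxiter=max_generations,
        seed=seed,
        tol=0.0,
        polish=False,
        callback=cb,
    )
    # rank the final population to seed local refinement
    pop = getattr(result, "population", None)
    energies = getattr(result, "population_energies", None)
    cands = [np.asarray(result.x)]
    if pop is not None and energies is not None:
        order = np.argsort(energies)
        for i in order[:n_best]:
            c = np.asarray(pop[i])
            if not any(np.allclose(c, prev) for prev in cands):
                cands.append(c)
    return cands[:n_best], trace
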