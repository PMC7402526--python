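"""Synthetic assay data with the statistical structure the analysis assumes.

The generator emulates two data kinds: six-donor drug-free kinetic counts
(days 0-6) and per-compound dose-response tables normalized to the mean of
six virtual vehicle-control wells per donor.  Noise is multiplicative
lognormal with unit mean and a configurable coefficient of variation — a
surrogate for the unpublished donor-to-donor variance structure of the real
assay, chosen because cell counts are positive and errors scale with
abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import DoseResponseDataset, KineticDataset
from .model import READOUTS, DrugEffectParameters, ModelState, SystemParameters
from .simulate import DEFAULT_KINETIC_DAYS, integrate, simulate_control_kinetics

__all__ = ["NoiseModel", "generate_kinetic_dataset", "generate_dose_response_dataset"]


@dataclass
class NoiseModel:
    """Donor replication and multiplicative lognormal noise.

    ``cv`` is the coefficient of variation of the unit-mean lognormal factor
    applied independently per readout, day/dose, and donor.
    """

    donor_count: int = 6
    cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.donor_count < 1:
            raise ValueError("donor_count must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    def factors(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.cv == 0.0:
            return np.ones(shape)
        sigma2 = math.log(1.0 + self.cv ** 2)
        mu = -0.5 * sigma2
        return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=shape)


def generate_kinetic_dataset(
    sys: SystemParameters,
    initial: ModelState,
    noise: NoiseModel,
    days=DEFAULT_KINETIC_DAYS,
) -> KineticDataset:
    """Per-donor noisy copies of the drug-free model trajectory."""
    rng = np.random.default_rng(noise.seed)
    traj = simulate_control_kinetics(sys, initial, days=days)
    truth = traj.table[list(READOUTS)]
    records = []
    for donor in range(1, noise.donor_count + 1):
        f = noise.factors(rng, truth.shape)
        noisy = truth.values * f
        for i, day in enumerate(truth.index):
            for j, readout in enumerate(READOUTS):
                records.append(
                    {"donor_id": f"donor{donor}", "day": float(day),
                     "readout": readout, "cells_per_ml": float(noisy[i, j])}
                )
    return KineticDataset(donors=pd.DataFrame.from_records(records))


def generate_dose_response_dataset(
    sys: SystemParameters,
    drug: DrugEffectParameters,
    doses,
    noise: NoiseModel,
    initial: ModelState,
    compound: str = "synthetic",
    n_vehicle_wells: int = 6,
    readout_day: float = 6.0,
    donor_scales=None,
) -> DoseResponseDataset:
    """Simulate treated and vehicle wells, normalize per donor, pool by mean.

    Each virtual donor contributes one treated well per dose and
    ``n_vehicle_wells`` vehicle wells; every treated readout is divided by
    the mean of that donor's vehicle wells, mirroring plate-level vehicle
    normalization, then donors are averaged.  ``donor_scales`` optionally
    multiplies all of one donor's counts by a global factor (e.g. seeding
    density differences); normalization cancels it exactly.
    """
    rng = np.random.default_rng(noise.seed)
    doses = [float(d) for d in doses]
    t_grid = np.array([0.0, readout_day])
    vehicle_truth = _day6_readouts(
        integrate(sys, None, 0.0, initial, t_grid), readout_day)
    treated_truth = {
        d: _day6_readouts(integrate(sys, drug, d, initial, t_grid), readout_day)
        for d in doses if d > 0
    }
    if donor_scales is None:
        donor_scales = [1.0] * noise.donor_count
    donor_tables = []
    for donor in range(noise.donor_count):
        scale = float(donor_scales[donor])
        veh = vehicle_truth.values * scale * noise.factors(
            rng, (n_vehicle_wells, len(READOUTS)))
        veh_mean = veh.mean(axis=0)
        rows = {}
        for d in doses:
            if d == 0:
                well = vehicle_truth.values * scale * noise.factors(
                    rng, len(READOUTS))
            else:
                well = treated_truth[d].values * scale * noise.factors(
                    rng, len(READOUTS))
            safe = np.where(veh_mean > 0, veh_mean, np.nan)
            norm = well / safe
            rows[d] = np.where(np.isnan(norm), 1.0, norm)
        donor_tables.append(pd.DataFrame(rows, index=list(READOUTS)).T)
    pooled = sum(donor_tables) / len(donor_tables)
    if noise.cv == 0.0 and 0.0 in doses:
        pooled.loc[0.0] = 1.0  # exact self-normalization without noise
    return DoseResponseDataset(compound=compound, table=pooled,
                               n_donors=noise.donor_count)


def _day6_readouts(traj, day: float) -> pd.Series:
    st = traj.state_at(day)
    return pd.Series(st.readouts())[list(READOUTS)]
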