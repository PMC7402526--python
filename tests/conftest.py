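"""Shared fixtures: reference parameters and small synthetic datasets."""

import math

import numpy as np
import pytest

from hemodecon import (
    CELL_TYPES,
    DOSE_GRID_NM,
    DrugEffectParameters,
    ModelState,
    NoiseModel,
    SystemParameters,
    default_initial_state,
    default_system_parameters,
)
from hemodecon.synthetic import generate_dose_response_dataset, generate_kinetic_dataset


@pytest.fixture(scope="session")
def ref_sys() -> SystemParameters:
    return default_system_parameters()


@pytest.fixture(scope="session")
def ref_init() -> ModelState:
    return default_initial_state()


@pytest.fixture(scope="session")
def inert_drug() -> DrugEffectParameters:
    return DrugEffectParameters.inert()


@pytest.fixture(scope="session")
def sparse_drug() -> DrugEffectParameters:
    """Known sparse mechanism: anti-proliferation on HSC only."""
    d = DrugEffectParameters.inert()
    d.emax_total["HSC"] = 0.8
    d.log_ec50["HSC"] = math.log(50.0)
    return d


@pytest.fixture(scope="session")
def noiseless_kinetics(ref_sys, ref_init):
    return generate_kinetic_dataset(
        ref_sys, ref_init, NoiseModel(donor_count=6, cv=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def sparse_dose_response(ref_sys, ref_init, sparse_drug):
    return generate_dose_response_dataset(
        ref_sys, sparse_drug, (0.0,) + DOSE_GRID_NM,
        NoiseModel(donor_count=1, cv=0.0, seed=1), ref_init,
        compound="sparse-test",
    )


def zeroed_system(**overrides) -> SystemParameters:
    """All-zero-rate system with valid branch fractions, for closed-form
    reductions; overrides patch individual fields."""
    sys = SystemParameters(
        kappa={ct: 0.0 for ct in CELL_TYPES},
        rho={ct: 0.5 if ct != "HSC" else 0.5 for ct in
             ("HSC", "MPP", "GMP", "GranP", "Gran", "MonoP", "ErythI")},
        beta={("MPP", "GMP"): 0.25, ("MPP", "ErythI"): 0.25,
              ("MPP", "MK"): 0.25, ("MPP", "LymP"): 0.25,
              ("GMP", "GranP"): 0.5, ("GMP", "MonoP"): 0.5},
        delta=0.0,
        k_quiescence=0.0,
    )
    for key, value in overrides.items():
        if key in ("delta", "k_quiescence"):
            setattr(sys, key, value)
        elif key.startswith("kappa_"):
            sys.kappa[key[6:]] = value
        elif key.startswith("rho_"):
            sys.rho[key[4:]] = value
        else:
            raise KeyError(key)
    return sys


def empty_state(**counts) -> ModelState:
    c = {ct: 0.0 for ct in CELL_TYPES}
    c.update(counts)
    return ModelState(counts=c)
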