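"""Reference parameter sets.

``REFERENCE_DRUGS`` holds published fitted Emax_T / EC50 values for an
eight-compound reference panel with well-characterized hematopoietic
toxicity (four CDK inhibitors, two taxanes, one PI3K inhibitor, and
thalidomide as negative control).  These serve as fixtures for forward
simulation and comparative analytics, not as refitting targets.

``default_system_parameters`` / ``default_initial_state`` are a synthetic
drug-free parameter set: plausible six-day expansion kinetics of a CD34+
culture, chosen once as the reference configuration for the synthetic-data
generator.  They are not fitted to any experimental dataset.
"""

from __future__ import annotations

import math

from .model import CELL_TYPES, DrugEffectParameters, ModelState, SystemParameters

__all__ = [
    "REFERENCE_DRUGS",
    "DOSE_GRID_NM",
    "reference_drug",
    "default_system_parameters",
    "default_initial_state",
]

#: The printed assay dose panel (nM).
DOSE_GRID_NM: tuple[float, ...] = (0.2, 1.0, 5.0, 25.0, 100.0, 500.0, 2500.0)

# EC50 in nM per cell type (canonical order: HSC, MPP, GMP, GranP, Gran,
# MonoP, Mono, Neut, ErythI, ErythII, MK, LymP, B)
_EC50 = {
    "abemaciclib": (111.199, 46.123, 37.326, 33.181, 38.891, 42.516, 46.187,
                    66.213, 29.184, 45.082, 486.023, 36.507, 69.229),
    "dinaciclib": (70.670, 16.681, 49.137, 548.688, 167.897, 31.343, 28.381,
                   14.199, 25.770, 32.781, 23.213, 25.655, 41.555),
    "docetaxel": (33.732, 4.706, 102.942, 127.836, 7.907, 7.885, 9.030,
                  13.699, 8.136, 6.299, 7.789, 17.633, 10.386),
    "paclitaxel": (62.300, 42.378, 28.210, 98.209, 15.772, 24.767, 30.004,
                   25.092, 15.356, 20.180, 51.732, 11.696, 36.695),
    "palbociclib": (165.661, 354.142, 54.617, 0.105, 20.732, 33.480, 39.336,
                    74.956, 42.506, 99.537, 758.847, 23.977, 90.551),
    "pictilisib": (289.334, 368.700, 1.406, 93.047, 0.167, 116.627, 1023.971,
                   131.773, 190.664, 190.999, 1070.272, 3.805, 91.304),
    "ribociclib": (372.722, 700.610, 140.666, 21.418, 22.176, 75.973, 180.253,
                   177.785, 88.607, 222.347, 2044.762, 12.339, 35.828),
    "thalidomide": (189.555, 718.402, 176.993, 128.605, 36.708, 305.042,
                    694.357, 0.302, 424.670, 1379.963, 321.784, 20.077, 130.058),
}

_EMAX_T = {
    "abemaciclib": (0.910, 0.002, 1.034, 0.002, 0.002, 0.002, 0.231,
                    0.235, 1.024, 0.033, 0.068, 0.002, 0.649),
    "dinaciclib": (1.031, 0.694, 0.001, 0.000, 2.010, 0.000, 0.482,
                   0.281, 1.115, 0.071, 0.331, 1.149, 0.774),
    "docetaxel": (1.300, 2.014, 0.000, 0.000, 2.762, 1.459, 0.198,
                  0.232, 1.726, 0.016, 0.126, 0.002, 1.019),
    "paclitaxel": (1.188, 0.002, 0.001, 0.000, 2.360, 1.556, 0.258,
                   0.214, 1.466, 0.071, 0.259, 0.002, 0.914),
    "palbociclib": (0.776, 0.000, 0.884, 0.047, 0.000, 0.000, 0.142,
                    0.184, 0.000, 0.118, 0.074, 0.000, 0.499),
    "pictilisib": (0.486, 0.000, 0.071, 0.605, 0.232, 1.399, 0.039,
                   0.165, 0.000, 0.136, 0.123, 0.000, 0.514),
    "ribociclib": (0.489, 0.000, 0.760, 0.064, 0.000, 0.000, 0.195,
                   0.139, 0.001, 0.108, 0.048, 0.000, 0.305),
    "thalidomide": (0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000,
                    0.011, 0.000, 0.000, 0.000, 0.000, 0.002),
}

#: Fitted drug-effect parameters for the reference compound panel,
#: keyed by compound name, as (emax_total, ec50_nM) dicts per cell type.
REFERENCE_DRUGS: dict[str, dict[str, dict[str, float]]] = {
    name: {
        "emax_total": dict(zip(CELL_TYPES, _EMAX_T[name])),
        "ec50": dict(zip(CELL_TYPES, _EC50[name])),
    }
    for name in _EC50
}


def reference_drug(name: str) -> DrugEffectParameters:
    """Return the reference panel entry for ``name`` as drug parameters."""
    try:
        entry = REFERENCE_DRUGS[name]
    except KeyError:
        raise KeyError(
            f"unknown reference compound {name!r}; "
            f"available: {sorted(REFERENCE_DRUGS)}"
        ) from None
    return DrugEffectParameters(
        emax_total=dict(entry["emax_total"]),
        log_ec50={ct: math.log(v) for ct, v in entry["ec50"].items()},
    )


def default_system_parameters() -> SystemParameters:
    """Synthetic reference system parameters (drug-free kinetics).

    Rates are chosen so the culture expands roughly 70-fold over six days
    with lineage-appropriate ordering: progenitors cycle faster than stem
    cells, the erythroid branch dominates output, and lymphoid cells trickle
    through without dividing.
    """
    kappa = {
        "HSC": 0.8, "MPP": 1.2, "GMP": 1.5, "GranP": 1.6, "Gran": 1.3,
        "MonoP": 1.5, "Mono": 0.3, "Neut": 0.1, "ErythI": 1.8,
        "ErythII": 0.4, "MK": 0.2, "LymP": 0.5, "B": 0.3,
    }
    rho = {
        "HSC": 0.90, "MPP": 0.45, "GMP": 0.30, "GranP": 0.20,
        "Gran": 0.10, "MonoP": 0.20, "ErythI": 0.35,
    }
    beta = {
        ("MPP", "GMP"): 0.50, ("MPP", "ErythI"): 0.25,
        ("MPP", "MK"): 0.10, ("MPP", "LymP"): 0.15,
        ("GMP", "GranP"): 0.55, ("GMP", "MonoP"): 0.45,
    }
    return SystemParameters(kappa=kappa, rho=rho, beta=beta, delta=0.3)


def default_initial_state() -> ModelState:
    """Synthetic day-0 seeding state: a CD34+-enriched inoculum (cells/mL)."""
    counts = {ct: 200.0 for ct in CELL_TYPES}
    counts.update({
        "HSC": 20000.0, "MPP": 10000.0, "GMP": 2000.0,
        "ErythI": 1000.0, "MK": 500.0, "LymP": 500.0,
    })
    return ModelState(counts=counts, quiescent_neutrophils=0.0, total_dead=0.0)
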