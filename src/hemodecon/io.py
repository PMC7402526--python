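"""File formats: tidy CSV tables and flat key-value JSON parameter files.

Parameter keys follow the canonical naming ``kappa_<CellType>``,
``rho_<CellType>``, ``beta_<Parent>_<Child>``, ``delta``, ``k_quiescence``
for the system, and ``emaxT_<CellType>``, ``logEC50_<CellType>`` for drug
effects.  EC50 values are stored as logEC50; derived ``EC50_<CellType>``
entries are echoed on write for readability and ignored on read.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .datasets import DoseResponseDataset, KineticDataset
from .model import (
    BRANCH_EDGES,
    CELL_TYPES,
    DrugEffectParameters,
    SystemParameters,
)

__all__ = [
    "RunConfig",
    "read_kinetics",
    "write_kinetics",
    "read_dose_response",
    "write_dose_response",
    "read_parameters",
    "write_parameters",
]

log = logging.getLogger("hemodecon")


@dataclass
class RunConfig:
    """Resolved run settings written alongside every output for
    reproducibility."""

    seed: int = 0
    lam: float = 0.1
    dead_cell_weight: float = 2.0
    max_generations: int = 30
    population_size: int = 300
    emax_upper_bound: float = 3.0
    dose_grid: tuple[float, ...] = (0.2, 1.0, 5.0, 25.0, 100.0, 500.0, 2500.0)
    rtol: float = 1e-8
    extras: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def read_kinetics(path) -> KineticDataset:
    """Read a tidy kinetic CSV (donor_id, day, readout, cells_per_ml)."""
    df = pd.read_csv(path)
    return KineticDataset(donors=df)


def write_kinetics(data: KineticDataset, path) -> None:
    data.donors.to_csv(path, index=False)


def read_dose_response(path) -> list[DoseResponseDataset]:
    """Read a tidy dose-response CSV (compound, dose_nM, readout,
    normalized_value); returns one dataset per compound."""
    df = pd.read_csv(path)
    req = {"compound", "dose_nM", "readout", "normalized_value"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"dose-response CSV missing columns: {sorted(missing)}")
    out = []
    for compound, grp in df.groupby("compound", sort=True):
        table = grp.pivot_table(
            index="dose_nM", columns="readout", values="normalized_value"
        )
        out.append(DoseResponseDataset(compound=str(compound), table=table))
    return out


def write_dose_response(data: DoseResponseDataset, path) -> None:
    long = data.table.reset_index().melt(
        id_vars="dose_nM", var_name="readout", value_name="normalized_value"
    )
    long.insert(0, "compound", data.compound)
    long.to_csv(path, index=False)


def write_parameters(params, path) -> None:
    """Write system and/or drug parameters as flat key-value JSON."""
    doc: dict[str, float | bool] = {}
    items = params if isinstance(params, (list, tuple)) else [params]
    for p in items:
        if isinstance(p, SystemParameters):
            for ct in CELL_TYPES:
                doc[f"kappa_{ct}"] = p.kappa[ct]
            for ct, v in sorted(p.rho.items()):
                doc[f"rho_{ct}"] = v
            for (a, b) in BRANCH_EDGES:
                doc[f"beta_{a}_{b}"] = p.beta[(a, b)]
            doc["delta"] = p.delta
            doc["k_quiescence"] = p.k_quiescence
        elif isinstance(p, DrugEffectParameters):
            for ct in CELL_TYPES:
                doc[f"emaxT_{ct}"] = p.emax_total[ct]
            for ct in CELL_TYPES:
                doc[f"logEC50_{ct}"] = p.log_ec50[ct]
            for ct in CELL_TYPES:  # derived, read-only echo
                doc[f"EC50_{ct}"] = math.exp(p.log_ec50[ct])
        else:
            raise TypeError(f"cannot serialize parameters of type {type(p)!r}")
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_parameters(path, emax_upper_bound: float = 3.0):
    """Read a flat key-value JSON parameter file.

    Returns a SystemParameters, a DrugEffectParameters, or a (system, drug)
    tuple depending on which key families are present.  Out-of-bounds values
    raise a ValueError listing every violation.
    """
    doc = json.loads(Path(path).read_text())
    has_system = any(k.startswith("kappa_") for k in doc)
    has_drug = any(k.startswith("emaxT_") for k in doc)
    if not has_system and not has_drug:
        raise ValueError(f"{path}: no recognizable parameter keys")

    results = []
    if has_system:
        sys = SystemParameters(
            kappa={ct: float(doc[f"kappa_{ct}"]) for ct in CELL_TYPES},
            rho={ct: float(doc[f"rho_{ct}"])
                 for ct in CELL_TYPES if f"rho_{ct}" in doc},
            beta={(a, b): float(doc[f"beta_{a}_{b}"]) for (a, b) in BRANCH_EDGES},
            delta=float(doc["delta"]),
            k_quiescence=float(doc.get("k_quiescence", 0.5)),
        )
        sys.validate()
        results.append(sys)
    if has_drug:
        drug = DrugEffectParameters(
            emax_total={ct: float(doc[f"emaxT_{ct}"]) for ct in CELL_TYPES},
            log_ec50={ct: float(doc[f"logEC50_{ct}"]) for ct in CELL_TYPES},
        )
        drug.validate(emax_upper_bound=emax_upper_bound)
        over = {ct: e for ct, e in drug.emax_total.items() if e > 2.0}
        if over:
            log.warning(
                "Emax_T above the conventional [0, 2] range (upper bound "
                "%.1f in force): %s", emax_upper_bound, over,
            )
        results.append(drug)
    return results[0] if len(results) == 1 else tuple(results)
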