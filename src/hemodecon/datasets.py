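"""Observed-data containers shared by calibration, synthesis, and I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import READOUTS

__all__ = ["KineticDataset", "DoseResponseDataset"]


@dataclass
class KineticDataset:
    """Drug-free kinetic count data across donors.

    ``donors`` is a tidy table (donor_id, day, readout, cells_per_ml);
    ``mean_table`` averages across donors (day x readout); ``day0_counts``
    are the measured day-0 means, used only to bound fitted initial
    conditions.
    """

    donors: pd.DataFrame
    mean_table: pd.DataFrame = None
    day0_counts: pd.Series = None

    def __post_init__(self) -> None:
        req = {"donor_id", "day", "readout", "cells_per_ml"}
        missing = req - set(self.donors.columns)
        if missing:
            raise ValueError(f"kinetic table missing columns: {sorted(missing)}")
        unknown = set(self.donors["readout"]) - set(READOUTS)
        if unknown:
            raise ValueError(f"unknown readouts in kinetic data: {sorted(unknown)}")
        if (self.donors["cells_per_ml"] < 0).any():
            raise ValueError("negative cell counts in kinetic data")
        if self.mean_table is None:
            self.mean_table = (
                self.donors.pivot_table(
                    index="day", columns="readout", values="cells_per_ml",
                    aggfunc="mean",
                )
                .reindex(columns=[r for r in READOUTS])
            )
        if self.day0_counts is None and 0 in self.mean_table.index:
            self.day0_counts = self.mean_table.loc[0]

    @property
    def days(self) -> tuple[float, ...]:
        return tuple(sorted(self.mean_table.index))

    def fitting_days(self) -> list[float]:
        """Days entering the objective (2-6; day 0 and any replating days
        are excluded)."""
        return [d for d in self.days if 2.0 <= d <= 6.0]


@dataclass
class DoseResponseDataset:
    """Vehicle-normalized day-6 dose response for one compound.

    ``table`` is dose_nM x 14 readouts of pooled normalized values
    (M_C^data); donor replicates are pooled by averaging upstream.
    """

    compound: str
    table: pd.DataFrame
    n_donors: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.table.columns) - set(READOUTS)
        if unknown:
            raise ValueError(
                f"unknown readouts in dose-response data: {sorted(unknown)}"
            )
        missing = set(READOUTS) - set(self.table.columns)
        if missing:
            raise ValueError(
                f"dose-response data missing readouts: {sorted(missing)}"
            )
        if (self.table.values < 0).any():
            raise ValueError("negative normalized values in dose-response data")
        self.table = self.table[list(READOUTS)].sort_index()
        self.table.index.name = "dose_nM"

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(float(d) for d in self.table.index)
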