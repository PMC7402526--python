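"""Traditional curve-level dose-response analysis: IC50s and percent
inhibition.

The IC50 here is the concentration halving an observed readout relative to
vehicle.  Because a readout reflects the cumulative loss along its lineage
(direct drug effect plus propagated loss of upstream progenitors), these
curve-level IC50s describe cumulative suppression — the quantity the
mechanistic model deconvolves into per-cell-type Emax/EC50 effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "InhibitionFit",
    "percent_inhibition",
    "fit_ic50",
    "inhibition_matrix",
]


@dataclass
class InhibitionFit:
    """One-parameter inhibition fit for a single readout."""

    readout: str
    ic50: float | None  # nM; None when undetermined
    residual: float = float("nan")

    @property
    def determined(self) -> bool:
        return self.ic50 is not None


def percent_inhibition(conc: float, ic50: float) -> float:
    """Percent inhibition 100 * conc / (conc + ic50), in [0, 100)."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if ic50 <= 0:
        raise ValueError("IC50 must be > 0")
    return 100.0 * conc / (conc + ic50)


def fit_ic50(curve: pd.Series | dict, readout: str = "") -> InhibitionFit:
    """Least-squares fit of value = 1 - conc/(conc + IC50) (Hill slope 1).

    ``curve`` maps dose (nM) to the normalized viable fraction.  The fit is
    flagged undetermined when the curve never falls below 0.5 within the
    tested range (the half-suppression point is not bracketed) or the
    optimizer fails; curves rising above baseline additionally raise a
    monotonicity warning.
    """
    s = pd.Series(curve).sort_index()
    s = s[s.index > 0]
    if len(s) < 4:
        raise ValueError("IC50 fitting needs at least 4 positive-dose points")
    doses = s.index.to_numpy(float)
    values = s.to_numpy(float)
    if values.max() > 1.0 + 1e-9 and values[-1] > values[0]:
        warnings.warn(
            f"readout {readout or '<unnamed>'}: response increases above "
            "baseline; the inhibition model cannot exceed 1",
            stacklevel=2,
        )
        return InhibitionFit(readout=readout, ic50=None)
    if values.min() > 0.5:
        return InhibitionFit(readout=readout, ic50=None)

    def resid(log_ic50):
        ic50 = np.exp(log_ic50[0])
        return 1.0 - doses / (doses + ic50) - values

    x0 = np.array([np.log(np.median(doses))])
    res = least_squares(resid, x0, bounds=([-20.0], [25.0]), method="trf")
    if not res.success:
        return InhibitionFit(readout=readout, ic50=None)
    return InhibitionFit(
        readout=readout,
        ic50=float(np.exp(res.x[0])),
        residual=float(2.0 * res.cost),
    )


def inhibition_matrix(fits, doses) -> pd.DataFrame:
    """Percent-inhibition table (dose x readout); undetermined readouts are
    reported as 0% suppression at every dose."""
    doses = [float(d) for d in doses]
    cols = {}
    for fit in fits:
        if fit.determined:
            cols[fit.readout] = [percent_inhibition(d, fit.ic50) for d in doses]
        else:
            cols[fit.readout] = [0.0] * len(doses)
    return pd.DataFrame(cols, index=pd.Index(doses, name="dose_nM"))
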