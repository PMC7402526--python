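"""Multi-lineage hematopoiesis model: cell types, topology, parameters, dynamics.

The model tracks 13 live hematopoietic cell types differentiating from
hematopoietic stem cells (HSC) over a 6-day in vitro CD34+ culture, plus a
quiescent neutrophil sub-pool and a cumulative dead-cell pool.  Cell division
consumes one parent and produces two daughters, each of which independently
renews (probability rho) or differentiates (1 - rho); this gives a net self
term (2*rho - 1)*kappa*[C] and a differentiation outflow 2*(1 - rho)*kappa*[C]
split across children by branching fractions beta.  Drug effects enter as an
Emax model per cell type: the anti-proliferative component min(1, Emax_T)
scales the basal division rate, and the excess max(0, Emax_T - 1) drives a
first-order cell-killing flux into the dead pool.

For a constant drug concentration the system is linear time-invariant, so the
dynamics are fully described by a 15x15 rate matrix (13 live types + quiescent
neutrophils + dead pool); see :func:`rate_matrix`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CELL_TYPES",
    "TERMINAL_TYPES",
    "RENEWING_TYPES",
    "READOUTS",
    "REPORTED_SPECIES",
    "KAPPA_MAX",
    "CellType",
    "LineageTopology",
    "SystemParameters",
    "DrugEffectParameters",
    "ModelState",
    "build_reference_topology",
    "hill_occupancy",
    "decompose_emax",
    "effective_division_rate",
    "killing_flux",
    "rate_matrix",
    "evaluate_rhs",
]

#: Canonical ordering of the 13 live cell-type readouts.
CELL_TYPES: tuple[str, ...] = (
    "HSC", "MPP", "GMP", "GranP", "Gran", "MonoP", "Mono",
    "Neut", "ErythI", "ErythII", "MK", "LymP", "B",
)

#: Most mature type of each lineage; the only types that die naturally.
TERMINAL_TYPES: frozenset[str] = frozenset({"ErythII", "MK", "Mono", "Neut", "B"})

#: Types carrying a renewal fraction rho.  LymP differentiates without
#: dividing and has no renewal parameter.
RENEWING_TYPES: frozenset[str] = frozenset(
    {"HSC", "MPP", "GMP", "GranP", "Gran", "MonoP", "ErythI"}
)

#: The 14 observable readouts of the assay (13 live + total dead cells).
READOUTS: tuple[str, ...] = CELL_TYPES + ("totalDeadCells",)

#: Reported population species: 13 live readouts plus the derived
#: totalViableCells sum and totalDeadCells.
REPORTED_SPECIES: tuple[str, ...] = CELL_TYPES + ("totalViableCells", "totalDeadCells")

#: Upper bound on basal proliferation rates (1/day); 4/ln(2) caps division at
#: four doublings per day.
KAPPA_MAX: float = 4.0 / math.log(2.0)

# state-vector layout: 13 live types, quiescent neutrophils, dead pool
_IDX = {ct: i for i, ct in enumerate(CELL_TYPES)}
IDX_NEUT_Q = 13
IDX_DEAD = 14
N_STATE = 15


@dataclass(frozen=True)
class CellType:
    """One of the 13 modeled hematopoietic cell types."""

    id: str
    is_terminal: bool
    has_renewal: bool


def cell_type_table() -> dict[str, CellType]:
    """Return the canonical table of the 13 cell types."""
    return {
        ct: CellType(ct, ct in TERMINAL_TYPES, ct in RENEWING_TYPES)
        for ct in CELL_TYPES
    }


@dataclass(frozen=True)
class LineageTopology:
    """Directed differentiation tree rooted at HSC.

    ``edges`` lists (parent, child) pairs; ``branch_points`` maps each parent
    with more than one child to its ordered children.
    """

    edges: tuple[tuple[str, str], ...]
    branch_points: dict[str, tuple[str, ...]]

    def children(self, parent: str) -> tuple[str, ...]:
        return tuple(c for p, c in self.edges if p == parent)

    def reachable_from(self, root: str = "HSC") -> set[str]:
        seen = {root}
        frontier = [root]
        while frontier:
            node = frontier.pop()
            for child in self.children(node):
                if child not in seen:
                    seen.add(child)
                    frontier.append(child)
        return seen


def build_reference_topology() -> LineageTopology:
    """Build the canonical lineage tree.

    HSC self-renew and feed MPP; MPP branch into the granulocyte/monocyte
    (via GMP), erythroid, megakaryocyte, and lymphoid lineages; GMP branch
    into granulocyte and monocyte progenitors.
    """
    edges = (
        ("HSC", "MPP"),
        ("MPP", "GMP"), ("MPP", "ErythI"), ("MPP", "MK"), ("MPP", "LymP"),
        ("GMP", "GranP"), ("GMP", "MonoP"),
        ("GranP", "Gran"),
        ("Gran", "Neut"),
        ("MonoP", "Mono"),
        ("ErythI", "ErythII"),
        ("LymP", "B"),
    )
    branch_points = {
        "MPP": ("GMP", "ErythI", "MK", "LymP"),
        "GMP": ("GranP", "MonoP"),
    }
    return LineageTopology(edges=edges, branch_points=branch_points)


#: Branch edges carrying a free branching fraction, in canonical order.
BRANCH_EDGES: tuple[tuple[str, str], ...] = (
    ("MPP", "GMP"), ("MPP", "ErythI"), ("MPP", "MK"), ("MPP", "LymP"),
    ("GMP", "GranP"), ("GMP", "MonoP"),
)


@dataclass
class SystemParameters:
    """Drug-free system parameters: 13 kappa + 7 rho + 6 beta + delta = 27 free.

    Parameters
    ----------
    kappa
        Basal proliferation rate per cell type (1/day), 13 entries, each in
        [0, 4/ln 2].
    rho
        Renewal fraction per renewing type (dimensionless), 7 entries;
        rho_HSC in [0.5, 1], others in [0, 0.5].
    beta
        Branching fraction per branch edge, 6 entries in [0.001, 1]; the
        fractions out of MPP and out of GMP each sum to one.
    delta
        Uniform natural death rate of terminal types (1/day) in [0, 2].
    k_quiescence
        Fixed active-to-quiescent neutrophil transfer rate (1/day); not a
        free parameter.
    lymp_doubling
        If True, LymP differentiates with division (outflow 2*kappa*[LymP]);
        default is division-free first-order conversion to B.
    """

    kappa: dict[str, float]
    rho: dict[str, float]
    beta: dict[tuple[str, str], float]
    delta: float
    k_quiescence: float = 0.5
    lymp_doubling: bool = False

    N_FREE = 27  # 13 kappa + 7 rho + 6 beta + 1 delta

    def validate(self, beta_tol: float = 1e-6) -> None:
        """Raise ValueError listing every bound violation."""
        errs: list[str] = []
        if set(self.kappa) != set(CELL_TYPES):
            errs.append("kappa must have exactly the 13 cell types")
        if set(self.rho) != RENEWING_TYPES:
            errs.append("rho must have exactly the 7 renewing types")
        if set(self.beta) != set(BRANCH_EDGES):
            errs.append("beta must have exactly the 6 branch edges")
        for ct, k in self.kappa.items():
            if not 0.0 <= k <= KAPPA_MAX + 1e-12:
                errs.append(f"kappa_{ct}={k:g} outside [0, {KAPPA_MAX:.4f}]")
        for ct, r in self.rho.items():
            lo, hi = (0.5, 1.0) if ct == "HSC" else (0.0, 0.5)
            if not lo <= r <= hi:
                errs.append(f"rho_{ct}={r:g} outside [{lo}, {hi}]")
        for (p, c), b in self.beta.items():
            if not 0.001 <= b <= 1.0:
                errs.append(f"beta_{p}_{c}={b:g} outside [0.001, 1]")
        for parent in ("MPP", "GMP"):
            s = sum(b for (p, _), b in self.beta.items() if p == parent)
            if abs(s - 1.0) > beta_tol:
                errs.append(f"beta out of {parent} sums to {s:g}, expected 1")
        if not 0.0 <= self.delta <= 2.0:
            errs.append(f"delta={self.delta:g} outside [0, 2]")
        if self.k_quiescence < 0.0:
            errs.append("k_quiescence must be >= 0")
        if errs:
            raise ValueError("invalid system parameters: " + "; ".join(errs))

    def copy(self, **changes) -> "SystemParameters":
        out = replace(self)
        out.kappa = dict(self.kappa)
        out.rho = dict(self.rho)
        out.beta = dict(self.beta)
        for k, v in changes.items():
            setattr(out, k, v)
        return out


@dataclass
class DrugEffectParameters:
    """Per-cell-type drug effect: 13 Emax_T + 13 logEC50 = 26 free parameters.

    ``emax_total`` below or equal to one is pure anti-proliferation; the
    excess above one is the cell-killing component.  EC50 is stored as its
    natural logarithm (EC50 in nM).
    """

    emax_total: dict[str, float]
    log_ec50: dict[str, float]

    N_FREE = 26

    LOG_EC50_BOUNDS = (-2.3, 8.5)

    @property
    def ec50(self) -> dict[str, float]:
        return {ct: math.exp(v) for ct, v in self.log_ec50.items()}

    def validate(self, emax_upper_bound: float = 3.0) -> None:
        errs: list[str] = []
        if set(self.emax_total) != set(CELL_TYPES):
            errs.append("emax_total must cover exactly the 13 cell types")
        if set(self.log_ec50) != set(CELL_TYPES):
            errs.append("log_ec50 must cover exactly the 13 cell types")
        for ct, e in self.emax_total.items():
            if not 0.0 <= e <= emax_upper_bound:
                errs.append(f"emaxT_{ct}={e:g} outside [0, {emax_upper_bound:g}]")
        lo, hi = self.LOG_EC50_BOUNDS
        for ct, v in self.log_ec50.items():
            if not lo <= v <= hi:
                errs.append(f"logEC50_{ct}={v:g} outside [{lo}, {hi}]")
        if errs:
            raise ValueError("invalid drug parameters: " + "; ".join(errs))

    @classmethod
    def inert(cls) -> "DrugEffectParameters":
        """A drug with no effect on any cell type."""
        return cls(
            emax_total={ct: 0.0 for ct in CELL_TYPES},
            log_ec50={ct: math.log(100.0) for ct in CELL_TYPES},
        )


@dataclass
class ModelState:
    """Concentrations (cells/mL) of every compartment at one instant.

    The reported neutrophil readout is active + quiescent; drug concentration
    is a constant forcing input, not a dynamic state.
    """

    counts: dict[str, float]
    quiescent_neutrophils: float = 0.0
    total_dead: float = 0.0
    drug_conc: float = 0.0

    def to_vector(self) -> np.ndarray:
        x = np.empty(N_STATE)
        for ct, i in _IDX.items():
            x[i] = self.counts[ct]
        x[IDX_NEUT_Q] = self.quiescent_neutrophils
        x[IDX_DEAD] = self.total_dead
        return x

    @classmethod
    def from_vector(cls, x: np.ndarray, drug_conc: float = 0.0) -> "ModelState":
        return cls(
            counts={ct: float(x[i]) for ct, i in _IDX.items()},
            quiescent_neutrophils=float(x[IDX_NEUT_Q]),
            total_dead=float(x[IDX_DEAD]),
            drug_conc=drug_conc,
        )

    def readouts(self) -> dict[str, float]:
        """The 14 observable readouts; Neut includes the quiescent pool."""
        out = dict(self.counts)
        out["Neut"] = out["Neut"] + self.quiescent_neutrophils
        out["totalDeadCells"] = self.total_dead
        return out

    def total_viable(self) -> float:
        return sum(self.readouts()[ct] for ct in CELL_TYPES)

    def validate(self) -> None:
        bad = [ct for ct, v in self.counts.items() if v < 0]
        if bad or self.quiescent_neutrophils < 0 or self.total_dead < 0:
            raise ValueError(f"negative concentrations in state: {bad}")
        if self.drug_conc < 0:
            raise ValueError("drug concentration must be >= 0")


def hill_occupancy(conc: float, ec50: float) -> float:
    """Fractional receptor occupancy conc / (ec50 + conc) in [0, 1)."""
    if conc < 0:
        raise ValueError("drug concentration must be >= 0")
    if ec50 <= 0:
        raise ValueError("EC50 must be > 0")
    return conc / (ec50 + conc)


def decompose_emax(emax_total: float) -> tuple[float, float]:
    """Split a total Emax into anti-proliferative and cell-killing components.

    Emax_AP = min(1, Emax_T) saturates the proliferation block; the excess
    Emax_CK = max(0, Emax_T - 1) drives cell killing.
    """
    if emax_total < 0:
        raise ValueError("Emax_T must be >= 0")
    return min(1.0, emax_total), max(0.0, emax_total - 1.0)


def effective_division_rate(
    kappa0: float, emax_total: float, conc: float, ec50: float
) -> float:
    """Drug-attenuated division rate kappa0 * (1 - Emax_AP * occupancy)."""
    if kappa0 < 0:
        raise ValueError("kappa0 must be >= 0")
    emax_ap, _ = decompose_emax(emax_total)
    return kappa0 * (1.0 - emax_ap * hill_occupancy(conc, ec50))


def killing_flux(emax_total: float, conc: float, ec50: float, count: float) -> float:
    """Cell-killing flux Emax_CK * occupancy * [C] (cells/mL/day).

    Zero whenever Emax_T <= 1: anti-proliferation saturates before killing
    begins.
    """
    if count < 0:
        raise ValueError("cell count must be >= 0")
    _, emax_ck = decompose_emax(emax_total)
    if emax_ck == 0.0:
        return 0.0
    return emax_ck * hill_occupancy(conc, ec50) * count


_REFERENCE_TOPOLOGY: LineageTopology | None = None


def _topology() -> LineageTopology:
    global _REFERENCE_TOPOLOGY
    if _REFERENCE_TOPOLOGY is None:
        _REFERENCE_TOPOLOGY = build_reference_topology()
    return _REFERENCE_TOPOLOGY


def rate_matrix(
    sys: SystemParameters,
    drug: DrugEffectParameters | None = None,
    conc: float = 0.0,
) -> np.ndarray:
    """Assemble the 15x15 rate matrix A with dx/dt = A x.

    Rows/columns follow CELL_TYPES order, then the quiescent neutrophil pool,
    then the dead pool.  The quiescent pool neither divides nor differentiates
    and is not subject to the natural death rate; drug killing removes it at
    the neutrophil killing rate.
    """
    topo = _topology()
    A = np.zeros((N_STATE, N_STATE))

    def kappa_eff(ct: str) -> float:
        k0 = sys.kappa[ct]
        if drug is None or conc == 0.0:
            return k0
        return effective_division_rate(
            k0, drug.emax_total[ct], conc, math.exp(drug.log_ec50[ct])
        )

    def kill_rate(ct: str) -> float:
        if drug is None or conc == 0.0:
            return 0.0
        _, emax_ck = decompose_emax(drug.emax_total[ct])
        if emax_ck == 0.0:
            return 0.0
        return emax_ck * hill_occupancy(conc, math.exp(drug.log_ec50[ct]))

    for ct in CELL_TYPES:
        i = _IDX[ct]
        ke = kappa_eff(ct)
        if ct in RENEWING_TYPES:
            # division: net self gain (2*rho-1)*kappa, outflow 2*(1-rho)*kappa
            r = sys.rho[ct]
            A[i, i] += (2.0 * r - 1.0) * ke
            outflow = 2.0 * (1.0 - r) * ke
            children = topo.children(ct)
            for child in children:
                b = sys.beta.get((ct, child), 1.0)
                A[_IDX[child], i] += b * outflow
        elif ct == "LymP":
            if sys.lymp_doubling:
                A[i, i] += -ke
                A[_IDX["B"], i] += 2.0 * ke
            else:
                # division-free first-order conversion to B
                A[i, i] += -ke
                A[_IDX["B"], i] += ke
        else:  # terminal types: net self-proliferation, natural death
            A[i, i] += ke - sys.delta
            A[IDX_DEAD, i] += sys.delta
        # drug killing removes cells from every compartment into the dead pool
        kr = kill_rate(ct)
        if kr > 0.0:
            A[i, i] -= kr
            A[IDX_DEAD, i] += kr

    # neutrophil quiescence: transfer from active pool; quiescent pool is
    # inert apart from drug killing
    i_neut = _IDX["Neut"]
    A[i_neut, i_neut] -= sys.k_quiescence
    A[IDX_NEUT_Q, i_neut] += sys.k_quiescence
    kr_q = kill_rate("Neut")
    if kr_q > 0.0:
        A[IDX_NEUT_Q, IDX_NEUT_Q] -= kr_q
        A[IDX_DEAD, IDX_NEUT_Q] += kr_q
    return A


def evaluate_rhs(
    state: ModelState,
    sys: SystemParameters,
    drug: DrugEffectParameters | None = None,
) -> ModelState:
    """Time derivative of the model state (cells/mL/day per compartment)."""
    state.validate()
    sys.validate()
    if drug is not None:
        drug.validate(emax_upper_bound=float("inf"))
    A = rate_matrix(sys, drug, state.drug_conc)
    dx = A @ state.to_vector()
    out = ModelState.from_vector(dx, drug_conc=0.0)
    return out
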