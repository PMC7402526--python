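"""Cross-compound comparison: parameter matrices and PCA.

Compounds are embedded in a 13-dimensional space of per-cell-type drug
parameters (Emax_T, logEC50, or curve-level logIC50) and compared by
principal component analysis.  Emax_T and logEC50 values share a common
scale across cell types, so the PCA is mean-centered but not standardized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .model import CELL_TYPES, DrugEffectParameters

__all__ = ["CompoundMatrix", "PcaResult", "assemble_parameter_matrix", "run_pca"]

VALUE_KINDS = ("emaxT", "logEC50", "logIC50")


@dataclass
class CompoundMatrix:
    """Compound x cell-type value matrix with provenance metadata."""

    values: pd.DataFrame  # rows: compounds (sorted); columns: 13 cell types
    value_kind: str
    class_labels: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


@dataclass
class PcaResult:
    """Unscaled, mean-centered PCA of a compound matrix."""

    scores: pd.DataFrame        # compound x component
    loadings: pd.DataFrame      # variable x component (orthonormal columns)
    variance_pct: pd.Series     # percent variance per component (sums to 100)
    correlations: pd.DataFrame  # variable-to-score correlations
    mean: pd.Series


def assemble_parameter_matrix(
    fits: dict,
    value_kind: str,
    class_labels: dict[str, str] | None = None,
    undetermined_policy: str = "error",
    impute_value: float | None = None,
) -> CompoundMatrix:
    """Build the compound x cell-type matrix for one value kind.

    ``fits`` maps compound name to a ``DrugEffectParameters`` (for emaxT /
    logEC50) or to a mapping cell type -> IC50 in nM with ``None`` marking
    undetermined entries (for logIC50).  Undetermined IC50s require an
    explicit policy: ``"error"`` (default), ``"impute"`` with
    ``impute_value`` (nM), or ``"drop_compound"``; the choice is recorded in
    the metadata.  Rows are sorted by compound name, so assembly is
    invariant to input ordering.
    """
    if value_kind not in VALUE_KINDS:
        raise ValueError(f"value_kind must be one of {VALUE_KINDS}")
    rows = {}
    dropped = []
    for compound in sorted(fits):
        entry = fits[compound]
        if value_kind in ("emaxT", "logEC50"):
            if not isinstance(entry, DrugEffectParameters):
                raise TypeError(
                    f"{compound}: expected DrugEffectParameters for "
                    f"value_kind={value_kind!r}"
                )
            src = entry.emax_total if value_kind == "emaxT" else entry.log_ec50
            missing = [ct for ct in CELL_TYPES if ct not in src]
            if missing:
                raise ValueError(f"{compound}: missing cell types {missing}")
            rows[compound] = [float(src[ct]) for ct in CELL_TYPES]
        else:
            missing = [ct for ct in CELL_TYPES if ct not in entry]
            if missing:
                raise ValueError(f"{compound}: missing cell types {missing}")
            vals = []
            undet = [ct for ct in CELL_TYPES if entry[ct] is None]
            if undet and undetermined_policy == "error":
                raise ValueError(
                    f"{compound}: undetermined IC50 for {undet}; choose an "
                    "explicit undetermined_policy"
                )
            if undet and undetermined_policy == "drop_compound":
                dropped.append(compound)
                continue
            for ct in CELL_TYPES:
                v = entry[ct]
                if v is None:
                    if undetermined_policy != "impute" or impute_value is None:
                        raise ValueError(
                            f"{compound}: policy {undetermined_policy!r} "
                            "requires impute_value"
                        )
                    v = impute_value
                vals.append(float(np.log(v)))
            rows[compound] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CELL_TYPES))
    return CompoundMatrix(
        values=df,
        value_kind=value_kind,
        class_labels=class_labels or {},
        metadata={
            "undetermined_policy": undetermined_policy,
            "impute_value": impute_value,
            "dropped_compounds": dropped,
        },
    )


def run_pca(
    matrix: CompoundMatrix,
    standardize: bool = False,
    label_threshold: float = 0.1,
) -> PcaResult:
    """Column-mean-centered PCA via singular value decomposition.

    No column scaling by default (the values share a scale); signs are fixed
    so each loading vector's largest-magnitude entry is positive, making the
    decomposition deterministic.  ``correlations`` annotates each variable
    with its correlation to every score vector (the loadings-plot labeling
    convention, threshold ``label_threshold``).
    """
    X = matrix.values
    if len(X) < 2:
        raise ValueError("PCA needs at least 2 compounds")
    mean = X.mean(axis=0)
    Xc = X - mean
    if standardize:
        sd = Xc.std(axis=0, ddof=1).replace(0.0, 1.0)
        Xc = Xc / sd
    if np.allclose(Xc.values, 0.0):
        warnings.warn("zero-variance matrix: no principal components")
        empty = pd.DataFrame(index=X.index)
        return PcaResult(
            scores=empty, loadings=pd.DataFrame(index=X.columns),
            variance_pct=pd.Series(dtype=float),
            correlations=pd.DataFrame(index=X.columns), mean=mean,
        )
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(Xc.values)
    loadings = pca.components_.T  # variable x component
    # drop numerically null components beyond the matrix rank
    keep = pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]
    scores, loadings = scores[:, keep], loadings[:, keep]
    var = pca.explained_variance_[keep]
    # sign convention: largest-|loading| entry positive per component
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    scores_df = pd.DataFrame(scores, index=X.index, columns=comp)
    loadings_df = pd.DataFrame(loadings, index=X.columns, columns=comp)
    variance_pct = pd.Series(100.0 * var / var.sum(), index=comp)
    corr = pd.DataFrame(
        {c: X.apply(lambda col: _safe_corr(col.values, scores_df[c].values))
         for c in comp}
    )
    corr.attrs["label_threshold"] = label_threshold
    return PcaResult(scores=scores_df, loadings=loadings_df,
                     variance_pct=variance_pct, correlations=corr, mean=mean)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
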