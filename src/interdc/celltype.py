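"""Reference-free cell-type correction via surrogate proportion variables.

Bulk expression mixes cell-intrinsic signal with cell-composition effects.
To expose the former, a per-sample surrogate proportion variable (SPV) is
extracted for each major cell type as the leading right singular vector of
that type's (row-standardized) marker-gene submatrix, after discarding
markers that differ between the disease and control groups (a one-way
F-test; such markers would leak group signal into the composition scores).
Expression is then residualized on all SPVs, gene by gene, so downstream
differential-correlation results are not driven by composition shifts.

SPVs are relative scores, not absolute cell fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import RegionExpression, ValidationError
from .preprocess import CovariateResidualizer

logger = logging.getLogger(__name__)


@dataclass
class MarkerSet:
    """Marker genes declared for one cell type."""

    cell_type: str
    gene_ids: list[str]

    def present_in(self, genes: set[str]) -> "MarkerSet":
        kept = [g for g in self.gene_ids if g in genes]
        dropped = len(self.gene_ids) - len(kept)
        if dropped:
            logger.warning(
                "cell type %s: %d marker(s) absent from the expression matrix",
                self.cell_type,
                dropped,
            )
        return MarkerSet(self.cell_type, kept)


@dataclass
class SPVModel:
    """Fitted surrogate proportion variables for one region.

    ``spvs`` is a cell-type x sample DataFrame; each row has unit Euclidean
    norm and is oriented so its mean correlation with the robust markers of
    its cell type is positive.
    """

    spvs: pd.DataFrame
    robust_markers: dict[str, list[str]]
    variance_explained: dict[str, float]


def validate_marker_sets(marker_sets: list[MarkerSet]) -> None:
    seen: dict[str, str] = {}
    for ms in marker_sets:
        for g in ms.gene_ids:
            if g in seen and seen[g] != ms.cell_type:
                raise ValidationError(
                    f"marker '{g}' assigned to both {seen[g]} and {ms.cell_type}"
                )
            seen[g] = ms.cell_type


def filter_robust_markers(
    expr: pd.DataFrame,
    markers: MarkerSet,
    groups: np.ndarray,
    alpha: float = 0.05,
) -> list[str]:
    """Markers not differentially expressed between groups (F-test p >= alpha).

    ``expr`` is genes x samples; ``groups`` is a per-sample label vector with
    exactly two levels. Markers whose one-way F-test p-value falls below
    ``alpha`` are considered contaminated by the group contrast and dropped.
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"need exactly two groups, got {list(levels)}")
    present = markers.present_in(set(expr.index))
    if not present.gene_ids:
        raise ValidationError(
            f"no markers of cell type {markers.cell_type} found in the matrix; "
            "supply a larger marker set"
        )
    sub = expr.loc[present.gene_ids].to_numpy(float)
    a = sub[:, groups == levels[0]]
    b = sub[:, groups == levels[1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.f_oneway(a, b, axis=1)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance markers cannot show a group effect
    kept = [g for g, pv in zip(present.gene_ids, p) if pv >= alpha]
    if not kept:
        raise ValidationError(
            f"all markers of cell type {markers.cell_type} are group-associated; "
            "supply a larger marker set"
        )
    return kept


def _leading_spv(sub: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading right singular vector of a row-standardized matrix."""
    sd = sub.std(axis=1, ddof=0)
    keep = sd > 0
    z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    spv = vt[0]
    var_exp = float(s[0] ** 2 / np.sum(s**2))
    # orient: mean correlation between the SPV and its marker rows positive
    corr = z @ spv / (np.linalg.norm(spv) * np.linalg.norm(z, axis=1))
    if corr.mean() < 0:
        spv = -spv
    return spv / np.linalg.norm(spv), var_exp


def estimate_spvs(
    expr: pd.DataFrame,
    marker_sets: list[MarkerSet],
    groups: np.ndarray,
    alpha: float = 0.05,
) -> SPVModel:
    """One SPV per cell type from the robust-marker submatrix SVD."""
    validate_marker_sets(marker_sets)
    spvs, robust, var_exp = {}, {}, {}
    for ms in marker_sets:
        kept = filter_robust_markers(expr, ms, groups, alpha=alpha)
        sub = expr.loc[kept].to_numpy(float)
        nz = (sub.std(axis=1) > 0).sum()
        if nz < 3:
            raise ValidationError(
                f"cell type {ms.cell_type}: fewer than 3 usable robust markers"
            )
        spv, ve = _leading_spv(sub)
        spvs[ms.cell_type] = spv
        robust[ms.cell_type] = kept
        var_exp[ms.cell_type] = ve
    return SPVModel(
        spvs=pd.DataFrame(spvs, index=expr.columns).T,
        robust_markers=robust,
        variance_explained=var_exp,
    )


def correct_cell_types(expr: pd.DataFrame, spv_model: SPVModel | None) -> pd.DataFrame:
    """OLS-residualize each gene on all SPVs (plus intercept), mean preserved."""
    if spv_model is None or spv_model.spvs.shape[0] == 0:
        return expr.copy()
    spvs = spv_model.spvs
    if list(spvs.columns) != list(expr.columns):
        if set(spvs.columns) != set(expr.columns):
            raise ValidationError("SPVs are not defined for all samples of the matrix")
        spvs = spvs[expr.columns]
    X = spvs.to_numpy(float).T  # samples x cell types
    X = X - X.mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        keep = sorted(piv[:rank])
        dropped = [spvs.index[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping collinear SPV(s): {dropped}", UserWarning)
        X = X[:, keep]
    Y = expr.to_numpy(float).T
    beta, *_ = np.linalg.lstsq(X, Y - Y.mean(axis=0), rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid.T, index=expr.index, columns=expr.columns)


def select_marker_model(
    expr: pd.DataFrame,
    ranked_markers: dict[str, list[str]],
    candidate_sizes: list[int],
    truth_proportions: pd.Series,
    groups: np.ndarray,
    target_type: str,
    alpha: float = 0.05,
) -> int:
    """Pick the per-type marker count whose SPV best tracks known proportions.

    ``ranked_markers`` orders each cell type's markers best-first; for each
    candidate size the top-k markers per type build one SPV model, and the
    Spearman correlation between the ``target_type`` SPV and
    ``truth_proportions`` (aligned on samples) is scored. Ties break toward
    the smaller size.
    """
    truth = truth_proportions.loc[expr.columns].to_numpy(float)
    best_size, best_score = None, -np.inf
    for size in sorted(candidate_sizes):
        sets = [MarkerSet(ct, gl[:size]) for ct, gl in ranked_markers.items()]
        try:
            model = estimate_spvs(expr, sets, groups, alpha=alpha)
        except ValidationError:
            continue
        rho = stats.spearmanr(model.spvs.loc[target_type].to_numpy(), truth).statistic
        score = abs(float(rho))
        if score > best_score + 1e-12:  # strict improvement: ties keep smaller size
            best_score, best_size = score, size
    if best_size is None:
        raise ValidationError("no candidate marker size produced a valid SPV model")
    return best_size


class CellTypeCorrector(BaseEstimator, TransformerMixin):
    """scikit-learn-style transformer: estimate SPVs, then residualize.

    Works on samples x genes frames (sklearn orientation). ``fit`` requires
    the per-sample group labels as ``y`` for the robust-marker filter.

    Attributes
    ----------
    spv_model_ : SPVModel
        Fitted surrogate proportion variables.
    """

    def __init__(self, marker_sets: list[MarkerSet] | None = None, alpha: float = 0.05):
        self.marker_sets = marker_sets
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            raise ValidationError("group labels are required to fit the corrector")
        self.spv_model_ = estimate_spvs(
            X.T, self.marker_sets or [], np.asarray(y), alpha=self.alpha
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return correct_cell_types(X.T, self.spv_model_).T


def correct_region(
    region: RegionExpression, marker_sets: list[MarkerSet], groups: np.ndarray, alpha: float = 0.05
) -> tuple[RegionExpression, SPVModel]:
    """Fit one SPV model for a region and return the corrected expression."""
    model = estimate_spvs(region.expr, marker_sets, groups, alpha=alpha)
    corrected = correct_cell_types(region.expr, model)
    return (
        RegionExpression(region.region_id, corrected, region.sample_meta),
        model,
    )
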