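"""Group assignment, paired-sample selection and linear covariate adjustment.

The disease/control split follows the CERAD neuropathological score: 1 is
normal (CTL), 2 is definite AD, while probable (3) and possible (4) AD are
excluded from analysis. Two regions are analysed at a time, restricted to the
individuals profiled in both; a generic per-gene ordinary-least-squares
residualizer removes known technical/demographic covariates while preserving
each gene's mean.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    AD,
    CTL,
    EXCLUDED,
    VALID_CERAD,
    PairedDataset,
    RegionExpression,
    ValidationError,
)

logger = logging.getLogger(__name__)


def assign_groups(sample_meta: pd.DataFrame) -> pd.Series:
    """Map each individual to CTL / AD / EXCLUDED from its CERAD score.

    CERAD 1 -> CTL, 2 -> AD, 3 or 4 -> EXCLUDED. Any other value raises.
    If an individual appears in several samples, its CERAD must be consistent.
    """
    if "CERAD" not in sample_meta.columns or "individual_id" not in sample_meta.columns:
        raise ValidationError("sample_meta needs 'individual_id' and 'CERAD' columns")
    cerad = pd.to_numeric(sample_meta["CERAD"], errors="coerce")
    bad = sample_meta.index[~cerad.isin(list(VALID_CERAD))]
    if len(bad):
        raise ValidationError(
            f"CERAD outside {{1,2,3,4}} for samples: {list(bad[:5])}"
        )
    per_ind = pd.DataFrame(
        {"individual_id": sample_meta["individual_id"].to_numpy(), "CERAD": cerad.to_numpy()}
    )
    consistency = per_ind.groupby("individual_id")["CERAD"].nunique()
    inconsistent = consistency[consistency > 1].index.tolist()
    if inconsistent:
        raise ValidationError(f"inconsistent CERAD per individual: {inconsistent[:5]}")
    mapping = {1: CTL, 2: AD, 3: EXCLUDED, 4: EXCLUDED}
    out = per_ind.drop_duplicates("individual_id").set_index("individual_id")["CERAD"]
    return out.map(mapping).rename("group")


def _dedupe_samples(region: RegionExpression) -> RegionExpression:
    """Keep the first sample (by sample id) per individual, warning on drops."""
    meta = region.sample_meta.loc[region.sample_ids]
    order = meta.sort_index().drop_duplicates("individual_id", keep="first")
    keep = [s for s in region.sample_ids if s in set(order.index)]
    dropped = len(region.sample_ids) - len(keep)
    if dropped:
        logger.warning(
            "%s: dropped %d duplicate sample(s); kept first sample id per individual",
            region.region_id,
            dropped,
        )
    return region.subset_samples(keep)


def pair_regions(
    expr_a: RegionExpression,
    expr_b: RegionExpression,
    min_group_size: int = 10,
) -> PairedDataset:
    """Align two regions on shared CTL/AD individuals.

    Only individuals profiled in both regions and assigned to CTL or AD are
    retained; columns on both sides are reordered to a common individual
    order. Raises if either group falls below ``min_group_size``.
    """
    expr_a = _dedupe_samples(expr_a)
    expr_b = _dedupe_samples(expr_b)
    meta_all = pd.concat(
        [expr_a.sample_meta.loc[expr_a.sample_ids], expr_b.sample_meta.loc[expr_b.sample_ids]]
    )
    groups = assign_groups(meta_all)

    ind_a = {
        expr_a.sample_meta.loc[s, "individual_id"]: s for s in expr_a.sample_ids
    }
    ind_b = {
        expr_b.sample_meta.loc[s, "individual_id"]: s for s in expr_b.sample_ids
    }
    shared = sorted(
        i for i in set(ind_a) & set(ind_b) if groups.get(i) in (CTL, AD)
    )
    for grp in (CTL, AD):
        size = sum(groups[i] == grp for i in shared)
        if size < min_group_size:
            raise ValidationError(
                f"shared {grp} group has {size} individuals, below minimum {min_group_size}"
            )
    samples_a = [ind_a[i] for i in shared]
    samples_b = [ind_b[i] for i in shared]
    return PairedDataset(
        br1=expr_a.subset_samples(samples_a),
        br2=expr_b.subset_samples(samples_b),
        individuals=shared,
        groups=groups.loc[shared],
    )


class CovariateResidualizer(BaseEstimator, TransformerMixin):
    """Per-gene OLS residualization on sample covariates, mean preserved.

    Follows the scikit-learn transformer protocol with samples as rows and
    genes as columns. Categorical covariates are one-hot encoded with the
    reference level dropped; missing continuous values are imputed with the
    covariate mean (categoricals with the mode); design columns are centered
    so each gene's mean survives the adjustment. Collinear design columns are
    dropped with a warning.

    Attributes
    ----------
    design_ : ndarray of shape (n_samples, n_kept_columns)
        Centered design matrix used for the fit.
    design_columns_ : list of str
        Names of the retained design columns.
    """

    def __init__(self, covariates: pd.DataFrame | None = None, covariate_names=None):
        self.covariates = covariates
        self.covariate_names = covariate_names

    def _build_design(self, n_samples: int) -> np.ndarray:
        cov = self.covariates
        names = self.covariate_names
        if cov is None or (names is not None and len(names) == 0):
            self.design_ = np.empty((n_samples, 0))
            self.design_columns_ = []
            return self.design_
        if names is not None:
            missing = [c for c in names if c not in cov.columns]
            if missing:
                raise ValidationError(f"covariates not in metadata: {missing}")
            cov = cov[list(names)]
        blocks, colnames = [], []
        for name in cov.columns:
            col = cov[name]
            if pd.api.types.is_numeric_dtype(col):
                vals = pd.to_numeric(col, errors="coerce").astype(float)
                vals = vals.fillna(vals.mean())
                blocks.append(vals.to_numpy()[:, None])
                colnames.append(name)
            else:
                col = col.astype("object")
                if col.isna().any():
                    col = col.fillna(col.mode().iloc[0])
                levels = sorted(col.unique())
                if len(levels) < 2:
                    raise ValidationError(
                        f"categorical covariate '{name}' has <2 levels present"
                    )
                for lev in levels[1:]:  # reference level dropped
                    blocks.append((col == lev).to_numpy(float)[:, None])
                    colnames.append(f"{name}[{lev}]")
        X = np.hstack(blocks)
        X = X - X.mean(axis=0, keepdims=True)
        # drop collinear columns via pivoted QR
        if X.shape[1]:
            rank = np.linalg.matrix_rank(X)
            if rank < X.shape[1]:
                from scipy.linalg import qr

                _, _, piv = qr(X, mode="economic", pivoting=True)
                keep = sorted(piv[:rank])
                dropped = [colnames[j] for j in range(X.shape[1]) if j not in keep]
                warnings.warn(
                    f"dropping collinear covariate column(s): {dropped}", UserWarning
                )
                logger.warning("dropping collinear covariate column(s): %s", dropped)
                X = X[:, keep]
                colnames = [colnames[j] for j in keep]
        self.design_ = X
        self.design_columns_ = colnames
        return X

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self._build_design(X.shape[0])
        if self.design_.shape[1]:
            self.coef_, *_ = np.linalg.lstsq(self.design_, X - X.mean(axis=0), rcond=None)
        else:
            self.coef_ = np.empty((0, X.shape[1]))
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.design_.shape[1] == 0:
            return X.copy()
        return X - self.design_ @ self.coef_

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


def residualize_covariates(
    region: RegionExpression, covariate_names: list[str]
) -> RegionExpression:
    """Linearly adjust a region's expression for the named covariates.

    Thin wrapper over :class:`CovariateResidualizer` that keeps the
    genes x samples layout and the metadata untouched.
    """
    if not covariate_names:
        return RegionExpression(
            region_id=region.region_id,
            expr=region.expr.copy(),
            sample_meta=region.sample_meta,
        )
    cov = region.sample_meta.loc[region.sample_ids]
    rez = CovariateResidualizer(covariates=cov, covariate_names=covariate_names)
    adjusted = rez.fit_transform(region.expr.to_numpy(float).T).T
    return RegionExpression(
        region_id=region.region_id,
        expr=pd.DataFrame(adjusted, index=region.expr.index, columns=region.expr.columns),
        sample_meta=region.sample_meta,
    )
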