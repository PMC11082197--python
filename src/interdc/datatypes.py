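"""Core data containers for paired two-region expression analysis.

Expression matrices are pandas DataFrames with genes as rows and samples as
columns, on a continuous (log-like, already normalized) scale. Sample metadata
is a DataFrame indexed by sample id with at least ``individual_id`` and
``CERAD`` columns; any further columns are treated as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CERAD = {1, 2, 3, 4}

CTL = "CTL"
AD = "AD"
EXCLUDED = "EXCLUDED"


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class RegionExpression:
    """One region's gene x sample expression matrix plus sample metadata.

    Parameters
    ----------
    region_id:
        Label of the brain region (e.g. ``"BR1"``, ``"PHG"``).
    expr:
        Genes x samples DataFrame of continuous expression values.
    sample_meta:
        Per-sample metadata indexed by sample id, with columns
        ``individual_id``, ``CERAD`` and optional covariates. Missing
        covariate values are allowed (imputed downstream); missing
        expression values are not.
    """

    region_id: str
    expr: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.expr.index.duplicated().any():
            dups = self.expr.index[self.expr.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in {self.region_id}: {dups[:5]}")
        if self.expr.columns.duplicated().any():
            raise ValidationError(f"duplicate sample ids in {self.region_id}")
        if np.isnan(self.expr.to_numpy(dtype=float)).any():
            raise ValidationError(f"missing expression values in {self.region_id}")
        missing = set(self.expr.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(
                f"samples without metadata in {self.region_id}: {sorted(missing)[:5]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expr.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expr.columns)

    def subset_samples(self, sample_ids: list[str]) -> "RegionExpression":
        return RegionExpression(
            region_id=self.region_id,
            expr=self.expr.loc[:, sample_ids],
            sample_meta=self.sample_meta.loc[sample_ids],
        )


@dataclass
class PairedDataset:
    """Two regions aligned on shared individuals, with CTL/AD group labels.

    ``br1.expr`` and ``br2.expr`` have the same number of columns; column *j*
    on both sides belongs to ``individuals[j]``. Only individuals with
    CERAD in {1, 2} (CTL / definite AD) are retained.
    """

    br1: RegionExpression
    br2: RegionExpression
    individuals: list[str]
    groups: pd.Series  # individual_id -> "CTL" | "AD"
    missing_individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.individuals)
        if self.br1.expr.shape[1] != n or self.br2.expr.shape[1] != n:
            raise ValidationError("paired sides must cover the same individuals")
        bad = set(self.groups.loc[self.individuals]) - {CTL, AD}
        if bad:
            raise ValidationError(f"retained individuals with group outside CTL/AD: {bad}")

    def group_mask(self, group: str) -> np.ndarray:
        labels = self.groups.loc[self.individuals].to_numpy()
        return labels == group

    def group_size(self, group: str) -> int:
        return int(self.group_mask(group).sum())

    def expr_by_group(self, side: int, group: str) -> pd.DataFrame:
        """Expression of one side (1 or 2) restricted to one group."""
        region = self.br1 if side == 1 else self.br2
        mask = self.group_mask(group)
        return region.expr.loc[:, np.asarray(region.expr.columns)[mask]]
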