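"""Hand-built tiny cohorts for controlled tests (importable helpers)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from interdc.datatypes import PairedDataset, RegionExpression


def make_region(mat: np.ndarray, region_id: str, cerad: np.ndarray,
                gene_prefix: str = "G", individuals=None, **covariates) -> RegionExpression:
    """Wrap a genes x samples array into a RegionExpression."""
    n_genes, n_samples = mat.shape
    if individuals is None:
        individuals = [f"I{i:03d}" for i in range(n_samples)]
    samples = [f"{ind}_{region_id}" for ind in individuals]
    meta = pd.DataFrame(
        {"individual_id": individuals, "CERAD": cerad, **covariates},
        index=pd.Index(samples, name="sample_id"),
    )
    genes = [f"{gene_prefix}{i:03d}" for i in range(n_genes)]
    return RegionExpression(region_id, pd.DataFrame(mat, index=genes, columns=samples), meta)


def make_paired(mat1: np.ndarray, mat2: np.ndarray, n_ctl: int) -> PairedDataset:
    """Two genes x samples arrays over the same individuals; first n_ctl are CTL."""
    n = mat1.shape[1]
    cerad = np.array([1] * n_ctl + [2] * (n - n_ctl))
    individuals = [f"I{i:03d}" for i in range(n)]
    br1 = make_region(mat1, "BR1", cerad, gene_prefix="A", individuals=individuals)
    br2 = make_region(mat2, "BR2", cerad, gene_prefix="B", individuals=individuals)
    groups = pd.Series(
        ["CTL"] * n_ctl + ["AD"] * (n - n_ctl), index=individuals, name="group"
    )
    return PairedDataset(br1=br1, br2=br2, individuals=individuals, groups=groups)
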