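"""Over-representation analysis of module gene sets with an empirical FDR.

Each passing bipartite module contributes two query sets (one per region
side). Enrichment against a gene-set collection uses the upper-tail
hypergeometric test — with background size N, K background genes in the
set, a query of n genes and an overlap of k, p = P[X >= k] for
X ~ Hypergeom(N, K, n) — followed by BH correction across all
(module-side x set) tests within a collection. The background for a side is
that region's correlated gene list (union of the two groups). Robustness is
quantified by an empirical FDR: the mean, over structure-preserving random
modules, of the random significant-call count divided by the real one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError
from .network import bh_adjust


@dataclass
class EnrichmentResult:
    """One (query set, gene set) hypergeometric over-representation test."""

    query_id: str
    set_name: str
    background_size: int  # N
    set_size: int  # K (within background)
    query_size: int  # n
    overlap: int  # k
    p: float
    overlap_genes: tuple[str, ...] = ()


def hypergeom_ora(
    query: set[str], gene_set: set[str], background: set[str], query_id: str = "", set_name: str = ""
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of query/set overlap in a background.

    The gene set is intersected with the background first; the query must be
    a subset of the background (anything else signals a background bug).
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise ValidationError(
            f"query genes outside the background: {sorted(stray)[:5]}"
        )
    k_set = set(gene_set) & background
    n_bg, n_set, n_query = len(background), len(k_set), len(query)
    overlap = query & k_set
    k = len(overlap)
    p = float(stats.hypergeom.sf(k - 1, n_bg, n_set, n_query))
    return EnrichmentResult(
        query_id=query_id,
        set_name=set_name,
        background_size=n_bg,
        set_size=n_set,
        query_size=n_query,
        overlap=k,
        p=min(1.0, p),
        overlap_genes=tuple(sorted(overlap)),
    )


def _module_queries(
    modules: dict[int, dict[str, set[str]]],
    module_ids: list[int],
    backgrounds: dict[str, set[str]],
) -> list[tuple[str, str, set[str]]]:
    """(query id, region, genes) per module side, clipped to the background."""
    queries = []
    for mid in module_ids:
        for region in sorted(modules[mid]):
            genes = set(modules[mid][region]) & backgrounds[region]
            if genes:
                queries.append((f"mod{mid}:{region}", region, genes))
    return queries


def run_module_ora(
    modules: dict[int, dict[str, set[str]]],
    module_ids: list[int],
    collection: dict[str, set[str]],
    backgrounds: dict[str, set[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """ORA of every passing module side against one gene-set collection.

    BH runs across all (module-side x set) tests within the collection;
    ``significant`` marks q <= ``fdr``. Backgrounds are keyed by region.
    """
    rows = []
    for query_id, region, genes in _module_queries(modules, module_ids, backgrounds):
        for set_name in sorted(collection):
            res = hypergeom_ora(
                genes, collection[set_name], backgrounds[region],
                query_id=query_id, set_name=set_name,
            )
            rows.append(
                {
                    "query_id": res.query_id,
                    "region": region,
                    "set_name": res.set_name,
                    "background_size": res.background_size,
                    "set_size": res.set_size,
                    "query_size": res.query_size,
                    "overlap": res.overlap,
                    "p": res.p,
                    "overlap_genes": ";".join(res.overlap_genes),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "query_id", "region", "set_name", "background_size", "set_size",
            "query_size", "overlap", "p", "overlap_genes",
        ],
    )
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] <= fdr
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def empirical_fdr(
    real_results: pd.DataFrame,
    random_results_per_perm: list[pd.DataFrame],
    threshold: float = 0.05,
) -> float:
    """Mean over permutations of (#random significant) / max(1, #real significant).

    Significance is q <= ``threshold`` in both the real and random tables.
    """
    if not random_results_per_perm:
        raise ValidationError("need results from at least one permutation")
    n_real = int((real_results["q"] <= threshold).sum()) if len(real_results) else 0
    ratios = [
        (int((r["q"] <= threshold).sum()) if len(r) else 0) / max(1, n_real)
        for r in random_results_per_perm
    ]
    return float(np.mean(ratios))
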