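"""Network-level summaries: degrees and hubs, overlap, exclusivity, projection.

Hub genes are the nodes with many DC partners; since the DC network is
bipartite, the degree sum over one side equals the edge count. Region
exclusivity asks how much of the DC gene repertoire a focal region re-uses
across its comparisons with other regions. The intra-region projection
re-tests inter-region DC pairs *within* one region, restricting the multiple
testing family to the projected pair list to keep the burden comparable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ValidationError
from .network import (
    DCNetwork,
    _spearman_pvalue,
    bh_adjust,
    classify_dc_edge,
    fisher_z_dc_test,
)

logger = logging.getLogger(__name__)


def node_degrees(
    network: DCNetwork,
    biotype_map: dict[str, str] | None = None,
    protein_coding_only: bool = False,
) -> pd.DataFrame:
    """Per-(gene, region) DC-partner counts, descending.

    With ``protein_coding_only`` the degree table is filtered (before
    ranking) to genes whose biotype is ``protein_coding``; genes absent from
    ``biotype_map`` are excluded with a warning.
    """
    rows = []
    r1, r2 = network.region_pair
    for side, (gene_col, region) in enumerate(
        [("gene_a", r1), ("gene_b", r2)], start=1
    ):
        if len(network.edges) == 0:
            continue
        partner_col = "gene_b" if side == 1 else "gene_a"
        deg = network.edges.groupby(gene_col)[partner_col].nunique()
        for gene, d in deg.items():
            rows.append({"gene": gene, "region": region, "degree": int(d)})
    table = pd.DataFrame(rows, columns=["gene", "region", "degree"])
    if protein_coding_only:
        if biotype_map is None:
            raise ValidationError("protein_coding_only requires a biotype_map")
        known = table["gene"].map(biotype_map)
        n_unknown = int(known.isna().sum())
        if n_unknown:
            logger.warning("excluding %d gene(s) with unknown biotype", n_unknown)
        table = table[known == "protein_coding"]
    elif biotype_map is not None:
        table = table.assign(biotype=table["gene"].map(biotype_map))
    return table.sort_values(
        ["degree", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


def jaccard_index(set_a, set_b) -> float:
    """|A intersect B| / |A union B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def region_exclusivity(dc_gene_sets: dict[str, set[str]]) -> dict:
    """Pool one region's DC genes over its comparisons; how many are shared?

    ``dc_gene_sets`` maps comparison label -> the focal region's DC gene set
    in that comparison (at least two comparisons). Returns the pooled set,
    the genes seen in >= 2 comparisons, ``shared_fraction`` and a per-gene
    membership matrix.
    """
    if len(dc_gene_sets) < 2:
        raise ValidationError("region exclusivity needs at least 2 comparisons")
    pooled: set[str] = set()
    for s in dc_gene_sets.values():
        pooled |= set(s)
    counts = {
        g: sum(g in s for s in dc_gene_sets.values()) for g in pooled
    }
    shared = {g for g, c in counts.items() if c >= 2}
    membership = pd.DataFrame(
        {
            comp: [g in set(s) for g in sorted(pooled)]
            for comp, s in dc_gene_sets.items()
        },
        index=sorted(pooled),
    )
    return {
        "pooled": pooled,
        "shared": shared,
        "shared_fraction": (len(shared) / len(pooled)) if pooled else 0.0,
        "membership": membership,
    }


def intra_dc_projection(
    expr_region: pd.DataFrame,
    groups: np.ndarray,
    inter_pairs: list[tuple[str, str]],
    fdr_corr: float = 0.01,
    rho_min: float = 0.4,
    fdr_dc: float = 0.01,
) -> pd.DataFrame:
    """DC test of inter-region pairs projected within one region.

    For each inter-edge (gA@BR, gB@BR2) the within-region pair (gA, gB) is
    tested with the same correlation gate, Fisher z statistic and BH
    machinery, with the BH family restricted to the projected pair list.
    Pairs with a gene absent from the region are skipped (counted in the
    log); duplicate projected pairs are tested once.
    """
    groups = np.asarray(groups)
    if not inter_pairs:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "rho_ctl", "rho_ad", "z", "p_dc", "q_dc", "significant"]
        )
    genes = set(expr_region.index)
    pairs, skipped = [], 0
    seen = set()
    for ga, gb in inter_pairs:
        if ga == gb:
            skipped += 1
            continue
        key = tuple(sorted((ga, gb)))
        if key in seen:
            continue
        if ga not in genes or gb not in genes:
            skipped += 1
            continue
        seen.add(key)
        pairs.append((ga, gb))
    if skipped:
        logger.info("intra projection: skipped %d pair(s)", skipped)
    if not pairs:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "rho_ctl", "rho_ad", "z", "p_dc", "q_dc", "significant"]
        )

    arr = expr_region.to_numpy(float)
    gene_idx = {g: i for i, g in enumerate(expr_region.index)}
    masks = {lev: groups == lev for lev in ("CTL", "AD")}
    from scipy.stats import rankdata

    stats_cols: dict[str, np.ndarray] = {}
    for lev, mask in masks.items():
        n = int(mask.sum())
        sub = arr[:, mask]
        ranks = rankdata(sub, axis=1)
        ranks -= ranks.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(ranks, axis=1)
        rho = np.array(
            [
                np.dot(ranks[gene_idx[ga]], ranks[gene_idx[gb]])
                / (norms[gene_idx[ga]] * norms[gene_idx[gb]])
                if norms[gene_idx[ga]] > 0 and norms[gene_idx[gb]] > 0
                else np.nan
                for ga, gb in pairs
            ]
        )
        rho = np.clip(rho, -1, 1)
        p = _spearman_pvalue(rho, n)
        q = bh_adjust(np.where(np.isnan(p), 1.0, p))
        key = lev.lower()
        stats_cols[f"rho_{key}"] = rho
        stats_cols[f"n_{key}"] = np.full(len(pairs), n)
        stats_cols[f"correlated_{key}"] = (q <= fdr_corr) & (np.abs(rho) >= rho_min)

    df = pd.DataFrame({"gene_a": [p[0] for p in pairs], "gene_b": [p[1] for p in pairs], **stats_cols})
    df = df[df["correlated_ctl"] | df["correlated_ad"]].reset_index(drop=True)
    if df.empty:
        df["z"] = df["p_dc"] = df["q_dc"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    z, p = fisher_z_dc_test(
        df["rho_ctl"].to_numpy(), df["n_ctl"].to_numpy(),
        df["rho_ad"].to_numpy(), df["n_ad"].to_numpy(),
    )
    df["z"] = z
    df["p_dc"] = p
    df["q_dc"] = bh_adjust(p)
    df["significant"] = df["q_dc"] <= fdr_dc
    df["category"] = [
        classify_dc_edge(rc, ra) for rc, ra in zip(df["rho_ctl"], df["rho_ad"])
    ]
    return df


def neighbor_jaccard(net_a: DCNetwork, net_b: DCNetwork, side: int = 1) -> pd.DataFrame:
    """Neighbor-set Jaccard per gene shared between two comparisons."""
    col = "gene_a" if side == 1 else "gene_b"
    partner = "gene_b" if side == 1 else "gene_a"
    shared = net_a.dc_genes(side) & net_b.dc_genes(side)
    rows = []
    for g in sorted(shared):
        na = set(net_a.edges.loc[net_a.edges[col] == g, partner])
        nb = set(net_b.edges.loc[net_b.edges[col] == g, partner])
        rows.append({"gene": g, "jaccard": jaccard_index(na, nb)})
    return pd.DataFrame(rows, columns=["gene", "jaccard"])
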