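"""Cross-region differential correlation: the pipeline's core statistic.

For a pair of brain regions, every cross-region gene pair gets a Spearman
correlation per group (CTL, AD). A pair is *correlated* in a group when its
BH-adjusted correlation p-value passes ``fdr_corr`` AND |rho| >= ``rho_min``;
the union of correlated pairs over the two groups is the universe tested for
differential correlation (DC). The DC statistic is the difference of
Fisher r-to-z transformed correlations scaled by its standard error,

    Z = (atanh(rho_AD) - atanh(rho_CTL)) / sqrt(1/(n_AD-3) + 1/(n_CTL-3)),

so a positive Z means the pair's correlation increased in AD. DC p-values
are BH-corrected within the region pair's universe; edges at q <= ``fdr_dc``
form the DC network. Each edge is classified by which group dominates in
|rho|: AD-dominant edges gained correlation (PG if rho_AD > 0 else NG),
CTL-dominant edges lost it (LC_pos / LC_neg by the sign of rho_CTL).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import AD, CTL, PairedDataset, ValidationError

logger = logging.getLogger(__name__)

CATEGORY_TO_CLASS = {"PG": "PG", "NG": "NG", "LC_pos": "LC", "LC_neg": "LC"}


# ---------------------------------------------------------------- primitives
def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ties receive average ranks. Returns ``(nan, nan)`` for zero-variance
    input (the pair is excluded upstream with a flag); |rho| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 4:
        raise ValidationError(f"need at least 4 paired observations, got {n}")
    if x.std() == 0 or y.std() == 0:
        return (float("nan"), float("nan"))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, _spearman_pvalue(np.array([rho]), n)[0]


def _spearman_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from t = rho * sqrt((n-2)/(1-rho^2))."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rho) >= 1.0, 0.0, p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving w.r.t. input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def fisher_z_dc_test(rho_ctl, n_ctl, rho_ad, n_ad) -> tuple[np.ndarray, np.ndarray]:
    """Fisher r-to-z difference test, oriented AD minus CTL.

    Accepts scalars or arrays. Correlations at |rho| = 1 are clamped to
    1 - 1e-12 with a warning; group sizes must exceed 3.
    """
    rho_ctl = np.asarray(rho_ctl, dtype=float)
    rho_ad = np.asarray(rho_ad, dtype=float)
    n_ctl = np.asarray(n_ctl)
    n_ad = np.asarray(n_ad)
    if np.any(n_ctl <= 3) or np.any(n_ad <= 3):
        raise ValidationError("group sizes must exceed 3 for the Fisher z test")
    clip = 1.0 - 1e-12
    if np.any(np.abs(rho_ctl) >= 1.0) or np.any(np.abs(rho_ad) >= 1.0):
        logger.warning("correlation at |rho| >= 1 clamped to %.0e below 1", 1e-12)
    rc = np.clip(rho_ctl, -clip, clip)
    ra = np.clip(rho_ad, -clip, clip)
    se = np.sqrt(1.0 / (n_ad - 3.0) + 1.0 / (n_ctl - 3.0))
    z = (np.arctanh(ra) - np.arctanh(rc)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def classify_dc_edge(rho_ctl: float, rho_ad: float) -> str:
    """Four-category DC rule: dominant side is the group with larger |rho|.

    AD-dominant -> gained (PG if rho_ad > 0 else NG); CTL-dominant -> lost
    (LC_pos if rho_ctl > 0 else LC_neg).
    """
    if abs(rho_ad) >= abs(rho_ctl):
        return "PG" if rho_ad > 0 else "NG"
    return "LC_pos" if rho_ctl > 0 else "LC_neg"


# ------------------------------------------------------------- all-pairs rho
def _rank_standardize(mat: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centered and scaled to unit norm."""
    ranks = stats.rankdata(mat, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return ranks / norms


def _all_pairs_spearman(
    mat_a: np.ndarray, mat_b: np.ndarray, block_size: int
) -> np.ndarray:
    """Spearman rho for every (row of A) x (row of B) pair, block-streamed."""
    za = _rank_standardize(mat_a)
    zb = _rank_standardize(mat_b)
    out = np.empty((za.shape[0], zb.shape[0]))
    for lo in range(0, za.shape[0], block_size):
        hi = min(lo + block_size, za.shape[0])
        out[lo:hi] = np.clip(za[lo:hi] @ zb.T, -1.0, 1.0)
    return out


def correlated_pair_universe(
    paired: PairedDataset,
    fdr_corr: float = 0.01,
    rho_min: float = 0.4,
    block_size: int = 512,
) -> pd.DataFrame:
    """All cross-region pairs with per-group rho/p/q and correlated flags.

    BH is applied within each (group, region pair) family over every tested
    pair; a pair enters the returned universe when it is correlated (q <=
    ``fdr_corr`` and |rho| >= ``rho_min``) in either group. Zero-variance
    genes are excluded beforehand with a logged count. Results do not depend
    on ``block_size``.
    """
    masks = {g: paired.group_mask(g) for g in (CTL, AD)}
    for g, m in masks.items():
        if m.sum() < 4:
            raise ValidationError(f"{g} group has fewer than 4 individuals")

    mats = {1: paired.br1.expr, 2: paired.br2.expr}
    keep: dict[int, np.ndarray] = {}
    for side, df in mats.items():
        arr = df.to_numpy(float)
        ok = np.ones(arr.shape[0], dtype=bool)
        for m in masks.values():
            ok &= arr[:, m].std(axis=1) > 0
        n_drop = int((~ok).sum())
        if n_drop:
            logger.info("side %d: excluded %d zero-variance gene(s)", side, n_drop)
        keep[side] = ok
    genes_a = np.asarray(mats[1].index)[keep[1]]
    genes_b = np.asarray(mats[2].index)[keep[2]]
    arr_a = mats[1].to_numpy(float)[keep[1]]
    arr_b = mats[2].to_numpy(float)[keep[2]]

    res: dict[str, np.ndarray] = {}
    n_by_group: dict[str, int] = {}
    for grp, mask in masks.items():
        n = int(mask.sum())
        n_by_group[grp] = n
        rho = _all_pairs_spearman(arr_a[:, mask], arr_b[:, mask], block_size)
        p = _spearman_pvalue(rho, n)
        q = bh_adjust(p)
        res[f"rho_{grp.lower()}"] = rho
        res[f"p_{grp.lower()}"] = p
        res[f"q_{grp.lower()}"] = q
        res[f"correlated_{grp.lower()}"] = (q <= fdr_corr) & (np.abs(rho) >= rho_min)

    in_universe = res["correlated_ctl"] | res["correlated_ad"]
    ia, ib = np.nonzero(in_universe)
    uni = pd.DataFrame(
        {
            "gene_a": genes_a[ia],
            "gene_b": genes_b[ib],
            "rho_ctl": res["rho_ctl"][ia, ib],
            "p_ctl": res["p_ctl"][ia, ib],
            "q_ctl": res["q_ctl"][ia, ib],
            "rho_ad": res["rho_ad"][ia, ib],
            "p_ad": res["p_ad"][ia, ib],
            "q_ad": res["q_ad"][ia, ib],
            "n_ctl": n_by_group[CTL],
            "n_ad": n_by_group[AD],
            "correlated_ctl": res["correlated_ctl"][ia, ib],
            "correlated_ad": res["correlated_ad"][ia, ib],
        }
    )
    if uni.empty:
        logger.warning("correlated-pair universe is empty")
    logger.info(
        "universe: %d pairs out of %d tested", len(uni), len(genes_a) * len(genes_b)
    )
    return uni


# ----------------------------------------------------------------- DC calls
@dataclass
class DCNetwork:
    """The significant DC edge list for one region pair, plus bookkeeping."""

    edges: pd.DataFrame
    tested_pair_count: int
    region_pair: tuple[str, str]
    params: dict = field(default_factory=dict)

    @property
    def dysregulation_percentage(self) -> float:
        if self.tested_pair_count == 0:
            return 0.0
        return 100.0 * len(self.edges) / self.tested_pair_count

    def dc_genes(self, side: int) -> set[str]:
        col = "gene_a" if side == 1 else "gene_b"
        return set(self.edges[col]) if len(self.edges) else set()


def call_dc_edges(
    universe: pd.DataFrame,
    fdr_dc: float = 0.01,
    region_pair: tuple[str, str] = ("BR1", "BR2"),
) -> DCNetwork:
    """Fisher z test + BH within the universe; keep edges at q <= fdr_dc."""
    uni = universe.copy()
    if uni.empty:
        edges = uni.assign(z=[], p_dc=[], q_dc=[], category=[], dc_class=[])
        return DCNetwork(edges, 0, region_pair, {"fdr_dc": fdr_dc})
    z, p = fisher_z_dc_test(
        uni["rho_ctl"].to_numpy(),
        uni["n_ctl"].to_numpy(),
        uni["rho_ad"].to_numpy(),
        uni["n_ad"].to_numpy(),
    )
    uni["z"] = z
    uni["p_dc"] = p
    uni["q_dc"] = bh_adjust(p)
    edges = uni[uni["q_dc"] <= fdr_dc].copy()
    edges["category"] = [
        classify_dc_edge(rc, ra) for rc, ra in zip(edges["rho_ctl"], edges["rho_ad"])
    ]
    edges["dc_class"] = edges["category"].map(CATEGORY_TO_CLASS)
    edges = edges.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    net = DCNetwork(
        edges,
        tested_pair_count=len(uni),
        region_pair=region_pair,
        params={"fdr_dc": fdr_dc},
    )
    logger.info(
        "%s-%s: %d DC edges / %d tested (%.2f%%)",
        region_pair[0],
        region_pair[1],
        len(edges),
        len(uni),
        net.dysregulation_percentage,
    )
    return net


# --------------------------------------------------- differential expression
def wilcoxon_de(
    expr: pd.DataFrame,
    groups: np.ndarray,
    fdr_cutoffs: tuple[float, ...] = (0.05, 0.1, 0.2),
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum CTL-vs-AD test with BH q and DE flags.

    ``expr`` is genes x samples; ``groups`` per-sample labels with two
    levels. Constant genes get p = 1 with a ``constant`` flag.
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"need exactly two groups, got {list(levels)}")
    a = expr.loc[:, np.asarray(expr.columns)[groups == levels[0]]].to_numpy(float)
    b = expr.loc[:, np.asarray(expr.columns)[groups == levels[1]]].to_numpy(float)
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValidationError("both groups need at least 3 samples")
    constant = np.concatenate([a, b], axis=1).std(axis=1) == 0
    stat = np.full(len(expr), np.nan)
    p = np.ones(len(expr))
    if (~constant).any():
        res = stats.mannwhitneyu(
            a[~constant], b[~constant], axis=1, alternative="two-sided", method="auto"
        )
        stat[~constant] = res.statistic
        p[~constant] = res.pvalue
    out = pd.DataFrame(
        {"gene": expr.index, "statistic": stat, "p": p, "constant": constant}
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    for cut in fdr_cutoffs:
        out[f"de_q{cut:g}"] = out["q"] <= cut
    return out


def flag_de_driven(
    network: DCNetwork, de_genes: dict[str, set[str]]
) -> tuple[DCNetwork, float]:
    """Flag edges with a DE gene on either side; return the flagged percentage.

    ``de_genes`` is keyed by region id (matching ``network.region_pair``).
    """
    r1, r2 = network.region_pair
    de1 = set(de_genes.get(r1, set()))
    de2 = set(de_genes.get(r2, set()))
    edges = network.edges.copy()
    if len(edges):
        edges["de_driven"] = edges["gene_a"].isin(de1) | edges["gene_b"].isin(de2)
        pct = 100.0 * edges["de_driven"].mean()
    else:
        edges["de_driven"] = pd.Series(dtype=bool)
        pct = 0.0
    return (
        DCNetwork(edges, network.tested_pair_count, network.region_pair, network.params),
        float(pct),
    )


# ------------------------------------------------------------ the estimator
class InterRegionDCAnalysis(BaseEstimator):
    """End-to-end DC analysis for one region pair, sklearn-estimator style.

    Parameters
    ----------
    fdr_corr : float, default 0.01
        BH FDR gate on per-group correlation significance.
    rho_min : float, default 0.4
        Minimum |Spearman rho| (moderate strength) to call a pair correlated.
    fdr_dc : float, default 0.01
        BH FDR cut-off on the DC test within the correlated-pair universe.
    block_size : int, default 512
        Gene-block width for the streamed all-pairs correlation; has no
        effect on results.

    Attributes
    ----------
    universe_ : DataFrame
        The correlated-pair universe with per-group statistics.
    network_ : DCNetwork
        Significant DC edges with z, q, category and class.
    dysregulation_percentage_ : float
        100 x edges / tested pairs.
    """

    def __init__(self, fdr_corr=0.01, rho_min=0.4, fdr_dc=0.01, block_size=512):
        self.fdr_corr = fdr_corr
        self.rho_min = rho_min
        self.fdr_dc = fdr_dc
        self.block_size = block_size

    def fit(self, paired: PairedDataset, y=None):
        self.universe_ = correlated_pair_universe(
            paired,
            fdr_corr=self.fdr_corr,
            rho_min=self.rho_min,
            block_size=self.block_size,
        )
        self.network_ = call_dc_edges(
            self.universe_,
            fdr_dc=self.fdr_dc,
            region_pair=(paired.br1.region_id, paired.br2.region_id),
        )
        self.network_.params.update(
            {"fdr_corr": self.fdr_corr, "rho_min": self.rho_min}
        )
        self.tested_pair_count_ = self.network_.tested_pair_count
        self.dysregulation_percentage_ = self.network_.dysregulation_percentage
        return self
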