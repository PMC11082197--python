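"""Self-validation experiments: known-truth simulations exercising the pipeline.

Each function sets up a simulation whose correct outcome is known by
construction (a planted rewiring, a global null, a composition confound, a
planted block structure) or checks a statistic against an independent
high-precision or brute-force evaluation. They are used by the test suite
and the reproduction script; problem sizes are chosen so each experiment
runs in seconds to minutes on one CPU while leaving no ambiguity about the
expected outcome.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .bimodules import (
    build_bipartite_graph,
    louvain_partition,
    random_modules,
    recompute_modularity,
)
from .celltype import MarkerSet, correct_cell_types, estimate_spvs
from .datatypes import PairedDataset, RegionExpression
from .enrich import empirical_fdr, hypergeom_ora, run_module_ora
from .network import DCNetwork, InterRegionDCAnalysis, fisher_z_dc_test
from .simulate import (
    PlantedEdge,
    SimulationConfig,
    default_planted_edges,
    generate_paired_dataset,
)

PLANTED_CLASS_TO_DC_CLASS = {"PG": "PG", "NG": "NG", "LC_pos": "LC", "LC_neg": "LC"}


def fisher_z_oracle_error(n_tuples: int = 1000, seed: int = 42) -> float:
    """Worst |Z - oracle| over random tuples vs a 60-digit mpmath evaluation."""
    import mpmath

    rng = np.random.default_rng(seed)
    rho1 = rng.uniform(-0.99, 0.99, n_tuples)
    rho2 = rng.uniform(-0.99, 0.99, n_tuples)
    n1 = rng.integers(5, 2000, n_tuples)
    n2 = rng.integers(5, 2000, n_tuples)
    z, _ = fisher_z_dc_test(rho1, n1, rho2, n2)
    worst = 0.0
    with mpmath.workdps(60):
        for i in range(n_tuples):
            oracle = (mpmath.atanh(rho2[i]) - mpmath.atanh(rho1[i])) / mpmath.sqrt(
                mpmath.mpf(1) / (int(n2[i]) - 3) + mpmath.mpf(1) / (int(n1[i]) - 3)
            )
            worst = max(worst, abs(z[i] - float(oracle)))
    return worst


def null_fdp_experiment(
    n_replicates: int = 20,
    n_genes: int = 200,
    n_per_group: int = 150,
    seed: int = 0,
) -> float:
    """Mean false-discovery proportion under a two-group null.

    Both groups share the same planted correlation structure (50 cross-region
    pairs at rho 0.5-0.7, identical in CTL and AD), so every DC call is
    false; FDP per replicate is V / max(R, 1). BH at FDR 1% should keep the
    mean well under 0.05.
    """
    fdps = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_genes_per_region=n_genes, n_ctl=n_per_group, n_ad=n_per_group,
            seed=seed * 1000 + rep, n_cell_types=2, markers_per_type=10, n_de_genes=0,
        )
        genes = cfg.gene_ids()
        idx = 20
        edges = []
        for rho in [0.5] * 15 + [0.6] * 20 + [0.7] * 15:
            edges.append(PlantedEdge(genes[idx], genes[idx + 1], rho, rho, "NULL"))
            idx += 2
        cfg.planted_edges = edges
        paired, _ = generate_paired_dataset(cfg)
        est = InterRegionDCAnalysis().fit(paired)
        n_called = len(est.network_.edges)
        fdps.append(n_called / max(1, n_called))  # every call is false here
    return float(np.mean(fdps))


def power_classification_experiment(
    n_per_class: int = 50,
    n_per_group: int = 150,
    n_genes: int = 400,
    seed: int = 0,
) -> dict[str, float]:
    """Recovery of planted rewiring: PG 0->0.7, NG 0->-0.7, LC 0.7->0.

    Returns recall of planted edges at FDR 1%, the fraction of called
    planted edges with the correct class, and the false-call fraction among
    all called edges.
    """
    cfg = SimulationConfig(
        n_genes_per_region=n_genes, n_ctl=n_per_group, n_ad=n_per_group,
        seed=seed, n_cell_types=2, markers_per_type=10, n_de_genes=0,
    )
    cfg.planted_edges = default_planted_edges(
        cfg.gene_ids(), n_per_class=n_per_class, start_index=20
    )
    paired, truth = generate_paired_dataset(cfg)
    est = InterRegionDCAnalysis().fit(paired)
    edges = est.network_.edges.set_index(["gene_a", "gene_b"])
    called = correct = 0
    for row in truth.planted_edge_table.itertuples():
        key = (row.gene_a, row.gene_b)
        if key in edges.index:
            called += 1
            if edges.loc[key, "dc_class"] == PLANTED_CLASS_TO_DC_CLASS[row.edge_class]:
                correct += 1
    n_planted = len(truth.planted_edge_table)
    return {
        "recall": called / n_planted,
        "class_accuracy": correct / max(1, called),
        "false_call_fraction": (len(edges) - called) / max(1, len(edges)),
        "n_called": len(edges),
    }


def ctc_efficacy_experiment(seed: int = 0) -> dict[str, float]:
    """Composition-confounded cohort: SPV fidelity and DC edge reduction.

    Sixty genes per region load on shared cell-type proportions whose
    variability differs between groups (AD Dirichlet concentration scaled
    by 0.3), creating composition-driven DC edges with no cell-intrinsic
    rewiring. Correction should track the true proportions (|Spearman| >=
    0.9 per type) and remove most of those edges.
    """
    cfg = SimulationConfig(
        n_genes_per_region=200, n_ctl=150, n_ad=150, seed=seed,
        n_confounded_genes=60, confound_loading=2.0, ad_alpha_scale=0.3,
        n_de_genes=0,
    )
    paired, truth = generate_paired_dataset(cfg)
    groups = paired.groups.loc[paired.individuals].to_numpy()
    marker_sets = [MarkerSet(ct, gl) for ct, gl in truth.marker_map.items()]
    props = truth.true_cell_proportions[paired.individuals]

    spv_corr_min = 1.0
    corrected_regions = []
    for region in (paired.br1, paired.br2):
        model = estimate_spvs(region.expr, marker_sets, groups)
        for ct in model.spvs.index:
            rho = spearmanr(
                model.spvs.loc[ct].to_numpy(), props.loc[ct].to_numpy()
            ).statistic
            spv_corr_min = min(spv_corr_min, abs(float(rho)))
        corrected_regions.append(
            RegionExpression(
                region.region_id,
                correct_cell_types(region.expr, model),
                region.sample_meta,
            )
        )
    edges_before = len(InterRegionDCAnalysis().fit(paired).network_.edges)
    paired_ctc = PairedDataset(
        br1=corrected_regions[0], br2=corrected_regions[1],
        individuals=paired.individuals, groups=paired.groups,
    )
    edges_after = len(InterRegionDCAnalysis().fit(paired_ctc).network_.edges)
    reduction = 100.0 * (1 - edges_after / edges_before) if edges_before else 0.0
    return {
        "spv_truth_min_abs_spearman": spv_corr_min,
        "edges_before_ctc": edges_before,
        "edges_after_ctc": edges_after,
        "edge_reduction_pct": reduction,
    }


def _planted_block_network(seed: int = 77, n_blocks: int = 4, per_side: int = 30):
    rng = np.random.default_rng(seed)
    rows, truth = [], {}
    for i in range(n_blocks * per_side):
        for j in range(n_blocks * per_side):
            p = 0.3 if i // per_side == j // per_side else 0.01
            if rng.random() < p:
                rows.append({"gene_a": f"a{i:03d}", "gene_b": f"b{j:03d}"})
    for i in range(n_blocks * per_side):
        truth[f"a{i:03d}@R1"] = i // per_side
        truth[f"b{i:03d}@R2"] = i // per_side
    net = DCNetwork(
        edges=pd.DataFrame(rows),
        tested_pair_count=(n_blocks * per_side) ** 2,
        region_pair=("R1", "R2"),
    )
    return net, truth


def modularity_benchmark(seed: int = 77, n_seeds: int = 10) -> dict[str, float]:
    """Exact two-triangle modularity plus planted-block recovery across seeds."""
    from sklearn.metrics import adjusted_rand_score

    tri = nx.Graph()
    tri.add_edges_from(combinations([0, 1, 2], 2))
    tri.add_edges_from(combinations([3, 4, 5], 2))
    q_triangles = louvain_partition(tri, seed=0).modularity

    net, truth = _planted_block_network(seed=seed)
    graph = build_bipartite_graph(net)
    nodes = sorted(graph.nodes)
    min_ari, max_q_err = 1.0, 0.0
    for s in range(n_seeds):
        part = louvain_partition(graph, seed=s)
        ari = adjusted_rand_score(
            [truth[n] for n in nodes], [part.assignment[n] for n in nodes]
        )
        min_ari = min(min_ari, float(ari))
        max_q_err = max(
            max_q_err, abs(part.modularity - recompute_modularity(graph, part.assignment))
        )
    return {
        "two_triangle_q": q_triangles,
        "planted_block_min_ari": min_ari,
        "q_recompute_max_error": max_q_err,
    }


def ora_benchmark(seed: int = 0, n_perm_null: int = 50) -> dict[str, float]:
    """Hypergeometric exactness, null calibration and the permutation contract."""
    # exactness vs brute-force tail sums for every small instance
    max_err = 0.0
    for n_bg in (5, 12, 20, 30):
        bg = [f"g{i:03d}" for i in range(n_bg)]
        for n_set in (0, 2, n_bg // 2, n_bg):
            for n_query in (0, 1, n_bg // 3, n_bg // 2):
                gene_set = set(bg[:n_set])
                query = set(bg[n_bg - n_query:]) if n_query else set()
                res = hypergeom_ora(query, gene_set, set(bg))
                total = comb(n_bg, n_query)
                brute = sum(
                    comb(n_set, i) * comb(n_bg - n_set, n_query - i)
                    for i in range(res.overlap, min(n_set, n_query) + 1)
                    if n_query - i <= n_bg - n_set
                ) / total
                max_err = max(max_err, abs(res.p - brute))

    # null modules: raw-p rate at alpha stays near (below) nominal
    rng = np.random.default_rng(seed)
    bg = [f"g{i:04d}" for i in range(1000)]
    collection = {
        f"s{j}": set(rng.choice(bg, size=50, replace=False)) for j in range(10)
    }
    structure = {1: {"R1": 50}}
    perms = random_modules({"R1": bg}, structure, n_perm=n_perm_null, seed=seed + 1)
    sizes_ok = all(len(p[1]["R1"]) == 50 for p in perms)
    rates = []
    rand_tables = []
    for perm in perms:
        out = run_module_ora(perm, [1], collection, {"R1": set(bg)})
        rates.append(float((out["p"] < 0.05).mean()))
        rand_tables.append(out)

    # a planted, set-aligned module against the same permutations
    planted = {1: {"R1": set(sorted(collection["s0"]))}}
    real = run_module_ora(planted, [1], collection, {"R1": set(bg)})
    efdr = empirical_fdr(real, rand_tables[:10], threshold=0.05)
    return {
        "hypergeom_max_abs_error": max_err,
        "null_raw_rate_at_0.05": float(np.mean(rates)),
        "size_contract_preserved": float(sizes_ok),
        "planted_module_empirical_fdr": efdr,
    }


def default_cohort_summary(seed: int = 0, n_genes: int = 300) -> dict[str, float]:
    """One full analysis on the default synthetic cohort (372 CTL / 264 AD)."""
    cfg = SimulationConfig(n_genes_per_region=n_genes, seed=seed)
    start = cfg.n_cell_types * cfg.markers_per_type
    cfg.planted_edges = default_planted_edges(cfg.gene_ids(), n_per_class=10, start_index=start)
    paired, truth = generate_paired_dataset(cfg)
    groups = paired.groups.loc[paired.individuals].to_numpy()
    marker_sets = [MarkerSet(ct, gl) for ct, gl in truth.marker_map.items()]
    corrected = []
    for region in (paired.br1, paired.br2):
        model = estimate_spvs(region.expr, marker_sets, groups)
        corrected.append(
            RegionExpression(region.region_id, correct_cell_types(region.expr, model),
                             region.sample_meta)
        )
    paired_ctc = PairedDataset(br1=corrected[0], br2=corrected[1],
                               individuals=paired.individuals, groups=paired.groups)
    est = InterRegionDCAnalysis().fit(paired_ctc)
    edges = est.network_.edges.set_index(["gene_a", "gene_b"])
    planted_called = sum(
        (row.gene_a, row.gene_b) in edges.index
        for row in truth.planted_edge_table.itertuples()
    )
    return {
        "n_ctl": paired.group_size("CTL"),
        "n_ad": paired.group_size("AD"),
        "tested_pair_count": est.tested_pair_count_,
        "n_dc_edges": len(est.network_.edges),
        "dysregulation_pct": est.dysregulation_percentage_,
        "planted_recall": planted_called / len(truth.planted_edge_table),
    }
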