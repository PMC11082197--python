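"""Shared fixtures: small synthetic cohorts built in memory, no data files."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from synthcases import make_paired, make_region  # noqa: F401  (re-exported for tests)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_block_network():
    """Planted 4-block bipartite model: 30+30 genes per block, dense within
    (p=0.3), sparse between (p=0.01). Returns (DCNetwork, node -> block)."""
    from interdc.network import DCNetwork

    rng = np.random.default_rng(77)
    n_blocks, per_side = 4, 30
    rows, truth = [], {}
    genes_a = [f"a{i:03d}" for i in range(n_blocks * per_side)]
    genes_b = [f"b{i:03d}" for i in range(n_blocks * per_side)]
    for i, ga in enumerate(genes_a):
        truth[f"{ga}@R1"] = i // per_side
        for j, gb in enumerate(genes_b):
            truth[f"{gb}@R2"] = j // per_side
            p = 0.3 if i // per_side == j // per_side else 0.01
            if rng.random() < p:
                rows.append({"gene_a": ga, "gene_b": gb, "z": rng.normal()})
    edges = pd.DataFrame(rows)
    net = DCNetwork(edges=edges, tested_pair_count=len(genes_a) * len(genes_b),
                    region_pair=("R1", "R2"))
    return net, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """A modest planted-rewiring cohort shared across read-only tests."""
    from interdc.simulate import SimulationConfig, default_planted_edges, generate_paired_dataset

    cfg = SimulationConfig(
        n_genes_per_region=160, n_ctl=150, n_ad=150, seed=11,
        n_cell_types=2, markers_per_type=10, n_de_genes=10,
    )
    cfg.planted_edges = default_planted_edges(cfg.gene_ids(), n_per_class=8, start_index=20)
    paired, truth = generate_paired_dataset(cfg)
    return cfg, paired, truth
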