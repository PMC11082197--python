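# interdc

**Inter-region differential correlation networks from paired bulk transcriptomes.**

Bulk RNA-seq studies of brain disease usually ask how genes change *within*
one region. `interdc` asks a different question: when the same individuals
are profiled in two brain regions, which **cross-region gene pairs** gain or
lose correlation in the disease group relative to controls? Such rewiring of
inter-region co-expression is a molecular counterpart of the disrupted
functional connectivity seen in neurodegeneration, and the resulting network
of differentially correlated (DC) pairs exposes hub genes, bipartite gene
modules and candidate signaling pathways whose inter-region coupling the
disease disturbs.

The package is aimed at computational biologists working with paired
multi-region cohorts (e.g. post-mortem brain banks with CERAD-scored
Alzheimer's cases and controls), and ships a synthetic-cohort generator with
planted ground truth so the entire pipeline is testable without any data
download.

## The statistic

For a region pair (BR1, BR2) and groups CTL / AD:

1. **Correlation gate.** For every cross-region gene pair, Spearman's ρ is
   computed per group. A pair is *correlated* in a group when its
   BH-adjusted correlation p-value passes FDR 1% **and** |ρ| ≥ 0.4. The
   union of correlated pairs over the two groups is the universe tested for
   differential correlation.
2. **DC test.** Each universe pair gets the Fisher r-to-z difference score

   ```
   Z = [atanh(ρ_AD) − atanh(ρ_CTL)] / sqrt( 1/(n_AD−3) + 1/(n_CTL−3) )
   ```

   with a two-sided normal p-value, BH-corrected within the universe;
   edges at q ≤ 0.01 form the DC network. Z > 0 means the pair's
   correlation increased in AD. Each edge falls into one of four
   categories — the group with the larger |ρ| dominates: AD-dominant edges
   *gained* correlation (PG if ρ_AD > 0, NG if ρ_AD < 0), CTL-dominant
   edges *lost* it (LC_pos / LC_neg) — grouped into the three classes
   PG, NG, LC. The *dysregulation percentage* is 100 × edges / tested pairs.
3. **Cell-type correction.** Because bulk correlations can be driven by
   shared cell-composition variation rather than cell-intrinsic signal,
   expression is first residualized on surrogate proportion variables
   (SPVs): per cell type, the leading singular vector of the
   row-standardized marker-gene submatrix, after an F-test discards markers
   that differ between groups.
4. **Network structure.** The bipartite DC network is summarized by node
   degrees (hubs), region-exclusivity of pooled DC genes, and Louvain
   modularity modules (≥ 20 genes); module gene sets per region side are
   tested for functional over-representation (hypergeometric, BH at FDR 5%)
   against a correlated-gene background, with an empirical FDR from
   structure-preserving random modules (10 permutations).

## Worked example

```python
from interdc import (SimulationConfig, default_planted_edges, generate_paired_dataset,
                     InterRegionDCAnalysis, LouvainBipartitePartitioner)

cfg = SimulationConfig(n_genes_per_region=200, n_ctl=150, n_ad=150, seed=7,
                       n_cell_types=2, markers_per_type=10)
cfg.planted_edges = default_planted_edges(cfg.gene_ids(), n_per_class=10, start_index=20)
paired, truth = generate_paired_dataset(cfg)

dc = InterRegionDCAnalysis(fdr_corr=0.01, rho_min=0.4, fdr_dc=0.01).fit(paired)
print(f"tested pairs: {dc.tested_pair_count_}")
print(f"DC edges:     {len(dc.network_.edges)}  ({dc.dysregulation_percentage_:.2f}% dysregulation)")
print(dc.network_.edges["dc_class"].value_counts().to_dict())
```

prints

```
tested pairs: 433
DC edges:     29  (6.70% dysregulation)
{'NG': 10, 'LC': 10, 'PG': 9}
```

The 30 planted rewired pairs (10 per class: PG ρ 0→0.7, NG 0→−0.7, LC
0.7→0) were recovered almost completely — 29 edges called out of 433
correlated pairs, with the class counts matching the planted design — and
the universe consists of the planted pairs plus marker-gene pairs that
correlate through shared cell composition in both groups (correlated, but
not differentially so). The first called edges look like:

```
gene_a gene_b   rho_ctl   rho_ad        z         q_dc category
 G0021  G0022 -0.072158 0.520363 5.565049 4.728341e-07       PG
 G0023  G0024  0.001193 0.687008 7.210714 1.721463e-11       PG
```

The same analysis is available as a staged CLI (`interdc simulate`,
`preprocess`, `ctc`, `dcnet`, `netstats`, `modules`, `ora`, or `all`), each
stage writing deterministic artifacts plus the resolved configuration into
one pipeline directory:

```bash
interdc simulate --out run/ --seed 7
interdc all --dir run/ --seed 7
```

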