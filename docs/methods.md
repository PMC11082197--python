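# Methods

This note documents the statistical model, the synthetic-cohort generator,
the numerical choices and the known limitations of `interdc`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The differential-correlation model

### Groups and pairing

Individuals are assigned by CERAD neuropathological score: 1 → CTL,
2 (definite AD) → AD, 3–4 (probable/possible) → excluded. Analyses run on
one region pair at a time, restricted to individuals profiled in both
regions; if an individual contributes several samples to one region, the
first by sample id is kept with a warning (the choice is arbitrary but
deterministic). Both groups must reach a configurable minimum size
(default 10).

### Covariate adjustment

Inputs are assumed normalized (e.g. TMM) on a continuous log-like scale;
the package does not re-implement normalization. A generic per-gene OLS
residualizer removes named covariates: categoricals are one-hot encoded
with the reference level dropped, missing continuous values are imputed
with the covariate mean (categoricals with the mode), design columns are
centered so each gene's mean is preserved, and collinear columns are
dropped with a warning (pivoted QR). Residualization is idempotent by OLS
orthogonality.

### Cell-type correction

Bulk expression mixes cell-intrinsic signal with composition effects. Per
cell type, a surrogate proportion variable (SPV) is the leading right
singular vector of the row-standardized marker submatrix, computed on both
groups jointly (one model per region). Markers are first filtered by a
one-way F-test between groups: markers with p < α (default 0.05) are
considered contaminated by the group contrast and dropped, because a
group-associated marker would leak disease signal into the composition
score and the subsequent residualization would erase genuine disease
effects. Each SPV has unit norm and is oriented so its mean correlation
with its own markers is positive. Expression is then OLS-residualized on
all SPVs (mean preserved).

This is a deliberate simplification of the full iterative "mixed"
surrogate-variable procedure used by reference-free deconvolution tools:
the robust-marker filter plus one SVD per cell type captures the contract
downstream correctness needs — a group-uncontaminated leading-variation
score per cell type — without replicating the iteration. SPVs are relative
scores, not absolute cell fractions. Marker rows are z-scored before the
SVD so high-expression markers do not dominate. When known proportions are
available (e.g. immunohistochemistry), `select_marker_model` picks the
per-type marker count (candidates such as 20/40/80/200/500/1000 markers)
whose SPV best Spearman-correlates with the truth, ties toward the smaller
model; without such ground truth, 20 markers per type (80 for the four
major brain cell types) is the default.

### The DC statistic

Per group, all cross-region pairs get Spearman's ρ on average ranks and a
two-sided p from the t-approximation `t = ρ·sqrt((n−2)/(1−ρ²))` (standard
at the sample sizes in scope; |ρ| = 1 gives p = 0). BH runs within each
(group × region-pair) family; a pair is *correlated* when q ≤ 1% **and**
|ρ| ≥ 0.4, and the universe is the union of correlated pairs over groups.
The DC score is the Fisher r-to-z difference

    Z = (atanh ρ_AD − atanh ρ_CTL) / sqrt(1/(n_AD−3) + 1/(n_CTL−3)),

oriented AD-minus-CTL, with a two-sided normal p, BH-corrected within the
universe only; edges at q ≤ 1% are reported. Degenerate inputs: |ρ| = 1 is
clamped to 1 − 1e−12 with a warning; group sizes ≤ 3 are rejected;
zero-variance genes are excluded from the pair grid with a logged count.

**Edge categories.** The published three-class scheme (PG gained positive,
NG gained negative, LC lost) arises from four clusters in the
(ρ_CTL, ρ_AD) plane, but no numeric threshold defines them publicly. The
deterministic rule used here: the *dominant* side is the group with larger
|ρ|; AD-dominant → gained (PG if ρ_AD > 0 else NG), CTL-dominant → lost
(LC_pos / LC_neg by the sign of ρ_CTL). For a significant edge the
dominant side is well separated, so the rule reproduces the four clusters;
it is an interpretation, not a published formula. Ties (|ρ_AD| = |ρ_CTL|)
resolve to the gained branch; such edges have Z = 0 and are never
significant.

**Multiple-testing families.** The DC family (the region pair's universe)
follows the published description. Whether correlation-side BH pooled the
two groups is not stated; per-group families are used as the natural
per-analysis unit.

**Anticonservatism of the union gate.** A genuinely null pair that passes
the correlation gate in exactly one group is, conditionally, almost certain
to be called DC — entering the gate at |ρ| ≥ 0.4 while the other group
sits near 0 already implies |Z| ≈ 5 at n = 150/group. Under a global null
this inflates the realized false-discovery proportion above the nominal 1%,
because the gate itself is a selection event. At desk scale (200
genes/region, 40k pairs) stray gate entries occur in a few percent of
replicates, so the mean FDP stays small (the null benchmark bounds it at
0.05) but is not 0.01; users should read the FDR as controlling error
*within the selected universe*, which is how the procedure is defined.

### DE accounting, hubs, exclusivity, projection

Differential expression per region uses the Wilcoxon rank-sum test on
corrected data (exact p for small groups, normal approximation with tie
correction otherwise; constant genes get p = 1 with a flag), BH q, and DE
flags at FDR 0.05/0.1/0.2. An edge is *DE-driven* when either gene is DE in
its own region. Hubs are reported as a ranked degree table (top-k, default
20) rather than by a degree cutoff, since no cutoff is published; an
optional biotype filter restricts to protein-coding genes. Region
exclusivity pools one region's DC genes across its comparisons and reports
the fraction seen in ≥ 2 comparisons. The intra-region projection re-tests
inter-region DC pairs within one region using the identical gate + Fisher-z
+ BH machinery, with the BH family restricted to the projected list to keep
the multiple-testing burden comparable.

### Bipartite modules and enrichment

DC edges form a bipartite graph of (gene, region) nodes. Standard
unipartite Newman modularity is maximized with the seeded Louvain heuristic
(networkx); a bipartite-specific modularity (e.g. Barber's) is *not* used,
matching the practice of running a general-graph Louvain routine on the
two-layered network. Modules are relabelled deterministically by descending
size (ties by smallest member node id), and the reported Q always equals a
from-scratch recomputation. Only modules with ≥ 20 genes total enter
enrichment; each contributes two query sets (one per region side). Edges
are unweighted by default; |Z| weighting is available behind a flag. Only
DC nodes enter the graph (correlated-but-not-DC genes are not nodes).

ORA is the upper-tail hypergeometric test — p = P[X ≥ k] for
X ~ Hypergeom(N, K, n) — against the region's correlated gene list as
background, BH across all (module-side × set) tests within a collection,
significant at q ≤ 0.05. Redundancy reduction of enriched terms (affinity
propagation, weighted set cover) is a presentation-layer feature of
enrichment web tools and is out of scope; all results are reported with
q-values. The permutation null shuffles module-id labels over the
background gene list per region side, preserving the module-size multiset
exactly (10 permutations by default); the empirical FDR is the mean over
permutations of (#significant in random) / max(1, #significant in real).
Custom gene-set enrichment uses region-specific backgrounds for consistency
with the GO procedure (the pooled-background alternative is ambiguous in
the source description).

## 2. The synthetic cohort generator

The generator emulates a paired post-mortem cohort: the same individuals in
two regions, CERAD labels, covariates (age, sex, RIN), four cell types ×
20 markers mixed into bulk signal, and planted cross-region rewiring.
Defaults are the cohort conditions the pipeline targets: 372 CTL and 264 AD
individuals, four cell types, 20 markers each.

- **Planted correlations** use a Gaussian copula: the bivariate-normal
  Pearson r maps to Spearman ρ_S via ρ_S = (6/π)·arcsin(r/2), so the
  generator draws at r = 2·sin(π·ρ_S/6) per group. For planted genes the
  copula draw *is* the stochastic core of the expression value, so the
  realized rank correlation is unattenuated by noise (small covariate
  effects attenuate it by < 3% under defaults).
- **Cell composition** is Dirichlet per individual (default concentration
  (8, 4, 2, 2): one dominant and three minor types), identical in both
  regions of an individual. Scaling the AD concentration (`ad_alpha_scale`)
  changes composition *variability* between groups without changing means —
  a confound that produces composition-driven DC edges while staying
  invisible to the mean-based robust-marker F-test, exactly the situation
  cell-type correction must fix. Marker genes load on their own type's
  standardized proportion signal with loading 5 (per proportion-sd, vs
  unit-sd noise); optional "confounded" bystander genes load with a
  configurable strength (default 2) to create composition-driven pairs.
- **Covariates and DE.** Per-(gene, region) covariate slopes are drawn
  N(0, σ_k) with small defaults (age 0.05, sex 0.2, RIN 0.1 per
  standardized covariate); a configurable number of genes per region
  (default 25) gets a mean shift (default 0.8) in AD.
- Output is bitwise-reproducible given the seed; distinct seeds give
  distinct realizations.

What the generator does **not** emulate: count-level sampling and library
size, region-specific composition within an individual, correlated
covariates, realistic effect-size spectra of disease rewiring (defaults are
chosen for testability, not realism), and more than two regions per dataset
(multi-region studies are composed from multiple paired datasets). Passing
tests therefore demonstrate the statistical machinery on its stated model,
not performance on raw count data.

## 3. Validation experiments and problem sizes

The self-validation experiments (`interdc.benchmarks`) were sized so the
whole suite runs in seconds to minutes on one CPU while leaving the
expected outcome unambiguous:

- DC z-score vs a 60-digit mpmath evaluation on 1000 random tuples.
- Null FDR: 20 replicates, 200 genes/region, 150/group, 50 planted pairs
  with identical ρ (0.5–0.7) in both groups; every call is false.
- Power: 50 planted edges per class (PG 0→0.7, NG 0→−0.7, LC 0.7→0) at
  150/group over 400 genes/region.
- CTC: 200 genes/region with 60 confounded genes (loading 2) and AD
  Dirichlet concentration scaled by 0.3; SPV fidelity against true
  proportions and DC edge counts before vs after correction.
- Modularity: two disjoint triangles (Q = 0.5, verified against exhaustive
  partition enumeration), a planted 4-block bipartite model (30+30 genes
  per block, within-block edge probability 0.3, between 0.01) across 10
  Louvain seeds.
- ORA: brute-force tail enumeration for every background ≤ 30; null-module
  calibration over 50 permutations at a 1000-gene background.

## 4. Known limitations

- The Fisher z standard error 1/(n−3) is the Pearson/bivariate-normal
  theory value; Spearman's estimator has slightly larger variance
  (≈ 1.06/(n−3)), making the DC test marginally anticonservative. The
  published procedure makes the same approximation.
- The union-gate selection effect described above means nominal FDR applies
  within the selected universe, not unconditionally.
- SPVs capture relative, not absolute, cell fractions; only as many
  composition axes as supplied marker sets are removed.
- Louvain is a heuristic: Q is a lower bound on the optimum and partitions
  can vary across seeds on weakly modular graphs (the planted-block
  benchmark quantifies stability where structure is real).
- Gene identifiers are opaque strings; identifier translation is a
  user-supplied mapping table, and GO/KEGG content arrives as GMT files —
  no ontology download or propagation is performed.
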