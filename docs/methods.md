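# Methods

This note documents the statistical models, the defaults and their
rationale, the synthetic-data design, and the numerical choices behind
`glyconet`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential expression

The marker-selection stage targets small two-class bulk designs (the
package warns below 3 replicates per class and refuses below 2).

**Filtering.** Genes are kept when their counts-per-million exceed
`cpm_min = 0.5` in at least `cpm_min_samples = 3` samples. The filter is
idempotent and preserves gene order.

**TMM normalization.** Between-sample scaling factors are the
precision-weighted trimmed mean of M-values: for sample *s* against the
reference *r*, over genes expressed in both,
`M_g = log2((y_gs/N_s)/(y_gr/N_r))`, `A_g = ½·log2(y_gs y_gr /(N_s N_r))`,
with two-sided trims of 30% on M and 5% on A and delta-method weights
`w_g = (N_s−y_gs)/(N_s y_gs) + (N_r−y_gr)/(N_r y_gr)` — the published TMM
defaults. The reference is the sample whose 75th CPM percentile is closest
to the mean of those percentiles. Factors are rescaled to geometric mean 1.
A fixed 60×4 fixture with planted composition bias is checked against
factors computed once with edgeR's `calcNormFactors` (agreement to 1e-6).

**log-CPM.** `log2((y + 0.5)/(N·f + 1)·10^6)` with pseudocount 0.5 and
effective library size `N·f`. Strictly increasing in the pseudocount and
deterministic.

**Test statistic.** Per-gene Welch *t* on log-CPM. To avoid infinite
statistics at vanishing within-group variance, each group SD is floored at
the 10th percentile of the per-gene pooled SDs (recomputed per permutation,
so the statistic is exchangeable under the null).

**Permutation p-values.** Class labels are permuted. When the number of
distinct assignments `C(n, n₁)` is at most `max(B, 1000)` all assignments
are enumerated and `p = #{|t_b| ≥ |t_obs|}/C(n, n₁)` exactly (the identity
assignment counts, so `p ≥ 1/C(n, n₁)`); otherwise `B` random permutations
are drawn and the add-one estimator `(1 + #{|t_b| ≥ |t_obs|})/(B + 1)` is
used. Small designs are therefore always exact: 5 vs 5 gives 252
assignments, so the default `B = 999` runs the exhaustive branch. Ties are
compared with a 1e-12 slack.

**Selection.** BH step-up FDR across genes; selected ⇔ `p ≤ 0.05`,
`FDR ≤ 0.1`, `|log2FC| ≥ 1`. The twofold gate is applied symmetrically on
the log2 scale. Already-log microarray matrices (scale `log2`) enter
directly at the test, skipping filter/TMM/log-CPM.

**Known power limitation.** With 5 vs 5 samples the exhaustive permutation
p-values live on the grid k/252 with minimum 2/252 ≈ 0.0079 (each
assignment and its complement give the same |t|). Under BH at FDR 0.1 with
~2,000 genes, only genes at the grid minimum — i.e. genes whose observed
|t| is the strict maximum over all 252 assignments — can clear the FDR
gate; the second grid level (4/252) would need ≥ 317 genes at or below it.
Weakly expressed genes with a true 4-fold shift often cannot reach that
rank for *any* assignment-ranking statistic (their groups are not
separable), which caps attainable sensitivity in the high-dispersion /
low-count tail. A moderated parametric test with smooth p-values does not
share this cap, but exchanges exactness for distributional assumptions;
this package deliberately keeps the exact permutation contract and reports
the realized sensitivity and false-discovery proportion in the acceptance
script rather than hiding the trade-off.

## Family reduction

Symbols are matched case-insensitively after whitespace stripping; approved
symbols map to themselves; unmapped inputs and post-mapping duplicates are
reported, never silently dropped. Families are ranked per direction (up and
down lists separately — mirroring the three-category bookkeeping of
blood / brain / treated analyses; a joint mode is available via
`family_per_direction: false`). Ties share the minimum rank (the Excel RANK
convention). The selection cutoff defaults to ≥ 5 members. Glycogenes found
among the selected DEGs are appended to the reduced list regardless of
family rank, since the glyco endpoint is the point of the downstream
analysis.

## Over-representation analysis

Upper-tail hypergeometric test per set: `p = P(X ≥ k)` with
`N = |universe|`, `K = |set|`, `n = |query ∩ universe|`, `k = |overlap|`,
computed with `scipy.stats.hypergeom.sf`. The universe defaults to the
union of set members; for expression-derived queries the measured-gene
universe should be passed instead (both choices are visible in the output).
Multiple testing uses BH across the whole collection before the p-cutoff
filter (0.05 genes, 0.01 metabolites). No set-size filters are applied by
default. Service-specific corrections of the original web tools (e.g.
g:SCS) are not reimplemented; BH is used uniformly and labelled as such in
outputs.

## Induced network module

All edge types are treated as undirected for the statistic; the type is
kept as an annotation. Candidates are the distance-1 neighbors of the seed
set. For candidate *v* with degree `d(v)` in the full network of `N` nodes
and `n` seeds present, seed-adjacency is modelled as binomial with success
probability `q = d(v)/(N−1)`:

    z = (o − n·q) / sqrt(n·q·(1−q))

Degenerate cases: `q = 1` gives `z = +∞` when the candidate touches every
seed (it is then included at any threshold) and `−∞` otherwise; `q = 0`
cannot occur for a candidate. The default threshold is 20, a deliberately
stringent compactness setting carried over from interactive use of
induced-module services; because this package's statistic is its own,
synthetic-data analyses here use thresholds calibrated on the generators'
nulls (z ≈ 5 comfortably separates a planted connector wired to 8/10 seeds
from the best background candidate in 200-node preferential-attachment
graphs, where background z rarely exceeds ~4). Raising the threshold can
only shrink the module.

Display attributes follow network-visualization conventions: node size by
neighborhood connectivity (mean degree of a node's module neighbors;
isolated nodes 0), node colour by expression state (wine-red up, dark-green
down, grey absent). Exports are GraphML (via networkx) and a minimal XGMML
dialect for Cytoscape with fixed attribute names (`role`, `expr`, `z`,
`nconn`, `etype`); both round-trip through `load_exported`. Edges are
written with lexicographically ordered endpoints in sorted order so exports
are byte-stable across processes.

## Glyco registry and epitope inference

The registry holds glycogene records (categories: lectin, enzyme,
transporter, other, proteoglycan), reactions (code, catalysing enzymes,
substrate, product, pattern id) and epitopes (id, name, required reaction
codes). Referential integrity is enforced at load time and violations are
errors naming the offending row — a knowledge base with dangling references
would silently corrupt every downstream prediction.

Epitope inference formalizes the manual "maximum combination of reaction
codes" lookup as coverage: the available code set is the union over
reactions catalysed by any query enzyme, and an epitope's coverage is
`|required ∩ available| / |required|`. Full coverage (the default
`min_coverage = 1`) is the prediction criterion; partial coverage is
reported when asked for, never silently promoted to a prediction. Coverage
is monotone in the enzyme set, and predictions at a higher threshold are a
subset of those at a lower one.

## Synthetic data

The generators define the conditions under which the pipeline is validated;
they are deliberately simple and fully seeded.

- **Counts**: negative binomial with gene-wise log-normal baseline means
  (meanlog 4, sdlog 1.5 — a typical bulk RNA-seq mean distribution) and
  constant dispersion 0.1; defaults 2,000 genes, 5 vs 5, 10% planted DE at
  |log2FC| = 2 with alternating sign. Variance is `μ + φμ²`.
- **Gene sets**: 50 random 20-member sets over a 1,000-id universe plus one
  planted set sharing 15 of 30 query ids.
- **Networks**: Barabási–Albert graphs (attachment 3) plus one planted
  connector node wired to 80% of 10 seeds; edge types drawn at 70/20/10%.
- **Registries**: planted enzymes catalyse a dedicated reaction block;
  planted epitopes require exactly that block, decoys require it plus one
  code catalysed only by other enzymes (coverage `(m−1)/m` by
  construction).
- **Bundle**: one namespace-coherent set of all inputs, in which the
  planted families are built from the most strongly expressed planted DE
  genes so family/connector/epitope recovery is not confounded by DE power
  at the low-count tail.

What these generators do *not* emulate: library-size heterogeneity and
composition bias beyond TMM's reach, gene–gene correlation, batch effects,
microarray probe-level noise, the topology of curated interactomes, or the
biochemical structure of real glycosylation networks. Passing recovery
tests therefore demonstrates correctness of the algorithms under their own
stated models, not clinical validity on real cohorts.

## Problem sizes

Test-suite and acceptance-script runs use the generator defaults above:
2,000-gene matrices (null calibration and 20-replicate DE recovery),
100-replicate network and gene-set recovery runs, 100–200 random
registries, and one full pipeline execution; these sizes make every
quantity stable to well within its asserted tolerance while keeping a full
run in the seconds-to-minutes range.

## Design choices on open points

- The exact marker statistic of the original interactive tools is not
  published; Welch *t* with permutation calibration was chosen as the
  assumption-light default, configurable in principle at the function
  level.
- The ~twofold gate is read as `|log2FC| ≥ 1` (symmetric up/down).
- The family cutoff is applied per direction; a joint mode exists.
- "Mapped to 19, 25, 32 and 45 reaction codes" style bookkeeping is treated
  as code identifiers, not per-enzyme counts; the loader depends on
  neither reading.
- Metabolite markers are resolved to KEGG ids for set testing; PubChem and
  HMDB ids are carried in reports.

## Limitations

- Sensitivity of the DE stage at 5 vs 5 is capped by the permutation-grid /
  BH interaction described above; designs with ≥ 7 replicates per class or
  pre-normalized inputs with parametric p-values do not hit this cap.
- The module-inclusion z is a binomial approximation that ignores degree
  correlation between seeds; it is validated against planted structure, not
  against any proprietary service statistic.
- Gene-set testing is overlap-based ORA only; no ranked GSEA.
- The registry TSV dialects are this package's own; real curated exports
  must be mapped onto them column-wise by the user.
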