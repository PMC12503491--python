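# Methods

This note documents the models, parameter choices and numerical
conventions behind `dvcatlas`, and what the synthetic testbed does and
does not show about real single-nucleus data.

## Data model

Counts are unique-molecule (UMI) integers in an `AnnData`, cells as
observations and genes as variables; `obs` carries `sample_id`,
`condition` (fasted / adlib / refed / licl / vehicle / none) and
`species`.  On disk the matrix uses the 10x-style triplet (matrix-market
coordinate file, genes × cells, 1-based indices as the format requires;
0-based and cells × genes in memory).  Hierarchies are flat record lists
`(name, layer, parent, species_origin)` — deliberately not nested, so
diffs and manual curation stay readable.

## Synthetic generator

The generator emulates the statistical skeleton of a multi-sample
droplet experiment, not its full biological texture.  Counts for cell
*i*, gene *g* are negative binomial with mean

```
mu = baseline_g · 2^(marker effect) · 2^(batch shift) · 2^(condition effect) · s_i
```

and a single genome-wide dispersion (`theta = 2` by default; per-gene
dispersion is not modeled because QC/marker/label logic, not expression
realism, is under test).  Per-gene baselines `baseline_g` are log-normal
(sigma 0.8) draws from a dedicated `abundance_seed`, *separate* from the
sampling seed: baseline abundance is biology of the gene universe, so
two datasets simulated over the same universe share it — without this,
harmonization and label transfer between datasets would be impossible by
construction.  Size factors `s_i` are log-normal (sigma 0.35), which
also produces the UMI/gene-ratio tail the QC percentile filter targets.

Doublets are sums of two independently drawn singlet count vectors,
created before depth thinning so doublet and low-quality states are
disjoint and truth labels unambiguous.  Low-quality cells are binomially
thinned to `lowq_depth_factor` (0.15) of their depth.

The packaged study conditions (`default_config`): 1,500 genes; 8
identities in a 3-layer hierarchy (5 neuronal in 3 classes, 3 glial in
2 classes); 8 planted markers per identity with log2FC drawn from
[2, 3.5] plus 4 class-level markers at 2.5; 6 samples × 450 cells across
ad-libitum / fasted / refed conditions with batch shifts of ±0.1 log2;
6 % doublets, 5 % low-quality cells; a 20-gene refeeding program
(log2FC 1.5) planted in the excitatory class.  These sizes keep the full
pipeline to seconds per run while leaving ≥ 300 cells per side for
effect-size checks; they are desk-scale stand-ins for a 30-animal
experiment, so absolute cell numbers are not comparable to a real atlas.

The cross-species variant reuses species-A marker programs for shared
identities through a 1:1 ortholog map covering 90 % of genes (the rest
are species-A-specific), keeps species-A baselines on orthologs
(conserved biology), and gives novel species-B identities fresh 8-gene
programs at log2FC 3.  With zero dropout the gene universes are in
bijection.

What passing tests do *not* show: ambient RNA, per-gene dispersion
structure, spliced/unspliced mixtures, spatial effects, and realistic
batch geometry are all absent, so recovery rates here are upper bounds
on real-data behavior.

## Quality control

Per-cell statistics are exact integer counts; the ratio
UMI-total / genes-detected is undefined (flagged) for empty cells.  The
ratio filter is generative-rule-first: the threshold is the 2nd
percentile of the ratio distribution within each sample, with the fixed
constant 1.22 retained as an exact-reproduction mode — the constant is
one realized instance of the percentile rule.  Both filters are strict
on the documented side (genes ≥ 500 inclusive, ratio strictly >).
"Median RNA content" of a cluster is the median per-cell UMI total; the
cluster filter removes clusters strictly below the first quartile of
cluster medians.  Quantiles use linear interpolation (type 7)
everywhere.  With fewer than 4 clusters the quartile is unstable and
nothing is removed (warning).

Doublet scoring, per sample in sorted-barcode order (making scores
invariant to cell order): `round(pN·n/(1−pN))` artificial doublets
(pN = 0.25) are synthesized by averaging random cell pairs; real and
artificial cells are co-embedded (normalize → 500 HVG → 30 PCs) and a
cell's score is the fraction of artificial neighbours among its
`round(pK·(n + n_art))` nearest, pK = 0.10.  pK was fixed by a pilot
sweep on the two-identity benchmark (heterotypic recall 0.63–0.79
across seeds); the upstream method's pK sweep is intentionally not
reproduced.  The expected call count is `rate · n`, multiplied by the
heterotypic fraction `1 − Σ fᵢ²` over annotation frequencies when an
annotation is supplied; the rate comes from a loaded-nuclei lookup
table (linear interpolation).

## Normalization, HVG, embedding, clustering

Log-normalization is `ln(1 + 10000·c/total)`; `expm1` of a cell's
values sums back to 10,000 exactly.  Variable genes are ranked by a
dispersion (variance/mean) z-score computed within 20 *equal-count*
bins of mean expression, ties broken by gene id.  UMI-count regression
is per-gene simple linear regression (closed form); scaling clips
z-scores at ±10.  PCA signs are fixed by making each component's
largest-magnitude loading positive, so embeddings are deterministic.
The SNN graph uses Jaccard weights over k = 20 neighbourhoods
(self-inclusive), pruned below 1/15; Leiden (RBConfiguration, seeded,
2 iterations) optimizes modularity at the requested resolution.
Communities smaller than 10 cells are dissolved into the nearest larger
cluster by centroid distance — singleton outlier clusters are
meaningless as units of marker discovery or label transfer
(`min_size=1` restores raw output).  Cluster ids are dense, ordered by
decreasing size.

Subclustering re-normalizes, re-embeds and re-clusters target clusters
in isolation over a resolution grid.  "The lowest resolution that
separates the populations" is a manual judgement in practice; it is
operationalized as the smallest grid resolution at which every provided
discriminating marker panel attains its maximum mean expression in a
distinct subcluster.  Without panels the smallest grid resolution is
kept (conservative).

`PCALatent` stores the gene list, centering/scaling and loadings fitted
on a reference so queries project into the *same* coordinates — the
shared latent used for tree training, prediction and harmonization.
Atlas-scale batch integration is out of scope; optional per-sample mean
centering in PC space is the only correction offered.

## Reference consensus

The reference scorer is a deliberately simplified correlation assigner:
Spearman rank correlation between a cell and each identity centroid
over the union of per-identity top-50 enriched genes, ties between
labels broken by label order.  Rank correlation makes the score
invariant to per-cell monotone transforms.  The unanimity rule is exact:
a consensus label exists iff every reference maps to it through the
common vocabulary; unassigned counts as disagreement.  Unanimity is
required at the common-vocabulary level (neuron, astrocyte, …), since
heterogeneous references rarely share fine-grained nomenclature.

## Markers and differential expression

log2FC is `log2((mean expm1(a) + ε)/(mean expm1(b) + ε))` with
ε = 1e−9, so the printed thresholds (0.25, 0.1, 1, 4, 8) apply to a
defined quantity.  Genes with |log2FC| below the floor or detected in
fewer than 10 % of both groups are excluded before testing.  The
default test is the Wilcoxon rank-sum (asymptotic, vectorized); a
two-part hurdle variant (detection chi-square + rank-sum on expressing
cells, Fisher-combined) is selectable — the aggregation rule, not the
base test, is the load-bearing statistic.  Correction is Bonferroni
over tested genes by default, Benjamini–Hochberg selectable.

Conserved-marker aggregation uses the intersection of genes tested in
every sample (the conservative choice), mean log2FC strictly > 1,
significance (adjusted p ≤ 0.05) in strictly more than 80 % of samples,
and detection ≥ 40 % computed on the pooled cluster (the per-sample
alternative is noted but not default).  Display rules: balloon —
(detection > 0.80 ∧ log2FC > 4) ∨ (detection > 0.70 ∧ log2FC > 8);
heatmap — upregulated genes above the 80th percentile of upregulated
mean log2FC.  Top-5 panels rank by mean log2FC with deterministic gene-id
ties; with uniqueness on, a duplicated gene stays only where it ranks
higher.

## Label hierarchy

The tree is rooted at the unlabeled "cell" node; layers strictly
increase along every path (a layer-5 refinement under a layer-4 node is
legal).  `TreeClassifier` fits, for every trained child of every node, a
*binary* one-vs-rest logistic scorer (child members vs the node's other
members).  Binary scorers give absolute membership probabilities — a
multinomial softmax can only rank siblings and would force-route cells
that resemble no child, which is precisely the case that must be
rejected.  The acceptance threshold per child is the larger of 0.6 and
the 1 % lower order statistic of the child's own training-member scores
("lower" so separable training data is never self-rejected).  Descent
stops when no child clears its threshold; the stopping node is the
label, `rejected` at the root.  Predictions are ancestor-consistent by
construction and asserted per batch in the tests.

Harmonization of a second labeled dataset, per query label: predict its
cells through the tree; if ≥ θ = 0.6 of them stop at one node, check
reciprocity by nearest-query-centroid classification of the node's own
training cells — reciprocal (≥ θ − 0.1) means *merged*, otherwise the
label is *attached* one layer below the node; if the mass splits across
non-sibling nodes (≥ 0.3 each) the label is a *conflict* and the tree is
unchanged (the multi-parent case); anything else is *rejected*.
Re-harmonizing a merged label changes nothing (idempotence).  Manual
edits (`move_node`, `add_parent`, `rename`) re-validate and recompute
subtree layers; cycles are refused.

The packaged rodent hierarchy encodes the published atlas structure —
123 labels: 4 layer-1, 20 layer-2 (18 mouse classes plus the rat-only
immunity-akin and ortus-akin classes) and 99 high-resolution labels
(50 mouse layer-3, 9 layer-4, 2 layer-5 monoamine refinements).  The
per-layer counts are exact; node membership within classes is a
plausible reconstruction where the source figures are ambiguous, and
the fixture header says so.

## Cross-species transfer

Ortholog tables are reduced to 1:1 pairs (duplicated genes dropped and
flagged; genes absent from the map counted species-specific).  Donor
identities are top-5 marker panels translated through the map; panels
with fewer than 2 surviving genes are excluded as low-coverage.  A query
cluster's score per identity is the mean z-scored expression of the
panel over the cluster's cells; it is *assigned* to the argmax identity
when the score reaches s_min = 0.5 with margin m_min = 0.25 over the
runner-up (z-score units; explicit stand-ins for judgements made
manually in practice, calibrated once on the packaged benchmark),
*novel_candidate* otherwise, and *unspecific* when additionally its own
de-novo markers appear in no donor panel.  The packaged benchmark
clusters the query species at resolution 2.0 — a smaller dataset needs
finer clustering to keep one identity per cluster unit.

## Co-expression

A cell expresses a gene set when any member gene has log-normalized
value strictly greater than zero — the printed rule, no count-level
minimum.  The transmission panel groups 10 genes into 8 systems
(Gad1/Gad2 → GABA; Slc6a5 → glycine; Slc17a6 → glutamate;
Slc18a2 + Ddc → monoamine; Sst; Npy; Cck; Slc5a7 → acetylcholine);
the alias "Addc" seen in print maps to Ddc (aromatic L-amino-acid
decarboxylase), consistent with the monoamine system — the substitution
is recorded here rather than silently failing on real gene tables.
Co-transmission means ≥ 2 positive systems after collapsing genes to
systems; gene-level counting is exposed as an option because the
system-level convention is one of two defensible readings.

## Condition contrasts

Contrasts are computed within one identity at a chosen layer (layer 2
by default, matching how per-class results are reported), with the
0.1 log2FC floor; log2FC > 0 means higher in the first-named condition.
Effect bins over significant genes default to [0.5, 1.0) and ≥ 1.0 with
a below-floor bin completing the partition; overlaps intersect
upregulated significant genes at a fold-change cut.

## Known limitations

* The synthetic testbed is deliberately minimal (see above); passing
  recovery thresholds here does not certify performance on real tissue.
* The reference scorer omits the iterative fine-tuning of the method it
  simplifies; the tree classifier replaces the cited harmonization
  package's kNN/SVM internals with linear scorers.
* Batch correction is reduced to per-sample centering; atlas-scale
  integration must happen upstream.
* The packaged hierarchy's node names inside classes are
  reconstructions; only the per-layer counts are authoritative.
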