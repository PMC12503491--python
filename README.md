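# dvcatlas

Toolkit for building hierarchical single-nucleus RNA-seq cell atlases of
the brainstem **dorsal vagal complex** (DVC) — the area postrema, nucleus
of the solitary tract and dorsal motor nucleus of the vagus.  It is aimed
at researchers who want to reproduce, extend or stress-test the
atlas-construction computation itself: every stage runs end-to-end on
synthetic droplet counts with planted ground truth, so no sequencing data
or downloads are required.

## What it implements

* **Adaptive quality control** — cells kept when genes detected ≥ 500 and
  the UMI/genes-detected ratio strictly exceeds the 2nd percentile of its
  sample (realized value ~1.22 on the source data, available as a fixed
  mode); clusters at resolution 1.0 whose median UMI content falls below
  the first quartile of cluster medians are removed.
* **Doublet scoring** — artificial-nearest-neighbour scores with the
  expected call count `round(rate · n · (1 − Σᵢ fᵢ²))`, where the sum of
  squared annotation frequencies models homotypic doublets.
* **Clustering** — library scaling to 10,000 UMIs with log transform,
  binned-dispersion z-score HVG selection (20 equal-count bins), UMI-count
  regression, PCA (30 components), Leiden on a shared-nearest-neighbour
  graph, and marker-guided subclustering.
* **Consensus reference labeling** — rank-correlation scoring against
  labeled reference panels with a strict unanimity rule: a cell keeps a
  label only when *every* reference agrees after vocabulary harmonization,
  otherwise it is `unknown`.
* **Conserved markers** — per-sample one-vs-rest differential expression
  aggregated per gene: a marker needs mean log2FC > 1 across samples,
  adjusted p ≤ 0.05 in > 80 % of samples, and detection in ≥ 40 % of the
  cluster's cells; display rules and unique top-5 panels included.
* **Label hierarchy** — a five-layer identity tree with tree-consistent
  prediction and rejection (per-node one-vs-rest linear scorers with
  calibrated thresholds), plus harmonization of a second labeled dataset
  with merge / attach-as-child / conflict / reject semantics and manual
  edit operations.  The published 123-label rodent hierarchy ships as a
  flat-record fixture.
* **Cross-species transfer** — donor identities travel as top-5 marker
  panels through a filtered 1:1 ortholog map; query clusters are assigned,
  flagged `novel_candidate`, or `unspecific`.
* **Co-expression profiling** — GABA/glutamate partitions, 8-system
  neurotransmitter co-transmission counts, and pairwise co-expression
  fractions (e.g. the share of *Th*⁺ neurons that also express *Cck*).
* **Condition contrasts** — per-identity differential expression between
  feeding states (effect floor 0.1 log2FC), |log2FC| effect binning, and
  cross-class overlap partitions.
* **Synthetic data** — a negative-binomial multi-sample generator with a
  planted 3-layer identity hierarchy, marker effects of stated log2FC,
  batch shifts, condition programs, heterotypic doublets, depth-thinned
  low-quality cells, and a second-species variant connected by an
  ortholog map.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from dvcatlas import qc, reduce_cluster, markers
from dvcatlas.synthetic_data import default_config, generate_atlas

cfg = default_config(seed=0)          # 6 samples, 8 identities, 3 conditions
adata, truth = generate_atlas(cfg)
print(f"cells x genes: {adata.shape}")

stats = qc.compute_cell_stats(adata)
kept, thresholds = qc.filter_cells(stats)
print(f"kept {len(kept)} / {adata.n_obs} cells "
      f"(sample m1 ratio threshold {thresholds['m1']:.3f})")

sub = adata[kept].copy()
labels = reduce_cluster.run_standard_pipeline(sub, n_top=1000, seed=0)
tk = truth.cells.loc[kept]
singlet = (~(tk.is_doublet | tk.is_lowq)).to_numpy()
ari = adjusted_rand_score(tk.identity[singlet], labels[singlet])
print(f"{len(np.unique(labels))} clusters, ARI vs planted truth = {ari:.3f}")

rec = markers.find_conserved_markers(sub, tk.identity.to_numpy(), "mono_a")
top = rec[rec.is_marker].sort_values("mean_log2fc", ascending=False).head(3)
for g, row in top.iterrows():
    print(f"{g}: mean log2FC {row.mean_log2fc:.2f}, "
          f"significant in {row.significant_fraction:.0%} of samples, "
          f"detected in {row.detection_fraction:.0%} of cells")
```

prints (seed 0):

```
cells x genes: (2700, 1500)
kept 2573 / 2700 cells (sample m1 ratio threshold 1.365)
8 clusters, ARI vs planted truth = 0.991
g1125: mean log2FC 3.45, significant in 100% of samples, detected in 93% of cells
g0702: mean log2FC 3.28, significant in 100% of samples, detected in 97% of cells
g0889: mean log2FC 3.08, significant in 100% of samples, detected in 94% of cells
```

The QC stage dropped the 127 cells whose detected-gene count or
UMI/gene ratio fell below the adaptive thresholds (mostly the planted
low-quality cells), Leiden recovered the eight planted identities almost
exactly (adjusted Rand index 0.991), and the conserved-marker rule
surfaced the monoamine-like identity's strongest planted markers with
full cross-sample support.

A `dvcatlas` command-line interface exposes the same stages
(`simulate`, `qc`, `cluster`, `consensus`, `markers`, `tree`, `transfer`,
`coexpr`, `de`), each taking `--config`, `--seed`, `--out`,
`--log-level`.

## Layout

```
src/dvcatlas/      data_io, synthetic_data, qc, reduce_cluster,
                   reference_consensus, markers, hierarchy, crossspecies,
                   coexpression, de_response, cli
src/dvcatlas/data/ packaged hierarchy fixtures (flat TSV records)
docs/methods.md    models, parameters, numerical choices, limitations
tests/             pytest suite incl. end-to-end acceptance checks
```
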