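"""Three-stage quality control for droplet single-nucleus counts.

Stage 1 filters individual cells on two statistics: the number of genes
detected (kept if >= ``min_genes``, default 500) and the UMI/genes-detected
ratio, which must strictly exceed a threshold.  The ratio threshold is, by
default, the 2nd percentile of the ratio distribution within each sample
(its realized value on the source data was 1.22, available as the fixed
mode for exact-reproduction runs).

Stage 2 clusters the merged data at resolution 1.0, computes each cluster's
median per-cell UMI total ("median RNA content"), and removes clusters
whose median falls strictly below the first quartile of the cluster-median
distribution.

Stage 3 scores doublets with artificial nearest neighbours: per sample,
artificial doublets are synthesized by averaging random cell pairs, real
and artificial cells are co-embedded, and a cell's score is the fraction of
artificial doublets among its nearest neighbours.  The number of cells
called is the expected doublet count (expected rate x n), reduced by the
homotypic fraction modeled as the sum of squared annotation frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from . import reduce_cluster as rc
from .data_io import make_count_matrix
from .errors import ValidationError

__all__ = [
    "QCThresholds", "DoubletConfig", "compute_cell_stats", "filter_cells",
    "filter_clusters_by_median", "score_doublets", "expected_doublet_rate",
]

# loaded-nuclei -> expected multiplet rate, per the droplet platform's
# published loading table (recovered cells, approximately linear)
DOUBLET_RATE_TABLE = {
    500: 0.004, 1000: 0.008, 2000: 0.016, 3000: 0.023, 4000: 0.031,
    5000: 0.039, 6000: 0.046, 7000: 0.054, 8000: 0.061, 9000: 0.069,
    10000: 0.076, 16000: 0.122,
}


def expected_doublet_rate(n_loaded: int) -> float:
    """Linear interpolation of the loading-rate lookup table."""
    xs = np.array(sorted(DOUBLET_RATE_TABLE))
    ys = np.array([DOUBLET_RATE_TABLE[x] for x in xs])
    return float(np.interp(n_loaded, xs, ys))


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int = 500
    ratio_mode: str = "per_sample_percentile"  # or "fixed"
    ratio_percentile: float = 2.0
    ratio_fixed: float = 1.22
    cluster_resolution: float = 1.0
    cluster_median_quantile: float = 0.25

    def __post_init__(self):
        if self.min_genes < 0:
            raise ValidationError("min_genes must be >= 0")
        if not 0 < self.ratio_percentile < 100:
            raise ValidationError("ratio_percentile must lie in (0, 100)")
        if not 0 < self.cluster_median_quantile < 1:
            raise ValidationError("cluster_median_quantile must lie in (0,1)")
        if self.ratio_mode not in ("per_sample_percentile", "fixed"):
            raise ValidationError(f"unknown ratio_mode {self.ratio_mode!r}")


@dataclass(frozen=True)
class DoubletConfig:
    expected_rate: float | None = None  # None: look up from cells loaded
    n_loaded: int = 10_000
    artificial_fraction: float = 0.25   # pN
    neighborhood_fraction: float = 0.10  # pK
    n_pcs: int = 30
    n_hvg: int = 500
    homotypic_adjust: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.expected_rate is not None and not 0 <= self.expected_rate < 1:
            raise ValidationError("expected_rate must lie in [0, 1)")
        if not 0 < self.artificial_fraction < 1:
            raise ValidationError("artificial_fraction must lie in (0, 1)")

    @property
    def rate(self) -> float:
        if self.expected_rate is not None:
            return self.expected_rate
        return expected_doublet_rate(self.n_loaded)


def compute_cell_stats(adata) -> pd.DataFrame:
    """Exact per-cell statistics: genes_detected, umi_total, their ratio.

    The ratio is NaN (flagged ``undefined``) for zero-gene cells.
    """
    X = sp.csr_matrix(adata.X)
    genes_detected = X.getnnz(axis=1)
    umi_total = np.asarray(X.sum(axis=1)).ravel().astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(genes_detected > 0, umi_total / np.maximum(
            genes_detected, 1), np.nan)
    return pd.DataFrame({
        "genes_detected": genes_detected.astype(np.int64),
        "umi_total": umi_total,
        "ratio": ratio,
        "undefined": genes_detected == 0,
        "sample_id": adata.obs["sample_id"].to_numpy(),
    }, index=adata.obs_names)


def filter_cells(stats: pd.DataFrame, th: QCThresholds = QCThresholds()
                 ) -> tuple[pd.Index, dict[str, float]]:
    """Apply the per-cell gene-count and ratio filters.

    A cell is kept iff ``genes_detected >= min_genes`` and its ratio is
    strictly greater than its sample's threshold.  Returns the kept cell
    index and the realized per-sample ratio thresholds.
    """
    thresholds: dict[str, float] = {}
    keep = np.zeros(len(stats), dtype=bool)
    for sample, sub in stats.groupby("sample_id", observed=True, sort=True):
        mode = th.ratio_mode
        valid = sub["ratio"].dropna()
        if mode == "per_sample_percentile" and len(valid) < 2:
            warnings.warn(f"sample {sample}: <2 cells, falling back to the "
                          "fixed ratio threshold", stacklevel=2)
            mode = "fixed"
        if mode == "per_sample_percentile":
            cut = float(np.percentile(valid, th.ratio_percentile))
        else:
            cut = th.ratio_fixed
        thresholds[str(sample)] = cut
        ok = (sub["genes_detected"] >= th.min_genes) & (sub["ratio"] > cut)
        keep[stats.index.get_indexer(sub.index[ok.fillna(False)])] = True
    return stats.index[keep], thresholds


def filter_clusters_by_median(stats: pd.DataFrame, clustering,
                              quantile: float = 0.25
                              ) -> tuple[list, list, pd.DataFrame]:
    """Remove clusters whose median UMI total is below the first quartile
    of the cluster-median distribution (strict <; quantiles use linear
    interpolation).  With fewer than 4 clusters nothing is removed.

    Returns (kept cluster ids, removed cluster ids, per-cluster report).
    """
    clustering = np.asarray(clustering)
    if len(clustering) != len(stats):
        raise ValidationError("clustering length mismatch")
    med = (pd.Series(stats["umi_total"].to_numpy())
           .groupby(clustering).median())
    if len(med) < 4:
        warnings.warn("fewer than 4 clusters: quartile unstable, no cluster "
                      "removed", stacklevel=2)
        report = pd.DataFrame({"median_umi": med, "removed": False})
        return med.index.tolist(), [], report
    q = float(np.quantile(med.to_numpy(), quantile))
    removed = med.index[med < q].tolist()
    kept = med.index[~(med < q)].tolist()
    report = pd.DataFrame({"median_umi": med, "removed": med < q})
    report.attrs["quantile_cut"] = q
    return kept, removed, report


def _score_sample(X_counts, cfg: DoubletConfig, rng) -> np.ndarray:
    """Artificial-nearest-neighbour doublet scores for one sample."""
    import anndata as ad

    n = X_counts.shape[0]
    pN = cfg.artificial_fraction
    n_art = int(round(pN * n / (1 - pN)))
    i = rng.integers(0, n, size=n_art)
    j = rng.integers(0, n, size=n_art)
    art = (X_counts[i] + X_counts[j]) / 2.0
    art = sp.csr_matrix(np.rint(_densify(art)))
    combined = ad.AnnData(X=sp.vstack([sp.csr_matrix(X_counts), art]).tocsr())
    rc.normalize_log(combined)
    genes = rc.select_hvg(combined, n_top=min(cfg.n_hvg, combined.n_vars))
    emb = rc.embed_pca(combined, genes,
                       n_pcs=min(cfg.n_pcs, combined.n_obs - 2))
    k = max(2, int(round(cfg.neighborhood_fraction * (n + n_art))))
    nbrs = NearestNeighbors(n_neighbors=k).fit(emb)
    knn = nbrs.kneighbors(emb[:n], return_distance=False)
    return (knn >= n).mean(axis=1)


def _densify(M):
    return M.toarray() if sp.issparse(M) else np.asarray(M)


def score_doublets(adata, cfg: DoubletConfig = DoubletConfig(),
                   annotation=None) -> pd.DataFrame:
    """Per-cell doublet score in [0, 1] and boolean call.

    Scores are computed per sample.  The called count per sample is
    ``round(rate * n)``; with ``homotypic_adjust`` and an annotation, the
    count is scaled by ``1 - sum_i f_i^2`` over annotation frequencies
    (the heterotypic fraction), and the top-scoring cells up to that count
    are called.
    """
    if annotation is None and cfg.homotypic_adjust:
        warnings.warn("no annotation given: homotypic adjustment skipped",
                      stacklevel=2)
    ann = None if annotation is None else np.asarray(annotation)
    score = np.zeros(adata.n_obs)
    call = np.zeros(adata.n_obs, dtype=bool)
    order = adata.obs["sample_id"]
    for si, sample in enumerate(sorted(order.unique())):
        m = np.flatnonzero((order == sample).to_numpy())
        n = int(m.size)
        if n < 50:
            raise ValidationError(
                f"sample {sample}: need >= 50 cells for doublet scoring")
        # canonical barcode order makes scores invariant to cell order
        canon = m[np.argsort(adata.obs_names[m])]
        s = _score_sample(_densify(adata.X[canon]), cfg,
                          np.random.default_rng([cfg.seed, si]))
        score[canon] = s
        m = canon
        expected = cfg.rate * n
        if cfg.homotypic_adjust and ann is not None:
            f = pd.Series(ann[m]).value_counts(normalize=True).to_numpy()
            expected *= 1.0 - float((f ** 2).sum())
        n_call = int(round(expected))
        if n_call > 0:
            idx = np.argsort(-s, kind="stable")[:n_call]
            local = np.zeros(n, dtype=bool)
            local[idx] = True
            call[m] = local
    return pd.DataFrame({"doublet_score": score, "doublet_call": call,
                         "sample_id": order.to_numpy()},
                        index=adata.obs_names)
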