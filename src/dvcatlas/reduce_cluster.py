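"""Normalization, variable-gene selection, embedding and graph clustering.

The processing recipe is the standard droplet workflow: counts are scaled
to 10,000 UMIs per cell and log-transformed (``ln(1 + 1e4 * c / total)``);
highly variable genes are ranked by a dispersion z-score computed within 20
equal-count bins of mean expression; the library-size covariate can be
regressed out gene-wise; cells are embedded with PCA on the scaled (z-score,
clipped at +/-10) variable genes; and clusters come from Leiden modularity
optimization on a shared-nearest-neighbour graph built from the first 30
principal components.
"""

from __future__ import annotations

import warnings

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError

__all__ = [
    "normalize_log", "select_hvg", "regress_covariate", "embed_pca",
    "cluster_graph", "subcluster", "run_standard_pipeline",
]

TARGET_SUM = 10_000.0
Z_CLIP = 10.0


def normalize_log(adata, layer_out: str = "lognorm"):
    """Scale each cell to 10,000 UMIs and log-transform.

    Writes ``adata.layers[layer_out]`` (sparse, ``ln(1 + 1e4 * count /
    cell_total)``) and returns ``adata``.  All-zero cells stay all-zero.
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    scale = np.divide(TARGET_SUM, totals, out=np.zeros_like(totals),
                      where=totals > 0)
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    adata.layers[layer_out] = X.tocsr()
    return adata


def _dense(M) -> np.ndarray:
    return M.toarray() if sp.issparse(M) else np.asarray(M)


def select_hvg(adata, n_bins: int = 20, n_top: int = 2000,
               layer: str = "lognorm") -> list[str]:
    """Top variable genes by binned dispersion z-score.

    Genes are placed in ``n_bins`` equal-count bins of mean log-normalized
    expression; dispersion (variance / mean) is z-scored within each bin;
    the ``n_top`` genes by z-score are returned, ties broken by gene id.
    """
    X = adata.layers[layer]
    mean = np.asarray(X.mean(axis=0)).ravel()
    if sp.issparse(X):
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        sq = np.asarray(np.square(X).mean(axis=0)).ravel()
    var = np.maximum(sq - mean ** 2, 0.0)
    nonzero = mean > 0
    if nonzero.sum() < n_bins:
        raise ValidationError(f"need >= {n_bins} genes with nonzero mean")
    disp = np.divide(var, mean, out=np.zeros_like(var), where=nonzero)
    df = pd.DataFrame({"gene": adata.var_names, "mean": mean, "disp": disp})
    df = df[nonzero].copy()
    df["bin"] = pd.qcut(df["mean"].rank(method="first"), q=n_bins,
                        labels=False, duplicates="drop")
    grp = df.groupby("bin")["disp"]
    mu, sd = grp.transform("mean"), grp.transform("std").replace(0, np.nan)
    df["z"] = ((df["disp"] - mu) / sd).fillna(0.0)
    if n_top > len(df):
        warnings.warn(f"n_top={n_top} exceeds {len(df)} usable genes; "
                      "returning all", stacklevel=2)
        n_top = len(df)
    df = df.sort_values(["z", "gene"], ascending=[False, True])
    return df["gene"].head(n_top).tolist()


def regress_covariate(adata, covariate=None, layer: str = "lognorm",
                      layer_out: str = "regressed"):
    """Per-gene simple linear regression on a per-cell covariate.

    Default covariate is the per-cell UMI total.  Residuals (dense) are
    stored in ``adata.layers[layer_out]``; with a constant covariate this
    reduces to per-gene mean-centering.
    """
    Y = _dense(adata.layers[layer]).astype(float)
    if covariate is None:
        covariate = np.asarray(sp.csr_matrix(adata.X).sum(axis=1)).ravel()
    x = np.asarray(covariate, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    ym = Y.mean(axis=0)
    if denom == 0:
        resid = Y - ym
    else:
        beta = (xc @ (Y - ym)) / denom
        resid = Y - ym - np.outer(xc, beta)
    adata.layers[layer_out] = resid
    return adata


def _scale_clip(Y: np.ndarray) -> np.ndarray:
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0)
    sd[sd == 0] = 1.0
    return np.clip((Y - mu) / sd, -Z_CLIP, Z_CLIP)


def embed_pca(adata, genes: list[str], n_pcs: int = 30, center: bool = True,
              scale: bool = True, layer: str = "lognorm",
              key: str = "X_pca") -> np.ndarray:
    """PCA embedding on the selected genes of the given layer.

    The sign of each component is fixed by making its largest-magnitude
    loading positive, so the embedding is deterministic.  Stored in
    ``adata.obsm[key]`` and returned.
    """
    sub = adata[:, genes]
    Y = _dense(sub.layers[layer]).astype(float)
    if scale:
        Y = _scale_clip(Y)
    elif center:
        Y = Y - Y.mean(axis=0)
    n_pcs = min(n_pcs, min(Y.shape) - 1) if min(Y.shape) > 1 else 1
    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(Y)
    flip = np.sign(pca.components_[
        np.arange(n_pcs), np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    emb = emb * flip
    adata.obsm[key] = emb
    adata.uns[f"{key}_variance_ratio"] = pca.explained_variance_ratio_
    return emb


class PCALatent:
    """Shared linear latent: fit on a reference, project any query.

    Stores the gene list, per-gene centering/scaling and PCA loadings
    fitted on the reference, so reference and query land in the same
    coordinate system (the shared latent used for tree training,
    prediction and harmonization).  Missing query genes contribute zeros.
    """

    def __init__(self, genes: list[str], n_pcs: int = 30, scale: bool = True):
        self.genes = list(genes)
        self.n_pcs = n_pcs
        self.scale = scale

    def _matrix(self, adata, layer: str) -> np.ndarray:
        present = [g for g in self.genes if g in adata.var_names]
        Y = np.zeros((adata.n_obs, len(self.genes)))
        if present:
            sub = _dense(adata[:, present].layers[layer]).astype(float)
            pos = {g: i for i, g in enumerate(self.genes)}
            Y[:, [pos[g] for g in present]] = sub
        return Y

    def fit(self, adata, layer: str = "lognorm") -> "PCALatent":
        Y = self._matrix(adata, layer)
        self.mu_ = Y.mean(axis=0)
        sd = Y.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd_ = sd if self.scale else np.ones_like(sd)
        Z = np.clip((Y - self.mu_) / self.sd_, -Z_CLIP, Z_CLIP)
        n_pcs = min(self.n_pcs, min(Z.shape) - 1)
        pca = PCA(n_components=n_pcs, svd_solver="full")
        pca.fit(Z)
        flip = np.sign(pca.components_[
            np.arange(n_pcs), np.abs(pca.components_).argmax(axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = pca.components_ * flip[:, None]
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self

    def transform(self, adata, layer: str = "lognorm") -> np.ndarray:
        Z = np.clip((self._matrix(adata, layer) - self.mu_) / self.sd_,
                    -Z_CLIP, Z_CLIP)
        return Z @ self.components_.T

    def fit_transform(self, adata, layer: str = "lognorm") -> np.ndarray:
        return self.fit(adata, layer).transform(adata, layer)


def _snn_graph(emb: np.ndarray, k: int) -> igraph.Graph:
    """Shared-nearest-neighbour graph with Jaccard edge weights."""
    n = emb.shape[0]
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    knn = nn.kneighbors(return_distance=False)
    knn = np.hstack([np.arange(n)[:, None], knn])  # include self
    rows = np.repeat(np.arange(n), knn.shape[1])
    A = sp.csr_matrix((np.ones(rows.size), (rows, knn.ravel())), shape=(n, n))
    shared = (A @ A.T).tocoo()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    union = 2 * (k + 1) - s
    w = s / union
    keep = w >= 1.0 / 15.0  # prune weak links, keeps the graph sparse
    g = igraph.Graph(n=n, edges=list(zip(r[keep].tolist(), c[keep].tolist())))
    g.es["weight"] = w[keep].tolist()
    return g


def cluster_graph(emb: np.ndarray, k: int = 20, resolution: float = 1.0,
                  seed: int = 0, min_size: int = 10) -> np.ndarray:
    """Leiden modularity clustering of the SNN graph; dense ids from 0.

    Communities smaller than ``min_size`` (graph outliers, typically
    singletons) are dissolved into the nearest larger cluster by centroid
    distance; set ``min_size=1`` to keep them.
    """
    emb = np.asarray(emb, dtype=float)
    if k >= emb.shape[0]:
        raise ValidationError(f"k={k} must be < n_cells={emb.shape[0]}")
    g = _snn_graph(emb, k)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
        n_iterations=2)
    labels = np.asarray(part.membership)
    sizes = pd.Series(labels).value_counts()
    big = sizes.index[sizes >= min_size]
    if 0 < len(big) < len(sizes):
        cen = np.stack([emb[labels == c].mean(axis=0) for c in big])
        tiny = ~np.isin(labels, big)
        d = ((emb[tiny][:, None, :] - cen[None, :, :]) ** 2).sum(axis=2)
        labels = labels.copy()
        labels[tiny] = np.asarray(big)[d.argmin(axis=1)]
    # dense renumber by decreasing cluster size, ties by original id
    counts = pd.Series(labels).value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.asarray([remap[v] for v in labels])


def run_standard_pipeline(adata, n_top: int = 2000, n_pcs: int = 30,
                          k: int = 20, resolution: float = 1.0,
                          seed: int = 0, regress: bool = True,
                          sample_center: bool = False) -> np.ndarray:
    """Normalize -> HVG -> (regress) -> PCA -> SNN Leiden; returns labels.

    ``sample_center`` subtracts per-sample means in PC space, a light
    stand-in for atlas-scale batch integration.
    """
    normalize_log(adata)
    genes = select_hvg(adata, n_top=n_top)
    layer = "lognorm"
    if regress:
        regress_covariate(adata)
        layer = "regressed"
    emb = embed_pca(adata, genes, n_pcs=n_pcs, layer=layer)
    if sample_center and "sample_id" in adata.obs:
        emb = emb.copy()
        for s in adata.obs["sample_id"].unique():
            m = (adata.obs["sample_id"] == s).to_numpy()
            emb[m] -= emb[m].mean(axis=0)
        adata.obsm["X_pca"] = emb
    labels = cluster_graph(emb, k=k, resolution=resolution, seed=seed)
    adata.obs["cluster"] = pd.Categorical(labels.astype(str))
    return labels


def subcluster(adata, clustering: np.ndarray, targets: list[int],
               resolution_grid=(0.1, 0.25, 0.5, 1.0),
               marker_panels: dict[str, list[str]] | None = None,
               n_top: int = 500, n_pcs: int = 15, k: int = 15,
               seed: int = 0) -> tuple[np.ndarray, dict]:
    """Re-cluster the target clusters' cells in isolation.

    Each target is re-normalized, re-embedded and re-clustered over the
    resolution grid.  With ``marker_panels`` given, the chosen resolution is
    the smallest at which every panel attains its maximum mean expression
    in a distinct subcluster (the operational form of "the lowest
    resolution that separates the populations"); without panels the
    smallest grid resolution is kept.  Non-target clusters are unchanged.

    Returns dense re-numbered labels and a report mapping each target to
    the resolution used and its subcluster count.
    """
    clustering = np.asarray(clustering)
    new = clustering.astype(object).copy()
    report = {}
    for t in targets:
        mask = clustering == t
        sub = adata[mask].copy()
        normalize_log(sub)
        genes = select_hvg(sub, n_top=min(n_top, sub.n_vars))
        emb = embed_pca(sub, genes, n_pcs=min(n_pcs, sub.n_obs - 2))
        chosen, chosen_res = None, None
        for res in resolution_grid:
            labels = cluster_graph(emb, k=min(k, sub.n_obs - 1),
                                   resolution=res, seed=seed)
            if marker_panels is None:
                chosen, chosen_res = labels, res
                break
            if _panels_separated(sub, labels, marker_panels):
                chosen, chosen_res = labels, res
                break
        if chosen is None:  # no grid point separated the panels: keep finest
            chosen, chosen_res = labels, res
        new[mask] = [f"{t}.{s}" for s in chosen]
        report[t] = {"resolution": chosen_res,
                     "n_subclusters": int(len(np.unique(chosen)))}
    # dense renumber, preserving non-target ids first
    uniq = sorted({str(v) for v in new}, key=lambda s: (len(s.split(".")), s))
    remap = {u: i for i, u in enumerate(uniq)}
    return np.asarray([remap[str(v)] for v in new]), report


def _panels_separated(sub, labels: np.ndarray,
                      panels: dict[str, list[str]]) -> bool:
    """True if every panel peaks (mean lognorm) in a distinct subcluster."""
    X = _dense(sub.layers["lognorm"])
    names = list(sub.var_names)
    peaks = []
    for genes in panels.values():
        idx = [names.index(g) for g in genes if g in names]
        if not idx:
            return False
        panel_mean = X[:, idx].mean(axis=1)
        means = [panel_mean[labels == c].mean() for c in np.unique(labels)]
        peaks.append(int(np.argmax(means)))
    return len(set(peaks)) == len(peaks)
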