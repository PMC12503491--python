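"""Multi-reference cell scoring and the unanimity consensus rule.

Cells are scored against each labeled reference panel by Spearman rank
correlation between the cell's log-normalized profile and each identity
centroid, over the union of the panel's per-identity top marker genes (a
deliberately simplified correlation assigner; the consensus rule is the
part implemented exactly).  Each reference's labels are mapped into a
common vocabulary, and a cell's consensus label is set only when every
reference agrees after mapping — a conflicting or unassigned label from
any single reference makes the cell "unknown".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .errors import ValidationError

__all__ = [
    "ReferencePanel", "build_panel_from_labeled", "score_reference",
    "consensus", "score_marker_panels", "DEFAULT_COMMON_VOCABULARY",
    "UNKNOWN", "UNASSIGNED",
]

UNKNOWN = "unknown"
UNASSIGNED = "unassigned"

# default harmonization targets for the common coarse classes
DEFAULT_COMMON_VOCABULARY = (
    "neuron", "astrocyte", "oligodendrocyte", "opc", "microglia", "vascular",
)


@dataclass
class ReferencePanel:
    """A labeled reference: identity centroids over its own gene universe."""
    name: str
    centroids: pd.DataFrame  # genes x identities, non-negative

    def __post_init__(self):
        if self.centroids.columns.has_duplicates:
            raise ValidationError(f"panel {self.name}: duplicate labels")
        if (self.centroids.to_numpy() < 0).any():
            raise ValidationError(f"panel {self.name}: negative profile")

    @property
    def labels(self) -> list[str]:
        return list(self.centroids.columns)

    def top_marker_genes(self, n_top: int = 50) -> list[str]:
        """Union over identities of the top genes by centroid enrichment
        (centroid value minus the mean of the other centroids)."""
        C = self.centroids
        out: set[str] = set()
        for lab in C.columns:
            others = C.drop(columns=lab).mean(axis=1)
            enrich = (C[lab] - others).sort_values(ascending=False)
            out.update(enrich.head(n_top).index)
        return sorted(out)


def build_panel_from_labeled(adata, labels, name: str,
                             layer: str = "lognorm") -> ReferencePanel:
    """Centroid panel (mean log-normalized profile per label) from a
    labeled dataset."""
    labels = np.asarray(labels)
    X = adata.layers[layer]
    cols = {}
    for lab in sorted(pd.unique(labels)):
        m = labels == lab
        cols[str(lab)] = np.asarray(X[m].mean(axis=0)).ravel()
    return ReferencePanel(name, pd.DataFrame(cols, index=adata.var_names))


def score_reference(adata, panel: ReferencePanel, n_top: int = 50,
                    layer: str = "lognorm") -> pd.DataFrame:
    """Best label and Spearman score per cell against one reference.

    Rank correlation makes the score invariant to per-cell monotone
    transforms of expression.  Ties between labels break by label order.
    """
    genes = [g for g in panel.top_marker_genes(n_top)
             if g in adata.var_names]
    if not genes:
        raise ValidationError(
            f"no shared genes between query and panel {panel.name!r}")
    X = adata[:, genes].layers[layer]
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    cell_ranks = scipy.stats.rankdata(X, axis=1)
    cen_ranks = scipy.stats.rankdata(
        panel.centroids.loc[genes].to_numpy(), axis=0)
    cr = cell_ranks - cell_ranks.mean(axis=1, keepdims=True)
    kr = cen_ranks - cen_ranks.mean(axis=0, keepdims=True)
    num = cr @ kr
    denom = np.outer(np.linalg.norm(cr, axis=1),
                     np.linalg.norm(kr, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    best = corr.argmax(axis=1)  # argmax takes the first max: label order
    return pd.DataFrame({
        "label": np.asarray(panel.labels, dtype=object)[best],
        "score": corr[np.arange(len(best)), best],
    }, index=adata.obs_names)


def consensus(per_reference: pd.DataFrame,
              harmonization_map: dict[str, str]) -> pd.Series:
    """Unanimity consensus across references.

    ``per_reference`` has one column per reference holding that
    reference's best label per cell ("unassigned" allowed);
    ``harmonization_map`` sends reference labels into the common
    vocabulary.  The consensus is the common label iff every reference
    maps to it; an unassigned or unmapped label counts as disagreement.
    """
    if per_reference.shape[1] == 0:
        raise ValidationError("need >= 1 reference column")
    mapped = per_reference.apply(
        lambda col: col.map(lambda v: harmonization_map.get(v, UNASSIGNED)))
    first = mapped.iloc[:, 0]
    agree = mapped.eq(first, axis=0).all(axis=1) & (first != UNASSIGNED)
    return pd.Series(np.where(agree, first, UNKNOWN),
                     index=per_reference.index, name="consensus")


def score_marker_panels(adata, clustering,
                        panels: dict[str, list[str]],
                        layer: str = "lognorm"
                        ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Mean scaled expression of each marker panel per cluster.

    Genes are z-scored across all cells; value(cluster, panel) is the mean
    over panel genes of the per-gene z-score averaged over the cluster's
    cells.  Panel genes absent from the data (or with zero variance) are
    skipped and reported.
    """
    if not panels or any(len(g) == 0 for g in panels.values()):
        raise ValidationError("panels must be non-empty")
    clustering = np.asarray(clustering)
    X = adata.layers[layer]
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    usable = sd > 0
    Z = np.zeros_like(X)
    Z[:, usable] = (X[:, usable] - mu[usable]) / sd[usable]
    gene_idx = {g: j for j, g in enumerate(adata.var_names)}
    clusters = sorted(pd.unique(clustering).tolist())
    table = pd.DataFrame(index=pd.Index(clusters, name="cluster"),
                         columns=sorted(panels), dtype=float)
    skipped: dict[str, list[str]] = {}
    for pname in sorted(panels):
        idx, missing = [], []
        for g in panels[pname]:
            j = gene_idx.get(g)
            if j is None or not usable[j]:
                missing.append(g)
            else:
                idx.append(j)
        skipped[pname] = missing
        if not idx:
            table[pname] = np.nan
            continue
        for c in clusters:
            table.loc[c, pname] = float(Z[np.ix_(clustering == c, idx)].mean())
    return table, skipped
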