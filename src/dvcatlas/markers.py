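"""Differential expression and the conserved-marker aggregation rule.

``de_test`` is a two-group test on log-normalized values: genes are
pre-filtered on effect size (|log2FC| >= ``min_logfc``) and detection
(expressed in >= ``min_detect`` of at least one group), tested with the
Wilcoxon rank-sum test (or a two-part hurdle variant), and corrected for
multiple testing over the tested genes (Bonferroni by default).

``conserved_markers`` aggregates per-sample DE results for one cluster:
a gene is a marker iff its mean log2FC across samples is strictly > 1, it
is significant (adjusted p <= 0.05) in strictly more than 80% of samples,
and it is detected in at least 40% of the cluster's cells.

log2FC is ``log2((mean(expm1 a) + eps) / (mean(expm1 b) + eps))`` with
``eps = 1e-9``, so every printed threshold applies to a defined quantity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "de_test", "detection_fraction", "conserved_markers",
    "find_conserved_markers", "select_display_markers", "top_n_markers",
]

EPS = 1e-9
ALPHA = 0.05


def _dense(M):
    return M.toarray() if sp.issparse(M) else np.asarray(M)


def de_test(adata, group_a, group_b, layer: str = "lognorm",
            min_logfc: float = 0.25, min_detect: float = 0.10,
            method: str = "ranksum", correction: str = "bonferroni"
            ) -> pd.DataFrame:
    """Two-group differential expression on log-normalized values.

    ``group_a`` / ``group_b`` are boolean masks or cell-index arrays.
    Returns a table over the *tested* genes: log2fc (positive = higher in
    group a), detection fractions, p and adjusted p.
    """
    mask_a = _as_mask(group_a, adata.n_obs)
    mask_b = _as_mask(group_b, adata.n_obs)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na < 3 or nb < 3:
        raise ValidationError(f"groups need >= 3 cells (got {na}, {nb})")
    X = adata.layers[layer]
    Xa, Xb = _dense(X[mask_a]), _dense(X[mask_b])
    det_a, det_b = (Xa > 0).mean(axis=0), (Xb > 0).mean(axis=0)
    mean_a, mean_b = np.expm1(Xa).mean(axis=0), np.expm1(Xb).mean(axis=0)
    log2fc = np.log2((mean_a + EPS) / (mean_b + EPS))
    tested = (np.abs(log2fc) >= min_logfc) & (
        np.maximum(det_a, det_b) >= min_detect)
    idx = np.flatnonzero(tested)
    out = pd.DataFrame({
        "log2fc": log2fc[idx], "det_a": det_a[idx], "det_b": det_b[idx],
    }, index=adata.var_names[idx])
    if len(idx) == 0:
        out["p"] = out["p_adj"] = np.array([], dtype=float)
        return out
    if method == "ranksum":
        p = _ranksum_p(Xa[:, idx], Xb[:, idx])
    elif method == "hurdle":
        p = _hurdle_p(Xa[:, idx], Xb[:, idx])
    else:
        raise ValidationError(f"unknown method {method!r}")
    out["p"] = p
    if correction == "bonferroni":
        out["p_adj"] = np.minimum(p * len(idx), 1.0)
    elif correction == "bh":
        out["p_adj"] = multipletests(p, method="fdr_bh")[1]
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    out.attrs.update({"n_a": na, "n_b": nb, "method": method,
                      "correction": correction})
    return out


def _as_mask(sel, n: int) -> np.ndarray:
    sel = np.asarray(sel)
    if sel.dtype == bool:
        if sel.shape[0] != n:
            raise ValidationError("mask length mismatch")
        return sel
    mask = np.zeros(n, dtype=bool)
    mask[sel] = True
    return mask


def _ranksum_p(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    res = scipy.stats.mannwhitneyu(Xa, Xb, axis=0, alternative="two-sided",
                                   method="asymptotic")
    return np.asarray(res.pvalue)


def _hurdle_p(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Two-part test: detection-rate chi-square combined (Fisher) with a
    rank-sum test restricted to expressing cells."""
    na, nb = Xa.shape[0], Xb.shape[0]
    ka, kb = (Xa > 0).sum(axis=0), (Xb > 0).sum(axis=0)
    p_det = np.ones(Xa.shape[1])
    for g in range(Xa.shape[1]):
        table = np.array([[ka[g], na - ka[g]], [kb[g], nb - kb[g]]])
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            continue
        p_det[g] = scipy.stats.chi2_contingency(table, correction=True)[1]
    p_cont = np.ones(Xa.shape[1])
    for g in range(Xa.shape[1]):
        a, b = Xa[Xa[:, g] > 0, g], Xb[Xb[:, g] > 0, g]
        if len(a) >= 3 and len(b) >= 3:
            p_cont[g] = scipy.stats.mannwhitneyu(
                a, b, alternative="two-sided")[1]
    stat = -2 * (np.log(np.clip(p_det, 1e-300, 1)) +
                 np.log(np.clip(p_cont, 1e-300, 1)))
    return scipy.stats.chi2.sf(stat, df=4)


def detection_fraction(adata, cells, layer: str = "lognorm") -> pd.Series:
    """Fraction of the given cells with value > 0, per gene."""
    mask = _as_mask(cells, adata.n_obs)
    X = adata.layers[layer]
    frac = np.asarray((X[mask] > 0).mean(axis=0)).ravel()
    return pd.Series(frac, index=adata.var_names)


def conserved_markers(sample_results: dict[str, pd.DataFrame],
                      det_frac: pd.Series, min_detect: float = 0.40,
                      min_mean_log2fc: float = 1.0,
                      min_significant_fraction: float = 0.80
                      ) -> pd.DataFrame:
    """Aggregate per-sample DE tables into conserved-marker records.

    Genes are those tested in *every* sample (the conservative
    intersection).  ``is_marker`` iff mean log2FC strictly >
    ``min_mean_log2fc``, adjusted p <= 0.05 in strictly more than
    ``min_significant_fraction`` of samples, and pooled detection fraction
    >= ``min_detect``.
    """
    if not sample_results:
        raise ValidationError("need >= 1 sample result")
    samples = sorted(sample_results)
    common = set.intersection(*(set(sample_results[s].index)
                                for s in samples))
    genes = sorted(common)
    fc = np.array([[sample_results[s].loc[g, "log2fc"] for s in samples]
                   for g in genes])
    padj = np.array([[sample_results[s].loc[g, "p_adj"] for s in samples]
                     for g in genes])
    if not genes:
        return pd.DataFrame(columns=["mean_log2fc", "significant_fraction",
                                     "detection_fraction", "is_marker"])
    mean_fc = fc.mean(axis=1)
    sig_frac = (padj <= ALPHA).mean(axis=1)
    det = det_frac.reindex(genes).fillna(0.0).to_numpy()
    rec = pd.DataFrame({
        "mean_log2fc": mean_fc,
        "significant_fraction": sig_frac,
        "detection_fraction": det,
        "n_samples": len(samples),
    }, index=pd.Index(genes, name="gene"))
    rec["per_sample_log2fc"] = [list(map(float, row)) for row in fc]
    rec["per_sample_p_adj"] = [list(map(float, row)) for row in padj]
    rec["is_marker"] = ((rec["detection_fraction"] >= min_detect)
                        & (rec["mean_log2fc"] > min_mean_log2fc)
                        & (rec["significant_fraction"]
                           > min_significant_fraction))
    return rec


def find_conserved_markers(adata, clustering, cluster, sample_key="sample_id",
                           layer: str = "lognorm", min_logfc: float = 0.25,
                           min_detect_test: float = 0.10,
                           method: str = "ranksum", min_cells: int = 3,
                           **agg_kwargs) -> pd.DataFrame:
    """Per-sample one-vs-rest DE for one cluster, aggregated into
    conserved-marker records."""
    clustering = np.asarray(clustering)
    in_cluster = clustering == cluster
    results = {}
    for sample in sorted(adata.obs[sample_key].unique()):
        m = (adata.obs[sample_key] == sample).to_numpy()
        a, b = in_cluster & m, ~in_cluster & m
        if a.sum() < min_cells or b.sum() < min_cells:
            continue
        results[str(sample)] = de_test(adata, a, b, layer=layer,
                                       min_logfc=min_logfc,
                                       min_detect=min_detect_test,
                                       method=method)
    if not results:
        raise ValidationError(f"cluster {cluster}: no sample with enough cells")
    det = detection_fraction(adata, in_cluster, layer=layer)
    return conserved_markers(results, det, **agg_kwargs)


def select_display_markers(records: pd.DataFrame, rule: str = "balloon"
                           ) -> list[str]:
    """Figure-display marker selection.

    balloon: (detection > 0.80 and mean log2FC > 4) or (detection > 0.70
    and mean log2FC > 8).  heatmap: upregulated genes whose mean log2FC
    exceeds the 80th percentile of upregulated genes' mean log2FC.
    """
    if rule == "balloon":
        keep = (((records["detection_fraction"] > 0.80)
                 & (records["mean_log2fc"] > 4))
                | ((records["detection_fraction"] > 0.70)
                   & (records["mean_log2fc"] > 8)))
        return records.index[keep].tolist()
    if rule == "heatmap":
        up = records[records["mean_log2fc"] > 0]
        if up.empty:
            return []
        cut = float(np.percentile(up["mean_log2fc"], 80))
        return up.index[up["mean_log2fc"] > cut].tolist()
    raise ValidationError(f"unknown display rule {rule!r}")


def top_n_markers(records_by_identity: dict[str, pd.DataFrame], n: int = 5,
                  unique: bool = True) -> dict[str, list[str]]:
    """Per-identity top-n marker panels ranked by mean log2FC.

    Only ``is_marker`` genes are eligible; ties break by gene id.  With
    ``unique``, a gene claimed by an identity where it ranks higher (by
    mean log2FC, ties by identity order) is dropped from lower-ranked
    panels.
    """
    ranked: dict[str, list[tuple[float, str]]] = {}
    for ident in sorted(records_by_identity):
        rec = records_by_identity[ident]
        mk = rec.loc[rec["is_marker"], "mean_log2fc"]
        items = sorted(((float(fc), g) for g, fc in mk.items()),
                       key=lambda t: (-t[0], t[1]))
        ranked[ident] = items
    if unique:
        best: dict[str, tuple[float, str]] = {}
        for ident, items in ranked.items():
            for fc, g in items:
                if g not in best or fc > best[g][0]:
                    best[g] = (fc, ident)
        ranked = {ident: [(fc, g) for fc, g in items
                          if best[g][1] == ident]
                  for ident, items in ranked.items()}
    return {ident: [g for _, g in sorted(items,
                                         key=lambda t: (-t[0], t[1]))][:n]
            for ident, items in ranked.items()}
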