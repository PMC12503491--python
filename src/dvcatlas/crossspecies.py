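"""Ortholog-mediated transfer of donor identities to query-species clusters.

Donor identities travel as top-5 marker panels translated through a 1:1
ortholog map (duplicated and species-specific genes are excluded first).
Each query cluster is scored by the mean z-scored expression of every
translated panel; the call is the argmax identity when its score clears
``s_min`` with a margin of ``m_min`` over the runner-up, ``novel_candidate``
when no panel scores high enough, and ``unspecific`` when additionally the
cluster's own de-novo markers appear in no donor panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import markers as mk
from .errors import ValidationError
from .reference_consensus import score_marker_panels

__all__ = ["filter_orthologs", "panel_transfer", "describe_novel",
           "TransferResult"]

S_MIN = 0.5   # z-score units; calibrated on the packaged benchmark
M_MIN = 0.25
MIN_PANEL_COVERAGE = 2  # translated panels with fewer genes are excluded


@dataclass
class TransferResult:
    scores: pd.DataFrame   # query cluster x donor identity
    calls: pd.DataFrame    # per cluster: call, identity, margin
    low_coverage: list[str]  # donor panels excluded after translation


def filter_orthologs(pairs: pd.DataFrame, genes_a=None, genes_b=None
                     ) -> tuple[pd.DataFrame, dict]:
    """Reduce an ortholog table to usable 1:1 pairs.

    ``pairs`` has columns ``gene_a``/``gene_b`` (extra columns ignored).
    Genes appearing in more than one pair are flagged duplicated and
    dropped; genes of a provided universe absent from the map are counted
    species-specific.  Returns the 1:1 map and a report.
    """
    if not {"gene_a", "gene_b"}.issubset(pairs.columns):
        raise ValidationError("ortholog table needs gene_a and gene_b")
    pairs = pairs[["gene_a", "gene_b"]].drop_duplicates()
    dup_a = pairs["gene_a"].duplicated(keep=False)
    dup_b = pairs["gene_b"].duplicated(keep=False)
    dup = dup_a | dup_b
    usable = pairs[~dup].reset_index(drop=True)
    report = {
        "n_pairs_in": int(len(pairs)),
        "n_usable": int(len(usable)),
        "duplicated_genes_a": sorted(pairs.loc[dup, "gene_a"].unique()),
        "duplicated_genes_b": sorted(pairs.loc[dup, "gene_b"].unique()),
    }
    for side, genes in (("a", genes_a), ("b", genes_b)):
        if genes is not None:
            mapped = set(usable[f"gene_{side}"])
            specific = [g for g in genes if g not in mapped]
            report[f"species_specific_{side}"] = specific
            report[f"species_specific_fraction_{side}"] = (
                len(specific) / len(list(genes)) if len(list(genes)) else 0.0)
    return usable, report


def panel_transfer(adata, clustering, donor_panels: dict[str, list[str]],
                   ortholog_map: pd.DataFrame, s_min: float = S_MIN,
                   m_min: float = M_MIN, layer: str = "lognorm",
                   denovo_markers: dict | None = None) -> TransferResult:
    """Score translated donor marker panels on every query cluster.

    ``donor_panels`` maps donor identity -> top marker genes in donor
    (species-A) symbols; ``ortholog_map`` is a usable 1:1 table from
    :func:`filter_orthologs`.  ``denovo_markers`` optionally maps query
    cluster -> its own top de-novo markers (query symbols) and feeds the
    "unspecific" call.
    """
    clustering = np.asarray(clustering)
    if clustering.size == 0 or adata.n_obs == 0:
        raise ValidationError("empty clustering")
    a2b = dict(zip(ortholog_map["gene_a"], ortholog_map["gene_b"]))
    translated: dict[str, list[str]] = {}
    low_coverage: list[str] = []
    for ident, genes in donor_panels.items():
        tr = [a2b[g] for g in genes if g in a2b]
        tr = [g for g in tr if g in adata.var_names]
        if len(tr) < MIN_PANEL_COVERAGE:
            low_coverage.append(ident)
        else:
            translated[ident] = tr
    if not translated:
        raise ValidationError("no donor panel survived ortholog translation")
    scores, _skipped = score_marker_panels(adata, clustering, translated,
                                           layer=layer)
    donor_gene_pool = {g for genes in translated.values() for g in genes}
    rows = []
    for cluster in scores.index:
        row = scores.loc[cluster].astype(float)
        ranked = row.sort_values(ascending=False)
        best, best_score = str(ranked.index[0]), float(ranked.iloc[0])
        margin = (best_score - float(ranked.iloc[1])
                  if len(ranked) > 1 else np.inf)
        if best_score >= s_min and margin >= m_min:
            call, ident = "assigned", best
        else:
            call, ident = "novel_candidate", ""
            if denovo_markers is not None:
                own = set(denovo_markers.get(cluster, []))
                if own and not (own & donor_gene_pool):
                    call = "unspecific"
        rows.append({"cluster": cluster, "call": call, "identity": ident,
                     "margin": margin, "best_score": best_score})
    calls = pd.DataFrame(rows).set_index("cluster")
    return TransferResult(scores, calls, sorted(low_coverage))


def describe_novel(adata, clustering, novel_clusters, n_top: int = 20,
                   layer: str = "lognorm", min_logfc: float = 0.25
                   ) -> dict:
    """De-novo one-vs-rest marker tables for novel query clusters, ranked
    by log2FC, so the operator can name them."""
    clustering = np.asarray(clustering)
    out = {}
    for cluster in novel_clusters:
        a = clustering == cluster
        res = mk.de_test(adata, a, ~a, layer=layer, min_logfc=min_logfc)
        res = res[(res["log2fc"] > 0) & (res["p_adj"] <= 0.05)]
        out[cluster] = res.sort_values("log2fc", ascending=False).head(n_top)
    return out
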