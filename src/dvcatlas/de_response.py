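"""Condition-contrast differential expression per identity.

Contrasts (e.g. refed versus fasted) are computed within one identity at a
chosen hierarchy layer, delegating to the two-group test with the
condition-contrast effect-size floor of 0.1 log2FC.  Positive log2FC means
higher in the first-named condition.  Significant genes (adjusted p < 0.05)
are binned by |log2FC| (default edges 0.5 and 1.0), and upregulated
significant genes at a fold-change cut can be intersected across two
identities (the magnaclass-overlap analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import markers as mk
from .errors import ValidationError

__all__ = ["DEResult", "contrast_de", "bin_effects", "overlap_analysis"]

ALPHA = 0.05


@dataclass
class DEResult:
    identity: str
    contrast: tuple[str, str]
    table: pd.DataFrame  # per tested gene: log2fc, p, p_adj

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < ALPHA]


def contrast_de(adata, identity_cells, contrast: tuple[str, str],
                identity: str = "", min_logfc: float = 0.1,
                layer: str = "lognorm", method: str = "ranksum",
                correction: str = "bonferroni") -> DEResult:
    """Pairwise condition contrast within one identity.

    ``identity_cells`` is a boolean mask (or index array) of the identity's
    cells; ``contrast`` is (condition_a, condition_b) with log2FC > 0
    meaning higher in condition_a.
    """
    mask = mk._as_mask(identity_cells, adata.n_obs)
    cond = adata.obs["condition"].to_numpy()
    a = mask & (cond == contrast[0])
    b = mask & (cond == contrast[1])
    for name, m in zip(contrast, (a, b)):
        if m.sum() == 0:
            raise ValidationError(
                f"identity {identity or '<cells>'} has no cells in "
                f"condition {name!r}")
    table = mk.de_test(adata, a, b, layer=layer, min_logfc=min_logfc,
                       method=method, correction=correction)
    return DEResult(identity, contrast, table)


def bin_effects(de: DEResult, edges=(0.5, 1.0)) -> dict:
    """Bin |log2FC| of significant genes at the given edges.

    Default bins: [edges[0], edges[1]) and >= edges[1]; a below-floor bin
    (< edges[0]) completes the partition.  Returns counts and fractions
    (zero-count flagged).
    """
    lo, hi = edges
    fc = de.significant["log2fc"].abs().to_numpy()
    n = len(fc)
    n_below = int((fc < lo).sum())
    n_mid = int(((fc >= lo) & (fc < hi)).sum())
    n_high = int((fc >= hi).sum())
    out = {"n_significant": n, "n_below": n_below, "n_mid": n_mid,
           "n_high": n_high, "empty": n == 0}
    for key, k in (("frac_below", n_below), ("frac_mid", n_mid),
                   ("frac_high", n_high)):
        out[key] = (k / n) if n else 0.0
    return out


def overlap_analysis(de_a: DEResult, de_b: DEResult, min_fc: float = 1.0
                     ) -> dict:
    """Venn partition of upregulated significant genes at a fold-change cut.

    Gene sets are significant genes with log2FC >= ``min_fc`` (upregulated
    orientation) in each result; returns shared / a_only / b_only sets and
    counts.
    """
    set_a = set(de_a.significant.index[de_a.significant["log2fc"] >= min_fc])
    set_b = set(de_b.significant.index[de_b.significant["log2fc"] >= min_fc])
    shared = set_a & set_b
    return {"shared": sorted(shared), "a_only": sorted(set_a - shared),
            "b_only": sorted(set_b - shared),
            "n_shared": len(shared), "n_a_only": len(set_a - shared),
            "n_b_only": len(set_b - shared)}
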