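"""Gene-set expression flags and neurotransmitter co-expression profiling.

A cell expresses a gene set when any member gene has log-normalized value
strictly greater than zero (no count-level minimum).  On top of the flags
the module computes the GABA/glutamate partition per cell group, per-cell
counts of positive neurotransmitter systems (co-transmission = two or more
systems), and pairwise co-expression fractions such as the share of
Th-expressing neurons that also express Cck.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError

__all__ = [
    "GABA_GENES", "GLUTAMATE_GENES", "TRANSMISSION_SYSTEMS",
    "expression_flags", "nt_partition", "cotransmission_count", "cofraction",
]

GABA_GENES = ("Slc32a1", "Gad1", "Gad2")
GLUTAMATE_GENES = ("Slc17a6", "Slc17a7")

# the 10-gene transmission/release panel grouped into 8 systems; the
# monoamine system is Slc18a2 (VMAT2) + Ddc (aromatic L-amino-acid
# decarboxylase; the alias "Addc" occasionally seen in print maps here)
TRANSMISSION_SYSTEMS: dict[str, tuple[str, ...]] = {
    "GABA": ("Gad1", "Gad2"),
    "glycine": ("Slc6a5",),
    "glutamate": ("Slc17a6",),
    "monoamine": ("Slc18a2", "Ddc"),
    "Sst": ("Sst",),
    "Npy": ("Npy",),
    "Cck": ("Cck",),
    "acetylcholine": ("Slc5a7",),
}


def _dense(M):
    return M.toarray() if sp.issparse(M) else np.asarray(M)


def expression_flags(adata, sets: dict[str, tuple[str, ...]],
                     layer: str = "lognorm") -> pd.DataFrame:
    """Per-cell boolean per gene set: any member gene with value > 0.

    Genes absent from the data contribute nothing; a set with no present
    genes yields all-False.
    """
    if not sets:
        raise ValidationError("no gene sets given")
    X = adata.layers[layer]
    out = {}
    for name, genes in sets.items():
        present = [g for g in genes if g in adata.var_names]
        if not present:
            out[name] = np.zeros(adata.n_obs, dtype=bool)
            continue
        sub = _dense(adata[:, present].layers[layer])
        out[name] = (sub > 0).any(axis=1)
    return pd.DataFrame(out, index=adata.obs_names)


def nt_partition(flags: pd.DataFrame, groups,
                 set_a: str = "GABA", set_b: str = "glutamate"
                 ) -> pd.DataFrame:
    """Per-group proportions (a_only, b_only, both, neither); rows sum to 1."""
    groups = np.asarray(groups)
    rows = {}
    for g in pd.unique(groups):
        m = groups == g
        a, b = flags.loc[m, set_a].to_numpy(), flags.loc[m, set_b].to_numpy()
        n = m.sum()
        rows[g] = {
            f"{set_a}_only": float((a & ~b).sum() / n),
            f"{set_b}_only": float((~a & b).sum() / n),
            "both": float((a & b).sum() / n),
            "neither": float((~a & ~b).sum() / n),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def cotransmission_count(adata, groups,
                         systems: dict[str, tuple[str, ...]] | None = None,
                         layer: str = "lognorm",
                         collapse_systems: bool = True
                         ) -> tuple[pd.Series, pd.Series]:
    """Positive-system count per cell and per-group co-transmission rate.

    A system is positive when any of its genes is flagged; a cell
    co-transmits when >= 2 systems are positive.  ``collapse_systems=False``
    counts flagged genes instead of collapsed systems.
    """
    systems = TRANSMISSION_SYSTEMS if systems is None else systems
    if collapse_systems:
        flags = expression_flags(adata, systems, layer=layer)
    else:
        genes = [g for gs in systems.values() for g in gs]
        flags = expression_flags(adata, {g: (g,) for g in genes}, layer=layer)
    count = flags.sum(axis=1)
    groups = np.asarray(groups)
    frac = (pd.Series((count >= 2).to_numpy(), index=groups)
            .groupby(level=0).mean())
    frac.name = "cotransmission_fraction"
    return count, frac


def cofraction(flags: pd.DataFrame, gene_a: str, gene_b: str,
               subset=None) -> dict:
    """Exact co-expression counts: (n_a, n_b, n_ab, n_ab / n_a).

    ``flags`` holds per-cell booleans for the two genes (columns named by
    gene).  The fraction is NaN (flagged) when n_a = 0.
    """
    sub = flags if subset is None else flags.loc[np.asarray(subset)]
    a, b = sub[gene_a].to_numpy(), sub[gene_b].to_numpy()
    n_a, n_b, n_ab = int(a.sum()), int(b.sum()), int((a & b).sum())
    return {"n_a": n_a, "n_b": n_b, "n_ab": n_ab,
            "fraction": (n_ab / n_a) if n_a else float("nan"),
            "undefined": n_a == 0}
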