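"""Exchange formats and the core count-matrix data model.

The universal in-memory container is an :class:`anndata.AnnData` with cells
as observations and genes as variables: ``X`` holds sparse non-negative
integer unique-molecule counts, ``obs`` carries ``sample_id``, ``condition``
and ``species`` per cell, and named ``layers`` (e.g. ``"lognorm"``) hold
derived matrices of the same shape.

On disk, count matrices use the 10x-style triplet dialect: a matrix-market
coordinate file (genes x cells, 1-based indices as the format requires) next
to TSV gene and barcode tables.  In memory everything is 0-based and
cells x genes.  Hierarchies are flat record lists (name, layer, parent,
species_origin), chosen over nested formats for diff-ability.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, InputError, ValidationError
from .hierarchy import LabelHierarchy, build_tree

CONDITIONS = ("fasted", "adlib", "refed", "licl", "vehicle", "none")
SPECIES = ("mouse", "rat", "synthetic")

__all__ = [
    "CONDITIONS", "SPECIES",
    "make_count_matrix", "validate_count_matrix",
    "read_10x_triplet", "write_10x_triplet",
    "merge_samples",
    "read_hierarchy", "write_hierarchy",
]


def make_count_matrix(counts, gene_ids, cell_ids, sample_id="s1",
                      condition="none", species="synthetic",
                      cell_meta: pd.DataFrame | None = None) -> ad.AnnData:
    """Assemble a validated count matrix.

    ``counts`` is cells x genes (dense or sparse, non-negative integers).
    Scalar ``sample_id``/``condition``/``species`` are broadcast; a full
    ``cell_meta`` table (indexed like ``cell_ids``) overrides them.
    """
    X = sp.csr_matrix(counts)
    obs = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    if cell_meta is not None:
        obs = cell_meta.copy()
        obs.index = pd.Index(cell_ids, name="cell_id")
    for col, val in (("sample_id", sample_id), ("condition", condition),
                     ("species", species)):
        if col not in obs:
            obs[col] = val
    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    adata = ad.AnnData(X=X, obs=obs, var=var)
    validate_count_matrix(adata)
    return adata


def validate_count_matrix(adata: ad.AnnData) -> None:
    """Raise :class:`ValidationError` on any violated invariant."""
    X = adata.X
    data = X.data if sp.issparse(X) else np.asarray(X)
    if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
        raise ValidationError("counts must be non-negative integers")
    if adata.obs_names.has_duplicates:
        raise ValidationError("duplicate cell barcodes")
    if adata.var_names.has_duplicates:
        raise ValidationError("duplicate gene ids")
    if "sample_id" not in adata.obs or adata.obs["sample_id"].isna().any():
        raise ValidationError("every cell needs a sample_id")
    for name, layer in adata.layers.items():
        if layer.shape != adata.shape:
            raise ValidationError(f"layer {name!r} shape mismatch")


def _find(dir_path: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = dir_path / f"{stem}{suffix}"
            if p.exists():
                return p
    raise InputError(f"none of {stems} found in {dir_path}")


def _read_tsv(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", header=None, dtype=str)


def read_10x_triplet(dir_path) -> ad.AnnData:
    """Read a 10x-style triplet directory into a count matrix.

    Expects ``matrix.mtx``, ``genes.tsv`` (or ``features.tsv``) and
    ``barcodes.tsv``, each optionally gzipped.  An optional
    ``cell_meta.tsv`` (written by :func:`write_10x_triplet`) restores
    per-cell metadata; otherwise defaults apply.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise InputError(f"not a directory: {dir_path}")
    mtx_path = _find(dir_path, ("matrix.mtx",))
    genes_path = _find(dir_path, ("genes.tsv", "features.tsv"))
    bc_path = _find(dir_path, ("barcodes.tsv",))
    try:
        M = scipy.io.mmread(str(mtx_path))  # genes x cells on disk
    except Exception as exc:
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    M = sp.csr_matrix(M.T)
    if M.data.size and np.any(M.data != np.round(M.data)):
        raise FormatError("matrix contains non-integer entries")
    genes = _read_tsv(genes_path)[0].tolist()
    barcodes = _read_tsv(bc_path)[0].tolist()
    if len(set(barcodes)) != len(barcodes):
        raise ValidationError("duplicate barcodes in barcode table")
    if M.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"matrix dims {M.shape[::-1]} do not match gene/barcode tables "
            f"({len(genes)}, {len(barcodes)})")
    meta_path = dir_path / "cell_meta.tsv"
    cell_meta = None
    if meta_path.exists():
        cell_meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
        cell_meta = cell_meta.loc[barcodes]
    return make_count_matrix(M, genes, barcodes, cell_meta=cell_meta)


def write_10x_triplet(adata: ad.AnnData, dir_path) -> None:
    """Write the triplet dialect (genes x cells on disk) plus cell_meta.tsv."""
    validate_count_matrix(adata)
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    M = sp.coo_matrix(adata.X.T)
    M = sp.coo_matrix((M.data.astype(np.int64), (M.row, M.col)), shape=M.shape)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), M, field="integer")
    pd.Series(adata.var_names).to_csv(dir_path / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(dir_path / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(dir_path / "cell_meta.tsv", sep="\t")


def merge_samples(matrices: list[ad.AnnData],
                  suffix_samples: bool = False) -> ad.AnnData:
    """Merge count matrices over the union of their gene universes.

    Genes are aligned by symbol (case-sensitive, same species); a gene
    absent from an input contributes zero counts for that input's cells.
    Colliding cell ids raise unless ``suffix_samples`` appends each cell's
    sample_id to its barcode.
    """
    if not matrices:
        raise ValidationError("need at least one matrix")
    mats = []
    for m in matrices:
        validate_count_matrix(m)
        if suffix_samples:
            m = m.copy()
            m.obs_names = [f"{c}-{s}" for c, s in
                           zip(m.obs_names, m.obs["sample_id"])]
        mats.append(m)
    all_ids = np.concatenate([m.obs_names for m in mats])
    if len(set(all_ids)) != len(all_ids):
        raise ValidationError(
            "colliding cell ids across inputs (enable suffix_samples)")
    if len(mats) == 1:
        return mats[0].copy()
    merged = ad.concat(mats, join="outer", merge="same", fill_value=0)
    merged.X = sp.csr_matrix(merged.X)
    validate_count_matrix(merged)
    return merged


def read_hierarchy(path) -> LabelHierarchy:
    """Read a flat-record hierarchy file (TSV: name, layer, parent,
    species_origin; '#' comments allowed)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"name", "layer", "parent"}
    if not required.issubset(df.columns):
        raise FormatError(f"hierarchy file needs columns {sorted(required)}")
    if "species_origin" not in df:
        df["species_origin"] = "both"
    df["parent"] = df["parent"].fillna("")
    try:
        df["layer"] = df["layer"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer layer in {path}: {exc}") from exc
    try:
        return build_tree(df[["name", "layer", "parent", "species_origin"]]
                          .itertuples(index=False, name=None))
    except ValidationError as exc:
        raise FormatError(f"invalid hierarchy in {path}: {exc}") from exc


def write_hierarchy(tree: LabelHierarchy, path) -> None:
    tree.validate()
    tree.to_records().to_csv(path, sep="\t", index=False)
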