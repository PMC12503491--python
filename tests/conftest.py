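"""Shared fixtures: one synthetic atlas generated per session."""

import numpy as np
import pytest

from dvcatlas import qc, reduce_cluster
from dvcatlas.synthetic_data import (default_config, generate_atlas,
                                     truth_hierarchy)

SEED = 11


@pytest.fixture(scope="session")
def atlas_cfg():
    return default_config(seed=SEED)


@pytest.fixture(scope="session")
def atlas(atlas_cfg):
    """Raw generated atlas: (AnnData, SyntheticTruth)."""
    return generate_atlas(atlas_cfg)


@pytest.fixture(scope="session")
def clean_atlas(atlas):
    """QC-passed singlets with a log-normalized layer, plus matched truth."""
    adata, truth = atlas
    stats = qc.compute_cell_stats(adata)
    kept, _ = qc.filter_cells(stats)
    sub = adata[kept].copy()
    tk = truth.cells.loc[kept]
    singlet = (~(tk["is_doublet"] | tk["is_lowq"])).to_numpy()
    sub = sub[singlet].copy()
    reduce_cluster.normalize_log(sub)
    return sub, tk[singlet]


@pytest.fixture(scope="session")
def latent(clean_atlas):
    """Shared latent fitted on the clean atlas: (genes, PCALatent, emb)."""
    sub, _ = clean_atlas
    genes = reduce_cluster.select_hvg(sub, n_top=1000)
    lat = reduce_cluster.PCALatent(genes, n_pcs=30).fit(sub)
    return genes, lat, lat.transform(sub)


@pytest.fixture(scope="session")
def sim_tree(atlas_cfg):
    return truth_hierarchy(atlas_cfg)


@pytest.fixture(scope="session")
def fitted_tree_clf(sim_tree, clean_atlas, latent):
    from dvcatlas.hierarchy import TreeClassifier

    _, _, emb = latent
    _, tk = clean_atlas
    clf = TreeClassifier(sim_tree, random_state=0)
    return clf.fit(emb, tk["identity"].to_numpy())


@pytest.fixture(scope="session")
def clustered_atlas(clean_atlas):
    """Leiden labels at resolution 1.0 on the clean atlas."""
    sub, tk = clean_atlas
    sub = sub.copy()
    labels = reduce_cluster.run_standard_pipeline(sub, n_top=1000, seed=SEED)
    return sub, tk, labels


def rng(n: int = 0) -> np.random.Generator:
    return np.random.default_rng(SEED + n)
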