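"""Label-tree structure, tree-consistent prediction, harmonization, edits."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import f1_score

from dvcatlas import qc, reduce_cluster
from dvcatlas.errors import ValidationError
from dvcatlas.hierarchy import (REJECTED, TreeClassifier, build_tree,
                                edit_tree, harmonize, load_mouse_tree,
                                load_rat_labels, load_rodent_atlas)
from dvcatlas.synthetic_data import Identity, Sample, generate_atlas


def prep(cfg):
    adata, truth = generate_atlas(cfg)
    stats = qc.compute_cell_stats(adata)
    kept, _ = qc.filter_cells(stats)
    sub = adata[kept].copy()
    tk = truth.cells.loc[kept]
    singlet = (~(tk["is_doublet"] | tk["is_lowq"])).to_numpy()
    sub = sub[singlet].copy()
    reduce_cluster.normalize_log(sub)
    return sub, tk[singlet]


class TestBuildTree:
    def test_packaged_fixtures_are_valid(self):
        for tree in (load_rodent_atlas(), load_mouse_tree(),
                     load_rat_labels()):
            assert tree.violations() == []

    def test_orphan_node_reported(self):
        with pytest.raises(ValidationError, match="orphan"):
            build_tree([("a", 1, ""), ("b", 2, "missing")])

    def test_cycle_reported(self):
        with pytest.raises(ValidationError, match="cycle|layer"):
            build_tree([("a", 1, "b"), ("b", 2, "a")])

    def test_duplicate_name_reported(self):
        with pytest.raises(ValidationError, match="duplicate"):
            build_tree([("a", 1, ""), ("a", 1, "")])


class TestPackagedCounts:
    def test_rodent_atlas_printed_counts(self):
        tree = load_rodent_atlas()
        by_layer = tree.counts_by_layer()
        assert len(tree) == 123
        assert by_layer[3] + by_layer[4] + by_layer[5] == 99
        assert by_layer[2] == 20
        assert by_layer[1] == 4

    def test_mouse_tree_printed_counts(self):
        tree = load_mouse_tree()
        assert tree.counts_by_layer() == {1: 4, 2: 18, 3: 50}
        l3 = tree.labels_at_layer(3)
        neuronal = [n for n in l3
                    if "neurons" in tree.path_to_root(n)]
        assert len(neuronal) == 35
        assert len(l3) - len(neuronal) == 15

    def test_rat_label_printed_counts(self):
        assert load_rat_labels().counts_by_layer() == {1: 4, 2: 19, 3: 52}

    def test_rat_novel_classes_present(self):
        tree = load_rodent_atlas()
        for novel in ("immunity_akin", "ortus_akin"):
            assert tree.nodes[novel].layer == 2
            assert tree.nodes[novel].species_origin == "rat"
        for deep in ("m3_rat", "m5_rat"):
            assert tree.nodes[deep].layer == 5


class TestTreeClassifier:
    def test_separable_children_perfect_training_accuracy(self, sim_tree):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (50, 3)) + [5, 0, 0],
                       rng.normal(0, 0.1, (50, 3)) + [0, 5, 0]])
        y = np.array(["inhib_a"] * 50 + ["astro_a"] * 50, dtype=object)
        clf = TreeClassifier(sim_tree, random_state=0).fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_single_child_passes_through(self):
        tree = build_tree([("t", 1, ""), ("only", 2, "t"),
                           ("other", 1, "")])
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (30, 2)) + [3, 0],
                       rng.normal(0, 0.1, (30, 2)) + [0, 3]])
        y = np.array(["only"] * 30 + ["other"] * 30, dtype=object)
        clf = TreeClassifier(tree, random_state=0).fit(X, y)
        pred = clf.predict(X[:30])
        assert (pred == "only").all()

    def test_refit_with_permuted_cells_identical(self, sim_tree, latent,
                                                 clean_atlas):
        _, _, emb = latent
        _, tk = clean_atlas
        y = tk["identity"].to_numpy()
        perm = np.random.default_rng(3).permutation(len(y))
        c1 = TreeClassifier(sim_tree, random_state=0).fit(emb, y)
        c2 = TreeClassifier(sim_tree, random_state=0).fit(emb[perm], y[perm])
        assert (c1.predict(emb) == c2.predict(emb)).all()

    def test_recovers_training_identities_with_ancestors(
            self, fitted_tree_clf, latent, clean_atlas, sim_tree):
        _, _, emb = latent
        _, tk = clean_atlas
        y = tk["identity"].to_numpy()
        pred = fitted_tree_clf.predict(emb)
        idents = sorted(set(y))
        f1 = f1_score(y, pred.astype(str), labels=idents, average=None)
        assert min(f1) >= 0.9
        for p, t in zip(pred, y):
            if p in idents:
                # a layer-3 prediction always implies the true-layer path
                assert sim_tree.path_to_root(p)[1:] \
                    == sim_tree.path_to_root(t)[1:] or p != t

    def test_ancestor_consistency_structural(self, fitted_tree_clf, latent,
                                             sim_tree):
        _, _, emb = latent
        for path in fitted_tree_clf.predict_paths(emb[:500]):
            assert path[0] == "cell"
            for parent, child in zip(path, path[1:]):
                assert sim_tree.nodes[child].parent == parent

    def test_withheld_novel_identity_not_deep_labeled(
            self, fitted_tree_clf, latent, atlas_cfg):
        genes_lat, lat, _ = latent
        used = {g for spec in atlas_cfg.marker_spec.values()
                for g, _ in spec}
        free = [g for g in atlas_cfg.gene_names() if g not in used][:10]
        novel_cfg = replace(
            atlas_cfg, seed=91,
            identities=[Identity("novel_x", "neurons", "novel_class", 1.0)],
            marker_spec={"novel_x": [(g, 3.0) for g in free]},
            samples=[Sample("q1", 300)], condition_effects=[],
            doublet_fraction=0.0, lowq_fraction=0.0)
        sub, _ = prep(novel_cfg)
        pred = fitted_tree_clf.predict(lat.transform(sub))
        deep = {i.name for i in atlas_cfg.identities}
        assert np.isin(pred, list(deep)).mean() <= 0.15
        # a stricter calibration rejects the majority outright
        strict = TreeClassifier(fitted_tree_clf.tree, member_quantile=0.10,
                                random_state=0)
        strict.fit(fitted_tree_clf.X_train_, fitted_tree_clf.y_train_)
        pred_strict = strict.predict(lat.transform(sub))
        assert (pred_strict == REJECTED).mean() >= 0.5


@pytest.fixture(scope="module")
def query_pack(atlas_cfg, latent):
    """A second labeled dataset drawn from the same generative identities."""
    _, lat, _ = latent
    cfg2 = replace(atlas_cfg, seed=77,
                   samples=[Sample("h1", 500), Sample("h2", 500)],
                   condition_effects=[])
    sub2, tk2 = prep(cfg2)
    return lat.transform(sub2), tk2["identity"].to_numpy().astype(object)


class TestHarmonize:
    def test_same_identity_labels_merge(self, fitted_tree_clf, query_pack):
        emb2, y2 = query_pack
        tree2, report = harmonize(fitted_tree_clf, emb2, y2)
        acts = report.actions.set_index("query_label")
        assert (acts["action"] == "merged_with").all()
        assert (acts["node"] == acts.index).all()
        assert len(tree2) == len(fitted_tree_clf.tree)

    def test_idempotent_on_merged_labels(self, fitted_tree_clf, query_pack):
        emb2, y2 = query_pack
        tree2, _ = harmonize(fitted_tree_clf, emb2, y2)
        tree3, report = harmonize(fitted_tree_clf, emb2, y2)
        assert tree2.nodes == tree3.nodes
        assert (report.actions["action"] == "merged_with").all()

    def test_refinement_attached_one_layer_deeper(self, fitted_tree_clf,
                                                  query_pack, clean_atlas,
                                                  latent):
        emb2, y2 = query_pack
        # split one identity's query cells into an artificial subpopulation:
        # the tree cannot tell them apart, but reciprocity fails, so the
        # refined label attaches below the matching node
        y2 = y2.copy()
        is_e = y2 == "excit_a"
        idx = np.flatnonzero(is_e)
        half = idx[: len(idx) // 2]
        y2[half] = "excit_a_sub"
        _, _, emb = latent
        tree2, report = harmonize(fitted_tree_clf, emb2, y2)
        act = report.actions.set_index("query_label")
        assert act.loc["excit_a_sub", "action"] in ("attached_as_child",
                                                    "merged_with")
        if act.loc["excit_a_sub", "action"] == "attached_as_child":
            assert tree2.nodes["excit_a_sub"].parent == "excit_a"
            assert tree2.nodes["excit_a_sub"].layer == 4

    def test_nonsibling_mixture_yields_conflict(self, fitted_tree_clf,
                                                query_pack):
        emb2, y2 = query_pack
        y2 = y2.copy()
        # 50/50 mixture of a neuron identity and a glial identity
        ia = np.flatnonzero(y2 == "inhib_a")
        ga = np.flatnonzero(y2 == "astro_a")
        n = min(len(ia), len(ga))
        y2[ia[:n]] = "weird_mix"
        y2[ga[:n]] = "weird_mix"
        tree2, report = harmonize(fitted_tree_clf, emb2, y2)
        act = report.actions.set_index("query_label")
        assert act.loc["weird_mix", "action"] == "conflict"
        assert "weird_mix" not in tree2
        assert set(act.loc["weird_mix", "node"].split(",")) \
            == {"inhib_a", "astro_a"}


class TestEditTree:
    def base(self):
        return build_tree([
            ("neurons", 1, ""), ("glia", 1, ""),
            ("classa", 2, "neurons"), ("leaf1", 3, "classa"),
            ("mural", 2, "glia"),
        ])

    def test_move_updates_parent_and_layer(self):
        tree, log = edit_tree(self.base(),
                              [("move_node", "leaf1", "mural")])
        assert tree.nodes["leaf1"].parent == "mural"
        assert tree.nodes["leaf1"].layer == 3
        tree2, _ = edit_tree(tree, [("move_node", "leaf1", "neurons")])
        assert tree2.nodes["leaf1"].layer == 2
        assert any("moved" in line for line in log)

    def test_add_parent_then_move(self):
        tree, _ = edit_tree(self.base(), [
            ("add_parent", "immunity_akin", "neurons", "rat"),
            ("move_node", "leaf1", "immunity_akin"),
        ])
        assert tree.nodes["immunity_akin"].layer == 2
        assert tree.nodes["leaf1"].parent == "immunity_akin"
        assert tree.violations() == []

    def test_move_creating_cycle_rejected(self):
        with pytest.raises(ValidationError, match="cycle"):
            edit_tree(self.base(), [("move_node", "classa", "leaf1")])

    def test_rename_keeps_children(self):
        tree, _ = edit_tree(self.base(), [("rename", "classa", "classb")])
        assert tree.nodes["leaf1"].parent == "classb"
        assert "classa" not in tree
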