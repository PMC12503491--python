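"""Layered cell-identity hierarchies.

A :class:`LabelHierarchy` is a rooted tree of cell identities.  The root is
the unlabeled "cell" node (layer 0); identities live at layers 1-5, from
coarse types (neuron, glia) down to high-resolution populations.  Layer
strictly increases along every root-to-leaf path; in the common case a child
sits exactly one layer below its parent, but explicit deeper refinements
(e.g. a layer-5 subdivision of a layer-4 identity) are allowed.

The module also provides the sklearn-style :class:`TreeClassifier` used for
tree-consistent label prediction with rejection, and :func:`harmonize`,
which incorporates a second labeled dataset into an existing hierarchy with
attach / merge / conflict / reject semantics.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError

ROOT = "cell"
REJECTED = "rejected"

__all__ = [
    "ROOT",
    "REJECTED",
    "HierNode",
    "LabelHierarchy",
    "build_tree",
    "validate_records",
    "load_rodent_atlas",
    "load_mouse_tree",
    "load_rat_labels",
    "TreeClassifier",
    "harmonize",
    "HarmonizationReport",
    "edit_tree",
]


@dataclass(frozen=True)
class HierNode:
    name: str
    layer: int
    parent: str | None  # None only for the root
    species_origin: str = "both"  # mouse | rat | both | synthetic


class LabelHierarchy:
    """Rooted tree of identities with unique names and increasing layers."""

    def __init__(self, nodes: dict[str, HierNode] | None = None):
        self.nodes: dict[str, HierNode] = dict(nodes) if nodes else {}
        if ROOT not in self.nodes:
            self.nodes[ROOT] = HierNode(ROOT, 0, None)

    # -- construction -----------------------------------------------------
    def add_node(self, name: str, layer: int, parent: str,
                 species_origin: str = "both") -> None:
        if name in self.nodes:
            raise ValidationError(f"duplicate node name: {name!r}")
        self.nodes[name] = HierNode(name, layer, parent, species_origin)

    def copy(self) -> "LabelHierarchy":
        return LabelHierarchy(dict(self.nodes))

    # -- queries ----------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __len__(self) -> int:
        """Number of identity labels (the root is not a label)."""
        return len(self.nodes) - 1

    def children(self, name: str) -> list[str]:
        return sorted(n.name for n in self.nodes.values() if n.parent == name)

    def parent(self, name: str) -> str | None:
        return self.nodes[name].parent

    def path_to_root(self, name: str) -> list[str]:
        """Node names from ``name`` up to (and including) the root."""
        path = [name]
        seen = {name}
        while (p := self.nodes[path[-1]].parent) is not None:
            if p in seen:
                raise ValidationError(f"cycle through node {p!r}")
            path.append(p)
            seen.add(p)
        return path

    def ancestors(self, name: str) -> list[str]:
        return self.path_to_root(name)[1:]

    def descendants(self, name: str) -> list[str]:
        out, stack = [], [name]
        while stack:
            for c in self.children(stack.pop()):
                out.append(c)
                stack.append(c)
        return out

    def is_ancestor(self, anc: str, name: str) -> bool:
        return anc in self.path_to_root(name)

    def siblings(self, a: str, b: str) -> bool:
        return self.nodes[a].parent == self.nodes[b].parent

    def labels_at_layer(self, layer: int) -> list[str]:
        return sorted(n.name for n in self.nodes.values() if n.layer == layer)

    def counts_by_layer(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for n in self.nodes.values():
            if n.name == ROOT:
                continue
            out[n.layer] = out.get(n.layer, 0) + 1
        return dict(sorted(out.items()))

    # -- validation -------------------------------------------------------
    def violations(self) -> list[str]:
        """Itemized structural violations; empty list means valid."""
        out = []
        for n in self.nodes.values():
            if n.name == ROOT:
                if n.layer != 0 or n.parent is not None:
                    out.append("root node malformed")
                continue
            if n.parent is None:
                out.append(f"orphan node (no parent): {n.name}")
                continue
            if n.parent not in self.nodes:
                out.append(f"orphan node (parent {n.parent!r} absent): {n.name}")
                continue
            if n.layer <= self.nodes[n.parent].layer:
                out.append(
                    f"layer does not increase: {n.name} (layer {n.layer}) "
                    f"under {n.parent} (layer {self.nodes[n.parent].layer})")
        # cycle detection over the parent links
        for name in self.nodes:
            try:
                self.path_to_root(name)
            except ValidationError:
                out.append(f"cycle involving node: {name}")
            except KeyError:
                pass  # already reported as orphan
        return out

    def validate(self) -> None:
        v = self.violations()
        if v:
            raise ValidationError("; ".join(v))

    # -- serialization helpers --------------------------------------------
    def to_records(self) -> pd.DataFrame:
        rows = [
            {"name": n.name, "layer": n.layer,
             "parent": "" if n.parent is None else n.parent,
             "species_origin": n.species_origin}
            for n in self.nodes.values() if n.name != ROOT
        ]
        return pd.DataFrame(rows, columns=["name", "layer", "parent",
                                           "species_origin"])


def validate_records(records) -> list[str]:
    """Violation list for an iterable of (name, layer, parent, species) rows."""
    tree = LabelHierarchy()
    seen_dupes = []
    for rec in records:
        name, layer, parent = rec[0], int(rec[1]), rec[2]
        species = rec[3] if len(rec) > 3 else "both"
        if name in tree.nodes:
            seen_dupes.append(f"duplicate node name: {name}")
            continue
        tree.nodes[name] = HierNode(name, layer, parent or ROOT, species)
    return seen_dupes + tree.violations()


def build_tree(records) -> LabelHierarchy:
    """Build and validate a hierarchy from flat (name, layer, parent[, species])
    records; parent "" or None means the root."""
    records = list(records)
    problems = validate_records(records)
    if problems:
        raise ValidationError("; ".join(problems))
    tree = LabelHierarchy()
    for rec in records:
        name, layer, parent = rec[0], int(rec[1]), rec[2]
        species = rec[3] if len(rec) > 3 else "both"
        tree.nodes[name] = HierNode(name, layer, parent or ROOT, species)
    return tree


# ---------------------------------------------------------------------------
# Packaged atlas fixtures
# ---------------------------------------------------------------------------

def _load_packaged(fname: str) -> LabelHierarchy:
    ref = importlib.resources.files("dvcatlas.data").joinpath(fname)
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    df["layer"] = df["layer"].astype(int)
    df["parent"] = df["parent"].fillna("")
    return build_tree(df[["name", "layer", "parent", "species_origin"]]
                      .itertuples(index=False, name=None))


def load_rodent_atlas() -> LabelHierarchy:
    """The packaged harmonized rodent hierarchy: 123 labels over 5 layers
    (4 layer-1, 20 layer-2 and 99 high-resolution layer-3/4/5 identities),
    combining the mouse tree, the second murine dataset's layer-4
    refinements, and the appended rat identities including the two
    rat-specific classes (immunity-akin, ortus-akin) and the layer-5
    monoamine refinements."""
    return _load_packaged("rodent_tree.tsv")


def load_mouse_tree() -> LabelHierarchy:
    """The packaged mouse hierarchy: 4 layer-1, 18 layer-2 and 50 layer-3
    identities (15 non-neuronal, 35 neuronal)."""
    return _load_packaged("mouse_tree.tsv")


def load_rat_labels() -> LabelHierarchy:
    """The packaged rat label set at three granularities: 4 layer-1,
    19 layer-2 and 52 layer-3 identities (including 'unspecific')."""
    return _load_packaged("rat_labels.tsv")


# ---------------------------------------------------------------------------
# Tree-consistent classification with rejection
# ---------------------------------------------------------------------------

class TreeClassifier(BaseEstimator, ClassifierMixin):
    """Hierarchical classifier over a label tree with per-node rejection.

    Every trained child of every internal node gets a regularized *binary*
    one-vs-rest logistic scorer (child members vs the node's other
    members).  Binary scorers yield absolute membership probabilities, so a
    cell resembling none of a node's children is rejected there rather than
    force-routed to the least-bad sibling.  Descent goes to the child with
    the highest probability when that probability reaches
    ``conf_threshold``; otherwise it stops and the stopping node is the
    label ("rejected" when the cell cannot leave the root).  Predicted
    labels therefore always imply their ancestors.

    Parameters
    ----------
    tree:
        The :class:`LabelHierarchy` to train; training labels must be nodes
        of this tree.
    conf_threshold:
        Minimum one-vs-rest probability to descend into a child.
    C:
        Inverse regularization strength of the logistic scorers.
    """

    def __init__(self, tree: LabelHierarchy, conf_threshold: float = 0.6,
                 member_quantile: float = 0.01, C: float = 1.0,
                 random_state: int = 0):
        self.tree = tree
        self.conf_threshold = conf_threshold
        self.member_quantile = member_quantile
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.shape[0] != y.shape[0]:
            raise ValidationError("X and y length mismatch")
        unknown = sorted(set(y) - set(self.tree.nodes))
        if unknown:
            raise ValidationError(f"labels not in tree: {unknown}")
        # cells under a node = cells labeled at the node or any descendant
        self._membership_: dict[str, np.ndarray] = {}
        for name in self.tree.nodes:
            under = {name, *self.tree.descendants(name)}
            self._membership_[name] = np.isin(y, list(under))
        self.scorers_: dict[str, dict[str, LogisticRegression]] = {}
        self.thresholds_: dict[str, float] = {}
        self.centroids_: dict[str, np.ndarray] = {}
        for name in self.tree.nodes:
            kids = [c for c in self.tree.children(name)
                    if self._membership_[c].sum() > 0]
            for c in kids:
                self.centroids_[c] = X[self._membership_[c]].mean(axis=0)
            if not kids:
                continue
            node_members = self._membership_[name] | (
                np.ones(X.shape[0], bool) if name == ROOT else False)
            scorers = {}
            for c in kids:
                pos = self._membership_[c]
                neg = node_members & ~pos
                if neg.sum() == 0:
                    # single-child node: everything under the node belongs
                    # to the child; pass through without a scorer
                    continue
                sub = pos | neg
                clf = LogisticRegression(
                    C=self.C, max_iter=2000, random_state=self.random_state)
                clf.fit(X[sub], pos[sub].astype(int))
                scorers[c] = clf
                # per-child acceptance threshold calibrated on the child's
                # own members: a query must score at least as well as all
                # but the weakest `member_quantile` of training members
                member_p = clf.predict_proba(X[pos])[:, 1]
                # "lower" keeps the weakest training member above its own
                # gate, so separable training data is never self-rejected
                self.thresholds_[c] = max(
                    self.conf_threshold,
                    float(np.quantile(member_p, self.member_quantile,
                                      method="lower")))
            self.scorers_[name] = scorers
        self.X_train_, self.y_train_ = X, y
        self.classes_ = np.unique(y)
        return self

    def _child_probs(self, node: str, X: np.ndarray) -> dict[str, np.ndarray]:
        return {c: clf.predict_proba(X)[:, 1]
                for c, clf in self.scorers_.get(node, {}).items()}

    def predict_paths(self, X) -> list[list[str]]:
        """Root-to-stopping-node path for every query cell."""
        check_is_fitted(self, "centroids_")
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        paths = [[ROOT] for _ in range(n)]
        frontier = {ROOT: np.arange(n)}
        while frontier:
            nxt: dict[str, list] = {}
            for node, idx in frontier.items():
                kids = [c for c in self.tree.children(node)
                        if c in self.centroids_]
                if not kids:
                    continue
                probs = self._child_probs(node, X[idx])
                if not probs:
                    if len(kids) == 1:  # single trained child: pass through
                        child = kids[0]
                        for i in idx:
                            paths[i].append(child)
                        nxt.setdefault(child, []).extend(idx.tolist())
                    continue
                names = list(probs)
                P = np.stack([probs[c] for c in names], axis=1)
                best = P.argmax(axis=1)
                conf = P[np.arange(len(idx)), best]
                for j, i in enumerate(idx):
                    child = names[best[j]]
                    if conf[j] >= self.thresholds_[child]:
                        paths[i].append(child)
                        nxt.setdefault(child, []).append(i)
            frontier = {c: np.asarray(v) for c, v in nxt.items() if v}
        return paths

    def predict(self, X) -> np.ndarray:
        """Deepest confident node per cell, or "rejected" at the root."""
        labels = []
        for path in self.predict_paths(X):
            labels.append(REJECTED if len(path) == 1 else path[-1])
        return np.asarray(labels, dtype=object)


# ---------------------------------------------------------------------------
# Harmonization of a second labeled dataset
# ---------------------------------------------------------------------------

@dataclass
class HarmonizationReport:
    actions: pd.DataFrame  # one row per query label
    theta: float

    def action_of(self, label: str) -> str:
        return self.actions.set_index("query_label").loc[label, "action"]


def _nearest_query_label(X: np.ndarray, centroids: dict[str, np.ndarray]) -> np.ndarray:
    names = list(centroids)
    cen = np.stack([centroids[n] for n in names])
    d = ((X[:, None, :] - cen[None, :, :]) ** 2).sum(axis=2)
    return np.asarray(names, dtype=object)[d.argmin(axis=1)]


def harmonize(model: TreeClassifier, X_query, y_query, theta: float = 0.6,
              reciprocity_margin: float = 0.1, conflict_min: float = 0.3,
              species_origin: str = "both",
              ) -> tuple[LabelHierarchy, HarmonizationReport]:
    """Incorporate a labeled query dataset into the model's hierarchy.

    For each query label, its cells are predicted through the tree.  If at
    least ``theta`` of them stop at (or below) one node, the label is merged
    with that node when the node's own training cells reciprocally map to
    the query label, and otherwise attached one layer deeper as a new child.
    If the prediction mass splits across non-sibling nodes the label is a
    conflict and the tree is left unchanged; anything else is rejected.
    """
    check_is_fitted(model, "centroids_")
    X_query = np.asarray(X_query, dtype=float)
    y_query = np.asarray(y_query, dtype=object)
    tree = model.tree.copy()
    q_centroids = {lab: X_query[y_query == lab].mean(axis=0)
                   for lab in np.unique(y_query)}
    rows = []
    for lab in sorted(np.unique(y_query)):
        preds = model.predict(X_query[y_query == lab])
        mass = pd.Series(preds).value_counts(normalize=True)
        top, frac_top = mass.index[0], float(mass.iloc[0])
        action, node, detail = None, None, ""
        if top != REJECTED and frac_top >= theta:
            # reciprocity: do the node's own training cells point back?
            members = model._membership_[top]
            back = _nearest_query_label(model.X_train_[members], q_centroids)
            recip = float((back == lab).mean())
            if lab in tree and lab == top:
                action, node = "merged_with", top
            elif recip >= theta - reciprocity_margin:
                action, node = "merged_with", top
            else:
                action, node = "attached_as_child", top
                new_layer = tree.nodes[top].layer + 1
                if lab not in tree:
                    tree.add_node(lab, new_layer, top, species_origin)
                detail = f"reciprocity={recip:.2f}"
        else:
            heavy = [n for n, f in mass.items()
                     if f >= conflict_min and n != REJECTED]
            non_sib = (len(heavy) >= 2 and not all(
                tree.siblings(heavy[0], h) for h in heavy[1:]))
            if non_sib:
                action, node = "conflict", ",".join(sorted(heavy))
            else:
                action, node = "rejected", ""
        rows.append({"query_label": lab, "action": action, "node": node,
                     "purity": frac_top, "detail": detail})
    report = HarmonizationReport(pd.DataFrame(rows), theta)
    tree.validate()
    return tree, report


# ---------------------------------------------------------------------------
# Manual curation
# ---------------------------------------------------------------------------

def edit_tree(tree: LabelHierarchy, ops) -> tuple[LabelHierarchy, list[str]]:
    """Apply manual curation operations and re-validate.

    ``ops`` is a sequence of tuples:

    - ``("move_node", name, new_parent)`` — re-parent a node; the layers of
      the moved subtree are recomputed from the new parent.
    - ``("add_parent", name, parent[, species_origin])`` — create a new node
      one layer below ``parent`` (e.g. a new class to hang novel leaves on).
    - ``("rename", old, new)`` — rename a node, keeping links.

    Returns the edited tree and an audit log.  An edit that breaks the tree
    (cycle, orphan) raises :class:`ValidationError` and leaves the input
    untouched.
    """
    out = tree.copy()
    log = []
    for op in ops:
        kind = op[0]
        if kind == "move_node":
            _, name, new_parent = op
            if name not in out or new_parent not in out:
                raise ValidationError(f"move_node: unknown node in {op!r}")
            if new_parent == name or out.is_ancestor(name, new_parent):
                raise ValidationError(
                    f"move_node would create a cycle: {name} -> {new_parent}")
            out.nodes[name] = replace(out.nodes[name], parent=new_parent)
            _recompute_layers(out, name)
            log.append(f"moved {name} under {new_parent}")
        elif kind == "add_parent":
            _, name, parent = op[:3]
            species = op[3] if len(op) > 3 else "both"
            if parent not in out:
                raise ValidationError(f"add_parent: unknown parent {parent!r}")
            out.add_node(name, out.nodes[parent].layer + 1, parent, species)
            log.append(f"added {name} under {parent}")
        elif kind == "rename":
            _, old, new = op
            if old not in out:
                raise ValidationError(f"rename: unknown node {old!r}")
            if new in out:
                raise ValidationError(f"rename: target exists {new!r}")
            node = out.nodes.pop(old)
            out.nodes[new] = replace(node, name=new)
            for n in list(out.nodes.values()):
                if n.parent == old:
                    out.nodes[n.name] = replace(n, parent=new)
            log.append(f"renamed {old} to {new}")
        else:
            raise ValidationError(f"unknown edit op {kind!r}")
    out.validate()
    return out, log


def _recompute_layers(tree: LabelHierarchy, name: str) -> None:
    node = tree.nodes[name]
    new_layer = tree.nodes[node.parent].layer + 1
    shift = new_layer - node.layer
    if shift == 0:
        return
    for n in [name, *tree.descendants(name)]:
        tree.nodes[n] = replace(tree.nodes[n], layer=tree.nodes[n].layer + shift)
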