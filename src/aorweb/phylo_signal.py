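"""Blomberg's K phylogenetic signal on an ultrametric tree.

K compares the observed ratio of trait variance (measured from the
phylogenetically-corrected mean) to its phylogenetically-expected
counterpart, against the ratio expected under Brownian motion on the
candidate tree.  K near 1 means trait variation accumulates as Brownian
motion predicts (strong signal); K well below 1 means relatives resemble
each other less than the tree would predict.

The module consumes a user-supplied Newick tree (dendropy) pruned to the
community; tree estimation and dating are upstream concerns.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "read_tree",
    "check_ultrametric",
    "prune",
    "vcv_matrix",
    "blomberg_k",
    "DegenerateTraitError",
]

_SING_TOL = 1e-10


class DegenerateTraitError(ValueError):
    """Trait is constant across tips; K is undefined."""


def read_tree(path_or_string: str, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree with branch lengths (file path or literal)."""
    if "(" in path_or_string:
        return dendropy.Tree.get(data=path_or_string, schema=schema)
    return dendropy.Tree.get(path=path_or_string, schema=schema)


def _tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {
        leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()
    }


def check_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> None:
    """Raise if root-to-tip distances vary by more than ``tol``
    (relative to tree depth)."""
    depths = np.array(list(_tip_depths(tree).values()))
    scale = depths.max() if depths.max() > 0 else 1.0
    if (depths.max() - depths.min()) / scale > tol:
        raise ValueError(
            f"tree not ultrametric: root-to-tip range "
            f"[{depths.min():.6g}, {depths.max():.6g}]"
        )


def prune(tree: dendropy.Tree, keep: Sequence[str]) -> dendropy.Tree:
    """Induced subtree on ``keep`` tip labels.

    Degree-2 nodes are suppressed with branch lengths summed, so
    patristic distances among retained tips — and ultrametricity — are
    preserved.  Unknown labels raise with the missing set listed.
    """
    labels = {t.label for t in tree.taxon_namespace if t is not None}
    missing = sorted(set(keep) - labels)
    if missing:
        raise KeyError(f"species not in tree: {missing}")
    sub = tree.extract_tree_with_taxa_labels(labels=set(keep))
    sub.suppress_unifurcations()
    return sub


def vcv_matrix(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Phylogenetic covariance matrix: V[i, j] is the root-to-MRCA
    distance shared by tips i and j (tip depth on the diagonal)."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    labels = [nd.taxon.label for nd in leaves]
    index = {id(nd): i for i, nd in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    tree.calc_node_root_distances(return_leaf_distances_only=False)

    # postorder: for each internal node, pairs of tips whose MRCA is that
    # node get its root distance
    below: dict[int, list[int]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            i = index[id(nd)]
            below[id(nd)] = [i]
            V[i, i] = nd.root_distance
            continue
        child_sets = [below.pop(id(ch)) for ch in nd.child_nodes()]
        h = nd.root_distance or 0.0
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        V[i, j] = V[j, i] = h
        below[id(nd)] = [i for s in child_sets for i in s]
    return V, labels


def blomberg_k(
    tree: dendropy.Tree, trait: Mapping[str, float]
) -> float:
    """Blomberg's K for a continuous trait on the tips of ``tree``.

    With V the phylogenetic covariance matrix, phylogenetic mean
    a = (1'V⁻¹x)/(1'V⁻¹1), the observed MSE₀/MSE ratio
    (x−a)'(x−a) / (x−a)'V⁻¹(x−a) is divided by its Brownian expectation
    (tr V − n/(1'V⁻¹1)) / (n−1).
    """
    V, labels = vcv_matrix(tree)
    missing = sorted(set(labels) - set(trait))
    if missing:
        raise KeyError(f"trait missing for tips: {missing}")
    x = np.array([float(trait[lab]) for lab in labels])
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 tips")
    if np.ptp(x) == 0:
        raise DegenerateTraitError("constant trait: K undefined")
    # solve, never an explicit inverse
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1.0 / _SING_TOL:
        raise np.linalg.LinAlgError(
            f"phylogenetic covariance matrix near-singular (cond={cond:.3g})"
        )
    ones = np.ones(n)
    Vi_x = np.linalg.solve(V, x)
    Vi_1 = np.linalg.solve(V, ones)
    a = (ones @ Vi_x) / (ones @ Vi_1)
    dev = x - a
    mse0 = dev @ dev  # (n-1) factors cancel in the ratio
    mse = dev @ np.linalg.solve(V, dev)
    observed = mse0 / mse
    expected = (np.trace(V) - n / (ones @ Vi_1)) / (n - 1)
    return float(observed / expected)
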