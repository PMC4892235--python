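"""Reading, pruning and measuring phylogenies.

Trees are :class:`dendropy.Tree` objects throughout; this module adds the
validation the audit needs (unique tip labels, non-negative branch lengths,
no silently-missing edge lengths) and the patristic
:class:`DistanceMatrix` that every downstream statistic consumes.

Patristic distances are measured along the unrooted path between two tips,
so root placement never affects them.  Polytomies and zero-length branches
are accepted as-is: both occur in published supertrees and pairwise path
lengths remain well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "read_newick",
    "read_tree",
    "tip_labels",
    "prune_to_taxa",
    "patristic_matrix",
]


class TreeError(ValueError):
    """Raised for malformed or invalid input trees."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric tip-to-tip patristic distances in branch-length units.

    ``labels`` fixes the row/column order; ``values`` is a square symmetric
    matrix with a zero diagonal.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError(f"matrix shape {vals.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if not np.allclose(vals, vals.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(vals) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(vals < 0):
            raise ValueError("negative distances")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def indices_of(self, labels: Iterable[str]) -> np.ndarray:
        """Row indices of ``labels``, in sorted-label order (deterministic)."""
        missing = set(labels) - set(self.labels)
        if missing:
            raise KeyError(f"labels not in matrix: {sorted(missing)}")
        return np.array([self._index[lab] for lab in sorted(set(labels))], dtype=int)

    def submatrix(self, labels: Iterable[str]) -> "DistanceMatrix":
        idx = self.indices_of(labels)
        labs = tuple(self.labels[i] for i in idx)
        return DistanceMatrix(labs, self.values[np.ix_(idx, idx)])

    def relabel(self, mapping: Mapping[str, str]) -> "DistanceMatrix":
        """Return a copy with labels renamed through ``mapping``."""
        labs = tuple(mapping.get(lab, lab) for lab in self.labels)
        return DistanceMatrix(labs, self.values.copy())


def tip_labels(tree: dendropy.Tree) -> set[str]:
    """Set of leaf taxon labels of ``tree``."""
    return {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None}


def _validate(tree: dendropy.Tree, *, missing_length_zero: bool = False) -> dendropy.Tree:
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise TreeError("tree contains an unlabeled tip")
        labels.append(leaf.taxon.label)
    dups = {lab for lab in labels if labels.count(lab) > 1}
    if dups:
        raise TreeError(f"duplicate tip labels: {sorted(dups)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root stem carries no tip-to-tip information
        if edge.length is None:
            if missing_length_zero:
                edge.length = 0.0
            else:
                head = edge.head_node.taxon.label if edge.head_node.taxon else "<internal>"
                raise TreeError(f"missing branch length on edge above {head!r}")
        elif edge.length < 0:
            head = edge.head_node.taxon.label if edge.head_node.taxon else "<internal>"
            raise TreeError(f"negative branch length {edge.length} on edge above {head!r}")
    return tree


def read_newick(
    text: str,
    *,
    underscores_to_spaces: bool = True,
    missing_length_zero: bool = False,
) -> dendropy.Tree:
    """Parse a Newick string into a validated tree.

    Unquoted underscores become spaces by default (the standard Newick
    dialect); pass ``underscores_to_spaces=False`` to keep them.  Missing
    branch lengths are an error unless ``missing_length_zero`` substitutes 0.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=not underscores_to_spaces,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise TreeError(f"could not parse Newick: {exc}") from exc
    return _validate(tree, missing_length_zero=missing_length_zero)


def read_tree(path: str, **kwargs) -> dendropy.Tree:
    """Read a tree from a Newick or NEXUS file (auto-detected)."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip()[:6].upper() == "#NEXUS":
        underscores = kwargs.pop("underscores_to_spaces", True)
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="nexus",
                preserve_underscores=not underscores,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise TreeError(f"could not parse NEXUS tree: {exc}") from exc
        return _validate(tree, missing_length_zero=kwargs.pop("missing_length_zero", False))
    return read_newick(text, **kwargs)


def prune_to_taxa(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Restrict ``tree`` to the tips in ``keep``, preserving path lengths.

    Degree-2 internal nodes created by the pruning are collapsed with their
    branch lengths summed, so patristic distances between retained tips are
    unchanged.
    """
    keep = set(keep)
    tips = tip_labels(tree)
    missing = keep - tips
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise TreeError(f"need at least 2 taxa to keep, got {len(keep)}")
    pruned = tree.extract_tree_with_taxa_labels(labels=keep)
    # detach from the source tree's taxon namespace so neither tree can
    # mutate the other's
    pruned.migrate_taxon_namespace(dendropy.TaxonNamespace())
    return pruned


def patristic_matrix(tree: dendropy.Tree, labels: Sequence[str] | None = None) -> DistanceMatrix:
    """Patristic (sum-of-branch-lengths) distance matrix of the tree's tips.

    Rows/columns follow ``labels`` if given, otherwise sorted tip labels.
    """
    tips = tip_labels(tree)
    if len(tips) < 2:
        raise TreeError("patristic matrix needs at least 2 tips")
    if labels is None:
        labels = tuple(sorted(tips))
    else:
        labels = tuple(labels)
        if set(labels) != tips:
            raise TreeError("labels must be exactly the tree's tip labels")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {leaf.taxon.label: leaf.taxon for leaf in tree.leaf_node_iter()}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, d)
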