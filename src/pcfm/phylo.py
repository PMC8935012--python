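"""Rooted species phylogeny wrapper.

Thin layer over :mod:`dendropy` providing the conventions the rest of the
pipeline relies on: unique leaf labels, branch lengths in substitutions
per site (missing lengths default to 0 with a warning), and edges
identified by the set of leaf labels below them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, Iterable

import dendropy

log = logging.getLogger(__name__)

EdgeId = FrozenSet[str]


class TreeParseError(ValueError):
    pass


class DuplicateLeafError(ValueError):
    pass


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, leaves labelled by species id."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dups = sorted({x for x in labels if labels.count(x) > 1})
            raise DuplicateLeafError(f"duplicate leaf labels: {dups}")
        n_missing = 0
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
                n_missing += 1
        if n_missing:
            log.warning("%d branch lengths missing; set to 0", n_missing)

    # -- basic accessors -------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_edges(self) -> int:
        return sum(1 for n in self.tree.preorder_node_iter()
                   if n is not self.tree.seed_node)

    def leaves_below(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def edge_map(self) -> dict[EdgeId, dendropy.Node]:
        """Map each edge (identified by the leaf set below it) to its
        head node.  The root itself carries no edge."""
        out: dict[EdgeId, dendropy.Node] = {}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            out[self.leaves_below(node)] = node
        return out

    def validate_species(self, species: Iterable[str]) -> None:
        missing = set(species) - set(self.leaf_labels)
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")

    # -- queries used downstream ----------------------------------------
    def mrca(self, species: Iterable[str]) -> dendropy.Node:
        species = list(species)
        self.validate_species(species)
        if len(species) == 1:
            return next(l for l in self.tree.leaf_node_iter()
                        if l.taxon.label == species[0])
        node = self.tree.mrca(taxon_labels=species)
        if node is None:
            raise ValueError(f"no MRCA found for {species}")
        return node

    def root_to_node_path(self, node: dendropy.Node) -> list[dendropy.Node]:
        path = []
        while node is not None and node is not self.tree.seed_node:
            path.append(node)
            node = node.parent_node
        return path


def edge_label(edge: EdgeId) -> str:
    """Human-readable stable label for an edge id."""
    return "|".join(sorted(edge))


def read_tree(path: str | Path) -> Phylogeny:
    """Read one Newick tree, rooted, with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeParseError(f"{path}: {exc}") from exc
    tree.is_rooted = True
    return Phylogeny(tree=tree)


def tree_from_newick(newick: str) -> Phylogeny:
    """Parse a Newick string (convenience for tests and simulation)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeParseError(str(exc)) from exc
    tree.is_rooted = True
    return Phylogeny(tree=tree)
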