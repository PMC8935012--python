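"""Parsimony reconstruction of insertion/deletion events.

Gap presence/absence in each maximal identical-carrier gap block is
treated as a binary character on the species tree.  A block is accepted
as a single indel event only when the minimum-change (Fitch)
reconstruction needs exactly one state change on exactly one edge and
the root state is unambiguous; homoplastic blocks and polarity ties are
discarded.  Gap gained below the edge means a deletion in the species
below it; gap ancestral with nucleotides gained below the edge means an
insertion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy

from .phylo import EdgeId, Phylogeny, edge_label
from .seqio import GeneAlignment

log = logging.getLogger(__name__)

GAP, BASE = 1, 0  # binary character states


class UninformativeBlockError(ValueError):
    """Gap block with carriers empty or covering all included species."""


class TooFewSpeciesError(ValueError):
    pass


@dataclass(frozen=True)
class GapBlock:
    """A maximal run of alignment columns gapped in one fixed species set."""

    col_start: int
    col_end: int  # half-open
    carriers: frozenset[str]

    @property
    def length(self) -> int:
        return self.col_end - self.col_start


@dataclass(frozen=True)
class IndelEvent:
    """One reconstructed indel assigned to a tree edge.

    ``descendant_species`` are exactly the leaves below the edge showing
    the derived state (the gap carriers for a deletion; the base carriers
    for an insertion).
    """

    gene_id: str
    kind: str  # "insertion" | "deletion"
    length_nt: int
    col_start: int
    col_end: int
    edge: EdgeId
    descendant_species: frozenset[str]
    polarity_confident: bool = True

    @property
    def frame_disrupting(self) -> bool:
        return self.length_nt % 3 != 0

    @property
    def edge_label(self) -> str:
        return edge_label(self.edge)

    @property
    def signed_offset(self) -> int:
        """Net CDS length change in the descendants: +ins / −del."""
        return self.length_nt if self.kind == "insertion" else -self.length_nt


def find_gap_blocks(aln: GeneAlignment) -> list[GapBlock]:
    """All maximal gap blocks of an alignment, sorted by start column.

    Columns gapped in every species are not part of any block; they are
    counted and logged (they carry no phylogenetic information).
    """
    blocks: list[GapBlock] = []
    all_species = set(aln.species_ids)
    n_all_gap = 0
    cur_start: Optional[int] = None
    cur_carriers: frozenset[str] = frozenset()

    def close(end: int) -> None:
        nonlocal cur_start
        if cur_start is not None:
            blocks.append(GapBlock(cur_start, end, cur_carriers))
            cur_start = None

    for col in range(aln.n_columns):
        carriers = frozenset(
            sp for sp in aln.species_ids if aln.rows[sp][col] == "-"
        )
        if carriers == all_species:
            n_all_gap += 1
            close(col)
            continue
        if not carriers:
            close(col)
            continue
        if cur_start is None:
            cur_start, cur_carriers = col, carriers
        elif carriers != cur_carriers:
            close(col)
            cur_start, cur_carriers = col, carriers
    close(aln.n_columns)
    if n_all_gap:
        log.warning("%s: dropped %d all-gap columns", aln.gene_id, n_all_gap)
    return blocks


def _fitch_sets(
    phylo: Phylogeny,
    leaf_state: dict[str, int],
) -> tuple[dict[dendropy.Node, frozenset[int]], int]:
    """Bottom-up Fitch pass.

    Leaves absent from ``leaf_state`` (excluded species) are treated as
    missing data (both states possible).  Returns the per-node state sets
    and the minimum number of changes.
    """
    sets: dict[dendropy.Node, frozenset[int]] = {}
    changes = 0
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label in leaf_state:
                sets[node] = frozenset({leaf_state[label]})
            else:
                sets[node] = frozenset({GAP, BASE})
        else:
            child_sets = [sets[c] for c in node.child_nodes()]
            inter = frozenset.intersection(*child_sets)
            if inter:
                sets[node] = inter
            else:
                sets[node] = frozenset.union(*child_sets)
                changes += 1
    return sets, changes


def place_event(
    block: GapBlock,
    phylo: Phylogeny,
    included_species: Iterable[str],
    gene_id: str = "",
) -> Optional[IndelEvent]:
    """Assign a gap block to a tree edge by parsimony, or return None.

    Returns None ("ambiguous") when the minimal reconstruction needs more
    than one change, or when the Fitch root state does not resolve the
    polarity.  Raises :class:`UninformativeBlockError` when the carriers
    are empty or cover all included species.
    """
    included = frozenset(included_species)
    phylo.validate_species(included)
    carriers = block.carriers & included
    non_carriers = included - carriers
    if not carriers or not non_carriers:
        raise UninformativeBlockError(
            f"block [{block.col_start},{block.col_end}) uninformative within "
            f"included species"
        )
    leaf_state = {sp: (GAP if sp in carriers else BASE) for sp in included}
    sets, changes = _fitch_sets(phylo, leaf_state)
    if changes != 1:
        return None
    root_set = sets[phylo.tree.seed_node]
    if len(root_set) != 1:
        return None  # polarity tie: discarded, not resolved
    (root_state,) = root_set

    # With exactly one change and a resolved root, the derived leaves are
    # the ones whose state differs from the root, and they must form a
    # clade of the tree restricted to the included species.
    derived = carriers if root_state == BASE else non_carriers
    edge_node = _clade_node(phylo, derived, included)
    if edge_node is None:
        return None
    edge = phylo.leaves_below(edge_node) & included
    kind = "deletion" if root_state == BASE else "insertion"
    return IndelEvent(
        gene_id=gene_id,
        kind=kind,
        length_nt=block.length,
        col_start=block.col_start,
        col_end=block.col_end,
        edge=frozenset(edge),
        descendant_species=frozenset(derived),
        polarity_confident=True,
    )


def _clade_node(
    phylo: Phylogeny, group: frozenset[str], included: frozenset[str]
) -> Optional[dendropy.Node]:
    """The highest node whose included-leaf set equals ``group``, if any.

    Restriction to the included species means excluded leaves are ignored
    when comparing leaf sets; among equivalent nested nodes the one
    closest to the root is taken (the earliest edge on which the single
    change can be placed is not identifiable below it anyway).
    """
    best: Optional[dendropy.Node] = None
    for node in phylo.tree.preorder_node_iter():
        if node is phylo.tree.seed_node:
            continue
        if phylo.leaves_below(node) & included == group:
            best = node
            break  # preorder: first hit is the rootmost
    return best


def infer_indels(
    aln: GeneAlignment,
    phylo: Phylogeny,
    included_species: Iterable[str] | None = None,
) -> list[IndelEvent]:
    """Reconstruct all unambiguous indel events of one gene alignment.

    Requires at least four included species.  Ambiguous (homoplastic or
    polarity-tied) blocks are dropped with a logged count; events are
    returned sorted by start column.
    """
    included = frozenset(
        included_species if included_species is not None else aln.species_ids
    )
    if len(included) < 4:
        raise TooFewSpeciesError(
            f"{aln.gene_id}: only {len(included)} species included (need >= 4)"
        )
    phylo.validate_species(included)
    events: list[IndelEvent] = []
    n_ambiguous = 0
    for block in find_gap_blocks(aln):
        carriers = block.carriers & included
        if not carriers or carriers == included:
            continue  # uninformative within the included set
        ev = place_event(block, phylo, included, gene_id=aln.gene_id)
        if ev is None:
            n_ambiguous += 1
        else:
            events.append(ev)
    if n_ambiguous:
        log.info("%s: dropped %d ambiguous gap blocks", aln.gene_id, n_ambiguous)
    return sorted(events, key=lambda e: (e.col_start, e.col_end))
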