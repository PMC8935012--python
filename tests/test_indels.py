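"""Gap blocks and parsimony indel placement, checked against an
exhaustive minimum-change oracle."""

from itertools import product

import numpy as np
import pytest

from pcfm.indels import (GapBlock, UninformativeBlockError, find_gap_blocks,
                         infer_indels, place_event, TooFewSpeciesError)
from pcfm.phylo import Phylogeny, tree_from_newick
from pcfm.seqio import GeneAlignment

GAP, BASE = 1, 0


def brute_force_place(phylo: Phylogeny, carriers: frozenset, included: frozenset):
    """Independent oracle: enumerate every internal-node state assignment,
    count changes (excluded leaves are free), and return the unique
    single-change event as (derived included-leafset, kind), or None."""
    internal = [n for n in phylo.tree.preorder_node_iter() if not n.is_leaf()]
    leaf_state = {}
    for leaf in phylo.tree.leaf_node_iter():
        lbl = leaf.taxon.label
        if lbl in included:
            leaf_state[leaf] = GAP if lbl in carriers else BASE

    def included_below(node):
        return frozenset(l.taxon.label for l in node.leaf_iter()) & included

    solutions = []
    best = None
    for states in product((GAP, BASE), repeat=len(internal)):
        assign = dict(zip(internal, states))
        changes = []
        for node in phylo.tree.preorder_node_iter():
            if node is phylo.tree.seed_node:
                continue
            parent_state = assign[node.parent_node]
            if node.is_leaf():
                if node not in leaf_state:
                    continue  # excluded leaf: free
                child_state = leaf_state[node]
            else:
                child_state = assign[node]
            if child_state != parent_state:
                kind = "deletion" if child_state == GAP else "insertion"
                changes.append((included_below(node), kind))
        n = len(changes)
        if best is None or n < best:
            best, solutions = n, [changes]
        elif n == best:
            solutions.append(changes)
    if best != 1:
        return None
    events = {tuple(chg) for chg in solutions}
    if len(events) != 1:
        return None
    ((leafset, kind),) = events.pop()
    return leafset, kind


TOY_TREES = [
    "((a:1,b:1):1,(c:1,d:1):1);",
    "(((a:1,b:1):1,c:1):1,(d:1,e:1):1);",
    "(((a:1,b:1):1,(c:1,d:1):1):1,(e:1,f:1):1);",
    "((((a:1,b:1):1,c:1):1,d:1):1,(e:1,f:1):1);",
]


class TestPlacementOracle:
    @pytest.mark.parametrize("newick", TOY_TREES)
    def test_agrees_with_exhaustive_search_on_all_carrier_sets(self, newick):
        phylo = tree_from_newick(newick)
        leaves = frozenset(phylo.leaf_labels)
        names = sorted(leaves)
        for mask in range(1, 2 ** len(names) - 1):
            carriers = frozenset(n for i, n in enumerate(names) if mask >> i & 1)
            block = GapBlock(0, 2, carriers)
            got = place_event(block, phylo, leaves, gene_id="g")
            want = brute_force_place(phylo, carriers, leaves)
            if want is None:
                assert got is None, f"carriers={sorted(carriers)}"
            else:
                assert got is not None, f"carriers={sorted(carriers)}"
                assert (got.descendant_species, got.kind) == want

    def test_agrees_with_oracle_under_excluded_species(self):
        phylo = tree_from_newick(TOY_TREES[2])
        included = frozenset("abcd")  # e, f excluded -> missing data
        for carriers in [frozenset("ab"), frozenset("ac"), frozenset("abc")]:
            got = place_event(GapBlock(0, 1, carriers), phylo, included)
            want = brute_force_place(phylo, carriers, included)
            if want is None:
                assert got is None
            else:
                assert (got.descendant_species, got.kind) == want


class TestPlaceEvent:
    def test_root_adjacent_clade_is_polarity_ambiguous(self, balanced4):
        # deletion above {a,b} and insertion above {c,d} are equally
        # parsimonious: the event must be discarded, not guessed
        leaves = frozenset("abcd")
        assert place_event(GapBlock(0, 2, frozenset("ab")), balanced4, leaves) is None
        assert place_event(GapBlock(0, 2, frozenset("cd")), balanced4, leaves) is None

    def test_homoplastic_carriers_ambiguous(self, balanced4):
        assert place_event(
            GapBlock(0, 2, frozenset("ac")), balanced4, frozenset("abcd")
        ) is None

    def test_deep_clade_deletion_is_confident(self):
        phylo = tree_from_newick(TOY_TREES[2])
        ev = place_event(GapBlock(3, 6, frozenset("ab")), phylo, frozenset("abcdef"))
        assert ev is not None
        assert ev.kind == "deletion"
        assert ev.descendant_species == frozenset("ab")
        assert ev.length_nt == 3 and ev.polarity_confident

    def test_insertion_when_gap_is_ancestral(self):
        phylo = tree_from_newick(TOY_TREES[2])
        carriers = frozenset("cdef")  # everything except the {a,b} clade
        ev = place_event(GapBlock(0, 1, carriers), phylo, frozenset("abcdef"))
        assert ev is not None
        assert ev.kind == "insertion"
        assert ev.descendant_species == frozenset("ab")

    def test_uninformative_block_raises(self, balanced4):
        with pytest.raises(UninformativeBlockError):
            place_event(GapBlock(0, 1, frozenset("abcd")), balanced4,
                        frozenset("abcd"))


class TestGapBlocks:
    def test_single_block(self):
        aln = GeneAlignment("g", ["sp1", "sp2"],
                            {"sp1": "ATG---TAA", "sp2": "ATGGCGTAA"})
        blocks = find_gap_blocks(aln)
        assert blocks == [GapBlock(3, 6, frozenset({"sp1"}))]

    def test_shared_carriers_merge(self):
        aln = GeneAlignment("g", ["sp1", "sp2", "sp3"],
                            {"sp1": "A--T", "sp2": "A--T", "sp3": "ACGT"})
        assert find_gap_blocks(aln) == [GapBlock(1, 3, frozenset({"sp1", "sp2"}))]

    def test_carrier_change_splits_blocks(self):
        aln = GeneAlignment("g", ["sp1", "sp2", "sp3"],
                            {"sp1": "A--TT", "sp2": "AC--T", "sp3": "ACGTT"})
        assert find_gap_blocks(aln) == [
            GapBlock(1, 2, frozenset({"sp1"})),
            GapBlock(2, 3, frozenset({"sp1", "sp2"})),
            GapBlock(3, 4, frozenset({"sp2"})),
        ]

    def test_all_gap_columns_dropped(self):
        aln = GeneAlignment("g", ["sp1", "sp2"],
                            {"sp1": "A--TT", "sp2": "AC--T"})
        # column 2 is gapped in every species: not an event in any block
        assert find_gap_blocks(aln) == [
            GapBlock(1, 2, frozenset({"sp1"})),
            GapBlock(3, 4, frozenset({"sp2"})),
        ]

    def test_gap_free_alignment(self):
        aln = GeneAlignment("g", ["a", "b"], {"a": "ACGT", "b": "ACGT"})
        assert find_gap_blocks(aln) == []


class TestInferIndels:
    def test_terminal_deletion_recovered(self, balanced4):
        aln = GeneAlignment("g", list("abcd"), {
            "a": "ATGAA--AATAA", "b": "ATGAACCAATAA",
            "c": "ATGAACCAATAA", "d": "ATGAACCAATAA",
        })
        events = infer_indels(aln, balanced4)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "deletion" and ev.length_nt == 2
        assert ev.descendant_species == frozenset("a")
        assert (ev.col_start, ev.col_end) == (5, 7)

    def test_requires_four_species(self, balanced4):
        aln = GeneAlignment("g", list("abc"), {
            "a": "ATG", "b": "ATG", "c": "ATG"})
        with pytest.raises(TooFewSpeciesError):
            infer_indels(aln, balanced4, included_species={"a", "b", "c"})

    def test_species_order_irrelevant(self):
        phylo = tree_from_newick(TOY_TREES[1])
        rows = {"a": "ATG---CCCTAA", "b": "ATG---CCCTAA",
                "c": "ATGAAACCCTAA", "d": "ATGAAACCCTAA",
                "e": "ATGAAACCCTAA"}
        for order in (list("abcde"), list("edcba")):
            aln = GeneAlignment("g", order, dict(rows))
            events = infer_indels(aln, phylo)
            assert len(events) == 1
            assert events[0].descendant_species == frozenset("ab")

    def test_descendants_form_a_clade(self, tree20):
        rng = np.random.default_rng(0)
        from pcfm.simulate import SimConfig, PlantedIndel, simulate, plantable_edges
        edges = plantable_edges(tree20, min_leaves=2, max_leaves=8)
        cfg = SimConfig(
            tree=tree20, n_genes=3, gene_length_codons=100,
            indels=[PlantedIndel(g, edges[int(rng.integers(len(edges)))],
                                 "deletion", 3, 60) for g in range(3)],
            seed=5,
        )
        res = simulate(cfg)
        clades = set(tree20.edge_map())
        for aln in res.alignments:
            for ev in infer_indels(aln, tree20):
                assert ev.descendant_species in clades
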