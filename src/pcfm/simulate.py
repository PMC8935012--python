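"""Synthetic ortholog alignments with a known evolutionary history.

Genes are sampled as valid ORFs at the root of a species tree and
evolved down it under an equal-rates (Jukes-Cantor-like) substitution
process; planted indel events and compensatory pairs are then applied on
chosen edges, inserting gap columns so that the emitted alignment is the
true alignment (no aligner is simulated).  Substitutions never create
in-frame stop codons and never touch the first or last codon, so every
row without a planted frame disruption remains a quality-passing ORF.
A truth table records every planted event with its final alignment
columns, edge and carrier set.

This emulates the gap structure and the ORF-quality failure modes the
detection cascade is built for; it does not emulate alignment error,
sequencing error or rate heterogeneity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .effects import PcfmTemplate
from .phylo import EdgeId, Phylogeny, tree_from_newick
from .seqio import (CodingSequence, GeneAlignment, STOP_CODONS, quality_check)

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


class ConfigConflictError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedIndel:
    """A single indel to plant: ancestral-coordinate position ``pos`` on
    edge ``edge`` of gene ``gene`` (index into the simulated genes)."""

    gene: int
    edge: EdgeId
    kind: str  # insertion | deletion
    length: int
    pos: int


@dataclass(frozen=True)
class PlantedPair:
    """A compensatory pair to plant on one edge; ``pos`` is the ancestral
    position of the 5' indel (None: sampled uniformly among positions
    whose carriers stay quality-passing)."""

    gene: int
    edge: EdgeId
    template: PcfmTemplate
    pos: Optional[int] = None


@dataclass(frozen=True)
class CrossEdgePair:
    """Negative control: the two indels of a frame-restoring pair placed
    on two different (nested) edges."""

    gene: int
    edge_5p: EdgeId
    edge_3p: EdgeId
    template: PcfmTemplate
    pos: Optional[int] = None


@dataclass(frozen=True)
class Pseudogenization:
    gene: int
    species: str
    defect: str  # no_start | no_stop | internal_stop | len_mod3


@dataclass
class SimConfig:
    tree: Union[Phylogeny, str, None] = None
    n_leaves: int = 8
    branch_length_mean: float = 0.05
    n_genes: int = 1
    gene_length_codons: Union[int, tuple[int, int]] = 300
    sub_rate_scale: float = 1.0
    indels: list[PlantedIndel] = field(default_factory=list)
    pairs: list[PlantedPair] = field(default_factory=list)
    cross_edge_pairs: list[CrossEdgePair] = field(default_factory=list)
    pseudogenize: list[Pseudogenization] = field(default_factory=list)
    seed: int = 0
    max_placement_attempts: int = 200


@dataclass(frozen=True)
class TruthEvent:
    gene_id: str
    kind: str
    length: int
    col_start: int
    col_end: int
    edge: EdgeId
    carriers: frozenset[str]
    source: str  # "single" | "pair" | "cross_edge"


@dataclass(frozen=True)
class TruthPair:
    gene_id: str
    template: PcfmTemplate
    edge_5p: EdgeId
    edge_3p: EdgeId
    cols_5p: tuple[int, int]
    cols_3p: tuple[int, int]
    carriers: frozenset[str]
    pos: int  # ancestral position of the 5' indel
    same_edge: bool


@dataclass
class TruthTable:
    events: list[TruthEvent] = field(default_factory=list)
    pairs: list[TruthPair] = field(default_factory=list)


@dataclass
class SimResult:
    alignments: list[GeneAlignment]
    phylogeny: Phylogeny
    truth: TruthTable


# ---------------------------------------------------------------------------
# tree and root-sequence sampling


def plantable_edges(
    phylo: Phylogeny,
    min_leaves: int = 1,
    max_leaves: Optional[int] = None,
) -> list[EdgeId]:
    """Edges on which a planted indel is identifiable by parsimony.

    The two edges incident to the root are excluded: a single state
    change there is always mirrored by an equally parsimonious change on
    the sister edge, so polarity cannot be resolved and the detection
    stage (correctly) discards such blocks.
    """
    root_clades = {
        phylo.leaves_below(c) for c in phylo.tree.seed_node.child_nodes()
    }
    n = len(phylo.leaf_labels)
    cap = max_leaves if max_leaves is not None else n - 1
    return sorted(
        (e for e in phylo.edge_map()
         if e not in root_clades and min_leaves <= len(e) <= cap),
        key=sorted,
    )


def sample_tree(n_leaves: int, branch_length_mean: float,
                rng: np.random.Generator) -> Phylogeny:
    """Random rooted bifurcating tree by iterative joining, exponential
    branch lengths, leaves sp01..spNN."""
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves")
    subtrees = [f"sp{i + 1:02d}" for i in range(n_leaves)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        bl, br = rng.exponential(branch_length_mean, size=2)
        subtrees.append(f"({left}:{bl:.6f},{right}:{br:.6f})")
    return tree_from_newick(subtrees[0] + ";")


def sample_root_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A valid ORF: ATG start, random non-stop body codons, TAA/TAG/TGA end."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons")
    body = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2)
    stop = sorted(STOP_CODONS)[rng.integers(3)]
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in body) + stop


# ---------------------------------------------------------------------------
# substitution process


def _mutate(seq: np.ndarray, distance: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor-like substitutions; first/last codon frozen and
    mutations that would create an in-frame stop codon are reverted."""
    child = seq.copy()
    n = seq.size
    if distance <= 0 or n <= 6:
        return child
    p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * distance))
    mask = rng.random(n) < p
    mask[:3] = False
    mask[n - 3:] = False
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return child
    shift = rng.integers(1, 4, size=idx.size).astype(np.uint8)
    base_idx = np.searchsorted(_BASES, child[idx])
    child[idx] = _BASES[(base_idx + shift) % 4]
    # revert mutations whose codon became a stop
    stops = {tuple(s.encode()) for s in STOP_CODONS}
    for i in idx:
        c0 = (i // 3) * 3
        codon = tuple(child[c0:c0 + 3])
        if codon in stops:
            child[i] = seq[i]
    return child


def evolve_gene(phylo: Phylogeny, root_seq: str, sub_rate_scale: float,
                rng: np.random.Generator) -> dict[str, str]:
    """Evolve the root CDS down the tree; returns leaf label -> sequence."""
    root = np.frombuffer(root_seq.encode(), dtype=np.uint8).copy()
    seqs: dict = {phylo.tree.seed_node: root}
    leaves: dict[str, str] = {}
    for node in phylo.tree.preorder_node_iter():
        if node is phylo.tree.seed_node:
            continue
        d = (node.edge.length or 0.0) * sub_rate_scale
        seqs[node] = _mutate(seqs[node.parent_node], d, rng)
        if node.is_leaf():
            leaves[node.taxon.label] = seqs[node].tobytes().decode()
    return leaves


# ---------------------------------------------------------------------------
# planting


@dataclass
class _Edit:
    pos: int  # ancestral (root) coordinate
    kind: str
    length: int
    carriers: frozenset[str]
    edge: EdgeId
    source: str
    bases: Optional[str] = None  # inserted bases (insertions only)

    @property
    def anc_width(self) -> int:
        return self.length if self.kind == "deletion" else 0


def _pair_edits(pos: int, template: PcfmTemplate) -> tuple[int, int]:
    """Ancestral positions of the 5' and 3' indels of a planted pair."""
    cursor = pos + (template.len_5p if template.kind_5p == "deletion" else 0)
    return pos, cursor + template.spacer_nt


def _derived_carrier_seq(seq: str, edits: Sequence[_Edit]) -> str:
    """Apply edits (ancestral coordinates) to an ungapped sequence."""
    out = seq
    for e in sorted(edits, key=lambda e: e.pos, reverse=True):
        if e.kind == "deletion":
            out = out[:e.pos] + out[e.pos + e.length:]
        else:
            out = out[:e.pos] + e.bases + out[e.pos:]
    return out


def _carriers_pass(leaf_seqs: dict[str, str], carriers: frozenset[str],
                   edits: Sequence[_Edit]) -> bool:
    for sp in carriers:
        derived = _derived_carrier_seq(leaf_seqs[sp], edits)
        cds = CodingSequence("g", sp, derived)
        if not quality_check(cds).passes:
            return False
    return True


def _random_bases(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def simulate(config: SimConfig) -> SimResult:
    """Generate alignments, tree and truth table from a config."""
    rng = np.random.default_rng(config.seed)
    if isinstance(config.tree, Phylogeny):
        phylo = config.tree
    elif isinstance(config.tree, str):
        phylo = tree_from_newick(config.tree)
    else:
        phylo = sample_tree(config.n_leaves, config.branch_length_mean, rng)
    edge_map = phylo.edge_map()

    def leaves_of(edge: EdgeId) -> frozenset[str]:
        if edge not in edge_map:
            raise ConfigConflictError(f"edge {sorted(edge)} not in tree")
        return phylo.leaves_below(edge_map[edge])

    truth = TruthTable()
    alignments: list[GeneAlignment] = []
    for g in range(config.n_genes):
        gene_id = f"gene{g:04d}"
        if isinstance(config.gene_length_codons, tuple):
            lo, hi = config.gene_length_codons
            n_codons = int(rng.integers(lo, hi + 1))
        else:
            n_codons = config.gene_length_codons
        root_seq = sample_root_cds(n_codons, rng)
        leaf_seqs = evolve_gene(phylo, root_seq, config.sub_rate_scale, rng)
        L = len(root_seq)

        edits: list[_Edit] = []
        pair_plans: list[tuple[object, list[_Edit]]] = []

        for planted in config.indels:
            if planted.gene != g:
                continue
            edits.append(_Edit(
                pos=planted.pos, kind=planted.kind, length=planted.length,
                carriers=leaves_of(planted.edge), edge=planted.edge,
                source="single",
                bases=_random_bases(planted.length, rng)
                if planted.kind == "insertion" else None,
            ))

        for planted in list(config.pairs) + list(config.cross_edge_pairs):
            if planted.gene != g:
                continue
            tpl = planted.template
            if isinstance(planted, CrossEdgePair):
                e5, e3 = planted.edge_5p, planted.edge_3p
                source = "cross_edge"
            else:
                e5 = e3 = planted.edge
                source = "pair"
            carriers5, carriers3 = leaves_of(e5), leaves_of(e3)
            joint = carriers5 & carriers3
            if not joint:
                raise ConfigConflictError(
                    f"{gene_id}: cross-edge pair edges share no species"
                )
            span = tpl.ancestral_span
            occupied = _occupied_intervals(edits)

            def make_edits(pos: int) -> list[_Edit]:
                p5, p3 = _pair_edits(pos, tpl)
                return [
                    _Edit(pos=p5, kind=tpl.kind_5p, length=tpl.len_5p,
                          carriers=carriers5, edge=e5, source=source,
                          bases=_random_bases(tpl.len_5p, rng)
                          if tpl.kind_5p == "insertion" else None),
                    _Edit(pos=p3, kind=tpl.kind_3p, length=tpl.len_3p,
                          carriers=carriers3, edge=e3, source=source,
                          bases=_random_bases(tpl.len_3p, rng)
                          if tpl.kind_3p == "insertion" else None),
                ]

            if planted.pos is not None:
                pair_edit = make_edits(planted.pos)
                if _overlaps(planted.pos, span, occupied):
                    raise ConfigConflictError(
                        f"{gene_id}: planted events overlap at {planted.pos}"
                    )
            else:
                pair_edit = None
                for _ in range(config.max_placement_attempts):
                    pos = int(rng.integers(3, L - 3 - max(span, 1) + 1))
                    if _overlaps(pos, span, occupied):
                        continue
                    cand = make_edits(pos)
                    check_set = joint if source == "cross_edge" else carriers5
                    if _carriers_pass(leaf_seqs, check_set, cand):
                        pair_edit = cand
                        break
                if pair_edit is None:
                    raise ConfigConflictError(
                        f"{gene_id}: no valid placement found for {tpl}"
                    )
            edits.extend(pair_edit)
            pair_plans.append((planted, pair_edit))

        _check_overlaps(gene_id, edits, L)
        aln, final_cols = _edits_to_alignment(gene_id, phylo, leaf_seqs, edits)
        alignments.append(aln)

        for e in edits:
            c0, c1 = final_cols[id(e)]
            truth.events.append(TruthEvent(
                gene_id=gene_id, kind=e.kind, length=e.length,
                col_start=c0, col_end=c1, edge=e.edge,
                carriers=e.carriers, source=e.source,
            ))
        for planted, pair_edit in pair_plans:
            e5, e3 = pair_edit
            tpl = planted.template
            truth.pairs.append(TruthPair(
                gene_id=gene_id, template=tpl,
                edge_5p=e5.edge, edge_3p=e3.edge,
                cols_5p=final_cols[id(e5)], cols_3p=final_cols[id(e3)],
                carriers=e5.carriers & e3.carriers,
                pos=e5.pos, same_edge=e5.edge == e3.edge,
            ))

        _apply_pseudogenization(config, g, aln, rng)
    return SimResult(alignments=alignments, phylogeny=phylo, truth=truth)


def _occupied_intervals(edits: Sequence[_Edit]) -> list[tuple[int, int]]:
    return [(e.pos, e.pos + max(e.anc_width, 1)) for e in edits]


def _overlaps(pos: int, span: int, occupied: Sequence[tuple[int, int]],
              margin: int = 3) -> bool:
    lo, hi = pos - margin, pos + max(span, 1) + margin
    return any(not (hi <= a or b <= lo) for a, b in occupied)


def _check_overlaps(gene_id: str, edits: Sequence[_Edit], L: int) -> None:
    intervals = sorted(_occupied_intervals(edits))
    for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
        if b0 < a1:
            raise ConfigConflictError(
                f"{gene_id}: planted events overlap at {b0}"
            )
    for a0, a1 in intervals:
        if a0 < 3 or a1 > L - 3:
            raise ConfigConflictError(
                f"{gene_id}: planted event [{a0},{a1}) outside CDS interior"
            )


def _edits_to_alignment(
    gene_id: str,
    phylo: Phylogeny,
    leaf_seqs: dict[str, str],
    edits: Sequence[_Edit],
) -> tuple[GeneAlignment, dict[int, tuple[int, int]]]:
    """Apply edits to the leaf sequences, producing a gapped alignment and
    the final alignment columns of every edit."""
    species = sorted(leaf_seqs)
    rows = {sp: list(leaf_seqs[sp]) for sp in species}
    final_cols: dict[int, tuple[int, int]] = {}
    cum_ins = 0
    for e in sorted(edits, key=lambda e: e.pos):
        col = e.pos + cum_ins
        if e.kind == "deletion":
            for sp in species:
                if sp in e.carriers:
                    for c in range(col, col + e.length):
                        rows[sp][c] = "-"
            final_cols[id(e)] = (col, col + e.length)
        else:
            for sp in species:
                fill = e.bases if sp in e.carriers else "-" * e.length
                rows[sp][col:col] = list(fill)
            final_cols[id(e)] = (col, col + e.length)
            cum_ins += e.length
    aln = GeneAlignment(
        gene_id=gene_id, species_ids=species,
        rows={sp: "".join(chars) for sp, chars in rows.items()},
    )
    return aln, final_cols


def _apply_pseudogenization(config: SimConfig, g: int, aln: GeneAlignment,
                            rng: np.random.Generator) -> None:
    for p in config.pseudogenize:
        if p.gene != g:
            continue
        row = list(aln.rows[p.species])
        non_gap = [i for i, ch in enumerate(row) if ch != "-"]
        if p.defect == "no_start":
            row[non_gap[0]] = "C"
        elif p.defect == "no_stop":
            row[non_gap[-3]] = "G"
        elif p.defect == "internal_stop":
            k = len(non_gap) // 2
            k -= k % 3
            for off, ch in enumerate("TAA"):
                row[non_gap[k + off]] = ch
        elif p.defect == "len_mod3":
            row[non_gap[len(non_gap) // 2]] = "-"
        else:
            raise ConfigConflictError(f"unknown defect {p.defect!r}")
        aln.rows[p.species] = "".join(row)


# ---------------------------------------------------------------------------
# control pools and planting into existing alignments


def make_control_pool(
    n: int,
    mean_length_nt: float = 1897.0,
    sigma: float = 0.45,
    min_codons: int = 60,
    seed: int = 0,
) -> list[CodingSequence]:
    """Ungapped quality-passing CDS pool with lognormal lengths whose mean
    matches the clade's mean gene length (1897 nt vertebrates, 1204 nt
    insects)."""
    rng = np.random.default_rng(seed)
    mean_codons = mean_length_nt / 3.0
    mu = np.log(mean_codons) - sigma ** 2 / 2.0
    out = []
    for i in range(n):
        n_codons = max(min_codons, int(round(rng.lognormal(mu, sigma))))
        out.append(CodingSequence(
            gene_id=f"ctrl{i:04d}", species_id="pool",
            nt=sample_root_cds(n_codons, rng),
        ))
    return out


def plant_pair_in_alignment(
    aln: GeneAlignment,
    phylo: Phylogeny,
    edge: EdgeId,
    template: PcfmTemplate,
    rng: np.random.Generator,
    max_attempts: int = 50,
) -> Optional[GeneAlignment]:
    """Plant a compensatory pair on an edge of an existing alignment.

    A gap-free column window is sampled; deletions blank the carrier
    rows, insertions add new columns carried only by the edge's species.
    Returns None when no placement keeps all carriers quality-passing.
    """
    edge_map = phylo.edge_map()
    if edge not in edge_map:
        return None
    carriers = phylo.leaves_below(edge_map[edge]) & set(aln.species_ids)
    if not carriers or carriers == set(aln.species_ids):
        return None
    span = max(template.ancestral_span, 1)
    n = aln.n_columns
    if n - 6 - span <= 3:
        return None
    gap_free = np.ones(n, dtype=bool)
    for sp in aln.species_ids:
        row = np.frombuffer(aln.rows[sp].encode(), dtype=np.uint8)
        gap_free &= row != ord("-")
    ok_start = np.array([
        gap_free[i:i + span].all() for i in range(3, n - 3 - span + 1)
    ])
    candidates = np.nonzero(ok_start)[0] + 3
    if candidates.size == 0:
        return None
    for _ in range(max_attempts):
        pos = int(candidates[rng.integers(candidates.size)])
        p5, p3 = _pair_edits(pos, template)
        edits = [
            _Edit(pos=p5, kind=template.kind_5p, length=template.len_5p,
                  carriers=frozenset(carriers), edge=edge, source="pair",
                  bases=_random_bases(template.len_5p, rng)
                  if template.kind_5p == "insertion" else None),
            _Edit(pos=p3, kind=template.kind_3p, length=template.len_3p,
                  carriers=frozenset(carriers), edge=edge, source="pair",
                  bases=_random_bases(template.len_3p, rng)
                  if template.kind_3p == "insertion" else None),
        ]
        ungapped = {sp: aln.rows[sp] for sp in carriers}
        # edits are in column coordinates == per-row coordinates only when
        # rows are gap-free up to the window; validate on the edited rows
        rows = {sp: list(aln.rows[sp]) for sp in aln.species_ids}
        cum = 0
        for e in sorted(edits, key=lambda e: e.pos):
            col = e.pos + cum
            if e.kind == "deletion":
                for sp in carriers:
                    for c in range(col, col + e.length):
                        rows[sp][c] = "-"
            else:
                for sp in aln.species_ids:
                    fill = e.bases if sp in carriers else "-" * e.length
                    rows[sp][col:col] = list(fill)
                cum += e.length
        planted = GeneAlignment(
            gene_id=aln.gene_id, species_ids=list(aln.species_ids),
            rows={sp: "".join(ch) for sp, ch in rows.items()},
        )
        ok = True
        for sp in carriers:
            cds = planted.ungapped(sp)
            if not cds.nt or not quality_check(cds).passes:
                ok = False
                break
        if ok:
            return planted
    return None
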