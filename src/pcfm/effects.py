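"""Effect of a compensatory frameshift pair on the encoded protein.

Two physicochemical similarity metrics are used: the mean Miyata (1979)
distance between positionally paired residues, and the absolute
difference of the mean Kyte-Doolittle hydropathy of the two peptides.
The Miyata matrix is derived from Grantham's polarity and volume scales,
d(a, b) = sqrt((dp / sigma_p)^2 + (dv / sigma_v)^2), with the two
normalization constants calibrated so the matrix reproduces the
published table at its printed 2-decimal precision; its maximum, 5.13,
is attained by the glycine-tryptophan pair.  Gaps, stop codons and
undetermined residues score the maximum distance.

The expected similarity under "no selection on the frameshifted
peptide" comes from an empirical null: the same indel-pair template
(kinds, lengths, spacer) is planted in silico at random positions of
random genes, and the spanned region is scored before and after.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .detection import PcfmRecord
from .phylo import Phylogeny
from .seqio import CodingSequence, GeneAlignment, translate

GAP_OR_STOP_DISTANCE = 5.13  # maximum Miyata distance (Gly-Trp)

#: Grantham (1974) polarity and volume, the inputs of the Miyata scale
GRANTHAM_POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}
GRANTHAM_VOLUME = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0,
    "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0,
    "M": 105.0, "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0,
    "Y": 136.0, "V": 84.0,
}
# normalization constants of the Miyata scale (calibrated against the
# published distance table; see docs/methods.md)
_SIGMA_POLARITY = 2.15746
_SIGMA_VOLUME = 34.39636

#: Kyte-Doolittle hydropathy index, -4.5 (Arg) .. +4.5 (Ile)
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"


def _build_miyata() -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            dp = (GRANTHAM_POLARITY[a] - GRANTHAM_POLARITY[b]) / _SIGMA_POLARITY
            dv = (GRANTHAM_VOLUME[a] - GRANTHAM_VOLUME[b]) / _SIGMA_VOLUME
            table[(a, b)] = round(math.hypot(dp, dv), 2)
    return table


MIYATA_MATRIX = _build_miyata()


class PlacementError(ValueError):
    """In-silico pair placement does not fit inside the CDS."""


class InfeasibleTemplateError(ValueError):
    pass


class UndefinedScoreError(ValueError):
    pass


class LowConfidenceReconstructionError(ValueError):
    pass


@dataclass(frozen=True)
class PcfmTemplate:
    """Shape of a compensatory pair: indel kinds, lengths and spacer.

    The spacer counts nucleotides strictly between the two indels; the
    net length change must be divisible by 3 (frame restoration).
    """

    kind_5p: str
    len_5p: int
    kind_3p: str
    len_3p: int
    spacer_nt: int

    def __post_init__(self) -> None:
        for kind in (self.kind_5p, self.kind_3p):
            if kind not in ("insertion", "deletion"):
                raise ValueError(f"bad indel kind {kind!r}")
        if self.len_5p < 1 or self.len_3p < 1 or self.spacer_nt < 0:
            raise ValueError("lengths must be >= 1 and spacer >= 0")
        if self.net_offset % 3 != 0:
            raise ValueError(
                f"net length change {self.net_offset} not divisible by 3"
            )

    @property
    def net_offset(self) -> int:
        off5 = self.len_5p if self.kind_5p == "insertion" else -self.len_5p
        off3 = self.len_3p if self.kind_3p == "insertion" else -self.len_3p
        return off5 + off3

    @property
    def ancestral_span(self) -> int:
        """Nucleotides of the original sequence consumed by the pair."""
        span = self.spacer_nt
        if self.kind_5p == "deletion":
            span += self.len_5p
        if self.kind_3p == "deletion":
            span += self.len_3p
        return span

    @classmethod
    def from_record(cls, pair: PcfmRecord) -> "PcfmTemplate":
        return cls(
            kind_5p=pair.indel_5p.kind, len_5p=pair.indel_5p.length_nt,
            kind_3p=pair.indel_3p.kind, len_3p=pair.indel_3p.length_nt,
            spacer_nt=pair.spacer_nt,
        )


@dataclass
class NullDistribution:
    """Empirical null of region distances for one pair template."""

    template: PcfmTemplate
    metric: str
    draws: np.ndarray
    seed: int
    observed: Optional[float] = None
    percentile_p: Optional[float] = None

    @property
    def n_draws(self) -> int:
        return int(self.draws.size)

    def with_observed(self, observed: float) -> "NullDistribution":
        p = (1 + int(np.sum(self.draws <= observed))) / (self.n_draws + 1)
        return replace(self, observed=observed, percentile_p=p)


@dataclass
class StateQuartet:
    """Region peptides at the four states around a pair-carrying edge.

    A: ancestral; E: derived.  A_mut carries only the same-branch
    substitutions (ancestral frame); A_fr carries only the pair (shifted
    frame).  The intermediates are omitted when no same-branch
    substitutions exist, or when those substitutions are synonymous in
    one frame context but not the other (ill-defined intermediates).
    """

    A: str
    E: str
    A_mut: Optional[str] = None
    A_fr: Optional[str] = None
    n_substitutions: int = 0

    @property
    def defined_states(self) -> dict[str, str]:
        out = {"A": self.A, "E": self.E}
        if self.A_mut is not None:
            out["A_mut"] = self.A_mut
        if self.A_fr is not None:
            out["A_fr"] = self.A_fr
        return out


@dataclass
class QuartetDistances:
    distances: dict[tuple[str, str], float]
    hypothesis_subs_after: Optional[bool]  # d(A,E) < d(A,A_fr)
    hypothesis_subs_before: Optional[bool]  # d(A_mut,E) < d(A,A_fr)


# ---------------------------------------------------------------------------
# distance metrics


def _pad_pair(pep1: str, pep2: str) -> tuple[str, str]:
    """Right-pad the shorter peptide with gaps (positional pairing of two
    regions whose lengths differ by the net codon change of the pair)."""
    n = max(len(pep1), len(pep2))
    return pep1.ljust(n, "-"), pep2.ljust(n, "-")


def miyata_mean(pep1: str, pep2: str) -> float:
    """Mean Miyata distance over positionally paired residues.

    Positions involving a gap, stop or undetermined residue score the
    maximum distance 5.13.  Both peptides must have equal length (use
    :func:`region_distance` for raw frameshift regions).
    """
    if len(pep1) != len(pep2):
        raise ValueError("peptides must have equal length")
    if not pep1:
        raise UndefinedScoreError("empty peptides")
    total = 0.0
    for a, b in zip(pep1, pep2):
        if a in MIYATA_MATRIX_ROWS and b in MIYATA_MATRIX_ROWS:
            total += MIYATA_MATRIX[(a, b)]
        else:
            total += GAP_OR_STOP_DISTANCE
    return total / len(pep1)


MIYATA_MATRIX_ROWS = frozenset(AMINO_ACIDS)


def hydropathy_diff(pep1: str, pep2: str) -> float:
    """Absolute difference of mean Kyte-Doolittle hydropathy.

    Gaps, stops and undetermined residues are excluded from each mean;
    raises :class:`UndefinedScoreError` when either peptide has no
    scoreable residue.
    """
    def mean_h(pep: str) -> float:
        vals = [KYTE_DOOLITTLE[ch] for ch in pep if ch in KYTE_DOOLITTLE]
        if not vals:
            raise UndefinedScoreError("no scoreable residues")
        return sum(vals) / len(vals)

    return abs(mean_h(pep1) - mean_h(pep2))


def score_metric(metric: str, pep1: str, pep2: str) -> float:
    pep1, pep2 = _pad_pair(pep1, pep2)
    if metric == "miyata":
        return miyata_mean(pep1, pep2)
    if metric == "hydropathy":
        return hydropathy_diff(pep1, pep2)
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# in-silico pair application


def _edit_sequence(
    nt: str, pos: int, template: PcfmTemplate, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Apply the template; return (derived nt, anc span start, anc span end).

    The 5' indel acts at ancestral position ``pos``; the 3' indel acts
    ``spacer_nt`` ancestral nucleotides downstream of the 5' indel's 3'
    boundary.  Inserted bases are drawn uniformly from ACGT.
    """
    if template.kind_5p == "deletion":
        cursor = pos + template.len_5p
    else:
        cursor = pos
    pos3 = cursor + template.spacer_nt
    span_end = pos3 + (template.len_3p if template.kind_3p == "deletion" else 0)
    if pos < 3 or span_end > len(nt) - 3:
        raise PlacementError(
            f"pair at {pos} (span end {span_end}) does not fit inside the "
            f"CDS interior (length {len(nt)})"
        )
    # apply 3' edit first so the 5' coordinates stay valid
    def edit(seq: str, at: int, kind: str, length: int) -> str:
        if kind == "deletion":
            return seq[:at] + seq[at + length:]
        ins = "".join(rng.choice(list("ACGT"), size=length))
        return seq[:at] + ins + seq[at:]

    derived = edit(nt, pos3, template.kind_3p, template.len_3p)
    derived = edit(derived, pos, template.kind_5p, template.len_5p)
    return derived, pos, span_end


def apply_pcfm(
    cds: CodingSequence,
    pos: int,
    template: PcfmTemplate,
    seed: int | np.random.Generator = 0,
) -> CodingSequence:
    """Plant an in-silico compensatory pair in an ungapped CDS.

    The sequence outside the spanned region is untouched, and because the
    net length change is divisible by 3 the translation downstream of the
    3' indel is identical to the original.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    derived, _, _ = _edit_sequence(cds.nt, pos, template, rng)
    return CodingSequence(gene_id=cds.gene_id, species_id=cds.species_id, nt=derived)


def region_windows(
    nt_len: int, pos: int, template: PcfmTemplate
) -> tuple[int, int, int, int]:
    """Codon-aligned scoring windows around a planted pair.

    Returns (anc_start, anc_end, der_start, der_end): the ancestral
    window extended to codon boundaries, and the corresponding derived
    window (same start; end shifted by the net length change).
    """
    span_start = pos
    span_end_anc = (
        pos
        + (template.len_5p if template.kind_5p == "deletion" else 0)
        + template.spacer_nt
        + (template.len_3p if template.kind_3p == "deletion" else 0)
    )
    anc_start = (span_start // 3) * 3
    anc_end = -(-span_end_anc // 3) * 3
    anc_end = min(anc_end, (nt_len // 3) * 3)
    return anc_start, anc_end, anc_start, anc_end + template.net_offset


def pair_effect(
    cds: CodingSequence,
    pos: int,
    template: PcfmTemplate,
    metric: str,
    rng: np.random.Generator,
) -> float:
    """Distance between the original and in-silico-shifted region peptides."""
    derived, _, _ = _edit_sequence(cds.nt, pos, template, rng)
    a0, a1, d0, d1 = region_windows(len(cds.nt), pos, template)
    pep_anc = translate(cds.nt[a0:a1])
    pep_der = translate(derived[d0:d1])
    return score_metric(metric, pep_anc, pep_der)


def valid_positions(nt_len: int, template: PcfmTemplate) -> tuple[int, int]:
    """Half-open range of valid 5' positions (start and stop codons are
    excluded from placement)."""
    last = nt_len - 3 - template.ancestral_span
    return 3, last + 1


def build_null(
    genes: Sequence[CodingSequence],
    template: PcfmTemplate,
    metric: str = "miyata",
    n_draws: int = 10_000,
    seed: int = 0,
) -> NullDistribution:
    """Empirical null distribution of region distances for one template.

    Each draw samples a gene uniformly, a valid placement uniformly
    within it, plants the template, and scores the spanned region of the
    original versus the shifted sequence.  Deterministic under the seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    feasible = [
        (g, *valid_positions(len(g.nt), template))
        for g in genes
        if valid_positions(len(g.nt), template)[1]
        > valid_positions(len(g.nt), template)[0]
    ]
    if not feasible:
        raise InfeasibleTemplateError(
            f"no gene admits a valid placement for {template}"
        )
    draws = np.empty(n_draws)
    for i in range(n_draws):
        # a draw whose region peptide has no scoreable residue (e.g. all
        # stops in the shifted frame under the hydropathy metric) is
        # undefined and redrawn
        for _ in range(100):
            g, lo, hi = feasible[rng.integers(len(feasible))]
            pos = int(rng.integers(lo, hi))
            try:
                draws[i] = pair_effect(g, pos, template, metric, rng)
                break
            except UndefinedScoreError:
                continue
        else:
            raise InfeasibleTemplateError(
                f"metric undefined for virtually all placements of {template}"
            )
    return NullDistribution(template=template, metric=metric, draws=draws, seed=seed)


def bonferroni_significant(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Family-wise significance flags at alpha / k."""
    k = len(p_values)
    return [p < alpha / k for p in p_values]


# ---------------------------------------------------------------------------
# ancestral/derived quartet over the spanned region


_NUC_STATES = ("A", "C", "G", "T", "-")
_FULL_SET = frozenset(_NUC_STATES)


def _fitch_column(
    phylo: Phylogeny, leaf_state: dict[str, str]
) -> tuple[dict, dict]:
    """Fitch sets (bottom-up) and resolved states (top-down) for one
    alignment column over nucleotide-or-gap states; 'N' is missing."""
    sets: dict = {}
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            st = leaf_state.get(node.taxon.label, "N")
            sets[node] = _FULL_SET if st == "N" else frozenset({st})
        else:
            child_sets = [sets[c] for c in node.child_nodes()]
            inter = frozenset.intersection(*child_sets)
            sets[node] = inter if inter else frozenset.union(*child_sets)
    resolved: dict = {}
    for node in phylo.tree.preorder_node_iter():
        options = sets[node]
        if node is phylo.tree.seed_node:
            choice = min(options, key=_NUC_STATES.index)
        else:
            parent_state = resolved[node.parent_node]
            choice = (parent_state if parent_state in options
                      else min(options, key=_NUC_STATES.index))
        resolved[node] = choice
    return sets, resolved


def ancestral_states(
    aln: GeneAlignment,
    phylo: Phylogeny,
    pair: PcfmRecord,
    max_ambiguous_fraction: float = 0.5,
) -> StateQuartet:
    """Reconstruct the A / A_mut / A_fr / E peptides over the spanned region.

    Nucleotide (and gap) states at the two endpoints of the pair-carrying
    edge are reconstructed by parsimony per column; the scored window is
    the pair's span extended to ancestral codon boundaries.  All
    substitutions on the branch are assumed simultaneous, as are the two
    indels, yielding the two timing scenarios (substitutions before or
    after the frameshift).
    """
    if not pair.same_edge:
        raise ValueError("quartet reconstruction requires a single-edge pair")
    edge_map = phylo.edge_map()
    child = edge_map.get(pair.edge)
    if child is None:
        raise ValueError(f"edge {pair.edge_label} not found in tree")
    parent = child.parent_node

    cols = range(aln.n_columns)
    parent_state: list[str] = []
    child_state: list[str] = []
    span = pair.span_cols
    n_ambiguous = 0
    for col in cols:
        leaf_state = {sp: aln.rows[sp][col] for sp in aln.species_ids}
        sets, resolved = _fitch_column(phylo, leaf_state)
        parent_state.append(resolved[parent] if parent is not None
                            else resolved[child])
        child_state.append(resolved[child])
        if span[0] <= col < span[1]:
            amb = (len(sets[child]) > 1) or (
                parent is not None and len(sets[parent]) > 1
            )
            if amb:
                n_ambiguous += 1
    span_len = span[1] - span[0]
    if span_len and n_ambiguous / span_len > max_ambiguous_fraction:
        raise LowConfidenceReconstructionError(
            f"{pair.gene_id}: {n_ambiguous}/{span_len} spanned columns "
            f"ambiguous in the parsimony reconstruction"
        )

    window = _window_columns(parent_state, span)
    w0, w1 = window

    def build(presence_from: list[str], base_from: list[str],
              fallback: list[str]) -> str:
        chars = []
        for c in range(w0, w1):
            if presence_from[c] == "-":
                continue
            base = base_from[c] if base_from[c] != "-" else fallback[c]
            chars.append(base)
        return "".join(chars)

    a_nt = build(parent_state, parent_state, parent_state)
    e_nt = build(child_state, child_state, child_state)
    amut_nt = build(parent_state, child_state, parent_state)
    afr_nt = build(child_state, parent_state, child_state)

    A, E = translate(a_nt), translate(e_nt)
    A_mut, A_fr = translate(amut_nt), translate(afr_nt)

    subs = sum(
        1 for c in range(w0, w1)
        if parent_state[c] != "-" and child_state[c] != "-"
        and parent_state[c] != child_state[c]
    )
    if subs == 0:
        return StateQuartet(A=A, E=E, n_substitutions=0)
    syn_ancestral_frame = A_mut == A
    syn_shifted_frame = E == A_fr
    if syn_ancestral_frame != syn_shifted_frame:
        # synonymous in one frame context, nonsynonymous in the other:
        # the intermediates are ill-defined
        return StateQuartet(A=A, E=E, n_substitutions=subs)
    return StateQuartet(A=A, E=E, A_mut=A_mut, A_fr=A_fr, n_substitutions=subs)


def _window_columns(parent_state: list[str], span: tuple[int, int]) -> tuple[int, int]:
    """Column interval whose ancestral projection is codon-aligned and
    covers the pair's span."""
    anc_before_start = sum(1 for c in range(span[0]) if parent_state[c] != "-")
    anc_before_end = sum(1 for c in range(span[1]) if parent_state[c] != "-")
    w_start_anc = (anc_before_start // 3) * 3
    w_end_anc = -(-anc_before_end // 3) * 3
    total_anc = sum(1 for s in parent_state if s != "-")
    w_end_anc = min(w_end_anc, (total_anc // 3) * 3)

    count = 0
    w0 = 0
    w1 = len(parent_state)
    for c, st in enumerate(parent_state):
        if st != "-":
            if count == w_start_anc:
                w0 = c
            count += 1
            if count == w_end_anc:
                w1 = c + 1
                break
    # include trailing derived-only (inserted) columns of the span
    w1 = max(w1, span[1])
    w0 = min(w0, span[0])
    return w0, w1


def quartet_distances(q: StateQuartet, metric: str = "miyata") -> QuartetDistances:
    """Pairwise distances among the defined quartet states.

    Flags the substitutions-after scenario when d(A, E) < d(A, A_fr) and
    the substitutions-before scenario when d(A_mut, E) < d(A, A_fr).
    """
    states = q.defined_states
    dists: dict[tuple[str, str], float] = {}
    names = list(states)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            dists[(a, b)] = score_metric(metric, states[a], states[b])

    def d(a: str, b: str) -> Optional[float]:
        if (a, b) in dists:
            return dists[(a, b)]
        return dists.get((b, a))

    hyp1 = hyp2 = None
    if "A_fr" in states:
        base = d("A", "A_fr")
        hyp1 = d("A", "E") < base
        if "A_mut" in states:
            hyp2 = d("A_mut", "E") < base
    return QuartetDistances(
        distances=dists,
        hypothesis_subs_after=hyp1,
        hypothesis_subs_before=hyp2,
    )


@dataclass
class LeafTrajectory:
    species_id: str
    distance_to_ancestor: float
    compensated: bool  # closer to A than E is


def descendant_trajectories(
    aln: GeneAlignment,
    phylo: Phylogeny,
    pair: PcfmRecord,
    metric: str = "miyata",
) -> list[LeafTrajectory]:
    """Per-carrier-leaf region distance to the ancestral peptide.

    Substitutions on branches descending from the pair may pull the
    region peptide back toward the ancestral one; a leaf is flagged
    compensated when its distance to A is below d(A, E).
    """
    if not pair.carrier_species:
        raise ValueError("pair has no carrier species")
    q = ancestral_states(aln, phylo, pair)
    d_ae = score_metric(metric, q.A, q.E)

    # recompute the window from the ancestral reconstruction
    edge_map = phylo.edge_map()
    child = edge_map[pair.edge]
    parent = child.parent_node or child
    parent_state = []
    for col in range(aln.n_columns):
        leaf_state = {sp: aln.rows[sp][col] for sp in aln.species_ids}
        _, resolved = _fitch_column(phylo, leaf_state)
        parent_state.append(resolved[parent])
    w0, w1 = _window_columns(parent_state, pair.span_cols)

    out = []
    for sp in sorted(pair.carrier_species):
        leaf_nt = aln.rows[sp][w0:w1].replace("-", "")
        pep = translate(leaf_nt)
        dist = score_metric(metric, q.A, pep)
        out.append(LeafTrajectory(
            species_id=sp,
            distance_to_ancestor=dist,
            compensated=dist < d_ae,
        ))
    return out
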