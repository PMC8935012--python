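"""Pairing of mutually compensatory frameshifting indels and the filter
cascade.

A candidate pair is two frame-disrupting indels (length not divisible by
3) carried by a quality-passing species, with a net length change
divisible by 3 so that the reading frame downstream of the second indel
is restored.  Species carrying more than two frame-disrupting indels are
considered unreliable and contribute nothing.  The low-confidence filter
keeps pairs of short indels (each 1-2 nt, combined length <= 4) placed on
one tree edge; the high-confidence filter additionally requires the pair
to be inherited by at least two species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .indels import IndelEvent
from .phylo import edge_label
from .seqio import GeneAlignment, QualityReport

log = logging.getLogger(__name__)


class DegenerateSpanError(ValueError):
    """The pair spans the entire CDS; relative position undefined."""


@dataclass(frozen=True)
class PcfmRecord:
    """A validated pair of mutually compensatory frameshifting indels."""

    gene_id: str
    indel_5p: IndelEvent
    indel_3p: IndelEvent
    spacer_nt: int  # derived-frame nucleotides strictly between the indels
    spacer_nt_ancestral: int  # same interval counted on the ancestral row
    carrier_species: frozenset[str]
    p1: int  # ancestral ungapped coordinate of the 5' indel's 5' edge
    p2: int  # ancestral ungapped coordinate of the 3' indel's 3' edge
    cds_length: int  # ancestral ungapped reference length

    def __post_init__(self) -> None:
        if self.indel_5p.col_end > self.indel_3p.col_start:
            raise ValueError(f"{self.gene_id}: overlapping indels in pair")
        for ev in (self.indel_5p, self.indel_3p):
            if not ev.frame_disrupting:
                raise ValueError(f"{self.gene_id}: indel not frame-disrupting")
        if self.combined_offset % 3 != 0:
            raise ValueError(f"{self.gene_id}: net offset not divisible by 3")

    @property
    def combined_offset(self) -> int:
        return self.indel_5p.signed_offset + self.indel_3p.signed_offset

    @property
    def combined_length(self) -> int:
        return self.indel_5p.length_nt + self.indel_3p.length_nt

    @property
    def same_edge(self) -> bool:
        return self.indel_5p.edge == self.indel_3p.edge

    @property
    def edge(self):
        return self.indel_5p.edge if self.same_edge else None

    @property
    def edge_label(self) -> str:
        return edge_label(self.indel_5p.edge) if self.same_edge else "cross-edge"

    @property
    def span_cols(self) -> tuple[int, int]:
        return (self.indel_5p.col_start, self.indel_3p.col_end)


@dataclass(frozen=True)
class RelativePosition:
    """Relative position of a pair along the CDS: P = p1 / (L - (p2 - p1)).

    P = 0 when the 5' indel sits at the 5'-most end of the CDS and P = 1
    when the 3' indel sits at the 3'-most end.
    """

    p1: int
    p2: int
    L: int
    P: float


@dataclass
class PositionTestReport:
    """Comparison of observed relative positions with uniformity and with
    a reference distribution, plus bootstrap density bands."""

    ks_uniform_stat: float
    ks_uniform_p: float
    ks_twosample_stat: Optional[float]
    ks_twosample_p: Optional[float]
    bin_edges: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)
    density_ci_low: np.ndarray = field(repr=False)
    density_ci_high: np.ndarray = field(repr=False)


def _reference_species(
    aln: GeneAlignment,
    quality: Mapping[str, QualityReport],
    carriers: frozenset[str],
) -> str:
    """A deterministic non-carrier row used as the ancestral coordinate
    reference (prefer quality-passing non-carriers)."""
    passing = [sp for sp in aln.species_ids
               if sp not in carriers and quality.get(sp) and quality[sp].passes]
    if passing:
        return passing[0]
    non_carriers = [sp for sp in aln.species_ids if sp not in carriers]
    return non_carriers[0] if non_carriers else aln.species_ids[0]


def _ungapped_before(row: str, col: int) -> int:
    return sum(1 for ch in row[:col] if ch != "-")


def pair_pcfms(
    events: Sequence[IndelEvent],
    quality: Mapping[str, QualityReport],
    aln: GeneAlignment,
) -> list[PcfmRecord]:
    """Identify compensatory pairs among the reconstructed indel events.

    Only species passing all four ORF quality criteria are considered.  A
    passing species with exactly two frame-disrupting events forms a
    candidate pair; the pair is emitted iff its net length change is
    divisible by 3 and the events do not overlap.  Species sharing the
    same two events are merged into one record with the union carrier
    set.  Species with more than two frame-disrupting events contribute
    nothing.
    """
    by_pair: dict[tuple[IndelEvent, IndelEvent], set[str]] = {}
    for sp, rep in quality.items():
        if not rep.passes:
            continue
        mine = [e for e in events
                if sp in e.descendant_species and e.frame_disrupting]
        if len(mine) != 2:
            if len(mine) > 2:
                log.debug("%s: %d frame-disrupting indels, excluded", sp, len(mine))
            continue
        e1, e2 = sorted(mine, key=lambda e: (e.col_start, e.col_end))
        if (e1.signed_offset + e2.signed_offset) % 3 != 0:
            continue
        if e1.col_end > e2.col_start:
            continue
        by_pair.setdefault((e1, e2), set()).add(sp)

    records: list[PcfmRecord] = []
    for (e1, e2), carriers in sorted(
        by_pair.items(), key=lambda kv: (kv[0][0].col_start, kv[0][1].col_start)
    ):
        carriers_f = frozenset(carriers)
        carrier_row = aln.rows[min(carriers_f)]
        spacer_derived = sum(
            1 for ch in carrier_row[e1.col_end:e2.col_start] if ch != "-"
        )
        ref = _reference_species(aln, quality, carriers_f)
        ref_row = aln.rows[ref]
        spacer_anc = sum(
            1 for ch in ref_row[e1.col_end:e2.col_start] if ch != "-"
        )
        records.append(PcfmRecord(
            gene_id=e1.gene_id,
            indel_5p=e1,
            indel_3p=e2,
            spacer_nt=spacer_derived,
            spacer_nt_ancestral=spacer_anc,
            carrier_species=carriers_f,
            p1=_ungapped_before(ref_row, e1.col_start),
            p2=_ungapped_before(ref_row, e2.col_end),
            cds_length=_ungapped_before(ref_row, aln.n_columns),
        ))
    return records


#: allowed (sorted lengths, same kind?) combinations for short pairs
_ALLOWED_COMBOS = {
    ((1, 2), True),   # 1+2 insertions or 1+2 deletions, net 3
    ((1, 1), False),  # 1-nt insertion vs 1-nt deletion, net 0
    ((2, 2), False),  # 2-nt insertion vs 2-nt deletion, net 0
}


def postfilter(pairs: Sequence[PcfmRecord], mode: str) -> list[PcfmRecord]:
    """Apply the short-indel/same-edge filter cascade.

    ``low_confidence``: both indels 1-2 nt, combined length <= 4, allowed
    type combination, single-edge placement.  ``high_confidence``
    additionally requires the pair to be carried by >= 2 species.
    """
    if mode not in ("low_confidence", "high_confidence"):
        raise ValueError(f"unknown postfilter mode: {mode!r}")
    kept = []
    for pair in pairs:
        if not pair.same_edge:
            continue
        l5, l3 = pair.indel_5p.length_nt, pair.indel_3p.length_nt
        if max(l5, l3) > 2 or l5 + l3 > 4:
            continue
        combo = (tuple(sorted((l5, l3))), pair.indel_5p.kind == pair.indel_3p.kind)
        if combo not in _ALLOWED_COMBOS:
            continue
        if mode == "high_confidence" and len(pair.carrier_species) < 2:
            continue
        kept.append(pair)
    return kept


def relative_position(pair: PcfmRecord, cds_length: int | None = None) -> RelativePosition:
    """Relative position P of the pair along the (ancestral) CDS.

    P = p1 / (L - (p2 - p1)); raises :class:`DegenerateSpanError` when
    the pair spans the whole CDS.
    """
    L = cds_length if cds_length is not None else pair.cds_length
    p1, p2 = pair.p1, pair.p2
    if not (0 <= p1 <= p2 <= L):
        raise ValueError(f"inconsistent positions p1={p1}, p2={p2}, L={L}")
    denom = L - (p2 - p1)
    if denom == 0:
        raise DegenerateSpanError(f"{pair.gene_id}: pair spans the entire CDS")
    P = min(max(p1 / denom, 0.0), 1.0)
    return RelativePosition(p1=p1, p2=p2, L=L, P=P)


def compare_position_distributions(
    observed: Sequence[float],
    reference: Sequence[float] | None,
    n_boot: int = 1000,
    seed: int = 0,
    n_bins: int = 20,
) -> PositionTestReport:
    """KS tests of observed relative positions plus bootstrap density CIs.

    Tests the observed positions against Uniform(0, 1) (one-sample KS)
    and, when a reference sample is given, against it (two-sample KS).
    Binned density curves carry 95% bootstrap confidence bands.
    """
    if len(observed) == 0:
        raise ValueError("observed positions empty")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    obs = np.asarray(observed, dtype=float)
    ks1 = stats.kstest(obs, "uniform")
    if reference is not None and len(reference):
        ks2 = stats.ks_2samp(obs, np.asarray(reference, dtype=float))
        ks2_stat, ks2_p = float(ks2.statistic), float(ks2.pvalue)
    else:
        ks2_stat = ks2_p = None
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    density, _ = np.histogram(obs, bins=edges, density=True)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, n_bins))
    for b in range(n_boot):
        resample = rng.choice(obs, size=obs.size, replace=True)
        boot[b], _ = np.histogram(resample, bins=edges, density=True)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    return PositionTestReport(
        ks_uniform_stat=float(ks1.statistic),
        ks_uniform_p=float(ks1.pvalue),
        ks_twosample_stat=ks2_stat,
        ks_twosample_p=ks2_p,
        bin_edges=edges,
        density=density,
        density_ci_low=lo,
        density_ci_high=hi,
    )
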