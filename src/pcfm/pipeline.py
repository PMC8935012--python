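"""End-to-end detection cascade and tabular exports.

Ties the stages together: indel reconstruction on all rows (lower
quality rows still inform the parsimony placement), ORF quality
filtering, pairing, postfiltering, and relative positions.  Produces
pandas tables mirroring the TSV interfaces.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .detection import (PcfmRecord, pair_pcfms, postfilter, relative_position)
from .indels import IndelEvent, TooFewSpeciesError, infer_indels
from .phylo import Phylogeny, edge_label
from .seqio import GeneAlignment, quality_table

log = logging.getLogger(__name__)


def detect_in_alignment(
    aln: GeneAlignment,
    phylo: Phylogeny,
    mode: str = "low_confidence",
) -> list[PcfmRecord]:
    """Run the full cascade on one gene; returns the postfiltered pairs.

    Genes with fewer than four quality-passing sequences are skipped
    (empty result), mirroring the minimum-information requirement of the
    parsimony reconstruction.
    """
    quality = quality_table(aln)
    n_passing = sum(q.passes for q in quality.values())
    if n_passing < 4:
        return []
    try:
        events = infer_indels(aln, phylo)
    except TooFewSpeciesError:
        return []
    pairs = pair_pcfms(events, quality, aln)
    return postfilter(pairs, mode)


def detect_many(
    alignments: Sequence[GeneAlignment],
    phylo: Phylogeny,
    mode: str = "low_confidence",
) -> list[PcfmRecord]:
    out: list[PcfmRecord] = []
    for aln in alignments:
        out.extend(detect_in_alignment(aln, phylo, mode=mode))
    return out


def events_table(events: Sequence[IndelEvent]) -> pd.DataFrame:
    """Indel events as a TSV-ready table (1-based inclusive columns)."""
    return pd.DataFrame([
        {
            "gene_id": e.gene_id,
            "kind": e.kind,
            "length_nt": e.length_nt,
            "col_start_1based": e.col_start + 1,
            "col_end_1based": e.col_end,
            "edge_label": e.edge_label,
            "n_descendants": len(e.descendant_species),
            "descendants": ",".join(sorted(e.descendant_species)),
        }
        for e in events
    ])


def pairs_table(pairs: Sequence[PcfmRecord]) -> pd.DataFrame:
    """Compensatory pairs as a TSV-ready table with relative positions."""
    rows = []
    for p in pairs:
        try:
            P = relative_position(p).P
        except ValueError:
            P = float("nan")
        rows.append({
            "gene_id": p.gene_id,
            "kind_5p": p.indel_5p.kind,
            "len_5p": p.indel_5p.length_nt,
            "kind_3p": p.indel_3p.kind,
            "len_3p": p.indel_3p.length_nt,
            "spacer_nt": p.spacer_nt,
            "spacer_nt_ancestral": p.spacer_nt_ancestral,
            "edge_label": edge_label(p.indel_5p.edge) if p.same_edge
            else "cross-edge",
            "same_edge": p.same_edge,
            "n_carriers": len(p.carrier_species),
            "carriers": ",".join(sorted(p.carrier_species)),
            "p1_1based": p.p1 + 1,
            "p2_1based": p.p2,
            "P": P,
        })
    return pd.DataFrame(rows)


def reconstructed_events(
    alignments: Sequence[GeneAlignment], phylo: Phylogeny
) -> list[IndelEvent]:
    out: list[IndelEvent] = []
    for aln in alignments:
        if len(aln.species_ids) < 4:
            continue
        out.extend(infer_indels(aln, phylo))
    return out
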