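"""Core data model and sequence I/O.

Gapped per-gene CDS alignments (aligned FASTA, gap character ``-``), the
species phylogeny (Newick), ungapped coding sequences, per-species ORF
quality reports, and translation under the standard genetic code.

Coordinates are 0-based half-open alignment columns internally; any
tab-separated output uses 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

ALLOWED_CHARS = frozenset("ACGTN-")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # {TAA, TAG, TGA}
START_CODON = "ATG"
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"


class MalformedAlignmentError(ValueError):
    """Alignment rows of unequal length or other structural defects."""


class AlignmentParseError(ValueError):
    """Illegal character or empty input."""


@dataclass
class GeneAlignment:
    """A gapped orthologous CDS alignment for one gene.

    ``rows`` maps species id to its gapped nucleotide string; all rows
    share the same number of alignment columns.
    """

    gene_id: str
    species_ids: list[str]
    rows: dict[str, str]
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.species_ids)) != len(self.species_ids):
            raise MalformedAlignmentError(
                f"{self.gene_id}: duplicate species ids in alignment"
            )
        if set(self.species_ids) != set(self.rows):
            raise MalformedAlignmentError(
                f"{self.gene_id}: species_ids and rows disagree"
            )
        if not self.rows:
            raise AlignmentParseError(f"{self.gene_id}: empty alignment")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            bad = [s for s in self.species_ids
                   if len(self.rows[s]) != len(self.rows[self.species_ids[0]])]
            raise MalformedAlignmentError(
                f"{self.gene_id}: rows have unequal lengths (e.g. {bad[0]!r})"
            )
        self.n_columns = lengths.pop()
        if self.n_columns < 1:
            raise AlignmentParseError(f"{self.gene_id}: zero-length alignment")
        for sp in self.species_ids:
            row = self.rows[sp].upper()
            for i, ch in enumerate(row):
                if ch not in ALLOWED_CHARS:
                    raise AlignmentParseError(
                        f"{self.gene_id}/{sp}: illegal character {ch!r} "
                        f"at column {i + 1}"
                    )
            self.rows[sp] = row

    def ungapped(self, species_id: str) -> "CodingSequence":
        """Project one row to its ungapped coding sequence."""
        return CodingSequence(
            gene_id=self.gene_id,
            species_id=species_id,
            nt=self.rows[species_id].replace("-", ""),
        )


@dataclass(frozen=True)
class CodingSequence:
    """An ungapped per-species CDS."""

    gene_id: str
    species_id: str
    nt: str

    def __post_init__(self) -> None:
        if "-" in self.nt:
            raise ValueError(f"{self.gene_id}/{self.species_id}: gapped CDS")


@dataclass(frozen=True)
class QualityReport:
    """Per-species ORF sanity criteria used to call a gene copy functional.

    A copy passes when it starts with ATG, ends with a stop codon, has
    length divisible by 3 and carries no internal stop codon.
    ``n_frame_disrupting_indels`` is filled by the detection stage.
    """

    species_id: str
    has_start: bool
    has_terminal_stop: bool
    length_mod3_ok: bool
    internal_stop_free: bool
    n_frame_disrupting_indels: int = 0

    @property
    def passes(self) -> bool:
        return (self.has_start and self.has_terminal_stop
                and self.length_mod3_ok and self.internal_stop_free)


def read_alignment(path: str | Path, gene_id: str | None = None) -> GeneAlignment:
    """Read one aligned FASTA file into a :class:`GeneAlignment`.

    Record order is preserved; sequences are uppercased. Raises
    :class:`AlignmentParseError` on empty input or illegal characters and
    :class:`MalformedAlignmentError` on unequal row lengths.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentParseError(f"{path}: no FASTA records")
    species = [r.id for r in records]
    rows = {r.id: str(r.seq) for r in records}
    return GeneAlignment(gene_id=gene_id or path.stem, species_ids=species, rows=rows)


def write_alignment(aln: GeneAlignment, path: str | Path) -> None:
    """Write an alignment back to FASTA (round-trips with read_alignment)."""
    records = [
        SeqRecord(Seq(aln.rows[sp]), id=sp, description="")
        for sp in aln.species_ids
    ]
    SeqIO.write(records, str(path), "fasta")


def quality_check(cds: CodingSequence) -> QualityReport:
    """Evaluate the four ORF criteria on an ungapped CDS."""
    nt = cds.nt
    if not nt:
        raise ValueError(f"{cds.gene_id}/{cds.species_id}: empty CDS")
    mod3 = len(nt) % 3 == 0
    has_start = nt[:3] == START_CODON
    has_stop = mod3 and nt[-3:] in STOP_CODONS
    internal_stop_free = True
    # scan codons 1..n-2 in frame 0 (terminal codon may legitimately be a stop)
    for i in range(3, len(nt) - 3 if mod3 else len(nt) - 2, 3):
        if nt[i:i + 3] in STOP_CODONS:
            internal_stop_free = False
            break
    return QualityReport(
        species_id=cds.species_id,
        has_start=has_start,
        has_terminal_stop=has_stop,
        length_mod3_ok=mod3,
        internal_stop_free=internal_stop_free,
    )


def translate(nt: str, frame_offset: int = 0) -> str:
    """Translate an ungapped nucleotide string in the given frame.

    Stop codons are rendered ``*`` and kept in place (no truncation), so
    peptides over frameshifted regions keep positional alignment.  Codons
    containing ``N`` translate to ``X``; a trailing partial codon is
    dropped.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    if "-" in nt:
        raise ValueError("translate expects an ungapped sequence")
    out = []
    seq = nt[frame_offset:]
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def quality_table(
    aln: GeneAlignment, species: Iterable[str] | None = None
) -> dict[str, QualityReport]:
    """Quality-check every (or a subset of) species row of an alignment."""
    chosen = list(species) if species is not None else aln.species_ids
    out: dict[str, QualityReport] = {}
    for sp in chosen:
        cds = aln.ungapped(sp)
        if not cds.nt:
            out[sp] = QualityReport(sp, False, False, False, False)
        else:
            out[sp] = quality_check(cds)
    return out


def functional_fraction(quality: Mapping[str, QualityReport]) -> float:
    """Fraction of species whose gene copy passes all four ORF criteria."""
    if not quality:
        raise ValueError("empty quality table")
    return sum(q.passes for q in quality.values()) / len(quality)
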