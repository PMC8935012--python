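"""Conservation and dispensability context of pair-carrying genes.

Per-site Shannon entropy of protein alignment columns, sliding-window
region conservation percentiles, gene age (root-to-MRCA distance of the
species still carrying a functional copy), matched-control construction
with an in-silico detectability check, paired Wilcoxon tests, and the
likelihood-ratio test comparing one- versus two-ratio dN/dS fits
(log-likelihoods consumed from external codon-model fits).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .phylo import Phylogeny
from .seqio import GeneAlignment

log = logging.getLogger(__name__)

MAX_ENTROPY = math.log(20.0)

_AA = set("ACDEFGHIKLMNPQRSTVWY")


class InsufficientPairsError(ValueError):
    pass


class InconsistentLikelihoodsError(ValueError):
    pass


@dataclass
class EntropyProfile:
    """Per-site Shannon entropy of a protein alignment plus sliding-window
    means; all-gap sites are undefined (NaN) and skipped in windows."""

    gene_id: str
    per_site: np.ndarray
    window: int
    window_scores: np.ndarray


@dataclass
class GeneContext:
    gene_id: str
    functional_fraction: float
    gene_age: float
    omega_single: Optional[float] = None
    omega_pre: Optional[float] = None
    omega_post: Optional[float] = None
    lnL_1param: Optional[float] = None
    lnL_2param: Optional[float] = None


@dataclass(frozen=True)
class MatchedPair:
    case_gene: str
    control_gene: str


@dataclass
class PairedTestReport:
    n: int
    n_nonzero: int
    statistic: Optional[float]
    p_value: Optional[float]
    differences: np.ndarray
    degenerate: bool


def _peptide_rows(alignment) -> tuple[str, list[str]]:
    """Accept a GeneAlignment-like object, a mapping id -> row, or a plain
    sequence of equal-length peptide rows."""
    if hasattr(alignment, "rows"):
        gene_id = getattr(alignment, "gene_id", "")
        rows = [alignment.rows[sp] for sp in alignment.species_ids]
    elif isinstance(alignment, dict):
        gene_id, rows = "", list(alignment.values())
    else:
        gene_id, rows = "", list(alignment)
    if not rows or len({len(r) for r in rows}) != 1:
        raise ValueError("peptide rows must be nonempty and of equal length")
    return gene_id, rows


def entropy_profile(protein_alignment, window: int) -> EntropyProfile:
    """Shannon entropy H = -sum p_i ln p_i per alignment column.

    Accepts a protein alignment (GeneAlignment-shaped object over amino
    acids, mapping, or list of rows).  Gaps (and non-standard residues)
    are excluded from the per-site frequencies.  Sites with no scoreable
    residue get H = NaN and are skipped inside window means (logged).
    """
    gene_id, rows = _peptide_rows(protein_alignment)
    n_sites = len(rows[0])
    if window < 1 or window > n_sites:
        raise ValueError(f"window {window} out of range 1..{n_sites}")
    per_site = np.empty(n_sites)
    n_undefined = 0
    for col in range(n_sites):
        counts: dict[str, int] = {}
        for row in rows:
            ch = row[col]
            if ch in _AA:
                counts[ch] = counts.get(ch, 0) + 1
        total = sum(counts.values())
        if total == 0:
            per_site[col] = np.nan
            n_undefined += 1
            continue
        per_site[col] = -sum(
            (c / total) * math.log(c / total) for c in counts.values()
        )
    if n_undefined:
        log.info("%s: %d all-gap sites skipped", gene_id, n_undefined)
    window_scores = np.array([
        np.nanmean(per_site[i:i + window]) if
        np.any(~np.isnan(per_site[i:i + window])) else np.nan
        for i in range(n_sites - window + 1)
    ])
    return EntropyProfile(
        gene_id=gene_id,
        per_site=per_site,
        window=window,
        window_scores=window_scores,
    )


def region_conservation_percentile(
    profile: Sequence[float], span: tuple[int, int]
) -> float:
    """Fraction of same-length windows whose mean score is <= the mean
    over the given span (low value: the span is less conserved than the
    gene background; ties count as <=)."""
    scores = np.asarray(profile, dtype=float)
    s0, s1 = span
    if not (0 <= s0 < s1 <= scores.size):
        raise ValueError(f"span {span} outside profile of length {scores.size}")
    w = s1 - s0
    span_mean = np.nanmean(scores[s0:s1])
    window_means = np.array([
        np.nanmean(scores[i:i + w]) for i in range(scores.size - w + 1)
    ])
    scale = np.nanmax(np.abs(window_means)) or 1.0
    return float(np.mean(window_means <= span_mean + 1e-9 * scale))


def gene_age(
    phylo: Phylogeny, functional_species: Sequence[str], mode: str = "branch_sum"
) -> float:
    """Distance from the tree root to the MRCA of the species with a
    functional gene copy (larger = younger gene).

    ``branch_sum`` sums branch lengths along the root-to-MRCA path;
    ``branch_count`` counts the branches instead.
    """
    if mode not in ("branch_sum", "branch_count"):
        raise ValueError(f"unknown mode {mode!r}")
    species = list(functional_species)
    if not species:
        raise ValueError("functional_species is empty")
    mrca = phylo.mrca(species)
    path = phylo.root_to_node_path(mrca)
    if mode == "branch_count":
        return float(len(path))
    return float(sum(n.edge.length or 0.0 for n in path))


def build_matched_controls(
    cases: Sequence,
    pool: Sequence[GeneAlignment],
    phylo: Phylogeny,
    max_attempts: int = 20,
    seed: int = 0,
    detect: Optional[Callable] = None,
) -> list[MatchedPair]:
    """Pair each case gene with a random control in which the case's pair
    would have been detectable.

    For each case, pool genes are sampled without replacement (up to
    ``max_attempts``); the case's template is planted on the same edge
    (same carrier species) of the candidate control, the full detection
    cascade is re-run, and the first control where the planted pair is
    recovered is accepted.  Controls are verified pair-free before
    planting.  Unmatched cases are dropped with a warning.
    """
    from .effects import PcfmTemplate
    from .pipeline import detect_in_alignment  # local import to avoid cycle
    from .simulate import plant_pair_in_alignment

    detect = detect or detect_in_alignment
    rng = np.random.default_rng(seed)
    matched: list[MatchedPair] = []
    for case in cases:
        template, edge = PcfmTemplate.from_record(case), case.edge
        order = rng.permutation(len(pool))
        found = None
        for idx in order[:max_attempts]:
            control = pool[idx]
            if detect(control, phylo):  # control must be pair-free
                continue
            planted = plant_pair_in_alignment(
                control, phylo, edge, template, rng=rng
            )
            if planted is None:
                continue
            recovered = detect(planted, phylo)
            if any(
                r.same_edge and r.edge == edge
                and r.indel_5p.length_nt == template.len_5p
                and r.indel_3p.length_nt == template.len_3p
                for r in recovered
            ):
                found = control.gene_id
                break
        if found is None:
            log.warning("case %s: no detectable control found", case.gene_id)
        else:
            matched.append(MatchedPair(case_gene=case.gene_id, control_gene=found))
    return matched


def paired_comparison(
    values_case: Sequence[float],
    values_control: Sequence[float],
    alternative: str = "two-sided",
) -> PairedTestReport:
    """Wilcoxon signed-rank test on per-pair differences.

    Zero differences are dropped (Wilcoxon's original treatment).  A
    report with ``degenerate=True`` and no statistic is returned when all
    differences are zero.
    """
    case = np.asarray(values_case, dtype=float)
    control = np.asarray(values_control, dtype=float)
    if case.shape != control.shape:
        raise ValueError("paired samples must have equal length")
    if case.size < 5:
        raise InsufficientPairsError(f"need >= 5 pairs, got {case.size}")
    diffs = case - control
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return PairedTestReport(
            n=case.size, n_nonzero=0, statistic=None, p_value=None,
            differences=diffs, degenerate=True,
        )
    res = stats.wilcoxon(
        case, control, zero_method="wilcox", alternative=alternative,
        method="exact" if nonzero.size <= 25 else "approx",
    )
    return PairedTestReport(
        n=case.size, n_nonzero=int(nonzero.size),
        statistic=float(res.statistic), p_value=float(res.pvalue),
        differences=diffs, degenerate=False,
    )


def lrt_two_omega(
    lnL_1param: float, lnL_2param: float, tolerance: float = 1e-6
) -> tuple[float, float]:
    """Likelihood-ratio test of the two-ratio vs one-ratio dN/dS model.

    statistic = 2 (lnL2 - lnL1); p-value from chi-square with one degree
    of freedom (the extra dN/dS parameter).
    """
    statistic = 2.0 * (lnL_2param - lnL_1param)
    if statistic < -tolerance:
        raise InconsistentLikelihoodsError(
            f"two-parameter fit has lower likelihood (stat={statistic:.3g})"
        )
    statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p
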