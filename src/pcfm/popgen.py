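"""Expected frequency of compensatory frameshift pairs under
mutation-selection balance with stochastic tunneling.

A single frameshifting indel in a functional gene is deleterious
(selection coefficient s) and segregates at mutation-selection balance
frequency m1/s; a second, frame-restoring indel within l nucleotides
rescues the haplotype, and with exact compensation the pair fixes at the
rate it arises, Pfix = m1 m2 / s per generation.  Over T generations a
gene accumulates T m1 m2 / s expected pairs; with n genes the expected
count of pair-carrying genes follows, with a normal-approximation
binomial confidence interval.

Four indel types are considered (insertions and deletions of 1 or 2
nt).  A type is compensated exactly by the types that bring the combined
length to a multiple of 3: ins1 by {ins2, del1}, ins2 by {ins1, del2},
del1 by {del2, ins1}, del2 by {del1, ins2}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

INDEL_TYPES = ("ins1", "ins2", "del1", "del2")

#: per-type indel rates as multiples of the point mutation rate
RATE_MULTIPLIERS = {"ins1": 0.020, "ins2": 0.010, "del1": 0.042, "del2": 0.015}

COMPENSATION_SETS = {
    "ins1": ("ins2", "del1"),
    "ins2": ("ins1", "del2"),
    "del1": ("del2", "ins1"),
    "del2": ("del1", "ins2"),
}


class ParameterRegimeError(ValueError):
    """Per-gene probability exceeds 1; the linear approximation is invalid."""


@dataclass(frozen=True)
class PopGenParams:
    """All parameters of the tunneling model.

    mu: de novo point mutation rate per nucleotide per generation.
    rates: per-type indel rates (per nucleotide per generation).
    s: selection coefficient against the uncompensated intermediate.
    L: mean gene length (nt); l: compensation window around the first
    indel (nt); T: generations spanned by the phylogeny; n_genes: number
    of analyzed genes.
    """

    mu: float
    s: float
    L: int
    l: int
    T: float
    n_genes: int
    rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rates:
            object.__setattr__(
                self, "rates",
                {t: m * self.mu for t, m in RATE_MULTIPLIERS.items()},
            )
        if min(self.mu, self.s, self.L, self.l, self.T) <= 0 or self.n_genes <= 0:
            raise ValueError("all parameters must be positive")
        if self.s > 1:
            raise ValueError("s must be <= 1")
        for t, r in self.rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"rate {t}={r} outside [0, 1]")


#: printed parameters for the two clades
VERTEBRATE = PopGenParams(
    mu=1e-8, s=0.005, L=1897, l=100, T=176_536_337, n_genes=21_208
)
INSECT = PopGenParams(
    mu=4.9e-9, s=0.0015, L=1204, l=100, T=403_272_889, n_genes=15_283
)
PRESETS = {"vertebrate": VERTEBRATE, "insect": INSECT}


@dataclass(frozen=True)
class PopGenResult:
    m1_by_type: dict[str, float]
    m2_by_type: dict[str, float]
    P_gene: float
    P_gene_rounded: float  # one significant figure
    expected_count: float
    ci_halfwidth: float

    @property
    def expected_count_int(self) -> int:
        return round(self.expected_count)

    @property
    def ci_halfwidth_int(self) -> int:
        return round(self.ci_halfwidth)


def per_gene_mutation_prob(rate: float, span: int) -> float:
    """Probability of at least one hit in ``span`` sites per generation:
    1 - (1 - rate)^span, numerically stable for rate * span << 1."""
    if not 0 <= rate <= 1:
        raise ValueError(f"rate {rate} outside [0, 1]")
    if span < 1:
        raise ValueError("span must be >= 1")
    return -math.expm1(span * math.log1p(-rate))


def round_sigfig(x: float, sig: int = 1) -> float:
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp + sig - 1)


def expected_pcfm(params: PopGenParams) -> PopGenResult:
    """Per-gene pair-fixation probability and expected gene counts.

    P_gene = T * sum over first-indel types of m1(type) * m2(compensating
    types) / s; expected_count = n_genes * P_gene with a 95%
    normal-approximation binomial CI half-width.
    """
    m1 = {t: per_gene_mutation_prob(params.rates[t], params.L)
          for t in INDEL_TYPES}
    m2 = {t: per_gene_mutation_prob(params.rates[t], params.l)
          for t in INDEL_TYPES}
    total = sum(
        m1[t] * sum(m2[c] for c in COMPENSATION_SETS[t]) for t in INDEL_TYPES
    )
    P_gene = params.T * total / params.s
    if P_gene > 1:
        raise ParameterRegimeError(f"P_gene={P_gene:.3g} > 1")
    expected = params.n_genes * P_gene
    ci = 1.96 * math.sqrt(params.n_genes * P_gene * (1 - P_gene))
    return PopGenResult(
        m1_by_type=m1, m2_by_type=m2,
        P_gene=P_gene, P_gene_rounded=round_sigfig(P_gene),
        expected_count=expected, ci_halfwidth=ci,
    )


def simultaneous_scenario(params: PopGenParams) -> PopGenResult:
    """Lethal-intermediate scenario (s = 1, both indels in one step).

    Follows the headline arithmetic: the one-significant-figure per-gene
    probability of the tunneling result is rescaled by the lineage's own
    s (equivalent to substituting s = 1 into the rounded pipeline).  The
    unrounded probability is also reported via ``P_gene``.
    """
    base = expected_pcfm(params)
    P_unrounded = base.P_gene * params.s  # exact s=1 value
    P_from_rounded = base.P_gene_rounded * params.s
    expected = params.n_genes * P_from_rounded
    ci = 1.96 * math.sqrt(params.n_genes * P_from_rounded * (1 - P_from_rounded))
    return PopGenResult(
        m1_by_type=base.m1_by_type, m2_by_type=base.m2_by_type,
        P_gene=P_unrounded, P_gene_rounded=P_from_rounded,
        expected_count=expected, ci_halfwidth=ci,
    )


def result_as_dict(params: PopGenParams, result: PopGenResult) -> dict:
    """Flat JSON-ready view of a model evaluation."""
    return {
        "params": {
            "mu": params.mu, "s": params.s, "L": params.L, "l": params.l,
            "T": params.T, "n_genes": params.n_genes, "rates": params.rates,
        },
        "m1_by_type": result.m1_by_type,
        "m2_by_type": result.m2_by_type,
        "P_gene": result.P_gene,
        "P_gene_rounded": result.P_gene_rounded,
        "expected_count": result.expected_count,
        "expected_count_int": result.expected_count_int,
        "ci_halfwidth": result.ci_halfwidth,
        "ci_halfwidth_int": result.ci_halfwidth_int,
    }
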