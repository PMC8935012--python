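# Methods

## Problem and model

A frameshifting indel (length not divisible by 3) in a coding sequence
recodes everything downstream and typically gains premature stop
codons.  A second indel that restores the frame (combined length change
≡ 0 mod 3) confines the damage to the segment between the two indels.
This package detects such compensatory pairs in orthologous CDS
alignments on a species phylogeny, characterizes where they fall and
how conserved their context is, quantifies what the shifted segment
does to the protein, and predicts how many pair-carrying genes to
expect under a population-genetic model.

## Indel reconstruction

Gap presence in a maximal run of alignment columns sharing one carrier
set ("gap block") is treated as a binary character.  A block becomes an
indel event only when the Fitch minimum-change reconstruction needs
exactly one state change *and* the root state set resolves to a single
state; the event's edge is the one above the derived clade, and the
polarity follows the root state (ancestral bases, gap gained below the
edge → deletion; ancestral gap, bases gained → insertion).  Homoplastic
blocks (≥ 2 changes) and polarity ties are discarded rather than
resolved — in particular, a tie is *not* broken toward deletion, so the
observed deletion bias among detected pairs cannot be an artifact of
the tie-break.  One consequence, proved by the exhaustive-search oracle
in the test suite, is that a change on either edge incident to the root
is always mirrored by an equally parsimonious change on the sister
edge: events on the two basal edges are undetectable by construction,
and the simulator's `plantable_edges` helper excludes them.

Species excluded from an analysis are treated as missing data (both
states possible) rather than pruned, which keeps edge identities stable
across species subsets.

## Filter cascade

ORF quality per species: ATG start, terminal stop codon, length ≡ 0 mod
3, no internal stop codon in frame 0.  Quality filtering runs *after*
event reconstruction (low-quality rows still inform parsimony) but
*before* pairing.  Genes with fewer than four quality-passing species
are skipped.  A passing species with exactly two frame-disrupting
events whose net offset is ≡ 0 mod 3 defines a candidate pair; species
with more than two frame-disrupting events are considered unreliable
and contribute nothing.  The low-confidence filter keeps pairs with
both indels of 1–2 nt, combined length ≤ 4, an allowed type combination
(1+2 same-kind, 1+1 or 2+2 opposite-kind — exactly the frame-restoring
combinations at these lengths), and single-edge placement; the
high-confidence filter additionally requires ≥ 2 carrier species.
Cross-edge candidates are recorded but tagged and excluded from every
downstream analysis.  The original study's manual-inspection and
database-evidence filters are inherently non-computational and are not
reimplemented; an allowlist/blocklist can be applied by filtering the
pair table.

## Coordinates and positions

Internally all coordinates are 0-based, half-open, in alignment
columns; TSV outputs are 1-based inclusive.  The spacer between the two
indels is counted in derived-frame nucleotides (gaps excluded) on a
carrier row; the ancestral count is also emitted.  For the relative
position P = p₁ / (L − (p₂ − p₁)), positions p₁ (5′ edge of the 5′
indel) and p₂ (3′ edge of the 3′ indel) are measured in the ungapped
coordinates of a deterministic quality-passing non-carrier reference
row, so that they are comparable with genomic CDS coordinates of
reference indel sets.  P = 0 iff the 5′ indel is at the CDS start and
P = 1 iff the 3′ indel is at its end; a pair spanning the whole CDS is
a degenerate-span error.

## Distance scales

The Miyata amino-acid distance is reconstructed from Grantham polarity
and volume, d(a, b) = √((Δp/σₚ)² + (Δv/σᵥ)²), with σₚ = 2.15746 and
σᵥ = 34.39636 calibrated by least squares against the published
distance table and entries rounded to its printed 2-decimal precision;
the matrix maximum is 5.13 at (Gly, Trp), which is also the score
assigned to any position involving a gap, a stop ('*') or an
undetermined residue ('X').  Stop codons arising inside a shifted
region are kept in place as '*' (no truncation) so that region peptides
stay positionally aligned; when two region peptides differ in length by
the pair's net codon offset, the shorter is right-padded with gaps.
The hydropathy metric is |mean KD(pep₁) − mean KD(pep₂)| on the
Kyte–Doolittle scale (−4.5 Arg … +4.5 Ile, range 9), with gaps, stops
and unknowns excluded from each mean; a peptide with no scoreable
residue makes the metric undefined (such null draws are redrawn).

## Empirical null and quartet

The null for "how different should a frameshifted region look" plants
the observed template (indel kinds, lengths, spacer) at a uniformly
random valid position of a uniformly random pool gene — start and stop
codons excluded, inserted bases uniform on ACGT — and scores the
codon-extended spanned region before vs after.  Percentile p-values use
(1 + #{draws ≤ observed}) / (n_draws + 1); the test suite verifies they
are uniform under the null.  Default n_draws = 10,000.  Per-gene
p-values are Bonferroni-flagged at α/k and combined with a one-sample
KS test against Uniform(0, 1).

Ancestral states at the two endpoints of the pair-carrying edge are
reconstructed per column by Fitch parsimony over {A, C, G, T, −} ('N'
missing), resolving ties deterministically toward the parent state; a
pair whose spanned columns are ambiguous at > 50% of sites is rejected
as low-confidence.  This is a deliberate departure from
maximum-likelihood reconstruction: it needs no external tool, and at
the low divergences where pairs are called the two coincide.  The four
region states are A (parent presence and bases), E (child presence and
bases), A_mut (parent presence, child bases where both present) and
A_fr (child presence, parent bases where both present); all
substitutions on the branch are treated as simultaneous, as are the two
indels, giving the substitutions-before and substitutions-after
scenarios.  Intermediates are omitted when the branch carries no
substitutions in the window, or when the substitutions are synonymous
in one frame context and nonsynonymous in the other (ill-defined
intermediates).

## Conservation metrics

Shannon entropy H = −Σ pᵢ ln pᵢ per protein-alignment column, gaps
excluded from the frequencies, all-gap columns undefined and skipped in
window means.  The region-conservation percentile is the fraction of
same-length windows of the gene whose mean score is ≤ the spanned
region's mean (ties count; the statistic is invariant under affine
transforms of the score track, so entropy and external conservation
tracks are interchangeable).  Gene age is the root-to-MRCA path of the
functional species, as branch-length sum or branch count.  Matched
controls are drawn from pair-free genes and accepted only if the case's
template, planted on the same edge, is recovered by the full cascade —
so case/control differences cannot come from detectability.  Paired
comparisons use the Wilcoxon signed-rank test with zero differences
dropped.  dN/dS fitting itself is out of scope: ω values and
log-likelihoods come from external codon-model fits, and only the LRT
2(lnL₂ − lnL₁) ~ χ²(1) is computed here (one extra ω parameter).  When
exporting alignments for such fits the pair-spanned region must be
excised, since gap-tolerant codon models would otherwise misread codon
boundaries between the indels.

## Tunneling model

With per-nucleotide rates p₁ (first indel, over the gene length L) and
p₂ (compensating indel, over a window of l nt around the first), the
per-generation gene-level probabilities are m = 1 − (1 − p)^span
(computed via expm1/log1p for the small-rate regime).  The
uncompensated intermediate segregates at mutation–selection balance
m₁/s, compensated haplotypes arise at rate m₁m₂/s, and with exact
compensation they fix at that same rate, giving T·Σ m₁m₂/s expected
pairs per gene over T generations, summed over the four indel types
with their frame-restoring partners.  Defaults: indel rates 0.020μ,
0.010μ, 0.042μ, 0.015μ (ins1, ins2, del1, del2); vertebrates μ = 10⁻⁸,
s = 0.005, L = 1897, T = 176,536,337, n = 21,208; insects μ = 4.9 ×
10⁻⁹, s = 0.0015, L = 1204, T = 403,272,889, n = 15,283; l = 100 in
both.  T is treated as a generation count, the only reading under which
the formulas are dimensionally consistent.  Headline probabilities are
reported at one significant figure and counts with a 95%
normal-approximation binomial CI.  The lethal-intermediate scenario
(s = 1, both indels in one generation) is reported as the rounded
per-gene probability rescaled by the lineage's own s — the arithmetic
that reproduces both published one-significant-figure values — with the
exact unrounded value exposed alongside (insects: 4.5 × 10⁻⁶ rounded
vs 4.24 × 10⁻⁶ exact).

## Synthetic data

The generator samples a rooted bifurcating tree (iterative random
joins, exponential branch lengths) or accepts one, draws a valid-ORF
root CDS, and evolves it down the tree under an equal-rates
substitution process with probability p = ¾(1 − e^(−4d/3)) per site for
branch length d.  Substitutions never touch the first or last codon and
never create an in-frame stop (a nonsense-purifying filter): this keeps
every row without a planted frame disruption quality-passing, which is
what makes "recall of planted pairs" a well-defined quantity.  Planted
deletions blank carrier rows; planted insertions add columns carried
only by the edge's species, so the emitted alignment *is* the true
alignment.  Pair placements are resampled until every carrier remains
quality-passing (the shifted segment must not contain a stop), matching
the constructive fact that observed pairs passed the filters.  Planted
events keep a truth table with final alignment columns, edges and
carrier sets.  The control pool draws lognormal gene lengths (σ = 0.45)
calibrated to the clade's mean (1897 or 1204 nt).

What the simulator does not emulate: alignment error, sequencing and
assembly artifacts, rate heterogeneity, indel-rate variation along the
gene, and selection on the recoded segment.  Passing tests therefore
demonstrate the correctness of the machinery on clean inputs, not
robustness to the noise sources that motivated the filter cascade in
the first place.

## Problem sizes and numerical choices

The test suite exercises detection on 100 simulated genes of 300
codons on a 20-leaf tree, null calibration with 1,999-draw nulls and
1,000 observations, frame restoration on 1,000 random applications,
and positional uniformity on 200 planted pairs — sizes at which every
stochastic acceptance check has a comfortable margin while the whole
suite runs in seconds.  Window extension for region scoring is to
ancestral codon boundaries; region percentile ties use a 10⁻⁹ relative
tolerance; the LRT clamps tiny negative statistics to 0 and rejects
ones beyond tolerance as inconsistent inputs.  All randomness flows
through numpy Generators seeded explicitly; a single run seed is fanned
out to stage seeds so stages are independently reproducible.

## Known limitations

Adjacent indel pairs (spacer 0) of combined in-frame length merge into
a single gap block and are invisible by construction; all observed
high-confidence pair shapes have spacers ≥ 7.  Overlapping gap blocks
from different species subsets are treated as independent events, and
gap blocks interrupted by a single mismatching column are not merged.
The ancestral-state reconstruction is parsimony, not ML, and the
quartet analysis assumes within-branch simultaneity of substitutions.
The tunneling model ignores selection on the fixed pair and correlation
between the two indel mutations; both would shift the expected counts
in the directions discussed in the popgen module's docstrings.
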