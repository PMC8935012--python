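# pcfm — pairs of mutually compensatory frameshifting mutations

Insertions and deletions whose lengths are not multiples of 3 shift the
reading frame of a protein-coding gene, usually at a high fitness cost.
A second, nearby indel that brings the combined length change back to a
multiple of 3 restores the frame: downstream of the second indel the
protein is unchanged, and only the segment between the two indels is
recoded.  Such *pairs of mutually compensatory frameshifting mutations*
(pCFMs) are a source of radically novel protein sequence, and this
package implements the full analysis of their evolutionary footprint:

- **Detection** of pCFMs from gapped per-gene CDS alignments on a
  species phylogeny.  Maximal identical-carrier gap blocks are treated
  as binary characters and placed on the tree by Fitch parsimony; only
  blocks explained by a single state change with an unambiguous root
  state become indel events.  After per-species ORF quality filtering
  (ATG start, terminal stop, length ≡ 0 mod 3, no internal stop), a
  species with exactly two frame-disrupting indels whose net offset is
  ≡ 0 mod 3 defines a candidate pair; the filter cascade then keeps
  short (1–2 nt, combined ≤ 4 nt), same-edge pairs, optionally requiring
  ≥ 2 carrier species (high-confidence mode).
- **Position along the CDS**: P = p₁ / (L − (p₂ − p₁)), with P = 0 when
  the 5′ indel sits at the CDS start and P = 1 when the 3′ indel sits at
  its end, compared against Uniform(0, 1) and against a reference indel
  sample by Kolmogorov–Smirnov tests with bootstrap density bands.
- **Conservation context**: per-site Shannon entropy H = −Σ pᵢ ln pᵢ,
  sliding-window region percentiles, functional-species fraction, gene
  age (root-to-MRCA distance), matched controls with an in-silico
  detectability check, Wilcoxon signed-rank tests, and the
  likelihood-ratio test 2ΔlnL ~ χ²(1) for two-ratio vs one-ratio dN/dS
  fits consumed from external codon-model log-likelihoods.
- **Effect on the protein**: mean Miyata distance (gap/stop/unknown
  scored at the 5.13 maximum, the Gly–Trp distance) and mean
  Kyte–Doolittle hydropathy difference between the ancestral and
  frameshifted region peptides, with an empirical null built by planting
  the same indel-pair template at 10,000 random positions of random
  genes; percentile p-values, Bonferroni flags and KS combination.
  Parsimony reconstruction of the A / A_mut / A_fr / E state quartet
  (ancestral, substitutions-only, frameshift-only, derived) for the
  substitution-timing scenarios, and per-descendant-leaf trajectories.
- **Expected frequency** under mutation–selection balance with
  stochastic tunneling: m₁ = 1 − (1 − p₁)^L, m₂ = 1 − (1 − p₂)^l, a
  segregating intermediate at frequency m₁/s and pair fixation rate
  P_fix = m₁m₂/s, summed over the frame-restoring type pairs
  (ins1↔{ins2, del1}, ins2↔{ins1, del2}, del1↔{del2, ins1},
  del2↔{del1, ins2}), giving T·Σm₁m₂/s per gene over T generations.
- **Synthetic data**: a generator that evolves valid ORFs down a tree
  under an equal-rates substitution process and plants indels, pairs and
  pseudogenization defects with a machine-readable truth table, so every
  stage is testable without any external download.

## Worked example

```python
import numpy as np
from pcfm import (SimConfig, PlantedPair, PcfmTemplate, simulate,
                  detect_in_alignment, relative_position)
from pcfm.simulate import sample_tree, plantable_edges

phylo = sample_tree(12, 0.05, np.random.default_rng(1))
edge = plantable_edges(phylo, min_leaves=2, max_leaves=6)[0]
tpl = PcfmTemplate("deletion", 2, "deletion", 1, 26)   # 2-nt + 1-nt deletion
cfg = SimConfig(tree=phylo, n_genes=1, gene_length_codons=300,
                pairs=[PlantedPair(0, edge, tpl)], seed=7)
res = simulate(cfg)
pair = detect_in_alignment(res.alignments[0], phylo)[0]
print(pair.indel_5p.kind, pair.indel_5p.length_nt,
      pair.indel_3p.kind, pair.indel_3p.length_nt,
      pair.spacer_nt, sorted(pair.carrier_species))
print(round(relative_position(pair).P, 3))
```

prints

```
deletion 2 deletion 1 26 ['sp01', 'sp05']
0.371
```

i.e. the planted 2-nt + 1-nt deletion pair, 26 nt apart, is recovered on
its edge with its two carrier species, at relative CDS position 0.371.

The tunneling model from the command line:

```
pcfm popgen --clade vertebrate
```

reports a per-gene fixation probability of 0.002 (exact 2.44 × 10⁻³)
and an expected 52 ± 14 pair-carrying genes among 21,208 — the
mutation–selection-balance prediction that the observed number of pairs
should fall between the raw candidate count and the stringent
high-confidence count.

## Analysis scripts

`analysis/01_simulate_cohort.py` … `06_popgen.py` run the whole study on
a synthetic cohort: simulate 120 genes with planted pairs and negative
controls, detect pairs (printing recall and precision against the
truth), test positional uniformity, compute conservation metrics with
matched controls, score protein effects against 10,000-draw nulls, and
evaluate the tunneling model.  Each writes its tables under `results/`.

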