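#!/usr/bin/env python
"""Effect of detected pairs on the encoded amino-acid sequence.

For each detected pair gene: reconstruct the ancestral (A) and derived
(E) region peptides (plus the substitutions-only and frameshift-only
intermediates where defined), score A vs E with the mean Miyata distance
and the hydropathy difference, and compare the observed distance with an
empirical null built by planting the same pair template at 10,000 random
positions of random pool genes.  Per-gene percentile p-values are
combined with a one-sample Kolmogorov-Smirnov test against Uniform(0,1)
and Bonferroni-flagged individually.
"""

import json
from pathlib import Path

import pandas as pd
from scipy import stats

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results" / "effects"

from pcfm.effects import (PcfmTemplate, ancestral_states, build_null,
                          bonferroni_significant, quartet_distances,
                          score_metric)
from pcfm.phylo import read_tree
from pcfm.pipeline import detect_in_alignment
from pcfm.seqio import read_alignment
from pcfm.simulate import make_control_pool

N_DRAWS = 10_000
SEED = 99


def main() -> None:
    phylo = read_tree(SIM / "tree.nwk")
    alns = [read_alignment(f) for f in sorted(SIM.glob("gene*.fasta"))]
    pool = make_control_pool(300, mean_length_nt=1897.0, seed=SEED)

    rows = []
    nulls: dict[tuple, object] = {}
    for aln in alns:
        for pair in detect_in_alignment(aln, phylo):
            q = ancestral_states(aln, phylo, pair)
            tpl = PcfmTemplate.from_record(pair)
            for metric in ("miyata", "hydropathy"):
                key = (tpl, metric)
                if key not in nulls:
                    nulls[key] = build_null(pool, tpl, metric, N_DRAWS,
                                            seed=SEED + 1 + len(nulls))
                observed = score_metric(metric, q.A, q.E)
                scored = nulls[key].with_observed(observed)
                row = {
                    "gene_id": pair.gene_id, "metric": metric,
                    "observed": observed,
                    "null_mean": float(scored.draws.mean()),
                    "percentile_p": scored.percentile_p,
                    "n_substitutions": q.n_substitutions,
                }
                if q.A_fr is not None:
                    qd = quartet_distances(q, metric)
                    row["d_A_Afr"] = qd.distances.get(("A", "A_fr"))
                    row["subs_after_compensatory"] = qd.hypothesis_subs_after
                    row["subs_before_permissive"] = qd.hypothesis_subs_before
                rows.append(row)

    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "pair_effects.tsv", sep="\t", index=False)

    summary = {}
    for metric in ("miyata", "hydropathy"):
        ps = df.loc[df.metric == metric, "percentile_p"].tolist()
        ks = stats.kstest(ps, "uniform")
        flags = bonferroni_significant(ps)
        summary[metric] = {
            "n_genes": len(ps),
            "ks_uniform_p": float(ks.pvalue),
            "n_bonferroni_significant_low": int(sum(
                f and p < 0.5 for f, p in zip(flags, ps))),
        }
        print(f"{metric}: {len(ps)} genes, KS p-value combination "
              f"p={ks.pvalue:.3f}, "
              f"{summary[metric]['n_bonferroni_significant_low']} genes "
              f"below the Bonferroni threshold")
    (OUT / "effects_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print("planted pairs carry no selection toward the ancestral peptide, "
          "so uniform percentile p-values are the expected outcome")
    print(f"tables under {OUT}")


if __name__ == "__main__":
    main()
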