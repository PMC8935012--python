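#!/usr/bin/env python
"""Positional distribution of detected pairs along the CDS.

Computes the relative position P = p1 / (L - (p2 - p1)) for every
detected pair, tests the sample against Uniform(0, 1) with a one-sample
Kolmogorov-Smirnov test, and writes binned densities with 95% bootstrap
confidence bands.  With uniformly planted pairs the KS test should not
reject; with a real cohort this is where an excess near the gene ends
would show up.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "positions"

from pcfm.detection import compare_position_distributions


def main() -> None:
    pairs = pd.read_csv(ROOT / "results" / "detect" / "pcfm_pairs_low.tsv",
                        sep="\t")
    observed = pairs["P"].dropna().tolist()
    report = compare_position_distributions(observed, None, n_boot=1000, seed=7)

    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "bin_left": report.bin_edges[:-1],
        "bin_right": report.bin_edges[1:],
        "density": report.density,
        "ci_low": report.density_ci_low,
        "ci_high": report.density_ci_high,
    }).to_csv(OUT / "position_density.tsv", sep="\t", index=False)
    (OUT / "position_tests.json").write_text(json.dumps({
        "n": len(observed),
        "ks_uniform_stat": report.ks_uniform_stat,
        "ks_uniform_p": report.ks_uniform_p,
    }, indent=2) + "\n")

    print(f"{len(observed)} relative positions; "
          f"KS vs Uniform(0,1): D={report.ks_uniform_stat:.3f}, "
          f"p={report.ks_uniform_p:.3f}")
    print("uniformly planted pairs: non-rejection expected; density table "
          f"with bootstrap bands under {OUT}")


if __name__ == "__main__":
    main()
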