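#!/usr/bin/env python
"""Compare the simulated red-snow and white-snow communities.

Runs the full statistics chain on the tables from
03_simulate_counts.py: common-depth log normalization, Bray-Curtis
distances, PERMANOVA, SIMPROF cluster pruning, PCA on the ten most
variable features and per-feature ANOVA with BH adjustment. The JSON
report, ANOVA table and dendrogram land under results/community/.
"""

from pathlib import Path

import pandas as pd

from redsnow import RunConfig, run_compare

ROOT = Path(__file__).resolve().parents[1]
COUNTS = ROOT / "results" / "counts"
OUT = ROOT / "results" / "community"


def main() -> None:
    if not (COUNTS / "counts.tsv").exists():
        raise SystemExit("run analysis/03_simulate_counts.py first")
    report = run_compare(
        COUNTS / "counts.tsv", COUNTS / "groups.tsv", OUT, RunConfig(seed=2016)
    )
    perm = report["permanova"]
    print(
        f"PERMANOVA: pseudo-F = {perm['pseudo_F']:.3f}, "
        f"p = {perm['p_value']:.4f} ({perm['method']}, "
        f"{perm['n_permutations']} label arrangements)"
    )
    print(f"SIMPROF: {report['simprof']['n_clusters']} significant clusters")
    pv = report["pca"]["percent_variance"]
    print(
        f"PCA (top {report['pca']['top_k']} variable features): "
        f"PC1+PC2 explain {pv[0] + pv[1]:.1f}% of variance"
    )
    anova = pd.DataFrame(report["anova"])
    n_sig = int((anova["q"] <= 0.05).sum())
    print(f"per-feature ANOVA: {n_sig}/{len(anova)} features at q <= 0.05")
    print(f"full report under {OUT}")


if __name__ == "__main__":
    main()
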