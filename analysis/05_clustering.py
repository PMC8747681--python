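#!/usr/bin/env python
"""Exploratory structure: UPGMA trees for traits and genotypes (Newick),
k=3 genotype clusters, and canonical-variates biplots for the size/shape
and color trait sets (results/study/*.nwk, lda_*.csv)."""

import argparse
from pathlib import Path

import pandas as pd

from grainaging.config import StudyConfig
from grainaging.pipeline import stage_cluster


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    cfg = StudyConfig.from_json(args.outdir / "config.json")
    stage_cluster(cfg, args.outdir)

    clusters = pd.read_csv(args.outdir / "genotype_clusters.csv")
    sizes = clusters.cluster.value_counts().sort_index()
    print("genotype clusters (k=3):",
          {int(k): int(v) for k, v in sizes.items()})
    truth_path = args.outdir / "genotypes.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)[["genotype", "cluster"]]
        merged = clusters.merge(truth, on="genotype",
                                suffixes=("_found", "_true"))
        ct = pd.crosstab(merged.cluster_true, merged.cluster_found)
        # best-case agreement under label permutation (greedy)
        agree = ct.max(axis=1).sum() / len(merged)
        print(f"agreement with generating archetypes: {agree:.0%}")
    for name in ("size_shape", "color"):
        path = args.outdir / f"lda_{name}_loadings.csv"
        if path.exists():
            loadings = pd.read_csv(path)
            top = loadings.reindex(
                loadings.axis1.abs().sort_values(ascending=False).index
            ).head(3)
            print(f"LDA ({name}) axis-1 top loadings:",
                  {r.trait: round(r.axis1, 2) for r in top.itertuples()})
    print("trees written:",
          ", ".join(p.name for p in sorted(args.outdir.glob("*.nwk"))))


if __name__ == "__main__":
    main()
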