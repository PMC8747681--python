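#!/usr/bin/env python
"""Germination analysis: ANOVA on genotype/year, year-centering, outlier
cell exclusion (|centered| > 15), and envelope-tested correlations of
germination with every seed trait
(results/study/germination_correlations.csv)."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from grainaging.stats import germination_analysis


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/study"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-rep", type=int, default=2000)
    args = ap.parse_args()

    germ = pd.read_csv(args.outdir / "germination.csv")
    table = pd.read_csv(args.outdir / "traits.csv")
    rng = np.random.default_rng([args.seed, 0x6E47])
    res = germination_analysis(germ, table, n_rep=args.n_rep, rng=rng)

    a = res["anova"]
    print(f"germination ANOVA: genotype p = {a['genotype'].p:.3g}, "
          f"year p = {a['year'].p:.3g}")
    cells = res["cells"]
    excl = cells[cells.excluded]
    print(f"excluded {len(excl)} of {len(cells)} genotype x year cells "
          f"(|year-centered| > 15): "
          + ", ".join(f"{r.genotype}/{r.year} ({r.centered:+.1f})"
                      for r in excl.itertuples()))
    corr = res["correlations"].dropna(subset=["r"]).set_index("trait")
    sig = corr[corr.significant]
    print(f"\n{len(sig)} traits significantly correlated with germination "
          f"({res['n_seeds']} seeds); most negative:")
    print(sig.nsmallest(5, "r")[["r", "perm_min", "perm_max",
                                 "boot_min", "boot_max"]].round(3))
    res["correlations"].to_csv(
        args.outdir / "germination_correlations.csv", index=False,
        float_format="%.6f",
    )


if __name__ == "__main__":
    main()
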