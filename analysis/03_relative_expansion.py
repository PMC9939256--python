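#!/usr/bin/env python
"""Relative expansion over serial stimulations and the CD8-vs-CD4 contrast.

Normalizes the abundance series (median-of-ratios), computes per-domain
library-relative log2 fold-changes versus the pre-stimulation baseline,
tests each domain's CD8-minus-CD4 expansion difference (Wald + BH), and fits
the per-domain expansion trend over rounds.

Writes results/expansion_summary.tsv, results/cd8_cd4_wald.tsv and
results/expansion_trend.tsv.
"""

from pathlib import Path

import pandas as pd

from carpool.expansion import cd8_cd4_ratio_test, expansion_trend, relative_expansion

SCRATCH = Path("scratch/screen")
RESULTS = Path("results")


def main():
    abundance = pd.read_csv(SCRATCH / "abundance.tsv", sep="\t")
    res = relative_expansion(abundance)
    final_tp = int(res.per_replicate["timepoint"].max())

    res.summary.to_csv(RESULTS / "expansion_summary.tsv", sep="\t", index=False,
                       float_format="%.5g")
    wald = cd8_cd4_ratio_test(res.per_replicate, timepoint=final_tp)
    wald.to_csv(RESULTS / "cd8_cd4_wald.tsv", sep="\t", index=False,
                float_format="%.5g")
    trend = expansion_trend(res.per_replicate)
    trend.to_csv(RESULTS / "expansion_trend.tsv", sep="\t", index=False,
                 float_format="%.5g")

    top = (
        res.summary.query("condition == 'antigen+' and timepoint == @final_tp")
        .groupby("construct")["mean_rel_log2fc"].mean()
        .sort_values(ascending=False)
    )
    sig = wald[wald["q"] < 0.05]
    print(f"relative expansion at round {final_tp}: "
          f"top domain {top.index[0]} ({top.iloc[0]:+.2f} log2 vs library average), "
          f"bottom {top.index[-1]} ({top.iloc[-1]:+.2f})")
    print(f"CD8-vs-CD4 Wald test: {len(sig)}/{len(wald)} domains at q < 0.05")
    print(f"-> {RESULTS}/expansion_summary.tsv, cd8_cd4_wald.tsv, expansion_trend.tsv")


if __name__ == "__main__":
    main()
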