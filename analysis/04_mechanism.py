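#!/usr/bin/env python
"""Mechanistic follow-ups on the simulated bundle.

Summarises strand-orientation bias, the decay of the responsive fraction
with TSS distance, DREB/CBF motif content of consensus sequences, the
exemplar positional enrichment, and the start-site comparison — reading the
tables the pipeline run (02_enrichment.py) wrote.
"""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", type=Path, default=Path("scratch/analysis/run"))
    args = ap.parse_args()

    strand = pd.read_csv(args.run / "strand_bias.tsv", sep="\t", comment="#")
    sig = strand[strand.p_adjusted < 0.05]
    print(f"strand bias: {len(sig)}/{len(strand)} families significant after BH")

    decay = pd.read_csv(args.run / "distance_decay.tsv", sep="\t", comment="#")
    pooled = decay.groupby("bin_lo").agg(n=("n_genes", "sum"), up=("n_up", "sum"))
    pooled["prop_up"] = pooled.up / pooled.n
    print("\nresponsive fraction by upstream distance bin (enriched families):")
    print(pooled.to_string())

    motif = pd.read_csv(args.run / "motif_summary.tsv", sep="\t", comment="#")
    print("\nDREB/CBF site content of consensus sequences:")
    print(motif.to_string(index=False))

    regions = pd.read_csv(args.run / "positional_enrichment_regions.tsv",
                          sep="\t", comment="#")
    print(f"\nexemplar regions over-covered near responsive genes: {len(regions)}")
    if len(regions):
        print(regions.to_string(index=False))

    sites = pd.read_csv(args.run / "start_site_summary.tsv", sep="\t", comment="#")
    print("\nstart-site categories:")
    print(sites.to_string(index=False))


if __name__ == "__main__":
    main()
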