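#!/usr/bin/env python
"""Windowed population-genetic structure of the simulated panel:
nucleotide diversity in 500-kb windows, a null F_ST scan between two
arbitrary halves of the panel (expected ~0: one panmictic founder pool),
and the LD decay profile (MAF >= 0.10, pairs within 10 kb, 100-bp bins).
"""

import pandas as pd

from isopanel.io_variants import read_table, write_table
from isopanel.pipeline import RunConfig, run

cfg = RunConfig(outdir="results/run", seed=1)

run("pi", cfg)
pi = read_table("results/run/pi_windows.tsv")
print(f"mean pi (500-kb windows): {pi['value'].mean():.4f} "
      f"(founder target 0.0037)")

# null F_ST: split the panel into two arbitrary halves
meta = read_table("results/run/line_metadata.tsv")
groups = pd.DataFrame({"sample": meta["line"],
                       "population": ["A" if i % 2 else "B"
                                      for i in range(len(meta))]})
write_table(groups, "results/run/groups.tsv")
run("fst", cfg)
fst = read_table("results/run/fst_windows.tsv")
defined = fst["value"].dropna()
print(f"null F_ST over {len(defined)} windows with >= {cfg.fst_min_snps} SNPs: "
      f"mean {defined.mean():.4f}")

run("ld", cfg)
ld = read_table("results/run/ld_decay.tsv").dropna()
near = ld[ld["bin_left_bp"] < 500]["mean_r2"].mean()
far = ld[ld["bin_left_bp"] >= 9000]["mean_r2"].mean()
print(f"LD profile: mean r^2 {near:.4f} below 500 bp, {far:.4f} beyond 9 kb "
      f"({int(ld['n_pairs'].sum())} SNP pairs).")
print("note: founder haplotypes carry no background LD by construction, so "
      "panel LD reflects only shared-descent blocks and is nearly flat at "
      "this scale (see docs/methods.md)")
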