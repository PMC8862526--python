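#!/usr/bin/env python
"""Call homozygosity blocks: fit the 2-state Poisson HMM jointly on the
10-kb heterozygous-SNP counts of every line, Viterbi-decode each line, and
summarize per-line homozygous fractions against the simulator's truth.

Requires results/run/ from 01_simulate_panel.py.
"""

from isopanel.io_variants import read_table
from isopanel.pipeline import RunConfig, run

cfg = RunConfig(outdir="results/run", seed=1)
run("hmm-call", cfg)

frac = read_table("results/run/homozygous_fraction.tsv")
truth = read_table("results/run/truth_autozygosity.tsv")
merged = frac.merge(truth, on="line")
err = (merged["homozygous_fraction"] - merged["autozygous_fraction"]).abs()
pct70 = 100 * (frac["homozygous_fraction"] > 0.70).mean()
print(open("results/run/hmm_params.txt").read().strip())
print(f"mean HMM homozygous fraction (excl. sex chromosome): "
      f"{frac['homozygous_fraction'].mean():.3f}")
print(f"lines with homozygous fraction > 0.70: {pct70:.1f}%")
print(f"mean |HMM - truth|: {err.mean():.4f} (max {err.max():.4f})")
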