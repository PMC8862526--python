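#!/usr/bin/env python
"""Refine the obligate-heterozygous sex-determining region on chr1 with a
4-state HMM: count-based and state-weighted per-window heterozygosity tracks,
then the longest contiguous high-heterozygosity run as the candidate region.

The 4-state model is trained on the sex chromosome's windows of all lines;
the simulated truth segment is chr1:450001-550000 (1-based inclusive).
"""

import numpy as np

from isopanel import hmm
from isopanel.io_variants import (WindowCounts, WindowGrid, grid_from_matrix,
                                  read_vcf, window_het_counts, write_table)

gm = read_vcf("results/run/panel.vcf")
grid = grid_from_matrix(gm, 10_000)
wc = window_het_counts(gm, grid)

# restrict training and tracks to the sex chromosome
chr1_grid = WindowGrid(10_000, {"chr1": grid.chrom_lengths["chr1"]})
off = grid.window_offsets()["chr1"]
nw = grid.n_windows("chr1")
wc1 = WindowCounts(chr1_grid, wc.sample_ids,
                   wc.counts[:, off:off + nw], wc.n_sites[:, off:off + nw])

params, _ = hmm.fit_poisson_hmm(wc1, K=4, seed=1)
paths = hmm.viterbi_decode_all(params, wc1)
track = hmm.HetProportionTrack(chr1_grid, "chr1",
                               hmm.het_proportion_by_count(wc1, threshold=5),
                               hmm.het_proportion_weighted(paths, params))
interval = hmm.refine_obligate_het_region(track, min_level=0.8, min_span=50_000)

write_table(track.to_frame(), "results/run/sex_region_track.tsv")
print("4-state emission rates (het SNPs / 10-kb window):",
      np.round(params.lam, 3))
print("count-based track: windows with proportion > 0.8:",
      int((track.count_based > 0.8).sum()))
print("weighted track:    windows with proportion > 0.8:",
      int((track.weighted > 0.8).sum()))
print("refined obligate-heterozygous region:", interval,
      "(simulated truth chr1:450001-550000)")
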