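from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from isopanel import simulate as sim
from isopanel.io_variants import GenotypeMatrix


def make_gm(geno, positions=None, chrom="chr1", chrom_length=None,
            sample_ids=None, ref="A", alt="T") -> GenotypeMatrix:
    """Build a single-chromosome GenotypeMatrix from a genotype array."""
    geno = np.asarray(geno, dtype=np.int8)
    n_samples, n_variants = geno.shape
    if positions is None:
        positions = np.arange(1, n_variants + 1)
    positions = np.asarray(positions)
    if chrom_length is None:
        chrom_length = int(positions.max()) if n_variants else 1
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    variants = pd.DataFrame({"chrom": chrom, "pos": positions,
                             "ref": ref, "alt": alt})
    return GenotypeMatrix(list(sample_ids), variants, geno, {chrom: chrom_length})


@pytest.fixture(scope="session")
def small_panel() -> sim.PanelSim:
    """8 lines (4 sibling families), 4 x 1 Mb chromosomes, G=9, sex segment
    on chr1; shared across tests that only read from it."""
    spec = sim.default_genome(n_chromosomes=4)
    cfg = sim.SimConfig(n_founder_pairs=4, lines_per_family=2, generations=9,
                        seed=1, outcross_prob=0.0)
    return sim.simulate_panel(spec, cfg)


@pytest.fixture(scope="session")
def small_grid(small_panel):
    from isopanel.io_variants import grid_from_matrix
    return grid_from_matrix(small_panel.gm, 10_000)


@pytest.fixture(scope="session")
def small_counts(small_panel, small_grid):
    from isopanel.io_variants import window_het_counts
    return window_het_counts(small_panel.gm, small_grid)
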