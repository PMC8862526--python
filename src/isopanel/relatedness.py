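"""Identity-by-state relatedness: IBS matrix, clustering, sibling adjacency,
and windowed haplotype-sharing between inbred line pairs.

Sibling lines (two lines inbred independently from the same founder family)
are expected to fix the same founder haplotype at a quarter of the genome;
the windowed sharing fraction estimates this from near-perfect IBS windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_variants import MISSING, GenotypeMatrix, WindowGrid


def ibs_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise mean identity-by-state similarity.

    IBS between two samples is the mean over co-non-missing sites of
    (2 - |dosage_a - dosage_b|) / 2, so identical genotypes score 1 and
    opposite homozygotes 0.  Pairs without shared sites are NaN.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = gm.dosage()
    n = gm.n_samples
    out = np.ones((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ok = np.isfinite(d[a]) & np.isfinite(d[b])
            if not ok.any():
                out[a, b] = out[b, a] = np.nan
                continue
            sim = 1 - np.abs(d[a, ok] - d[b, ok]).mean() / 2
            out[a, b] = out[b, a] = sim
    return pd.DataFrame(out, index=gm.sample_ids, columns=gm.sample_ids)


def cluster_and_order(ibs: pd.DataFrame, linkage: str = "average",
                      impute_missing: bool = False) -> tuple[list[str], np.ndarray]:
    """Average-linkage hierarchical clustering on the 1 - IBS distance.

    Samples are pre-sorted lexicographically so that exact distance ties
    resolve deterministically.  Returns the leaf order and the scipy linkage
    matrix (rows refer to the sorted sample order).
    """
    ids = sorted(ibs.index)
    mat = ibs.loc[ids, ids].to_numpy(dtype=float)
    dist = 1 - mat
    np.fill_diagonal(dist, 0.0)
    if np.isnan(dist).any():
        if not impute_missing:
            raise ValueError("IBS matrix has missing entries; pass "
                             "impute_missing=True to fill them with the matrix mean")
        dist[np.isnan(dist)] = np.nanmean(dist)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    order = hierarchy.leaves_list(Z)
    return [ids[i] for i in order], Z


def dendrogram_newick(Z: np.ndarray, ids: list[str]) -> str:
    """Serialize a scipy linkage as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return ids[node.id]
        left, right = node.get_left(), node.get_right()
        return (f"({rec(left)}:{node.dist - left.dist:.6g},"
                f"{rec(right)}:{node.dist - right.dist:.6g})")

    return rec(tree) + ";"


def sibling_adjacency_fraction(order: list[str], pairs: pd.DataFrame) -> float:
    """Fraction of sibling pairs occupying adjacent leaf positions.

    ``pairs`` needs columns line_a, line_b (one row per sibling pair).
    """
    posn = {s: i for i, s in enumerate(order)}
    missing = ({*pairs["line_a"], *pairs["line_b"]} - set(posn))
    if missing:
        raise KeyError(f"paired line(s) absent from leaf order: {sorted(missing)}")
    adj = sum(abs(posn[a] - posn[b]) == 1
              for a, b in zip(pairs["line_a"], pairs["line_b"]))
    return adj / len(pairs)


def pairwise_sharing_fraction(gm: GenotypeMatrix, line_a: str, line_b: str,
                              grid: WindowGrid, identity_floor: float = 0.99,
                              denominator: str = "fixed",
                              max_het_frac: float = 0.05) -> float:
    """Genome fraction where two inbred lines carry the same fixed haplotype.

    A window is *shared* when the per-site IBS mean over co-genotyped sites
    is at least ``identity_floor``.  With ``denominator="fixed"`` (default)
    the fraction is taken over windows where both lines are fixed (their
    heterozygous-genotype fraction in the window is <= ``max_het_frac``),
    which estimates the pedigree probability of fixing the same founder
    haplotype — lines sampled before fixation is complete otherwise dilute
    the estimate.  ``denominator="all"`` uses every co-genotyped window.
    Returns NaN when the denominator is empty.
    """
    if denominator not in ("fixed", "all"):
        raise ValueError("denominator must be 'fixed' or 'all'")
    ia, ib = gm.sample_index(line_a), gm.sample_index(line_b)
    ga, gb = gm.geno[ia], gm.geno[ib]
    ok = (ga != MISSING) & (gb != MISSING)
    nw = grid.total_windows
    ibs_sum = np.zeros(nw)
    n_ok = np.zeros(nw, dtype=np.int64)
    het_a = np.zeros(nw, dtype=np.int64)
    het_b = np.zeros(nw, dtype=np.int64)
    called_a = np.zeros(nw, dtype=np.int64)
    called_b = np.zeros(nw, dtype=np.int64)
    for c, grp in gm.variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        widx = grid.window_index(c, grp["pos"].to_numpy())
        oki = ok[idx]
        sim = 1 - np.abs(ga[idx] - gb[idx]).astype(float) / 2
        np.add.at(ibs_sum, widx[oki], sim[oki])
        np.add.at(n_ok, widx[oki], 1)
        np.add.at(het_a, widx[ga[idx] == 1], 1)
        np.add.at(het_b, widx[gb[idx] == 1], 1)
        np.add.at(called_a, widx[ga[idx] != MISSING], 1)
        np.add.at(called_b, widx[gb[idx] != MISSING], 1)
    covered = n_ok > 0
    if denominator == "fixed":
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.where(called_a > 0, het_a / np.maximum(called_a, 1), 1.0)
            fb = np.where(called_b > 0, het_b / np.maximum(called_b, 1), 1.0)
        covered &= (fa <= max_het_frac) & (fb <= max_het_frac)
    if not covered.any():
        return float("nan")
    with np.errstate(invalid="ignore"):
        mean_ibs = ibs_sum / np.maximum(n_ok, 1)
    return float((mean_ibs[covered] >= identity_floor).mean())
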