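"""Windowed and per-site population-genetic statistics.

Implements the Hudson F_ST estimator with ratio-of-averages window
aggregation, windowed nucleotide diversity, LD decay (pairwise r^2 of
genotype dosages binned by distance), a moment-based inbreeding coefficient
against reference allele frequencies, and eta^2 broad-sense heritability
from a one-way ANOVA decomposition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_variants import MISSING, GenotypeMatrix, WindowGrid


def site_fst_hudson(p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Hudson (1992) per-site F_ST components.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    with n the allele sample sizes.  Sites monomorphic in both populations
    have den = 0 and must be excluded by the caller when forming ratios.
    """
    p1, n1, p2, n2 = (np.asarray(x, dtype=float) for x in (p1, n1, p2, n2))
    if ((n1 < 2) | (n2 < 2)).any():
        raise ValueError("need at least 2 alleles per population at every site")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def windowed_fst(variants: pd.DataFrame, p1, n1, p2, n2, grid: WindowGrid,
                 min_snps: int = 50) -> pd.DataFrame:
    """Windowed Hudson F_ST as a ratio of averages.

    Per window, F_ST = sum(num) / sum(den) over sites usable in both
    populations (den > 0); windows with fewer than ``min_snps`` usable sites
    get a missing value.  Returns a WindowStat frame with columns
    chrom, start, end, value, n_snps, log10_n_snps.
    """
    num, den = site_fst_hudson(p1, n1, p2, n2)
    usable = den > 0
    nw = grid.total_windows
    num_sum = np.zeros(nw)
    den_sum = np.zeros(nw)
    n_used = np.zeros(nw, dtype=np.int64)
    for c, grp in variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        widx = grid.window_index(c, grp["pos"].to_numpy())
        m = usable[idx]
        np.add.at(num_sum, widx[m], num[idx][m])
        np.add.at(den_sum, widx[m], den[idx][m])
        np.add.at(n_used, widx[m], 1)
    out = grid.windows()
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where((n_used >= min_snps) & (den_sum > 0),
                         num_sum / np.where(den_sum > 0, den_sum, 1), np.nan)
    out["value"] = value
    out["n_snps"] = n_used
    with np.errstate(divide="ignore"):
        out["log10_n_snps"] = np.where(n_used > 0, np.log10(np.maximum(n_used, 1)), np.nan)
    return out


def nucleotide_diversity(gm: GenotypeMatrix, grid: WindowGrid,
                         samples: list[str] | None = None) -> pd.DataFrame:
    """Windowed nucleotide diversity pi from genotype dosages.

    Per site the unbiased expected heterozygosity 2*p*q * n/(n-1) is summed
    over sites in the window (n = non-missing allele count) and divided by
    the full window span in bp; windows without genotyped sites are 0, not
    missing, consistent with summing sites over a fixed span.
    """
    if samples is not None:
        gm = gm.subset_samples(samples)
    p, n = gm.alt_freqs()
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(n >= 2, 2 * p * (1 - p) * n / np.maximum(n - 1, 1), 0.0)
    nw = grid.total_windows
    acc = np.zeros(nw)
    n_snps = np.zeros(nw, dtype=np.int64)
    for c, grp in gm.variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        widx = grid.window_index(c, grp["pos"].to_numpy())
        np.add.at(acc, widx, per_site[idx])
        np.add.at(n_snps, widx, (n[idx] >= 2).astype(np.int64))
    out = grid.windows()
    out["value"] = acc / (out["end"] - out["start"]).to_numpy()
    out["n_snps"] = n_snps
    return out


def ld_pairs_r2(gm: GenotypeMatrix, max_dist: int = 10_000,
                min_shared: int = 3) -> pd.DataFrame:
    """r^2 between all pairs of SNPs within ``max_dist`` bp on a chromosome.

    r^2 is the squared Pearson correlation of genotype dosages over samples
    non-missing at both sites (composite LD, appropriate for unphased inbred
    lines).  Pairs with fewer than ``min_shared`` shared samples or zero
    dosage variance at either site are skipped.  The caller is expected to
    have applied the MAF filter beforehand.

    Returns a frame with columns chrom, pos_i, pos_j, dist, r2.
    """
    frames = []
    dos = gm.dosage()
    for c, grp in gm.variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        sub = dos[:, idx]
        finite = np.isfinite(sub)
        m = len(pos)
        pi_acc, pj_acc, r2_acc = [], [], []
        for a in range(m - 1):
            b_hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            if b_hi <= a + 1:
                continue
            x = sub[:, a]
            Y = sub[:, a + 1:b_hi]
            ok = finite[:, a][:, None] & finite[:, a + 1:b_hi]
            cnt = ok.sum(axis=0)
            xm = np.where(ok, x[:, None], 0.0)
            ym = np.where(ok, Y, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                mx = xm.sum(0) / cnt
                my = ym.sum(0) / cnt
                sxy = (xm * ym).sum(0) / cnt - mx * my
                vx = (xm ** 2).sum(0) / cnt - mx ** 2
                vy = (ym ** 2).sum(0) / cnt - my ** 2
                r2 = sxy ** 2 / (vx * vy)
            keep = (cnt >= min_shared) & (vx > 0) & (vy > 0)
            if not keep.any():
                continue
            pj = pos[a + 1:b_hi][keep]
            pi_acc.append(np.full(len(pj), pos[a]))
            pj_acc.append(pj)
            r2_acc.append(r2[keep])
        if pi_acc:
            pi = np.concatenate(pi_acc)
            pj = np.concatenate(pj_acc)
            frames.append(pd.DataFrame({
                "chrom": c, "pos_i": pi, "pos_j": pj,
                "dist": pj - pi, "r2": np.concatenate(r2_acc)}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos_i", "pos_j", "dist", "r2"])
    return pd.concat(frames, ignore_index=True)


def ld_decay_profile(pairs: pd.DataFrame, bin_size: int = 100,
                     max_dist: int = 10_000) -> pd.DataFrame:
    """Mean r^2 in non-overlapping distance bins.

    Bin b covers distances [bin_size*b, bin_size*(b+1)); empty bins are
    reported with a missing mean.  Columns: bin_left_bp, mean_r2, n_pairs.
    """
    n_bins = -(-max_dist // bin_size)
    lefts = np.arange(n_bins) * bin_size
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    if len(pairs):
        d = pairs["dist"].to_numpy()
        r2 = pairs["r2"].to_numpy()
        keep = d < max_dist
        b = d[keep] // bin_size
        np.add.at(sums, b, r2[keep])
        np.add.at(counts, b, 1)
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"bin_left_bp": lefts, "mean_r2": mean, "n_pairs": counts})


def inbreeding_coefficient_moment(gm: GenotypeMatrix, ref_p: np.ndarray,
                                  ref_n: np.ndarray | None = None) -> pd.Series:
    """Moment (excess-homozygosity) inbreeding coefficient per sample.

    F = (O_hom - E_hom) / (L - E_hom), with E_hom the Hardy-Weinberg
    expected homozygote count under the supplied reference allele
    frequencies (unbiased per-site heterozygosity 2pq * n/(n-1) when the
    reference allele sample size ``ref_n`` is given), O_hom the observed
    homozygote count, and L the sample's non-missing site count.  This is the
    PLINK-style method-of-moments estimator.
    """
    ref_p = np.asarray(ref_p, dtype=float)
    if ref_n is not None:
        ref_n = np.asarray(ref_n, dtype=float)
        het_exp = 2 * ref_p * (1 - ref_p) * ref_n / np.maximum(ref_n - 1, 1)
    else:
        het_exp = 2 * ref_p * (1 - ref_p)
    out = {}
    for i, s in enumerate(gm.sample_ids):
        g = gm.geno[i]
        called = g != MISSING
        L = called.sum()
        o_hom = np.count_nonzero((g == 0) | (g == 2))
        e_hom = (1 - het_exp[called]).sum()
        denom = L - e_hom
        out[s] = float((o_hom - e_hom) / denom) if abs(denom) > 1e-12 else np.nan
    return pd.Series(out, name="F")


def eta_squared_heritability(values, groups) -> float:
    """eta^2 = SS_between / SS_total from a one-way ANOVA across lines.

    In a clonal or near-isogenic panel the between-line variance fraction of
    a trait is a proxy for broad-sense heritability H^2.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([(groups == g).sum() for g in labels])
    if (sizes < 1).any() or (sizes >= 2).sum() < 1:
        raise ValueError("every group needs >= 1 value and at least one group >= 2")
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    if ss_total <= 0:
        raise ValueError("zero total variance")
    ss_between = 0.0
    for g in labels:
        v = values[groups == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
    return float(ss_between / ss_total)
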