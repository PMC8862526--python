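"""ABBA-BABA introgression statistics on polarized allele frequencies.

Sites are polarized against a per-site ancestral-allele table (derived
allele = the non-ancestral allele), then Patterson's D and the f_d
admixture-fraction estimator (Martin, Davey & Jiggins 2015) are computed
over sliding windows for a population quartet (((P1, P2), P3), O): P1 the
close reference population, P2 the focal (possibly admixed) population,
P3 the candidate donor, O the outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_variants import GenotypeMatrix


@dataclass
class PolarizedFreqs:
    """Per-site derived-allele frequencies for the four populations.

    ``sites`` has columns chrom, pos, ancestral; p1, p2, p3, pO are aligned
    derived-allele frequency arrays in [0, 1].  ``n_dropped`` counts input
    sites lost to an unusable ancestral call.
    """

    sites: pd.DataFrame
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    pO: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for arr in (self.p1, self.p2, self.p3, self.pO):
            if arr.shape != (len(self.sites),):
                raise ValueError("frequency arrays must align with sites")
            if len(arr) and (np.nanmin(arr) < -1e-12 or np.nanmax(arr) > 1 + 1e-12):
                raise ValueError("derived frequencies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.sites)

    def subset(self, mask: np.ndarray) -> "PolarizedFreqs":
        return PolarizedFreqs(self.sites.loc[mask].reset_index(drop=True),
                              self.p1[mask], self.p2[mask], self.p3[mask],
                              self.pO[mask], self.n_dropped)


def _pop_freqs(gm: GenotypeMatrix, samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
    idx = np.array([gm.sample_index(s) for s in samples])
    return gm.alt_freqs(idx)


def polarize(gm: GenotypeMatrix, populations: dict[str, list[str]],
             ancestral: pd.DataFrame) -> PolarizedFreqs:
    """Polarize alt-allele frequencies to derived-allele frequencies.

    ``populations`` maps the keys "P1", "P2", "P3", "O" to sample lists;
    ``ancestral`` is a table with columns chrom, pos, ancestral_base.  Sites
    whose ancestral base is missing, not a single ACGT base, or equal to
    neither the ref nor the alt allele are dropped (tallied in
    ``n_dropped``).  Where the ancestral base equals the alt allele the
    frequency is flipped: derived = 1 - alt frequency.
    """
    for k in ("P1", "P2", "P3", "O"):
        if k not in populations:
            raise KeyError(f"populations must define {k}")
    anc = ancestral.set_index(["chrom", "pos"])["ancestral_base"]
    key = pd.MultiIndex.from_frame(gm.variants[["chrom", "pos"]])
    anc_base = anc.reindex(key).to_numpy(dtype=object)

    ref = gm.variants["ref"].to_numpy()
    alt = gm.variants["alt"].to_numpy()
    is_ref = anc_base == ref
    is_alt = anc_base == alt
    usable = is_ref | is_alt
    n_dropped = int((~usable).sum())

    freqs = {}
    for k in ("P1", "P2", "P3", "O"):
        p, n = _pop_freqs(gm, populations[k])
        usable &= n > 0
        freqs[k] = p
    n_dropped = int((~usable).sum())

    flip = is_alt[usable]
    sites = gm.variants.loc[usable, ["chrom", "pos"]].reset_index(drop=True)
    sites["ancestral"] = anc_base[usable]
    out = {}
    for k, p in freqs.items():
        pu = p[usable]
        out[k] = np.where(flip, 1 - pu, pu)
    return PolarizedFreqs(sites, out["P1"], out["P2"], out["P3"], out["O"], n_dropped)


def _abba_baba(p1, p2, p3, pO) -> tuple[np.ndarray, np.ndarray]:
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    return abba, baba


def d_statistic(freqs: PolarizedFreqs) -> float:
    """Patterson's D over the given site set; NaN when the denominator is 0."""
    if len(freqs) == 0:
        raise ValueError("need at least one site")
    abba, baba = _abba_baba(freqs.p1, freqs.p2, freqs.p3, freqs.pO)
    den = (abba + baba).sum()
    if den == 0:
        return float("nan")
    return float((abba - baba).sum() / den)


def fd_statistic(freqs: PolarizedFreqs) -> float:
    """f_d admixture-proportion estimator over one window.

    f_d = S(P1, P2, P3, O) / S(P1, P_D, P_D, O), with S the D numerator and
    P_D, site by site, whichever of P2 / P3 has the higher derived-allele
    frequency.  Defined only where the window's D is positive; returns NaN
    for D <= 0 or a zero denominator.
    """
    d = d_statistic(freqs)
    if not np.isfinite(d) or d <= 0:
        return float("nan")
    abba, baba = _abba_baba(freqs.p1, freqs.p2, freqs.p3, freqs.pO)
    pD = np.maximum(freqs.p2, freqs.p3)
    abba_d, baba_d = _abba_baba(freqs.p1, pD, pD, freqs.pO)
    den = (abba_d - baba_d).sum()
    if den == 0:
        return float("nan")
    return float((abba - baba).sum() / den)


def sliding_fd_scan(freqs: PolarizedFreqs, chrom_lengths: dict[str, int],
                    window: int = 500_000, step: int | None = None,
                    min_snps: int = 250) -> pd.DataFrame:
    """D and f_d in sliding windows; half-window step by default.

    Windows with fewer than ``min_snps`` polarized sites are reported with
    missing values; f_d is additionally missing wherever window D <= 0.
    Returns columns chrom, start, end, D, fd, n_snps plus the genome-wide
    mean f_d over defined windows in ``.attrs["mean_fd"]``.
    """
    if step is None:
        step = window // 2
    rows = []
    chrom_arr = freqs.sites["chrom"].to_numpy()
    pos_arr = freqs.sites["pos"].to_numpy()
    for c, L in chrom_lengths.items():
        on_c = np.flatnonzero(chrom_arr == c)
        pos_c = pos_arr[on_c]
        order = np.argsort(pos_c, kind="stable")
        on_c, pos_c = on_c[order], pos_c[order]
        start = 0
        while start < L:
            end = min(start + window, L)
            lo = np.searchsorted(pos_c, start + 1)
            hi = np.searchsorted(pos_c, end, side="right")
            n = hi - lo
            if n >= min_snps:
                sub = freqs.subset(on_c[lo:hi])
                d = d_statistic(sub)
                fd = fd_statistic(sub)
            else:
                d, fd = np.nan, np.nan
            rows.append((c, start, end, d, fd, int(n)))
            if end >= L:
                break
            start += step
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "D", "fd", "n_snps"])
    defined = out["fd"].dropna()
    out.attrs["mean_fd"] = float(defined.mean()) if len(defined) else float("nan")
    return out
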