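"""Variant and tabular I/O: genotype matrices and windowed heterozygosity counts.

All downstream stages consume a :class:`GenotypeMatrix` (sample x variant
genotype codes) built from a multi-sample VCF, and most of them operate on a
fixed genomic window grid (:class:`WindowGrid`).  Genotype codes follow the
usual dosage convention: 0 = homozygous reference, 1 = heterozygous,
2 = homozygous alternate, -1 = missing.  Internally all windows are 0-based
half-open (BED convention); VCF positions are 1-based, so a variant at
position ``p`` falls in window ``(p - 1) // window_size``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1
_BASES = {"A", "C", "G", "T"}


@dataclass
class GenotypeMatrix:
    """Biallelic-SNP genotype codes for a set of lines.

    Attributes
    ----------
    sample_ids : list of str
        Ordered line identifiers.
    variants : pandas.DataFrame
        Columns ``chrom, pos, ref, alt``; ``pos`` is 1-based as in VCF,
        strictly increasing within each chromosome.
    geno : numpy.ndarray of int8, shape (n_samples, n_variants)
        Codes in {-1, 0, 1, 2}.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    geno: np.ndarray
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"geno shape {self.geno.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.geno, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def subset_samples(self, samples: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeMatrix(list(samples), self.variants, self.geno[idx],
                              dict(self.chrom_lengths))

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.variants["chrom"]))

    def dosage(self, missing_to_nan: bool = True) -> np.ndarray:
        """Genotype codes as float dosage with missing as NaN."""
        d = self.geno.astype(float)
        if missing_to_nan:
            d[self.geno == MISSING] = np.nan
        return d

    def het_rate(self, exclude_chroms: set[str] | None = None) -> float:
        """Fraction of non-missing genotype calls that are heterozygous."""
        mask = np.ones(self.n_variants, dtype=bool)
        if exclude_chroms:
            mask = ~self.variants["chrom"].isin(exclude_chroms).to_numpy()
        g = self.geno[:, mask]
        n_called = np.count_nonzero(g != MISSING)
        if n_called == 0:
            return float("nan")
        return np.count_nonzero(g == 1) / n_called

    def alt_freqs(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant alternate-allele frequency and non-missing allele count.

        Returns ``(p, n)`` where ``n`` is the diploid allele count (2 x number
        of non-missing genotypes).  ``p`` is NaN where ``n`` is 0.
        """
        g = self.geno if sample_idx is None else self.geno[sample_idx]
        called = g != MISSING
        n = 2 * called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return p, n


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping tiling of each chromosome into fixed-size windows."""

    window_size: int
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        for c, l in self.chrom_lengths.items():
            if l <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {l}")

    def n_windows(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.window_size)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_windows(self) -> int:
        return sum(self.n_windows(c) for c in self.chrom_lengths)

    def windows(self) -> pd.DataFrame:
        """All windows as a DataFrame (chrom, start, end), 0-based half-open."""
        rows = []
        for c, l in self.chrom_lengths.items():
            starts = np.arange(0, l, self.window_size)
            ends = np.minimum(starts + self.window_size, l)
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def window_offsets(self) -> dict[str, int]:
        """Offset of each chromosome's first window in the flat window axis."""
        off, acc = {}, 0
        for c in self.chrom_lengths:
            off[c] = acc
            acc += self.n_windows(c)
        return off

    def window_index(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Flat window index for 1-based positions on ``chrom``."""
        pos = np.asarray(pos)
        if ((pos < 1) | (pos > self.chrom_lengths[chrom])).any():
            raise ValueError(f"position outside chromosome {chrom}")
        return self.window_offsets()[chrom] + (pos - 1) // self.window_size


@dataclass
class WindowCounts:
    """Per-line heterozygous-SNP counts on a window grid.

    ``counts[l, w]`` is the number of heterozygous genotypes of line ``l``
    in window ``w`` (flat window axis across chromosomes); ``n_sites[l, w]``
    the number of non-missing genotyped SNPs.
    """

    grid: WindowGrid
    sample_ids: list[str]
    counts: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.n_sites = np.asarray(self.n_sites, dtype=np.int64)
        shape = (len(self.sample_ids), self.grid.total_windows)
        if self.counts.shape != shape or self.n_sites.shape != shape:
            raise ValueError("counts/n_sites shape does not match grid")
        if (self.counts < 0).any() or (self.counts > self.n_sites).any():
            raise ValueError("need 0 <= counts <= n_sites elementwise")

    def per_chromosome(self) -> dict[str, np.ndarray]:
        """Counts split per chromosome: chrom -> (n_lines, n_windows) array."""
        out = {}
        off = self.grid.window_offsets()
        for c in self.grid.chroms:
            out[c] = self.counts[:, off[c]:off[c] + self.grid.n_windows(c)]
        return out

    def to_frame(self) -> pd.DataFrame:
        win = self.grid.windows()
        rows = []
        for i, line in enumerate(self.sample_ids):
            df = win.copy()
            df.insert(0, "line", line)
            df["n_het"] = self.counts[i]
            df["n_sites"] = self.n_sites[i]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _code_from_gt(gt: tuple) -> int:
    # cyvcf2 genotypes entries are [allele0, allele1, phased]
    a, b = gt[0], gt[1]
    if a < 0 or b < 0:
        return MISSING
    return int(a > 0) + int(b > 0)


def read_vcf(path, samples: list[str] | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`, keeping only biallelic SNPs.

    Multiallelic records and INDELs are dropped (and counted in the log);
    phasing is ignored.  Chromosome lengths come from ``##contig`` headers
    when present, otherwise from the last variant position rounded up.
    """
    vcf = VCF(str(path), gts012=False)
    if samples is not None:
        unknown = set(samples) - set(vcf.samples)
        if unknown:
            raise KeyError(f"unknown sample name(s): {sorted(unknown)}")
        vcf.set_samples(samples)
    sample_ids = list(vcf.samples)

    chrom_lengths: dict[str, int] = {}
    if vcf.seqnames and vcf.seqlens:
        chrom_lengths = dict(zip(vcf.seqnames, vcf.seqlens))

    records, codes = [], []
    n_dropped = 0
    saw_gt = False
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_dropped += 1
            continue
        if rec.REF not in _BASES or rec.ALT[0] not in _BASES:
            n_dropped += 1
            continue
        gts = rec.genotypes
        if gts is None:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} has no GT field")
        saw_gt = True
        records.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        codes.append([_code_from_gt(g) for g in gts])
    if records and not saw_gt:
        raise ValueError("VCF has no GT fields")
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)

    variants = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt"])
    geno = (np.array(codes, dtype=np.int8).T if codes
            else np.zeros((len(sample_ids), 0), dtype=np.int8))
    if not chrom_lengths and len(variants):
        for c, grp in variants.groupby("chrom", sort=False):
            chrom_lengths[c] = int(grp["pos"].max())
    return GenotypeMatrix(sample_ids, variants, geno, chrom_lengths)


_GT_STR = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT only) for a genotype matrix."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, l in gm.chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        chroms = gm.variants["chrom"].to_numpy()
        poss = gm.variants["pos"].to_numpy()
        refs = gm.variants["ref"].to_numpy()
        alts = gm.variants["alt"].to_numpy()
        for j in range(gm.n_variants):
            gts = "\t".join(_GT_STR[int(g)] for g in gm.geno[:, j])
            fh.write(f"{chroms[j]}\t{poss[j]}\t.\t{refs[j]}\t{alts[j]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def filter_variants(gm: GenotypeMatrix, max_missing_frac: float = 1.0,
                    min_maf: float = 0.0) -> GenotypeMatrix:
    """Keep variants with missingness <= ``max_missing_frac`` and MAF >= ``min_maf``.

    MAF is computed from allele dosage over non-missing genotypes; variants
    exactly at either threshold are retained.
    """
    if not (0 <= max_missing_frac <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must be fractions in [0, 1]")
    missing_frac = (gm.geno == MISSING).mean(axis=0)
    p, n = gm.alt_freqs()
    maf = np.fmin(p, 1 - p)
    keep = (missing_frac <= max_missing_frac) & (n > 0) & (maf >= min_maf)
    if not keep.any():
        warnings.warn("filter_variants: no variants retained", stacklevel=2)
    return GenotypeMatrix(
        gm.sample_ids,
        gm.variants.loc[keep].reset_index(drop=True),
        gm.geno[:, keep],
        dict(gm.chrom_lengths),
    )


def grid_from_matrix(gm: GenotypeMatrix, window_size: int) -> WindowGrid:
    """Build a window grid covering the matrix's chromosomes.

    Uses header contig lengths; chromosomes absent from the header get the
    last variant position rounded up to a whole window.
    """
    lengths = {}
    for c in gm.chroms():
        if c in gm.chrom_lengths:
            lengths[c] = gm.chrom_lengths[c]
        else:
            m = int(gm.variants.loc[gm.variants["chrom"] == c, "pos"].max())
            lengths[c] = -(-m // window_size) * window_size
    return WindowGrid(window_size, lengths)


def window_het_counts(gm: GenotypeMatrix, grid: WindowGrid) -> WindowCounts:
    """Count heterozygous genotypes per line per window.

    A variant at 1-based position ``p`` belongs to window ``(p-1) // size``.
    Raises if a variant lies beyond its chromosome's declared length or on a
    chromosome the grid does not cover.
    """
    missing_chroms = set(gm.chroms()) - set(grid.chrom_lengths)
    if missing_chroms:
        raise ValueError(f"grid does not cover chromosome(s) {sorted(missing_chroms)}")
    nw = grid.total_windows
    counts = np.zeros((gm.n_samples, nw), dtype=np.int64)
    n_sites = np.zeros((gm.n_samples, nw), dtype=np.int64)
    for c, grp in gm.variants.groupby("chrom", sort=False):
        widx = grid.window_index(c, grp["pos"].to_numpy())
        sub = gm.geno[:, grp.index.to_numpy()]
        for l in range(gm.n_samples):
            np.add.at(counts[l], widx[sub[l] == 1], 1)
            np.add.at(n_sites[l], widx[sub[l] != MISSING], 1)
    return WindowCounts(grid, list(gm.sample_ids), counts, n_sites)


def read_table(path) -> pd.DataFrame:
    """Read a headered TSV metadata table."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
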