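"""Full-sib inbreeding genome simulator.

Generates a desk-scale analogue of an inbred-line panel derived from a wild
founder population: founder haplotypes carry segregating sites whose
derived-allele frequencies follow the neutral site-frequency spectrum
(density proportional to 1/i), calibrated so that expected per-site
pairwise diversity matches a target (default 0.0037).  Each line descends
from one founder pair through G generations of single full-sib-pair
(brother-sister) matings with Poisson recombination and exact
founder-segment ancestry tracking, so the true autozygous fraction of every
line is known.  Optional features mirror the structure of a real panel:
sibling lines (two lines initiated from different F1 sib pairs of the same
founder family), a forced-heterozygous sex-determining segment kept
obligately heterozygous in the sampled males, accidental mid-pedigree
outcrosses to an unrelated inbred line, and genotyping error.

Under single full-sib mating the inbreeding coefficient follows Wright's
recurrence F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4 with F_0 = F_{-1} = 0, which
the realized autozygous fractions recover in expectation
(:func:`wright_inbreeding_coefficients`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_variants import GenotypeMatrix

_BASES = np.array(["A", "C", "G", "T"])

# ---------------------------------------------------------------------------
# genome / configuration


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int           # bp
    rate: float           # recombination rate, cM/Mb

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("chromosome length must be positive")
        if self.rate < 0:
            raise ValueError("recombination rate must be >= 0")


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome layout plus an optional obligate-heterozygous sex region."""

    chromosomes: tuple[Chromosome, ...]
    sex_region: tuple[str, int, int] | None = None  # (chrom, start, end), 0-based half-open

    def __post_init__(self) -> None:
        if self.sex_region is not None:
            c, s, e = self.sex_region
            lengths = {ch.name: ch.length for ch in self.chromosomes}
            if c not in lengths or not (0 <= s < e <= lengths[c]):
                raise ValueError("sex_region must lie within its chromosome")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


def default_genome(n_chromosomes: int = 24, length: int = 1_000_000,
                   rate: float = 3.0,
                   sex_region: tuple[str, int, int] | None = ("chr1", 450_000, 550_000),
                   ) -> GenomeSpec:
    """Desk-scale genome: 24 x 1 Mb at 3 cM/Mb (~0.7 crossovers per meiosis
    genome-wide in miniature), sex segment mid-chr1."""
    chroms = tuple(Chromosome(f"chr{i + 1}", length, rate) for i in range(n_chromosomes))
    return GenomeSpec(chroms, sex_region)


@dataclass(frozen=True)
class SimConfig:
    n_founder_pairs: int = 40
    lines_per_family: int = 2
    generations: int = 9
    target_pi: float = 0.0037
    n_sites: int | None = None         # override the pi-derived site count
    sfs_pool_size: int = 200           # 2N gridding of the frequency spectrum
    outcross_prob: float = 0.05
    genotype_error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("need at least one generation of inbreeding")
        for p in (self.outcross_prob, self.genotype_error_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.target_pi < 0.05:
            raise ValueError("target_pi must lie in [0, 0.05)")


def wright_inbreeding_coefficients(generations: int) -> np.ndarray:
    """Expected inbreeding coefficient after each full-sib generation.

    F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4, F_0 = F_{-1} = 0; the returned
    array holds F_1 .. F_G (F_1 = 0.25, F_9 = 0.859375).
    """
    f_prev2, f_prev1 = 0.0, 0.0
    out = []
    for _ in range(generations):
        f = (1 + 2 * f_prev1 + f_prev2) / 4
        out.append(f)
        f_prev2, f_prev1 = f_prev1, f
    return np.array(out)


# ---------------------------------------------------------------------------
# founder sites and haplotypes


@dataclass
class SiteTable:
    """Segregating sites of the founder population.

    Per chromosome: 1-based positions, the derived-allele frequency under
    the sampled SFS, whether the derived allele was labelled as the VCF ALT
    allele, and the ref/alt bases.  The true ancestral base is therefore
    ``ref`` where ``derived_is_alt`` else ``alt``.
    """

    chroms: list[str]
    pos: dict[str, np.ndarray]
    p_derived: dict[str, np.ndarray]
    derived_is_alt: dict[str, np.ndarray]
    ref: dict[str, np.ndarray]
    alt: dict[str, np.ndarray]

    def n_sites(self, chrom: str) -> int:
        return len(self.pos[chrom])

    @property
    def total_sites(self) -> int:
        return sum(len(v) for v in self.pos.values())

    def p_alt(self, chrom: str) -> np.ndarray:
        p = self.p_derived[chrom]
        return np.where(self.derived_is_alt[chrom], p, 1 - p)

    def variants_frame(self) -> pd.DataFrame:
        rows = [pd.DataFrame({"chrom": c, "pos": self.pos[c],
                              "ref": self.ref[c], "alt": self.alt[c]})
                for c in self.chroms]
        return pd.concat(rows, ignore_index=True)

    def ancestral_table(self) -> pd.DataFrame:
        rows = []
        for c in self.chroms:
            anc = np.where(self.derived_is_alt[c], self.ref[c], self.alt[c])
            rows.append(pd.DataFrame({"chrom": c, "pos": self.pos[c],
                                      "ancestral_base": anc}))
        return pd.concat(rows, ignore_index=True)


def _sfs_expected_het(pool_2n: int) -> float:
    i = np.arange(1, pool_2n)
    w = 1.0 / i
    p = i / pool_2n
    return float((w * 2 * p * (1 - p)).sum() / w.sum())


def sample_sites(spec: GenomeSpec, cfg: SimConfig, rng: np.random.Generator) -> SiteTable:
    """Place segregating sites and draw their derived-allele frequencies.

    Site density is chosen so that expected per-site diversity over the
    whole genome equals ``target_pi`` given the SFS's mean heterozygosity;
    an explicit ``n_sites`` (total) overrides the density, raising if it
    cannot reach the target.
    """
    e_het = _sfs_expected_het(cfg.sfs_pool_size)
    required = cfg.target_pi * spec.total_length / e_het
    if cfg.n_sites is not None:
        if cfg.n_sites < required * 0.9:
            raise ValueError(
                f"target_pi={cfg.target_pi} needs ~{required:.0f} sites "
                f"({required / spec.total_length:.4g} per bp); got n_sites={cfg.n_sites}")
        total = cfg.n_sites
    else:
        total = int(round(required))

    i = np.arange(1, cfg.sfs_pool_size)
    sfs_p = (1.0 / i) / (1.0 / i).sum()
    chroms, pos, pder, dalt, ref, alt = [], {}, {}, {}, {}, {}
    for ch in spec.chromosomes:
        n_c = int(round(total * ch.length / spec.total_length))
        chroms.append(ch.name)
        if cfg.target_pi == 0 or n_c == 0:
            pos[ch.name] = np.empty(0, dtype=np.int64)
            pder[ch.name] = np.empty(0)
            dalt[ch.name] = np.empty(0, dtype=bool)
            ref[ch.name] = np.empty(0, dtype=object)
            alt[ch.name] = np.empty(0, dtype=object)
            continue
        loc = np.sort(rng.choice(ch.length, size=min(n_c, ch.length), replace=False)) + 1
        n_c = len(loc)
        freq_idx = rng.choice(len(sfs_p), size=n_c, p=sfs_p)
        pos[ch.name] = loc.astype(np.int64)
        pder[ch.name] = (freq_idx + 1) / cfg.sfs_pool_size
        dalt[ch.name] = rng.random(n_c) < 0.8
        r = rng.integers(0, 4, size=n_c)
        a = (r + rng.integers(1, 4, size=n_c)) % 4
        ref[ch.name] = _BASES[r].astype(object)
        alt[ch.name] = _BASES[a].astype(object)
    return SiteTable(chroms, pos, pder, dalt, ref, alt)


class FounderSet:
    """Lazy per-family founder haplotype alleles.

    Family ``f`` owns global haplotype ids ``4f .. 4f+3``: the founder
    father carries (4f, 4f+1), the mother (4f+2, 4f+3).  Haplotype
    ``4f + 1`` is the family's Y-tagged haplotype: inside the sex region its
    alleles are drawn at frequency 1/2 independently of the population
    frequencies, modelling a diverged non-recombining Y segment.
    """

    Y_ROW = 1

    def __init__(self, spec: GenomeSpec, sites: SiteTable, seed_seq: np.random.SeedSequence):
        self.spec = spec
        self.sites = sites
        self._seed_seq = seed_seq
        self._cache: dict[int, dict[str, np.ndarray]] = {}

    def alleles(self, family: int) -> dict[str, np.ndarray]:
        """ALT-allele indicators: chrom -> (4, n_sites) int8 array."""
        if family not in self._cache:
            child = np.random.SeedSequence(
                entropy=self._seed_seq.entropy,
                spawn_key=self._seed_seq.spawn_key + (family,))
            rng = np.random.default_rng(child)
            fam = {}
            for c in self.sites.chroms:
                p_alt = self.sites.p_alt(c)
                fam[c] = (rng.random((4, len(p_alt))) < p_alt).astype(np.int8)
            if self.spec.sex_region is not None:
                sc, s, e = self.spec.sex_region
                in_reg = (self.sites.pos[sc] > s) & (self.sites.pos[sc] <= e)
                fam[sc][self.Y_ROW, in_reg] = (rng.random(int(in_reg.sum())) < 0.5
                                               ).astype(np.int8)
            self._cache[family] = fam
        return self._cache[family]

    def hap_alleles(self, hap_id: int, chrom: str) -> np.ndarray:
        return self.alleles(hap_id // 4)[chrom][hap_id % 4]


def simulate_founders(spec: GenomeSpec, cfg: SimConfig) -> tuple[SiteTable, FounderSet]:
    """Sites plus a lazy founder-haplotype set (4 haplotypes per family)."""
    ss = np.random.SeedSequence(cfg.seed)
    kids = ss.spawn(2)
    sites = sample_sites(spec, cfg, np.random.default_rng(kids[0]))
    return sites, FounderSet(spec, sites, kids[1])


# ---------------------------------------------------------------------------
# pedigree machinery: segment haplotypes, meiosis, inbreeding

Segments = list[tuple[int, int, int]]  # (start, end, founder_hap_id), 0-based half-open


@dataclass
class Individual:
    """Two founder-segment mosaic haplotypes per chromosome.

    ``haps[chrom] = (maternal, paternal)`` segment lists; ``y_hap`` is the
    index (0/1) of the Y-carrying haplotype in males, None in females.
    """

    haps: dict[str, tuple[Segments, Segments]]
    y_hap: int | None = None


def _extract(segs: Segments, lo: int, hi: int) -> Segments:
    out = []
    for s, e, h in segs:
        if e <= lo or s >= hi:
            continue
        out.append((max(s, lo), min(e, hi), h))
    return out


def _splice(segs: Segments, lo: int, hi: int, donor: Segments) -> Segments:
    out = _extract(segs, 0, lo) + _extract(donor, lo, hi) + _extract(segs, hi, 10**18)
    return _merge(out)


def _merge(segs: Segments) -> Segments:
    out: Segments = []
    for s, e, h in segs:
        if out and out[-1][2] == h and out[-1][1] == s:
            out[-1] = (out[-1][0], e, h)
        else:
            out.append((s, e, h))
    return out


def meiosis(parent: Individual, spec: GenomeSpec, rng: np.random.Generator
            ) -> tuple[dict[str, Segments], dict[str, list[int]]]:
    """One gamete: per chromosome a mosaic of the parent's two haplotypes.

    Crossover counts are Poisson with mean length_Mb * rate / 100 (no
    interference), positions uniform; the starting haplotype is random.
    Returns the gamete and the crossover positions per chromosome.
    """
    gamete: dict[str, Segments] = {}
    xovers: dict[str, list[int]] = {}
    for ch in spec.chromosomes:
        lam = ch.length / 1e6 * ch.rate / 100.0
        n_xo = rng.poisson(lam)
        bps = sorted(int(x) for x in rng.integers(1, ch.length, size=n_xo))
        cur = int(rng.integers(2))
        segs: Segments = []
        prev = 0
        pair = parent.haps[ch.name]
        for bp in bps + [ch.length]:
            if bp > prev:
                segs.extend(_extract(pair[cur], prev, bp))
            prev = bp
            cur = 1 - cur
        gamete[ch.name] = _merge(segs)
        xovers[ch.name] = bps
    return gamete, xovers


def _make_child(mother: Individual, father: Individual, spec: GenomeSpec,
                rng: np.random.Generator, male: bool) -> Individual:
    egg, _ = meiosis(mother, spec, rng)
    sperm, _ = meiosis(father, spec, rng)
    y_hap = None
    if spec.sex_region is not None and father.y_hap is not None:
        # recombination is suppressed across the sex segment: sons always
        # receive the father's Y ancestry there, daughters the X ancestry
        sc, s, e = spec.sex_region
        src = father.haps[sc][father.y_hap if male else 1 - father.y_hap]
        sperm[sc] = _splice(sperm[sc], s, e, _extract(src, s, e))
        y_hap = 1 if male else None
    elif male:
        y_hap = 1
    haps = {c.name: (egg[c.name], sperm[c.name]) for c in spec.chromosomes}
    return Individual(haps, y_hap)


def _founder_pair(family: int, spec: GenomeSpec) -> tuple[Individual, Individual]:
    base = 4 * family

    def whole(hid: int) -> dict[str, Segments]:
        return {c.name: [(0, c.length, hid)] for c in spec.chromosomes}

    father = Individual({c: (whole(base)[c], whole(base + 1)[c])
                         for c in (ch.name for ch in spec.chromosomes)},
                        y_hap=1 if spec.sex_region is not None else None)
    mother = Individual({c: (whole(base + 2)[c], whole(base + 3)[c])
                         for c in (ch.name for ch in spec.chromosomes)})
    return father, mother


def autozygous_fraction(ind: Individual, spec: GenomeSpec,
                        exclude_chroms: set[str] | None = None) -> float:
    """Genome fraction where the two haplotypes descend from the same
    founder haplotype (interval-intersection arithmetic on the segments)."""
    total = 0
    auto = 0
    for ch in spec.chromosomes:
        if exclude_chroms and ch.name in exclude_chroms:
            continue
        total += ch.length
        a, b = ind.haps[ch.name]
        ia = ib = 0
        while ia < len(a) and ib < len(b):
            s = max(a[ia][0], b[ib][0])
            e = min(a[ia][1], b[ib][1])
            if e > s and a[ia][2] == b[ib][2]:
                auto += e - s
            if a[ia][1] <= b[ib][1]:
                ia += 1
            else:
                ib += 1
    if total == 0:
        raise ValueError("all chromosomes excluded")
    return auto / total


def inbreed_line(family: int, spec: GenomeSpec, cfg: SimConfig,
                 rng: np.random.Generator,
                 outcross: tuple[int, Individual] | None = None,
                 track_generations: bool = False,
                 ) -> tuple[Individual, list[float]]:
    """Breed one line: G generations of single full-sib-pair matings.

    Starts from an F1 brother-sister pair (children of the founder pair) and
    returns the sampled male of the final brood.  With ``outcross=(g, ind)``
    the generation-g father is replaced by the supplied unrelated individual
    before breeding that generation.  ``track_generations`` also returns the
    per-generation realized autozygous fraction of each brood (sex
    chromosome excluded when a sex region is configured).
    """
    f_father, f_mother = _founder_pair(family, spec)
    sister = _make_child(f_mother, f_father, spec, rng, male=False)
    brother = _make_child(f_mother, f_father, spec, rng, male=True)
    excl = {spec.sex_region[0]} if spec.sex_region is not None else None
    per_gen: list[float] = []
    for g in range(1, cfg.generations + 1):
        if outcross is not None and outcross[0] == g:
            brother = outcross[1]
        daughter = _make_child(sister, brother, spec, rng, male=False)
        son = _make_child(sister, brother, spec, rng, male=True)
        if track_generations:
            per_gen.append(autozygous_fraction(daughter, spec, excl))
        sister, brother = daughter, son
    return brother, per_gen


# ---------------------------------------------------------------------------
# panel assembly


@dataclass
class SimTruth:
    """Ground truth for a simulated panel.

    Per line the founder-segment ancestry of both haplotypes, the realized
    autozygous fraction, and the pedigree-expected inbreeding coefficients.
    """

    spec: GenomeSpec
    individuals: dict[str, Individual]
    expected_f: np.ndarray
    outcrossed: dict[str, int | None] = field(default_factory=dict)

    def autozygous_fraction(self, line_id: str,
                            exclude_chroms: set[str] | None = None) -> float:
        return autozygous_fraction(self.individuals[line_id], self.spec, exclude_chroms)

    def segments_frame(self) -> pd.DataFrame:
        rows = []
        for line, ind in self.individuals.items():
            for c, (m, p) in ind.haps.items():
                for which, segs in (("maternal", m), ("paternal", p)):
                    for s, e, h in segs:
                        rows.append((line, c, which, s, e, h))
        return pd.DataFrame(rows, columns=["line", "chrom", "haplotype",
                                           "start", "end", "founder_hap_id"])


@dataclass
class PanelSim:
    """A simulated panel: genotypes plus every truth table."""

    gm: GenotypeMatrix
    truth: SimTruth
    sites: SiteTable
    sibling_pairs: pd.DataFrame     # line_a, line_b, founder_family_id
    metadata: pd.DataFrame          # line, family, outcross_generation
    ancestral: pd.DataFrame         # chrom, pos, ancestral_base


def _genotype_individual(ind: Individual, founders: FounderSet) -> np.ndarray:
    sites = founders.sites
    parts = []
    for c in sites.chroms:
        n = sites.n_sites(c)
        geno = np.zeros(n, dtype=np.int8)
        for segs in ind.haps[c]:
            for s, e, h in segs:
                lo = np.searchsorted(sites.pos[c], s + 1)
                hi = np.searchsorted(sites.pos[c], e, side="right")
                geno[lo:hi] += founders.hap_alleles(h, c)[lo:hi]
        parts.append(geno)
    return np.concatenate(parts) if parts else np.zeros(0, dtype=np.int8)


def _apply_genotype_errors(geno: np.ndarray, rate: float,
                           rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return geno
    hit = rng.random(geno.shape) < rate
    out = geno.copy()
    # het errors become a random homozygote; homozygote errors become het
    het = hit & (geno == 1)
    out[het] = 2 * (rng.random(int(het.sum())) < 0.5).astype(np.int8)
    out[hit & (geno != 1)] = 1
    return out


def simulate_panel(spec: GenomeSpec | None = None,
                   cfg: SimConfig | None = None) -> PanelSim:
    """Simulate a full panel of inbred lines with truth tables.

    Families of ``lines_per_family`` lines share a founder pair (recorded as
    sibling pairs when there are exactly two); each line independently
    undergoes ``generations`` of full-sib inbreeding.  With probability
    ``outcross_prob`` a line's pedigree suffers one accidental mid-pedigree
    outcross: the male of a random middle generation is replaced by an
    individual from an unrelated contaminant lineage inbred to the same
    depth.  The sampled individuals are males, obligately heterozygous
    across the configured sex region.
    """
    spec = spec if spec is not None else default_genome()
    cfg = cfg if cfg is not None else SimConfig()
    sites, founders = simulate_founders(spec, cfg)
    ss = np.random.SeedSequence(cfg.seed + 2**31)
    rng_ped, rng_err = (np.random.default_rng(k) for k in ss.spawn(2))

    n_lines = cfg.n_founder_pairs * cfg.lines_per_family
    contaminant_family = cfg.n_founder_pairs  # extra founder pair for outcrosses

    line_ids, genos, meta_rows, sib_rows = [], [], [], []
    individuals: dict[str, Individual] = {}
    outcrossed: dict[str, int | None] = {}
    for fam in range(cfg.n_founder_pairs):
        fam_lines = []
        for k in range(cfg.lines_per_family):
            line = f"line_{fam + 1}_{k + 1}"
            outcross = None
            ogen: int | None = None
            if cfg.outcross_prob > 0 and rng_ped.random() < cfg.outcross_prob:
                lo = 2
                hi = max(cfg.generations - 1, lo)
                ogen = int(rng_ped.integers(lo, hi + 1))
                donor_cfg = replace(cfg, generations=max(ogen - 1, 1),
                                    outcross_prob=0.0)
                donor, _ = inbreed_line(contaminant_family, spec, donor_cfg, rng_ped)
                outcross = (ogen, donor)
            ind, _ = inbreed_line(fam, spec, cfg, rng_ped, outcross=outcross)
            individuals[line] = ind
            outcrossed[line] = ogen
            line_ids.append(line)
            fam_lines.append(line)
            meta_rows.append((line, fam, ogen))
            genos.append(_genotype_individual(ind, founders))
        if len(fam_lines) == 2:
            sib_rows.append((fam_lines[0], fam_lines[1], fam))

    geno = np.stack(genos) if genos else np.zeros((0, sites.total_sites), dtype=np.int8)
    geno = _apply_genotype_errors(geno, cfg.genotype_error_rate, rng_err)
    gm = GenotypeMatrix(line_ids, sites.variants_frame(), geno, spec.chrom_lengths)
    truth = SimTruth(spec, individuals,
                     wright_inbreeding_coefficients(cfg.generations), outcrossed)
    return PanelSim(
        gm=gm, truth=truth, sites=sites,
        sibling_pairs=pd.DataFrame(sib_rows,
                                   columns=["line_a", "line_b", "founder_family_id"]),
        metadata=pd.DataFrame(meta_rows,
                              columns=["line", "family", "outcross_generation"]),
        ancestral=sites.ancestral_table(),
    )


# ---------------------------------------------------------------------------
# admixture / introgression scenario


@dataclass
class AdmixedSim:
    """Four-population scenario for ABBA-BABA testing."""

    gm: GenotypeMatrix
    populations: dict[str, list[str]]
    ancestral: pd.DataFrame
    introgressed_blocks: pd.DataFrame   # sample, hap, chrom, start, end


def simulate_admixed_populations(spec: GenomeSpec, cfg: SimConfig, f: float,
                                 n_per_pop: int = 30, n_outgroup: int = 4,
                                 drift: float = 0.05, p3_drift: float = 0.15,
                                 block_len: int = 50_000) -> AdmixedSim:
    """Simulate (((P1, P2), P3), O) with a fraction ``f`` of P2 introgressed.

    Allele frequencies drift from the common ancestral frequencies along
    each branch under a Balding-Nichols (beta) model; P3 diverged earlier
    (larger drift), the outgroup retains near-ancestral frequencies.
    Introgression replaces each ``block_len`` tile of each P2 haplotype with
    P3 ancestry independently with probability ``f``; block boundaries are
    recorded.  Genotypes are Hardy-Weinberg draws from the population
    frequencies.
    """
    if not 0 <= f <= 1:
        raise ValueError("admixture fraction must lie in [0, 1]")
    spec_nosex = GenomeSpec(spec.chromosomes, None)
    ss = np.random.SeedSequence(cfg.seed + 2**30)
    rng_sites, rng_freqs, rng_geno = (np.random.default_rng(k) for k in ss.spawn(3))
    sites = sample_sites(spec_nosex, cfg, rng_sites)

    def drifted(p0: np.ndarray, c: float) -> np.ndarray:
        if c <= 0:
            return p0.copy()
        a = p0 * (1 - c) / c
        b = (1 - p0) * (1 - c) / c
        return rng_freqs.beta(np.maximum(a, 1e-6), np.maximum(b, 1e-6))

    samples: list[str] = []
    pops: dict[str, list[str]] = {}
    geno_cols: dict[str, list[np.ndarray]] = {}
    blocks_rows = []

    p_pop: dict[str, dict[str, np.ndarray]] = {"P1": {}, "P2": {}, "P3": {}, "O": {}}
    for c in sites.chroms:
        p0 = sites.p_derived[c]
        anc12 = drifted(drifted(p0, drift), drift)
        p_pop["P1"][c] = drifted(anc12, drift)
        p_pop["P2"][c] = drifted(anc12, drift)
        p_pop["P3"][c] = drifted(drifted(p0, drift), p3_drift)
        p_pop["O"][c] = drifted(p0, 0.01)

    for pop, n in (("P1", n_per_pop), ("P2", n_per_pop), ("P3", n_per_pop),
                   ("O", n_outgroup)):
        pops[pop] = []
        for i in range(n):
            name = f"{pop}_{i + 1}"
            pops[pop].append(name)
            samples.append(name)
            per_chrom = []
            for ch in spec_nosex.chromosomes:
                c = ch.name
                pd_c = p_pop[pop][c]
                hap_sum = np.zeros(len(pd_c), dtype=np.int8)
                for hap in range(2):
                    alleles = (rng_geno.random(len(pd_c)) < pd_c).astype(np.int8)
                    if pop == "P2" and f > 0:
                        for start in range(0, ch.length, block_len):
                            if rng_geno.random() < f:
                                end = min(start + block_len, ch.length)
                                lo = np.searchsorted(sites.pos[c], start + 1)
                                hi = np.searchsorted(sites.pos[c], end, side="right")
                                alleles[lo:hi] = (rng_geno.random(hi - lo)
                                                  < p_pop["P3"][c][lo:hi]).astype(np.int8)
                                blocks_rows.append((name, hap, c, start, end))
                    hap_sum += alleles
                per_chrom.append(hap_sum)
            geno_cols[name] = per_chrom

    # derived-allele dosages -> ALT dosages where the derived allele is REF
    geno = np.stack([np.concatenate(geno_cols[s]) for s in samples])
    flip = np.concatenate([~sites.derived_is_alt[c] for c in sites.chroms])
    geno[:, flip] = 2 - geno[:, flip]
    gm = GenotypeMatrix(samples, sites.variants_frame(), geno,
                        spec_nosex.chrom_lengths)
    return AdmixedSim(gm, pops, sites.ancestral_table(),
                      pd.DataFrame(blocks_rows,
                                   columns=["sample", "hap", "chrom", "start", "end"]))


# ---------------------------------------------------------------------------
# phenotypes


def simulate_line_phenotypes(line_ids: list[str], n_per_line: int = 8,
                             between_var: float = 2.0, within_var: float = 1.0,
                             seed: int = 0) -> pd.DataFrame:
    """Per-individual trait values with line-level (genetic) effects.

    Broad-sense heritability of the generating model is
    between_var / (between_var + within_var).
    """
    rng = np.random.default_rng(seed)
    effects = rng.normal(0.0, np.sqrt(between_var), size=len(line_ids))
    rows = []
    for line, eff in zip(line_ids, effects):
        vals = eff + rng.normal(0.0, np.sqrt(within_var), size=n_per_line)
        rows.extend((line, v) for v in vals)
    return pd.DataFrame(rows, columns=["line", "value"])
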