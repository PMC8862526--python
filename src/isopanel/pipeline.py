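"""Stage orchestration: run any pipeline stage from one declarative config.

Each stage is idempotent, reads its inputs from the paths in the config,
writes its outputs under ``outdir`` and records a manifest (inputs,
parameters, seed, package version, output checksums).  All randomness flows
from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, hmm, introgression, popgen, relatedness, simulate
from .io_variants import (GenotypeMatrix, grid_from_matrix, read_table, read_vcf,
                          window_het_counts, write_table, write_vcf)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters; defaults mirror the pipeline's standard values
    (10-kb HMM windows, het threshold 5, 50 SNPs per F_ST window, 500-kb
    pi / f_d windows with 250 SNPs, MAF 0.10, 10-kb LD pairs in 100-bp bins)."""

    outdir: str = "results/run"
    seed: int = 0
    # inputs (produced by the simulate stage unless supplied)
    vcf: str | None = None
    ancestral_table: str | None = None
    sibling_table: str | None = None
    group_table: str | None = None
    phenotype_table: str | None = None
    # stage parameters
    window_size: int = 10_000
    het_threshold: int = 5
    hmm_k: int = 2
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 500
    sex_chrom: str = "chr1"
    sex_hmm_k: int = 4
    sex_min_level: float = 0.8
    sex_min_span: int = 200_000
    fst_window: int = 10_000
    fst_min_snps: int = 50
    fst_groups: tuple[str, str] = ("A", "B")
    pi_window: int = 500_000
    min_maf: float = 0.10
    ld_max_dist: int = 10_000
    ld_bin: int = 100
    fd_window: int = 500_000
    fd_step: int | None = None
    fd_min_snps: int = 250
    identity_floor: float = 0.99
    # simulator
    n_founder_pairs: int = 40
    lines_per_family: int = 2
    generations: int = 9
    target_pi: float = 0.0037
    outcross_prob: float = 0.05
    genotype_error_rate: float = 1e-3
    n_chromosomes: int = 24
    chrom_length: int = 1_000_000
    recomb_rate: float = 3.0
    sex_region: tuple[str, int, int] | None = ("chr1", 450_000, 550_000)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "sex_region" in data and data["sex_region"] is not None:
            data["sex_region"] = tuple(data["sex_region"])
        if "fst_groups" in data:
            data["fst_groups"] = tuple(data["fst_groups"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        positive = ("window_size", "hmm_k", "fst_window", "pi_window",
                    "ld_max_dist", "ld_bin", "fd_window", "fd_min_snps",
                    "fst_min_snps", "generations")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")
        if self.het_threshold < 0:
            raise ValueError("het_threshold must be >= 0")

    def path(self, name: str, default: str) -> Path:
        configured = getattr(self, name, None)
        return Path(configured) if configured else Path(self.outdir) / default

    def genome_spec(self) -> simulate.GenomeSpec:
        chroms = tuple(simulate.Chromosome(f"chr{i + 1}", self.chrom_length,
                                           self.recomb_rate)
                       for i in range(self.n_chromosomes))
        return simulate.GenomeSpec(chroms, self.sex_region)

    def sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(
            n_founder_pairs=self.n_founder_pairs,
            lines_per_family=self.lines_per_family,
            generations=self.generations,
            target_pi=self.target_pi,
            outcross_prob=self.outcross_prob,
            genotype_error_rate=self.genotype_error_rate,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage: str, cfg: RunConfig, inputs: list[Path],
                    outputs: list[Path]) -> None:
    out = Path(cfg.outdir)
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {k: v for k, v in asdict(cfg).items()},
        "inputs": [str(p) for p in inputs],
        "outputs": {str(p): _sha256(p) for p in outputs},
    }
    with open(out / f"manifest_{stage.replace('-', '_')}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _load_gm(cfg: RunConfig) -> GenotypeMatrix:
    vcf = cfg.path("vcf", "panel.vcf")
    if not vcf.exists():
        raise FileNotFoundError(f"VCF not found: {vcf} (run the simulate stage "
                                "or point the config at an input VCF)")
    return read_vcf(vcf)


def _stage_simulate(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.outdir)
    sim = simulate.simulate_panel(cfg.genome_spec(), cfg.sim_config())
    paths = {
        "vcf": out / "panel.vcf",
        "truth": out / "truth_segments.tsv",
        "sibs": out / "sibling_pairs.tsv",
        "anc": out / "ancestral_alleles.tsv",
        "meta": out / "line_metadata.tsv",
        "pheno": out / "phenotypes.tsv",
        "autoz": out / "truth_autozygosity.tsv",
    }
    write_vcf(sim.gm, paths["vcf"])
    write_table(sim.truth.segments_frame(), paths["truth"])
    write_table(sim.sibling_pairs, paths["sibs"])
    write_table(sim.ancestral, paths["anc"])
    write_table(sim.metadata, paths["meta"])
    write_table(simulate.simulate_line_phenotypes(sim.gm.sample_ids, seed=cfg.seed),
                paths["pheno"])
    excl = ({cfg.sex_region[0]}
            if cfg.sex_region and cfg.n_chromosomes > 1 else None)
    autoz = pd.DataFrame({
        "line": sim.gm.sample_ids,
        "autozygous_fraction": [sim.truth.autozygous_fraction(l, excl)
                                for l in sim.gm.sample_ids]})
    write_table(autoz, paths["autoz"])
    return list(paths.values())


def _stage_hmm_call(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.outdir)
    gm = _load_gm(cfg)
    grid = grid_from_matrix(gm, cfg.window_size)
    wc = window_het_counts(gm, grid)
    params, _ = hmm.fit_poisson_hmm(wc, K=cfg.hmm_k, max_iter=cfg.hmm_max_iter,
                                    tol=cfg.hmm_tol, seed=cfg.seed)
    paths = hmm.viterbi_decode_all(params, wc)
    blocks = pd.concat([hmm.states_to_blocks(p).blocks for p in paths],
                       ignore_index=True)
    bed = out / "homozygosity_blocks.bed"
    hmm.BlockSet(blocks).to_bed(bed)
    frac = pd.DataFrame({
        "line": [p.line_id for p in paths],
        "homozygous_fraction": [
            hmm.homozygous_fraction(hmm.BlockSet(blocks), p.line_id,
                                    exclude_chroms={cfg.sex_chrom})
            for p in paths]})
    frac_path = out / "homozygous_fraction.tsv"
    write_table(frac, frac_path)
    report = out / "hmm_params.txt"
    report.write_text(params.to_report())
    return [bed, frac_path, report]


def _stage_sex_region(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.outdir)
    gm = _load_gm(cfg)
    grid = grid_from_matrix(gm, cfg.window_size)
    wc = window_het_counts(gm, grid)
    params, _ = hmm.fit_poisson_hmm(wc, K=cfg.sex_hmm_k, max_iter=cfg.hmm_max_iter,
                                    tol=cfg.hmm_tol, seed=cfg.seed)
    paths = hmm.viterbi_decode_all(params, wc)
    off = grid.window_offsets()[cfg.sex_chrom]
    nw = grid.n_windows(cfg.sex_chrom)
    count_track = hmm.het_proportion_by_count(wc, cfg.het_threshold)[off:off + nw]
    weighted = hmm.het_proportion_weighted(paths, params)[off:off + nw]
    track = hmm.HetProportionTrack(grid, cfg.sex_chrom, count_track, weighted)
    interval = hmm.refine_obligate_het_region(track, cfg.sex_min_level,
                                              cfg.sex_min_span)
    track_path = out / "sex_region_track.tsv"
    write_table(track.to_frame(), track_path)
    ivl_path = out / "sex_region_interval.tsv"
    df = (pd.DataFrame([interval], columns=["chrom", "start", "end"])
          if interval else pd.DataFrame(columns=["chrom", "start", "end"]))
    write_table(df, ivl_path)
    return [track_path, ivl_path]


def _two_group_freqs(gm: GenotypeMatrix, cfg: RunConfig):
    groups = read_table(cfg.path("group_table", "groups.tsv"))
    g1, g2 = cfg.fst_groups
    s1 = groups.loc[groups["population"] == g1, "sample"].tolist()
    s2 = groups.loc[groups["population"] == g2, "sample"].tolist()
    if not s1 or not s2:
        raise ValueError(f"groups {g1!r}/{g2!r} not found in the group table")
    i1 = np.array([gm.sample_index(s) for s in s1])
    i2 = np.array([gm.sample_index(s) for s in s2])
    return gm.alt_freqs(i1), gm.alt_freqs(i2)


def _stage_fst(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.outdir)
    gm = _load_gm(cfg)
    (p1, n1), (p2, n2) = _two_group_freqs(gm, cfg)
    keep = (n1 >= 2) & (n2 >= 2)
    grid = grid_from_matrix(gm, cfg.fst_window)
    stat = popgen.windowed_fst(gm.variants.loc[keep].reset_index(drop=True),
                               p1[keep], n1[keep], p2[keep], n2[keep],
                               grid, cfg.fst_min_snps)
    path = out / "fst_windows.tsv"
    write_table(stat, path)
    return [path]


def _stage_pi(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.outdir)
    gm = _load_gm(cfg)
    grid = grid_from_matrix(gm, cfg.pi_window)
    stat = popgen.nucleotide_diversity(gm, grid)
    path = out / "pi_windows.tsv"
    write_table(stat, path)
    return [path]


def _stage_ld(cfg: RunConfig) -> list[Path]:
    from .io_variants import filter_variants
    out = Path(cfg.outdir)
    gm = _load_gm(cfg)
    gm = filter_variants(gm, min_maf=cfg.min_maf)
    pairs = popgen.ld_pairs_r2(gm, max_dist=cfg.ld_max_dist)
    profile = popgen.ld_decay_profile(pairs, cfg.ld_bin, cfg.ld_max_dist)
    path = out / "ld_decay.tsv"
    write_table(profile, path)
    return [path]


def _stage_introgression(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.outdir)
    gm = _load_gm(cfg)
    groups = read_table(cfg.path("group_table", "groups.tsv"))
    pops = {p: groups.loc[groups["population"] == p, "sample"].tolist()
            for p in ("P1", "P2", "P3", "O")}
    anc = read_table(cfg.path("ancestral_table", "ancestral_alleles.tsv"))
    freqs = introgression.polarize(gm, pops, anc)
    scan = introgression.sliding_fd_scan(freqs, gm.chrom_lengths, cfg.fd_window,
                                         cfg.fd_step, cfg.fd_min_snps)
    path = out / "fd_windows.tsv"
    write_table(scan, path)
    return [path]


def _stage_relatedness(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.outdir)
    gm = _load_gm(cfg)
    ibs = relatedness.ibs_matrix(gm)
    order, Z = relatedness.cluster_and_order(ibs)
    ibs_path = out / "ibs_matrix.tsv"
    ibs.to_csv(ibs_path, sep="\t")
    nwk = out / "ibs_dendrogram.nwk"
    nwk.write_text(relatedness.dendrogram_newick(Z, sorted(ibs.index)) + "\n")
    outputs = [ibs_path, nwk]
    sib_path = cfg.path("sibling_table", "sibling_pairs.tsv")
    if sib_path.exists():
        pairs = read_table(sib_path)
        grid = grid_from_matrix(gm, cfg.window_size)
        rows = []
        for _, row in pairs.iterrows():
            share = relatedness.pairwise_sharing_fraction(
                gm, row["line_a"], row["line_b"], grid, cfg.identity_floor)
            rows.append((row["line_a"], row["line_b"], share))
        rep = pd.DataFrame(rows, columns=["line_a", "line_b", "sharing_fraction"])
        rep_path = out / "sibling_sharing.tsv"
        write_table(rep, rep_path)
        adj = relatedness.sibling_adjacency_fraction(order, pairs)
        adj_path = out / "sibling_adjacency.tsv"
        write_table(pd.DataFrame({"n_pairs": [len(pairs)],
                                  "adjacent_fraction": [adj]}), adj_path)
        outputs += [rep_path, adj_path]
    return outputs


def _stage_heritability(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.outdir)
    pheno = read_table(cfg.path("phenotype_table", "phenotypes.tsv"))
    traits = [c for c in pheno.columns if c != "line"]
    rows = [(t, popgen.eta_squared_heritability(pheno[t].to_numpy(),
                                                pheno["line"].to_numpy()))
            for t in traits]
    path = out / "heritability.tsv"
    write_table(pd.DataFrame(rows, columns=["trait", "eta_squared"]), path)
    return [path]


def _stage_report(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.outdir)
    summary: dict[str, object] = {}
    frac = out / "homozygous_fraction.tsv"
    if frac.exists():
        df = read_table(frac)
        summary["mean_homozygous_fraction"] = float(df["homozygous_fraction"].mean())
        summary["pct_lines_above_0.70"] = float(
            100 * (df["homozygous_fraction"] > 0.70).mean())
    ivl = out / "sex_region_interval.tsv"
    if ivl.exists():
        df = read_table(ivl)
        summary["sex_region_interval"] = (df.iloc[0].to_dict() if len(df) else None)
    pi = out / "pi_windows.tsv"
    if pi.exists():
        summary["mean_pi"] = float(read_table(pi)["value"].mean())
    shr = out / "sibling_sharing.tsv"
    if shr.exists():
        summary["mean_sibling_sharing"] = float(
            read_table(shr)["sharing_fraction"].mean())
    fd = out / "fd_windows.tsv"
    if fd.exists():
        summary["mean_fd"] = float(read_table(fd)["fd"].mean())
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return [path]


STAGES = {
    "simulate": _stage_simulate,
    "hmm-call": _stage_hmm_call,
    "sex-region": _stage_sex_region,
    "fst": _stage_fst,
    "pi": _stage_pi,
    "ld": _stage_ld,
    "introgression": _stage_introgression,
    "relatedness": _stage_relatedness,
    "heritability": _stage_heritability,
    "report": _stage_report,
}


def run(stage: str, cfg: RunConfig) -> list[Path]:
    """Run one stage; returns the output paths and writes a manifest."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; available stages: "
                         + ", ".join(STAGES))
    cfg.validate()
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    logger.info("running stage %s (seed=%d)", stage, cfg.seed)
    inputs = [p for p in (cfg.vcf, cfg.ancestral_table, cfg.sibling_table,
                          cfg.group_table, cfg.phenotype_table) if p]
    outputs = STAGES[stage](cfg)
    _write_manifest(stage, cfg, [Path(p) for p in inputs], outputs)
    return outputs
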